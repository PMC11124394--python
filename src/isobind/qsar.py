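"""Censoring-aware logIC50 transformation and linear correlation models.

The response is logIC50 (log base 10 of the µM potency by default). A
">100 µM" entry carries only the information that the true IC50 exceeds
the bound; the default policy excludes such compounds from a fit (recorded
per cell line), the alternative ``at_bound`` imputes log10(bound). Fits are
ordinary least squares; R² in the univariate case equals the squared
Pearson correlation, and is invariant to affine changes of either axis —
so the log base and the concentration unit cannot change any R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (
    DegenerateFitError,
    InsufficientDataError,
    LabelError,
    ValidationError,
)
from .tables_io import CENSORED, OBSERVED, CensoredPotencyTable, WeightedEnergyTable

__all__ = [
    "RegressionResult",
    "log_transform",
    "fit_linear",
    "fit_bivariate",
    "r2_panel",
    "descriptors_from_smiles",
    "CENSOR_POLICIES",
    "DESCRIPTOR_NAMES",
]

CENSOR_POLICIES = ("exclude", "at_bound")
#: descriptor rows of the correlation panel, alongside the weighted energy
DESCRIPTOR_NAMES = ("MLogP", "TPSA", "HBD", "POL")

#: minimum observations for a reported fit
MIN_N = 3


@dataclass
class RegressionResult:
    """OLS fit summary: coefficients, R², bookkeeping of excluded compounds."""

    slopes: dict[str, float]
    intercept: float
    r_squared: float
    n_used: int
    excluded: list[tuple[str, str]] = field(default_factory=list)
    residuals: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.r_squared <= 1 + 1e-12):
            raise ValidationError(f"r_squared {self.r_squared} outside [0, 1]")
        self.r_squared = float(min(max(self.r_squared, 0.0), 1.0))
        if self.n_used != len(self.residuals):
            raise ValidationError("n_used must equal the number of residuals")
        if self.n_used < MIN_N:
            raise ValidationError(f"a reported fit needs n ≥ {MIN_N}")


def log_transform(
    potencies: CensoredPotencyTable,
    cell_line: str,
    policy: str = "exclude",
    base: float = 10.0,
) -> tuple[dict[str, float], list[tuple[str, str]]]:
    """logIC50 for one cell line, honoring the censoring policy.

    Returns ``(values, excluded)`` where ``values`` maps compound →
    log_base(IC50 in µM) and ``excluded`` lists (compound, reason) pairs
    dropped under the ``exclude`` policy. ``at_bound`` keeps censored
    entries at log(bound), biasing the response floor-ward — the report
    always says which policy produced it.
    """
    if policy not in CENSOR_POLICIES:
        raise ValidationError(f"unknown censor policy {policy!r}; use {CENSOR_POLICIES}")
    if not base > 1:
        raise ValidationError("log base must exceed 1")
    column = potencies.column(cell_line)  # raises LabelError if absent
    values: dict[str, float] = {}
    excluded: list[tuple[str, str]] = []
    for cid, (value, status) in column.items():
        if status == CENSORED and policy == "exclude":
            excluded.append((cid, f"right-censored at {value:g} µM"))
            continue
        values[cid] = math.log(value, base)
    return values, excluded


def _design(x: np.ndarray) -> np.ndarray:
    return sm.add_constant(x, has_constant="add")


def fit_linear(
    x: np.ndarray, y: np.ndarray, predictor_name: str = "x"
) -> RegressionResult:
    """Univariate OLS of y on x with R² = 1 − SS_res/SS_tot."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length vectors")
    if x.size < MIN_N:
        raise InsufficientDataError(f"need at least {MIN_N} points, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor")
    model = sm.OLS(y, _design(x)).fit()
    return RegressionResult(
        slopes={predictor_name: float(model.params[1])},
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n_used=int(x.size),
        residuals=np.asarray(model.resid),
    )


def fit_bivariate(
    bw: np.ndarray,
    descriptor: np.ndarray,
    y: np.ndarray,
    names: tuple[str, str] = ("BE_w", "TPSA"),
) -> RegressionResult:
    """Two-predictor OLS (weighted energy + one descriptor, typically TPSA).

    Because the univariate BE_w model is nested in this one, its R² can
    never decrease when the descriptor is added.
    """
    bw = np.asarray(bw, dtype=float)
    descriptor = np.asarray(descriptor, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (bw.shape == descriptor.shape == y.shape) or bw.ndim != 1:
        raise ValidationError("predictors and response must be equal-length vectors")
    if bw.size < 4:
        raise InsufficientDataError("bivariate fit needs at least 4 points")
    X = np.column_stack([bw, descriptor])
    if np.linalg.matrix_rank(_design(X)) < 3:
        raise DegenerateFitError("collinear predictors")
    model = sm.OLS(y, _design(X)).fit()
    return RegressionResult(
        slopes={names[0]: float(model.params[1]), names[1]: float(model.params[2])},
        intercept=float(model.params[0]),
        r_squared=float(model.rsquared),
        n_used=int(y.size),
        residuals=np.asarray(model.resid),
    )


def r2_panel(
    bw: WeightedEnergyTable,
    potencies: CensoredPotencyTable,
    descriptors: pd.DataFrame | None = None,
    policy: str = "exclude",
    base: float = 10.0,
) -> tuple[pd.DataFrame, dict[str, object]]:
    """Per-cell-line R² of logIC50 against BE_w and each descriptor.

    ``descriptors`` (optional) is a compound-indexed frame with columns from
    ``DESCRIPTOR_NAMES``; descriptor predictors are cell-line-independent
    while the response stays cell-line-specific. Returns ``(panel, report)``
    where the panel holds R² values (NaN where a fit was impossible) and the
    report records n_used, exclusions and coefficients per cell.
    """
    rows = ["BE_w"] + ([c for c in descriptors.columns] if descriptors is not None else [])
    panel = pd.DataFrame(
        np.nan, index=rows, columns=bw.cell_line_ids, dtype=float
    )
    details: dict[str, object] = {}
    for line in bw.cell_line_ids:
        logs, excluded = log_transform(potencies, line, policy=policy, base=base)
        cell: dict[str, object] = {
            "policy": policy,
            "log_base": base,
            "excluded": [list(e) for e in excluded],
            "fits": {},
        }
        for predictor in rows:
            if predictor == "BE_w":
                pred_map = dict(zip(bw.compound_ids, bw.column(line)))
            else:
                pred_map = descriptors[predictor].dropna().to_dict()
            shared = [c for c in bw.compound_ids if c in logs and c in pred_map]
            if len(shared) < MIN_N:
                cell["fits"][predictor] = {
                    "missing": True,
                    "reason": f"only {len(shared)} usable compounds (< {MIN_N})",
                }
                continue
            x = np.array([pred_map[c] for c in shared])
            y = np.array([logs[c] for c in shared])
            try:
                fit = fit_linear(x, y, predictor_name=predictor)
            except DegenerateFitError as exc:
                cell["fits"][predictor] = {"missing": True, "reason": str(exc)}
                continue
            panel.at[predictor, line] = fit.r_squared
            cell["fits"][predictor] = {
                "missing": False,
                "r_squared": fit.r_squared,
                "slope": fit.slopes[predictor],
                "intercept": fit.intercept,
                "n_used": fit.n_used,
                "compounds": shared,
            }
        details[line] = cell
    return panel, details


def descriptors_from_smiles(records: dict[str, str]) -> pd.DataFrame:
    """Compute TPSA/MLogP/HBD/POL from SMILES with RDKit (optional extra).

    ``records`` maps compound_id → SMILES. POL is the Crippen molar
    refractivity (proportional to polarizability, Å³ scale). The returned
    frame's ``attrs`` records the engine name and version for provenance.
    """
    try:
        from rdkit import Chem
        from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
        import rdkit
    except ImportError as exc:  # pragma: no cover - rdkit is an extra
        raise ImportError("descriptor computation needs the 'chem' extra (rdkit)") from exc

    rows = {}
    for cid, smiles in records.items():
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValidationError(f"unparseable SMILES for compound {cid!r}")
        rows[cid] = {
            "TPSA": rdMolDescriptors.CalcTPSA(mol),
            "MLogP": Descriptors.MolLogP(mol),
            "HBD": float(rdMolDescriptors.CalcNumHBD(mol)),
            "POL": Crippen.MolMR(mol),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.attrs["descriptor_engine"] = f"rdkit {rdkit.__version__}"
    return df
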