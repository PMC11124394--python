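"""Expression-weighted binding energies and their inverse/consistency diagnostics.

The forward computation is the pipeline's core: for a compound c with
per-isotype docking energies E(c, i) and a cell line whose isotype
abundance fractions are w (a simplex vector),

    BE_w(c) = Σ_i w_i · E(c, i)          [kcal/mol]

i.e. a convex combination of the row, so BE_w always lies between the row
minimum and maximum over the isotypes that carry weight. Two diagnostics
exploit this:

* ``hull_check`` — the necessary condition row_min ≤ BE_w ≤ row_max,
  applied per compound to a published (matrix, weighted-column) pair;
* ``recover_weights`` — the inverse problem: the simplex-constrained
  least-squares weights that best reproduce a weighted column, with the
  residual measuring how consistent the pair is with *any* single
  abundance profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import LabelError, ValidationError
from .tables_io import (
    ExpressionPanel,
    ExpressionProfile,
    IsotypeBindingMatrix,
    WeightedEnergyTable,
)

__all__ = [
    "RecoveryResult",
    "weighted_energy",
    "weighted_energy_panel",
    "recover_weights",
    "hull_check",
    "diagnose_pair",
    "DEFAULT_FEASIBILITY_TOL",
]

#: 4× the 0.005 rounding half-width of tables printed to 2 decimals;
#: separates rounding noise from genuine matrix/weighted-table inconsistency.
DEFAULT_FEASIBILITY_TOL = 0.02


def _profile_weights(
    matrix: IsotypeBindingMatrix, profile: ExpressionProfile
) -> np.ndarray:
    extra = [i for i in profile.fractions if i not in matrix.isotype_ids]
    if extra:
        raise LabelError(
            f"profile {profile.cell_line_id!r} references isotypes absent from "
            f"the binding matrix: {extra}; restrict the profile first if intended"
        )
    return profile.vector(matrix.isotype_ids)


def weighted_energy(
    matrix: IsotypeBindingMatrix, profile: ExpressionProfile
) -> np.ndarray:
    """Per-compound expression-weighted binding energy E·w (kcal/mol).

    The profile's isotypes must be a subset of the matrix columns (use
    :func:`isobind.expression.restrict_to_matrix` to drop extras first).
    """
    w = _profile_weights(matrix, profile)
    return matrix.energies @ w


def weighted_energy_panel(
    matrix: IsotypeBindingMatrix, panel: ExpressionPanel
) -> WeightedEnergyTable:
    """Column-wise :func:`weighted_energy` over a panel of cell lines."""
    cols = [weighted_energy(matrix, p) for p in panel]
    return WeightedEnergyTable(
        compound_ids=list(matrix.compound_ids),
        cell_line_ids=panel.cell_line_ids,
        values=np.column_stack(cols) if cols else np.empty((len(matrix.compound_ids), 0)),
    )


@dataclass
class RecoveryResult:
    """Simplex-constrained least-squares solution of E·w ≈ bw.

    ``feasible`` means every compound's fitted BE_w is within ``tolerance``
    of the given column — i.e. some single abundance profile explains the
    pair to within (at least) rounding error. ``non_unique`` flags a
    rank-deficient energy matrix, where the fitted values are still unique
    (the problem is convex) but the weights are not; the reported weights
    are then the minimum-norm minimizer.
    """

    weights: dict[str, float]
    fitted: np.ndarray
    residual_rms: float
    residual_max: float
    feasible: bool
    tolerance: float
    non_unique: bool = False

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()))
        if np.any(w < -1e-8) or abs(w.sum() - 1.0) > 1e-8:
            raise ValidationError("recovered weights leave the simplex")
        if not (self.residual_max + 1e-12 >= self.residual_rms >= 0):
            raise ValidationError("residual_max must be ≥ residual_rms ≥ 0")


def _simplex_lsq(E: np.ndarray, b: np.ndarray) -> np.ndarray:
    """argmin ‖E·w − b‖² s.t. w ≥ 0, Σw = 1, from the uniform start."""
    k = E.shape[1]
    x0 = np.full(k, 1.0 / k)

    def loss(w):
        r = E @ w - b
        return 0.5 * r @ r

    def grad(w):
        return E.T @ (E @ w - b)

    res = optimize.minimize(
        loss,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def _min_norm_refine(E: np.ndarray, fitted: np.ndarray, w_start: np.ndarray) -> np.ndarray:
    """Among simplex weights reproducing ``fitted``, pick the min-norm one."""
    k = E.shape[1]

    res = optimize.minimize(
        lambda w: 0.5 * w @ w,
        w_start,
        jac=lambda w: w,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[
            {"type": "eq", "fun": lambda w: w.sum() - 1.0,
             "jac": lambda w: np.ones_like(w)},
            {"type": "eq", "fun": lambda w: E @ w - fitted, "jac": lambda w: E},
        ],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    if not res.success:
        return w_start
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def recover_weights(
    matrix: IsotypeBindingMatrix,
    bw_column: np.ndarray,
    tolerance: float = DEFAULT_FEASIBILITY_TOL,
) -> RecoveryResult:
    """Recover the abundance weights that best explain a BE_w column.

    Solves min ‖E·w − bw‖² over the probability simplex (deterministic
    SLSQP from the uniform vector). ``feasible`` is True when the worst
    per-compound residual is ≤ ``tolerance`` (kcal/mol).
    """
    b = np.asarray(bw_column, dtype=float)
    if b.shape != (len(matrix.compound_ids),):
        raise ValidationError(
            f"bw column has length {b.shape}, expected {len(matrix.compound_ids)}"
        )
    if b.size < 1:
        raise ValidationError("need at least one compound")
    E = matrix.energies
    w = _simplex_lsq(E, b)
    non_unique = np.linalg.matrix_rank(E) < E.shape[1]
    if non_unique:
        fitted0 = E @ w
        w = _min_norm_refine(E, fitted0, w)
    fitted = E @ w
    resid = fitted - b
    rms = float(np.sqrt(np.mean(resid**2)))
    rmax = float(np.max(np.abs(resid)))
    return RecoveryResult(
        weights={iso: float(v) for iso, v in zip(matrix.isotype_ids, w)},
        fitted=fitted,
        residual_rms=rms,
        residual_max=max(rmax, rms),
        feasible=rmax <= tolerance,
        tolerance=tolerance,
        non_unique=bool(non_unique),
    )


def hull_check(
    matrix: IsotypeBindingMatrix, bw_column: np.ndarray
) -> list[dict[str, object]]:
    """Necessary-condition screen: each BE_w must lie in its row's [min, max].

    Returns one report per compound with ``within_bounds``, the row extrema
    and ``excess`` — the distance (kcal/mol) from the value to the interval,
    0 when inside. Any convex combination of a row lies inside; an excess
    beyond rounding error means no abundance profile can produce the value.
    """
    b = np.asarray(bw_column, dtype=float)
    if b.shape != (len(matrix.compound_ids),):
        raise ValidationError(
            f"bw column has length {b.shape}, expected {len(matrix.compound_ids)}"
        )
    reports = []
    for cid, row, value in zip(matrix.compound_ids, matrix.energies, b):
        lo, hi = float(row.min()), float(row.max())
        excess = max(lo - value, value - hi, 0.0)
        reports.append(
            {
                "compound_id": cid,
                "value": float(value),
                "row_min": lo,
                "row_max": hi,
                "within_bounds": bool(lo <= value <= hi),
                "excess": float(excess),
            }
        )
    return reports


def diagnose_pair(
    matrix: IsotypeBindingMatrix,
    weighted: WeightedEnergyTable,
    tolerance: float = DEFAULT_FEASIBILITY_TOL,
) -> dict[str, object]:
    """Full consistency diagnosis of a (binding matrix, weighted table) pair.

    Per cell line: the hull screen and the inverse weight recovery. Pairs
    with out-of-hull entries or infeasible recoveries are surfaced in a
    ``warnings`` list (and as a Python warning) — published table pairs can
    fail this screen, which is a data-provenance finding, not a crash.
    """
    if weighted.compound_ids != matrix.compound_ids:
        raise LabelError(
            "weighted table and matrix must list the same compounds in order; "
            f"got {weighted.compound_ids} vs {matrix.compound_ids}"
        )
    per_line: dict[str, object] = {}
    warn_msgs: list[str] = []
    for line in weighted.cell_line_ids:
        col = weighted.column(line)
        hull = hull_check(matrix, col)
        rec = recover_weights(matrix, col, tolerance=tolerance)
        outside = [r["compound_id"] for r in hull if not r["within_bounds"]]
        if outside:
            warn_msgs.append(
                f"cell line {line}: BE_w outside the row [min, max] for "
                f"compounds {outside} — no isotype abundance profile can "
                "reproduce these values from this matrix"
            )
        if not rec.feasible:
            warn_msgs.append(
                f"cell line {line}: best simplex weights leave residual_max "
                f"{rec.residual_max:.3f} kcal/mol > tolerance {tolerance:g}"
            )
        per_line[line] = {
            "hull": hull,
            "n_out_of_hull": len(outside),
            "recovered_weights": rec.weights,
            "residual_rms": rec.residual_rms,
            "residual_max": rec.residual_max,
            "feasible": rec.feasible,
            "non_unique": rec.non_unique,
        }
    for msg in warn_msgs:
        warnings.warn(msg, stacklevel=2)
    return {
        "tolerance": tolerance,
        "cell_lines": per_line,
        "consistent": not warn_msgs,
        "warnings": warn_msgs,
    }
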