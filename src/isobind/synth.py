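"""Seeded generators for ground-truth binding/expression/potency datasets.

The generators emulate the statistical shape of the real inputs so every
pipeline stage can be tested end to end with a known answer:

* energy matrices with additive compound and isotype effects around a mean
  of −8.5 kcal/mol (matching the observed docking range of roughly −7 to
  −10 kcal/mol);
* simplex abundance profiles drawn from a symmetric Dirichlet;
* potencies with logIC50 exactly linear in the weighted energy BE_w plus
  Gaussian noise, right-censored at 100 µM — the data-generating model the
  correlation analysis assumes.

One root seed expands into fixed per-stage child seeds (root*1000 + offset,
offsets 1/2/3 for matrix/profiles/potency), so each stage is independently
reproducible and regenerating with the same root seed is bitwise stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .tables_io import (
    CENSORED,
    OBSERVED,
    CensoredPotencyTable,
    ExpressionPanel,
    ExpressionProfile,
    IsotypeBindingMatrix,
    WeightedEnergyTable,
)
from .weighting import weighted_energy_panel

__all__ = [
    "SyntheticTruth",
    "gen_binding_matrix",
    "gen_profiles",
    "gen_potency",
    "make_truth",
    "DEFAULT_ISOTYPES",
    "DEFAULT_CELL_LINES",
]

DEFAULT_ISOTYPES = [
    "αβI", "αβIIa", "αβIIb", "αβIII", "αβIVa", "αβIVb", "αβV", "αβVI", "αβVIII",
]
DEFAULT_CELL_LINES = ["L1", "L2", "L3", "L4", "L5", "L6", "L7"]

_MATRIX_OFFSET, _PROFILE_OFFSET, _POTENCY_OFFSET = 1, 2, 3


def _child_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1000 + offset) % (2**31 - 1)


def gen_binding_matrix(
    n_compounds: int = 9,
    isotype_ids: list[str] | None = None,
    compound_effect_sd: float = 0.5,
    isotype_effect_sd: float = 0.15,
    residual_sd: float = 0.1,
    mean_energy: float = -8.5,
    seed: int = 0,
) -> IsotypeBindingMatrix:
    """Energy matrix E(c,i) = mean + a_c + b_i + ε_ci, all Gaussian.

    Compound effects dominate isotype effects, as in real docking panels
    where a ligand's affinity varies more across ligands than across
    isotypes of the same target.
    """
    if n_compounds < 1:
        raise ValidationError("need at least one compound")
    isotype_ids = list(isotype_ids) if isotype_ids is not None else list(DEFAULT_ISOTYPES)
    if not isotype_ids:
        raise ValidationError("empty isotype set")
    for name, sd in (
        ("compound_effect_sd", compound_effect_sd),
        ("isotype_effect_sd", isotype_effect_sd),
        ("residual_sd", residual_sd),
    ):
        if sd < 0:
            raise ValidationError(f"{name} must be ≥ 0")
    rng = np.random.default_rng(_child_seed(seed, _MATRIX_OFFSET))
    a = rng.normal(0.0, compound_effect_sd, size=n_compounds)
    b = rng.normal(0.0, isotype_effect_sd, size=len(isotype_ids))
    eps = rng.normal(0.0, residual_sd, size=(n_compounds, len(isotype_ids)))
    energies = mean_energy + a[:, None] + b[None, :] + eps
    return IsotypeBindingMatrix(
        compound_ids=[f"C{i + 1}" for i in range(n_compounds)],
        isotype_ids=isotype_ids,
        energies=energies,
    )


def gen_profiles(
    n_lines: int = 7,
    isotype_ids: list[str] | None = None,
    dirichlet_concentration: float = 1.0,
    seed: int = 0,
    cell_line_ids: list[str] | None = None,
) -> ExpressionPanel:
    """Abundance panel with each profile drawn from a symmetric Dirichlet.

    Concentration 1 (flat) gives realistically uneven profiles; large
    concentrations shrink every profile toward the uniform 1/k vector.
    """
    if n_lines < 1:
        raise ValidationError("need at least one cell line")
    if not dirichlet_concentration > 0:
        raise ValidationError("dirichlet_concentration must be > 0")
    isotype_ids = list(isotype_ids) if isotype_ids is not None else list(DEFAULT_ISOTYPES)
    if not isotype_ids:
        raise ValidationError("empty isotype set")
    if cell_line_ids is None:
        cell_line_ids = [f"L{i + 1}" for i in range(n_lines)]
    if len(cell_line_ids) != n_lines:
        raise ValidationError("cell_line_ids length must equal n_lines")
    rng = np.random.default_rng(_child_seed(seed, _PROFILE_OFFSET))
    alpha = np.full(len(isotype_ids), dirichlet_concentration)
    draws = rng.dirichlet(alpha, size=n_lines)
    draws = draws / draws.sum(axis=1, keepdims=True)
    profiles = [
        ExpressionProfile(
            cell_line_id=line,
            fractions={iso: float(f) for iso, f in zip(isotype_ids, row)},
        )
        for line, row in zip(cell_line_ids, draws)
    ]
    return ExpressionPanel(profiles=profiles)


@dataclass
class SyntheticTruth:
    """Complete ground truth: inputs plus the potency-generating parameters.

    logIC50(c, line) = intercept + slope · BE_w(c, line) + N(0, noise_sd²),
    IC50 = 10^logIC50 µM, right-censored at ``censor_bound``.
    """

    matrix: IsotypeBindingMatrix
    panel: ExpressionPanel
    slope: float
    intercept: float
    noise_sd: float
    censor_bound: float
    seed: int

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be ≥ 0")
        if not self.censor_bound > 0:
            raise ValidationError("censor_bound must be > 0")

    @property
    def weighted(self) -> WeightedEnergyTable:
        return weighted_energy_panel(self.matrix, self.panel)


def make_truth(
    n_compounds: int = 9,
    n_lines: int = 7,
    isotype_ids: list[str] | None = None,
    slope: float = 1.2,
    intercept: float = 11.8,
    noise_sd: float = 0.1,
    censor_bound: float = 100.0,
    dirichlet_concentration: float = 1.0,
    compound_effect_sd: float = 0.5,
    isotype_effect_sd: float = 0.15,
    residual_sd: float = 0.1,
    mean_energy: float = -8.5,
    seed: int = 0,
) -> SyntheticTruth:
    """Generate a coherent dataset under the linear logIC50 model.

    Defaults mirror the real study's scale: 9 compounds × 9 isotypes × 7
    cell lines, energies ≈ −8.5 ± 0.5 kcal/mol, and a slope/intercept
    placing IC50 in the tens-of-µM range with censoring at 100 µM
    (intercept 11.8 + slope 1.2 × (−8.5) ≈ logIC50 1.6, i.e. ~40 µM).
    """
    matrix = gen_binding_matrix(
        n_compounds=n_compounds,
        isotype_ids=isotype_ids,
        compound_effect_sd=compound_effect_sd,
        isotype_effect_sd=isotype_effect_sd,
        residual_sd=residual_sd,
        mean_energy=mean_energy,
        seed=seed,
    )
    panel = gen_profiles(
        n_lines=n_lines,
        isotype_ids=list(matrix.isotype_ids),
        dirichlet_concentration=dirichlet_concentration,
        seed=seed,
    )
    return SyntheticTruth(
        matrix=matrix,
        panel=panel,
        slope=slope,
        intercept=intercept,
        noise_sd=noise_sd,
        censor_bound=censor_bound,
        seed=int(seed),
    )


def gen_potency(truth: SyntheticTruth) -> CensoredPotencyTable:
    """Potency table from the truth's linear-with-noise logIC50 model."""
    bw = truth.weighted
    rng = np.random.default_rng(_child_seed(truth.seed, _POTENCY_OFFSET))
    noise = rng.normal(0.0, truth.noise_sd, size=bw.values.shape)
    log_ic50 = truth.intercept + truth.slope * bw.values + noise
    ic50 = np.power(10.0, log_ic50)
    entries: dict[tuple[str, str], tuple[float, str]] = {}
    for i, cid in enumerate(bw.compound_ids):
        for j, line in enumerate(bw.cell_line_ids):
            v = float(ic50[i, j])
            if v > truth.censor_bound:
                entries[(cid, line)] = (float(truth.censor_bound), CENSORED)
            else:
                entries[(cid, line)] = (v, OBSERVED)
    return CensoredPotencyTable(entries=entries)
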