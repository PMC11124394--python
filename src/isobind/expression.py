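"""Build tubulin-isotype abundance profiles on the probability simplex.

Profiles can come from raw gene-expression values (CellMiner-style),
from tissue averages when a cell line itself is not profiled, or from a
uniform assumption over the commonly expressed isotypes when no usable
expression data exist at all. Gene symbols are mapped to isotype labels
through an editable key=value config (TUBB→βI, TUBB2A→βIIa, ...).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables_io import (
    ExpressionPanel,
    ExpressionProfile,
    IsotypeBindingMatrix,
    _read_delimited,
    fixture_path,
)

__all__ = [
    "normalize_expression",
    "average_profiles",
    "uniform_profile",
    "load_gene_map",
    "read_expression_panel",
    "restrict_to_matrix",
]

logger = logging.getLogger(__name__)


def normalize_expression(raw: dict[str, float], cell_line_id: str = "") -> ExpressionProfile:
    """Convert raw nonnegative expression values to abundance fractions.

    fractions = raw / sum(raw); scale-invariant, so counts, TPM or percent
    inputs all give the same profile.
    """
    if not raw:
        raise ValidationError("empty expression map")
    vals = np.array(list(raw.values()), dtype=float)
    if np.any(vals < 0) or not np.all(np.isfinite(vals)):
        raise ValidationError("expression values must be finite and nonnegative")
    total = vals.sum()
    if total <= 0:
        raise ValidationError(
            f"degenerate profile {cell_line_id!r}: all expression values are zero"
        )
    fracs = vals / total
    # close the simplex exactly against accumulated FP error
    fracs = fracs / fracs.sum()
    return ExpressionProfile(
        cell_line_id=cell_line_id,
        fractions={k: float(v) for k, v in zip(raw, fracs)},
    )


def average_profiles(
    profiles: list[ExpressionProfile], cell_line_id: str
) -> ExpressionProfile:
    """Unweighted mean of simplex profiles, renormalized to sum exactly to 1.

    Used to stand in for an unprofiled cell line with the average of its
    tissue (e.g. a colon-cancer average for SW480, a lung average for A549).
    Missing isotypes count as 0 in the mean, so each input profile carries
    equal weight regardless of its isotype set.
    """
    if not profiles:
        raise ValidationError("cannot average an empty profile collection")
    isotypes: dict[str, None] = {}
    for p in profiles:
        for iso in p.fractions:
            isotypes.setdefault(iso)
    keys = list(isotypes)
    mat = np.array([p.vector(keys) for p in profiles])
    mean = mat.mean(axis=0)
    mean = mean / mean.sum()
    return ExpressionProfile(
        cell_line_id=cell_line_id,
        fractions={k: float(v) for k, v in zip(keys, mean)},
    )


def uniform_profile(
    isotype_ids: list[str] | set[str], cell_line_id: str = ""
) -> ExpressionProfile:
    """Equal abundance 1/k over the listed isotypes (e.g. HaCaT fallback)."""
    ids = list(isotype_ids)
    if not ids:
        raise ValidationError("uniform profile needs at least one isotype")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate isotype labels in uniform profile")
    fracs = np.full(len(ids), 1.0 / len(ids))
    fracs = fracs / fracs.sum()
    return ExpressionProfile(
        cell_line_id=cell_line_id,
        fractions={k: float(v) for k, v in zip(ids, fracs)},
    )


def load_gene_map(path: str | Path | None = None) -> dict[str, str]:
    """Read the gene→isotype map (key=value lines, '#' comments).

    Defaults to the bundled map covering TUBB, TUBB2A, TUBB2B, TUBB3,
    TUBB4 and TUBB2C.
    """
    path = Path(path) if path is not None else fixture_path("gene_map")
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if "=" not in s:
            raise ValidationError(f"{path}:{lineno}: expected KEY=VALUE, got {s!r}")
        key, _, value = s.partition("=")
        mapping[key.strip()] = value.strip()
    if not mapping:
        raise ValidationError(f"gene map {path} is empty")
    return mapping


def _looks_like_fractions(col: pd.Series) -> bool:
    return abs(col.sum() - 1.0) <= 0.01


def read_expression_panel(
    path: str | Path,
    gene_map: dict[str, str] | None = None,
) -> ExpressionPanel:
    """Read an expression file (rows = genes or isotypes, columns = cell lines).

    If any row label is a gene symbol in the map, the file is taken as
    gene-keyed: mapped rows are translated to isotype labels and unmapped
    rows are dropped with a warning. Otherwise the row labels are used as
    isotype labels verbatim (energy tables name isotypes αβI, αβIIa, ...,
    which are not gene symbols). Columns summing to 1 ± 0.01 are taken as
    pre-normalized fractions, anything else as raw expression; either way
    each column is renormalized onto the simplex.
    """
    gene_map = gene_map if gene_map is not None else load_gene_map()
    df = _read_delimited(path).astype(float)
    gene_keyed = any(label in gene_map for label in df.index)
    rows: dict[str, pd.Series] = {}
    for label in df.index:
        if label in gene_map:
            iso = gene_map[label]
        elif not gene_keyed:
            iso = label
        else:
            msg = f"unmapped gene row {label!r} ignored"
            logger.warning(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        if iso in rows:
            raise ValidationError(f"rows {label!r} map to duplicate isotype {iso!r}")
        rows[iso] = df.loc[label]
    if not rows:
        raise ValidationError(f"no mappable expression rows in {path}")
    mapped = pd.DataFrame(rows).T
    profiles = []
    for line in mapped.columns:
        col = mapped[line]
        if not _looks_like_fractions(col):
            logger.info("column %r treated as raw expression", line)
        profiles.append(normalize_expression(col.to_dict(), cell_line_id=str(line)))
    return ExpressionPanel(profiles=profiles)


def restrict_to_matrix(
    profile: ExpressionProfile, matrix: IsotypeBindingMatrix
) -> ExpressionProfile:
    """Drop isotypes absent from the binding matrix and renormalize.

    Explicit opt-in handling for label mismatch between an expression source
    and an energy table; without it, weighting a profile that references
    unknown isotypes is an error.
    """
    kept = {
        iso: f for iso, f in profile.fractions.items() if iso in matrix.isotype_ids
    }
    if not kept or sum(kept.values()) <= 0:
        raise ValidationError(
            f"profile {profile.cell_line_id!r} shares no expressed isotype "
            "with the binding matrix"
        )
    return normalize_expression(kept, cell_line_id=profile.cell_line_id)
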