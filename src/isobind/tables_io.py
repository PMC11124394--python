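"""Typed tables and delimited-text I/O for the binding/expression/potency pipeline.

All tables travel as TSV/CSV with compounds as rows and isotypes or cell
lines as columns. Binding energies are kcal/mol with their docking sign
(more negative = stronger binding); potencies are IC50 in µM, where a cell
``">100"`` means the true IC50 exceeds 100 µM (right-censored). The parser
accepts both the Unicode minus sign used in typeset tables and the ASCII
hyphen; the decimal separator is always a period.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import LabelError, ParseError, ValidationError

__all__ = [
    "CompoundRecord",
    "IsotypeBindingMatrix",
    "ExpressionProfile",
    "ExpressionPanel",
    "CensoredPotencyTable",
    "WeightedEnergyTable",
    "read_binding_matrix",
    "read_potency_table",
    "read_weighted_table",
    "write_binding_matrix",
    "write_potency_table",
    "write_weighted_table",
    "write_report",
    "load_fixture",
    "fixture_path",
]

#: Simplex tolerance shared by ExpressionProfile validation.
SIMPLEX_TOL = 1e-9

_UNICODE_MINUS = "−"
_CENSOR_RE = re.compile(r"^>\s*(\S+)$")
_PM_RE = re.compile(r"^(.+?)\s*±\s*(.+)$")


def _clean_number(text: str, where: str) -> float:
    """Parse one numeric cell, accepting Unicode minus; reject anything else."""
    s = text.strip().replace(_UNICODE_MINUS, "-")
    try:
        v = float(s)
    except ValueError:
        raise ParseError(f"non-numeric cell {text!r} at {where}") from None
    if not math.isfinite(v):
        raise ParseError(f"non-finite cell {text!r} at {where}")
    return v


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV of strings, first column = row labels.

    Delimiter auto-detection is limited to tab and comma (tab wins when a
    tab is present in the header line); everything is kept as text so each
    table type applies its own cell grammar.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise ParseError(f"empty file: {path}")
    header = text.splitlines()[0]
    sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str, index_col=0, encoding="utf-8")
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _check_unique(labels: Iterable[str], what: str) -> None:
    labels = list(labels)
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate {what} labels: {dupes}")


def _format_value(v: float) -> str:
    """Shortest decimal text that round-trips the float exactly."""
    return repr(float(v))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CompoundRecord:
    """One compound: opaque id (e.g. "4", "CA4"), optional SMILES/descriptors.

    Descriptors use the field's standard names: TPSA (Å²), MLogP (unitless),
    HBD (count), POL (Å³).
    """

    compound_id: str
    name: str = ""
    smiles: str | None = None
    descriptors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValidationError("compound_id must be non-empty")
        hbd = self.descriptors.get("HBD")
        if hbd is not None and (hbd < 0 or hbd != int(hbd)):
            raise ValidationError(
                f"HBD must be a nonnegative integer, got {hbd!r} "
                f"for compound {self.compound_id}"
            )
        for key in ("TPSA", "POL"):
            v = self.descriptors.get(key)
            if v is not None and v < 0:
                raise ValidationError(
                    f"{key} must be nonnegative, got {v!r} "
                    f"for compound {self.compound_id}"
                )


@dataclass
class IsotypeBindingMatrix:
    """Compounds × tubulin isotypes binding energies (kcal/mol)."""

    compound_ids: list[str]
    isotype_ids: list[str]
    energies: np.ndarray

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.shape != (len(self.compound_ids), len(self.isotype_ids)):
            raise ValidationError(
                f"energy matrix shape {self.energies.shape} does not match "
                f"{len(self.compound_ids)} compounds × {len(self.isotype_ids)} isotypes"
            )
        if not np.all(np.isfinite(self.energies)):
            raise ValidationError("binding energies must be finite")
        _check_unique(self.compound_ids, "compound")
        _check_unique(self.isotype_ids, "isotype")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.energies, index=self.compound_ids, columns=self.isotype_ids
        )

    def row(self, compound_id: str) -> np.ndarray:
        try:
            i = self.compound_ids.index(compound_id)
        except ValueError:
            raise LabelError(f"unknown compound {compound_id!r}") from None
        return self.energies[i]

    def column(self, isotype_id: str) -> np.ndarray:
        try:
            j = self.isotype_ids.index(isotype_id)
        except ValueError:
            raise LabelError(f"unknown isotype {isotype_id!r}") from None
        return self.energies[:, j]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IsotypeBindingMatrix):
            return NotImplemented
        return (
            self.compound_ids == other.compound_ids
            and self.isotype_ids == other.isotype_ids
            and np.array_equal(self.energies, other.energies)
        )


@dataclass
class ExpressionProfile:
    """A cell line's isotype abundance fractions: a point on the simplex."""

    cell_line_id: str
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise ValidationError(
                f"profile {self.cell_line_id!r} has no isotypes"
            )
        vals = np.array(list(self.fractions.values()), dtype=float)
        if np.any(vals < 0):
            raise ValidationError(
                f"profile {self.cell_line_id!r} has negative fractions"
            )
        if abs(vals.sum() - 1.0) > SIMPLEX_TOL:
            raise ValidationError(
                f"profile {self.cell_line_id!r} fractions sum to {vals.sum()!r}, "
                "not 1"
            )

    def vector(self, isotype_ids: list[str]) -> np.ndarray:
        """Fractions aligned to ``isotype_ids``; missing isotypes get 0."""
        return np.array([self.fractions.get(i, 0.0) for i in isotype_ids])


@dataclass
class ExpressionPanel:
    """Ordered collection of profiles with unique cell-line ids."""

    profiles: list[ExpressionProfile]

    def __post_init__(self) -> None:
        _check_unique([p.cell_line_id for p in self.profiles], "cell line")

    @property
    def cell_line_ids(self) -> list[str]:
        return [p.cell_line_id for p in self.profiles]

    def __iter__(self):
        return iter(self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)


#: status flags for potency entries
OBSERVED = "observed"
CENSORED = "right_censored"


@dataclass
class CensoredPotencyTable:
    """Compound × cell line IC50 (µM) with right-censoring flags.

    ``entries`` maps ``(compound_id, cell_line_id)`` to
    ``(value, status)`` where status is ``"observed"`` or
    ``"right_censored"`` (value is then the censor bound). Reported SDs from
    "mean ± SD" cells are kept in ``sd`` but unused downstream.
    """

    entries: dict[tuple[str, str], tuple[float, str]]
    sd: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (cid, line), (value, status) in self.entries.items():
            if status not in (OBSERVED, CENSORED):
                raise ValidationError(
                    f"unknown status {status!r} for ({cid}, {line})"
                )
            if not (value > 0) or not math.isfinite(value):
                kind = "IC50" if status == OBSERVED else "censor bound"
                raise ValidationError(
                    f"nonpositive {kind} {value!r} for ({cid}, {line})"
                )

    @property
    def compound_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cid, _ in self.entries:
            seen.setdefault(cid)
        return list(seen)

    @property
    def cell_line_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, line in self.entries:
            seen.setdefault(line)
        return list(seen)

    def column(self, cell_line_id: str) -> dict[str, tuple[float, str]]:
        """All entries for one cell line, keyed by compound."""
        if cell_line_id not in self.cell_line_ids:
            raise LabelError(f"unknown cell line {cell_line_id!r}")
        return {
            cid: v
            for (cid, line), v in self.entries.items()
            if line == cell_line_id
        }

    def n_observed(self) -> int:
        return sum(1 for v, s in self.entries.values() if s == OBSERVED)


@dataclass
class WeightedEnergyTable:
    """Compound × cell line expression-weighted binding energies (kcal/mol)."""

    compound_ids: list[str]
    cell_line_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.cell_line_ids)):
            raise ValidationError(
                f"value matrix shape {self.values.shape} does not match labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("weighted energies must be finite")
        _check_unique(self.compound_ids, "compound")
        _check_unique(self.cell_line_ids, "cell line")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.compound_ids, columns=self.cell_line_ids
        )

    def column(self, cell_line_id: str) -> np.ndarray:
        try:
            j = self.cell_line_ids.index(cell_line_id)
        except ValueError:
            raise LabelError(f"unknown cell line {cell_line_id!r}") from None
        return self.values[:, j]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedEnergyTable):
            return NotImplemented
        return (
            self.compound_ids == other.compound_ids
            and self.cell_line_ids == other.cell_line_ids
            and np.array_equal(self.values, other.values)
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_binding_matrix(path: str | Path) -> IsotypeBindingMatrix:
    """Read a compounds × isotypes energy table (kcal/mol) from TSV/CSV.

    One header row of isotype labels, one row per compound; row/column order
    is preserved exactly as in the file.
    """
    df = _read_delimited(path)
    energies = np.empty(df.shape, dtype=float)
    for i, cid in enumerate(df.index):
        for j, iso in enumerate(df.columns):
            energies[i, j] = _clean_number(
                str(df.iat[i, j]), f"row {cid!r}, column {iso!r}"
            )
    return IsotypeBindingMatrix(
        compound_ids=list(df.index), isotype_ids=list(df.columns), energies=energies
    )


def read_weighted_table(path: str | Path) -> WeightedEnergyTable:
    """Read a compounds × cell lines BE_w table (kcal/mol) from TSV/CSV."""
    df = _read_delimited(path)
    values = np.empty(df.shape, dtype=float)
    for i, cid in enumerate(df.index):
        for j, line in enumerate(df.columns):
            values[i, j] = _clean_number(
                str(df.iat[i, j]), f"row {cid!r}, column {line!r}"
            )
    return WeightedEnergyTable(
        compound_ids=list(df.index), cell_line_ids=list(df.columns), values=values
    )


def parse_potency_cell(
    text: str, where: str = "?"
) -> tuple[float, str, float | None]:
    """Parse one IC50 cell: number, "mean ± SD", or ">bound".

    Returns (value_µM, status, sd_or_None).
    """
    s = text.strip()
    m = _CENSOR_RE.match(s)
    if m:
        bound = _clean_number(m.group(1), where)
        return bound, CENSORED, None
    m = _PM_RE.match(s)
    if m:
        mean = _clean_number(m.group(1), where)
        sd = _clean_number(m.group(2), where)
        return mean, OBSERVED, sd
    return _clean_number(s, where), OBSERVED, None


def read_potency_table(
    path: str | Path, censor_token: str = ">"
) -> CensoredPotencyTable:
    """Read a compound × cell line IC50 table (µM) with ">X" censoring.

    "a ± b" cells keep the mean a as the value; the SD b is stored in the
    table's side channel and ignored by the QSAR stage.
    """
    if censor_token != ">":
        raise ValidationError(
            f"only the '>' censor grammar is supported, got {censor_token!r}"
        )
    df = _read_delimited(path)
    _check_unique(df.index, "compound")
    _check_unique(df.columns, "cell line")
    entries: dict[tuple[str, str], tuple[float, str]] = {}
    sds: dict[tuple[str, str], float] = {}
    for cid in df.index:
        for line in df.columns:
            cell = df.at[cid, line]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)):
                continue  # missing entry allowed
            value, status, sd = parse_potency_cell(
                str(cell), f"row {cid!r}, column {line!r}"
            )
            entries[(str(cid), str(line))] = (value, status)
            if sd is not None:
                sds[(str(cid), str(line))] = sd
    return CensoredPotencyTable(entries=entries, sd=sds)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _write_frame(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(index_label + "\t" + "\t".join(map(str, df.columns)) + "\n")
        for idx, row in df.iterrows():
            fh.write(str(idx) + "\t" + "\t".join(row) + "\n")


def write_binding_matrix(matrix: IsotypeBindingMatrix, path: str | Path) -> None:
    df = matrix.to_frame().map(_format_value)
    _write_frame(df, path, "compound")


def write_weighted_table(table: WeightedEnergyTable, path: str | Path) -> None:
    df = table.to_frame().map(_format_value)
    _write_frame(df, path, "compound")


def write_potency_table(table: CensoredPotencyTable, path: str | Path) -> None:
    compounds = table.compound_ids
    lines = table.cell_line_ids
    cells = {}
    for (cid, line), (value, status) in table.entries.items():
        if status == CENSORED:
            cells[(cid, line)] = f">{_format_value(value)}"
        elif (cid, line) in table.sd:
            cells[(cid, line)] = (
                f"{_format_value(value)} ± {_format_value(table.sd[(cid, line)])}"
            )
        else:
            cells[(cid, line)] = _format_value(value)
    df = pd.DataFrame(
        [[cells.get((cid, line), "") for line in lines] for cid in compounds],
        index=compounds,
        columns=lines,
    )
    _write_frame(df, path, "compound")


def write_report(tables: Mapping[str, object], path: str | Path) -> None:
    """Serialize a run report (dicts of tables/metadata) to JSON.

    Table objects are converted to nested {row: {column: value}} mappings;
    numpy scalars are converted to Python floats.
    """

    def convert(obj):
        if isinstance(obj, (IsotypeBindingMatrix, WeightedEnergyTable)):
            return json.loads(obj.to_frame().to_json(orient="index"))
        if isinstance(obj, pd.DataFrame):
            return json.loads(obj.to_json(orient="index"))
        if isinstance(obj, ExpressionProfile):
            return {"cell_line_id": obj.cell_line_id, "fractions": obj.fractions}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {str(k): convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        return obj

    Path(path).write_text(
        json.dumps(convert(dict(tables)), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# bundled fixtures
# ---------------------------------------------------------------------------

_FIXTURES = {
    "binding": "table3_binding.tsv",
    "weighted": "table4_weighted.tsv",
    "ic50": "table2_ic50.tsv",
    "r2_reference": "table5_r2_reference.tsv",
    "gene_map": "gene_isotype_map.txt",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a bundled data file (binding, weighted, ic50, ...)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; have {sorted(_FIXTURES)}")
    return Path(resources.files("isobind").joinpath("data", _FIXTURES[name]))


def load_fixture(name: str):
    """Load a bundled table with the appropriate typed reader."""
    path = fixture_path(name)
    if name == "binding":
        return read_binding_matrix(path)
    if name == "weighted":
        return read_weighted_table(path)
    if name == "ic50":
        return read_potency_table(path)
    if name == "r2_reference":
        df = _read_delimited(path)
        return df.astype(float)
    raise KeyError(f"fixture {name!r} has no typed loader")
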