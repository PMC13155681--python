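"""Core domain types and tabular readers/writers.

The atomic record of the method is one measured combination response: two
drugs, their two assay concentrations, a cell line, and the observed response
(a synergy score or percent growth — the models are scale-agnostic). All
on-disk tables are long-format CSV with a header row; column names are
configurable through a simple mapping so exports from the common combination
screens (NCI-ALMANAC-style, O'Neil-style) can be read without rewriting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ComboSample",
    "MonoSample",
    "DrugRecord",
    "CellLineProfile",
    "PairKey",
    "ValidationError",
    "ConfigurationError",
    "canonical_pair_key",
    "canonical_orientation",
    "read_combo_table",
    "write_combo_table",
    "read_mono_table",
    "read_drug_library",
    "read_expression_matrix",
    "write_expression_matrix",
    "COMBO_COLUMNS",
    "MONO_COLUMNS",
]


class ValidationError(ValueError):
    """A row or value violates a domain invariant."""


class ConfigurationError(ValueError):
    """The input file does not match the declared schema."""


@dataclass(frozen=True)
class ComboSample:
    """One measured (drug1, drug2, dose1, dose2, cell line, response) tuple."""

    drug1_id: str
    drug2_id: str
    dose1: float
    dose2: float
    cell_id: str
    response: float

    def __post_init__(self):
        if not (self.dose1 > 0 and self.dose2 > 0):
            raise ValidationError(
                f"doses must be positive, got ({self.dose1}, {self.dose2})"
            )
        if not math.isfinite(self.response):
            raise ValidationError(f"response must be finite, got {self.response}")

    def swapped(self) -> "ComboSample":
        """The same measurement with the two (drug, dose) slots exchanged."""
        return ComboSample(
            self.drug2_id, self.drug1_id, self.dose2, self.dose1,
            self.cell_id, self.response,
        )


@dataclass(frozen=True)
class MonoSample:
    """One single-drug (monotherapy) response measurement."""

    drug_id: str
    dose: float
    cell_id: str
    response: float

    def __post_init__(self):
        if not self.dose > 0:
            raise ValidationError(f"dose must be positive, got {self.dose}")
        if not math.isfinite(self.response):
            raise ValidationError(f"response must be finite, got {self.response}")


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    smiles: str

    def __post_init__(self):
        if not self.smiles:
            raise ValidationError(f"empty SMILES for drug {self.drug_id!r}")


@dataclass(frozen=True)
class CellLineProfile:
    """A cell line's expression vector (fixed length within one dataset)."""

    cell_id: str
    expression: tuple[float, ...]

    def __post_init__(self):
        if not all(math.isfinite(v) for v in self.expression):
            raise ValidationError(f"non-finite expression value for {self.cell_id!r}")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.expression, dtype=np.float64)


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical unordered (drug, drug) pair within a cell line.

    ``drug_lo <= drug_hi`` under plain string ordering, so (A, B, c) and
    (B, A, c) map to the same key — synergy is physically symmetric.
    """

    drug_lo: str
    drug_hi: str
    cell_id: str


def canonical_pair_key(sample: ComboSample) -> PairKey:
    if sample.drug2_id < sample.drug1_id:
        return PairKey(sample.drug2_id, sample.drug1_id, sample.cell_id)
    return PairKey(sample.drug1_id, sample.drug2_id, sample.cell_id)


def canonical_orientation(sample: ComboSample) -> ComboSample:
    """Reorder so drug1 <= drug2; doses travel with their drug."""
    if sample.drug2_id < sample.drug1_id:
        return sample.swapped()
    return sample


# ---------------------------------------------------------------------------
# Tabular IO

COMBO_COLUMNS: Mapping[str, str] = {
    "drug1_id": "drug1_id",
    "drug2_id": "drug2_id",
    "dose1": "dose1",
    "dose2": "dose2",
    "cell_id": "cell_id",
    "response": "response",
}

MONO_COLUMNS: Mapping[str, str] = {
    "drug_id": "drug_id",
    "dose": "dose",
    "cell_id": "cell_id",
    "response": "response",
}


def _resolve_columns(
    df: pd.DataFrame, columns: Mapping[str, str] | None, defaults: Mapping[str, str]
) -> dict[str, str]:
    mapping = dict(defaults)
    if columns:
        mapping.update(columns)
    for logical, actual in mapping.items():
        if actual not in df.columns:
            raise ConfigurationError(
                f"required column {actual!r} (for field {logical!r}) not found; "
                f"available: {list(df.columns)}"
            )
    return mapping


def read_combo_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[ComboSample]:
    """Read a long-format combination-response CSV.

    Extra columns are ignored; row order is preserved. Rows violating the
    dose/response invariants raise :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(path)
    cols = _resolve_columns(df, columns, COMBO_COLUMNS)
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = {logical: getattr(row, actual) for logical, actual in cols.items()}
        try:
            samples.append(
                ComboSample(
                    str(rec["drug1_id"]), str(rec["drug2_id"]),
                    float(rec["dose1"]), float(rec["dose2"]),
                    str(rec["cell_id"]), float(rec["response"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return samples


def write_combo_table(
    samples: Iterable[ComboSample], path: str | Path,
) -> None:
    df = pd.DataFrame([s.__dict__ for s in samples])
    df.to_csv(path, index=False)


def read_mono_table(
    path: str | Path, columns: Mapping[str, str] | None = None
) -> list[MonoSample]:
    df = pd.read_csv(path)
    cols = _resolve_columns(df, columns, MONO_COLUMNS)
    samples = []
    for i, row in enumerate(df.itertuples(index=False)):
        rec = {logical: getattr(row, actual) for logical, actual in cols.items()}
        try:
            samples.append(
                MonoSample(
                    str(rec["drug_id"]), float(rec["dose"]),
                    str(rec["cell_id"]), float(rec["response"]),
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {i}: {exc}") from exc
    return samples


def write_mono_table(samples: Iterable[MonoSample], path: str | Path) -> None:
    pd.DataFrame([s.__dict__ for s in samples]).to_csv(path, index=False)


def read_drug_library(path: str | Path) -> list[DrugRecord]:
    """Two-column (drug_id, smiles) CSV; drug_id must be unique."""
    df = pd.read_csv(path)
    for col in ("drug_id", "smiles"):
        if col not in df.columns:
            raise ConfigurationError(f"required column {col!r} not found")
    dupes = df["drug_id"][df["drug_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"duplicate drug_id values: {dupes}")
    return [DrugRecord(str(r.drug_id), str(r.smiles)) for r in df.itertuples()]


def write_drug_library(records: Iterable[DrugRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


def read_expression_matrix(path: str | Path) -> dict[str, CellLineProfile]:
    """Read a cell × gene matrix (first column = cell id) as profiles.

    All rows must have the same length; NaN entries and duplicated cell ids
    are rejected.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].tolist()
        raise ValidationError(f"duplicated cell id(s): {dupes}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ConfigurationError("expression matrix contains non-numeric entries")
    if np.isnan(values).any():
        bad = df.index[np.isnan(values).any(axis=1)].tolist()
        raise ValidationError(f"NaN expression entries in cell(s): {bad}")
    return {
        str(cell): CellLineProfile(str(cell), tuple(map(float, row)))
        for cell, row in zip(df.index, values)
    }


def write_expression_matrix(
    profiles: Mapping[str, CellLineProfile], path: str | Path
) -> None:
    ids = list(profiles)
    mat = np.stack([profiles[c].as_array() for c in ids])
    df = pd.DataFrame(mat, index=ids)
    df.columns = [f"g{j}" for j in range(mat.shape[1])]
    df.to_csv(path, index_label="cell_id")
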