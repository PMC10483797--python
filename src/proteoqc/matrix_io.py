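"""Read, validate, and write protein quantification matrices and run metadata.

The canonical on-disk layout is a wide table: first column protein
identifier, remaining columns one MS run each. Empty cells and ``NA`` denote
missing values (distinct from zero). Lines starting with ``#`` are comment
headers; ``write_quant_matrix`` records the unit tag there as
``# unit_tag: FOT``. Missing values are carried as NaN in memory -- the
1e-5 sentinel is applied only by the normalization stage, never at I/O, so
raw missingness stays recoverable.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

UNIT_TAGS = ("iBAQ", "FOT", "copies_per_cell", "arbitrary")

_DIALECTS = {"tsv": "\t", "csv": ","}

REQUIRED_METADATA_COLUMNS = ("run_id", "group_label", "replicate_index")

_METADATA_DEFAULTS = {
    "experiment_id": "E1",
    "site_id": "S1",
    "instrument_id": "unknown",
    "month": 1,
    "material_form": "peptide",
}


def _sep(dialect: str) -> str:
    try:
        return _DIALECTS[dialect]
    except KeyError:
        raise ValidationError(f"unknown dialect {dialect!r}; use 'tsv' or 'csv'") from None


@dataclass
class QuantMatrix:
    """Proteins x runs matrix of non-negative abundances with explicit missingness.

    ``values`` is a DataFrame indexed by protein identifier with one column
    per run; NaN marks a missing (undetected) entry.
    """

    values: pd.DataFrame
    unit_tag: str = "arbitrary"

    def __post_init__(self) -> None:
        if self.unit_tag not in UNIT_TAGS:
            raise ValidationError(
                f"unit_tag {self.unit_tag!r} not one of {UNIT_TAGS}")
        self.values = self.values.rename_axis(index="protein_id", columns=None)
        idx = self.values.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate protein identifiers: {dup}")
        cols = self.values.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate run identifiers: {dup}")
        vals = self.values.to_numpy(dtype=float, copy=False)
        neg = np.argwhere(np.nan_to_num(vals, nan=0.0) < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"negative value at protein {idx[r]!r}, run {cols[c]!r}")

    @property
    def protein_ids(self) -> list:
        return list(self.values.index)

    @property
    def run_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_runs(self) -> int:
        return self.values.shape[1]

    def subset_runs(self, run_ids) -> "QuantMatrix":
        missing = [r for r in run_ids if r not in self.values.columns]
        if missing:
            raise ValidationError(f"unknown runs requested: {missing}")
        return QuantMatrix(self.values.loc[:, list(run_ids)], self.unit_tag)

    def with_unit(self, values: pd.DataFrame, unit_tag: str) -> "QuantMatrix":
        return QuantMatrix(values, unit_tag)


@dataclass
class RunMetadata:
    """Per-run annotations matching the columns of a QuantMatrix.

    Required columns: run_id, group_label, replicate_index. Optional columns
    (experiment_id, site_id, instrument_id, injection_index, month,
    material_form) receive documented defaults when absent.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in REQUIRED_METADATA_COLUMNS:
            if col not in t.columns:
                raise ValidationError(f"metadata missing required column {col!r}")
        for col, default in _METADATA_DEFAULTS.items():
            if col not in t.columns:
                if col == "month":
                    warnings.warn("metadata has no 'month' column; defaulting to 1")
                t[col] = default
        if "injection_index" not in t.columns:
            t["injection_index"] = np.arange(1, len(t) + 1)
        t["run_id"] = t["run_id"].astype(str)
        t["group_label"] = t["group_label"].astype(str)
        t["material_form"] = t["material_form"].astype(str).str.lower()
        t["replicate_index"] = t["replicate_index"].astype(int)
        t["injection_index"] = t["injection_index"].astype(int)
        t["month"] = t["month"].astype(int)
        if t["run_id"].duplicated().any():
            dup = t.loc[t["run_id"].duplicated(), "run_id"].tolist()
            raise ValidationError(f"duplicate run_id in metadata: {dup}")
        if (t["replicate_index"] < 1).any():
            raise ValidationError("replicate_index must be >= 1")
        if (t["month"] < 1).any():
            raise ValidationError("month must be >= 1")
        if (t["injection_index"] < 1).any():
            raise ValidationError("injection_index must be >= 1")
        key = t[["experiment_id", "group_label", "replicate_index"]]
        if key.duplicated().any():
            raise ValidationError(
                "(experiment_id, group_label, replicate_index) must be unique")
        bad_form = set(t["material_form"]) - {"peptide", "protein"}
        if bad_form:
            raise ValidationError(f"material_form must be peptide/protein, got {bad_form}")
        self.table = t.reset_index(drop=True)

    @property
    def run_ids(self) -> list:
        return list(self.table["run_id"])

    def groups(self, experiment_id: str | None = None) -> list:
        t = self._subset(experiment_id)
        return list(dict.fromkeys(t["group_label"]))

    def experiments(self) -> list:
        return list(dict.fromkeys(self.table["experiment_id"]))

    def months(self) -> list:
        return sorted(self.table["month"].unique())

    def n_replicates(self, experiment_id: str | None = None) -> int:
        t = self._subset(experiment_id)
        return int(t.groupby("group_label")["run_id"].count().max())

    def runs_for(self, experiment_id: str | None = None,
                 group: str | None = None, month: int | None = None) -> list:
        t = self._subset(experiment_id)
        if group is not None:
            t = t[t["group_label"] == group]
        if month is not None:
            t = t[t["month"] == month]
        return list(t["run_id"])

    def _subset(self, experiment_id: str | None) -> pd.DataFrame:
        if experiment_id is None:
            return self.table
        t = self.table[self.table["experiment_id"] == experiment_id]
        if t.empty:
            raise ValidationError(f"unknown experiment_id {experiment_id!r}")
        return t


def validate_pairing(matrix: QuantMatrix, metadata: RunMetadata) -> None:
    """Ensure metadata rows correspond one-to-one with matrix columns."""
    m_runs = set(matrix.run_ids)
    d_runs = set(metadata.run_ids)
    if m_runs != d_runs:
        only_matrix = sorted(m_runs - d_runs)
        only_meta = sorted(d_runs - m_runs)
        raise ValidationError(
            "matrix/metadata run mismatch; "
            f"only in matrix: {only_matrix}; only in metadata: {only_meta}")


def read_quant_matrix(path, dialect: str = "tsv") -> QuantMatrix:
    """Read a wide quantification matrix; '#' lines may carry a unit_tag."""
    sep = _sep(dialect)
    unit_tag = "arbitrary"
    data_lines = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("unit_tag:"):
                    unit_tag = body.split(":", 1)[1].strip()
                continue
            data_lines.append(line)
    df = pd.read_csv(io.StringIO("".join(data_lines)), sep=sep, index_col=0,
                     na_values=["NA"], keep_default_na=False)
    df.index = df.index.astype(str)
    df = df.astype(float)
    return QuantMatrix(df, unit_tag=unit_tag)


def write_quant_matrix(matrix: QuantMatrix, path, dialect: str = "tsv") -> None:
    """Write TSV/CSV with missing as 'NA' and a '# unit_tag:' comment header.

    Values are written at full repr precision so a read round-trips
    bit-exactly for representable decimals.
    """
    sep = _sep(dialect)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# unit_tag: {matrix.unit_tag}\n")
        matrix.values.to_csv(fh, sep=sep, na_rep="NA", index_label="protein_id")


def read_metadata(path, dialect: str = "tsv") -> RunMetadata:
    """Read a run-metadata table; see RunMetadata for required columns."""
    sep = _sep(dialect)
    df = pd.read_csv(path, sep=sep, comment="#")
    return RunMetadata(df)


def write_metadata(metadata: RunMetadata, path, dialect: str = "tsv") -> None:
    sep = _sep(dialect)
    metadata.table.to_csv(path, sep=sep, index=False)


def from_long(df: pd.DataFrame, protein_col: str = "protein_id",
              run_col: str = "run_id", value_col: str = "value",
              unit_tag: str = "arbitrary") -> QuantMatrix:
    """Convenience converter from long (protein, run, value) records."""
    wide = df.pivot(index=protein_col, columns=run_col, values=value_col)
    wide.index = wide.index.astype(str)
    wide.columns = [str(c) for c in wide.columns]
    return QuantMatrix(wide, unit_tag=unit_tag)
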