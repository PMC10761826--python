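"""Core data containers and plain-text readers/writers.

Expression and count matrices are genes-in-rows, samples-in-columns TSV
files whose first header cell is ``gene_id``.  Gene sets use the Broad GMT
dialect.  Clinical tables are TSV with one row per sample.  All identifiers
are case-sensitive opaque strings; no symbol aliasing is attempted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("pnstrat")

EXPRESSION_SCALES = ("linear", "log2", "residual")

#: canonical clinical columns; anything else is preserved as an opaque covariate
CLINICAL_COLUMNS = (
    "time_years",
    "event",
    "age",
    "gender",
    "stage",
    "pigmentation_score",
    "subsequent_metastasis",
)


class DataError(ValueError):
    """Raised when an input file or container violates its contract."""


def _check_unique(ids, what: str) -> None:
    counts = pd.Index(ids).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise DataError(f"duplicate {what} identifiers: {sorted(map(str, dups))}")


def _validate_matrix(df: pd.DataFrame, *, integral: bool, nonnegative: bool) -> None:
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "sample")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.map(lambda v: not isinstance(v, (int, float, np.number)))
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if not np.isfinite(values).all():
        r, c = np.argwhere(~np.isfinite(values))[0]
        raise DataError(
            f"non-finite value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if nonnegative and (values < 0).any():
        r, c = np.argwhere(values < 0)[0]
        raise DataError(
            f"negative value at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if integral and not np.array_equal(values, np.round(values)):
        r, c = np.argwhere(values != np.round(values))[0]
        raise DataError(
            f"non-integer count at gene {df.index[r]!r}, sample {df.columns[c]!r}"
        )


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _validate_matrix(self.data, integral=True, nonnegative=True)
        self.data = self.data.astype(np.int64)

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class ExpressionMatrix:
    """Real-valued expression, genes x samples, with an explicit scale tag.

    ``scale`` is one of ``linear`` (FPKM-like), ``log2``, or ``residual``
    (purity-regression residuals).  Residual-scale matrices carry the purity
    vector that produced them in ``purity_used``.
    """

    data: pd.DataFrame
    scale: str
    purity_used: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.scale not in EXPRESSION_SCALES:
            raise DataError(
                f"unknown scale {self.scale!r}; expected one of {EXPRESSION_SCALES}"
            )
        _validate_matrix(self.data, integral=False, nonnegative=False)
        self.data = self.data.astype(np.float64)
        if self.scale == "residual" and self.purity_used is None:
            raise DataError("residual-scale matrix must record the purity vector used")

    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional role tag per set.

    Roles distinguish the curated core proteostasis-network list
    (``pn_core``) from chaperone families, subcellular compartments and
    transcription-factor target sets.
    """

    sets: dict[str, frozenset[str]]
    roles: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise DataError(f"gene set {name!r} is empty")

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample clinical records.

    Missing values are pandas NA, never sentinel numbers.  ``time_years``
    must be positive where present and ``event`` is 0 (censored) / 1
    (death).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample")
        df = self.data
        if "time_years" in df:
            t = pd.to_numeric(df["time_years"], errors="raise")
            if (t.dropna() <= 0).any():
                bad = t.index[t <= 0][0]
                raise DataError(f"non-positive time_years for sample {bad!r}")
        if "event" in df:
            e = df["event"].dropna()
            if not e.isin([0, 1]).all():
                bad = e.index[~e.isin([0, 1])][0]
                raise DataError(f"event outside {{0,1}} for sample {bad!r}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path, scale_tag: str
) -> CountMatrix | ExpressionMatrix:
    """Read a genes x samples TSV.

    ``scale_tag`` is ``counts`` for a :class:`CountMatrix` or one of the
    :data:`EXPRESSION_SCALES` for an :class:`ExpressionMatrix`.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = df.index[coerced.isna()][0]
            raise DataError(f"non-numeric cell at gene {row!r}, sample {col!r}")
        df[col] = coerced
    if scale_tag == "counts":
        return CountMatrix(df)
    return ExpressionMatrix(df, scale=scale_tag)


def write_expression_table(matrix: CountMatrix | ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id")


def read_gene_sets_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name <tab> description <tab> members."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise DataError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in sets:
                raise DataError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gene_sets_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for name in collection.names():
            desc = collection.descriptions.get(name, "")
            members = sorted(collection[name])
            handle.write("\t".join([name, desc, *members]) + "\n")


def read_purity_table(path: str | Path) -> pd.Series:
    """Read per-sample tumour purity (TSV: sample_id, purity) into a Series."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "purity" not in df.columns:
        raise DataError(f"{path}: expected a 'purity' column")
    purity = pd.to_numeric(df["purity"], errors="raise")
    purity.index.name = None
    present = purity.dropna()
    if ((present < 0) | (present > 1)).any():
        bad = present.index[(present < 0) | (present > 1)][0]
        raise DataError(f"purity outside [0, 1] for sample {bad!r}")
    _check_unique(purity.index, "sample")
    purity.index = purity.index.astype(str)
    return purity


def write_purity_table(purity: pd.Series, path: str | Path) -> None:
    purity.rename("purity").to_csv(path, sep="\t", index_label="sample_id")


def read_clinical_table(path: str | Path) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return ClinicalTable(df)


def write_clinical_table(table: ClinicalTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", index_label="sample_id")


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102 - numpy/pandas to plain JSON
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (pd.Series,)):
            return o.to_dict()
        if isinstance(o, (pd.Index,)):
            return list(o)
        if isinstance(o, frozenset):
            return sorted(o)
        return super().default(o)


def write_report(report: Mapping, path: str | Path) -> None:
    """Write the pipeline report as a single JSON document."""
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=True, cls=_ReportEncoder)
        handle.write("\n")
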