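"""Tabular I/O and between-array normalization for two-group expression matrices.

The pipeline's substrate is a probes × samples intensity matrix with a
sample → group mapping (``control`` vs ``treated``) plus a per-probe
annotation table carrying the probe class (lncRNA/mRNA) and genomic locus.
Everything is plain TSV; coordinates are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTROL = "control"
TREATED = "treated"
GROUPS = (CONTROL, TREATED)

ANNOTATION_COLUMNS = [
    "seqname",
    "gene_symbol",
    "probe_class",
    "rna_length",
    "chrom",
    "start",
    "end",
    "strand",
]


class ParseError(ValueError):
    """A file violated the expected tabular contract."""


@dataclass
class ExpressionMatrix:
    """Probes × samples intensity matrix with group labels and a scale flag.

    ``values`` is a DataFrame indexed by probe id with sample-id columns.
    ``scale`` is ``"linear"`` (positive intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    groups: dict[str, str]
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.validate()

    # -- contract ---------------------------------------------------------
    def validate(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ParseError(f"duplicate probe id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ParseError(f"duplicate sample id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.groups]
        if missing:
            raise ParseError(f"samples missing from group map: {missing}")
        bad = set(self.groups.values()) - set(GROUPS)
        if bad:
            raise ParseError(f"unknown group labels: {sorted(bad)}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise ParseError("non-finite expression values")
        if self.scale == "linear" and (arr <= 0).any():
            raise ValueError("linear-scale values must be positive")

    # -- convenience ------------------------------------------------------
    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in_group(group)]

    def subset(self, probes) -> "ExpressionMatrix":
        return replace(self, values=self.values.loc[list(probes)])

    # -- I/O --------------------------------------------------------------
    def write_tsv(self, matrix_path, groups_path=None) -> None:
        out = self.values.copy()
        out.index.name = "probe_id"
        out.to_csv(matrix_path, sep="\t", float_format="%.10g")
        if groups_path is not None:
            pd.Series(self.groups, name="group").rename_axis("sample_id").to_csv(
                groups_path, sep="\t"
            )


def read_group_map(path) -> dict[str, str]:
    """Read a two-column TSV (sample_id, group) into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "group"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns sample_id, group")
    return dict(zip(df["sample_id"], df["group"]))


def read_expression_matrix(path, group_map: dict[str, str], scale: str = "linear") -> ExpressionMatrix:
    """Read a probe × sample TSV (first column probe id, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        values = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression cell ({exc})") from exc
    try:
        return ExpressionMatrix(values=values, groups=dict(group_map), scale=scale)
    except (ParseError, ValueError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


def log2_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Base-2 log of a linear-scale matrix; flips the scale flag."""
    if matrix.scale != "linear":
        raise ValueError("log2_transform expects a linear-scale matrix")
    arr = matrix.values.to_numpy(dtype=float)
    if (arr <= 0).any():
        raise ValueError("log2 undefined for non-positive values")
    return replace(matrix, values=np.log2(matrix.values), scale="log2")


def linear_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`log2_transform`."""
    if matrix.scale != "log2":
        raise ValueError("linear_transform expects a log2-scale matrix")
    return replace(matrix, values=2.0 ** matrix.values, scale="linear")


def as_log2(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return matrix if matrix.scale == "log2" else log2_transform(matrix)


def as_linear(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return matrix if matrix.scale == "linear" else linear_transform(matrix)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's sorted values are replaced by the row means of the sorted
    input columns; ties receive the mean of their would-be quantile values
    (average ranks interpolated into the reference distribution). Within-
    column rank order is preserved.
    """
    X = matrix.values.to_numpy(dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    positions = np.arange(1, n + 1, dtype=float)
    for j in range(m):
        ranks = pd.Series(X[:, j]).rank(method="average").to_numpy()
        out[:, j] = np.interp(ranks, positions, reference)
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values)


def median_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each column's median (log2 scale): a lighter alternative."""
    values = matrix.values - matrix.values.median(axis=0)
    return replace(matrix, values=values)


NORMALIZERS = {
    "none": lambda m: m,
    "quantile": quantile_normalize,
    "median_center": median_center,
}


def normalize(matrix: ExpressionMatrix, method: str = "quantile") -> ExpressionMatrix:
    if method not in NORMALIZERS:
        raise ValueError(f"unknown normalization {method!r}; choose from {sorted(NORMALIZERS)}")
    return NORMALIZERS[method](matrix)


@dataclass
class ProbeAnnotation:
    """Per-probe metadata: transcript id, gene symbol, class and genomic locus.

    ``table`` is indexed by probe id with columns ``seqname, gene_symbol,
    probe_class, rna_length, chrom, start, end, strand``. ``start <= end``,
    1-based inclusive. ``probe_class`` is ``lncRNA`` or ``mRNA``; missing
    gene symbols are empty strings (such probes stay in DE analysis but are
    excluded from enrichment universes).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ParseError(f"annotation missing columns: {missing}")
        self.table.index.name = "probe_id"
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ParseError(f"duplicate probe id {dup!r} in annotation")
        bad = set(self.table["probe_class"]) - {"lncRNA", "mRNA"}
        if bad:
            raise ParseError(f"unknown probe_class values: {sorted(bad)}")
        located = self.table.dropna(subset=["start", "end"])
        if (located["start"] > located["end"]).any():
            bad_id = located.index[located["start"] > located["end"]][0]
            raise ParseError(f"start > end for probe {bad_id!r}")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    def probes_of_class(self, probe_class: str) -> list[str]:
        return list(self.table.index[self.table["probe_class"] == probe_class])

    def gene_symbol(self, probe: str) -> str:
        return str(self.table.at[probe, "gene_symbol"])

    def locus(self, probe: str):
        """(chrom, start, end) for a probe, or None if unlocated."""
        row = self.table.loc[probe]
        if pd.isna(row["start"]) or pd.isna(row["end"]) or not row["chrom"]:
            return None
        return str(row["chrom"]), int(row["start"]), int(row["end"])

    def symbols_for(self, probes) -> list[str]:
        """Unique, order-preserving non-empty gene symbols for an iterable of probes."""
        seen: dict[str, None] = {}
        for p in probes:
            sym = self.gene_symbol(p)
            if sym and sym not in seen:
                seen[sym] = None
        return list(seen)

    def write_tsv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "probe_id"
        out.to_csv(path, sep="\t")


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        dtype={"chrom": str, "gene_symbol": str, "strand": str},
        keep_default_na=False,
        na_values=[""],
    )
    df.index = df.index.astype(str)
    df["gene_symbol"] = df["gene_symbol"].fillna("")
    return ProbeAnnotation(table=df)
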