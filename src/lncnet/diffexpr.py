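"""Two-group differential-expression screening and heatmap ordering.

The screen follows the classic microarray volcano recipe: fold change is
the ratio of linear-scale group means, always reported >= 1 with an
Up/Down regulation label; significance is a two-sided Student's t-test on
log2 intensities; probes are called differentially expressed when fold
change strictly exceeds 2.0 and the raw p-value is strictly below 0.05.
Benjamini-Hochberg FDR is reported alongside but never used for filtering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .array_io import CONTROL, TREATED, ExpressionMatrix, as_linear, as_log2

logger = logging.getLogger(__name__)

UP = "Up"
DOWN = "Down"

#: smallest positive double, reported instead of an exact zero p-value
TINY_P = np.nextafter(0.0, 1.0)

TOP_TABLE_COLUMNS = [
    "Probe name",
    "Regulation",
    "Seqname",
    "Gene Symbol",
    "RNA length",
    "chrom",
    "Fold change",
    "P-value",
]


def _folded_ratio(ratio: np.ndarray):
    """Map raw treated/control ratios to (fold >= 1, Up/Down).

    A ratio of exactly 1 is labelled Up by tie-break; it can never pass a
    fold-change filter, so the label is inert.
    """
    up = ratio >= 1.0
    fc = np.where(up, ratio, 1.0 / ratio)
    regulation = np.where(up, UP, DOWN)
    return fc, regulation


def group_fold_change(matrix: ExpressionMatrix, probe: str) -> tuple[float, str]:
    """Fold change for one probe: treated/control linear-mean ratio, folded to >= 1."""
    linear = as_linear(matrix)
    mc = float(linear.group_values(CONTROL).loc[probe].mean())
    mt = float(linear.group_values(TREATED).loc[probe].mean())
    if mc <= 0 or mt <= 0:
        raise ValueError(f"non-positive group mean for probe {probe!r}")
    fc, reg = _folded_ratio(np.array([mt / mc]))
    return float(fc[0]), str(reg[0])


def _pooled_t(a: np.ndarray, b: np.ndarray, variant: str):
    """Vectorized two-sided t-test on rows of a (treated) vs b (control).

    Zero-variance rows are resolved by policy: equal means -> p = 1,
    unequal means -> smallest positive double with a warning.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("t-test needs >= 2 samples per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=(variant == "pooled"))
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    if degenerate.any():
        equal = np.isclose(a.mean(axis=1), b.mean(axis=1))
        p = np.where(degenerate & equal, 1.0, p)
        if (degenerate & ~equal).any():
            logger.warning(
                "%d probe(s) with zero pooled variance and unequal means; "
                "reporting smallest positive p",
                int((degenerate & ~equal).sum()),
            )
            p = np.where(degenerate & ~equal, TINY_P, p)
    return np.clip(np.nan_to_num(p, nan=1.0), TINY_P, 1.0)


def two_group_ttest(matrix: ExpressionMatrix, probe: str, variant: str = "pooled") -> float:
    """Two-sided Student's t p-value for one probe, computed on log2 values."""
    log2 = as_log2(matrix)
    a = log2.group_values(TREATED).loc[[probe]].to_numpy(dtype=float)
    b = log2.group_values(CONTROL).loc[[probe]].to_numpy(dtype=float)
    return float(_pooled_t(a, b, variant)[0])


def differential_expression(
    matrix: ExpressionMatrix,
    variant: str = "pooled",
    fc_mode: str = "mean_ratio",
) -> pd.DataFrame:
    """Full per-probe DE table.

    Returns a DataFrame indexed by probe id with columns ``fold_change``
    (>= 1), ``regulation`` (Up/Down), ``p_value``, ``fdr`` (Benjamini-
    Hochberg), ``mean_control``, ``mean_treated`` (linear scale).

    ``fc_mode``: ``mean_ratio`` (default; ratio of linear group means) or
    ``log2_diff`` (2 ** difference of log2 group means).
    """
    linear = as_linear(matrix)
    log2 = as_log2(matrix)
    mc = linear.group_values(CONTROL).mean(axis=1).to_numpy()
    mt = linear.group_values(TREATED).mean(axis=1).to_numpy()
    if fc_mode == "mean_ratio":
        ratio = mt / mc
    elif fc_mode == "log2_diff":
        dlog = log2.group_values(TREATED).mean(axis=1) - log2.group_values(CONTROL).mean(axis=1)
        ratio = 2.0 ** dlog.to_numpy()
    else:
        raise ValueError(f"unknown fc_mode {fc_mode!r}")
    fc, regulation = _folded_ratio(ratio)
    p = _pooled_t(
        log2.group_values(TREATED).to_numpy(dtype=float),
        log2.group_values(CONTROL).to_numpy(dtype=float),
        variant,
    )
    fdr = bh_adjust(p)
    return pd.DataFrame(
        {
            "fold_change": fc,
            "regulation": regulation,
            "p_value": p,
            "fdr": fdr,
            "mean_control": mc,
            "mean_treated": mt,
        },
        index=matrix.values.index,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def volcano_filter(
    de_table: pd.DataFrame, fc_threshold: float = 2.0, p_threshold: float = 0.05
) -> tuple[set[str], set[str]]:
    """Volcano rule: fold change strictly > threshold AND p strictly < threshold.

    Boundary values (fold change exactly 2.0, p exactly 0.05) are excluded,
    matching the printed strict inequalities.
    """
    passing = (de_table["fold_change"] > fc_threshold) & (de_table["p_value"] < p_threshold)
    up = set(de_table.index[passing & (de_table["regulation"] == UP)])
    down = set(de_table.index[passing & (de_table["regulation"] == DOWN)])
    return up, down


def summarize_de(up_set, down_set) -> dict[str, int]:
    """DE count summary; ``total`` is by construction ``up + down``."""
    up, down = len(set(up_set)), len(set(down_set))
    return {"up": up, "down": down, "total": up + down}


def top_table(
    de_table: pd.DataFrame,
    annotation,
    n_up: int,
    n_down: int,
) -> pd.DataFrame:
    """Top-N up- and down-regulated records in publication column layout.

    Sorted by descending fold change within each direction; ties broken by
    ascending p-value, then lexicographic probe id.
    """
    if n_up < 0 or n_down < 0:
        raise ValueError("n_up and n_down must be >= 0")
    blocks = []
    for direction, n in ((UP, n_up), (DOWN, n_down)):
        sub = de_table[de_table["regulation"] == direction].copy()
        sub["_probe"] = sub.index
        sub = sub.sort_values(
            ["fold_change", "p_value", "_probe"], ascending=[False, True, True]
        ).head(n)
        blocks.append(sub)
    ranked = pd.concat(blocks) if blocks else de_table.iloc[:0]
    ann = annotation.table
    records = pd.DataFrame(
        {
            "Probe name": ranked.index,
            "Regulation": ranked["regulation"].to_numpy(),
            "Seqname": ann.loc[ranked.index, "seqname"].to_numpy(),
            "Gene Symbol": ann.loc[ranked.index, "gene_symbol"].to_numpy(),
            "RNA length": ann.loc[ranked.index, "rna_length"].to_numpy(),
            "chrom": ann.loc[ranked.index, "chrom"].to_numpy(),
            "Fold change": ranked["fold_change"].to_numpy(),
            "P-value": ranked["p_value"].to_numpy(),
        }
    ).reset_index(drop=True)
    return records


@dataclass
class ClusterOrder:
    """Leaf orders and merge trees from agglomerative clustering."""

    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None = field(default=None, repr=False)
    col_linkage: np.ndarray | None = field(default=None, repr=False)
    dropped_rows: list[str] = field(default_factory=list)


def _zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sd = values.std(axis=1, ddof=1)
    constant = list(values.index[sd == 0])
    kept = values.loc[sd > 0]
    z = kept.sub(kept.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return z, constant


def _linkage_order(data: np.ndarray, labels, metric: str, method: str):
    if data.shape[0] < 2:
        return list(labels), None
    dist = pdist(data, metric=metric)
    Z = hierarchy.linkage(dist, method=method)
    order = hierarchy.leaves_list(Z)
    return [labels[i] for i in order], Z


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    axis: str = "both",
    metric: str = "correlation",
    method: str = "average",
    standardize: bool = True,
) -> ClusterOrder:
    """Agglomerative clustering order for heatmaps.

    By default rows are z-scored on log2 values first and constant rows
    (undefined under the correlation metric) are dropped with a warning.
    Defaults mirror common microarray practice: 1 - Pearson distance,
    average linkage. Deterministic given input order.
    """
    if axis not in ("rows", "cols", "both"):
        raise ValueError(f"unknown axis {axis!r}")
    log2 = as_log2(matrix)
    if standardize or metric == "correlation":
        z, dropped = _zscore_rows(log2.values) if standardize else (log2.values, [])
        if metric == "correlation" and not standardize:
            sd = z.std(axis=1, ddof=1)
            dropped = list(z.index[sd == 0])
            z = z.loc[sd > 0]
    else:
        z, dropped = log2.values, []
    if dropped:
        logger.warning("dropped %d constant row(s) before clustering", len(dropped))
    if z.shape[0] < 2:
        raise ValueError("need >= 2 non-constant rows to cluster")
    row_order, col_order = list(z.index), list(z.columns)
    row_Z = col_Z = None
    if axis in ("rows", "both"):
        row_order, row_Z = _linkage_order(z.to_numpy(), list(z.index), metric, method)
    if axis in ("cols", "both"):
        col_order, col_Z = _linkage_order(z.to_numpy().T, list(z.columns), metric, method)
    return ClusterOrder(
        row_order=row_order,
        col_order=col_order,
        row_linkage=row_Z,
        col_linkage=col_Z,
        dropped_rows=dropped,
    )


def write_de_table(de_table: pd.DataFrame, annotation, path) -> None:
    """Full DE table as TSV with publication column names plus fdr/means."""
    ann = annotation.table
    out = pd.DataFrame(
        {
            "Probe name": de_table.index,
            "Regulation": de_table["regulation"].to_numpy(),
            "Seqname": ann.loc[de_table.index, "seqname"].to_numpy(),
            "Gene Symbol": ann.loc[de_table.index, "gene_symbol"].to_numpy(),
            "RNA length": ann.loc[de_table.index, "rna_length"].to_numpy(),
            "chrom": ann.loc[de_table.index, "chrom"].to_numpy(),
            "Fold change": de_table["fold_change"].to_numpy(),
            "P-value": de_table["p_value"].to_numpy(),
            "FDR": de_table["fdr"].to_numpy(),
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")
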