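"""Coding-non-coding (CNC) co-expression network construction.

Differentially expressed lncRNA and mRNA probes are paired across all
samples pooled (both groups); an edge is drawn when the absolute Pearson
correlation is at least the threshold (default |r| >= 0.9, inclusive —
"no less than"). The result is a bipartite graph whose negative edges are
retained with sign, matching how such networks draw positive and negative
correlations separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .array_io import ExpressionMatrix, as_log2
from .diffexpr import TINY_P

logger = logging.getLogger(__name__)

EDGE_COLUMNS = ["lnc_probe", "mrna_probe", "r", "p_value", "sign"]
NODE_COLUMNS = ["id", "kind", "regulation", "degree"]


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p (t with n-2 df).

    |r| = 1 is reported with the smallest positive p rather than 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantVectorError("constant vector: correlation undefined")
    r, p = stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0 or p == 0.0:
        p = TINY_P
    return r, float(p)


def correlation_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r via t = r sqrt((n-2)/(1-r^2)), df = n-2."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    return np.clip(np.where(np.isfinite(t), p, 0.0), TINY_P, 1.0)


def correlation_matrix(matrix: ExpressionMatrix, probes_a, probes_b):
    """(r, p) matrices between two probe lists across all pooled samples.

    Constant probes are dropped with a warning; returns the retained lists
    alongside the matrices.
    """
    log2 = as_log2(matrix)
    n = len(log2.sample_ids)

    def _keep(probes):
        vals = log2.values.loc[list(probes)]
        sd = vals.std(axis=1, ddof=1)
        dropped = list(vals.index[sd == 0])
        if dropped:
            logger.warning("dropped %d constant probe(s) from correlation", len(dropped))
        return list(vals.index[sd > 0])

    keep_a, keep_b = _keep(probes_a), _keep(probes_b)
    if not keep_a or not keep_b:
        return keep_a, keep_b, np.empty((len(keep_a), len(keep_b))), np.empty((len(keep_a), len(keep_b)))
    A = log2.values.loc[keep_a].to_numpy(dtype=float)
    B = log2.values.loc[keep_b].to_numpy(dtype=float)
    A = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    B = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    R = np.clip(A @ B.T / n, -1.0, 1.0)
    P = correlation_p(R, n)
    return keep_a, keep_b, R, P


@dataclass
class CncNetwork:
    """Bipartite lncRNA-mRNA co-expression network.

    ``edges`` has columns lnc_probe, mrna_probe, r, p_value, sign;
    ``nodes`` has id, kind, regulation, degree. Only endpoints of retained
    edges appear as nodes.
    """

    edges: pd.DataFrame = field(repr=False)
    nodes: pd.DataFrame = field(repr=False)
    r_threshold: float = 0.9

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for _, row in self.nodes.iterrows():
            g.add_node(row["id"], kind=row["kind"], regulation=row["regulation"])
        for _, row in self.edges.iterrows():
            g.add_edge(row["lnc_probe"], row["mrna_probe"], r=row["r"], p=row["p_value"], sign=row["sign"])
        return g


def build_cnc_network(
    matrix: ExpressionMatrix,
    lnc_up,
    lnc_down,
    mrna_up,
    mrna_down,
    r_threshold: float = 0.9,
) -> CncNetwork:
    """Score all DE-lncRNA x DE-mRNA pairs; keep |r| >= r_threshold (inclusive)."""
    lnc_reg = {p: "Up" for p in lnc_up} | {p: "Down" for p in lnc_down}
    mrna_reg = {p: "Up" for p in mrna_up} | {p: "Down" for p in mrna_down}
    lncs, mrnas = sorted(lnc_reg), sorted(mrna_reg)
    if not lncs or not mrnas:
        return CncNetwork(
            edges=pd.DataFrame(columns=EDGE_COLUMNS),
            nodes=pd.DataFrame(columns=NODE_COLUMNS),
            r_threshold=r_threshold,
        )
    keep_l, keep_m, R, P = correlation_matrix(matrix, lncs, mrnas)
    rows = []
    if len(keep_l) and len(keep_m):
        ii, jj = np.nonzero(np.abs(R) >= r_threshold)
        for i, j in zip(ii, jj):
            r = float(R[i, j])
            rows.append((keep_l[i], keep_m[j], r, float(P[i, j]), "positive" if r > 0 else "negative"))
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    node_rows = []
    if len(edges):
        degree_l = edges["lnc_probe"].value_counts()
        degree_m = edges["mrna_probe"].value_counts()
        for p in sorted(degree_l.index):
            node_rows.append((p, "lncRNA", lnc_reg[p], int(degree_l[p])))
        for p in sorted(degree_m.index):
            node_rows.append((p, "mRNA", mrna_reg[p], int(degree_m[p])))
    nodes = pd.DataFrame(node_rows, columns=NODE_COLUMNS)
    return CncNetwork(edges=edges, nodes=nodes, r_threshold=r_threshold)


def export_network(network: CncNetwork, node_path, edge_path, sif_path) -> None:
    """Node/edge TSVs plus a Cytoscape SIF (``lnc pos|neg mrna`` triples)."""
    network.nodes.to_csv(node_path, sep="\t", index=False)
    network.edges.to_csv(edge_path, sep="\t", index=False, float_format="%.10g")
    with open(sif_path, "w") as fh:
        for _, row in network.edges.iterrows():
            rel = "pos" if row["sign"] == "positive" else "neg"
            fh.write(f"{row['lnc_probe']}\t{rel}\t{row['mrna_probe']}\n")


def read_edge_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"lnc_probe": str, "mrna_probe": str, "sign": str})
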