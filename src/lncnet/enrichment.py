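"""Fisher's-exact (hypergeometric upper-tail) gene-set over-representation.

Given a query gene list, a background universe and a GMT-style collection
of GO terms / pathways, each term is scored by P(X >= k) under the
hypergeometric distribution with parameters (N = universe size, K = term
size in universe, n = query size in universe). This equals the one-sided
(greater) Fisher's exact p on the corresponding 2x2 table. Only
over-representation is tested; raw p ranks the output (FDR reported as a
column only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
import numpy as np

logger = logging.getLogger(__name__)

CATEGORIES = (
    "biological_process",
    "cellular_component",
    "molecular_function",
    "pathway",
)

RESULT_COLUMNS = ["term_id", "name", "category", "k", "K", "n", "N", "p_value", "fdr", "neg_log10_p"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    category: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class GeneSetCollection:
    """term id -> GeneSet; round-trips through GMT.

    GMT convention here: one line per term, fields term id, description,
    then member gene symbols, tab-separated. The description field encodes
    the category as ``category:name``.
    """

    terms: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.terms)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.terms.values():
            out |= gs.genes
        return out

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        terms: dict[str, GeneSet] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 fields")
                term_id, desc = fields[0], fields[1]
                category, _, name = desc.partition(":")
                if category not in CATEGORIES:
                    category, name = "pathway", desc
                terms[term_id] = GeneSet(
                    name=name or term_id, category=category, genes=frozenset(g for g in fields[2:] if g)
                )
        return cls(terms=terms)

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for term_id, gs in self.terms.items():
                genes = "\t".join(sorted(gs.genes))
                fh.write(f"{term_id}\t{gs.category}:{gs.name}\t{genes}\n")


def fisher_enrichment(
    query, sets: GeneSetCollection, universe
) -> pd.DataFrame:
    """Score every term with >= 1 universe member; sorted by ascending p.

    Query symbols outside the universe are dropped (with a logged count);
    duplicate symbols are collapsed before testing.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    query_set = set(query)
    dropped = query_set - universe_set
    if dropped:
        logger.info("dropped %d query gene(s) outside the universe", len(dropped))
    query_set &= universe_set
    N, n = len(universe_set), len(query_set)
    rows = []
    for term_id, gs in sets.terms.items():
        members = gs.genes & universe_set
        K = len(members)
        if K == 0:
            continue
        k = len(members & query_set)
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
        rows.append((term_id, gs.name, gs.category, k, K, n, N, p))
    result = pd.DataFrame(rows, columns=RESULT_COLUMNS[:8])
    if len(result):
        result["fdr"] = bh_adjust(result["p_value"].to_numpy())
        result["neg_log10_p"] = -np.log10(result["p_value"])
        result = result.sort_values(["p_value", "term_id"], kind="mergesort").reset_index(drop=True)
    else:
        result["fdr"] = pd.Series(dtype=float)
        result["neg_log10_p"] = pd.Series(dtype=float)
    return result


def top_terms(results: pd.DataFrame, category: str, n: int) -> pd.DataFrame:
    """The n smallest-p results within a category; ties broken by larger
    overlap k, then term id."""
    if n < 0:
        raise ValueError("n must be >= 0")
    sub = results[results["category"] == category].copy()
    sub = sub.sort_values(["p_value", "k", "term_id"], ascending=[True, False, True], kind="mergesort")
    return sub.head(n).reset_index(drop=True)


def write_enrichment(results: pd.DataFrame, path) -> None:
    results.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")
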