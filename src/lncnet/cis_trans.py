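"""Cis/trans classification of co-expressed lncRNA-mRNA pairs.

Candidate pairs are first filtered on correlation (|r| strictly > 0.85
and p strictly < 0.01 by default), then classified by genomic distance:
same chromosome with an inter-locus gap within the cis window (default
300 kb) is *cis*; everything else — a gap beyond the trans floor (default
100 kb) or a different chromosome — is *trans*. A pair inside the
ambiguous 100-300 kb zone satisfies both printed rules and resolves to
cis by precedence (proximity is the stronger claim); the count of such
pairs is logged.

Distance is the gap between full transcript loci (1-based inclusive),
not TSS-to-TSS; overlapping or abutting loci have gap 0. ``tss`` mode is
available as a config alternative.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .array_io import ExpressionMatrix, ProbeAnnotation
from .coexpression import correlation_matrix

logger = logging.getLogger(__name__)

CIS = "cis"
TRANS = "trans"

PAIR_COLUMNS = ["lnc_probe", "mrna_probe", "r", "p_value"]
ASSIGNMENT_COLUMNS = [
    "lnc_probe",
    "mrna_probe",
    "gene_symbol",
    "r",
    "p_value",
    "chrom_lnc",
    "chrom_gene",
    "gap",
    "klass",
]


def _check_locus(locus) -> tuple[str, int, int]:
    try:
        chrom, start, end = locus
        start, end = int(start), int(end)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"malformed locus {locus!r}") from exc
    if start > end:
        raise ValueError(f"locus start > end: {locus!r}")
    return str(chrom), start, end


def genomic_gap(locus_a, locus_b, mode: str = "gap"):
    """Distance in bp between two loci, or None for different chromosomes.

    ``gap`` mode: max(0, max(starts) - min(ends)) — 0 for overlapping or
    abutting intervals. ``tss`` mode: |start_a - start_b|. Symmetric.
    """
    chrom_a, start_a, end_a = _check_locus(locus_a)
    chrom_b, start_b, end_b = _check_locus(locus_b)
    if chrom_a != chrom_b:
        return None
    if mode == "gap":
        return max(0, max(start_a, start_b) - min(end_a, end_b))
    if mode == "tss":
        return abs(start_a - start_b)
    raise ValueError(f"unknown distance mode {mode!r}")


def coexpressed_pairs(
    matrix: ExpressionMatrix,
    lnc_set,
    gene_set,
    r_threshold: float = 0.85,
    p_threshold: float = 0.01,
) -> pd.DataFrame:
    """lncRNA-mRNA pairs with |r| strictly > r_threshold and p strictly < p_threshold."""
    lncs, genes = sorted(set(lnc_set)), sorted(set(gene_set))
    if not lncs or not genes:
        return pd.DataFrame(columns=PAIR_COLUMNS)
    keep_l, keep_g, R, P = correlation_matrix(matrix, lncs, genes)
    rows = []
    if len(keep_l) and len(keep_g):
        ii, jj = np.nonzero((np.abs(R) > r_threshold) & (P < p_threshold))
        for i, j in zip(ii, jj):
            rows.append((keep_l[i], keep_g[j], float(R[i, j]), float(P[i, j])))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def classify_targets(
    pairs: pd.DataFrame,
    annotation: ProbeAnnotation,
    cis_window: int = 300_000,
    trans_floor: int = 100_000,
    distance_mode: str = "gap",
) -> pd.DataFrame:
    """Assign each filtered pair a cis or trans class.

    cis: same chromosome and gap <= cis_window. trans: otherwise (gap >
    trans_floor, or different chromosomes). cis_window must exceed
    trans_floor so every pair lands in exactly one class. Pairs whose
    members lack a locus are skipped with a logged count.
    """
    if cis_window <= trans_floor:
        raise ValueError("cis_window must be greater than trans_floor")
    rows = []
    skipped = ambiguous = 0
    for _, pair in pairs.iterrows():
        lnc, gene = pair["lnc_probe"], pair["mrna_probe"]
        locus_l, locus_g = annotation.locus(lnc), annotation.locus(gene)
        if locus_l is None or locus_g is None:
            skipped += 1
            continue
        gap = genomic_gap(locus_l, locus_g, mode=distance_mode)
        if gap is not None and gap <= cis_window:
            klass = CIS
            if gap > trans_floor:
                ambiguous += 1
        else:
            klass = TRANS
        rows.append(
            (
                lnc,
                gene,
                annotation.gene_symbol(gene),
                pair["r"],
                pair["p_value"],
                locus_l[0],
                locus_g[0],
                gap if gap is not None else pd.NA,
                klass,
            )
        )
    if skipped:
        logger.warning("skipped %d pair(s) lacking a genomic locus", skipped)
    if ambiguous:
        logger.info(
            "%d pair(s) in the %d-%d bp zone satisfied both rules; classified cis",
            ambiguous,
            trans_floor,
            cis_window,
        )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def target_gene_lists(assignments: pd.DataFrame) -> tuple[list[str], list[str]]:
    """De-duplicated gene-symbol lists (cis, trans), ready for enrichment.

    A gene classified cis for one lncRNA and trans for another appears in
    both lists; within a list each symbol appears once, order-preserving.
    """

    def _unique(symbols) -> list[str]:
        seen: dict[str, None] = {}
        for s in symbols:
            if s and s not in seen:
                seen[s] = None
        return list(seen)

    cis = _unique(assignments.loc[assignments["klass"] == CIS, "gene_symbol"])
    trans = _unique(assignments.loc[assignments["klass"] == TRANS, "gene_symbol"])
    return cis, trans


def write_assignments(assignments: pd.DataFrame, path) -> None:
    assignments.to_csv(path, sep="\t", index=False, float_format="%.10g")
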