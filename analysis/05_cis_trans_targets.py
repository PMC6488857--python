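"""Classify co-expressed lncRNA-mRNA pairs (|r| > 0.85, p < 0.01) as cis
(same chromosome, gap <= 300 kb) or trans, and enrich both gene lists."""

import pandas as pd

from _common import DATA_DIR, load_dataset, results_dir
from lncnet.array_io import as_log2, quantile_normalize
from lncnet.cis_trans import classify_targets, coexpressed_pairs, target_gene_lists, write_assignments
from lncnet.enrichment import fisher_enrichment, read_gene_list, write_enrichment, write_gene_list
from lncnet.pipeline import default_universe

if __name__ == "__main__":
    matrix, annotation, gene_sets = load_dataset()
    out = results_dir()
    norm = quantile_normalize(as_log2(matrix))
    lnc_de = read_gene_list(out / "up_lnc.txt") + read_gene_list(out / "down_lnc.txt")
    mrna_de = read_gene_list(out / "up_mrna.txt") + read_gene_list(out / "down_mrna.txt")
    pairs = coexpressed_pairs(norm, lnc_de, mrna_de)
    assignments = classify_targets(pairs, annotation)
    write_assignments(assignments, out / "cis_trans_assignments.tsv")
    cis_genes, trans_genes = target_gene_lists(assignments)
    write_gene_list(cis_genes, out / "cis_genes.txt")
    write_gene_list(trans_genes, out / "trans_genes.txt")
    n_cis = int((assignments["klass"] == "cis").sum())
    print(f"{len(pairs)} co-expressed pairs -> {n_cis} cis, {len(assignments) - n_cis} trans")
    print(f"unique target genes: {len(cis_genes)} cis, {len(trans_genes)} trans")

    planted = set(map(tuple, pd.read_csv(DATA_DIR / "truth_cis.tsv", sep="\t")[["lnc_probe", "mrna_probe"]].to_numpy()))
    got = set(zip(assignments.loc[assignments["klass"] == "cis", "lnc_probe"],
                  assignments.loc[assignments["klass"] == "cis", "mrna_probe"]))
    print(f"planted cis pairs recovered: {len(got & planted)}/{len(planted)}")

    universe = default_universe(annotation, gene_sets)
    for tag, genes in (("cis", cis_genes), ("trans", trans_genes)):
        res = fisher_enrichment(genes, gene_sets, universe)
        write_enrichment(res, out / f"enrichment_{tag}.tsv")
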