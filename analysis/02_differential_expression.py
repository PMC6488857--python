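"""Volcano-filter DE screening: log2 + quantile normalization, pooled
t-test, fold-change > 2 and p < 0.05, ranked top tables per probe class."""

import pandas as pd

from _common import DATA_DIR, load_dataset, results_dir
from lncnet.array_io import as_log2, quantile_normalize
from lncnet.diffexpr import (
    differential_expression,
    hierarchical_cluster,
    summarize_de,
    top_table,
    volcano_filter,
    write_de_table,
)
from lncnet.enrichment import write_gene_list

if __name__ == "__main__":
    matrix, annotation, _ = load_dataset()
    out = results_dir()
    norm = quantile_normalize(as_log2(matrix))
    de = differential_expression(norm)

    truth = set(pd.read_csv(DATA_DIR / "truth_de.tsv", sep="\t")["probe_id"])
    all_de = set()
    for klass, tag in (("lncRNA", "lnc"), ("mRNA", "mrna")):
        sub = de.loc[annotation.probes_of_class(klass)]
        up, down = volcano_filter(sub)
        all_de |= up | down
        s = summarize_de(up, down)
        write_de_table(sub, annotation, out / f"de_{tag}.tsv")
        top = top_table(sub.loc[sorted(up | down)], annotation, 10, 10)
        top.to_csv(out / f"top_{tag}.tsv", sep="\t", index=False, float_format="%.6g")
        write_gene_list(sorted(up), out / f"up_{tag}.txt")
        write_gene_list(sorted(down), out / f"down_{tag}.txt")
        print(f"{klass}: {s['up']} up + {s['down']} down = {s['total']} DE probes")

    recovery = len(all_de & truth) / len(truth)
    print(f"planted-DE recovery at FC>2, p<0.05: {100 * recovery:.1f}% "
          f"({len(all_de - truth)} calls outside the planted set)")

    order = hierarchical_cluster(norm.subset(sorted(all_de)))
    with open(out / "cluster_order.tsv", "w") as fh:
        fh.write("axis\tid\n")
        for rid in order.row_order:
            fh.write(f"row\t{rid}\n")
        for cid in order.col_order:
            fh.write(f"col\t{cid}\n")
    print(f"heatmap ordering over {len(order.row_order)} DE probes written to cluster_order.tsv")
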