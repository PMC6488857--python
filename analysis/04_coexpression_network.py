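"""Build the coding-non-coding (CNC) network over the DE probes:
all lncRNA-mRNA pairs across the 10 pooled samples, |r| >= 0.9 kept."""

import pandas as pd

from _common import DATA_DIR, load_dataset, results_dir
from lncnet.array_io import as_log2, quantile_normalize
from lncnet.coexpression import build_cnc_network, export_network
from lncnet.enrichment import read_gene_list

if __name__ == "__main__":
    matrix, annotation, _ = load_dataset()
    out = results_dir()
    norm = quantile_normalize(as_log2(matrix))
    net = build_cnc_network(
        norm,
        read_gene_list(out / "up_lnc.txt"),
        read_gene_list(out / "down_lnc.txt"),
        read_gene_list(out / "up_mrna.txt"),
        read_gene_list(out / "down_mrna.txt"),
    )
    export_network(net, out / "cnc_nodes.tsv", out / "cnc_edges.tsv", out / "cnc.sif")
    pos = int((net.edges["sign"] == "positive").sum())
    print(f"CNC network: {len(net.nodes)} nodes, {net.n_edges} edges "
          f"({pos} positive, {net.n_edges - pos} negative)")
    if len(net.nodes):
        hub = net.nodes.sort_values("degree", ascending=False).iloc[0]
        print(f"highest-degree node: {hub['id']} ({hub['kind']}, degree {hub['degree']})")
    planted = set(map(tuple, pd.read_csv(DATA_DIR / "truth_edges.tsv", sep="\t")[["lnc_probe", "mrna_probe"]].to_numpy()))
    got = set(map(tuple, net.edges[["lnc_probe", "mrna_probe"]].to_numpy()))
    print(f"planted edges recovered: {len(got & planted)}/{len(planted)}")
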