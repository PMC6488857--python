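"""Generate the synthetic two-group lncRNA/mRNA array dataset.

Emulates the study design — 5 control vs 5 LPS-treated samples, 200
lncRNA + 300 mRNA probes — with 50 planted DE probes (log2FC ±2), three
co-expression modules (2 lncRNAs x 3 mRNAs each) and 5 cis-proximal
lncRNA-mRNA pairs. Raw tables go to scratch/data; the planted-truth
summary is echoed here.
"""

import pandas as pd

from _common import DATA_DIR, SEED, simulate

if __name__ == "__main__":
    simulate(SEED)
    truth_de = pd.read_csv(DATA_DIR / "truth_de.tsv", sep="\t")
    truth_edges = pd.read_csv(DATA_DIR / "truth_edges.tsv", sep="\t")
    truth_cis = pd.read_csv(DATA_DIR / "truth_cis.tsv", sep="\t")
    print(f"dataset written to {DATA_DIR} (seed {SEED})")
    print(f"planted DE probes: {len(truth_de)} "
          f"({(truth_de['direction'] == 'Up').sum()} up, {(truth_de['direction'] == 'Down').sum()} down)")
    print(f"planted co-expression edges: {len(truth_edges)} "
          f"({(truth_edges['sign'] == 'negative').sum()} negative)")
    print(f"planted cis pairs: {len(truth_cis)} (max gap {truth_cis['gap'].max()} bp)")
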