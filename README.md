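# lncnet

Analysis pipeline for two-group lncRNA/mRNA expression-microarray
studies, of the kind used to profile long non-coding RNA responses in an
LPS-induced acute-lung-injury mouse model (5 control vs 5 treated
animals). It implements, as a tested library plus numbered analysis
scripts:

1. **Differential expression** — volcano filtering on the linear
   fold change of group means (reported ≥ 1 with an Up/Down label) and a
   pooled Student's t-test on log2 intensities: a probe is called DE
   when FC > 2.0 and p < 0.05 (strict), with BH-FDR reported alongside;
   ranked top tables and hierarchical-clustering heatmap order.
2. **Gene-set enrichment** — Fisher's exact / hypergeometric upper tail
   P(X ≥ k) for GO terms and pathways from a GMT file, against the
   annotated-array universe.
3. **CNC network** — the coding–non-coding co-expression network over DE
   probes: Pearson correlation across all pooled samples, edges kept at
   |r| ≥ 0.9 (inclusive), signed, exported as node/edge TSV + Cytoscape
   SIF.
4. **Cis/trans targets** — co-expressed pairs (|r| > 0.85, p < 0.01)
   classified *cis* when the lncRNA and gene loci lie on one chromosome
   within a 300 kb gap, *trans* otherwise (beyond 100 kb or another
   chromosome).
5. **qRT-PCR validation** — cross-platform concordance as the Pearson r
   of signed natural-log fold changes (+ln FC for up, −ln FC for down),
   one point per probe.
6. **Synthetic data** — a seeded generator that emulates the study
   design with planted DE probes, planted co-expression modules
   (including negative edges) and planted cis-proximal pairs, returning
   truth tables so every stage's recovery can be measured.

See `docs/methods.md` for the statistical details and design rationale.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (raw tables under `scratch/data`, derived tables under
`results/`):

```bash
cd analysis
python 01_simulate.py
python 02_differential_expression.py
python 03_enrichment.py
python 04_coexpression_network.py
python 05_cis_trans_targets.py
python 06_qpcr_validation.py
```

Output of the run at the default seed:

```
dataset written to .../scratch/data (seed 7)
planted DE probes: 50 (25 up, 25 down)
planted co-expression edges: 18 (9 negative)
planted cis pairs: 5 (max gap 275795 bp)

lncRNA: 11 up + 10 down = 21 DE probes
mRNA: 15 up + 15 down = 30 DE probes
planted-DE recovery at FC>2, p<0.05: 100.0% (1 calls outside the planted set)

down-regulated (15 genes): top biological_process term TERM0000 p = 0.00188 (k/K = 5/15)

CNC network: 49 nodes, 189 edges (92 positive, 97 negative)
planted edges recovered: 18/18

352 co-expressed pairs -> 5 cis, 347 trans
planted cis pairs recovered: 5/5

qPCR panel: 10 lncRNAs (5 up, 5 down)
signed-ln fold-change concordance: r = 0.9803 (p = 6.42e-07)
```

Reading this: the volcano filter recalls all 50 planted DE probes with
one extra call (the `up + down = total` partition always holds); the
network recovers every planted module edge — the additional edges arise
because DE probes share the treatment pattern and genuinely correlate;
all 5 planted proximal pairs classify cis; and the two platforms'
fold changes agree at r ≈ 0.98 on the signed ln scale.

The same stages are available as a CLI for file-based use:

```bash
lncnet simulate --outdir data --seed 3
lncnet run --config pipeline.yaml     # normalize -> DE -> enrichment -> CNC -> cis/trans -> validation
```

with standalone subcommands `de`, `enrich`, `cnc`, `cistrans`,
`validate`, each a thin wrapper over the library.

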