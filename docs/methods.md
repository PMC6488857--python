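# Methods

`lncnet` implements the statistical core of a two-group lncRNA/mRNA
expression-microarray study — differential-expression screening by
volcano filtering, gene-set over-representation, coding–non-coding (CNC)
co-expression network inference, cis/trans target classification by
genomic distance, and cross-platform qRT-PCR validation — together with
a synthetic-data generator that plants each kind of structure so every
stage can be tested against known truth.

## Differential expression

Intensities are log2-transformed and normalized between arrays
(quantile normalization by default; `median_center` and `none` are
available). Raw-file normalization method choices vary between vendors'
software; quantile normalization is the conventional default for this
array era and is exposed as a switch rather than hard-coded.

Per probe, the fold change is the ratio of linear-scale group means
(treated/control), reported folded to ≥ 1 with an `Up`/`Down` label; a
ratio of exactly 1 is labelled `Up` by tie-break (it can never pass the
filter, so the label is inert). `fc_mode="log2_diff"` substitutes
2^(difference of log2 group means). Significance is a two-sided
Student's t-test on log2 values, pooled variance by default (df =
n₁+n₂−2), Welch as an option. Degenerate inputs are handled by policy:
zero variance in both groups with equal means gives p = 1; with unequal
means, the smallest positive double is reported with a warning. A probe
is called differentially expressed when fold change > 2.0 **strictly**
and p < 0.05 **strictly** — the boundary values are excluded, matching
the way such thresholds are printed. Benjamini–Hochberg FDR is computed
and reported per probe but never used for filtering, because the screen
is defined on raw p.

Heatmap ordering uses agglomerative clustering on row-z-scored log2
values, 1 − Pearson distance, average linkage; constant rows are dropped
with a warning. `standardize=False` clusters raw values (used for the
analytic test cases).

## Enrichment

Over-representation of a query gene list in GMT-declared GO terms and
pathways is the upper-tail hypergeometric probability P(X ≥ k) with
parameters (N = universe, K = term size in universe, n = query in
universe), identical to a one-sided (greater) Fisher's exact test on the
2×2 margins — a property the tests verify by exhaustive enumeration on
small tables. Only over-representation is tested. The default universe
is the array's annotated gene symbols that carry at least one term;
query symbols outside the universe are dropped with a logged count, and
duplicate symbols are collapsed before testing. Results are ranked by
raw p (FDR reported as a column only); ties in `top_terms` break by
larger overlap, then term id. No GO-DAG topology handling is attempted:
membership is whatever the GMT declares.

## CNC network

All DE-lncRNA × DE-mRNA pairs are scored by Pearson correlation across
the pooled samples (both groups, n = 10 at the default design) on
normalized log2 values — pooling is the only reading under which
treatment-driven co-expression is visible. An edge is kept when
|r| ≥ 0.9 **inclusive** ("no less than"), with sign retained, since
negatively correlated pairs are part of such networks. Correlation
p-values (t = r·√((n−2)/(1−r²)), df = n−2, two-sided) accompany edges
but are not filtered on in this module. Nodes are the endpoints of
retained edges, annotated with kind, regulation and degree; export is
node/edge TSV plus Cytoscape SIF. Constant probes, for which correlation
is undefined, are dropped with a warning.

Note that on a DE-restricted probe set the group-mean difference itself
induces correlation between unrelated DE probes (two probes shifted in
the same direction share the group pattern), so the network is denser
than the planted modules alone; planted-edge recovery is therefore
always measured against the generator's truth table, not against total
edge count.

## Cis/trans classification

Candidate lncRNA–mRNA pairs are first filtered on |r| > 0.85 **strict**
and p < 0.01 **strict** (the same filter for both classes). Distance is
the inter-interval gap between full transcript loci on 1-based inclusive
coordinates: same chromosome → max(0, max(starts) − min(ends));
different chromosomes → unlinked. The gap-based reading (rather than
TSS-to-TSS, available via `distance_mode="tss"`) is the most permissive
faithful interpretation of a symmetric "upstream and downstream" window;
strand is ignored accordingly. Classification: same chromosome with gap
≤ 300 kb → **cis**; otherwise (gap > 100 kb or different chromosome) →
**trans**. A pair in the ambiguous 100–300 kb zone satisfies both
printed rules and resolves to cis — proximity is the stronger claim —
with the count of such pairs logged. Candidate mRNAs default to the DE
set, consistent with the rest of the pipeline. Gene lists per class are
de-duplicated symbol lists ready for enrichment.

## qRT-PCR validation

Each platform's fold change is mapped to a **signed** natural-log value:
+ln(fc) for up-, −ln(fc) for down-regulation. Concordance is the Pearson
correlation of the signed values across probes, one point per probe. The
signed mapping is essential: an unsigned ln of ≥ 1 folds would discard
direction and could not show near-perfect concordance on a mixed up/down
panel. qPCR fold change is the ratio of group-mean relative quantities
(reference-gene-normalized), tested by the same pooled t policy on
ln-quantities. Concordance r is invariant to global rescaling of the
qPCR quantities, and equals 1 to machine precision in the noise-free
limit — both are tested.

## Synthetic data generator

The generator emulates the study design; its defaults are the study
conditions, chosen once:

| parameter | default | why |
|---|---|---|
| n_per_group | 5 | the emulated two-group design (5 vs 5 mice) |
| n_lnc_probes / n_mrna_probes | 200 / 300 | desk-scale stand-in for a mixed lncRNA/mRNA array |
| effect_log2fc | 2.0 | 4-fold planted shift, comfortably above the FC > 2 screen |
| noise_sd | 0.5 | log2-scale Gaussian array noise, a typical between-replicate SD |
| n_de_lnc / n_de_mrna | 20 / 30 | ~10% of probes DE, half up / half down |
| n_coexp_modules, module_size | 3, (2, 3) | 18 planted bipartite edges incl. negative ones |
| module_latent_sd | 0.5 | shared per-sample factor added to module members |
| module_noise_sd | noise_sd/10 | member idiosyncratic noise (see below) |
| n_cis_pairs, cis_max_gap | 5, 300 000 | planted proximal pairs within the cis window |
| genome | 5 × 100 Mb chromosomes | enough room that chance proximity is negligible |

Expression is generated on the log2 scale (baseline per probe uniform
on [6, 12], Gaussian noise) and exponentiated to linear intensities,
because reported fold changes are linear-scale ratios. DE probes get a
constant ±effect shift in the treated group. Module members are drawn
from the DE probes; their latent-factor loading sign follows their DE
direction, so modules mixing up- and down-regulated members produce the
negative edges the network must handle, and the DE pattern reinforces
rather than fights the planted correlation. Cis pairs reuse module edges
(so they pass the correlation filter) and relocate the mRNA onto the
lncRNA's chromosome at a uniform gap ≤ 300 kb.

**Why module members carry reduced idiosyncratic noise.** For two module
members x = L + ε, the population correlation is r = λ²/(λ² + σ²). For
edges to clear the inclusive 0.9 threshold reliably at n = 10 (Fisher-z
SD ≈ 0.38 there), population r must sit near 0.99, i.e. λ ≈ 10σ. But if
that is achieved by inflating the shared factor against the global noise
(λ = 5 at σ = 0.5), the members' within-group variance is ~25× that of
ordinary probes and their planted differential expression becomes
undetectable at n = 5/group — the two requirements are incompatible
under a single global noise level. The generator therefore keeps the
latent factor modest (λ = 0.5) and shrinks the members' own noise to
σ/10, which preserves both properties: planted pairwise |r| ≈ 0.99 and
member per-sample variance comparable to ordinary probes. At the
boundary ratio λ = 3σ the inclusive 0.9 threshold would drop roughly
half the planted edges at n = 10 — an analytic fact worth knowing when
tuning these knobs. `module_noise_sd=0` gives the noise-free limit
(|r| = 1 exactly), used for the cis round-trip checks.

qPCR measurements are generated so the treated/control geometric-mean
log-ratio equals the array's ln fold change plus N(0, qpcr_noise_sd)
probe-level error, with mean-centered per-sample scatter of the same SD;
at zero noise the planted ratio is exact. The default validation noise
(0.2 on the ln scale) yields panel concordance r ≈ 0.98–0.99, the same
qualitative regime as published array-vs-qPCR comparisons.

**What the generator does not emulate:** scanner artifacts, dye bias,
probe cross-hybridization, intensity-dependent variance, outlier
samples, or realistic annotation (loci are uniform, gene sets are random
draws seeded with DE symbols). Passing tests therefore demonstrate the
statistical machinery is correct under the stated model, not that the
pipeline is robust to every failure mode of real arrays.

## Problem sizes and seeds

All stochastic checks are seeded and deterministic. The calibration and
recovery studies use 200-probe null datasets over 100 replicates
(t-test false-positive rate, network emptiness) and 500-probe planted
datasets over 20 replicates (DE, edge, concordance recovery); replicate
seeds derive from one base seed by a fixed prime stride. These sizes
give binomial standard errors well below the margins being asserted
while keeping a full run in seconds.

## Known limitations

- The t-test is unmoderated; at n = 5/group an empirical-Bayes
  variance-shrinkage test would be more powerful, but the screen is
  defined as a plain Student's t.
- No paired designs, no covariates, no low-intensity probe filtering
  (none is applied by default since none is defined for the emulated
  protocol).
- The CNC network reports degree only; no further topology statistics.
- Enrichment treats terms independently (no parent-term propagation).
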