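"""Synthetic two-group lncRNA/mRNA array data with planted ground truth.

Emulates the study design end-to-end: a probes × samples intensity matrix
for 5 control vs 5 treated samples over mixed lncRNA and mRNA probes,
plus probe annotation with genomic loci, GMT gene sets, and optional
qRT-PCR measurements. Three kinds of structure are planted and returned
as truth tables:

* differential expression — a subset of probes shifted by a fixed log2
  fold change in the treated group (half up, half down);
* co-expression modules — blocks of DE lncRNAs and DE mRNAs sharing an
  additive per-sample latent factor; a member's loading sign follows its
  DE direction, so module edges between opposite-direction members are
  negatively correlated;
* cis pairs — module lncRNA-mRNA pairs whose loci are placed on one
  chromosome within a bounded gap (default <= 300 kb).

Expression is generated on the log2 scale (Gaussian noise) and
exponentiated to linear intensities for output, matching how array fold
changes are reported as linear ratios.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .array_io import (
    ANNOTATION_COLUMNS,
    CONTROL,
    TREATED,
    ExpressionMatrix,
    ProbeAnnotation,
)
from .enrichment import CATEGORIES, GeneSet, GeneSetCollection
from .validation import QpcrTable

DEFAULT_GENOME = tuple((f"chr{i}", 100_000_000) for i in range(1, 6))


class ConfigError(ValueError):
    """A SimConfig field violated its invariant; the message names it."""


@dataclass
class SimConfig:
    """Study-design knobs for the generator.

    Defaults mirror the emulated design: 5 samples per group, log2 effect
    of 2.0 (4-fold), per-probe Gaussian noise SD 0.5 on the log2 scale.
    Co-expression module members share an additive latent factor
    (``module_latent_sd``) and carry reduced idiosyncratic noise
    (``module_noise_sd``, default noise_sd / 10): the latent-to-noise
    ratio of 10 puts planted pairwise |r| near 0.99 so edges clear the
    0.9 network threshold at n = 10 samples, while the members' total
    per-sample variance stays comparable to ordinary probes so their
    planted differential expression remains detectable at n = 5/group.
    """

    n_lnc_probes: int = 200
    n_mrna_probes: int = 300
    n_per_group: int = 5
    n_de_lnc: int = 20
    n_de_mrna: int = 30
    effect_log2fc: float = 2.0
    noise_sd: float = 0.5
    n_coexp_modules: int = 3
    module_size: tuple[int, int] = (2, 3)
    module_latent_sd: float = 0.5
    module_noise_sd: float | None = None
    n_cis_pairs: int = 5
    cis_max_gap: int = 300_000
    genome: tuple[tuple[str, int], ...] = DEFAULT_GENOME
    n_terms: int = 20
    genes_per_term: int = 15
    seed: int = 0

    def validate(self) -> None:
        counts = [
            "n_lnc_probes",
            "n_mrna_probes",
            "n_de_lnc",
            "n_de_mrna",
            "n_coexp_modules",
            "n_cis_pairs",
            "n_terms",
            "genes_per_term",
        ]
        for name in counts:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_per_group < 2:
            raise ConfigError("n_per_group must be >= 2")
        if self.n_de_lnc > self.n_lnc_probes:
            raise ConfigError("n_de_lnc exceeds n_lnc_probes")
        if self.n_de_mrna > self.n_mrna_probes:
            raise ConfigError("n_de_mrna exceeds n_mrna_probes")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if self.module_latent_sd < 0:
            raise ConfigError("module_latent_sd must be >= 0")
        if self.module_noise_sd is not None and self.module_noise_sd < 0:
            raise ConfigError("module_noise_sd must be >= 0")
        if self.cis_max_gap <= 0:
            raise ConfigError("cis_max_gap must be > 0")
        if len(self.module_size) != 2 or min(self.module_size) < 1:
            if self.n_coexp_modules > 0:
                raise ConfigError("module_size must be a pair of positive counts")
        if self.n_coexp_modules > 0:
            if self.n_coexp_modules * self.module_size[0] > self.n_de_lnc:
                raise ConfigError("n_coexp_modules * module_size[0] exceeds n_de_lnc")
            if self.n_coexp_modules * self.module_size[1] > self.n_de_mrna:
                raise ConfigError("n_coexp_modules * module_size[1] exceeds n_de_mrna")
        if not self.genome:
            raise ConfigError("genome must list at least one chromosome")
        for chrom, length in self.genome:
            if length <= 2 * self.cis_max_gap:
                raise ConfigError(f"genome chromosome {chrom} too short for cis_max_gap")
        if self.genes_per_term > 0 and self.n_terms > 0 and self.genes_per_term > self.n_mrna_probes:
            raise ConfigError("genes_per_term exceeds n_mrna_probes")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["module_size"] = list(self.module_size)
        d["genome"] = [list(g) for g in self.genome]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "module_size" in d:
            d["module_size"] = tuple(d["module_size"])
        if "genome" in d:
            d["genome"] = tuple((str(c), int(n)) for c, n in d["genome"])
        return cls(**d)


@dataclass
class TruthTables:
    """Planted structure, the acceptance surface for recovery checks.

    ``de_probes``: (probe id, direction Up/Down, planted log2fc);
    ``coexp_edges``: (lnc probe, mrna probe, sign positive/negative);
    ``cis_pairs``: (lnc probe, mrna probe, gap bp).
    """

    de_probes: set[tuple[str, str, float]] = field(default_factory=set)
    coexp_edges: set[tuple[str, str, str]] = field(default_factory=set)
    cis_pairs: set[tuple[str, str, int]] = field(default_factory=set)

    def de_probe_ids(self) -> set[str]:
        return {p for p, _, _ in self.de_probes}

    def de_ids_by_direction(self, direction: str) -> set[str]:
        return {p for p, d, _ in self.de_probes if d == direction}

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(a, b) for a, b, _ in self.coexp_edges}

    def write_tsv(self, de_path, edges_path, cis_path) -> None:
        pd.DataFrame(sorted(self.de_probes), columns=["probe_id", "direction", "log2fc"]).to_csv(
            de_path, sep="\t", index=False
        )
        pd.DataFrame(sorted(self.coexp_edges), columns=["lnc_probe", "mrna_probe", "sign"]).to_csv(
            edges_path, sep="\t", index=False
        )
        pd.DataFrame(sorted(self.cis_pairs), columns=["lnc_probe", "mrna_probe", "gap"]).to_csv(
            cis_path, sep="\t", index=False
        )


def _probe_ids(config: SimConfig) -> tuple[list[str], list[str]]:
    lnc = [f"LNCP{i:05d}" for i in range(config.n_lnc_probes)]
    mrna = [f"MRNP{i:05d}" for i in range(config.n_mrna_probes)]
    return lnc, mrna


def _alternating_directions(n: int) -> list[str]:
    return ["Up" if i % 2 == 0 else "Down" for i in range(n)]


def _random_locus(rng, genome, span: int):
    chrom, length = genome[rng.integers(0, len(genome))]
    start = int(rng.integers(1, length - span))
    return chrom, start, start + span - 1


def generate_dataset(
    config: SimConfig,
) -> tuple[ExpressionMatrix, ProbeAnnotation, GeneSetCollection, TruthTables]:
    """Generate (matrix, annotation, gene sets, truth) from one config.

    All randomness is driven by ``config.seed``; identical configs yield
    bit-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lnc_ids, mrna_ids = _probe_ids(config)
    probes = lnc_ids + mrna_ids
    n_probes, n_samples = len(probes), 2 * config.n_per_group
    samples = [f"CON_{i + 1}" for i in range(config.n_per_group)] + [
        f"LPS_{i + 1}" for i in range(config.n_per_group)
    ]
    groups = {s: (CONTROL if s.startswith("CON") else TREATED) for s in samples}
    treated_cols = np.arange(config.n_per_group, n_samples)

    # baseline + noise on log2 scale
    base = rng.uniform(6.0, 12.0, size=n_probes)
    X = base[:, None] + rng.normal(0.0, config.noise_sd, size=(n_probes, n_samples))

    truth = TruthTables()

    # planted differential expression: half up, half down, fixed |log2fc|
    de_lnc = [lnc_ids[i] for i in rng.choice(config.n_lnc_probes, config.n_de_lnc, replace=False)]
    de_mrna = [
        mrna_ids[i] for i in rng.choice(config.n_mrna_probes, config.n_de_mrna, replace=False)
    ]
    index_of = {p: i for i, p in enumerate(probes)}
    direction_of: dict[str, str] = {}
    for ids in (de_lnc, de_mrna):
        for probe, direction in zip(ids, _alternating_directions(len(ids))):
            shift = config.effect_log2fc if direction == "Up" else -config.effect_log2fc
            X[index_of[probe], treated_cols] += shift
            direction_of[probe] = direction
            truth.de_probes.add((probe, direction, float(shift)))

    # co-expression modules: shared latent factor with reduced member
    # noise; loading sign follows the member's DE direction, so the DE
    # pattern reinforces (never fights) the planted correlation
    module_noise = config.noise_sd / 10.0 if config.module_noise_sd is None else config.module_noise_sd
    module_edges: list[tuple[str, str]] = []
    n_ml, n_mm = (config.module_size if config.n_coexp_modules else (0, 0))
    for m in range(config.n_coexp_modules):
        members_l = de_lnc[m * n_ml : (m + 1) * n_ml]
        members_m = de_mrna[m * n_mm : (m + 1) * n_mm]
        latent = rng.normal(0.0, config.module_latent_sd, size=n_samples)
        for probe in members_l + members_m:
            sign = 1.0 if direction_of[probe] == "Up" else -1.0
            shift = sign * config.effect_log2fc
            idx = index_of[probe]
            X[idx] = base[idx] + sign * latent + rng.normal(0.0, module_noise, size=n_samples)
            X[idx, treated_cols] += shift
        for lnc, mrna in itertools.product(members_l, members_m):
            same = direction_of[lnc] == direction_of[mrna]
            truth.coexp_edges.add((lnc, mrna, "positive" if same else "negative"))
            module_edges.append((lnc, mrna))

    # annotation: transcript ids, symbols, loci
    ann_rows = {}
    for i, probe in enumerate(lnc_ids):
        rna_len = int(rng.integers(200, 3000))
        chrom, start, end = _random_locus(rng, config.genome, rna_len)
        symbol = "" if i % 5 == 4 else f"AK{600000 + i:06d}"
        ann_rows[probe] = (f"TCONS_{i:08d}", symbol, "lncRNA", rna_len, chrom, start, end, "+" if i % 2 else "-")
    for i, probe in enumerate(mrna_ids):
        rna_len = int(rng.integers(500, 5000))
        chrom, start, end = _random_locus(rng, config.genome, rna_len)
        ann_rows[probe] = (f"NM_{100000 + i:06d}", f"GENE{i:04d}", "mRNA", rna_len, chrom, start, end, "+" if i % 2 else "-")
    annotation_df = pd.DataFrame.from_dict(ann_rows, orient="index", columns=ANNOTATION_COLUMNS)
    annotation_df = annotation_df.loc[probes]

    # cis pairs: relocate the mRNA of selected module edges next to its lncRNA
    used_mrna: set[str] = set()
    chosen: list[tuple[str, str]] = []
    for lnc, mrna in module_edges:
        if len(chosen) >= config.n_cis_pairs:
            break
        if mrna in used_mrna:
            continue
        chosen.append((lnc, mrna))
        used_mrna.add(mrna)
    # fall back to arbitrary DE pairs if modules supply too few
    if len(chosen) < config.n_cis_pairs:
        for lnc, mrna in itertools.product(de_lnc, de_mrna):
            if len(chosen) >= config.n_cis_pairs:
                break
            if mrna not in used_mrna and (lnc, mrna) not in chosen:
                chosen.append((lnc, mrna))
                used_mrna.add(mrna)
    chrom_len = dict(config.genome)
    for lnc, mrna in chosen:
        chrom, l_start, l_end = annotation_df.loc[lnc, ["chrom", "start", "end"]]
        gap = int(rng.integers(0, config.cis_max_gap + 1))
        span = int(annotation_df.at[mrna, "end"]) - int(annotation_df.at[mrna, "start"]) + 1
        g_start = int(l_end) + gap + 1
        g_end = g_start + span - 1
        if g_end > chrom_len[chrom]:
            # place upstream instead; same gap
            g_end = int(l_start) - gap - 1
            g_start = g_end - span + 1
        annotation_df.loc[mrna, ["chrom", "start", "end"]] = (chrom, g_start, g_end)
        truth.cis_pairs.add((lnc, mrna, gap))
    annotation = ProbeAnnotation(table=annotation_df)

    # gene sets over mRNA symbols; the first few terms are seeded with DE
    # symbols so enrichment has signal to find
    mrna_symbols = [ann_rows[p][1] for p in mrna_ids]
    de_mrna_symbols = [ann_rows[p][1] for p in de_mrna]
    terms: dict[str, GeneSet] = {}
    for t in range(config.n_terms):
        category = CATEGORIES[t % len(CATEGORIES)]
        if t < len(CATEGORIES) and de_mrna_symbols:
            n_seed = min(config.genes_per_term // 2, len(de_mrna_symbols))
            seeded = list(rng.choice(de_mrna_symbols, n_seed, replace=False))
            rest_pool = [s for s in mrna_symbols if s not in seeded]
            rest = list(rng.choice(rest_pool, config.genes_per_term - n_seed, replace=False))
            members = seeded + rest
        else:
            members = list(rng.choice(mrna_symbols, config.genes_per_term, replace=False))
        terms[f"TERM{t:04d}"] = GeneSet(
            name=f"synthetic term {t}", category=category, genes=frozenset(members)
        )
    gene_sets = GeneSetCollection(terms=terms)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(2.0**X, index=probes, columns=samples),
        groups=groups,
        scale="linear",
    )
    return matrix, annotation, gene_sets, truth


def generate_qpcr_measurements(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation,
    selected,
    qpcr_noise_sd: float,
    seed: int,
) -> QpcrTable:
    """Reference-gene-normalized relative quantities for selected probes.

    Per probe, the treated/control geometric-mean log-ratio equals the
    array's ln fold change plus N(0, qpcr_noise_sd) probe-level error;
    per-sample scatter (same SD) is mean-centered within each group so
    the planted ratio is exact at qpcr_noise_sd = 0.
    """
    if qpcr_noise_sd < 0:
        raise ValueError("qpcr_noise_sd must be >= 0")
    known = set(matrix.probe_ids)
    for probe in selected:
        if probe not in known:
            raise KeyError(f"unknown probe id {probe!r}")
    rng = np.random.default_rng(seed)
    con = matrix.samples_in_group(CONTROL)
    trt = matrix.samples_in_group(TREATED)
    linear = matrix.values if matrix.scale == "linear" else 2.0**matrix.values
    rows = []
    for probe in selected:
        ln_fc = math.log(linear.loc[probe, trt].mean() / linear.loc[probe, con].mean())
        delta = rng.normal(0.0, qpcr_noise_sd) if qpcr_noise_sd > 0 else 0.0
        for group_samples, mean_log in ((con, 0.0), (trt, ln_fc + delta)):
            eps = rng.normal(0.0, qpcr_noise_sd, size=len(group_samples)) if qpcr_noise_sd > 0 else np.zeros(len(group_samples))
            eps -= eps.mean()
            for sample, e in zip(group_samples, eps):
                rows.append((probe, sample, math.exp(mean_log + e)))
    data = pd.DataFrame(rows, columns=["probe", "sample", "quantity"])
    return QpcrTable(data=data, groups=dict(matrix.groups))


def select_validation_panel(de_table: pd.DataFrame, up_set, down_set, n_up: int = 5, n_down: int = 5, seed: int = 0) -> list[str]:
    """Randomly pick up- and down-regulated probes for qPCR validation."""
    rng = np.random.default_rng(seed)
    panel = []
    for pool, n in ((sorted(up_set), n_up), (sorted(down_set), n_down)):
        if len(pool) < n:
            raise ValueError("not enough probes to fill the validation panel")
        panel.extend(rng.choice(pool, n, replace=False))
    return [str(p) for p in panel]
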