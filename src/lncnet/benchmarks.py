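"""Seeded calibration and recovery studies over the synthetic generator.

Each function regenerates its datasets from scratch and pushes them
through the same code paths the pipeline uses, returning summary rates:

* null calibration — no planted effects; the t-test false-positive rate
  at p < 0.05 and the fraction of replicates whose CNC network (built on
  whatever probes survive the volcano filter) is empty;
* planted-DE recovery — fraction of planted DE probes recovered by the
  FC > 2, p < 0.05 volcano rule, plus the false-discovery rate among the
  calls;
* planted-edge recovery — fraction of planted module edges retained at
  |r| >= 0.9 when the network is built on the planted DE sets;
* cis recovery — fraction of planted cis pairs that survive the
  |r| > 0.85, p < 0.01 filter and classify cis (noise-free module limit);
* cross-platform concordance — Pearson r of signed ln fold changes for
  10-probe qPCR panels (5 up, 5 down) at moderate qPCR noise.

Replicate seeds are derived deterministically from one base seed.
"""

from __future__ import annotations

import math

from .array_io import as_log2, quantile_normalize
from .cis_trans import CIS, classify_targets, coexpressed_pairs
from .coexpression import build_cnc_network
from .diffexpr import differential_expression, volcano_filter
from .synthetic_data import (
    SimConfig,
    generate_dataset,
    generate_qpcr_measurements,
    select_validation_panel,
)
from .validation import platform_concordance

_SEED_STRIDE = 10_007  # prime stride keeps derived replicate seeds distinct


def _rep_seed(base_seed: int, i: int) -> int:
    return (base_seed * _SEED_STRIDE + i) % (2**31 - 1)


def _split_by_class(annotation, probes):
    lnc = set(annotation.probes_of_class("lncRNA"))
    return probes & lnc, probes - lnc


def null_calibration(n_replicates: int = 100, seed: int = 0) -> dict:
    """False-positive rate and end-to-end network emptiness with no effects.

    200 probes x 10 samples per replicate (100 lncRNA + 100 mRNA, 5 vs 5),
    processed with the pipeline's standard log2 + quantile normalization.
    """
    fp = trials = empty = 0
    for i in range(n_replicates):
        cfg = SimConfig(
            n_lnc_probes=100,
            n_mrna_probes=100,
            n_de_lnc=0,
            n_de_mrna=0,
            n_coexp_modules=0,
            n_cis_pairs=0,
            seed=_rep_seed(seed, i),
        )
        matrix, annotation, _, _ = generate_dataset(cfg)
        norm = quantile_normalize(as_log2(matrix))
        de = differential_expression(norm)
        fp += int((de["p_value"] < 0.05).sum())
        trials += len(de)
        up, down = volcano_filter(de)
        up_l, up_m = _split_by_class(annotation, up)
        down_l, down_m = _split_by_class(annotation, down)
        network = build_cnc_network(norm, up_l, down_l, up_m, down_m)
        empty += int(network.n_edges == 0)
    return {
        "fp_rate": fp / trials,
        "n_tests": trials,
        "band_3sd": 3 * math.sqrt(0.05 * 0.95 / trials),
        "cnc_empty_fraction": empty / n_replicates,
        "n_replicates": n_replicates,
    }


def de_recovery(n_replicates: int = 20, seed: int = 0) -> dict:
    """Volcano-filter recovery of planted DE probes at the default design
    (log2FC 2.0, noise SD 0.5, n = 5/group)."""
    recovered = planted_total = false_pos = called = 0
    for i in range(n_replicates):
        cfg = SimConfig(seed=_rep_seed(seed, i))
        matrix, _, _, truth = generate_dataset(cfg)
        norm = quantile_normalize(as_log2(matrix))
        up, down = volcano_filter(differential_expression(norm))
        calls = up | down
        planted = truth.de_probe_ids()
        recovered += len(calls & planted)
        planted_total += len(planted)
        false_pos += len(calls - planted)
        called += len(calls)
    return {
        "recovery": recovered / planted_total,
        "fdr": false_pos / called if called else 0.0,
        "n_planted": planted_total,
        "n_replicates": n_replicates,
    }


def edge_recovery(n_replicates: int = 20, seed: int = 0) -> dict:
    """CNC retention of planted module edges at |r| >= 0.9, n = 10 samples,
    with the network built on the planted DE sets."""
    recovered = planted_total = 0
    for i in range(n_replicates):
        cfg = SimConfig(seed=_rep_seed(seed, i))
        matrix, annotation, _, truth = generate_dataset(cfg)
        norm = quantile_normalize(as_log2(matrix))
        up_l, up_m = _split_by_class(annotation, truth.de_ids_by_direction("Up"))
        down_l, down_m = _split_by_class(annotation, truth.de_ids_by_direction("Down"))
        network = build_cnc_network(norm, up_l, down_l, up_m, down_m)
        got = set(map(tuple, network.edges[["lnc_probe", "mrna_probe"]].to_numpy()))
        recovered += len(got & truth.edge_pairs())
        planted_total += len(truth.edge_pairs())
    return {
        "recovery": recovered / planted_total,
        "n_planted": planted_total,
        "n_replicates": n_replicates,
    }


def cis_recovery(seed: int = 0) -> dict:
    """Noise-free module limit: every planted cis pair must survive the
    correlation filter and classify cis."""
    cfg = SimConfig(seed=_rep_seed(seed, 0), module_noise_sd=0.0)
    matrix, annotation, _, truth = generate_dataset(cfg)
    norm = quantile_normalize(as_log2(matrix))
    lncs = {l for l, _, _ in truth.cis_pairs}
    mrnas = {m for _, m, _ in truth.cis_pairs}
    pairs = coexpressed_pairs(norm, lncs, mrnas)
    assignments = classify_targets(pairs, annotation)
    got = set(
        zip(
            assignments.loc[assignments["klass"] == CIS, "lnc_probe"],
            assignments.loc[assignments["klass"] == CIS, "mrna_probe"],
        )
    )
    planted = {(l, m) for l, m, _ in truth.cis_pairs}
    return {
        "recovery": len(got & planted) / len(planted),
        "n_planted": len(planted),
    }


def concordance_study(n_replicates: int = 20, seed: int = 0, qpcr_noise_sd: float = 0.2) -> dict:
    """Array vs qPCR signed-ln fold-change correlation for 5+5 panels."""
    rs = []
    for i in range(n_replicates):
        rep_seed = _rep_seed(seed, i)
        matrix, annotation, _, _ = generate_dataset(SimConfig(seed=rep_seed))
        de = differential_expression(matrix)
        up, down = volcano_filter(de)
        panel = select_validation_panel(de, up, down, 5, 5, seed=rep_seed)
        qpcr = generate_qpcr_measurements(matrix, annotation, panel, qpcr_noise_sd, seed=rep_seed)
        rs.append(platform_concordance(de.loc[panel], qpcr).r)
    return {
        "r_mean": sum(rs) / len(rs),
        "r_min": min(rs),
        "r_max": max(rs),
        "n_probes_per_panel": 10,
        "n_replicates": n_replicates,
    }
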