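import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_matrix
from lncnet.array_io import ANNOTATION_COLUMNS, ProbeAnnotation
from lncnet.cis_trans import (
    classify_targets,
    coexpressed_pairs,
    genomic_gap,
    target_gene_lists,
)
from lncnet.coexpression import correlation_matrix
from lncnet.synthetic_data import SimConfig, generate_dataset


def annotation_from_loci(loci):
    """Build a ProbeAnnotation from {probe: (class, symbol, chrom, start, end)}."""
    rows = {
        probe: (f"TX_{probe}", symbol, klass, end - start + 1, chrom, start, end, "+")
        for probe, (klass, symbol, chrom, start, end) in loci.items()
    }
    return ProbeAnnotation(table=pd.DataFrame.from_dict(rows, orient="index", columns=ANNOTATION_COLUMNS))


class TestGenomicGap:
    def test_overlap_is_zero(self):
        assert genomic_gap(("chr1", 100, 200), ("chr1", 150, 250)) == 0

    def test_coordinate_arithmetic(self):
        assert genomic_gap(("chr1", 100_000, 105_000), ("chr1", 350_000, 360_000)) == 245_000

    def test_cross_chromosome_unlinked(self):
        assert genomic_gap(("chr1", 1, 10), ("chr2", 1, 10)) is None

    def test_symmetric_and_nonnegative(self):
        a, b = ("chr3", 500, 600), ("chr3", 10, 20)
        assert genomic_gap(a, b) == genomic_gap(b, a) == 480
        assert genomic_gap(a, a) == 0

    def test_adjacent_and_touching_loci(self):
        assert genomic_gap(("chr1", 1, 100), ("chr1", 101, 200)) == 1
        assert genomic_gap(("chr1", 1, 100), ("chr1", 100, 200)) == 0  # share base 100

    def test_tss_mode(self):
        assert genomic_gap(("chr1", 100, 500), ("chr1", 400, 900), mode="tss") == 300

    def test_malformed_locus_rejected(self):
        with pytest.raises(ValueError, match="locus"):
            genomic_gap(("chr1", 200, 100), ("chr1", 1, 10))


class TestCoexpressedPairs:
    def make_planted(self):
        rng = np.random.default_rng(7)
        latent = rng.normal(0, 2, 10)
        rows = [latent + rng.normal(0, 0.05, 10), latent + rng.normal(0, 0.05, 10), rng.normal(0, 1, 10)]
        return make_matrix(np.vstack(rows), 5, 5)

    def test_planted_pair_passes_noise_fails(self):
        m = self.make_planted()
        pairs = coexpressed_pairs(m, {"P0"}, {"P1", "P2"})
        assert set(map(tuple, pairs[["lnc_probe", "mrna_probe"]].to_numpy())) == {("P0", "P1")}

    def test_boundary_r_excluded_strict(self):
        m = self.make_planted()
        _, _, R, _ = correlation_matrix(m, ["P0"], ["P1"])
        r = abs(float(R[0, 0]))
        pairs = coexpressed_pairs(m, {"P0"}, {"P1"}, r_threshold=r)
        assert pairs.empty  # |r| == threshold fails the strict rule

    def test_p_threshold_conjunction(self):
        m = self.make_planted()
        pairs = coexpressed_pairs(m, {"P0"}, {"P1"}, r_threshold=0.85, p_threshold=1e-300)
        assert pairs.empty

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_grid(self, seed):
        from test_coexpression import pearson_from_definition
        from scipy import stats

        rng = np.random.default_rng(seed)
        m = make_matrix(rng.normal(size=(10, 8)), 4, 4)
        lncs, mrnas = [f"P{i}" for i in range(5)], [f"P{i}" for i in range(5, 10)]
        thr = float(rng.uniform(0.2, 0.9))
        pairs = coexpressed_pairs(m, set(lncs), set(mrnas), r_threshold=thr, p_threshold=0.05)
        brute = set()
        n = 8
        for l in lncs:
            for g in mrnas:
                r = pearson_from_definition(m.values.loc[l], m.values.loc[g])
                t = abs(r) * np.sqrt((n - 2) / (1 - r**2))
                p = 2 * stats.t.sf(t, n - 2)
                if abs(r) > thr and p < 0.05:
                    brute.add((l, g))
        assert set(map(tuple, pairs[["lnc_probe", "mrna_probe"]].to_numpy())) == brute


class TestClassifyTargets:
    ANN = annotation_from_loci(
        {
            "L1": ("lncRNA", "", "chr1", 1_000_000, 1_005_000),
            "G_near": ("mRNA", "NEAR", "chr1", 1_055_000, 1_060_000),  # gap 50 kb
            "G_far": ("mRNA", "FAR", "chr1", 1_505_000, 1_510_000),  # gap 500 kb
            "G_mid": ("mRNA", "MID", "chr1", 1_205_000, 1_210_000),  # gap 200 kb
            "G_other": ("mRNA", "OTHER", "chr2", 1_000_000, 1_005_000),
        }
    )

    def pairs_for(self, genes):
        return pd.DataFrame(
            {"lnc_probe": "L1", "mrna_probe": genes, "r": 0.95, "p_value": 1e-4}
        )

    def test_rule_application(self):
        out = classify_targets(self.pairs_for(["G_near", "G_far", "G_mid", "G_other"]), self.ANN)
        klass = dict(zip(out["mrna_probe"], out["klass"]))
        assert klass == {"G_near": "cis", "G_far": "trans", "G_mid": "cis", "G_other": "trans"}
        gaps = dict(zip(out["mrna_probe"], out["gap"]))
        assert gaps["G_near"] == 50_000 and gaps["G_far"] == 500_000
        assert pd.isna(gaps["G_other"])

    def test_partition_every_pair_exactly_one_class(self):
        out = classify_targets(self.pairs_for(["G_near", "G_far", "G_mid", "G_other"]), self.ANN)
        assert set(out["klass"]) <= {"cis", "trans"} and len(out) == 4

    def test_window_shrink_monotone(self):
        pairs = self.pairs_for(["G_near", "G_far", "G_mid", "G_other"])
        wide = classify_targets(pairs, self.ANN, cis_window=300_000, trans_floor=100_000)
        narrow = classify_targets(pairs, self.ANN, cis_window=120_000, trans_floor=100_000)
        assert set(narrow.loc[narrow["klass"] == "cis", "mrna_probe"]) <= set(
            wide.loc[wide["klass"] == "cis", "mrna_probe"]
        )

    def test_invalid_window_order_rejected(self):
        with pytest.raises(ValueError, match="cis_window"):
            classify_targets(self.pairs_for(["G_near"]), self.ANN, cis_window=50_000, trans_floor=100_000)

    def test_gene_lists_deduplicate_and_split(self):
        out = classify_targets(self.pairs_for(["G_near", "G_near", "G_far"]), self.ANN)
        cis, trans = target_gene_lists(out)
        assert cis == ["NEAR"] and trans == ["FAR"]

    def test_empty_assignments(self):
        out = classify_targets(self.pairs_for([]).iloc[:0], self.ANN)
        assert target_gene_lists(out) == ([], [])

    @settings(derandomize=True, max_examples=60)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_matches_brute_force_rule(self, seed):
        rng = np.random.default_rng(seed)
        loci = {"L1": ("lncRNA", "", "chr1", 5_000_000, 5_010_000)}
        genes = []
        for i in range(8):
            chrom = "chr1" if rng.random() < 0.7 else "chr2"
            start = int(rng.integers(1, 10_000_000))
            loci[f"G{i}"] = ("mRNA", f"S{i}", chrom, start, start + 1000)
            genes.append(f"G{i}")
        ann = annotation_from_loci(loci)
        out = classify_targets(self.pairs_for(genes), ann)
        for _, row in out.iterrows():
            gap = genomic_gap(ann.locus("L1"), ann.locus(row["mrna_probe"]))
            expected = "cis" if (gap is not None and gap <= 300_000) else "trans"
            assert row["klass"] == expected


def test_generator_round_trip_noise_free_cis_recovery():
    """Every planted cis pair survives the r/p filter and classifies cis
    when module members carry no idiosyncratic noise."""
    cfg = SimConfig(seed=3, module_noise_sd=0.0)
    matrix, annotation, _, truth = generate_dataset(cfg)
    lnc = {l for l, _, _ in truth.cis_pairs}
    mrna = {m for _, m, _ in truth.cis_pairs}
    pairs = coexpressed_pairs(matrix, lnc, mrna)
    out = classify_targets(pairs, annotation)
    got = set(zip(out.loc[out["klass"] == "cis", "lnc_probe"], out.loc[out["klass"] == "cis", "mrna_probe"]))
    planted = {(l, m) for l, m, _ in truth.cis_pairs}
    assert planted <= got
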