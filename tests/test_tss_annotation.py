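"""Gene models, TSS distances, target assignment, feature maps, profiles."""

import numpy as np
import pytest

from reachmap.interval_core import GenomeDef, Interval, IntervalSet
from reachmap.tss_annotation import (
    AnnotationParams,
    GeneModel,
    GeneSet,
    assign_target_genes,
    feature_distribution,
    gene_set_overlap_test,
    gene_table_from_records,
    read_gene_models,
    signed_tss_distance,
    tss_profile,
)

from conftest import coverage_mask


@pytest.fixture
def small_genome():
    return GenomeDef([("c", 100_000)])


def _genes(records, genome=None):
    return gene_table_from_records([GeneModel(*r) for r in records], genome)


class TestGeneModels:
    def test_tss_derivation_by_strand(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text(
            "chr1\t1000\t2000\tgeneA\t0\t+\nchr1\t1000\t2000\tgeneB\t0\t-\n"
        )
        t = read_gene_models(p)
        assert t.loc[t.gene_id == "geneA", "tss"].item() == 1000
        assert t.loc[t.gene_id == "geneB", "tss"].item() == 1999  # half-open

    def test_missing_strand_rejected(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t1000\t2000\tgeneA\t0\t.\n")
        with pytest.raises(ValueError):
            read_gene_models(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t0\t10\tg\t0\t+\nchr1\t50\t60\tg\t0\t+\n")
        with pytest.raises(ValueError):
            read_gene_models(p)

    def test_unknown_chromosome_dropped(self, tmp_path, small_genome):
        p = tmp_path / "genes.bed"
        p.write_text("c\t0\t10\tg1\t0\t+\nchrZ\t0\t10\tg2\t0\t+\n")
        t = read_gene_models(p, small_genome)
        assert list(t.gene_id) == ["g1"]


class TestSignedDistance:
    def test_orientation_plus_strand(self):
        gene = GeneModel("g", "c", 10_000, 12_000, "+")  # tss 10000
        peak = Interval("c", 9400, 9600)  # midpoint 9500
        assert signed_tss_distance(peak, gene) == -500

    def test_strand_flip(self):
        gene = GeneModel("g", "c", 8002, 10_001, "-")  # tss 10000
        peak = Interval("c", 9400, 9600)
        assert signed_tss_distance(peak, gene) == +500

    def test_anchor_on_tss_is_zero(self):
        gene = GeneModel("g", "c", 10_000, 12_000, "+")
        peak = Interval("c", 9900, 10_100)
        assert signed_tss_distance(peak, gene) == 0

    def test_cross_chromosome_rejected(self):
        gene = GeneModel("g", "c2", 0, 100, "+")
        with pytest.raises(ValueError):
            signed_tss_distance(Interval("c1", 0, 10), gene)


class TestAssignTargets:
    def test_within_bound_included_boundary_excluded(self, small_genome):
        genes = _genes([("g", "c", 10_000, 12_000, "+")])
        near = IntervalSet(["c"], [10_400], [10_600], genome=small_genome)  # d=+500
        at_bound = IntervalSet(["c"], [8900], [9100], genome=small_genome)  # d=-1000
        t1, _ = assign_target_genes(near, genes)
        t2, _ = assign_target_genes(at_bound, genes)
        assert "g" in t1 and "g" not in t2  # strict <

    def test_planted_targets_match_all_pairs_oracle(self, small_genome):
        rng = np.random.default_rng(21)
        genes = _genes(
            [
                (f"g{i}", "c", int(s), int(s) + 1500, "+" if i % 2 else "-")
                for i, s in enumerate(range(1000, 99_000, 1960))
            ]
        )
        starts = rng.integers(0, 99_000, size=10)
        peaks = IntervalSet(["c"] * 10, starts, starts + 200)
        params = AnnotationParams(target_max_dist=1000)
        targets, table = assign_target_genes(peaks, genes, params)
        # oracle: every (peak, gene) pair by scalar signed distance
        expected = set()
        for iv in peaks:
            for g in genes.itertuples(index=False):
                gm = GeneModel(g.gene_id, g.chrom, g.start, g.end, g.strand)
                if abs(signed_tss_distance(iv, gm)) < 1000:
                    expected.add(g.gene_id)
        assert targets.gene_ids == expected

    def test_monotone_in_max_dist(self, small_genome):
        rng = np.random.default_rng(13)
        genes = _genes(
            [(f"g{i}", "c", int(1000 + 3000 * i), int(2500 + 3000 * i), "+") for i in range(30)]
        )
        starts = rng.integers(0, 95_000, size=40)
        peaks = IntervalSet(["c"] * 40, starts, starts + 300, genome=small_genome)
        prev: set = set()
        for d in (100, 500, 1000, 3000, 10_000):
            t, _ = assign_target_genes(peaks, genes, AnnotationParams(target_max_dist=d))
            assert prev <= t.gene_ids
            prev = t.gene_ids

    def test_empty_gene_table_rejected(self, small_genome):
        peaks = IntervalSet(["c"], [0], [10], genome=small_genome)
        import pandas as pd

        with pytest.raises(ValueError):
            assign_target_genes(peaks, _genes([]), AnnotationParams())


class TestFeatureDistribution:
    def test_all_promoter(self, small_genome):
        genes = _genes([("g", "c", 50_000, 60_000, "+")])  # promoter [47000,50000)
        peaks = IntervalSet(["c"] * 3, [47_100, 48_000, 49_500], [47_300, 48_200, 49_700])
        fd = feature_distribution(peaks, genes, small_genome)
        assert fd.peak_fractions["promoter"] == 1.0

    def test_gene_free_genome_is_all_intergenic(self, small_genome):
        peaks = IntervalSet(["c"], [10], [200])
        fd = feature_distribution(peaks, _genes([]), small_genome)
        assert fd.peak_fractions["intergenic"] == 1.0
        assert fd.genome_fractions["intergenic"] == 1.0

    def test_fractions_sum_to_one(self, small_genome):
        rng = np.random.default_rng(3)
        genes = _genes(
            [(f"g{i}", "c", int(s), int(s) + 2000, "-" if i % 3 else "+")
             for i, s in enumerate(range(2000, 90_000, 9000))]
        )
        starts = rng.integers(0, 99_000, size=60)
        peaks = IntervalSet(["c"] * 60, starts, starts + 100, genome=small_genome)
        fd = feature_distribution(peaks, genes, small_genome)
        assert sum(fd.peak_fractions.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(fd.genome_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_matches_per_base_oracle_classification(self, small_genome):
        """Anchor categories equal an independently painted per-base map."""
        rng = np.random.default_rng(5)
        genes = _genes(
            [(f"g{i}", "c", int(s), int(s) + 4000, "-" if i % 2 else "+")
             for i, s in enumerate(range(5000, 90_000, 17_000))]
        )
        params = AnnotationParams()
        # oracle map painted with plain python, lowest precedence first
        cat = np.zeros(100_000, dtype=np.uint8)  # 0=intergenic
        for g in genes.itertuples(index=False):
            lo, hi = (g.end, g.end + 3000) if g.strand == "+" else (g.start - 3000, g.start)
            cat[max(lo, 0) : hi] = np.maximum(cat[max(lo, 0) : hi], 1)
        for g in genes.itertuples(index=False):
            cat[g.start : g.end] = np.maximum(cat[g.start : g.end], 2)
        for g in genes.itertuples(index=False):
            if g.strand == "+":
                lo, hi = g.tss - 3000, g.tss
            else:
                lo, hi = g.tss + 1, g.tss + 3001
            cat[max(lo, 0) : min(hi, 100_000)] = 3
        names = {0: "intergenic", 1: "downstream", 2: "gene_body", 3: "promoter"}
        starts = rng.integers(0, 99_000, size=300)
        peaks = IntervalSet(["c"] * 300, starts, starts + 100, genome=small_genome)
        fd = feature_distribution(peaks, genes, small_genome, params)
        anchors = (peaks.starts + peaks.ends) // 2
        from collections import Counter

        counts = Counter(names[int(cat[a])] for a in anchors)
        for name in fd.peak_fractions:
            assert fd.peak_fractions[name] == pytest.approx(counts[name] / 300)
        genome_counts = Counter(cat.tolist())
        for code, name in names.items():
            assert fd.genome_fractions[name] == pytest.approx(
                genome_counts[code] / 100_000
            )


class TestTssProfile:
    def test_all_mass_at_zero_bin(self, small_genome):
        genes = _genes([("g", "c", 50_000, 52_000, "+")])
        peaks = IntervalSet(["c"] * 3, [49_900] * 3, [50_100] * 3)  # midpoint = TSS
        prof = tss_profile(peaks, genes)
        zero_bin = np.nonzero((prof.bin_left <= 0) & (prof.bin_left + 100 > 0))[0]
        assert prof.density[zero_bin].sum() == pytest.approx(1.0)

    def test_normalized_when_any_in_window(self, small_genome):
        genes = _genes([("g", "c", 50_000, 52_000, "+")])
        rng = np.random.default_rng(2)
        starts = rng.integers(41_000, 59_000, size=50)
        peaks = IntervalSet(["c"] * 50, starts, starts + 100)
        prof = tss_profile(peaks, genes)
        assert prof.density.sum() == pytest.approx(1.0)

    def test_uniform_anchors_give_flat_profile(self, small_genome):
        genes = _genes([("g", "c", 50_000, 52_000, "+")])
        rng = np.random.default_rng(44)
        n = 20_000
        anchors = rng.integers(40_000, 60_000, size=n)
        peaks = IntervalSet(["c"] * n, anchors, anchors + 1)
        params = AnnotationParams(profile_window=10_000, profile_bin=1000)
        prof = tss_profile(peaks, genes, params)
        expected = n / len(prof.density)
        dev = np.abs(prof.density * prof.n_in_window - expected)
        assert dev.max() < 5 * np.sqrt(expected)

    def test_no_peaks_in_window_warns_and_zeroes(self, small_genome):
        genes = _genes([("g", "c", 90_000, 92_000, "+")])
        peaks = IntervalSet(["c"], [100], [200])
        with pytest.warns(UserWarning):
            prof = tss_profile(peaks, genes)
        assert prof.density.sum() == 0.0


class TestGeneSetOverlap:
    def test_identical_sets(self):
        u = GeneSet.from_iterable("u", [f"g{i}" for i in range(100)])
        a = GeneSet.from_iterable("a", [f"g{i}" for i in range(30)])
        cont, frac = gene_set_overlap_test(a, a, u)
        assert frac == 1.0

    def test_disjoint_sets(self):
        u = GeneSet.from_iterable("u", [f"g{i}" for i in range(500)])
        a = GeneSet.from_iterable("a", [f"g{i}" for i in range(40)])
        b = GeneSet.from_iterable("b", [f"g{i}" for i in range(40, 90)])
        cont, frac = gene_set_overlap_test(a, b, u)
        assert frac == 0.0

    def test_direct_set_arithmetic(self):
        u = GeneSet.from_iterable("u", [f"g{i}" for i in range(1000)])
        a = GeneSet.from_iterable("a", [f"g{i}" for i in range(100)])
        b_ids = [f"g{i}" for i in range(48, 100)] + [f"g{i}" for i in range(100, 348)]
        b = GeneSet.from_iterable("b", b_ids)
        cont, frac = gene_set_overlap_test(a, b, u)
        assert cont.table == (52, 48, 248, 652)
        assert frac == pytest.approx(0.52)

    def test_empty_inputs_rejected(self):
        u = GeneSet.from_iterable("u", ["g1"])
        with pytest.raises(ValueError):
            gene_set_overlap_test(GeneSet.from_iterable("a", []), u, u)


def test_strand_mirror_symmetry():
    """Mirroring the genome and flipping strands preserves target calls
    and |signed distance| values."""
    L = 100_000
    g = GenomeDef([("c", L)])
    genes = _genes(
        [("g1", "c", 10_000, 14_000, "+"), ("g2", "c", 40_000, 47_000, "-")]
    )
    rng = np.random.default_rng(77)
    starts = rng.integers(0, L - 201, size=50)
    # odd length keeps the integer midpoint exactly mirror-symmetric
    peaks = IntervalSet(["c"] * 50, starts, starts + 201, genome=g)
    # mirrored world: base x -> L - 1 - x, strands flipped
    m_genes = _genes(
        [
            ("g1", "c", L - 14_000, L - 10_000, "-"),
            ("g2", "c", L - 47_000, L - 40_000, "+"),
        ]
    )
    m_peaks = IntervalSet(
        ["c"] * 50, L - (starts + 201), L - starts, genome=g
    )
    t, tab = assign_target_genes(peaks, genes)
    mt, mtab = assign_target_genes(m_peaks, m_genes)
    assert t.gene_ids == mt.gene_ids
    lhs = sorted(zip(tab.gene_id, tab.distance.abs()))
    rhs = sorted(zip(mtab.gene_id, mtab.distance.abs()))
    assert lhs == rhs
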