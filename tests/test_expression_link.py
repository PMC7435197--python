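"""Rank-sum tests, gene-set shift tests, ddCt quantification, pooled t test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as st

from reachmap.expression_link import (
    bh_adjust,
    ddct,
    gene_set_shift_test,
    t_test_homoscedastic,
    wilcoxon_rank_sum,
)
from reachmap.tss_annotation import GeneSet


class TestWilcoxonRankSum:
    def test_exact_one_sided_enumeration(self):
        res = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], alternative="less")
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 20)

    def test_identical_samples_two_sided_p_is_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_matches_scipy(self, alternative):
        rng = np.random.default_rng(10)
        scipy_alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}
        for _ in range(30):
            x = rng.normal(size=6)
            y = rng.normal(0.5, size=7)
            res = wilcoxon_rank_sum(x, y, alternative=alternative)
            assert res.method == "exact"
            ref = st.mannwhitneyu(x, y, alternative=scipy_alt[alternative], method="exact")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(4)
        x = np.round(rng.normal(size=40), 1)
        y = np.round(rng.normal(0.3, size=50), 1)
        res = wilcoxon_rank_sum(x, y, alternative="greater")
        assert res.method == "normal-approx"
        ref = st.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-8)

    def test_exact_and_normal_agree_for_n12(self):
        """Spot check: tie-free n_x = n_y = 12 exact vs approximation."""
        rng = np.random.default_rng(123)
        import reachmap.expression_link as el

        old = el.EXACT_ENUM_LIMIT
        try:
            for _ in range(100):
                x = rng.normal(size=12)
                y = rng.normal(0.4, size=12)
                el.EXACT_ENUM_LIMIT = 3_000_000  # force full enumeration
                exact = wilcoxon_rank_sum(x, y)
                assert exact.method == "exact"
                el.EXACT_ENUM_LIMIT = 0  # force the approximation branch
                approx = wilcoxon_rank_sum(x, y)
                assert approx.method == "normal-approx"
                assert abs(exact.p_value - approx.p_value) < 0.01
        finally:
            el.EXACT_ENUM_LIMIT = old

    def test_w_is_rank_sum_of_x(self):
        res = wilcoxon_rank_sum([10, 20], [1, 2, 3])
        assert res.w_statistic == 4 + 5


class TestGeneSetShift:
    @staticmethod
    def _expr(lfc_t, lfc_b):
        n_t, n_b = len(lfc_t), len(lfc_b)
        return (
            pd.DataFrame(
                {
                    "gene_id": [f"t{i}" for i in range(n_t)]
                    + [f"b{i}" for i in range(n_b)],
                    "log2fc": list(lfc_t) + list(lfc_b),
                }
            ),
            GeneSet.from_iterable("targets", [f"t{i}" for i in range(n_t)]),
        )

    def test_no_shift_gives_large_p(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=60)
        expr, targets = self._expr(vals[:20], vals[:20].tolist() + vals[20:].tolist())
        expr, targets = self._expr(vals[:30], vals[:30])  # identical distributions
        res = gene_set_shift_test(expr, targets)
        assert res.test.p_value > 0.9
        assert res.median_targets == pytest.approx(res.median_background)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(1)
        expr, targets = self._expr(
            rng.normal(0.5, 0.5, size=100), rng.normal(0, 0.5, size=900)
        )
        res = gene_set_shift_test(expr, targets, alternative="greater")
        assert res.test.p_value <= 1e-6
        assert res.direction == "up"

    def test_label_symmetry(self):
        rng = np.random.default_rng(2)
        expr, targets = self._expr(rng.normal(0.3, 1, 40), rng.normal(0, 1, 60))
        background = GeneSet.from_iterable("bg", [f"b{i}" for i in range(60)])
        p1 = gene_set_shift_test(expr, targets, alternative="greater").test.p_value
        p2 = gene_set_shift_test(
            expr, background, background=targets, alternative="less"
        ).test.p_value
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_absent_genes_dropped_and_counted(self):
        expr, _ = self._expr([0.5, 0.6], [0.0, 0.1, -0.1])
        targets = GeneSet.from_iterable("t", ["t0", "t1", "missing1", "missing2"])
        res = gene_set_shift_test(expr, targets)
        assert res.n_targets == 2 and res.n_dropped == 2

    def test_no_overlap_rejected(self):
        expr, _ = self._expr([0.1], [0.2])
        with pytest.raises(ValueError):
            gene_set_shift_test(expr, GeneSet.from_iterable("t", ["nope"]))

    def test_type_one_error_near_nominal(self):
        """Under the null the rejection rate at alpha = 0.05 stays in the
        binomial 99% band."""
        rng = np.random.default_rng(7)
        n_rej = 0
        n_sim = 500
        for _ in range(n_sim):
            expr, targets = self._expr(rng.normal(size=25), rng.normal(size=75))
            res = gene_set_shift_test(expr, targets)
            n_rej += res.test.p_value <= 0.05
        assert 0.02 <= n_rej / n_sim <= 0.09


class TestDdct:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["condition", "gene", "replicate", "ct"])

    def test_control_condition_folds_are_one(self):
        t = self._table(
            [
                ("CTRL", "REF", 1, 20.0),
                ("CTRL", "GENE", 1, 25.0),
                ("KD", "REF", 1, 20.0),
                ("KD", "GENE", 1, 24.0),
            ]
        )
        res = ddct(t, "REF", "CTRL")
        assert res.fold("CTRL", "GENE") == pytest.approx(1.0)
        assert res.fold("CTRL", "REF") == pytest.approx(1.0)
        assert res.fold("KD", "REF") == pytest.approx(1.0)

    def test_one_cycle_drop_doubles(self):
        t = self._table(
            [
                ("CTRL", "REF", 1, 20.0),
                ("CTRL", "GENE", 1, 25.0),
                ("KD", "REF", 1, 20.0),
                ("KD", "GENE", 1, 24.0),
            ]
        )
        assert ddct(t, "REF", "CTRL").fold("KD", "GENE") == pytest.approx(2.0)

    def test_two_cycle_drop_quadruples(self):
        t = self._table(
            [
                ("CTRL", "REF", 1, 20.0),
                ("CTRL", "GENE", 1, 25.0),
                ("KD", "REF", 1, 20.0),
                ("KD", "GENE", 1, 23.0),
            ]
        )
        assert ddct(t, "REF", "CTRL").fold("KD", "GENE") == pytest.approx(4.0)

    def test_condition_wide_ct_offset_cancels(self):
        rng = np.random.default_rng(5)
        rows = []
        for cond in ("CTRL", "KD"):
            for gene in ("REF", "G1", "G2"):
                for rep in range(1, 4):
                    rows.append((cond, gene, rep, 20 + rng.normal(0, 0.2)))
        t = self._table(rows)
        res = ddct(t, "REF", "CTRL")
        shifted = t.copy()
        shifted.loc[shifted.condition == "KD", "ct"] += 3.7  # plate offset
        res2 = ddct(shifted, "REF", "CTRL")
        pd.testing.assert_series_equal(res.table["fold"], res2.table["fold"])

    def test_missing_reference_rejected(self):
        t = self._table([("CTRL", "GENE", 1, 25.0), ("KD", "GENE", 1, 24.0)])
        with pytest.raises(ValueError):
            ddct(t, "REF", "CTRL")


class TestPooledTTest:
    def test_identical_samples(self):
        res = t_test_homoscedastic([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["t"] == 0.0 and res["p"] == 1.0

    def test_hand_worked_statistic(self):
        res = t_test_homoscedastic([1, 2, 3], [2, 3, 4])
        assert res["t"] == pytest.approx(-1.2247, abs=1e-4)
        assert res["df"] == 4

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError):
            t_test_homoscedastic([1.0], [1.0, 2.0])

    def test_zero_pooled_variance_unequal_means_rejected(self):
        with pytest.raises(ValueError):
            t_test_homoscedastic([1.0, 1.0], [2.0, 2.0])


def test_bh_adjustment_is_monotone_and_bounded():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    adj = bh_adjust(p)
    assert np.all(adj >= p)
    assert np.all(adj <= 1.0)
    assert np.all(np.diff(adj[np.argsort(p)]) >= 0)
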