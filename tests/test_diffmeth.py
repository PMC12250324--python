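"""Differential methylation calling: Fisher test, filters, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact

import dmrkit as dk
from dmrkit.diffmeth import fisher_exact_pvalues

from conftest import fisher_oracle, make_callset


class TestFisher:
    def test_identical_groups_give_p_one_and_zero_diff(self):
        ctrl = [make_callset([("chr1", 100, "+", 10, 5)])]
        trt = [make_callset([("chr1", 100, "+", 10, 5)])]
        out = dk.call_dmcs(ctrl, trt)
        assert out.loc[0, "diff_meth"] == 0.0
        assert out.loc[0, "p_value"] == 1.0

    def test_strong_difference_matches_enumeration_oracle(self):
        # 1/10 methylated vs 9/10: p must equal the exact tail sum
        ctrl = [make_callset([("chr1", 100, "+", 10, 1)])]
        trt = [make_callset([("chr1", 100, "+", 10, 9)])]
        out = dk.call_dmcs(ctrl, trt)
        expected = fisher_oracle(1, 9, 9, 1)
        assert out.loc[0, "p_value"] == pytest.approx(expected, abs=1e-12)
        assert out.loc[0, "diff_meth"] == pytest.approx(80.0)

    def test_batch_agrees_with_scipy(self):
        rng = np.random.default_rng(0)
        a, b, c, d = (rng.integers(0, 25, 300) for _ in range(4))
        mine = fisher_exact_pvalues(a, b, c, d)
        ref = [fisher_exact([[w, x], [y, z]])[1] for w, x, y, z in zip(a, b, c, d)]
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_degenerate_margins_give_p_one(self):
        p = fisher_exact_pvalues([0], [10], [0], [12])
        assert p[0] == 1.0


class TestCallDmcs:
    def test_coverage_filter_requires_every_sample(self):
        ctrl = [
            make_callset([("chr1", 100, "+", 12, 6), ("chr1", 200, "+", 9, 4)]),
            make_callset([("chr1", 100, "+", 15, 7), ("chr1", 200, "+", 30, 15)]),
        ]
        trt = [
            make_callset([("chr1", 100, "+", 20, 19), ("chr1", 200, "+", 20, 2)]),
            make_callset([("chr1", 100, "+", 11, 10), ("chr1", 200, "+", 25, 3)]),
        ]
        out = dk.call_dmcs(ctrl, trt, min_coverage=10)
        # position 200 has coverage 9 in one control sample -> not tested
        assert list(out["start"] + 1) == [100]

    def test_pooling_sums_counts_within_group(self):
        ctrl = [make_callset([("chr1", 50, "+", 10, 2)]),
                make_callset([("chr1", 50, "+", 10, 2)])]
        trt = [make_callset([("chr1", 50, "+", 10, 8)]),
               make_callset([("chr1", 50, "+", 10, 8)])]
        out = dk.call_dmcs(ctrl, trt)
        assert out.loc[0, "cov_c"] == 20 and out.loc[0, "m_c"] == 4
        assert out.loc[0, "p_value"] == pytest.approx(fisher_oracle(4, 16, 16, 4), abs=1e-12)

    def test_destranding_merges_cpg_dinucleotide(self):
        cs = make_callset([("chr1", 100, "+", 10, 3), ("chr1", 101, "-", 8, 5)])
        merged = cs.destranded().calls
        assert len(merged) == 1
        assert merged.loc[0, "pos"] == 100
        assert merged.loc[0, "coverage"] == 18 and merged.loc[0, "n_meth"] == 8

    def test_disjoint_positions_raise(self):
        ctrl = [make_callset([("chr1", 100, "+", 20, 5)])]
        trt = [make_callset([("chr1", 900, "+", 20, 5)])]
        with pytest.raises(ValueError, match="coverage filter"):
            dk.call_dmcs(ctrl, trt)

    def test_bh_is_monotone_and_order_invariant(self):
        rng = np.random.default_rng(1)
        rows = [("chr1", 10 * i + 10, "+", 30, int(rng.integers(0, 31))) for i in range(200)]
        rows_t = [("chr1", 10 * i + 10, "+", 30, int(rng.integers(0, 31))) for i in range(200)]
        out = dk.call_dmcs([make_callset(rows)], [make_callset(rows_t)])
        srt = out.sort_values("p_value")
        # q is a non-decreasing step function of the p rank
        assert (np.diff(srt["q_value"].to_numpy()) >= -1e-12).all()
        # permuting the input rows leaves every q unchanged
        perm = rng.permutation(len(rows))
        out2 = dk.call_dmcs(
            [make_callset([rows[i] for i in perm])],
            [make_callset([rows_t[i] for i in perm])],
        )
        merged = out.merge(out2, on="start", suffixes=("", "_p"))
        np.testing.assert_allclose(merged["q_value"], merged["q_value_p"])


class TestCallTiles:
    def test_balanced_tile_has_zero_diff(self):
        rows = [("chr1", p, "+", 20, 10) for p in (10, 60, 110)]
        out = dk.call_tiles([make_callset(rows)], [make_callset(rows)])
        assert len(out) == 1
        assert out.loc[0, "start"] == 0 and out.loc[0, "end"] == 200
        assert out.loc[0, "diff_meth"] == 0.0

    def test_pooled_tile_matches_fisher_oracle(self):
        # pooled 40/100 vs 70/100 split over CpGs in one tile
        ctrl_rows = [("chr1", 10, "+", 50, 20), ("chr1", 90, "+", 50, 20)]
        trt_rows = [("chr1", 10, "+", 50, 35), ("chr1", 90, "+", 50, 35)]
        out = dk.call_tiles([make_callset(ctrl_rows)], [make_callset(trt_rows)])
        assert out.loc[0, "diff_meth"] == pytest.approx(30.0)
        assert out.loc[0, "p_value"] == pytest.approx(fisher_oracle(40, 60, 70, 30), abs=1e-12)

    def test_tiles_sit_on_zero_anchored_grid(self, planted_study):
        callsets, _ = planted_study
        tiles = dk.call_tiles(callsets["CTRL"], callsets["IND50"])
        assert (tiles["start"] % 200 == 0).all()
        assert ((tiles["end"] - tiles["start"]) == 200).all()

    def test_overlapping_tiles_warn(self):
        rows = [("chr1", 150, "+", 20, 10)]
        with pytest.warns(UserWarning, match="overlapping tiles"):
            out = dk.call_tiles([make_callset(rows)], [make_callset(rows)],
                                window=200, step=100)
        # position 149 (0-based) is covered by windows starting at 0 and 100
        assert sorted(out["start"]) == [0, 100]


class TestGlobalShift:
    def test_identical_vectors_give_p_one_with_warning(self):
        a = np.linspace(0, 1, 30)
        with pytest.warns(UserWarning, match="non-zero pairs"):
            _stat, p = dk.global_shift_test(a, a)
        assert p == 1.0

    def test_uniform_shift_is_detected(self):
        a = np.linspace(10, 60, 50)
        stat, p = dk.global_shift_test(a, a + 10)
        assert p < 0.01
        # all differences positive: the minimum possible rank sum statistic
        assert stat == 0.0

    def test_antisymmetric_differences_sit_at_null_center(self):
        a = np.zeros(20)
        b = np.array([1, -1] * 10, dtype=float)
        stat, _p = dk.global_shift_test(a, b)
        # signed-rank statistic at the null center n(n+1)/4
        assert stat == pytest.approx(20 * 21 / 4, abs=20)


class TestChromosomeDistribution:
    def _dmcs(self, chroms, diffs, q=0.001):
        return pd.DataFrame(
            {"chrom": chroms, "start": range(len(chroms)), "diff_meth": diffs,
             "q_value": q}
        )

    def test_single_chromosome_takes_all(self):
        out = dk.chromosome_distribution(self._dmcs(["chr1"] * 5, [30, 40, -30, 50, -6]))
        assert out.loc["chr1", "hyper_pct"] == 100.0
        assert out.loc["chr1", "hypo_pct"] == 100.0

    def test_uniform_split_is_near_half(self):
        rng = np.random.default_rng(2)
        chroms = rng.choice(["chr1", "chr2"], size=1000)
        out = dk.chromosome_distribution(self._dmcs(chroms, [30.0] * 1000))
        # binomial 95% band around 50%
        assert abs(out.loc["chr1", "hyper_pct"] - 50) < 2 * 100 * np.sqrt(0.25 / 1000) * 1.96

    def test_relaxed_five_point_threshold(self):
        out = dk.chromosome_distribution(self._dmcs(["chr1", "chr2"], [6.0, 4.0]))
        # 6-point DMC passes the distribution filter, 4-point does not
        assert list(out.index) == ["chr1"]

    def test_empty_result_warns(self):
        with pytest.warns(UserWarning, match="no DMC"):
            out = dk.chromosome_distribution(self._dmcs(["chr1"], [2.0]))
        assert out.empty
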