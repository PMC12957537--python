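import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protmr import mr
from tests.conftest import make_pairs, make_stats


class TestHarmonize:
    def test_swapped_alleles_flip_outcome_beta_and_eaf(self):
        exp = make_stats([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02)])
        out = make_stats([("rs1", "1", 100, "G", "A", 0.7, -0.05, 0.01)])
        pairs = mr.harmonize(exp, out)
        row = pairs.iloc[0]
        assert row["action"] == "flipped"
        assert row["beta_out"] == pytest.approx(0.05)
        assert row["eaf_out"] == pytest.approx(0.3)

    def test_ambiguous_palindromic_dropped(self):
        exp = make_stats([("rs1", "1", 100, "A", "T", 0.50, 0.1, 0.02)])
        out = make_stats([("rs1", "1", 100, "A", "T", 0.50, 0.05, 0.01)])
        assert mr.harmonize(exp, out).iloc[0]["action"] == "dropped_palindromic"

    def test_informative_palindromic_kept(self):
        exp = make_stats([("rs1", "1", 100, "C", "G", 0.10, 0.1, 0.02)])
        out = make_stats([("rs1", "1", 100, "C", "G", 0.12, 0.05, 0.01)])
        assert mr.harmonize(exp, out).iloc[0]["action"] == "aligned"

    def test_irreconcilable_alleles_dropped(self):
        exp = make_stats([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02)])
        out = make_stats([("rs1", "1", 100, "A", "C", 0.3, 0.05, 0.01)])
        assert mr.harmonize(exp, out).iloc[0]["action"] == "dropped_mismatch"

    def test_variant_absent_from_outcome_excluded(self):
        exp = make_stats([("rs1", "1", 100, "A", "G", 0.3, 0.1, 0.02),
                          ("rs2", "1", 200, "A", "G", 0.3, 0.1, 0.02)])
        out = make_stats([("rs1", "1", 100, "A", "G", 0.3, 0.05, 0.01)])
        assert mr.harmonize(exp, out)["variant_id"].tolist() == ["rs1"]


class TestWaldRatio:
    def test_direct_formula(self):
        p = make_pairs([0.5], [0.05], [0.10], [0.02])
        res = mr.wald_ratio(p)
        assert res.estimate == pytest.approx(0.20, abs=1e-15)
        assert res.se == pytest.approx(0.04, abs=1e-15)

    def test_null_numerator(self):
        res = mr.wald_ratio(make_pairs([0.5], [0.05], [0.0], [0.02]))
        assert res.estimate == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_sign(self):
        res = mr.wald_ratio(make_pairs([-0.5], [0.05], [0.10], [0.02]))
        assert res.estimate == pytest.approx(-0.20)
        assert res.se == pytest.approx(0.04)

    def test_zero_exposure_beta_is_error(self):
        with pytest.raises(ZeroDivisionError):
            mr.wald_ratio(make_pairs([0.0], [0.05], [0.1], [0.02]))

    def test_second_order_se_adds_exposure_term(self):
        p = make_pairs([0.5], [0.05], [0.10], [0.02])
        first = mr.wald_ratio(p).se
        second = mr.wald_ratio(p, second_order=True).se
        expected = np.sqrt(0.02**2 / 0.5**2 + 0.10**2 * 0.05**2 / 0.5**4)
        assert second == pytest.approx(expected, rel=1e-12)
        assert second > first


class TestIVW:
    def test_two_equal_weight_ratios(self):
        # ratios 0.2 and 0.4, both ratio-se 0.04
        p = make_pairs([1.0, 1.0], [0.01, 0.01], [0.2, 0.4], [0.04, 0.04])
        res = mr.ivw(p)
        assert res.estimate == pytest.approx(0.30, abs=1e-12)
        assert res.extra["se_fixed"] == pytest.approx(0.04 / np.sqrt(2), rel=1e-12)
        assert res.cochran_q == pytest.approx(12.5, rel=1e-12)
        assert res.q_df == 1

    def test_identical_ratios_have_zero_q(self):
        p = make_pairs([0.5, 0.25], [0.01, 0.01], [0.1, 0.05], [0.02, 0.01])
        res = mr.ivw(p)
        assert res.estimate == pytest.approx(0.2, rel=1e-12)
        assert res.cochran_q == pytest.approx(0.0, abs=1e-18)

    def test_single_pair_forced_equals_wald_ratio(self):
        p = make_pairs([0.5], [0.05], [0.10], [0.02])
        forced = mr.ivw(p, allow_single=True)
        wald = mr.wald_ratio(p)
        assert forced.estimate == wald.estimate
        assert forced.se == wald.se

    def test_below_two_pairs_signalled(self):
        with pytest.raises(mr.TooFewInstruments):
            mr.ivw(make_pairs([0.5], [0.05], [0.1], [0.02]))

    def test_random_effects_scaling_never_deflates(self):
        p = make_pairs([1.0, 1.0, 1.0], [0.01] * 3, [0.2, 0.2001, 0.1999], [0.04] * 3)
        res = mr.ivw(p)
        assert res.se >= res.extra["se_fixed"]


class TestEgger:
    def test_exact_line_recovers_intercept_and_slope(self):
        bx = np.array([0.2, 0.3, 0.5, 0.8])
        by = 0.05 + 0.3 * bx
        res = mr.mr_egger(make_pairs(bx, [0.01] * 4, by, [0.02] * 4))
        assert res.egger_intercept == pytest.approx(0.05, abs=1e-10)
        assert res.estimate == pytest.approx(0.3, abs=1e-10)
        assert res.extra["rss_weighted"] == pytest.approx(0.0, abs=1e-16)

    def test_orientation_makes_result_sign_consistent(self):
        bx = np.array([0.2, -0.3, 0.5, -0.8])
        by = 0.05 * np.sign(bx) + 0.3 * bx  # same line after orientation
        res = mr.mr_egger(make_pairs(bx, [0.01] * 4, by, [0.02] * 4))
        assert res.estimate == pytest.approx(0.3, abs=1e-10)

    def test_collinear_design_is_error(self):
        with pytest.raises(mr.DegenerateDesign):
            mr.mr_egger(make_pairs([0.3, 0.3, 0.3], [0.01] * 3, [0.1, 0.2, 0.3], [0.02] * 3))

    def test_too_few_instruments(self):
        with pytest.raises(mr.TooFewInstruments):
            mr.mr_egger(make_pairs([0.3, 0.4], [0.01] * 2, [0.1, 0.2], [0.02] * 2))

    def test_no_intercept_equals_fixed_effect_ivw(self):
        rng = np.random.default_rng(2)
        bx = rng.uniform(0.1, 0.6, 6)
        by = 0.25 * bx + rng.normal(0, 0.01, 6)
        se_out = rng.uniform(0.01, 0.03, 6)
        p = make_pairs(bx, [0.01] * 6, by, se_out)
        slope = mr.mr_egger(p, fit_intercept=False).estimate
        b, se = by / bx, se_out / np.abs(bx)
        w = 1 / se**2
        ivw_fixed = np.sum(w * b) / np.sum(w)
        assert slope == pytest.approx(ivw_fixed, rel=1e-10)


def oracle_weighted_median(b, w):
    """Literal restatement of the interpolation definition, kept independent
    of the implementation: walk the ordered ratios accumulating weight and
    linearly interpolate where the half-weight point falls."""
    order = np.argsort(b)
    b = np.asarray(b, float)[order]
    w = np.asarray(w, float)[order] / np.sum(w)
    s = []
    run = 0.0
    for wi in w:
        s.append(run + wi / 2.0)
        run += wi
    for i in range(1, len(b)):
        if s[i - 1] <= 0.5 <= s[i]:
            frac = (0.5 - s[i - 1]) / (s[i] - s[i - 1])
            return b[i - 1] + frac * (b[i] - b[i - 1])
    return b[0] if 0.5 < s[0] else b[-1]


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        p = make_pairs([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        res = mr.weighted_median(p, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(0.2, abs=1e-12)

    def test_unequal_weights_match_interpolation_oracle(self):
        b = np.array([0.1, 0.2, 0.3])
        w = np.array([1.0, 1.0, 8.0])
        got = mr.weighted_median_estimate(b, w)
        assert got == pytest.approx(oracle_weighted_median(b, w), abs=1e-14)
        assert got == pytest.approx(0.2 + 0.35 / 0.45 * 0.1, abs=1e-12)

    @given(
        st.lists(st.floats(-2, 2), min_size=3, max_size=8),
        st.lists(st.floats(0.1, 10), min_size=8, max_size=8),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_matches_oracle_on_random_inputs(self, b, w):
        b = np.array(b)
        w = np.array(w[: len(b)])
        got = mr.weighted_median_estimate(b, w)
        assert got == pytest.approx(oracle_weighted_median(b, w), abs=1e-10)
        assert min(b) <= got <= max(b)

    def test_bootstrap_is_seeded(self):
        p = make_pairs([1, 1, 1], [0.01] * 3, [0.1, 0.2, 0.3], [0.05] * 3)
        a = mr.weighted_median(p, n_boot=100, seed=7)
        b = mr.weighted_median(p, n_boot=100, seed=7)
        assert a.se == b.se


class TestEquivariance:
    @given(st.lists(st.booleans(), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_relabeling_alleles_leaves_estimates_unchanged(self, flips):
        # flipping both alleles negates both betas; estimators must not move
        rng = np.random.default_rng(0)
        bx = rng.uniform(0.1, 0.5, 4)
        by = 0.3 * bx + rng.normal(0, 0.02, 4)
        base = make_pairs(bx, [0.01] * 4, by, [0.02] * 4)
        flipped = base.copy()
        sign = np.where(flips, -1.0, 1.0)
        flipped["beta_exp"] *= sign
        flipped["beta_out"] *= sign
        flipped["eaf_exp"] = np.where(flips, 1 - flipped["eaf_exp"], flipped["eaf_exp"])
        assert mr.ivw(flipped).estimate == pytest.approx(mr.ivw(base).estimate, rel=1e-12)
        assert mr.mr_egger(flipped).estimate == pytest.approx(
            mr.mr_egger(base).estimate, rel=1e-12
        )
        assert mr.weighted_median(flipped, n_boot=10, seed=0).estimate == pytest.approx(
            mr.weighted_median(base, n_boot=10, seed=0).estimate, rel=1e-12
        )


def test_run_all_methods_adapts_to_instrument_count():
    one = make_pairs([0.5], [0.05], [0.1], [0.02])
    assert set(mr.run_all_methods(one)) == {"wald_ratio"}
    two = make_pairs([0.5, 0.4], [0.05] * 2, [0.1, 0.08], [0.02] * 2)
    assert set(mr.run_all_methods(two)) == {"ivw"}
    three = make_pairs([0.5, 0.4, 0.3], [0.05] * 3, [0.1, 0.08, 0.06], [0.02] * 3)
    assert set(mr.run_all_methods(three)) == {"ivw", "egger", "weighted_median"}
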