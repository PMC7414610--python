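"""Agreement statistics: ICC, CoV, bias, Bland-Altman, reliability table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cprnfl.extraction import build_pairs
from cprnfl.phantom import PhantomParams, simulate_quadrant_cohort
from cprnfl.reliability import (
    anova_mean_squares,
    bias_test,
    bland_altman,
    cov_percent,
    icc_absolute_agreement,
    icc_consistency,
    icc_sweep,
    reliability_table,
    results_to_frame,
)

from oracles import anova_mean_squares_loops, icc_a1_loops


def _random_pairs(seed, n=None):
    rng = np.random.default_rng(seed)
    n = n or int(rng.integers(3, 9))
    a = rng.normal(100, 15, n)
    b = a + rng.normal(0, 6, n) + rng.normal(0, 3)
    return a, b


class TestICC:
    def test_perfect_agreement(self):
        r = icc_absolute_agreement([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.icc == pytest.approx(1.0)
        assert not r.degenerate

    def test_five_pair_example_matches_loop_oracle(self):
        a = [10.0, 20.0, 30.0, 40.0, 50.0]
        b = [12.0, 19.0, 33.0, 38.0, 52.0]
        expected = icc_a1_loops(a, b)
        r = icc_absolute_agreement(a, b)
        assert r.icc == pytest.approx(expected, abs=1e-12)
        assert r.icc == pytest.approx(0.9911894273127753, abs=1e-12)  # frozen from the oracle

    def test_constant_offset_penalized_by_absolute_agreement(self):
        a = np.array([60.0, 75.0, 90.0, 105.0, 120.0])
        b = a + 10.0
        assert icc_absolute_agreement(a, b).icc < icc_consistency(a, b).icc
        assert icc_consistency(a, b).icc == pytest.approx(1.0)

    def test_zero_variance_degenerate_not_one(self):
        r = icc_absolute_agreement([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert r.degenerate
        assert np.isnan(r.icc)

    def test_affine_invariance(self):
        a, b = _random_pairs(3, 12)
        r0 = icc_absolute_agreement(a, b)
        r1 = icc_absolute_agreement(2.5 * a - 7.0, 2.5 * b - 7.0)
        assert r1.icc == pytest.approx(r0.icc, abs=1e-12)
        assert r1.ci_low == pytest.approx(r0.ci_low, abs=1e-9)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_loop_oracle_on_random_small_instances(self, seed):
        a, b = _random_pairs(seed)
        msr, msc, mse = anova_mean_squares(np.column_stack([a, b]))
        o_msr, o_msc, o_mse = anova_mean_squares_loops(np.column_stack([a, b]).tolist())
        assert msr == pytest.approx(o_msr, abs=1e-10)
        assert msc == pytest.approx(o_msc, abs=1e-10)
        assert mse == pytest.approx(o_mse, abs=1e-10)
        assert icc_absolute_agreement(a, b).icc == pytest.approx(icc_a1_loops(a, b), abs=1e-10)

    def test_matches_pingouin_value_and_ci(self):
        pg = pytest.importorskip("pingouin")
        a, b = _random_pairs(17, 20)
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(20), 2),
                "rater": ["r1", "r2"] * 20,
                "score": np.column_stack([a, b]).ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "subject", "rater", "score").set_index("Type")
        r = icc_absolute_agreement(a, b)
        assert r.icc == pytest.approx(ref.loc["ICC(A,1)", "ICC"], abs=1e-10)
        np.testing.assert_allclose(
            [round(r.ci_low, 2), round(r.ci_high, 2)], ref.loc["ICC(A,1)", "CI95"], atol=0.011
        )
        c = icc_consistency(a, b)
        assert c.icc == pytest.approx(ref.loc["ICC(C,1)", "ICC"], abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement([1.0, 2.0], [1.0, 2.0])


class TestCoV:
    def test_identical_pairs_zero(self):
        a = np.array([80.0, 95.0, 110.0])
        assert cov_percent(a, a) == 0.0

    def test_hand_computed_example(self):
        # S_w = sqrt(sum(d^2) / 2n) with d = (-20, 0): sqrt(400/4) = 10, grand mean 100
        assert cov_percent([90.0, 100.0], [110.0, 100.0]) == pytest.approx(10.0)

    def test_scale_invariance(self):
        a, b = _random_pairs(5, 10)
        assert cov_percent(3.7 * a, 3.7 * b) == pytest.approx(cov_percent(a, b), rel=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            cov_percent([1.0, -1.0], [-1.0, 1.0])

    def test_per_pair_method(self):
        got = cov_percent([90.0, 100.0], [110.0, 100.0], method="per_pair")
        # pair CoVs: sd/mean = 14.142/100 and 0
        assert got == pytest.approx(100 * (np.sqrt(200.0) / 100.0) / 2.0)


class TestBiasTest:
    def test_identical_arms(self):
        a = np.array([60.0, 75.0, 90.0])
        r = bias_test(a, a)
        assert r.bias == 0.0
        assert r.p == 1.0
        assert r.degenerate

    def test_constant_shift_degenerate(self):
        a = np.array([60.0, 75.0, 90.0, 105.0])
        r = bias_test(a, a - 1.0)
        assert r.bias == pytest.approx(1.0)
        assert r.ci == (pytest.approx(1.0), pytest.approx(1.0))
        assert r.p == 0.0
        assert r.degenerate

    @given(st.integers(min_value=0, max_value=5_000))
    @settings(max_examples=100, deadline=None)
    def test_equals_paired_t_test(self, seed):
        a, b = _random_pairs(seed)
        r = bias_test(a, b)
        t = stats.ttest_rel(a, b)
        ci = t.confidence_interval()
        assert r.p == pytest.approx(t.pvalue, abs=1e-10)
        assert r.bias == pytest.approx(np.mean(a - b), abs=1e-10)
        assert r.ci[0] == pytest.approx(ci.low, abs=1e-10)
        assert r.ci[1] == pytest.approx(ci.high, abs=1e-10)


class TestBlandAltman:
    def test_constant_difference(self):
        a = np.array([60.0, 75.0, 90.0, 105.0])
        ba = bland_altman(a, a - 2.0)
        assert ba.bias == pytest.approx(2.0)
        assert ba.loa_low == pytest.approx(ba.loa_high)
        assert ba.trend_slope == 0.0

    def test_forced_proportional_trend(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(60, 120, 50)
        d = 0.2 * m + rng.normal(0, 0.5, 50)
        a = m + d / 2
        b = m - d / 2
        ba = bland_altman(a, b)
        assert ba.trend_p < 1e-6
        assert ba.trend_slope == pytest.approx(0.2, abs=0.05)

    def test_loa_cover_point_differences(self):
        a, b = _random_pairs(9, 40)
        ba = bland_altman(a, b)
        d = a - b
        frac = np.mean((d >= ba.loa_low) & (d <= ba.loa_high))
        assert frac >= 0.9

    def test_null_trend_p_uniformity(self):
        # additive-only noise: the trend test should be calibrated
        rng = np.random.default_rng(4)
        hits = 0
        reps = 400
        for _ in range(reps):
            truth = rng.normal(100, 15, 50)
            a = truth + rng.normal(0, 5, 50)
            b = truth + rng.normal(0, 5, 50)
            if bland_altman(a, b).trend_p < 0.05:
                hits += 1
        assert hits / reps == pytest.approx(0.05, abs=0.03)


@pytest.fixture(scope="module")
def cohort_pairs():
    p = PhantomParams(sigma_pixel_um=0.0, missing_quadrant_prob=0.0, seed=21)
    table = simulate_quadrant_cohort(p, 20)
    return build_pairs(table, ("high_quality", "low_quality"))


class TestReliabilityTable:
    def test_shape_25_cells(self, cohort_pairs):
        results = reliability_table(cohort_pairs)
        assert len(results) == 25  # (4 quadrants + Average) x 5 locations
        frame = results_to_frame(results)
        assert set(frame["quadrant"]) == {"nasal", "temporal", "superior", "inferior", "Average"}
        assert frame["n"].eq(20).all()
        assert frame["icc"].between(-1, 1).all()
        assert (frame["cov_percent"] >= 0).all()
        assert (frame["bias_lci"] <= frame["bias_um"]).all()
        assert (frame["bias_um"] <= frame["bias_uci"]).all()

    def test_sweep_frame(self, cohort_pairs):
        sweep = icc_sweep(reliability_table(cohort_pairs))
        assert list(sweep.columns) == ["location", "quadrant", "icc", "ci_low", "ci_high"]
        assert len(sweep) == 25
        assert ((sweep["ci_low"] <= sweep["icc"]) & (sweep["icc"] <= sweep["ci_high"])).all()

    def test_icc_recovery_envelope(self):
        # true ICC 0.90: the n=51 estimate should land in [0.85, 0.95] on >=9/10 seeds
        hits = 0
        for seed in range(10):
            p = PhantomParams(
                sigma_subject_um=12.0,
                sigma_scan_um=4.0,
                sigma_assessor_um=0.0,
                sigma_pixel_um=0.0,
                missing_quadrant_prob=0.0,
                seed=3000 + seed,
            )
            df = simulate_quadrant_cohort(p, 51, locations=("ring6",))
            pairs = build_pairs(df, ("high_quality", "low_quality"))
            res = reliability_table(pairs, locations=["ring6"], quadrants=["nasal"])
            hits += 0.85 <= res[0].icc <= 0.95
        assert hits >= 9
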