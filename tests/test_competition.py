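import numpy as np
import pytest
from scipy import stats

from codonfit.competition import (
    CompetitionTrajectory,
    SelectionEstimate,
    compare_groups,
    estimate_s,
    filter_outliers,
    normality_check,
    normalize_to_reference,
)

GENS = np.array([0.0, 10.0, 20.0, 30.0])


def _traj(ratios, strain="x", dye="YFP", rep=1, gens=GENS):
    return CompetitionTrajectory(strain, dye, rep, np.asarray(gens, float), np.asarray(ratios, float))


def _est(s, strain="x", dye="YFP", rep=1):
    return SelectionEstimate(strain, dye, rep, s)


class TestEstimateS:
    def test_noiseless_recovery(self):
        traj = _traj(np.exp(-0.003 * GENS))
        assert estimate_s(traj).s == pytest.approx(-0.003, abs=1e-12)

    def test_constant_ratio_zero_slope(self):
        assert estimate_s(_traj([2.0, 2.0, 2.0, 2.0])).s == pytest.approx(0.0, abs=1e-15)

    def test_scale_equivariance_and_reciprocal_sign(self):
        ratios = np.exp(-0.004 * GENS) * 1.7
        s = estimate_s(_traj(ratios)).s
        assert estimate_s(_traj(ratios * 10)).s == pytest.approx(s)
        assert estimate_s(_traj(1 / ratios)).s == pytest.approx(-s)

    def test_endpoint_estimator(self):
        ratios = np.exp(-0.005 * GENS)
        assert estimate_s(_traj(ratios), method="endpoints").s == pytest.approx(-0.005)

    def test_monte_carlo_mean_unbiased(self, rng):
        """1,000 noisy trajectories with true s = -0.005: the mean estimate
        sits within 3 standard errors of truth."""
        true = -0.005
        sx2 = np.sum((GENS - GENS.mean()) ** 2)
        draws = []
        for _ in range(1000):
            lnr = true * GENS + rng.normal(0, 0.02, size=4)
            draws.append(estimate_s(_traj(np.exp(lnr))).s)
        se = 0.02 / np.sqrt(sx2) / np.sqrt(1000)
        assert np.mean(draws) == pytest.approx(true, abs=3 * se)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            CompetitionTrajectory("x", "YFP", 1, np.array([0.0]), np.array([1.0]))

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            _traj([1.0, 0.0, 1.0, 1.0])


class TestOutlierFilter:
    def test_tight_group_untouched(self):
        ests = [_est(0.001 + d) for d in np.linspace(-0.002, 0.002, 12)]
        kept, removed = filter_outliers(ests, window=0.008)
        assert len(kept) == 12 and not removed

    def test_single_outlier_removed(self):
        ests = [_est(0.0, rep=i) for i in range(11)] + [_est(0.01, rep=99)]
        kept, removed = filter_outliers(ests, window=0.008)
        assert [e.replicate for e in removed] == [99]

    def test_matches_brute_force_threshold(self, rng):
        vals = rng.normal(0, 0.003, size=24)
        vals[rng.choice(24, 3, replace=False)] += 0.02
        ests = [_est(v, rep=i) for i, v in enumerate(vals)]
        kept, removed = filter_outliers(ests, window=0.008)
        med = np.median(vals)
        brute = {i for i, v in enumerate(vals) if abs(v - med) > 0.008}
        assert {e.replicate for e in removed} == brute

    def test_idempotent_on_kept(self, rng):
        vals = rng.normal(0, 0.004, size=24)
        ests = [_est(v, rep=i) for i, v in enumerate(vals)]
        kept, _ = filter_outliers(ests)
        kept2, removed2 = filter_outliers(kept)
        assert kept2 == kept and not removed2


class TestNormalization:
    def test_simple_subtraction(self):
        ctrl = [_est(-0.001, strain="c", rep=i) for i in range(3)]
        [norm] = normalize_to_reference([_est(-0.004)], ctrl)
        assert norm.s == pytest.approx(-0.003)

    def test_control_mean_maps_to_zero(self):
        ctrl = [_est(-0.002 + d, strain="c", rep=i) for i, d in enumerate([-1e-3, 0, 1e-3])]
        norm = normalize_to_reference(ctrl, ctrl)
        assert np.mean([e.s for e in norm]) == pytest.approx(0.0, abs=1e-15)

    def test_batchwise_normalization(self):
        ctrl = [_est(-0.001, strain="c", dye="YFP"), _est(0.003, strain="c", dye="BFP")]
        tests = [_est(0.0, dye="YFP"), _est(0.0, dye="BFP")]
        norm = normalize_to_reference(tests, ctrl)
        assert norm[0].s == pytest.approx(0.001)
        assert norm[1].s == pytest.approx(-0.003)

    def test_missing_batch_named(self):
        with pytest.raises(ValueError, match="BFP"):
            normalize_to_reference([_est(0.0, dye="BFP")], [_est(0.0, dye="YFP")])


class TestCompareGroups:
    def test_identical_groups(self):
        g = [0.001, 0.002, 0.003]
        res = compare_groups(g, g)
        assert res.selective_disadvantage == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_pure_shift_reported_as_positive_cost(self):
        ctrl = [0.0, 1e-5, -1e-5]
        test = [v - 0.0072 for v in ctrl]
        res = compare_groups(test, ctrl)
        assert res.selective_disadvantage == pytest.approx(0.0072, abs=1e-9)
        assert res.ci95[0] <= res.selective_disadvantage <= res.ci95[1]

    def test_degenerate_variance_warns_and_collapses_ci(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = compare_groups([0.1, 0.1], [0.1, 0.1])
        assert res.ci95 == (0.0, 0.0)

    def test_ci_coverage_near_nominal(self, rng):
        """24 vs 24 with a true shift of 0.003 and sigma 0.0025: the 95% CI
        covers the truth in about 95% of 1,000 replicates."""
        hits = 0
        for _ in range(1000):
            ctrl = rng.normal(0, 0.0025, 24)
            test = rng.normal(-0.003, 0.0025, 24)
            res = compare_groups(test.tolist(), ctrl.tolist())
            hits += res.ci95[0] <= 0.003 <= res.ci95[1]
        assert 0.93 <= hits / 1000 <= 0.97


class TestNormalityCheck:
    def test_calibrated_on_normal_samples(self):
        """Repeated n=168 normal samples: ~5% rejection at alpha=0.05."""
        rejections = 0
        trials = 400
        for seed in range(trials):
            vals = np.random.default_rng(seed).normal(0, 0.0025, size=168)
            _, p = normality_check(vals)
            rejections += p < 0.05
        assert 0.02 <= rejections / trials <= 0.09

    def test_detects_heavy_contamination(self):
        small = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            vals = rng.normal(0, 0.0025, size=168)
            vals[:17] += rng.choice([-1, 1], 17) * 0.02
            _, p = normality_check(vals)
            small += p < 0.05
        assert small > 50

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normality_check([1.0] * 10)

    def test_n_out_of_range(self):
        with pytest.raises(ValueError):
            normality_check([0.0, 1.0])
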