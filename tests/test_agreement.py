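"""RMSE, Bland–Altman, reliability/SEM/MDC and non-inferiority statistics."""

import math

import numpy as np
import pytest

from spinemotion.agreement import (
    PairedAngleSamples,
    ReliabilityUndefinedError,
    bland_altman,
    interpret_rmse,
    mdc95_from_sem,
    noninferiority_speed,
    reliability_sem_mdc,
    rmse,
    round_half_up,
    sample_points,
    sem_from_reliability,
)


def _pair(x1, x2):
    return PairedAngleSamples(np.asarray(x1, float), np.asarray(x2, float))


class TestRMSE:
    def test_identical_is_zero(self):
        assert rmse(_pair([1, 2, 3], [1, 2, 3])) == 0.0

    @pytest.mark.parametrize("c", [-3.2, 0.5, 7.0])
    def test_constant_offset(self, c):
        x = np.linspace(0, 40, 50)
        assert rmse(_pair(x + c, x)) == pytest.approx(abs(c))

    def test_direct_evaluation(self):
        assert rmse(_pair([0, 0], [3, 4])) == pytest.approx(math.sqrt(12.5))

    def test_permutation_invariance(self, rng):
        x1 = rng.normal(size=30)
        x2 = rng.normal(size=30)
        perm = rng.permutation(30)
        assert rmse(_pair(x1, x2)) == pytest.approx(rmse(_pair(x1[perm], x2[perm])))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            _pair([1, 2], [1, 2, 3])


class TestInterpretation:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.0, "Good"),
            (1.9, "Good"),
            (2.0, "Good"),
            (2.01, "Acceptable"),
            (5.0, "Acceptable"),
            (7.5, "Tolerable"),
            (10.0, "Tolerable"),
            (12.0, "Unbearable"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_rmse(value) == band

    def test_monotone_step_function(self):
        order = {"Good": 0, "Acceptable": 1, "Tolerable": 2, "Unbearable": 3}
        grid = np.linspace(0, 15, 301)
        ranks = [order[interpret_rmse(v)] for v in grid]
        assert all(b >= a for a, b in zip(ranks, ranks[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            interpret_rmse(-0.1)


class TestSamplePoints:
    def test_full_series_when_k_equals_n(self):
        p = _pair(np.arange(10), np.arange(10))
        out = sample_points(p, k=10, seed=99)
        assert np.array_equal(out.x1, p.x1)

    def test_deterministic_for_seed(self):
        p = _pair(np.arange(100), np.arange(100) * 2.0)
        a = sample_points(p, k=10, seed=7)
        b = sample_points(p, k=10, seed=7)
        assert np.array_equal(a.x1, b.x1)
        c = sample_points(p, k=10, seed=8)
        assert not np.array_equal(a.x1, c.x1)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            sample_points(_pair([1, 2], [1, 2]), k=5, seed=0)

    def test_uniformity(self):
        # each of 100 indices should be drawn with frequency ~ k/n = 0.10
        counts = np.zeros(100)
        p = _pair(np.arange(100), np.arange(100))
        n_draws = 10_000
        for seed in range(n_draws):
            counts[sample_points(p, k=10, seed=seed).x1.astype(int)] += 1
        freq = counts / n_draws
        assert np.all(np.abs(freq - 0.10) < 0.01)


class TestBlandAltman:
    def test_identical_pairs(self):
        r = bland_altman(_pair([5, 6, 7], [5, 6, 7]))
        assert r.bias == 0.0 and r.loa_low == r.loa_high == 0.0
        assert r.degenerate

    def test_constant_difference(self):
        r = bland_altman(_pair([3, 4, 5], [1, 2, 3]))
        assert r.bias == pytest.approx(2.0)
        assert r.sd_diff == 0.0
        assert (r.loa_low, r.loa_high) == (pytest.approx(2.0), pytest.approx(2.0))
        assert r.normality_ok

    def test_seeded_normal_differences(self):
        rng = np.random.default_rng(2024)
        x2 = rng.uniform(0, 40, 400)
        d = rng.normal(0.5, 1.0, 400)
        r = bland_altman(_pair(x2 + d, x2))
        assert abs(r.bias - 0.5) < 0.15
        assert abs(r.loa_high - 2.46) < 0.25
        assert r.normality_ok and r.shapiro_W > 0.96

    def test_bias_is_mean_difference_and_loa_symmetric(self, rng):
        x1 = rng.normal(size=50)
        x2 = rng.normal(size=50)
        r = bland_altman(_pair(x1, x2))
        assert r.bias == pytest.approx(np.mean(x1 - x2), abs=1e-12)
        assert (r.loa_high - r.bias) == pytest.approx(r.bias - r.loa_low, abs=1e-12)


class TestReliability:
    def test_published_style_sem_cells(self):
        # closed-form SEM from (SD, r) pairs, at one-decimal rounding
        assert round_half_up(sem_from_reliability(25.2, 0.999)) == 0.8
        assert round_half_up(sem_from_reliability(14.1, 0.996)) == 0.9

    def test_published_style_mdc_cells(self):
        assert round_half_up(mdc95_from_sem(0.7)) == 1.9
        assert round_half_up(mdc95_from_sem(0.9)) == 2.5

    def test_perfect_agreement(self):
        x = np.linspace(0, 30, 20)
        r = reliability_sem_mdc(_pair(x, x))
        assert r.r == pytest.approx(1.0)
        assert r.sem == pytest.approx(0.0, abs=1e-9)
        assert r.mdc95 == pytest.approx(0.0, abs=1e-9)

    def test_mdc_sem_ratio_exact(self, rng):
        x = rng.uniform(0, 40, 200)
        res = reliability_sem_mdc(_pair(x + rng.normal(0, 1, 200), x))
        assert res.mdc95 / res.sem == pytest.approx(1.96 * math.sqrt(2))

    def test_sem_monotone_in_r(self):
        sems = [sem_from_reliability(20.0, r) for r in (0.9, 0.99, 0.999)]
        assert sems[0] > sems[1] > sems[2]

    def test_degenerate_variance(self):
        with pytest.raises(ReliabilityUndefinedError):
            reliability_sem_mdc(_pair([1, 1, 1, 1], [2, 3, 4, 5]))


class TestNonInferiority:
    def test_identical_groups_reject(self, rng):
        vals = rng.normal(1.0, 0.3, 20)
        r = noninferiority_speed(vals, vals.copy(), threshold=2.0)
        assert r.reject_h0 and r.p_value < 0.001

    def test_null_boundary(self, rng):
        # true difference exactly at the margin: p should hover near 0.5
        slow = rng.normal(1.0, 0.2, 5000)
        fast = rng.normal(3.0, 0.2, 5000)
        r = noninferiority_speed(fast, slow, threshold=2.0)
        assert 0.3 < r.p_value < 0.7

    def test_exceeding_margin_not_rejected(self, rng):
        slow = rng.normal(1.0, 0.2, 30)
        fast = rng.normal(4.0, 0.2, 30)
        r = noninferiority_speed(fast, slow, threshold=2.0)
        assert not r.reject_h0 and r.p_value > 0.975

    def test_power_under_true_equality(self):
        # sigma=0.5, n=20/group, margin 2 deg: rejection essentially certain
        rng = np.random.default_rng(31415)
        rejections = 0
        reps = 300
        for _ in range(reps):
            fast = rng.normal(1.0, 0.5, 20)
            slow = rng.normal(1.0, 0.5, 20)
            rejections += noninferiority_speed(fast, slow, threshold=2.0).reject_h0
        assert rejections / reps > 0.99

    def test_degenerate_variance_direct_decision(self):
        r = noninferiority_speed([1.0, 1.0], [1.0, 1.0], threshold=2.0)
        assert r.degenerate and r.reject_h0

    def test_paired_mode(self, rng):
        base = rng.normal(1.0, 0.3, 20)
        r = noninferiority_speed(base + 0.05, base, threshold=1.0, paired=True)
        assert r.reject_h0

    def test_invariants(self):
        with pytest.raises(ValueError):
            noninferiority_speed([1.0], [1.0, 2.0], threshold=1.0)
        with pytest.raises(ValueError):
            noninferiority_speed([1, 2], [1, 2], threshold=0.0)


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(0.25, 0.3), (0.24, 0.2), (-0.25, -0.3), (1.95, 2.0), (2.449, 2.4)]
    )
    def test_half_up(self, x, expected):
        assert round_half_up(x) == pytest.approx(expected)
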