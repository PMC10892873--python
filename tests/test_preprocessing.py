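"""Resampling, synchronization, outlier screening and signal repair."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from spinemotion.preprocessing import (
    IrreparableTrialError,
    UnsynchronizableError,
    detect_outliers,
    overlap_pair,
    repair,
    resample,
    synchronize,
)
from spinemotion.rotations import from_scipy, global_rotation_angle
from spinemotion.series import OrientationSeries, SchemaError


def _single_axis_series(rate=100.0, duration=5.0, amp=30.0, period=2.0, axis="y", valid=None):
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    ang = amp * np.sin(np.pi * t / period) ** 2
    q = from_scipy(Rotation.from_euler(axis, np.asarray(ang)[:, None], degrees=True))
    return OrientationSeries(t, q, valid), ang


def _neutral_padded(ang_fn, rate=100.0, duration=6.0, prefix=1.0, axis="y"):
    n = int(duration * rate) + 1
    t = np.arange(n) / rate
    ang = np.where(t < prefix, 0.0, ang_fn(np.maximum(t - prefix, 0.0)))
    q = from_scipy(Rotation.from_euler(axis, np.asarray(ang)[:, None], degrees=True))
    return OrientationSeries(t, q), ang


class TestResample:
    def test_own_rate_is_identity(self):
        s, _ = _single_axis_series()
        out = resample(s, 100.0)
        assert np.abs(out.quaternions - s.quaternions).max() < 1e-9
        assert np.allclose(out.timestamps, s.timestamps)

    def test_constant_orientation_any_rate(self):
        q = from_scipy(Rotation.from_euler("z", np.full((50, 1), 20.0), degrees=True))
        s = OrientationSeries(np.arange(50) / 50.0, q)
        out = resample(s, 173.0)
        assert np.abs(out.quaternions - out.quaternions[0]).max() < 1e-12

    def test_linear_trajectory_closed_form(self):
        # constant angular velocity: slerp reproduces the exact angle ramp
        rate = 60.0
        t = np.arange(int(3 * rate) + 1) / rate
        ang = 12.0 * t
        s = OrientationSeries(t, from_scipy(Rotation.from_euler("x", np.asarray(ang)[:, None], degrees=True)))
        out = resample(s, 97.0)
        got = global_rotation_angle(out.quaternions)
        assert np.abs(got - 12.0 * out.timestamps).max() < 1e-6

    def test_valid_mask_propagates_conservatively(self):
        valid = np.ones(501, dtype=bool)
        valid[100] = False
        s, _ = _single_axis_series(valid=valid)
        out = resample(s, 90.0)
        # any resampled point bracketed by the invalid source sample is invalid
        bad_t = s.timestamps[100]
        near = np.abs(out.timestamps - bad_t) < 1.0 / 90.0
        assert not out.valid[near].all()
        assert out.valid.sum() > 0.9 * len(out)

    def test_too_short_series(self):
        s = OrientationSeries([0.0], [[1, 0, 0, 0]])
        with pytest.raises(SchemaError):
            resample(s, 100.0)


def _shift_series(s: OrientationSeries, k: int) -> OrientationSeries:
    """Delay (k>0) or advance (k<0) by k samples with edge padding."""
    q = s.quaternions
    if k >= 0:
        qs = np.vstack([np.tile(q[0], (k, 1)), q[: len(q) - k]])
    else:
        qs = np.vstack([q[-k:], np.tile(q[-1], (-k, 1))])
    return OrientationSeries(s.timestamps, qs)


class TestSynchronize:
    def test_self_sync_zero_lag(self):
        s, _ = _neutral_padded(lambda u: 30.0 * np.sin(np.pi * u / 2.0) ** 2)
        r = synchronize(s, s)
        assert r.lag_samples == 0
        assert r.peak_correlation == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [-150, -17, 0, 17, 60, 199])
    def test_integer_shift_recovered_exactly(self, k):
        s, _ = _neutral_padded(lambda u: 30.0 * np.sin(np.pi * u / 2.0) ** 2, duration=8.0)
        b = _shift_series(s, k)
        r = synchronize(s, b, neutral_tolerance=np.inf)
        assert r.lag_samples == k
        assert r.peak_correlation > 0.999

    def test_channel_selection_prefers_largest_rom(self):
        rate = 100.0
        t = np.arange(int(6 * rate) + 1) / rate
        u = np.maximum(t - 1.0, 0.0)
        fl = 5.0 * np.sin(np.pi * u / 2.0) ** 2
        rot = 35.0 * np.sin(np.pi * u / 2.0) ** 2
        q = from_scipy(Rotation.from_euler("YXZ", np.column_stack([fl, 0 * fl, rot]), degrees=True))
        s = OrientationSeries(t, q)
        r = synchronize(s, s)
        assert r.channel_used == "rotation"

    def test_flat_signal_unsynchronizable(self):
        q = np.tile([1.0, 0, 0, 0], (400, 1))
        s = OrientationSeries(np.arange(400) / 100.0, q)
        with pytest.raises(UnsynchronizableError):
            synchronize(s, s)

    def test_missing_neutral_prefix_rejected(self):
        s, _ = _single_axis_series(amp=40.0, period=1.5)  # motion starts immediately
        with pytest.raises(UnsynchronizableError):
            synchronize(s, s)

    def test_overlap_pair_alignment(self):
        s, ang = _neutral_padded(lambda u: 25.0 * np.sin(np.pi * u / 2.0) ** 2)
        b = _shift_series(s, 40)
        a2, b2 = overlap_pair(s, b, 40)
        assert len(a2) == len(b2) == len(s) - 40
        assert np.abs(a2.quaternions - b2.quaternions).max() < 1e-12


class TestDetectOutliers:
    def test_constant_has_no_outliers(self):
        q = np.tile([1.0, 0, 0, 0], (100, 1))
        s = OrientationSeries(np.arange(100) / 100.0, q)
        assert not detect_outliers(s).any()

    def test_teleported_sample_flagged(self):
        s, _ = _single_axis_series(amp=20.0)
        q = s.quaternions.copy()
        q[250] = from_scipy(Rotation.from_euler("y", 10.0, degrees=True) * Rotation.from_quat(np.roll(q[250], -1)))
        s2 = OrientationSeries(s.timestamps, q)
        mask = detect_outliers(s2)
        assert mask[250]
        assert mask[249] or mask[251]

    def test_fast_but_legitimate_motion_not_flagged(self):
        # peak velocity amp*pi/period = 90 deg/s < 120 deg/s
        s, _ = _single_axis_series(amp=45.0, period=np.pi / 2)
        assert not detect_outliers(s).any()

    def test_rate_consistency(self):
        # same continuous trajectory sampled twice as fast flags the same times
        def make(rate):
            n = int(5 * rate) + 1
            t = np.arange(n) / rate
            ang = 20.0 * np.sin(np.pi * t / 2.0) ** 2
            ang[np.abs(t - 2.5) < 1e-9] += 15.0  # instantaneous glitch
            return OrientationSeries(t, from_scipy(Rotation.from_euler("y", np.asarray(ang)[:, None], degrees=True)))

        for rate in (100.0, 200.0):
            s = make(rate)
            flagged_times = s.timestamps[detect_outliers(s)]
            assert np.all(np.abs(flagged_times - 2.5) <= 1.5 / rate)
            assert len(flagged_times) > 0


class TestRepair:
    def _series_with_mask(self, flagged_idx, n=200, rate=100.0):
        t = np.arange(n) / rate
        ang = 10.0 * t  # constant velocity
        s = OrientationSeries(t, from_scipy(Rotation.from_euler("z", np.asarray(ang)[:, None], degrees=True)))
        mask = np.zeros(n, dtype=bool)
        mask[flagged_idx] = True
        return s, mask, ang

    def test_sparse_flag_filled_by_slerp(self):
        s, mask, ang = self._series_with_mask([50])
        out = repair(s, mask)
        assert out.valid[50]
        got = global_rotation_angle(out.quaternions[50])
        assert abs(got - ang[50]) < 1e-6

    def test_dense_window_left_invalid(self):
        # 12 of 20 samples flagged (60%) in every containing window
        t = np.arange(20) / 100.0
        ang = 5.0 + 0.0 * t
        s = OrientationSeries(t, from_scipy(Rotation.from_euler("z", np.asarray(ang)[:, None], degrees=True)))
        mask = np.zeros(20, dtype=bool)
        mask[4:16] = True
        out = repair(s, mask)
        assert not out.valid[4:16].any()

    def test_unflagged_samples_untouched(self):
        s, mask, _ = self._series_with_mask([30, 31])
        out = repair(s, mask)
        keep = ~mask
        assert np.array_equal(out.quaternions[keep], s.quaternions[keep])
        assert np.all(np.diff(out.timestamps) > 0)
        assert np.abs(np.linalg.norm(out.quaternions, axis=1) - 1).max() < 1e-9

    def test_fill_matches_ground_truth_on_constant_velocity(self):
        s, mask, ang = self._series_with_mask([80, 81, 82])
        out = repair(s, mask)
        got = global_rotation_angle(out.quaternions[80:83])
        assert np.abs(got - ang[80:83]).max() < 1e-6

    def test_everything_flagged_is_irreparable(self):
        s, mask, _ = self._series_with_mask(np.arange(200))
        with pytest.raises(IrreparableTrialError):
            repair(s, mask)
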