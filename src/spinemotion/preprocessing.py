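"""Temporal alignment of the two streams and reference-signal repair.

The encoder and mocap systems run on independent clocks at different
rates.  Both streams are slerp-resampled to a common rate, synchronized by
cross-correlating the anatomical-angle channel with the greatest range of
motion (each trial keeps one second of neutral rest before movement
initiation to standardize this), and the reference stream is screened for
marker-obstruction artifacts: samples moving faster than 120 deg/s of
global rotation are flagged, and flagged stretches are slerp-interpolated
when fewer than half the samples in a 0.2 s span are affected, otherwise
left invalid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Slerp

from .rotations import as_scipy, euler_series, from_scipy
from .series import OrientationSeries, SchemaError

__all__ = [
    "UnsynchronizableError",
    "IrreparableTrialError",
    "SyncResult",
    "resample",
    "synchronize",
    "shift_lag",
    "overlap_pair",
    "detect_outliers",
    "repair",
]

PLANE_NAMES = ("flexion", "lateral_flexion", "rotation")


class UnsynchronizableError(ValueError):
    """Signals are too flat or too short to cross-correlate."""


class IrreparableTrialError(ValueError):
    """Too much of the reference signal is corrupted to reconstruct."""


@dataclass(frozen=True)
class SyncResult:
    """Outcome of cross-correlation synchronization.

    Positive ``lag`` means the second stream trails the first: sample ``i``
    of the first stream pairs with sample ``i + lag_samples`` of the second.
    """

    lag: float
    lag_samples: int
    peak_correlation: float
    channel_used: str


def resample(series: OrientationSeries, rate: float) -> OrientationSeries:
    """Resample to a uniform grid at ``rate`` Hz using quaternion slerp.

    A resampled point is valid only when both bracketing source samples
    are valid (conservative propagation of the validity mask).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(series) < 2:
        raise SchemaError("cannot resample a series with fewer than 2 samples")
    t = series.timestamps
    dt = 1.0 / rate
    n_new = int(np.floor((t[-1] - t[0]) / dt + 1e-9)) + 1
    new_t = t[0] + dt * np.arange(n_new)
    new_t = np.minimum(new_t, t[-1])  # clamp FP overshoot at the end

    sl = Slerp(t, as_scipy(series.quaternions))
    new_q = from_scipy(sl(new_t))

    left = np.clip(np.searchsorted(t, new_t, side="right") - 1, 0, len(t) - 1)
    right = np.clip(left + 1, 0, len(t) - 1)
    exact = np.isclose(new_t, t[left], atol=1e-9)
    new_valid = np.where(
        exact, series.valid[left], series.valid[left] & series.valid[right]
    )
    return OrientationSeries(new_t, np.atleast_2d(new_q), new_valid, series.source, series.frame)


def _common_rate(a: OrientationSeries, b: OrientationSeries) -> float:
    ra, rb = a.rate, b.rate
    if abs(ra - rb) > 1e-3 * ra:
        raise UnsynchronizableError(
            f"streams must share a sampling rate before sync ({ra:.3f} vs {rb:.3f} Hz)"
        )
    return ra


def synchronize(
    a: OrientationSeries,
    b: OrientationSeries,
    max_lag: float = 2.0,
    min_rom: float = 1.0,
    neutral_prefix: float = 1.0,
    neutral_tolerance: float = 5.0,
    subsample_refine: bool = False,
) -> SyncResult:
    """Estimate the inter-system lag by normalized cross-correlation.

    The anatomical-angle channel with the greatest range of motion in ``a``
    is correlated (mean-removed) against the same channel of ``b`` over
    lags up to ``max_lag`` seconds.  Both streams must begin with at least
    ``neutral_prefix`` seconds of quasi-neutral rest.
    """
    rate = _common_rate(a, b)
    ea = euler_series(a.quaternions)
    eb = euler_series(b.quaternions)
    rom = ea.max(axis=0) - ea.min(axis=0)
    ch = int(np.argmax(rom))
    if rom[ch] < min_rom:
        raise UnsynchronizableError(
            f"largest anatomical range of motion is {rom[ch]:.2f} deg (< {min_rom} deg)"
        )
    n_pref = int(round(neutral_prefix * rate))
    for name, e in (("first", ea), ("second", eb)):
        pre = e[:n_pref, ch]
        if len(pre) < n_pref:
            raise UnsynchronizableError(f"{name} stream shorter than the neutral prefix")
        if pre.max() - pre.min() > neutral_tolerance:
            raise UnsynchronizableError(
                f"{name} stream does not start with {neutral_prefix} s of neutral rest"
            )

    x = ea[:, ch]
    y = eb[:, ch]
    max_k = int(round(max_lag * rate))
    lags = np.arange(-max_k, max_k + 1)
    corr = np.full(len(lags), -np.inf)
    for j, L in enumerate(lags):
        xs = x[: len(x) - L] if L >= 0 else x[-L:]
        ys = y[L:][: len(xs)] if L >= 0 else y[: len(xs)]
        if len(xs) < 2:
            continue
        xd = xs - xs.mean()
        yd = ys - ys.mean()
        norm = np.sqrt(np.sum(xd**2) * np.sum(yd**2))
        if norm == 0:
            continue
        corr[j] = float(np.dot(xd, yd) / norm)
    if not np.isfinite(corr).any():
        raise UnsynchronizableError("flat signals cannot be correlated")
    i = int(np.argmax(corr))
    lag_samples = int(lags[i])
    lag = lag_samples / rate
    if subsample_refine and 0 < i < len(corr) - 1:
        c0, c1, c2 = corr[i - 1], corr[i], corr[i + 1]
        denom = c0 - 2 * c1 + c2
        if denom < 0:
            lag = (lags[i] + 0.5 * (c0 - c2) / denom) / rate
    return SyncResult(
        lag=float(lag),
        lag_samples=lag_samples,
        peak_correlation=float(corr[i]),
        channel_used=PLANE_NAMES[ch],
    )


def shift_lag(series: OrientationSeries, lag: float) -> OrientationSeries:
    """Move a trailing stream's clock back by ``lag`` seconds."""
    out = series.copy()
    out.timestamps = out.timestamps - lag
    return out


def overlap_pair(
    a: OrientationSeries, b: OrientationSeries, lag_samples: int = 0
) -> tuple[OrientationSeries, OrientationSeries]:
    """Trim two same-rate streams to their paired overlap after a lag shift.

    Sample ``i`` of ``a`` is paired with sample ``i + lag_samples`` of
    ``b``; both outputs carry ``a``'s timestamps.
    """
    _common_rate(a, b)
    n = min(len(a), len(b) - lag_samples) if lag_samples >= 0 else min(len(a) + lag_samples, len(b))
    if n <= 0:
        raise UnsynchronizableError("no overlap between streams at this lag")
    ia = np.arange(n) if lag_samples >= 0 else np.arange(-lag_samples, -lag_samples + n)
    ib = ia + lag_samples
    ts = a.timestamps[ia]
    aa = OrientationSeries(ts, a.quaternions[ia], a.valid[ia], a.source, a.frame)
    bb = OrientationSeries(ts, b.quaternions[ib], b.valid[ib], b.source, b.frame)
    return aa, bb


def detect_outliers(series: OrientationSeries, velocity_threshold: float = 120.0) -> np.ndarray:
    """Flag samples whose instantaneous global velocity exceeds the threshold.

    Velocity between consecutive samples is the relative-rotation angle
    divided by the time step; both samples bounding an offending step are
    flagged (either could be the corrupted one).
    """
    n = len(series)
    mask = np.zeros(n, dtype=bool)
    if n < 2:
        return mask
    r = as_scipy(series.quaternions)
    step = np.degrees((r[:-1].inv() * r[1:]).magnitude())
    vel = step / np.diff(series.timestamps)
    bad = vel > velocity_threshold
    mask[:-1] |= bad
    mask[1:] |= bad
    return mask


def repair(
    series: OrientationSeries,
    mask: np.ndarray,
    window: float = 0.2,
    max_flagged_fraction: float = 0.5,
) -> OrientationSeries:
    """Reconstruct flagged samples where the corruption is sparse enough.

    Sliding ``window``-second spans (50% overlap) are examined; a flagged
    sample is eligible for repair if any span containing it has a flagged
    fraction below ``max_flagged_fraction``.  Eligible samples are replaced
    by slerp between the nearest unflagged valid neighbours and marked
    valid; the rest are marked invalid.  Unflagged samples are never
    modified.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape[0] != len(series):
        raise SchemaError("mask length must match the series")
    out = series.copy()
    if not mask.any():
        return out
    good = ~mask & series.valid
    if not good.any():
        raise IrreparableTrialError("every sample of the series is flagged")

    t = series.timestamps
    rate = series.rate
    w = max(2, int(round(window * rate)))
    step = max(1, w // 2)
    repairable = np.zeros(len(series), dtype=bool)
    for start in range(0, len(series), step):
        sl = slice(start, min(start + w, len(series)))
        frac = mask[sl].mean()
        if frac < max_flagged_fraction:
            repairable[sl] = True
    repairable &= mask

    good_idx = np.flatnonzero(good)
    rot_good = as_scipy(series.quaternions[good_idx])
    fix_idx = np.flatnonzero(repairable)
    pos = np.searchsorted(good_idx, fix_idx)
    interior = (pos > 0) & (pos < len(good_idx))
    fix_interior = fix_idx[interior]
    if len(fix_interior):
        sl = Slerp(t[good_idx], rot_good)
        out.quaternions[fix_interior] = np.atleast_2d(from_scipy(sl(t[fix_interior])))
        out.valid[fix_interior] = True
    # flagged but not repaired (dense corruption or no bracketing neighbour)
    dead = mask & ~np.isin(np.arange(len(series)), fix_interior)
    out.valid[dead] = False
    return out
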