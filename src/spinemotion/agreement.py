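"""Concurrent-validity statistics for paired angle measurements.

Four families of evidence are computed between the mannequin and the
reference system:

* **RMSE** — root-mean-square error of the paired angle traces, read
  against the clinical interpretation bands (<=2 deg good, <=5 acceptable,
  <=10 tolerable, above that unbearable).
* **Bland–Altman** — bias (mean difference) and limits of agreement
  (bias +/- 1.96 SD of the differences), with a Shapiro–Wilk check that
  the differences are approximately normal.
* **Parallel-forms reliability** — the Pearson correlation r between the
  two systems' scores, from which the standard error of measurement
  SEM = SD*sqrt(1-r) and the minimal detectable change
  MDC95 = 1.96*sqrt(2)*SEM follow.
* **Non-inferiority** — a one-sided t-test (alpha = 2.5%) that the RMSE
  difference between fast and slow trials stays below an MDC-based margin,
  i.e. that motion speed does not degrade accuracy.

Bland–Altman and reliability operate on a fixed number of randomly
sampled points per trial so fast and slow trials are equally represented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "PairedAngleSamples",
    "BlandAltmanResult",
    "ReliabilityResult",
    "NonInferiorityResult",
    "ReliabilityUndefinedError",
    "rmse",
    "interpret_rmse",
    "sample_points",
    "bland_altman",
    "reliability_sem_mdc",
    "sem_from_reliability",
    "mdc95_from_sem",
    "noninferiority_speed",
    "round_half_up",
    "RMSE_BANDS",
]

MDC_FACTOR = 1.96 * math.sqrt(2.0)

#: Upper edges (inclusive) of the RMSE interpretation bands, in degrees.
RMSE_BANDS = (("Good", 2.0), ("Acceptable", 5.0), ("Tolerable", 10.0))


class ReliabilityUndefinedError(ValueError):
    """Reliability statistics need non-degenerate variance in both series."""


@dataclass
class PairedAngleSamples:
    """Paired mannequin (x1) / reference (x2) angles in degrees."""

    x1: np.ndarray
    x2: np.ndarray
    trial_id: str = ""
    plane: str = "global"
    speed: str = ""

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if self.x1.shape != self.x2.shape or self.x1.ndim != 1:
            raise ValueError("x1 and x2 must be 1-D arrays of equal length")
        if len(self.x1) < 1:
            raise ValueError("paired samples must be non-empty")
        if not (np.isfinite(self.x1).all() and np.isfinite(self.x2).all()):
            raise ValueError("paired samples must be finite")

    def __len__(self) -> int:
        return len(self.x1)


@dataclass
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    shapiro_W: float
    normality_ok: bool
    degenerate: bool = False


@dataclass
class ReliabilityResult:
    r: float
    sd: float
    sem: float
    mdc95: float


@dataclass
class NonInferiorityResult:
    mean_diff: float
    threshold: float
    t_stat: float
    p_value: float
    alpha: float
    reject_h0: bool
    degenerate: bool = False


def rmse(pair: PairedAngleSamples) -> float:
    """Root-mean-square error sqrt(sum((x1-x2)^2)/n), in degrees."""
    d = pair.x1 - pair.x2
    return float(np.sqrt(np.mean(d**2)))


def interpret_rmse(value: float) -> str:
    """Clinical interpretation band for an RMSE value (degrees)."""
    if value < 0:
        raise ValueError("RMSE cannot be negative")
    for band, upper in RMSE_BANDS:
        if value <= upper:
            return band
    return "Unbearable"


def sample_points(pair: PairedAngleSamples, k: int = 10, seed: int = 0) -> PairedAngleSamples:
    """Draw ``k`` paired points uniformly without replacement, reproducibly.

    Sampling a fixed count per trial is what equalizes the weight of fast
    (short) and slow (long) trials in the pooled analyses.
    """
    n = len(pair)
    if k > n:
        raise ValueError(f"cannot sample {k} points from {n} pairs")
    if k == n:
        idx = np.arange(n)
    else:
        idx = np.sort(np.random.default_rng(seed).choice(n, size=k, replace=False))
    return PairedAngleSamples(pair.x1[idx], pair.x2[idx], pair.trial_id, pair.plane, pair.speed)


def bland_altman(pair: PairedAngleSamples) -> BlandAltmanResult:
    """Bias and 95% limits of agreement of the paired differences.

    The limits assume approximately normal differences; the Shapiro–Wilk
    statistic W is reported with ``normality_ok = (W > 0.96)`` as a soft
    gate — the analysis proceeds either way, mirroring standard practice
    with near-normal difference distributions.
    """
    d = pair.x1 - pair.x2
    bias = float(np.mean(d))
    if len(d) < 2 or np.allclose(d, d[0]):
        return BlandAltmanResult(bias, 0.0, bias, bias, 1.0, True, degenerate=True)
    sd = float(np.std(d, ddof=1))
    w = float(stats.shapiro(d).statistic) if len(d) >= 3 else float("nan")
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        shapiro_W=w,
        normality_ok=bool(w > 0.96) if np.isfinite(w) else True,
    )


def sem_from_reliability(sd: float, r: float) -> float:
    """Standard error of measurement SEM = SD * sqrt(1 - r)."""
    if not -1.0 <= r <= 1.0:
        raise ValueError("reliability coefficient must lie in [-1, 1]")
    return float(sd * math.sqrt(max(0.0, 1.0 - r)))


def mdc95_from_sem(sem: float) -> float:
    """Minimal detectable change MDC95 = 1.96 * sqrt(2) * SEM."""
    return float(MDC_FACTOR * sem)


def reliability_sem_mdc(pair: PairedAngleSamples) -> ReliabilityResult:
    """Parallel-forms reliability, SEM and MDC95 of pooled scores.

    ``r`` is the Pearson correlation between the two systems' scores; the
    score spread SD is the sample standard deviation of the per-point mean
    motion value, which is what the SEM scales.
    """
    if len(pair) < 3:
        raise ReliabilityUndefinedError("need at least 3 paired points")
    if np.std(pair.x1) == 0 or np.std(pair.x2) == 0:
        raise ReliabilityUndefinedError("degenerate variance in one of the series")
    r = float(stats.pearsonr(pair.x1, pair.x2).statistic)
    sd = float(np.std((pair.x1 + pair.x2) / 2.0, ddof=1))
    sem = sem_from_reliability(sd, r)
    return ReliabilityResult(r=r, sd=sd, sem=sem, mdc95=mdc95_from_sem(sem))


def noninferiority_speed(
    rmse_fast,
    rmse_slow,
    threshold: float,
    alpha: float = 0.025,
    paired: bool = False,
) -> NonInferiorityResult:
    """One-sided non-inferiority t-test on per-trial RMSE values.

    Tests H0: mean(RMSE_fast) - mean(RMSE_slow) >= threshold against
    H1: difference < threshold.  Rejecting H0 supports that motion speed
    does not influence accuracy beyond the detectable-change margin.
    Unpaired (Welch) by default; ``paired=True`` uses a paired test.
    """
    f = np.asarray(rmse_fast, dtype=float)
    s = np.asarray(rmse_slow, dtype=float)
    if len(f) < 2 or len(s) < 2:
        raise ValueError("need at least two RMSE values per speed group")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    mean_diff = float(f.mean() - s.mean())
    if np.std(f, ddof=1) == 0 and np.std(s, ddof=1) == 0:
        below = mean_diff < threshold
        return NonInferiorityResult(
            mean_diff, threshold, float("nan"),
            0.0 if below else 1.0, alpha, below, degenerate=True,
        )
    if paired:
        if len(f) != len(s):
            raise ValueError("paired mode needs equal group sizes")
        res = stats.ttest_rel(f - threshold, s, alternative="less")
    else:
        res = stats.ttest_ind(f - threshold, s, equal_var=False, alternative="less")
    p = float(res.pvalue)
    return NonInferiorityResult(
        mean_diff=mean_diff,
        threshold=threshold,
        t_stat=float(res.statistic),
        p_value=p,
        alpha=alpha,
        reject_h0=bool(p < alpha),
    )


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero, as in the report tables."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
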