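"""Study-level model: orchestrates calibration, preprocessing, kinematics
and agreement statistics over a set of trials.

The public surface follows the statsmodels idiom: build a
:class:`SpineValidationStudy` from trial records (a directory on disk, or
the synthetic generator), call :meth:`~SpineValidationStudy.fit`, and read
the returned :class:`ValidationResults` — per-trial and aggregated RMSE
tables, Bland–Altman and reliability/MDC tables, the speed non-inferiority
outcome, the per-segment alignment solutions, and a ``summary()`` text
report.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import agreement as ag
from .calibration import AlignmentSolution, align_systems, apply_alignment, zero_encoders
from .kinematics import DHChain, encoder_series_to_orientation, load_chain
from .preprocessing import (
    IrreparableTrialError,
    SyncResult,
    UnsynchronizableError,
    detect_outliers,
    overlap_pair,
    repair,
    resample,
    synchronize,
)
from .rotations import DEFAULT_SEQUENCE, euler_series, global_rotation_angle
from .series import OrientationSeries, TrialRecord, JointAngleSeries

__all__ = [
    "SpineValidationStudy",
    "ValidationResults",
    "run_study",
    "PUBLISHED_MDC_THRESHOLDS",
    "REPORT_PLANES",
]

#: MDC-based non-inferiority margins reported for the physical mannequin's
#: validation (degrees); available as ready-made threshold constants.
PUBLISHED_MDC_THRESHOLDS = {"cervical": 2.05, "lumbar": 2.45}

REPORT_PLANES = ("global", "flexion", "lateral_flexion", "rotation")
_PLANE_LABEL = {
    "global": "Global",
    "flexion": "Flexion",
    "lateral_flexion": "Lateral Flexion",
    "rotation": "Rotation",
}


@dataclass
class TrialAnalysis:
    """Per-trial outcome: RMSE per plane plus the full paired traces."""

    trial_id: str
    segment: str
    condition: str
    speed: str
    rmse: dict
    paired: dict  # plane -> PairedAngleSamples over valid samples
    sync: SyncResult
    n_valid: int
    n_total: int


class SpineValidationStudy:
    """Concurrent-validity model for an instrumented-spine study.

    Parameters
    ----------
    trials
        Trial records; those with ``is_calibration=True`` are used to fit
        the per-segment frame alignment and excluded from the statistics.
    chains
        Mapping segment -> :class:`DHChain`; defaults to the packaged
        cervical and lumbar chains.
    analysis_rate
        Common resampling rate (Hz) both streams are brought to.
    sample_k
        Paired points sampled per trial for the Bland–Altman and
        reliability pools (equalizes fast/slow representation).
    noninferiority_threshold
        ``"mdc"`` (use the study's own global MDC per segment), a number,
        or a mapping segment -> margin in degrees.
    min_valid_fraction
        Trials with fewer valid paired samples after repair are discarded
        (with reason) rather than analyzed.
    """

    def __init__(
        self,
        trials: list[TrialRecord],
        chains: dict | None = None,
        analysis_rate: float = 100.0,
        sample_k: int = 10,
        seed: int = 0,
        euler_sequence: str = DEFAULT_SEQUENCE,
        noninferiority_threshold="mdc",
        noninferiority_alpha: float = 0.025,
        min_valid_fraction: float = 0.7,
        neutral_prefix: float = 1.0,
        velocity_threshold: float = 120.0,
        alignment_weighting: str = "uniform",
        max_lag: float = 2.0,
    ) -> None:
        self.trials = list(trials)
        segments = sorted({t.segment for t in self.trials})
        self.chains = chains or {s: load_chain(s) for s in segments}
        self.analysis_rate = analysis_rate
        self.sample_k = sample_k
        self.seed = seed
        self.euler_sequence = euler_sequence
        self.noninferiority_threshold = noninferiority_threshold
        self.noninferiority_alpha = noninferiority_alpha
        self.min_valid_fraction = min_valid_fraction
        self.neutral_prefix = neutral_prefix
        self.velocity_threshold = velocity_threshold
        self.alignment_weighting = alignment_weighting
        self.max_lag = max_lag

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_directory(cls, study_dir, **kwargs) -> "SpineValidationStudy":
        """Build from a study directory written by :mod:`spinemotion.io`."""
        from .io import read_study

        trials, _ = read_study(study_dir)
        return cls(trials, **kwargs)

    @classmethod
    def from_synthetic(
        cls, design=None, noise=None, seed: int = 0, **kwargs
    ) -> "SpineValidationStudy":
        """Build from the synthetic generator (seeded, with ground truth)."""
        from .synthetic import generate_study

        trials, ledger = generate_study(design, noise, seed=seed)
        model = cls(trials, seed=kwargs.pop("seed", seed), **kwargs)
        model.ledger = ledger
        return model

    # -- pipeline stages ---------------------------------------------------

    def _preprocess(self, record: TrialRecord, chain: DHChain):
        """Zero encoders, run kinematics, resample, synchronize, repair."""
        enc = record.encoders
        pre_mask = enc.timestamps < enc.timestamps[0] + self.neutral_prefix - 0.05
        window = JointAngleSeries(
            enc.timestamps[pre_mask], enc.theta[pre_mask], enc.segment, enc.quantization_step
        )
        zero = zero_encoders(window)
        mann = encoder_series_to_orientation(chain, enc, zero)
        mann_r = resample(mann, self.analysis_rate)
        moc_r = resample(record.mocap, self.analysis_rate)
        sync = synchronize(mann_r, moc_r, max_lag=self.max_lag)
        a, b = overlap_pair(mann_r, moc_r, sync.lag_samples)
        mask = detect_outliers(b, self.velocity_threshold) | ~b.valid
        b_rep = repair(b, mask)
        return a, b_rep, sync, zero

    def _fit_alignment(self, record: TrialRecord, chain: DHChain) -> AlignmentSolution:
        a, b_rep, _, _ = self._preprocess(record, chain)
        return align_systems(
            a, b_rep, weighting=self.alignment_weighting, seed=self.seed
        )

    def _angle_traces(self, series: OrientationSeries) -> dict:
        eul = euler_series(series.quaternions, self.euler_sequence)
        return {
            "global": np.asarray(global_rotation_angle(series.quaternions)),
            "flexion": eul[:, 0],
            "lateral_flexion": eul[:, 1],
            "rotation": eul[:, 2],
        }

    def _analyze_trial(
        self, record: TrialRecord, chain: DHChain, alignment: AlignmentSolution
    ) -> TrialAnalysis:
        a, b_rep, sync, _ = self._preprocess(record, chain)
        ref = apply_alignment(b_rep, alignment)
        valid = a.valid & ref.valid
        frac = float(valid.mean())
        if frac < self.min_valid_fraction:
            raise IrreparableTrialError(
                f"only {100 * frac:.0f}% of paired samples valid after repair "
                f"(minimum {100 * self.min_valid_fraction:.0f}%)"
            )
        ta = self._angle_traces(a)
        tr = self._angle_traces(ref)
        rmse, paired = {}, {}
        for plane in REPORT_PLANES:
            pair = ag.PairedAngleSamples(
                ta[plane][valid], tr[plane][valid], record.trial_id, plane, record.speed
            )
            paired[plane] = pair
            rmse[plane] = ag.rmse(pair)
        return TrialAnalysis(
            record.trial_id, record.segment, record.condition, record.speed,
            rmse, paired, sync, int(valid.sum()), len(valid),
        )

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "ValidationResults":
        """Run the full pipeline and aggregate the validation statistics."""
        segments = sorted({t.segment for t in self.trials})
        cal_records = {t.segment: t for t in self.trials if t.is_calibration}
        alignments: dict = {}
        for seg in segments:
            if seg not in cal_records:
                raise ValueError(f"no calibration trial for segment {seg!r}")
            alignments[seg] = self._fit_alignment(cal_records[seg], self.chains[seg])

        analyses: list[TrialAnalysis] = []
        discarded: list[dict] = []
        measurement = [t for t in self.trials if not t.is_calibration]
        for i, rec in enumerate(measurement):
            try:
                analyses.append(
                    self._analyze_trial(rec, self.chains[rec.segment], alignments[rec.segment])
                )
            except (IrreparableTrialError, UnsynchronizableError) as exc:
                discarded.append(
                    {
                        "trial_id": rec.trial_id,
                        "segment": rec.segment,
                        "condition": rec.condition,
                        "speed": rec.speed,
                        "reason": str(exc),
                    }
                )
        return ValidationResults(self, analyses, discarded, alignments, len(measurement))


class ValidationResults:
    """Fitted validation statistics with report tables.

    Attributes
    ----------
    trial_table : pandas.DataFrame
        Per-trial RMSE by plane, with interpretation bands.
    rmse_table : pandas.DataFrame
        Mean +/- SD of per-trial RMSE for each segment and plane.
    bland_altman_table, reliability_table : pandas.DataFrame
        Pooled-sample agreement and reliability/SEM/MDC statistics.
    noninferiority : dict
        Per-segment :class:`~spinemotion.agreement.NonInferiorityResult`.
    discarded : list of dict
        Trials excluded from analysis, each with its reason.
    """

    def __init__(self, model, analyses, discarded, alignments, n_input):
        self.model = model
        self.analyses = analyses
        self.discarded = discarded
        self.alignments = alignments
        self.n_input = n_input
        self._aggregate()

    # -- aggregation -------------------------------------------------------

    def _aggregate(self) -> None:
        m = self.model
        rows = []
        for an in self.analyses:
            row = {
                "trial_id": an.trial_id,
                "segment": an.segment,
                "condition": an.condition,
                "speed": an.speed,
                "n_valid": an.n_valid,
                "n_total": an.n_total,
                "lag_s": an.sync.lag,
            }
            for plane in REPORT_PLANES:
                row[f"rmse_{plane}"] = an.rmse[plane]
                row[f"band_{plane}"] = ag.interpret_rmse(an.rmse[plane])
            rows.append(row)
        self.trial_table = pd.DataFrame(rows)

        # fixed-count random samples per trial, shared across planes
        pooled: dict = {}
        root = np.random.SeedSequence([int(m.seed), 424243])
        children = root.spawn(len(self.analyses))
        for an, child in zip(self.analyses, children):
            n = len(an.paired["global"])
            if n < m.sample_k:
                continue
            rng = np.random.default_rng(child)
            idx = np.sort(rng.choice(n, size=m.sample_k, replace=False))
            for plane in REPORT_PLANES:
                p = an.paired[plane]
                pooled.setdefault((an.segment, plane), []).append(
                    (p.x1[idx], p.x2[idx])
                )

        ba_rows, rel_rows = [], []
        segments = sorted({an.segment for an in self.analyses})
        self._pooled_samples = {}
        for seg in segments:
            for plane in REPORT_PLANES:
                chunks = pooled.get((seg, plane), [])
                if not chunks:
                    continue
                x1 = np.concatenate([c[0] for c in chunks])
                x2 = np.concatenate([c[1] for c in chunks])
                pair = ag.PairedAngleSamples(x1, x2, f"{seg}_pooled", plane)
                self._pooled_samples[(seg, plane)] = pair
                ba = ag.bland_altman(pair)
                ba_rows.append(
                    {
                        "segment": seg, "plane": plane, "n": len(pair),
                        "bias": ba.bias, "sd_diff": ba.sd_diff,
                        "loa_low": ba.loa_low, "loa_high": ba.loa_high,
                        "shapiro_W": ba.shapiro_W, "normality_ok": ba.normality_ok,
                    }
                )
                rel = ag.reliability_sem_mdc(pair)
                rel_rows.append(
                    {
                        "segment": seg, "plane": plane, "n": len(pair),
                        "r": rel.r, "sd": rel.sd, "sem": rel.sem, "mdc95": rel.mdc95,
                    }
                )
        self.bland_altman_table = pd.DataFrame(ba_rows)
        self.reliability_table = pd.DataFrame(rel_rows)

        agg_rows = []
        for seg in segments:
            sub = self.trial_table[self.trial_table.segment == seg]
            for plane in REPORT_PLANES:
                vals = sub[f"rmse_{plane}"].to_numpy()
                agg_rows.append(
                    {
                        "segment": seg, "plane": plane, "n_trials": len(vals),
                        "rmse_mean": float(vals.mean()),
                        "rmse_sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                        "band": ag.interpret_rmse(float(vals.mean())),
                    }
                )
        self.rmse_table = pd.DataFrame(agg_rows)

        self.noninferiority = {}
        self.noninferiority_thresholds = {}
        for seg in segments:
            sub = self.trial_table[self.trial_table.segment == seg]
            fast = sub[sub.speed == "fast"]["rmse_global"].to_numpy()
            slow = sub[sub.speed == "slow"]["rmse_global"].to_numpy()
            thr = self._threshold_for(seg)
            self.noninferiority_thresholds[seg] = thr
            if len(fast) >= 2 and len(slow) >= 2:
                self.noninferiority[seg] = ag.noninferiority_speed(
                    fast, slow, thr, alpha=self.model.noninferiority_alpha
                )

    def _threshold_for(self, seg: str) -> float:
        spec = self.model.noninferiority_threshold
        if isinstance(spec, dict):
            return float(spec[seg])
        if isinstance(spec, (int, float)):
            return float(spec)
        if spec == "mdc":
            t = self.reliability_table
            row = t[(t.segment == seg) & (t.plane == "global")]
            if len(row):
                return float(row.mdc95.iloc[0])
            return PUBLISHED_MDC_THRESHOLDS.get(seg, 2.0)
        raise ValueError(f"unknown threshold spec {spec!r}")

    # -- reporting ---------------------------------------------------------

    def to_dict(self) -> dict:
        ni = {
            seg: {
                "mean_diff": r.mean_diff, "threshold": r.threshold,
                "t_stat": r.t_stat, "p_value": r.p_value,
                "alpha": r.alpha, "reject_h0": r.reject_h0,
            }
            for seg, r in self.noninferiority.items()
        }
        return {
            "n_input_trials": self.n_input,
            "n_analyzed": len(self.analyses),
            "n_discarded": len(self.discarded),
            "discarded": self.discarded,
            "alignments": {s: a.to_dict() for s, a in self.alignments.items()},
            "rmse_table": self.rmse_table.to_dict(orient="records"),
            "bland_altman_table": self.bland_altman_table.to_dict(orient="records"),
            "reliability_table": self.reliability_table.to_dict(orient="records"),
            "noninferiority": ni,
            "trial_table": self.trial_table.drop(columns=["lag_s"]).to_dict(orient="records"),
        }

    def save(self, path) -> None:
        from .io import write_report

        write_report(self.to_dict(), path)

    def summary(self) -> str:
        """Plain-text report tables (one-decimal, ties away from zero)."""
        r1 = ag.round_half_up
        segs = sorted({an.segment for an in self.analyses})
        lines = []
        lines.append("Concurrent validity of instrumented-spine motion measurement")
        lines.append(
            f"Trials analyzed: {len(self.analyses)}   discarded: {len(self.discarded)}"
        )
        for seg, a in self.alignments.items():
            lines.append(f"Alignment residual ({seg}): {a.residual_rmse:.2f} deg RMS")
        lines.append("")
        lines.append("Root-mean-square error (deg)")
        lines.append(f"{'':18s}" + "".join(f"{s:>22s}" for s in segs))
        lines.append(f"{'':18s}" + "".join(f"{'RMSE':>12s}{'SD':>10s}" for _ in segs))
        for plane in REPORT_PLANES:
            cells = ""
            for seg in segs:
                row = self.rmse_table[
                    (self.rmse_table.segment == seg) & (self.rmse_table.plane == plane)
                ]
                if len(row):
                    cells += f"{r1(row.rmse_mean.iloc[0]):>12.1f}{r1(row.rmse_sd.iloc[0]):>10.1f}"
                else:
                    cells += f"{'-':>12s}{'-':>10s}"
            lines.append(f"{_PLANE_LABEL[plane]:18s}" + cells)
        lines.append("")
        lines.append("Bland-Altman (deg)")
        lines.append(f"{'':18s}" + "".join(f"{s:>26s}" for s in segs))
        lines.append(f"{'':18s}" + "".join(f"{'Bias':>10s}{'LoA':>16s}" for _ in segs))
        for plane in REPORT_PLANES:
            cells = ""
            for seg in segs:
                t = self.bland_altman_table
                row = t[(t.segment == seg) & (t.plane == plane)]
                if len(row):
                    lo, hi = r1(row.loa_low.iloc[0]), r1(row.loa_high.iloc[0])
                    cells += f"{r1(row.bias.iloc[0]):>10.1f}{f'{lo:.1f}-{hi:.1f}':>16s}"
                else:
                    cells += f"{'-':>10s}{'-':>16s}"
            lines.append(f"{_PLANE_LABEL[plane]:18s}" + cells)
        lines.append("")
        lines.append("Reliability / minimal detectable change (deg)")
        lines.append(f"{'':18s}" + "".join(f"{s:>36s}" for s in segs))
        lines.append(
            f"{'':18s}" + "".join(f"{'r':>9s}{'SD':>9s}{'SEm':>9s}{'MDC':>9s}" for _ in segs)
        )
        for plane in REPORT_PLANES:
            cells = ""
            for seg in segs:
                t = self.reliability_table
                row = t[(t.segment == seg) & (t.plane == plane)]
                if len(row):
                    cells += (
                        f"{row['r'].iloc[0]:>9.3f}{r1(row['sd'].iloc[0]):>9.1f}"
                        f"{r1(row['sem'].iloc[0]):>9.1f}{r1(row['mdc95'].iloc[0]):>9.1f}"
                    )
                else:
                    cells += f"{'-':>9s}" * 4
            lines.append(f"{_PLANE_LABEL[plane]:18s}" + cells)
        lines.append("")
        lines.append("Non-inferiority of fast vs slow motion (one-sided t, alpha=2.5%)")
        for seg, r in self.noninferiority.items():
            verdict = "speed has no effect" if r.reject_h0 else "inconclusive"
            lines.append(
                f"  {seg}: diff={r.mean_diff:+.2f} deg, margin={r.threshold:.2f} deg, "
                f"p={r.p_value:.2g} -> {verdict}"
            )
        if self.discarded:
            lines.append("")
            lines.append("Discarded trials:")
            for d in self.discarded:
                lines.append(f"  {d['trial_id']}: {d['reason']}")
        return "\n".join(lines)

    def plot_bland_altman(self, segment: str, plane: str = "global", ax=None):
        """Difference-vs-mean scatter with bias and limits of agreement."""
        import matplotlib.pyplot as plt

        pair = self._pooled_samples[(segment, plane)]
        ba = ag.bland_altman(pair)
        if ax is None:
            _, ax = plt.subplots()
        mean = (pair.x1 + pair.x2) / 2.0
        diff = pair.x1 - pair.x2
        ax.scatter(mean, diff, s=12, alpha=0.6)
        for y, style in ((ba.bias, "-"), (ba.loa_low, "--"), (ba.loa_high, "--")):
            ax.axhline(y, color="k", linestyle=style, linewidth=1)
        ax.set_xlabel("Mean of systems (deg)")
        ax.set_ylabel("Mannequin - reference (deg)")
        ax.set_title(f"{segment} / {_PLANE_LABEL[plane]}")
        return ax


def run_study(study_dir, out_json=None, **options) -> ValidationResults:
    """Analyze a study directory end to end; optionally write the report."""
    model = SpineValidationStudy.from_directory(study_dir, **options)
    results = model.fit()
    if out_json is not None:
        results.save(out_json)
    return results
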