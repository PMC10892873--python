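"""Neutral zeroing and mannequin-to-mocap frame alignment.

Two constant corrections connect the measurement systems: per-encoder zero
offsets (the software analogue of zeroing the encoders in the neutral
calibration jig) and a pair of constant frame rotations — one on the
reference-system side of the chain (``base_offset``) and one on the
body side (``sensor_offset``) — absorbing how the mocap rigid bodies were
defined relative to the mannequin's kinematic frames.

The alignment model is::

    q_ref(t) ≈ q_base ∘ q_mannequin(t) ∘ q_sensor

and the fit minimizes the mean squared relative-rotation angle between the
two sides over one combined-motion trial that excites all three anatomical
planes.  The cost is smooth and low-dimensional (two rotation vectors,
optionally four encoder-zero deltas), solved with a deterministic
quasi-Newton method from several seeded starts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .rotations import as_scipy, euler_series, from_scipy
from .series import JointAngleSeries, OrientationSeries

__all__ = [
    "CalibrationMotionError",
    "IllConditionedCalibrationError",
    "AlignmentSolution",
    "zero_encoders",
    "align_systems",
    "apply_alignment",
]


class CalibrationMotionError(ValueError):
    """The supposed static calibration window contains motion."""


class IllConditionedCalibrationError(ValueError):
    """The calibration trial does not excite enough planes of motion."""


@dataclass
class AlignmentSolution:
    """Constant corrections mapping the mannequin stream onto the reference.

    Quaternions are scalar-first; ``encoder_zero`` are additive corrections
    in degrees (all zero unless zero estimation was requested);
    ``residual_rmse`` is the RMS relative-rotation angle (degrees) left on
    the calibration trial after alignment.
    """

    base_offset: np.ndarray
    sensor_offset: np.ndarray
    encoder_zero: np.ndarray = field(default_factory=lambda: np.zeros(4))
    residual_rmse: float = 0.0
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "base_offset": list(map(float, self.base_offset)),
            "sensor_offset": list(map(float, self.sensor_offset)),
            "encoder_zero": list(map(float, self.encoder_zero)),
            "residual_rmse": float(self.residual_rmse),
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AlignmentSolution":
        return cls(
            base_offset=np.array(d["base_offset"], dtype=float),
            sensor_offset=np.array(d["sensor_offset"], dtype=float),
            encoder_zero=np.array(d["encoder_zero"], dtype=float),
            residual_rmse=float(d["residual_rmse"]),
            converged=bool(d.get("converged", True)),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "AlignmentSolution":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


def zero_encoders(
    neutral_window: JointAngleSeries,
    max_velocity: float = 2.0,
    min_duration: float = 0.5,
) -> np.ndarray:
    """Per-channel encoder zero offsets from a quasi-static neutral window.

    The window must span at least ``min_duration`` seconds and stay below
    ``max_velocity`` deg/s on every channel (velocities are measured over
    ~0.1 s spans so encoder quantization steps do not masquerade as
    motion).  Returns the per-channel means, in degrees.
    """
    t = neutral_window.timestamps
    if len(t) < 2 or t[-1] - t[0] < min_duration:
        raise CalibrationMotionError(
            f"neutral window must span >= {min_duration} s of data"
        )
    stride = max(1, int(round(0.1 * neutral_window.rate)))
    dth = neutral_window.theta[stride:] - neutral_window.theta[:-stride]
    dt = t[stride:] - t[:-stride]
    vel = np.abs(dth / dt[:, None])
    if vel.max() > max_velocity:
        raise CalibrationMotionError(
            f"motion of {vel.max():.1f} deg/s in calibration window "
            f"(limit {max_velocity} deg/s)"
        )
    return neutral_window.theta.mean(axis=0)


def _neutral_weights(mann: Rotation, scale_deg: float = 10.0) -> np.ndarray:
    """Sample weights concentrating the fit near the neutral posture."""
    ang = np.degrees(mann.magnitude())
    w = np.exp(-((ang / scale_deg) ** 2))
    return w / w.sum() * len(w)


def align_systems(
    mannequin: OrientationSeries,
    reference: OrientationSeries,
    estimate_zeros: bool = False,
    chain=None,
    encoders: JointAngleSeries | None = None,
    weighting: str = "uniform",
    n_restarts: int = 8,
    seed: int = 0,
    min_plane_rom: float = 5.0,
    max_samples: int = 600,
) -> AlignmentSolution:
    """Fit the constant frame rotations (and optionally encoder-zero deltas).

    Parameters
    ----------
    mannequin, reference
        Synchronized, equal-length orientation streams of the calibration
        trial (one per segment, moved in all three anatomical planes).
    estimate_zeros
        Also fit four encoder-zero corrections; requires ``chain`` and the
        raw ``encoders`` series the mannequin stream was derived from.
    weighting
        ``"uniform"`` (default) or ``"neutral"`` to down-weight samples far
        from the neutral posture.
    """
    if len(mannequin) != len(reference):
        raise ValueError("mannequin and reference series must be equal length")
    if estimate_zeros and (chain is None or encoders is None):
        raise ValueError("estimate_zeros requires the chain and raw encoder series")

    ok = mannequin.valid & reference.valid
    if ok.sum() < 10:
        raise IllConditionedCalibrationError("too few valid paired samples")
    eul = euler_series(mannequin.quaternions[ok])
    rom = eul.max(axis=0) - eul.min(axis=0)
    if np.any(rom < min_plane_rom):
        raise IllConditionedCalibrationError(
            f"calibration trial must excite all three planes by >= {min_plane_rom} deg "
            f"(observed ROM {np.round(rom, 1)})"
        )

    idx = np.flatnonzero(ok)
    if len(idx) > max_samples:
        idx = idx[np.linspace(0, len(idx) - 1, max_samples).round().astype(int)]
    ref_fit = as_scipy(reference.quaternions[idx])

    if estimate_zeros:
        from .kinematics import encoder_series_to_orientation

        theta_fit = encoders.theta[idx]

        def mann_rot(dz: np.ndarray) -> Rotation:
            sub = JointAngleSeries(
                encoders.timestamps[idx], theta_fit - dz, encoders.segment,
                encoders.quantization_step,
            )
            return as_scipy(encoder_series_to_orientation(chain, sub).quaternions)
    else:
        mann_fit = as_scipy(mannequin.quaternions[idx])

        def mann_rot(dz: np.ndarray) -> Rotation:
            return mann_fit

    weights = None
    if weighting == "neutral":
        weights = _neutral_weights(mann_rot(np.zeros(4)))
    elif weighting != "uniform":
        raise ValueError(f"unknown weighting {weighting!r}")

    n_par = 10 if estimate_zeros else 6

    def cost(p: np.ndarray) -> float:
        rb = Rotation.from_rotvec(p[:3])
        rs = Rotation.from_rotvec(p[3:6])
        dz = p[6:10] if estimate_zeros else np.zeros(4)
        pred = rb * mann_rot(dz) * rs
        ang = (pred.inv() * ref_fit).magnitude()
        if weights is None:
            return float(np.mean(ang**2))
        return float(np.mean(weights * ang**2))

    rng = np.random.default_rng(seed)
    starts = [np.zeros(n_par)]
    for _ in range(n_restarts):
        p0 = np.zeros(n_par)
        p0[:6] = rng.normal(scale=np.radians(10.0), size=6)
        starts.append(p0)

    best = None
    converged = False
    for p0 in starts:
        res = minimize(cost, p0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)

    p = best.x
    rb = Rotation.from_rotvec(p[:3])
    rs = Rotation.from_rotvec(p[3:6])
    dz = p[6:10] if estimate_zeros else np.zeros(4)

    # residual on the full valid series, not the optimizer subsample
    full_mann = as_scipy(mannequin.quaternions[ok])
    if estimate_zeros:
        sub = JointAngleSeries(
            encoders.timestamps[np.flatnonzero(ok)],
            encoders.theta[np.flatnonzero(ok)] - dz,
            encoders.segment,
            encoders.quantization_step,
        )
        from .kinematics import encoder_series_to_orientation

        full_mann = as_scipy(encoder_series_to_orientation(chain, sub).quaternions)
    pred = rb * full_mann * rs
    resid = np.degrees((pred.inv() * as_scipy(reference.quaternions[ok])).magnitude())
    rmse = float(np.sqrt(np.mean(resid**2)))

    return AlignmentSolution(
        base_offset=from_scipy(rb),
        sensor_offset=from_scipy(rs),
        encoder_zero=np.asarray(dz, dtype=float),
        residual_rmse=rmse,
        converged=converged,
    )


def apply_alignment(reference: OrientationSeries, solution: AlignmentSolution) -> OrientationSeries:
    """Express the reference stream in the mannequin's frames.

    Inverts the alignment model: ``q_base⁻¹ ∘ q_ref(t) ∘ q_sensor⁻¹`` is
    directly comparable to the mannequin's forward-kinematics output.
    """
    rb = as_scipy(solution.base_offset)
    rs = as_scipy(solution.sensor_offset)
    q = from_scipy(rb.inv() * as_scipy(reference.quaternions) * rs.inv())
    out = reference.copy()
    out.quaternions = np.atleast_2d(q)
    return out
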