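"""Timestamped series containers for the two measurement streams."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .rotations import canonicalize

__all__ = ["SchemaError", "JointAngleSeries", "OrientationSeries", "TrialRecord"]


class SchemaError(ValueError):
    """Input data violates the expected schema."""


@dataclass
class JointAngleSeries:
    """Encoder angles for one spine segment: 4 revolute joints, degrees.

    The mannequin's magnetic encoders report angular position on a
    quantization grid (0.0219 deg for the shipped hardware).
    """

    timestamps: np.ndarray
    theta: np.ndarray  # (N, 4) degrees
    segment: str = "cervical"
    quantization_step: float = 0.0219

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[1] != 4:
            raise SchemaError(
                f"encoder series must have exactly 4 channels, got shape {self.theta.shape}"
            )
        if self.theta.shape[0] != self.timestamps.shape[0]:
            raise SchemaError("timestamps and angles disagree in length")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise SchemaError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def rate(self) -> float:
        dt = np.diff(self.timestamps)
        return 1.0 / float(np.median(dt))

    def shifted(self, offsets: np.ndarray) -> "JointAngleSeries":
        """Series with per-channel offsets subtracted (encoder zeroing)."""
        return replace(self, theta=self.theta - np.asarray(offsets, dtype=float))


@dataclass
class OrientationSeries:
    """Unit-quaternion orientation of a body relative to a reference frame.

    ``valid`` marks samples that are trustworthy; invalid samples survive in
    the arrays (timestamps are never dropped) but are excluded from every
    statistic downstream.
    """

    timestamps: np.ndarray
    quaternions: np.ndarray  # (N, 4) scalar-first
    valid: Optional[np.ndarray] = None
    source: str = "mannequin"  # or "reference"
    frame: str = "base"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.quaternions = np.asarray(self.quaternions, dtype=float)
        if self.quaternions.ndim != 2 or self.quaternions.shape[1] != 4:
            raise SchemaError(f"expected (N, 4) quaternions, got {self.quaternions.shape}")
        if self.quaternions.shape[0] != self.timestamps.shape[0]:
            raise SchemaError("timestamps and quaternions disagree in length")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise SchemaError("timestamps must be strictly increasing")
        if self.valid is None:
            self.valid = np.ones(len(self.timestamps), dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape[0] != self.timestamps.shape[0]:
                raise SchemaError("valid mask and timestamps disagree in length")
        if np.any(self.valid):
            self.quaternions = self.quaternions.copy()
            self.quaternions[self.valid] = canonicalize(self.quaternions[self.valid])

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def rate(self) -> float:
        dt = np.diff(self.timestamps)
        return 1.0 / float(np.median(dt))

    def copy(self) -> "OrientationSeries":
        return OrientationSeries(
            self.timestamps.copy(),
            self.quaternions.copy(),
            self.valid.copy(),
            self.source,
            self.frame,
        )


@dataclass
class TrialRecord:
    """One validation trial: the paired mannequin and reference recordings.

    The mannequin side is stored as raw encoder angles (its orientation is
    derived through the kinematic chain during analysis); the reference side
    is the motion-capture orientation stream.
    """

    trial_id: str
    segment: str  # cervical | lumbar
    condition: str  # flexion | lateral_flexion | rotation | combined
    speed: str  # fast | slow
    encoders: JointAngleSeries
    mocap: OrientationSeries
    is_calibration: bool = False
    meta: dict = field(default_factory=dict)
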