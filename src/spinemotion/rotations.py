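"""Rotation representations shared by the whole package.

Quaternions are scalar-first ``(w, x, y, z)`` and canonicalized to the
``w >= 0`` hemisphere, which removes the double-cover ambiguity from
comparisons.  Angles are radians internally and degrees at API boundaries,
matching how spinal range of motion is reported clinically.

Conversions are delegated to :mod:`scipy.spatial.transform`; this module
fixes the conventions (scalar order, hemisphere, anatomical Euler
sequence, gimbal-lock handling) on top of it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation, Slerp

__all__ = [
    "InvalidRotationError",
    "AnatomicalAngles",
    "DEFAULT_SEQUENCE",
    "PLANE_AXES",
    "canonicalize",
    "quat_multiply",
    "quat_conjugate",
    "matrix_to_quaternion",
    "quaternion_to_matrix",
    "global_rotation_angle",
    "relative_rotation",
    "slerp",
    "decompose_anatomical",
    "recompose_anatomical",
    "as_scipy",
    "from_scipy",
]


class InvalidRotationError(ValueError):
    """Input does not describe a proper 3D rotation."""


#: Anatomical plane -> base-frame axis letter used for Euler decomposition.
#: Flexion/extension happens about the mediolateral (y) axis, lateral
#: flexion about the anteroposterior (x) axis, axial rotation about the
#: longitudinal (z) axis of the neutral segment frame.
PLANE_AXES = {"flexion": "Y", "lateral_flexion": "X", "rotation": "Z"}

#: Default intrinsic Euler sequence: flexion, then lateral flexion, then
#: axial rotation.  Configurable everywhere it is consumed; the underlying
#: hardware reports joint angles, not Euler angles, so the sequence is a
#: reporting convention rather than a physical property.
DEFAULT_SEQUENCE = "YXZ"

#: Half-width of the gimbal-lock guard band around +/-90 deg of the middle
#: Euler angle, in degrees.
GIMBAL_GUARD_DEG = 0.5


@dataclass(frozen=True)
class AnatomicalAngles:
    """Euler decomposition of a segment orientation, in degrees.

    ``degenerate`` flags samples whose middle angle fell inside the
    gimbal-lock guard band; the angles are still reported but the split
    between first and last rotation is ill-conditioned there.
    """

    flexion: float
    lateral_flexion: float
    rotation: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.flexion, self.lateral_flexion, self.rotation])


def _check_unit(q: np.ndarray, atol: float = 1e-9) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1)
    if np.any(norm < atol):
        raise InvalidRotationError("zero-norm quaternion")
    if np.any(np.abs(norm - 1.0) > 1e-6):
        raise InvalidRotationError("quaternion is not unit norm")
    if np.abs(norm - 1.0).max() <= atol:
        return q  # already unit within tolerance; keep values bit-stable
    return q / norm[..., None]


def canonicalize(q: np.ndarray) -> np.ndarray:
    """Normalize and map to the w >= 0 hemisphere (scalar-first)."""
    q = _check_unit(q)
    w = q[..., 0]
    sign = np.where(w < 0, -1.0, 1.0)
    return q * sign[..., None]


def as_scipy(q: np.ndarray) -> Rotation:
    """Scalar-first array -> scipy Rotation (which is scalar-last)."""
    q = np.asarray(q, dtype=float)
    return Rotation.from_quat(np.roll(q, -1, axis=-1))


def from_scipy(rot: Rotation) -> np.ndarray:
    """scipy Rotation -> canonical scalar-first array."""
    return canonicalize(np.roll(rot.as_quat(), 1, axis=-1))


def matrix_to_quaternion(R: np.ndarray) -> np.ndarray:
    """Convert a proper rotation matrix to a canonical unit quaternion.

    Raises
    ------
    InvalidRotationError
        If ``R`` is not orthonormal with determinant +1 (tolerance 1e-6).
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise InvalidRotationError(f"expected 3x3 matrix, got shape {R.shape}")
    err = np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)).max()
    if err > 1e-6 or np.any(np.linalg.det(R) < 0):
        raise InvalidRotationError("matrix is not a proper rotation")
    return from_scipy(Rotation.from_matrix(R))


def quaternion_to_matrix(q: np.ndarray) -> np.ndarray:
    """Convert a unit quaternion (scalar-first) to a rotation matrix."""
    return as_scipy(_check_unit(q)).as_matrix()


def global_rotation_angle(q: np.ndarray, degrees: bool = True) -> np.ndarray | float:
    """Total rotation magnitude ``2*arccos(|w|)`` of a quaternion.

    This is the axis-independent range-of-motion score: the single angle a
    body has rotated away from its reference orientation, regardless of the
    anatomical plane the motion happened in.  Always in [0, 180] degrees.
    """
    q = _check_unit(q)
    w = np.clip(np.abs(q[..., 0]), -1.0, 1.0)
    ang = 2.0 * np.arccos(w)
    if degrees:
        ang = np.degrees(ang)
    return float(ang) if np.isscalar(ang) or ang.ndim == 0 else ang


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Hamilton product; composes rotations like the matrix product R1 @ R2."""
    r = as_scipy(q1) * as_scipy(q2)
    return from_scipy(r)


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float).copy()
    q[..., 1:] = -q[..., 1:]
    return canonicalize(q)


def relative_rotation(q_a: np.ndarray, q_b: np.ndarray) -> np.ndarray:
    """Rotation ``r`` such that ``q_a ∘ r = q_b`` (both in a common frame)."""
    return quat_multiply(quat_conjugate(q_a), q_b)


def slerp(q_a: np.ndarray, q_b: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    """Shortest-arc geodesic interpolation between two unit quaternions."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("interpolation fraction must lie in [0, 1]")
    rots = Rotation.concatenate([as_scipy(canonicalize(q_a)), as_scipy(canonicalize(q_b))])
    out = Slerp([0.0, 1.0], rots)(t)
    return from_scipy(out)


def decompose_anatomical(
    R: np.ndarray,
    sequence: str = DEFAULT_SEQUENCE,
    guard_deg: float = GIMBAL_GUARD_DEG,
) -> AnatomicalAngles:
    """Decompose a rotation into intrinsic anatomical Euler angles (degrees).

    ``sequence`` is an ordered intrinsic axis string such as ``"YXZ"``
    (flexion about y, then lateral flexion about x, then axial rotation
    about z — the package default).  Inside the gimbal-lock guard band
    (middle angle within ``guard_deg`` of +/-90 deg) the returned angles
    are flagged degenerate rather than trusted.
    """
    import warnings

    _validate_sequence(sequence)
    q = matrix_to_quaternion(np.asarray(R, dtype=float))
    with warnings.catch_warnings():
        # degeneracy is reported through the flag, not scipy's warning
        warnings.simplefilter("ignore", UserWarning)
        angles = as_scipy(q).as_euler(sequence, degrees=True)
    degenerate = bool(abs(abs(angles[1]) - 90.0) <= guard_deg)
    by_axis = dict(zip(sequence, angles))
    return AnatomicalAngles(
        flexion=float(by_axis.get("Y", 0.0)),
        lateral_flexion=float(by_axis.get("X", 0.0)),
        rotation=float(by_axis.get("Z", 0.0)),
        degenerate=degenerate,
    )


def recompose_anatomical(angles: AnatomicalAngles, sequence: str = DEFAULT_SEQUENCE) -> np.ndarray:
    """Inverse of :func:`decompose_anatomical`; returns a rotation matrix."""
    _validate_sequence(sequence)
    by_axis = {"Y": angles.flexion, "X": angles.lateral_flexion, "Z": angles.rotation}
    eul = [by_axis[ax] for ax in sequence]
    return Rotation.from_euler(sequence, eul, degrees=True).as_matrix()


def euler_series(q: np.ndarray, sequence: str = DEFAULT_SEQUENCE) -> np.ndarray:
    """Vectorized intrinsic Euler angles (degrees) for an (N, 4) quaternion array.

    Columns are ordered (flexion, lateral_flexion, rotation) regardless of
    the sequence string, i.e. by anatomical plane, not by rotation order.
    """
    _validate_sequence(sequence)
    ang = as_scipy(np.atleast_2d(q)).as_euler(sequence, degrees=True)
    cols = {ax: ang[:, i] for i, ax in enumerate(sequence)}
    return np.column_stack([cols["Y"], cols["X"], cols["Z"]])


def _validate_sequence(sequence: str) -> None:
    if sorted(sequence) != ["X", "Y", "Z"]:
        raise ValueError(
            f"Euler sequence must be an intrinsic permutation of 'XYZ', got {sequence!r}"
        )
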