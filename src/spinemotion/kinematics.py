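"""Denavit–Hartenberg kinematic chains for the instrumented spine.

Each spine segment (cervical: head relative to trunk; lumbar: trunk
relative to pelvis) is a serial chain of four encoder-driven revolute
joints, described by the four classic DH parameters per link: link length
``a``, link twist ``alpha``, link offset ``d`` and joint angle ``theta``.
The chain maps the four encoder readings to the orientation of the
end-effector relative to the base, which is the quantity the validation
study compares against motion capture.

The homogeneous transform for one link is the standard DH matrix with
rotation block ``Rz(theta) @ Rx(alpha)``::

    [ cos(t)  -sin(t)cos(al)   sin(t)sin(al)   a cos(t) ]
    [ sin(t)   cos(t)cos(al)  -cos(t)sin(al)   a sin(t) ]
    [ 0        sin(al)         cos(al)         d        ]
    [ 0        0               0               1        ]

Link lengths only enter the translation column; the relative *orientation*
— the only quantity validated here — is independent of them, so the
shipped chain configs default every link length to 1.0.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import yaml

from .rotations import from_scipy
from .series import JointAngleSeries, OrientationSeries, SchemaError

__all__ = [
    "DHRow",
    "DHChain",
    "dh_transform",
    "forward_kinematics",
    "encoder_series_to_orientation",
    "load_chain",
    "JointRangeWarning",
]


class JointRangeWarning(UserWarning):
    """An encoder angle fell outside the configured joint range."""


@dataclass(frozen=True)
class DHRow:
    """One link of a DH chain.

    ``joint_index`` names the encoder channel (1-4) driving this row's
    theta, or ``"fixed"`` for the virtual alignment frame appended so the
    end-effector and base share an orientation in the neutral posture.
    ``plane``/``plane_sign`` record which anatomical plane the joint moves
    and with what sign, for trajectory design and reporting.
    """

    a: float
    alpha: float  # radians
    d: float
    theta_offset: float  # radians
    joint_index: Union[int, str] = "fixed"
    plane: str | None = None
    plane_sign: int = 1

    def __post_init__(self) -> None:
        if not (-np.pi < self.alpha <= np.pi + 1e-12):
            raise ValueError("alpha must lie in (-pi, pi]")
        if self.joint_index not in (1, 2, 3, 4, "fixed"):
            raise ValueError(f"joint_index must be 1-4 or 'fixed', got {self.joint_index!r}")


@dataclass
class DHChain:
    """Ordered DH rows for one spine segment plus link-length bookkeeping."""

    segment: str
    rows: Sequence[DHRow]
    link_lengths: dict = field(default_factory=lambda: {"r1": 1.0, "r2": 1.0, "r3": 1.0})
    joint_limits_deg: float = 90.0

    def __post_init__(self) -> None:
        actuated = [r for r in self.rows if r.joint_index != "fixed"]
        if len(actuated) != 4:
            raise ValueError(f"chain must have exactly 4 actuated rows, got {len(actuated)}")
        if sorted(r.joint_index for r in actuated) != [1, 2, 3, 4]:
            raise ValueError("actuated rows must cover joint indices 1-4 exactly once")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def joint_planes(self) -> dict:
        """Map encoder index -> (anatomical plane, sign)."""
        return {
            r.joint_index: (r.plane, r.plane_sign)
            for r in self.rows
            if r.joint_index != "fixed"
        }


def dh_transform(row: DHRow, theta: float = 0.0) -> np.ndarray:
    """Homogeneous 4x4 transform of one link; ``theta`` in radians.

    For fixed rows the encoder angle is ignored and only the constant
    ``theta_offset`` applies.
    """
    t = row.theta_offset + (0.0 if row.joint_index == "fixed" else theta)
    ct, st = np.cos(t), np.sin(t)
    ca, sa = np.cos(row.alpha), np.sin(row.alpha)
    return np.array(
        [
            [ct, -st * ca, st * sa, row.a * ct],
            [st, ct * ca, -ct * sa, row.a * st],
            [0.0, sa, ca, row.d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def forward_kinematics(
    chain: DHChain, theta_deg: Sequence[float], check_limits: bool = True
) -> np.ndarray:
    """End-effector pose relative to the base for one set of encoder angles.

    ``theta_deg`` are the four encoder angles in degrees, indexed by the
    chain rows' ``joint_index``.  Returns the 4x4 homogeneous transform;
    its rotation block is the head-to-trunk (or trunk-to-pelvis)
    orientation compared downstream.
    """
    theta_deg = np.asarray(theta_deg, dtype=float)
    if theta_deg.shape != (4,):
        raise SchemaError(f"expected 4 joint angles, got shape {theta_deg.shape}")
    if check_limits and np.any(np.abs(theta_deg) > chain.joint_limits_deg):
        import warnings

        warnings.warn(
            f"joint angle outside +/-{chain.joint_limits_deg} deg range", JointRangeWarning
        )
    T = np.eye(4)
    th = np.radians(theta_deg)
    for row in chain.rows:
        ang = 0.0 if row.joint_index == "fixed" else th[row.joint_index - 1]
        T = T @ dh_transform(row, ang)
    return T


def _rotation_stack(chain: DHChain, theta_deg: np.ndarray) -> np.ndarray:
    """Vectorized rotation blocks of forward kinematics over (N, 4) angles."""
    n = theta_deg.shape[0]
    th = np.radians(theta_deg)
    R = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    for row in chain.rows:
        ang = np.zeros(n) if row.joint_index == "fixed" else th[:, row.joint_index - 1]
        t = ang + row.theta_offset
        ct, st = np.cos(t), np.sin(t)
        ca, sa = np.cos(row.alpha), np.sin(row.alpha)
        Ri = np.empty((n, 3, 3))
        Ri[:, 0, 0] = ct
        Ri[:, 0, 1] = -st * ca
        Ri[:, 0, 2] = st * sa
        Ri[:, 1, 0] = st
        Ri[:, 1, 1] = ct * ca
        Ri[:, 1, 2] = -ct * sa
        Ri[:, 2, 0] = 0.0
        Ri[:, 2, 1] = sa
        Ri[:, 2, 2] = ca
        R = R @ Ri
    return R


def encoder_series_to_orientation(
    chain: DHChain,
    series: JointAngleSeries,
    zero_offsets: Sequence[float] | None = None,
) -> OrientationSeries:
    """Per-sample forward kinematics of an encoder series.

    ``zero_offsets`` (degrees, from neutral calibration) are subtracted
    from every sample before the chain is evaluated.
    """
    zero = np.zeros(4) if zero_offsets is None else np.asarray(zero_offsets, dtype=float)
    theta = series.theta - zero
    R = _rotation_stack(chain, theta)
    from scipy.spatial.transform import Rotation

    quats = from_scipy(Rotation.from_matrix(R))
    return OrientationSeries(
        timestamps=series.timestamps.copy(),
        quaternions=np.atleast_2d(quats),
        source="mannequin",
        frame="base",
    )


# --- chain configuration files -------------------------------------------

_LINK_KEYS = ("r1", "r2", "r3")


def _resolve_length(value, link_lengths: dict) -> float:
    """Resolve a config length that may be numeric or a link-length expression.

    Supported symbolic forms: a single link name ("r2") or a sum ("r2+r3").
    """
    if isinstance(value, (int, float)):
        return float(value)
    expr = str(value).replace(" ", "")
    total = 0.0
    for term in expr.split("+"):
        if term not in _LINK_KEYS:
            raise ValueError(f"unsupported length expression {value!r}")
        total += float(link_lengths[term])
    return total


def chain_from_dict(cfg: dict) -> DHChain:
    links = {k: float(v) for k, v in cfg.get("link_lengths", {}).items()}
    for k in _LINK_KEYS:
        links.setdefault(k, 1.0)
    rows = []
    for rc in cfg["rows"]:
        rows.append(
            DHRow(
                a=_resolve_length(rc.get("a", 0.0), links),
                alpha=float(rc.get("alpha", 0.0)),
                d=_resolve_length(rc.get("d", 0.0), links),
                theta_offset=float(rc.get("theta_offset", 0.0)),
                joint_index=rc.get("joint_index", "fixed"),
                plane=rc.get("plane"),
                plane_sign=int(rc.get("plane_sign", 1)),
            )
        )
    return DHChain(
        segment=cfg["segment"],
        rows=rows,
        link_lengths=links,
        joint_limits_deg=float(cfg.get("joint_limits_deg", 90.0)),
    )


def chain_to_dict(chain: DHChain) -> dict:
    return {
        "segment": chain.segment,
        "link_lengths": dict(chain.link_lengths),
        "joint_limits_deg": chain.joint_limits_deg,
        "rows": [
            {
                "a": r.a,
                "alpha": float(r.alpha),
                "d": r.d,
                "theta_offset": float(r.theta_offset),
                "joint_index": r.joint_index,
                "plane": r.plane,
                "plane_sign": r.plane_sign,
            }
            for r in chain.rows
        ],
    }


def load_chain(source: str) -> DHChain:
    """Load a chain config: ``"cervical"``/``"lumbar"`` (packaged) or a path."""
    if source in ("cervical", "lumbar"):
        ref = importlib.resources.files("spinemotion.chains") / f"{source}.yaml"
        cfg = yaml.safe_load(ref.read_text())
    else:
        with open(source, "r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
    return chain_from_dict(cfg)
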