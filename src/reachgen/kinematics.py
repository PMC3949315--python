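"""Planar arm geometry.

A three-segment (upper arm, forearm, hand) arm moving in the horizontal
plane.  Joint angles are *relative*: each angle is measured against the
orientation of the previous segment, with the base axis along +x of the
workspace frame.  Hand orientation in external space is therefore the sum
of the three relative angles.

All quantities are SI (meters, radians, seconds, newtons) internally;
helpers accept degrees and convert at the interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmModel",
    "JointPosture",
    "JointState",
    "Trajectory",
    "SingularPostureError",
    "UnreachableTargetError",
    "forward_kinematics",
    "jacobian",
    "constrained_joint_velocities",
    "inverse_kinematics_2joint",
    "min_jerk_trajectory",
    "virtual_segment",
]

#: 2x2 determinant below which a two-joint posture is treated as singular
#: (straight or fully folded arm); double-precision safe margin.
SINGULARITY_TOL = 1e-9

#: Average-arm segment lengths (upper arm, forearm, hand), meters.
DEFAULT_LINK_LENGTHS = (0.30, 0.25, 0.07)


class SingularPostureError(ValueError):
    """Raised when a Jacobian (sub)system cannot be inverted at a posture."""


class UnreachableTargetError(ValueError):
    """Raised by inverse kinematics when the target lies outside the arm's annulus."""


@dataclass(frozen=True)
class ArmModel:
    """Planar arm with up to three rigid segments.

    Parameters
    ----------
    link_lengths
        (upper arm, forearm, hand) lengths in meters; all positive.
    shoulder_position
        Shoulder location in the workspace frame, meters.
    """

    link_lengths: tuple[float, float, float] = DEFAULT_LINK_LENGTHS
    shoulder_position: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if any(l <= 0 for l in self.link_lengths):
            raise ValueError(f"link lengths must be positive, got {self.link_lengths}")

    @property
    def reach(self) -> float:
        return float(sum(self.link_lengths))


@dataclass(frozen=True)
class JointPosture:
    """Relative joint angles (shoulder, elbow, wrist) in radians."""

    q_s: float
    q_e: float
    q_w: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite([self.q_s, self.q_e, self.q_w])):
            raise ValueError("joint angles must be finite")

    @classmethod
    def from_degrees(cls, q_s: float, q_e: float, q_w: float = 0.0) -> "JointPosture":
        return cls(np.deg2rad(q_s), np.deg2rad(q_e), np.deg2rad(q_w))

    @property
    def hand_orientation(self) -> float:
        """Orientation of the hand segment in the external frame (rad)."""
        return self.q_s + self.q_e + self.q_w

    def as_array(self) -> np.ndarray:
        return np.array([self.q_s, self.q_e, self.q_w])

    def replace(self, **kw) -> "JointPosture":
        vals = {"q_s": self.q_s, "q_e": self.q_e, "q_w": self.q_w}
        vals.update(kw)
        return JointPosture(**vals)


@dataclass(frozen=True)
class JointState:
    """Joint velocities (rad/s) and optional torques (N.m)."""

    qdot: np.ndarray
    tau: np.ndarray | None = None


@dataclass
class Trajectory:
    """Uniformly sampled planar trajectory with optional hand force.

    Attributes
    ----------
    t : (n,) seconds, strictly increasing, uniform step
    pos : (n, 2) meters
    vel : (n, 2) m/s
    force : (n, 2) newtons or None
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    force: np.ndarray | None = None
    trial_id: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.pos = np.asarray(self.pos, float)
        self.vel = np.asarray(self.vel, float)
        if self.force is not None:
            self.force = np.asarray(self.force, float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("trajectory needs at least two samples")
        steps = np.diff(self.t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("time base must be strictly increasing and uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def speed(self) -> np.ndarray:
        return np.linalg.norm(self.vel, axis=1)


def _cumulative_angles(posture: JointPosture) -> np.ndarray:
    q = posture.as_array()
    return np.cumsum(q)


def forward_kinematics(arm: ArmModel, posture: JointPosture) -> tuple[np.ndarray, float]:
    """Hand position (m) and hand orientation (rad) for a posture.

    The hand sits at the vector sum of the three segments, each rotated by
    the cumulative angle of the joints proximal to it.
    """
    a = _cumulative_angles(posture)
    l = np.asarray(arm.link_lengths)
    pos = np.asarray(arm.shoulder_position, float) + np.array(
        [np.sum(l * np.cos(a)), np.sum(l * np.sin(a))]
    )
    return pos, float(a[-1])


def wrist_position(arm: ArmModel, posture: JointPosture) -> np.ndarray:
    """Position of the wrist joint (end of the forearm), meters."""
    a = _cumulative_angles(posture)[:2]
    l = np.asarray(arm.link_lengths[:2])
    return np.asarray(arm.shoulder_position, float) + np.array(
        [np.sum(l * np.cos(a)), np.sum(l * np.sin(a))]
    )


def virtual_segment(arm: ArmModel, posture: JointPosture) -> tuple[float, float]:
    """Equivalent single elbow-to-hand segment (length, angle offset).

    Folds forearm and hand into one rigid segment.  Returns the segment
    length and the offset of its direction relative to the forearm, so the
    equivalent two-joint arm has links ``(l1, length)`` and elbow angle
    ``q_e + offset``.
    """
    _, l2, l3 = arm.link_lengths
    qw = posture.q_w
    length = float(np.hypot(l2 + l3 * np.cos(qw), l3 * np.sin(qw)))
    offset = float(np.arctan2(l3 * np.sin(qw), l2 + l3 * np.cos(qw)))
    return length, offset


def jacobian(arm: ArmModel, posture: JointPosture, variant: str = "three_joint") -> np.ndarray:
    """Jacobian mapping joint angular velocities to hand velocity.

    Variants
    --------
    ``three_joint``
        2x3 map over (shoulder, elbow, wrist) velocities.
    ``two_joint``
        2x2 map over (shoulder, elbow) with the wrist frozen at its current
        angle (hand rides rigidly on the forearm).
    ``virtual_segment``
        2x2 map with forearm+hand replaced by the equivalent single segment.
    """
    l1, l2, l3 = arm.link_lengths
    a1, a2, a3 = _cumulative_angles(posture)
    if variant == "three_joint":
        s = np.sin([a1, a2, a3])
        c = np.cos([a1, a2, a3])
        row_x = -np.array([l1 * s[0] + l2 * s[1] + l3 * s[2], l2 * s[1] + l3 * s[2], l3 * s[2]])
        row_y = np.array([l1 * c[0] + l2 * c[1] + l3 * c[2], l2 * c[1] + l3 * c[2], l3 * c[2]])
        return np.vstack([row_x, row_y])
    if variant == "two_joint":
        J3 = jacobian(arm, posture, "three_joint")
        J = J3[:, :2]
    elif variant == "virtual_segment":
        leq, off = virtual_segment(arm, posture)
        b1, b2 = a1, a2 + off
        J = np.array(
            [
                [-(l1 * np.sin(b1) + leq * np.sin(b2)), -leq * np.sin(b2)],
                [l1 * np.cos(b1) + leq * np.cos(b2), leq * np.cos(b2)],
            ]
        )
    else:
        raise ValueError(f"unknown Jacobian variant {variant!r}")
    if abs(np.linalg.det(J)) < SINGULARITY_TOL:
        warnings.warn(
            f"near-singular two-joint posture (det={np.linalg.det(J):.2e}) at "
            f"q=({posture.q_s:.3f}, {posture.q_e:.3f}, {posture.q_w:.3f}) rad",
            stacklevel=2,
        )
    return J


def constrained_joint_velocities(
    arm: ArmModel, posture: JointPosture, xdot: np.ndarray
) -> np.ndarray:
    """Joint velocities achieving hand velocity ``xdot`` at constant hand orientation.

    Solves the 3x3 system stacking the three-joint Jacobian with the
    constraint q̇_s + q̇_e + q̇_w = 0 (the hand's external orientation is the
    sum of the relative angles, so zero summed angular velocity keeps it
    constant).
    """
    J = jacobian(arm, posture, "three_joint")
    A = np.vstack([J, np.ones((1, 3))])
    b = np.array([xdot[0], xdot[1], 0.0])
    det = np.linalg.det(A)
    if abs(det) < SINGULARITY_TOL:
        raise SingularPostureError(
            f"constant-orientation system singular at q=({posture.q_s:.4f}, "
            f"{posture.q_e:.4f}, {posture.q_w:.4f}) rad (det={det:.2e})"
        )
    return np.linalg.solve(A, b)


def inverse_kinematics_2joint(
    arm: ArmModel,
    hand: np.ndarray,
    link_lengths: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Elbow-down two-joint inverse kinematics.

    By default the hand segment is folded into the forearm (links
    ``(l1, l2 + l3)``), the configuration used when the wrist is splinted
    by the manipulandum handle.  Returns (q_s, q_e) in radians with
    q_e >= 0.

    Raises
    ------
    UnreachableTargetError
        If the target lies outside the reachable annulus; the message
        reports the distance deficit.
    """
    if link_lengths is None:
        l1 = arm.link_lengths[0]
        l2 = arm.link_lengths[1] + arm.link_lengths[2]
    else:
        l1, l2 = link_lengths
    rel = np.asarray(hand, float) - np.asarray(arm.shoulder_position, float)
    d = float(np.linalg.norm(rel))
    if d > l1 + l2 or d < abs(l1 - l2):
        deficit = max(d - (l1 + l2), abs(l1 - l2) - d)
        raise UnreachableTargetError(
            f"target at distance {d:.4f} m outside annulus "
            f"[{abs(l1 - l2):.4f}, {l1 + l2:.4f}] m (deficit {deficit:.4f} m)"
        )
    cos_qe = np.clip((d**2 - l1**2 - l2**2) / (2 * l1 * l2), -1.0, 1.0)
    q_e = float(np.arccos(cos_qe))
    q_s = float(np.arctan2(rel[1], rel[0]) - np.arctan2(l2 * np.sin(q_e), l1 + l2 * np.cos(q_e)))
    return q_s, q_e


def min_jerk_trajectory(
    start: np.ndarray, end: np.ndarray, duration: float, dt: float
) -> Trajectory:
    """Straight-line minimum-jerk point-to-point trajectory.

    Fifth-order polynomial position profile with zero velocity and
    acceleration at both endpoints; peak speed 15 D / (8 T) at midtime.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if dt >= duration:
        raise ValueError("dt must be smaller than duration")
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    tau = np.clip(t / duration, 0.0, 1.0)
    s = 10 * tau**3 - 15 * tau**4 + 6 * tau**5
    sdot = (30 * tau**2 - 60 * tau**3 + 30 * tau**4) / duration
    disp = end - start
    pos = start[None, :] + s[:, None] * disp[None, :]
    vel = sdot[:, None] * disp[None, :]
    return Trajectory(t=t, pos=pos, vel=vel)
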