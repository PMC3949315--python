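"""Viscous force fields and the mechanical channel.

The training perturbation is a velocity-dependent ("skew viscous") field
F = B ẋ whose matrix has unique axes — unlike a curl field, different
movement directions feel different forces.  The same dynamics can be
expressed in joint space as τ = W q̇ with W = J_trainᵀ B J_train; rendering
that joint-space field back at the hand at an arbitrary posture gives the
intrinsic field F = (Jᵀ)⁻¹ W q̇, which coincides with the Cartesian field
at the training posture and diverges from it elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kinematics import ArmModel, JointPosture, SingularPostureError, jacobian

__all__ = [
    "DEFAULT_B",
    "ViscousFieldSpec",
    "ChannelModel",
    "extrinsic_force",
    "joint_field_from_training",
    "intrinsic_force_render",
    "channel_force",
]

#: Velocity-to-force matrix of the training field, N.s/m.
DEFAULT_B = np.array([[-10.1, -11.2], [-11.2, 11.1]])


@dataclass(frozen=True)
class ViscousFieldSpec:
    """A velocity-dependent field in Cartesian, joint, or null form.

    ``kind`` is one of ``extrinsic`` (F = B ẋ), ``intrinsic``
    (τ = W q̇ rendered at the hand), or ``null`` (zero forces).  For the
    intrinsic kind, ``W`` defaults to J_trainᵀ B J_train with the Jacobian
    evaluated at ``train_posture``.
    """

    kind: str = "extrinsic"
    B: np.ndarray = field(default_factory=lambda: DEFAULT_B.copy())
    W: np.ndarray | None = None
    train_posture: JointPosture | None = None
    arm: ArmModel | None = None
    jacobian_variant: str = "two_joint"

    def __post_init__(self) -> None:
        if self.kind not in ("extrinsic", "intrinsic", "null"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        object.__setattr__(self, "B", np.asarray(self.B, float))
        if self.kind == "intrinsic" and self.W is None:
            if self.train_posture is None or self.arm is None:
                raise ValueError("intrinsic field needs train_posture and arm (or explicit W)")
            J = jacobian(self.arm, self.train_posture, self.jacobian_variant)
            object.__setattr__(self, "W", joint_field_from_training(self.B, J))


@dataclass(frozen=True)
class ChannelModel:
    """Simulated one-dimensional spring-damper wall along a straight line.

    Default stiffness 5000 N/m and damping 2 N.s/m; the wall resists any
    motion perpendicular to the start→end line and is transparent along it.
    """

    start: tuple[float, float]
    end: tuple[float, float]
    stiffness: float = 5000.0
    damping: float = 2.0

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.end, float) - np.asarray(self.start, float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("channel line has zero length")
        return d / n

    @property
    def normal(self) -> np.ndarray:
        ux, uy = self.direction
        return np.array([-uy, ux])


def extrinsic_force(spec: ViscousFieldSpec, xdot: np.ndarray) -> np.ndarray:
    """Hand force of a Cartesian (or null) field: F = B ẋ."""
    if spec.kind == "null":
        return np.zeros(2)
    if spec.kind != "extrinsic":
        raise ValueError("extrinsic_force requires an extrinsic or null field")
    return spec.B @ np.asarray(xdot, float)


def joint_field_from_training(B: np.ndarray, J_train: np.ndarray) -> np.ndarray:
    """Joint-space field matrix W = J_trainᵀ B J_train.

    Works for 2x2 or 2x3 training Jacobians, giving a 2x2 or 3x3 W.
    """
    B = np.asarray(B, float)
    J_train = np.asarray(J_train, float)
    if B.shape != (2, 2) or J_train.shape[0] != 2:
        raise ValueError(f"dimension mismatch: B {B.shape}, J_train {J_train.shape}")
    return J_train.T @ B @ J_train


def intrinsic_force_render(
    spec: ViscousFieldSpec,
    posture_now: JointPosture,
    qdot_now: np.ndarray,
    arm: ArmModel | None = None,
) -> np.ndarray:
    """Hand force rendering the joint-space field at the current posture.

    F = (Jᵀ)⁻¹ W q̇ with the two-joint Jacobian re-evaluated at
    ``posture_now`` every sample.
    """
    if spec.kind == "null":
        return np.zeros(2)
    if spec.kind != "intrinsic":
        raise ValueError("intrinsic_force_render requires an intrinsic or null field")
    arm = arm if arm is not None else spec.arm
    if arm is None:
        raise ValueError("an ArmModel is required to evaluate the current Jacobian")
    J = jacobian(arm, posture_now, spec.jacobian_variant)
    det = np.linalg.det(J)
    if abs(det) < 1e-9:
        raise SingularPostureError(
            f"Jacobian singular (det={det:.2e}) at q=({posture_now.q_s:.4f}, "
            f"{posture_now.q_e:.4f}) rad; cannot render intrinsic field"
        )
    return np.linalg.solve(J.T, spec.W @ np.asarray(qdot_now, float))


def channel_force(
    channel: ChannelModel, position: np.ndarray, velocity: np.ndarray
) -> np.ndarray:
    """Restoring force of the channel wall, perpendicular to the line.

    F = −(k·lateral displacement + c·lateral velocity) n̂; the component
    along the channel is identically zero.
    """
    n = channel.normal
    disp = float((np.asarray(position, float) - np.asarray(channel.start, float)) @ n)
    vlat = float(np.asarray(velocity, float) @ n)
    return -(channel.stiffness * disp + channel.damping * vlat) * n
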