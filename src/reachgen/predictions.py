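"""Predicted generalization forces under candidate coordinate frames.

After adapting to F = B ẋ at a single training posture, what force should a
subject produce on a channel trial at a novel posture?  Each coordinate
frame answers differently:

* Cartesian (C): the field is a property of hand space, F = B ẋ regardless
  of posture.
* Object-centered (O): the field belongs to the grasped handle and rotates
  with the hand's external orientation θ, F = R(θ) B R(θ)⁻¹ ẋ.
* Joint-based (J): the learned map is τ = W q̇ with W = J_trainᵀ B J_train;
  at a test posture the expected hand force is the least-squares solution
  F = (J Jᵀ)⁻¹ J W q̇ with the Jacobian re-evaluated along the movement.
  Three variants: the full 2x3 three-joint map (default), the plain
  two-joint map with the wrist as a fixed joint, and a two-joint map where
  forearm+hand form a single virtual segment.

The test battery crosses 3 joint configurations with 5 hand orientations
(wrist offsets 0 .. −45° in 11.25° steps): 15 postures, one 10-cm channel
movement each.  Predicted channel forces are summarized as the mean
perpendicular force 50–450 ms after movement onset, normalized to 1 at the
training posture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinematics import (
    ArmModel,
    JointPosture,
    Trajectory,
    constrained_joint_velocities,
    forward_kinematics,
    jacobian,
    min_jerk_trajectory,
)

__all__ = [
    "TRAIN_POSTURE",
    "JOINT_CONFIGS_DEG",
    "ORIENTATION_OFFSETS_DEG",
    "TestMovement",
    "PredictionSet",
    "build_test_movements",
    "movement_plan",
    "cartesian_prediction",
    "object_prediction",
    "joint_prediction_3joint",
    "joint_prediction_virtual_segment",
    "joint_prediction_2joint",
    "perp_force_summary",
    "compute_predictions",
    "distance_table",
]

#: Training posture: shoulder 35°, elbow 75°, wrist at the group-mean 12.3°.
TRAIN_POSTURE = JointPosture.from_degrees(35.0, 75.0, 12.3)

#: (shoulder, elbow) degrees for the three test joint configurations.
JOINT_CONFIGS_DEG = ((35.0, 75.0), (35.0, 120.0), (80.0, 75.0))

#: Hand-orientation offsets relative to the training wrist angle, degrees.
ORIENTATION_OFFSETS_DEG = (0.0, -11.25, -22.5, -33.75, -45.0)

#: Movement direction (unit vector) per joint configuration.  Configuration
#: 1 moves directly ahead (+y).  Configurations 2 and 3 share a single
#: maximally informative direction; the default (67.5° counterclockwise of
#: straight ahead, i.e. forward-left) makes the Cartesian prediction
#: strongly negative and the joint-based prediction near zero at
#: configuration 3.  It is a protocol parameter.
_D23 = (-np.sin(np.deg2rad(67.5)), np.cos(np.deg2rad(67.5)))
DEFAULT_DIRECTIONS = {1: (0.0, 1.0), 2: _D23, 3: _D23}

REACH_DISTANCE = 0.10  # m
MOVEMENT_DURATION = 0.4  # s
ONSET_SPEED = 0.005  # m/s, movement-onset threshold
FORCE_WINDOW = (0.050, 0.450)  # s after onset


def rotation_matrix(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class TestMovement:
    """One generalization posture and its 10-cm channel movement."""

    movement_id: int
    joint_config: int
    orientation_offset_deg: float
    posture: JointPosture
    start: tuple[float, float]
    target: tuple[float, float]
    duration: float = MOVEMENT_DURATION

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.target, float) - np.asarray(self.start, float)
        return d / np.linalg.norm(d)

    @property
    def channel_normal(self) -> np.ndarray:
        """Left normal of the movement direction (rotates with the movement)."""
        ux, uy = self.direction
        return np.array([-uy, ux])


def build_test_movements(
    arm: ArmModel | None = None,
    train_posture: JointPosture = TRAIN_POSTURE,
    directions: dict[int, tuple[float, float]] | None = None,
    reach_distance: float = REACH_DISTANCE,
) -> list[TestMovement]:
    """The 15 test movements: 3 joint configurations x 5 hand orientations.

    Within a configuration the shoulder/elbow angles (hence the wrist joint
    position) are identical across the 5 orientations; only the wrist angle
    changes, in 11.25° steps of flexion.
    """
    arm = arm or ArmModel()
    directions = directions or DEFAULT_DIRECTIONS
    movements = []
    mid = 0
    for cfg_idx, (qs_deg, qe_deg) in enumerate(JOINT_CONFIGS_DEG, start=1):
        u = np.asarray(directions[cfg_idx], float)
        u = u / np.linalg.norm(u)
        for off in ORIENTATION_OFFSETS_DEG:
            posture = JointPosture.from_degrees(
                qs_deg, qe_deg, np.rad2deg(train_posture.q_w) + off
            )
            start, _ = forward_kinematics(arm, posture)
            target = start + reach_distance * u
            movements.append(
                TestMovement(
                    movement_id=mid,
                    joint_config=cfg_idx,
                    orientation_offset_deg=off,
                    posture=posture,
                    start=tuple(start),
                    target=tuple(target),
                )
            )
            mid += 1
    return movements


def movement_plan(
    movement: TestMovement, dt: float = 0.001, pad: float = 0.2
) -> Trajectory:
    """Minimum-jerk kinematic plan for a test movement, padded at rest.

    ``pad`` seconds of stationary samples are appended so the 50–450 ms
    post-onset analysis window is always covered.
    """
    traj = min_jerk_trajectory(np.asarray(movement.start), np.asarray(movement.target),
                               movement.duration, dt)
    if pad > 0:
        n_pad = int(round(pad / dt))
        t = np.concatenate([traj.t, traj.t[-1] + dt * np.arange(1, n_pad + 1)])
        pos = np.vstack([traj.pos, np.repeat(traj.pos[-1:], n_pad, axis=0)])
        vel = np.vstack([traj.vel, np.zeros((n_pad, 2))])
        traj = Trajectory(t=t, pos=pos, vel=vel)
    return traj


def cartesian_prediction(B: np.ndarray, movement: TestMovement, plan: Trajectory) -> np.ndarray:
    """F(t) = B ẋ(t); identical for every posture sharing a movement direction."""
    return plan.vel @ np.asarray(B, float).T


def object_prediction(
    B: np.ndarray, theta: float, movement: TestMovement, plan: Trajectory
) -> np.ndarray:
    """F(t) = R(θ) B R(θ)⁻¹ ẋ(t) with θ the hand rotation from training.

    θ is the change in *hand orientation in external space*, not the wrist
    angle: shoulder, elbow, and wrist rotations all move the tool frame.
    """
    R = rotation_matrix(theta)
    B_gen = R @ np.asarray(B, float) @ R.T
    return plan.vel @ B_gen.T


def _integrate_posture_2joint(
    arm: ArmModel, movement: TestMovement, plan: Trajectory, variant: str
):
    """Track (q_s, q_e) along the plan by integrating q̇ = J⁻¹ẋ (wrist frozen)."""
    q = np.array([movement.posture.q_s, movement.posture.q_e])
    qw = movement.posture.q_w
    for vel in plan.vel:
        posture = JointPosture(q[0], q[1], qw)
        J = jacobian(arm, posture, variant)
        qdot = np.linalg.solve(J, vel)
        yield posture, J, qdot
        q = q + plan.dt * qdot


def joint_prediction_3joint(
    B: np.ndarray,
    arm: ArmModel,
    train_posture: JointPosture,
    movement: TestMovement,
    plan: Trajectory,
    track_training: bool = True,
) -> np.ndarray:
    """Three-joint intrinsic prediction F = (J Jᵀ)⁻¹ J W q̇.

    The 2x3 test Jacobian and the constrained joint velocities (constant
    hand orientation) are re-evaluated at each sample while the posture is
    integrated along the movement.  With ``track_training`` (default) the
    learned joint-space map W(t) = J_trainᵀ B J_train likewise follows the
    matched execution of the same velocity profile at the training posture,
    so the prediction collapses to F = B ẋ exactly when the test posture is
    the training posture; with ``track_training=False`` W is frozen at the
    training posture's start.
    """
    B = np.asarray(B, float)
    q = movement.posture.as_array()
    q_tr = train_posture.as_array()
    J_tr0 = jacobian(arm, train_posture, "three_joint")
    W = J_tr0.T @ B @ J_tr0
    out = np.empty_like(plan.vel)
    for i, vel in enumerate(plan.vel):
        posture = JointPosture(*q)
        qdot = constrained_joint_velocities(arm, posture, vel)
        J = jacobian(arm, posture, "three_joint")
        if track_training:
            tr_posture = JointPosture(*q_tr)
            # same planned velocity magnitude, direction-matched to training:
            # the training workspace saw this speed profile at this posture
            J_tr = jacobian(arm, tr_posture, "three_joint")
            W = J_tr.T @ B @ J_tr
            qdot_tr = constrained_joint_velocities(arm, tr_posture, vel)
            q_tr = q_tr + plan.dt * qdot_tr
        out[i] = np.linalg.solve(J @ J.T, J @ (W @ qdot))
        q = q + plan.dt * qdot
    return out


def _joint_prediction_2x2(
    B: np.ndarray,
    arm: ArmModel,
    train_posture: JointPosture,
    movement: TestMovement,
    plan: Trajectory,
    variant: str,
    track_training: bool = True,
) -> np.ndarray:
    B = np.asarray(B, float)
    J_tr = jacobian(arm, train_posture, variant)
    W = J_tr.T @ B @ J_tr
    q_tr = np.array([train_posture.q_s, train_posture.q_e])
    qw_tr = train_posture.q_w
    out = np.empty_like(plan.vel)
    for i, (_, J, qdot) in enumerate(_integrate_posture_2joint(arm, movement, plan, variant)):
        if track_training:
            tr_posture = JointPosture(q_tr[0], q_tr[1], qw_tr)
            J_tr = jacobian(arm, tr_posture, variant)
            W = J_tr.T @ B @ J_tr
            qdot_tr = np.linalg.solve(J_tr, plan.vel[i])
            q_tr = q_tr + plan.dt * qdot_tr
        out[i] = np.linalg.solve(J.T, W @ qdot)
    return out


def joint_prediction_virtual_segment(
    B: np.ndarray,
    arm: ArmModel,
    train_posture: JointPosture,
    movement: TestMovement,
    plan: Trajectory,
    track_training: bool = True,
) -> np.ndarray:
    """Two-joint intrinsic prediction with forearm+hand as one virtual segment.

    F(t) = (J_testᵀ)⁻¹ J_trainᵀ B J_train J_test⁻¹ ẋ(t) on the equivalent
    elbow-to-hand segment geometry.
    """
    return _joint_prediction_2x2(
        B, arm, train_posture, movement, plan, "virtual_segment", track_training
    )


def joint_prediction_2joint(
    B: np.ndarray,
    arm: ArmModel,
    train_posture: JointPosture,
    movement: TestMovement,
    plan: Trajectory,
    track_training: bool = True,
) -> np.ndarray:
    """Two-joint intrinsic prediction with the wrist treated as a fixed joint."""
    return _joint_prediction_2x2(
        B, arm, train_posture, movement, plan, "two_joint", track_training
    )


def onset_index(plan: Trajectory, threshold: float = ONSET_SPEED) -> int:
    """First sample whose speed exceeds the movement-onset threshold."""
    above = np.nonzero(plan.speed > threshold)[0]
    if len(above) == 0:
        raise ValueError("trajectory never exceeds the onset speed threshold")
    return int(above[0])


def perp_force_summary(
    force_series: np.ndarray,
    movement: TestMovement,
    plan: Trajectory,
    baseline_series: np.ndarray | None = None,
    training_magnitude: float = 1.0,
    window: tuple[float, float] = FORCE_WINDOW,
) -> float:
    """Windowed mean perpendicular force, baseline-subtracted and normalized.

    Projects the force onto the channel normal, averages it over the
    50–450 ms window after movement onset (speed first exceeds 0.5 cm/s),
    subtracts the same summary of the baseline series if given, and divides
    by the signed training-posture magnitude (so the training movement maps
    to exactly 1).
    """
    f_perp = np.asarray(force_series, float) @ movement.channel_normal
    i0 = onset_index(plan)
    dt = plan.dt
    lo = i0 + int(round(window[0] / dt))
    hi = i0 + int(round(window[1] / dt))
    if hi >= len(f_perp):
        raise ValueError(
            f"force series ends {plan.t[-1] - plan.t[i0]:.3f} s after onset; "
            f"needs at least {window[1]:.3f} s"
        )
    mean = float(np.mean(f_perp[lo : hi + 1]))
    if baseline_series is not None:
        b_perp = np.asarray(baseline_series, float) @ movement.channel_normal
        mean -= float(np.mean(b_perp[lo : hi + 1]))
    return mean / training_magnitude


MODEL_BUILDERS = {
    "J": lambda B, arm, tp, m, plan: joint_prediction_3joint(B, arm, tp, m, plan),
    "J2": lambda B, arm, tp, m, plan: joint_prediction_2joint(B, arm, tp, m, plan),
    "Jv": lambda B, arm, tp, m, plan: joint_prediction_virtual_segment(B, arm, tp, m, plan),
    "C": lambda B, arm, tp, m, plan: cartesian_prediction(B, m, plan),
    "O": lambda B, arm, tp, m, plan: object_prediction(
        B, m.posture.hand_orientation - tp.hand_orientation, m, plan
    ),
}


@dataclass
class PredictionSet:
    """Per-movement predicted channel forces and normalized adaptation."""

    movements: list[TestMovement]
    normalized: pd.DataFrame  # index movement_id, one column per model
    series: dict[tuple[str, int], np.ndarray] = field(repr=False, default_factory=dict)
    training_magnitude: dict[str, float] = field(default_factory=dict)

    def model_matrix(self, models=("J", "C", "O")) -> np.ndarray:
        """(n_movements, n_models) array of normalized adaptation values."""
        return self.normalized[list(models)].to_numpy()


def compute_predictions(
    arm: ArmModel | None = None,
    B: np.ndarray | None = None,
    train_posture: JointPosture = TRAIN_POSTURE,
    movements: list[TestMovement] | None = None,
    models: tuple[str, ...] = ("J", "C", "O"),
    dt: float = 0.001,
    keep_series: bool = False,
) -> PredictionSet:
    """Normalized predicted adaptation for each model at each test movement.

    The training reference is the configuration-1, offset-0 movement (the
    training posture itself); every model is normalized by its own signed
    windowed mean there, making the training value exactly 1 per model.
    """
    from .fields import DEFAULT_B

    arm = arm or ArmModel()
    B = DEFAULT_B if B is None else np.asarray(B, float)
    movements = movements if movements is not None else build_test_movements(arm, train_posture)

    train_mov = min(
        movements,
        key=lambda m: np.linalg.norm(m.posture.as_array() - train_posture.as_array()),
    )
    plans = {m.movement_id: movement_plan(m, dt=dt) for m in movements}

    raw = {name: {} for name in models}
    for name in models:
        builder = MODEL_BUILDERS[name]
        for m in movements:
            series = builder(B, arm, train_posture, m, plans[m.movement_id])
            raw[name][m.movement_id] = series

    training_magnitude = {}
    for name in models:
        tm_series = raw[name][train_mov.movement_id]
        training_magnitude[name] = perp_force_summary(
            tm_series, train_mov, plans[train_mov.movement_id]
        )

    table = {}
    series_out = {}
    for name in models:
        vals = []
        for m in movements:
            a = perp_force_summary(
                raw[name][m.movement_id],
                m,
                plans[m.movement_id],
                training_magnitude=training_magnitude[name],
            )
            vals.append(a)
            if keep_series:
                series_out[(name, m.movement_id)] = raw[name][m.movement_id]
        table[name] = vals
    normalized = pd.DataFrame(table, index=[m.movement_id for m in movements])
    normalized.index.name = "movement_id"
    return PredictionSet(
        movements=movements,
        normalized=normalized,
        series=series_out,
        training_magnitude=training_magnitude,
    )


def distance_table(
    arm: ArmModel | None = None,
    train_posture: JointPosture = TRAIN_POSTURE,
    movements: list[TestMovement] | None = None,
) -> pd.DataFrame:
    """Per-movement deviations from the training posture.

    Columns: d_joint_sq = Δθ_s²+Δθ_e²+Δθ_w² (rad²); d_cart_sq = Δx²+Δy²
    (m²); d_hand_sq = Δθ_hand² (rad²) — the squared distances entering the
    Gaussian decay terms of the local-learning models.
    """
    arm = arm or ArmModel()
    movements = movements if movements is not None else build_test_movements(arm, train_posture)
    train_pos, train_ori = forward_kinematics(arm, train_posture)
    rows = []
    for m in movements:
        dq = m.posture.as_array() - train_posture.as_array()
        pos, ori = forward_kinematics(arm, m.posture)
        rows.append(
            {
                "movement_id": m.movement_id,
                "d_joint_sq": float(dq @ dq),
                "d_cart_sq": float(np.sum((pos - train_pos) ** 2)),
                "d_hand_sq": float((ori - train_ori) ** 2),
            }
        )
    return pd.DataFrame(rows).set_index("movement_id")
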