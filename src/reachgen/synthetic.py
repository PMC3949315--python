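"""Synthetic study generator.

Everything the two human experiments produced, regenerated from code:
trial schedules (pseudorandom 10-cm reach walks with interleaved channel,
no-vision, and catch trials), simulated reach trajectories under viscous
fields with trial-by-trial adaptation, and channel-trial generalization
datasets drawn from a ground-truth mixture/decay model.

The trial-by-trial learner and the plan-tracking controller are
scaffolding for qualitative phenomenology (learning curves, aftereffects);
they are not biomechanical claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fields import ChannelModel, ViscousFieldSpec, channel_force, extrinsic_force
from .fitting import GeneralizationDataset, MixtureSpec, predict_mixture
from .kinematics import (
    ArmModel,
    JointPosture,
    Trajectory,
    inverse_kinematics_2joint,
    jacobian,
    min_jerk_trajectory,
)
from .predictions import (
    TRAIN_POSTURE,
    PredictionSet,
    build_test_movements,
    compute_predictions,
    distance_table,
    forward_kinematics,
)

__all__ = [
    "ProtocolConfig",
    "GroundTruthModel",
    "AdaptationState",
    "make_schedule_exp1",
    "make_schedule_exp2",
    "simulate_channel_dataset",
    "simulate_reach",
    "simulate_cohort",
    "CohortResult",
]

SCHEDULE_COLUMNS = [
    "trial_id",
    "stage",
    "type",
    "vision",
    "workspace",
    "start_x",
    "start_y",
    "target_x",
    "target_y",
    "movement_id",
    "direction_deg",
    "field_kind",
]


@dataclass(frozen=True)
class ProtocolConfig:
    """Trial counts and workspace geometry for one experiment variant.

    Factories (:meth:`experiment1`, :meth:`experiment2`) set the printed
    protocol counts; custom counts may be passed for scaled-down runs.
    """

    experiment: str = "1"
    workspace_halfwidth: float = 0.075  # 15 cm square
    reach_distance: float = 0.10
    n_directions: int = 8
    # experiment-1 counts
    n_pre_null: int = 113
    n_pre_channel: int = 15
    n_exposure: int = 496
    n_gen_field: int = 525
    n_gen_channel: int = 75
    # experiment-2 counts and geometry
    n_baseline_per_ws: int = 250
    n_baseline_novision: int = 48
    n_adapt_blocks: int = 2
    adapt_block_size: int = 500
    n_adapt_novision: int = 192
    n_generalization: int = 80
    shoulder_train: tuple[float, float] = (-0.15, -0.40)
    shoulder_test: tuple[float, float] = (-0.45, -0.40)
    generalization_subgroup: str = "split"  # "split" (40/40) or "mixed" (27/27/26)

    @classmethod
    def experiment1(cls, **kw) -> "ProtocolConfig":
        return cls(experiment="1", **kw)

    @classmethod
    def experiment2(cls, variant: str = "2", **kw) -> "ProtocolConfig":
        if variant not in ("2", "2B", "2C"):
            raise ValueError(f"unknown experiment-2 variant {variant!r}")
        cfg = cls(experiment=variant, **kw)
        if variant == "2C" and "n_adapt_blocks" not in kw:
            # extra exposure: a third 500-trial block, no-vision count at the same rate
            cfg = replace(cfg, n_adapt_blocks=3, n_adapt_novision=288)
        return cfg

    @property
    def n_adapt_total(self) -> int:
        return self.n_adapt_blocks * self.adapt_block_size


@dataclass(frozen=True)
class GroundTruthModel:
    """Generating model for synthetic channel-trial adaptation data.

    Adaptation for subject s at movement m is
    ``scale_s * mixture(m) + N(0, sigma)`` with scale_s ~ N(mean, sd).
    ``sigma`` is a fraction of the training-posture magnitude (which is 1
    after normalization).
    """

    spec: MixtureSpec
    weights: dict[str, float]
    decays: dict[str, float] = field(default_factory=dict)
    noise_sigma: float = 0.1
    subject_scale_mean: float = 1.0
    subject_scale_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be nonnegative")
        w = np.array([self.weights[c] for c in self.spec.components])
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("ground-truth weights must be nonnegative and sum to 1")

    def predict(self, predictions: pd.DataFrame, distances: pd.DataFrame) -> np.ndarray:
        comps = self.spec.components
        X = predictions[list(comps)].to_numpy()
        D = None
        if self.spec.decay:
            from .fitting import DISTANCE_COLUMN

            D = distances[[DISTANCE_COLUMN[c] for c in comps]].to_numpy()
        w = np.array([self.weights[c] for c in comps])
        d = np.array([self.decays.get(c, 0.0) for c in comps]) if self.spec.decay else None
        return predict_mixture(self.spec, w, d, X, D)


@dataclass
class AdaptationState:
    """Single-rate exponential learner toward an incomplete asymptote.

    Channel-trial force plateaus near 80% of full compensation in trained
    subjects; the fraction relaxes toward ``asymptote`` by ``rate`` per
    field trial.
    """

    fraction: float = 0.0
    rate: float = 0.01
    asymptote: float = 0.8

    def update(self) -> None:
        self.fraction += self.rate * (self.asymptote - self.fraction)


# ---------------------------------------------------------------------------
# trial schedules


def _direction_unit(angle_deg: float) -> np.ndarray:
    # 0 deg = straight ahead (+y), positive clockwise
    a = np.deg2rad(angle_deg)
    return np.array([np.sin(a), np.cos(a)])


def _random_walk(
    rng: np.random.Generator,
    n_steps: int,
    center: np.ndarray,
    halfwidth: float,
    step: float,
    n_directions: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Pseudorandom walk of fixed-length reaches staying inside the square.

    Returns (positions (n+1, 2), direction_deg (n,)).  Infeasible draws
    (target outside the square) are resampled.
    """
    angles = 360.0 / n_directions * np.arange(n_directions)
    pos = np.empty((n_steps + 1, 2))
    dirs = np.empty(n_steps)
    pos[0] = center
    for i in range(n_steps):
        feasible = []
        for a in angles:
            tgt = pos[i] + step * _direction_unit(a)
            if np.all(np.abs(tgt - center) <= halfwidth + 1e-12):
                feasible.append(a)
        if not feasible:
            raise RuntimeError("random walk stuck: no feasible direction")
        a = feasible[int(rng.integers(len(feasible)))]
        dirs[i] = a
        pos[i + 1] = pos[i] + step * _direction_unit(a)
    return pos, dirs


def _spread_channel_slots(rng: np.random.Generator, n_total: int, n_channel: int) -> np.ndarray:
    """Channel-trial slots: no two adjacent and never the final trial.

    Guarantees every channel trial is immediately followed by a field (or
    null) movement.  Uses a gap construction: a sorted draw without
    replacement plus its rank index yields strictly non-adjacent slots.
    """
    if n_channel > n_total - n_channel:
        raise ValueError(
            f"cannot place {n_channel} non-adjacent channel trials among {n_total} trials"
        )
    x = np.sort(rng.choice(n_total - n_channel, size=n_channel, replace=False))
    return x + np.arange(n_channel)


def make_schedule_exp1(
    config: ProtocolConfig | None = None,
    seed: int = 0,
    arm: ArmModel | None = None,
) -> pd.DataFrame:
    """Trial table for the three stages of the generalization experiment.

    Preexposure: null-field walk movements with one channel probe of each
    of the 15 test movements.  Exposure: force-field walk movements.
    Generalization: a pseudorandom mixture of field movements and channel
    probes (5 repetitions x 15 movements), each probe immediately followed
    by a field movement.
    """
    config = config or ProtocolConfig.experiment1()
    arm = arm or ArmModel()
    rng = np.random.default_rng(seed)
    center, _ = forward_kinematics(arm, TRAIN_POSTURE)
    movements = build_test_movements(arm, TRAIN_POSTURE, reach_distance=config.reach_distance)

    rows: list[dict] = []

    def add_walk(stage: str, trial_type: str, n: int, field_kind: str) -> None:
        pos, dirs = _random_walk(
            rng, n, center, config.workspace_halfwidth, config.reach_distance, config.n_directions
        )
        for i in range(n):
            rows.append(
                dict(
                    stage=stage,
                    type=trial_type,
                    vision=True,
                    workspace="training",
                    start_x=pos[i, 0],
                    start_y=pos[i, 1],
                    target_x=pos[i + 1, 0],
                    target_y=pos[i + 1, 1],
                    movement_id=-1,
                    direction_deg=dirs[i],
                    field_kind=field_kind,
                )
            )

    def channel_row(stage: str, movement) -> dict:
        return dict(
            stage=stage,
            type="channel",
            vision=True,
            workspace="test_posture",
            start_x=movement.start[0],
            start_y=movement.start[1],
            target_x=movement.target[0],
            target_y=movement.target[1],
            movement_id=movement.movement_id,
            direction_deg=np.nan,
            field_kind="channel",
        )

    # preexposure: null walk with the 15 probes interleaved (never last,
    # never adjacent, so each probe is followed by a walk movement)
    n_pre = config.n_pre_null + config.n_pre_channel
    pre_slots = _spread_channel_slots(rng, n_pre, config.n_pre_channel)
    probe_order = rng.permutation(len(movements))[: config.n_pre_channel]
    walk_rows_start = len(rows)
    add_walk("preexposure", "null", config.n_pre_null, "null")
    pre_walk = rows[walk_rows_start:]
    del rows[walk_rows_start:]
    probes = [channel_row("preexposure", movements[j]) for j in probe_order]
    rows.extend(_interleave(pre_walk, probes, pre_slots, n_pre))

    add_walk("exposure", "field", config.n_exposure, "extrinsic")

    reps = config.n_gen_channel // len(movements)
    probe_ids = np.tile(np.arange(len(movements)), reps)
    if len(probe_ids) != config.n_gen_channel:
        raise ValueError("n_gen_channel must be a multiple of the 15 test movements")
    probe_ids = rng.permutation(probe_ids)
    n_gen = config.n_gen_field + config.n_gen_channel
    gen_slots = _spread_channel_slots(rng, n_gen, config.n_gen_channel)
    walk_rows_start = len(rows)
    add_walk("generalization", "field", config.n_gen_field, "extrinsic")
    gen_walk = rows[walk_rows_start:]
    del rows[walk_rows_start:]
    gen_probes = [channel_row("generalization", movements[j]) for j in probe_ids]
    rows.extend(_interleave(gen_walk, gen_probes, gen_slots, n_gen))

    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return df[SCHEDULE_COLUMNS]


def _interleave(walk_rows, probe_rows, probe_slots, n_total):
    out = []
    slots = set(int(s) for s in probe_slots)
    wi = pi = 0
    for i in range(n_total):
        if i in slots:
            out.append(probe_rows[pi])
            pi += 1
        else:
            out.append(walk_rows[wi])
            wi += 1
    return out


def make_schedule_exp2(
    config: ProtocolConfig | None = None,
    seed: int = 0,
    field_group: str = "extrinsic",
) -> pd.DataFrame:
    """Trial table for the workspace-transfer experiment.

    Baseline: one walk block per workspace with random no-vision trials.
    Adaptation: 2 (or 3) blocks of 500 field trials in the training
    workspace; of the no-vision trials exactly half are null-field catch
    trials.  Generalization: all-no-vision center-out pairs in the testing
    workspace, balanced at 10 reaches per direction, with field assignment
    by subgroup.
    """
    config = config or ProtocolConfig.experiment2()
    rng = np.random.default_rng(seed)
    center = np.zeros(2)
    rows: list[dict] = []

    def add_block(stage, workspace, n, field_kind, novision_idx, catch_idx=()):
        pos, dirs = _random_walk(
            rng, n, center, config.workspace_halfwidth, config.reach_distance, config.n_directions
        )
        novision = set(map(int, novision_idx))
        catch = set(map(int, catch_idx))
        for i in range(n):
            is_catch = i in catch
            rows.append(
                dict(
                    stage=stage,
                    type="catch" if is_catch else ("field" if field_kind != "null" else "null"),
                    vision=i not in novision,
                    workspace=workspace,
                    start_x=pos[i, 0],
                    start_y=pos[i, 1],
                    target_x=pos[i + 1, 0],
                    target_y=pos[i + 1, 1],
                    movement_id=-1,
                    direction_deg=dirs[i],
                    field_kind="null" if is_catch else field_kind,
                )
            )

    for ws in ("training", "testing"):
        nv = rng.choice(config.n_baseline_per_ws, size=config.n_baseline_novision, replace=False)
        add_block("baseline", ws, config.n_baseline_per_ws, "null", nv)

    n_adapt = config.n_adapt_total
    nv = rng.choice(n_adapt, size=config.n_adapt_novision, replace=False)
    catch = rng.choice(nv, size=config.n_adapt_novision // 2, replace=False)
    add_block("adaptation", "training", n_adapt, field_group, nv, catch)

    # generalization: center-out pairs, 10 reaches per direction, all no-vision
    n_pairs = config.n_generalization // 2
    if 2 * n_pairs != config.n_generalization or n_pairs % config.n_directions:
        raise ValueError(
            "generalization trials cannot be balanced: need an even count whose "
            "pair total divides by the number of directions"
        )
    # each outward direction's return reach covers the opposite direction, so
    # n_pairs/n_directions outward pairs per direction gives equal totals
    out_dirs = np.repeat(
        360.0 / config.n_directions * np.arange(config.n_directions),
        n_pairs // config.n_directions,
    )
    out_dirs = rng.permutation(out_dirs)
    fields_seq = _generalization_fields(rng, config)
    k = 0
    for a in out_dirs:
        start = center
        tgt = center + config.reach_distance * _direction_unit(a)
        for s, t, ang in ((start, tgt, a), (tgt, start, (a + 180.0) % 360.0)):
            rows.append(
                dict(
                    stage="generalization",
                    type="field" if fields_seq[k] != "null" else "null",
                    vision=False,
                    workspace="testing",
                    start_x=s[0],
                    start_y=s[1],
                    target_x=t[0],
                    target_y=t[1],
                    movement_id=-1,
                    direction_deg=ang,
                    field_kind=fields_seq[k],
                )
            )
            k += 1

    df = pd.DataFrame(rows)
    df.insert(0, "trial_id", np.arange(len(df)))
    return df[SCHEDULE_COLUMNS]


def _generalization_fields(rng: np.random.Generator, config: ProtocolConfig) -> np.ndarray:
    n = config.n_generalization
    if config.generalization_subgroup == "split":
        seq = np.array(["extrinsic"] * (n // 2) + ["intrinsic"] * (n - n // 2))
    elif config.generalization_subgroup == "mixed":
        n_ext = int(round(27 / 80 * n))
        n_int = n_ext
        seq = np.array(
            ["extrinsic"] * n_ext + ["intrinsic"] * n_int + ["null"] * (n - n_ext - n_int)
        )
    else:
        raise ValueError(f"unknown subgroup {config.generalization_subgroup!r}")
    return rng.permutation(seq)


# ---------------------------------------------------------------------------
# channel-trial datasets


def simulate_channel_dataset(
    ground_truth: GroundTruthModel,
    predictions: PredictionSet | pd.DataFrame,
    n_subjects: int,
    seed: int = 0,
    distances: pd.DataFrame | None = None,
) -> GeneralizationDataset:
    """Normalized adaptation per subject per movement from a known model.

    value = subject_scale x mixture prediction + Gaussian noise(sigma);
    the generating parameters travel in ``meta`` for recovery scoring.
    """
    if isinstance(predictions, PredictionSet):
        pred_table = predictions.normalized
    else:
        pred_table = predictions
    if distances is None:
        distances = distance_table()
    rng = np.random.default_rng(seed)
    truth_per_movement = ground_truth.predict(pred_table, distances)
    scales = ground_truth.subject_scale_mean + ground_truth.subject_scale_sd * rng.standard_normal(
        n_subjects
    )
    noise = ground_truth.noise_sigma * rng.standard_normal((n_subjects, len(truth_per_movement)))
    values = scales[:, None] * truth_per_movement[None, :] + noise
    frame = pd.DataFrame(values, index=pd.RangeIndex(n_subjects, name="subject_id"),
                         columns=pred_table.index)
    return GeneralizationDataset(
        values=frame,
        predictions=pred_table,
        distances=distances,
        meta={
            "truth_components": list(ground_truth.spec.components),
            "truth_decay": ground_truth.spec.decay,
            "truth_weights": dict(ground_truth.weights),
            "truth_decays": dict(ground_truth.decays),
            "noise_sigma": ground_truth.noise_sigma,
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# reach simulation


def _field_force(
    spec: ViscousFieldSpec, arm: ArmModel, pos: np.ndarray, vel: np.ndarray
) -> np.ndarray:
    if spec.kind == "null":
        return np.zeros(2)
    if spec.kind == "extrinsic":
        return extrinsic_force(spec, vel)
    qs, qe = inverse_kinematics_2joint(arm, pos)
    posture = JointPosture(qs, qe, 0.0)
    J = jacobian(arm, posture, "two_joint")
    qdot = np.linalg.solve(J, vel)
    return np.linalg.solve(J.T, spec.W @ qdot)


def simulate_reach(
    arm: ArmModel,
    field_spec: ViscousFieldSpec,
    adaptation: AdaptationState | float,
    plan: Trajectory,
    noise_std: float = 0.0,
    dt: float | None = None,
    catch: bool = False,
    channel: ChannelModel | None = None,
    mass: float = 2.0,
    kp: float = 2000.0,
    kd: float = 40.0,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """Point-mass hand tracking a kinematic plan under a viscous field.

    The hand follows the plan with spring-damper feedback (kp, kd) plus a
    learned feedforward compensation equal to ``fraction`` x the ideal
    opposing force along the plan.  On catch trials the field is off but
    the feedforward remains, producing the mirror-image aftereffect.
    Optional white force noise and an optional channel wall.

    Raises on numerical blow-up with a report of the gains.
    """
    fraction = adaptation.fraction if isinstance(adaptation, AdaptationState) else float(adaptation)
    dt = dt if dt is not None else plan.dt
    if not np.isclose(dt, plan.dt):
        raise ValueError("simulation dt must match the plan sampling")
    rng = rng or np.random.default_rng(0)
    n = len(plan.t)
    x = plan.pos[0].astype(float).copy()
    v = np.zeros(2)
    pos = np.empty((n, 2))
    vel = np.empty((n, 2))
    frc = np.empty((n, 2))
    for i in range(n):
        f_field = np.zeros(2) if catch else _field_force(field_spec, arm, x, v)
        f_ff = -fraction * _field_force(field_spec, arm, plan.pos[i], plan.vel[i])
        f_fb = kp * (plan.pos[i] - x) + kd * (plan.vel[i] - v)
        f_ext = f_field.copy()
        if channel is not None:
            f_ch = channel_force(channel, x, v)
            f_ext += f_ch
        f_noise = noise_std * rng.standard_normal(2) if noise_std > 0 else 0.0
        a = (f_ext + f_ff + f_fb + f_noise) / mass
        v = v + dt * a
        x = x + dt * v
        pos[i], vel[i], frc[i] = x, v, f_ext
        if not np.all(np.isfinite(x)) or np.linalg.norm(x - plan.pos[i]) > 1.0:
            raise RuntimeError(
                f"reach simulation unstable at step {i} (kp={kp}, kd={kd}, "
                f"mass={mass}, dt={dt})"
            )
    return Trajectory(t=plan.t.copy(), pos=pos, vel=vel, force=frc)


# ---------------------------------------------------------------------------
# full cohorts


@dataclass
class CohortResult:
    """All artifacts of one synthetic cohort."""

    schedule: pd.DataFrame
    dataset: GeneralizationDataset
    exposure_metrics: pd.DataFrame  # subject_id, trial_index, type, signed_mpe, fraction
    predictions: PredictionSet


def simulate_cohort(
    protocol: ProtocolConfig | None = None,
    ground_truth: GroundTruthModel | None = None,
    n_subjects: int = 9,
    seed: int = 0,
    arm: ArmModel | None = None,
    learning_rate: float = 0.01,
    reach_stride: int = 10,
    reach_dt: float = 0.005,
) -> CohortResult:
    """Generate a full synthetic study for the generalization experiment.

    Builds the trial schedule, simulates the exposure-stage reaches of each
    subject (every ``reach_stride``-th trial, with catch-style aftereffect
    probes) while the learner adapts, and draws the channel-trial
    generalization dataset from ``ground_truth``.
    """
    protocol = protocol or ProtocolConfig.experiment1()
    arm = arm or ArmModel()
    if ground_truth is None:
        ground_truth = GroundTruthModel(
            spec=MixtureSpec(("J",), decay=True),
            weights={"J": 1.0},
            decays={"J": 0.93},
            noise_sigma=0.1,
        )
    rng = np.random.default_rng(seed)
    schedule = make_schedule_exp1(protocol, seed=int(rng.integers(2**31 - 1)), arm=arm)
    preds = compute_predictions(arm=arm)
    dataset = simulate_channel_dataset(
        ground_truth, preds, n_subjects, seed=int(rng.integers(2**31 - 1))
    )

    field_spec = ViscousFieldSpec(kind="extrinsic")
    exposure = schedule[schedule.stage == "exposure"].reset_index(drop=True)
    rows = []
    for s in range(n_subjects):
        state = AdaptationState(rate=learning_rate)
        sub_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))
        for idx, trial in exposure.iterrows():
            if idx % reach_stride == 0:
                start = np.array([trial.start_x, trial.start_y])
                target = np.array([trial.target_x, trial.target_y])
                plan = min_jerk_trajectory(start, target, 0.4, reach_dt)
                for trial_type, is_catch in (("field", False), ("catch", True)):
                    traj = simulate_reach(
                        arm,
                        field_spec,
                        state,
                        plan,
                        noise_std=0.05,
                        catch=is_catch,
                        rng=sub_rng,
                    )
                    from .metrics import signed_mpe

                    rows.append(
                        dict(
                            subject_id=s,
                            trial_index=int(idx),
                            type=trial_type,
                            direction_deg=float(trial.direction_deg),
                            signed_mpe=signed_mpe(traj, start, target),
                            fraction=state.fraction,
                        )
                    )
            state.update()
    exposure_metrics = pd.DataFrame(rows)
    return CohortResult(
        schedule=schedule,
        dataset=dataset,
        exposure_metrics=exposure_metrics,
        predictions=preds,
    )
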