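import numpy as np
import pandas as pd
import pytest

from reachgen.fields import ViscousFieldSpec
from reachgen.fitting import MixtureSpec, fit_mixture
from reachgen.kinematics import ArmModel, min_jerk_trajectory
from reachgen.metrics import mpe, signed_mpe
from reachgen.predictions import TRAIN_POSTURE, forward_kinematics
from reachgen.synthetic import (
    AdaptationState,
    GroundTruthModel,
    ProtocolConfig,
    make_schedule_exp1,
    make_schedule_exp2,
    simulate_channel_dataset,
    simulate_cohort,
    simulate_reach,
)


@pytest.fixture(scope="module")
def exp1_schedule():
    return make_schedule_exp1(seed=42)


@pytest.fixture(scope="module")
def exp2_schedule():
    return make_schedule_exp2(seed=1)


@pytest.fixture(scope="module")
def reach_plan():
    return min_jerk_trajectory([0.0, 0.3], [0.0, 0.4], 0.4, 0.002)


@pytest.fixture(scope="module")
def sim_arm():
    return ArmModel(link_lengths=(0.30, 0.32, 1e-9), shoulder_position=(-0.15, -0.10))


@pytest.fixture(scope="module")
def cohort():
    protocol = ProtocolConfig.experiment1(
        n_pre_null=20, n_pre_channel=15, n_exposure=120, n_gen_field=30, n_gen_channel=15
    )
    return simulate_cohort(
        protocol, n_subjects=3, seed=99, learning_rate=0.03, reach_stride=10
    )


class TestScheduleExp1:

    def test_stage_counts_match_protocol(self, exp1_schedule):
        pre = exp1_schedule[exp1_schedule.stage == "preexposure"]
        expo = exp1_schedule[exp1_schedule.stage == "exposure"]
        gen = exp1_schedule[exp1_schedule.stage == "generalization"]
        assert len(pre) == 128
        assert (pre.type == "null").sum() == 113
        assert (pre.type == "channel").sum() == 15
        assert len(expo) == 496 and (expo.type == "field").all()
        assert len(gen) == 600
        assert (gen.type == "field").sum() == 525
        assert (gen.type == "channel").sum() == 75

    def test_five_repetitions_of_each_test_movement(self, exp1_schedule):
        gen = exp1_schedule[(exp1_schedule.stage == "generalization") & (exp1_schedule.type == "channel")]
        counts = gen.movement_id.value_counts()
        assert sorted(counts.index) == list(range(15))
        assert (counts == 5).all()

    def test_channel_trials_followed_by_field_movement(self, exp1_schedule):
        types = exp1_schedule.type.to_numpy()
        for i in np.nonzero(types == "channel")[0]:
            assert i + 1 < len(types)
            assert types[i + 1] in ("field", "null")

    def test_walk_stays_inside_training_square(self, exp1_schedule):
        arm = ArmModel()
        center, _ = forward_kinematics(arm, TRAIN_POSTURE)
        walk = exp1_schedule[exp1_schedule.type != "channel"]
        for col, c in (("target_x", center[0]), ("target_y", center[1])):
            assert (np.abs(walk[col] - c) <= 0.075 + 1e-9).all()

    def test_walk_steps_are_ten_centimeters(self, exp1_schedule):
        walk = exp1_schedule[exp1_schedule.type != "channel"]
        steps = np.hypot(walk.target_x - walk.start_x, walk.target_y - walk.start_y)
        np.testing.assert_allclose(steps, 0.10, rtol=1e-9)

    def test_seed_determinism(self):
        a = make_schedule_exp1(seed=7)
        b = make_schedule_exp1(seed=7)
        c = make_schedule_exp1(seed=8)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)


class TestScheduleExp2:

    def test_baseline_blocks(self, exp2_schedule):
        base = exp2_schedule[exp2_schedule.stage == "baseline"]
        assert len(base) == 500
        for ws in ("training", "testing"):
            block = base[base.workspace == ws]
            assert len(block) == 250
            assert (~block.vision).sum() == 48

    def test_adaptation_block_and_catch_trials(self, exp2_schedule):
        adapt = exp2_schedule[exp2_schedule.stage == "adaptation"]
        assert len(adapt) == 1000
        novision = adapt[~adapt.vision]
        assert len(novision) == 192
        assert (novision.type == "catch").sum() == 96  # exactly half are catch
        assert (adapt[adapt.type == "catch"].field_kind == "null").all()

    def test_generalization_balanced_directions(self, exp2_schedule):
        gen = exp2_schedule[exp2_schedule.stage == "generalization"]
        assert len(gen) == 80
        assert (~gen.vision).all()
        counts = gen.direction_deg.value_counts()
        assert len(counts) == 8
        assert (counts == 10).all()

    def test_mixed_subgroup_field_counts(self):
        cfg = ProtocolConfig.experiment2(generalization_subgroup="mixed")
        sched = make_schedule_exp2(cfg, seed=3)
        gen = sched[sched.stage == "generalization"]
        assert (gen.field_kind == "extrinsic").sum() == 27
        assert (gen.field_kind == "intrinsic").sum() == 27
        assert (gen.field_kind == "null").sum() == 26

    def test_extended_exposure_variant(self):
        cfg = ProtocolConfig.experiment2("2C")
        sched = make_schedule_exp2(cfg, seed=2)
        assert (sched.stage == "adaptation").sum() == 1500

    def test_seed_determinism(self):
        pd.testing.assert_frame_equal(make_schedule_exp2(seed=5), make_schedule_exp2(seed=5))


class TestChannelDataset:
    def test_noiseless_equals_model(self, prediction_set, distances):
        truth = GroundTruthModel(MixtureSpec(("C",)), {"C": 1.0}, noise_sigma=0.0)
        ds = simulate_channel_dataset(truth, prediction_set, 5, seed=0, distances=distances)
        expected = prediction_set.normalized["C"].to_numpy()
        for i in range(5):
            np.testing.assert_allclose(ds.values.iloc[i].to_numpy(), expected, atol=1e-14)

    def test_large_sample_mean_near_model(self, prediction_set, distances):
        truth = GroundTruthModel(MixtureSpec(("J",)), {"J": 1.0}, noise_sigma=0.1)
        n = 4000
        ds = simulate_channel_dataset(truth, prediction_set, n, seed=1, distances=distances)
        expected = prediction_set.normalized["J"].to_numpy()
        err = ds.values.to_numpy().mean(axis=0) - expected
        # 4-sigma bound: 15 simultaneous central-limit comparisons
        assert np.all(np.abs(err) < 4 * 0.1 / np.sqrt(n))

    def test_fitting_recovers_generating_spec_noiselessly(self, prediction_set, distances):
        truth = GroundTruthModel(
            MixtureSpec(("J", "O")), {"J": 0.71, "O": 0.29}, noise_sigma=0.0
        )
        ds = simulate_channel_dataset(truth, prediction_set, 4, seed=2, distances=distances)
        res = fit_mixture(ds, MixtureSpec(("J", "O")), seed=0)
        assert res.weights["J"] == pytest.approx(0.71, abs=1e-6)
        assert res.mse == pytest.approx(0.0, abs=1e-12)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            GroundTruthModel(MixtureSpec(("J",)), {"J": 1.0}, noise_sigma=-0.1)

    def test_metadata_carries_truth(self, prediction_set, distances):
        truth = GroundTruthModel(MixtureSpec(("J",)), {"J": 1.0}, noise_sigma=0.05)
        ds = simulate_channel_dataset(truth, prediction_set, 3, seed=4, distances=distances)
        assert ds.meta["truth_weights"] == {"J": 1.0}
        assert ds.meta["noise_sigma"] == 0.05


class TestSimulateReach:

    def test_null_field_tracks_plan(self, sim_arm, reach_plan):
        traj = simulate_reach(sim_arm, ViscousFieldSpec(kind="null"), 0.0, reach_plan)
        assert mpe(traj, reach_plan.pos[0], reach_plan.pos[-1]) < 1e-3

    def test_compensation_reduces_error(self, sim_arm, reach_plan):
        spec = ViscousFieldSpec(kind="extrinsic")
        naive = simulate_reach(sim_arm, spec, 0.0, reach_plan)
        adapted = simulate_reach(sim_arm, spec, 1.0, reach_plan)
        assert mpe(adapted, reach_plan.pos[0], reach_plan.pos[-1]) < mpe(naive, reach_plan.pos[0], reach_plan.pos[-1])

    def test_catch_trial_mirror_aftereffect(self, sim_arm, reach_plan):
        spec = ViscousFieldSpec(kind="extrinsic")
        early = simulate_reach(sim_arm, spec, 0.0, reach_plan)
        catch = simulate_reach(sim_arm, spec, 0.8, reach_plan, catch=True)
        s_early = signed_mpe(early, reach_plan.pos[0], reach_plan.pos[-1])
        s_catch = signed_mpe(catch, reach_plan.pos[0], reach_plan.pos[-1])
        assert np.sign(s_early) == -np.sign(s_catch)

    def test_instability_reported(self, sim_arm, reach_plan):
        with pytest.raises(RuntimeError, match="unstable"):
            simulate_reach(sim_arm, ViscousFieldSpec(kind="null"), 0.0, reach_plan, kp=-5e4, kd=0.0)


class TestCohort:

    def test_end_to_end_fit_per_candidate_model(self, cohort):
        for spec in (MixtureSpec(("J",), decay=True), MixtureSpec(("J", "C", "O"))):
            res = fit_mixture(cohort.dataset, spec, seed=0)
            assert np.isfinite(res.mse)

    def test_exposure_mpe_decreases(self, cohort):
        field = cohort.exposure_metrics[cohort.exposure_metrics.type == "field"]
        by_trial = field.groupby("trial_index").signed_mpe.apply(lambda s: s.abs().mean())
        first, last = by_trial.iloc[0], by_trial.iloc[-1]
        assert last < first

    def test_catch_mpe_opposes_exposure_mpe(self, cohort):
        # mirror-image aftereffect: within a reach direction, late catch
        # trials deviate to the opposite side of early field trials
        em = cohort.exposure_metrics
        checked = 0
        for _, grp in em.groupby("direction_deg"):
            field = grp[grp.type == "field"]
            catch = grp[grp.type == "catch"]
            if len(field) < 3 or len(catch) < 3:
                continue
            assert np.sign(field.signed_mpe.mean()) == -np.sign(catch.signed_mpe.mean())
            checked += 1
        assert checked >= 3

    def test_adaptation_state_monotone(self):
        state = AdaptationState(rate=0.05)
        vals = []
        for _ in range(100):
            state.update()
            vals.append(state.fraction)
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] < 0.8
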