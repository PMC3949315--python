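import itertools

import numpy as np
import pandas as pd
import pytest

from reachgen.fitting import (
    GeneralizationDataset,
    MixtureSpec,
    all_model_specs,
    compare_models,
    compute_bic,
    fit_mixture,
    loocv,
    predict_mixture,
)
from reachgen.synthetic import GroundTruthModel, simulate_channel_dataset


def make_dataset(prediction_set, distances, truth, n_subjects=9, seed=0):
    return simulate_channel_dataset(truth, prediction_set, n_subjects, seed=seed,
                                    distances=distances)


def simplex_grid_mse(dataset, components, resolution=0.01):
    """Brute-force MSE minimum over the weight simplex at fixed resolution."""
    X = dataset.component_matrix(components)
    V = dataset.values.to_numpy()
    steps = int(round(1 / resolution))
    best = np.inf
    p = len(components)
    v_mean = V.mean(axis=0)
    v_sq = np.mean(V**2)
    for combo in itertools.product(range(steps + 1), repeat=p - 1):
        if sum(combo) > steps:
            continue
        w = np.array(list(combo) + [steps - sum(combo)]) / steps
        pred = X @ w
        # mean over subjects and movements without materializing residuals
        mse = v_sq - 2 * np.mean(v_mean * pred) + np.mean(pred**2)
        best = min(best, mse)
    return best


@pytest.fixture(scope="module")
def joc_truth():
    return GroundTruthModel(
        spec=MixtureSpec(("J", "C", "O")),
        weights={"J": 0.66, "C": 0.10, "O": 0.24},
        noise_sigma=0.0,
    )


class TestPredictMixture:
    def test_zero_decay_reduces_to_plain_mixture(self, prediction_set, distances):
        spec_d = MixtureSpec(("J", "C", "O"), decay=True)
        spec = MixtureSpec(("J", "C", "O"))
        X = prediction_set.normalized[["J", "C", "O"]].to_numpy()
        D = distances[["d_joint_sq", "d_cart_sq", "d_hand_sq"]].to_numpy()
        w = np.array([0.5, 0.3, 0.2])
        np.testing.assert_allclose(
            predict_mixture(spec_d, w, np.zeros(3), X, D),
            predict_mixture(spec, w, None, X),
            atol=1e-14,
        )

    def test_pure_component_verbatim(self, prediction_set):
        spec = MixtureSpec(("J",))
        X = prediction_set.normalized[["J"]].to_numpy()
        np.testing.assert_allclose(
            predict_mixture(spec, np.ones(1), None, X), X[:, 0], atol=1e-14
        )

    def test_manual_arithmetic_on_toy_set(self):
        # fitted three-component weights applied to a 3-movement toy battery
        spec = MixtureSpec(("J", "C", "O"))
        X = np.array([[1.0, 1.0, 1.0], [0.5, -1.0, 0.2], [0.0, -1.0, -0.9]])
        w = np.array([0.66, 0.10, 0.24])
        expected = [
            0.66 * 1.0 + 0.10 * 1.0 + 0.24 * 1.0,
            0.66 * 0.5 + 0.10 * -1.0 + 0.24 * 0.2,
            0.66 * 0.0 + 0.10 * -1.0 + 0.24 * -0.9,
        ]
        np.testing.assert_allclose(predict_mixture(spec, w, None, X), expected, rtol=1e-12)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            predict_mixture(MixtureSpec(("J",)), np.array([-0.1]), None, np.ones((3, 1)))


class TestFitMixture:
    def test_pure_joint_exact_recovery(self, prediction_set, distances):
        truth = GroundTruthModel(MixtureSpec(("J",)), {"J": 1.0}, noise_sigma=0.0)
        ds = make_dataset(prediction_set, distances, truth)
        res = fit_mixture(ds, MixtureSpec(("J", "C", "O")), seed=1)
        assert res.weights["J"] == pytest.approx(1.0, abs=1e-6)
        assert res.mse == pytest.approx(0.0, abs=1e-12)

    def test_three_component_recovery_noiseless(self, prediction_set, distances, joc_truth):
        ds = make_dataset(prediction_set, distances, joc_truth)
        res = fit_mixture(ds, MixtureSpec(("J", "C", "O")), seed=2)
        assert res.weights["J"] == pytest.approx(0.66, abs=1e-3)
        assert res.weights["C"] == pytest.approx(0.10, abs=1e-3)
        assert res.weights["O"] == pytest.approx(0.24, abs=1e-3)

    def test_weights_on_simplex(self, prediction_set, distances, joc_truth):
        truth = GroundTruthModel(**{**joc_truth.__dict__, "noise_sigma": 0.2})
        ds = make_dataset(prediction_set, distances, truth, seed=5)
        for spec in (MixtureSpec(("J", "C")), MixtureSpec(("J", "C", "O"), decay=True)):
            res = fit_mixture(ds, spec, seed=3)
            w = np.array(list(res.weights.values()))
            assert np.all(w >= 0)
            assert w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_simplex_grid_oracle(self, prediction_set, distances, joc_truth):
        truth = GroundTruthModel(**{**joc_truth.__dict__, "noise_sigma": 0.1})
        ds = make_dataset(prediction_set, distances, truth, seed=7)
        res = fit_mixture(ds, MixtureSpec(("J", "C", "O")), seed=4)
        grid = simplex_grid_mse(ds, ("J", "C", "O"), resolution=0.01)
        assert res.mse <= grid + 1e-10
        assert grid - res.mse <= 5e-3  # grid-resolution gap

    def test_decay_nests_no_decay(self, prediction_set, distances):
        truth = GroundTruthModel(
            MixtureSpec(("J",), decay=True), {"J": 1.0}, {"J": 0.93}, noise_sigma=0.1
        )
        ds = make_dataset(prediction_set, distances, truth, seed=11)
        plain = fit_mixture(ds, MixtureSpec(("J", "O")), seed=5)
        decayed = fit_mixture(ds, MixtureSpec(("J", "O"), decay=True), seed=5)
        assert decayed.mse <= plain.mse + 1e-12

    def test_too_few_movements_rejected(self, prediction_set, distances):
        vals = pd.DataFrame([[1.0, 0.5]], columns=[0, 1])
        ds = GeneralizationDataset(vals, prediction_set.normalized, distances)
        with pytest.raises(ValueError, match="fewer movements"):
            fit_mixture(ds, MixtureSpec(("J", "C", "O"), decay=True))


class TestBIC:
    def test_unit_mse(self):
        assert compute_bic(1.0, 3, 50) == pytest.approx(3 * np.log(50))

    def test_zero_dof(self):
        assert compute_bic(0.5, 0, 135) == pytest.approx(135 * np.log(0.5))

    def test_hand_evaluated_example(self):
        # 135 * ln 0.5 + 2 * ln 135
        assert compute_bic(0.5, 2, 135) == pytest.approx(-83.76432, abs=1e-4)

    def test_zero_mse_sentinel(self):
        with pytest.warns(UserWarning, match="zero"):
            assert compute_bic(0.0, 1, 10) == -np.inf


class TestCompareModels:
    def _result(self, spec, mse, n=135):
        from reachgen.fitting import FitResult

        w = {c: 1.0 / len(spec.components) for c in spec.components}
        return FitResult(spec, w, {}, mse=mse, n=n)

    def test_penalty_monotonicity_on_ties(self):
        r_simple = self._result(MixtureSpec(("J",)), 0.5)
        r_complex = self._result(MixtureSpec(("J", "C", "O")), 0.5)
        table = compare_models([r_complex, r_simple])
        assert table.iloc[0]["model"] == "J"

    def test_delta_vs_self_is_zero(self):
        r = self._result(MixtureSpec(("J",)), 0.3)
        table = compare_models([r])
        assert table["delta_bic"].iloc[0] == 0.0
        assert table["log_bayes_factor"].iloc[0] == 0.0

    def test_ordering_matches_manual_sort(self):
        results = [
            self._result(MixtureSpec(("J",)), 0.8),
            self._result(MixtureSpec(("C",)), 0.2),
            self._result(MixtureSpec(("O",)), 0.4),
        ]
        table = compare_models(results)
        bics = [compute_bic(m, 0, 135) for m in (0.2, 0.4, 0.8)]
        np.testing.assert_allclose(table["bic"].to_numpy(), bics)
        assert list(table["model"]) == ["C", "O", "J"]

    def test_reference_improvement_column(self):
        from reachgen.fitting import FitResult

        ref = FitResult(MixtureSpec(()), {}, {}, mse=1.2, n=135)
        r = self._result(MixtureSpec(("J",)), 0.3)
        table = compare_models([r], reference=ref)
        assert table["bic_improvement"].iloc[0] == pytest.approx(ref.bic - r.bic)

    def test_mixed_n_rejected(self):
        r1 = self._result(MixtureSpec(("J",)), 0.5, n=135)
        r2 = self._result(MixtureSpec(("C",)), 0.5, n=60)
        with pytest.raises(ValueError, match="different n"):
            compare_models([r1, r2])


class TestLOOCV:
    def test_perfect_model_on_homogeneous_cohort(self, prediction_set, distances):
        truth = GroundTruthModel(MixtureSpec(("J",)), {"J": 1.0}, noise_sigma=0.0)
        ds = make_dataset(prediction_set, distances, truth, n_subjects=4)
        ve = loocv(ds, MixtureSpec(("J",)))
        np.testing.assert_allclose(ve, 1.0, atol=1e-9)

    def test_mean_prediction_scores_zero(self, prediction_set, distances):
        # a subject whose data equal the model prediction's own mean
        # everywhere has SST == SSE for any prediction equal to that mean;
        # here: the no-generalization reference on centered data
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(rng.standard_normal((4, 15)), columns=range(15))
        vals = vals.sub(vals.mean(axis=1), axis=0)  # row-mean zero
        ds = GeneralizationDataset(vals, prediction_set.normalized, distances)
        ve = loocv(ds, MixtureSpec(()))
        np.testing.assert_allclose(ve, 0.0, atol=1e-9)

    def test_against_direct_sse_sst_oracle(self, prediction_set, distances):
        truth = GroundTruthModel(
            MixtureSpec(("J", "C", "O")),
            {"J": 0.66, "C": 0.10, "O": 0.24},
            noise_sigma=0.15,
        )
        ds = make_dataset(prediction_set, distances, truth, n_subjects=4, seed=3)
        spec = MixtureSpec(("J",))
        ve = loocv(ds, spec, seed=9)
        # independent computation
        X = ds.component_matrix(("J",))
        pred = X[:, 0]  # single-component fit is always k=1
        for i, subject in enumerate(ds.values.index):
            y = ds.values.loc[subject].to_numpy()
            sse = np.sum((y - pred) ** 2)
            sst = np.sum((y - y.mean()) ** 2)
            assert ve[i] == pytest.approx(1 - sse / sst, rel=1e-9)

    def test_needs_three_subjects(self, prediction_set, distances):
        vals = pd.DataFrame(np.ones((2, 15)), columns=range(15))
        ds = GeneralizationDataset(vals, prediction_set.normalized, distances)
        with pytest.raises(ValueError, match="3 subjects"):
            loocv(ds, MixtureSpec(("J",)))


def test_all_model_specs_enumeration():
    specs = all_model_specs()
    assert len(specs) == 14
    assert {s.dof for s in specs if not s.decay} == {0, 1, 2}
    assert {s.dof for s in specs if s.decay} == {1, 3, 5}
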