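"""Mixture and decaying-generalization model fits.

The measured generalization pattern (normalized adaptation per subject per
test movement) is modeled as a nonnegative mixture of the coordinate-frame
predictions J, C, O, with weights constrained to the simplex (sum to 1, so
the model fully accounts for learning at the training posture), optionally
multiplied by Gaussian decay terms in each frame's own distance metric:

    a(m) = k_j J(m) e^{-d_j Δθ²} + k_c C(m) e^{-d_c Δx²} + k_o O(m) e^{-d_o Δθ_hand²}

Models are compared with BIC = n·ln(MSE) + dof·ln(n) (ΔBIC/2 approximates a
log Bayes factor) and with leave-one-subject-out cross-validation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "GeneralizationDataset",
    "MixtureSpec",
    "FitResult",
    "ALL_COMPONENTS",
    "all_model_specs",
    "predict_mixture",
    "fit_mixture",
    "compute_bic",
    "compare_models",
    "loocv",
]

ALL_COMPONENTS = ("J", "C", "O")

#: Squared-distance column used by each component's decay term.
DISTANCE_COLUMN = {"J": "d_joint_sq", "C": "d_cart_sq", "O": "d_hand_sq"}

#: Bounds for decay rates (rad⁻² or m⁻²); log-uniform restart range.
DECAY_BOUNDS = (0.0, 1e4)
DECAY_LOG_RANGE = (-2.0, 3.0)


@dataclass
class GeneralizationDataset:
    """Subject x movement normalized adaptation plus movement metadata.

    ``values`` is a wide DataFrame (index subject_id, columns movement_id);
    ``predictions`` holds the per-movement model predictions (columns J, C,
    O); ``distances`` the squared deviations from the training posture used
    by the decay terms.
    """

    values: pd.DataFrame
    predictions: pd.DataFrame
    distances: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("adaptation values must be finite")
        missing = set(self.values.columns) - set(self.predictions.index)
        if missing:
            raise ValueError(f"movements without predictions: {sorted(missing)}")

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def movement_ids(self) -> list:
        return list(self.values.columns)

    def component_matrix(self, components) -> np.ndarray:
        return self.predictions.loc[self.movement_ids, list(components)].to_numpy()

    def distance_matrix(self, components) -> np.ndarray:
        cols = [DISTANCE_COLUMN[c] for c in components]
        return self.distances.loc[self.movement_ids, cols].to_numpy()

    def subject_average(self) -> np.ndarray:
        return self.values.to_numpy().mean(axis=0)


@dataclass(frozen=True)
class MixtureSpec:
    """Which coordinate-frame components are mixed, with or without decay.

    Degrees of freedom follow the mixture accounting: without decay a
    p-component simplex has p−1 free weights (0/1/2 dof); with decay each
    component adds one rate (1/3/5 dof).  The empty spec is the
    no-generalization reference (prediction ≡ 0, dof 0).
    """

    components: tuple[str, ...] = ALL_COMPONENTS
    decay: bool = False

    def __post_init__(self) -> None:
        bad = set(self.components) - set(ALL_COMPONENTS)
        if bad:
            raise ValueError(f"unknown components {sorted(bad)}")

    @property
    def dof(self) -> int:
        p = len(self.components)
        if p == 0:
            return 0
        return (p - 1) + (p if self.decay else 0)

    @property
    def label(self) -> str:
        if not self.components:
            return "none"
        name = "+".join(self.components)
        return f"{name} (decay)" if self.decay else name


def all_model_specs(decay: bool | None = None) -> list[MixtureSpec]:
    """All one-, two-, and three-component specs (14 when decay is None)."""
    subsets = [
        tuple(c for c in ALL_COMPONENTS if c in combo)
        for r in (1, 2, 3)
        for combo in itertools.combinations(ALL_COMPONENTS, r)
    ]
    flags = [False, True] if decay is None else [decay]
    return [MixtureSpec(s, d) for d in flags for s in subsets]


@dataclass
class FitResult:
    """Fitted mixture weights, decay rates, and fit diagnostics."""

    spec: MixtureSpec
    weights: dict[str, float]
    decays: dict[str, float]
    mse: float
    n: int
    converged: bool = True
    seed: int | None = None
    variance_explained: np.ndarray | None = None

    @property
    def dof(self) -> int:
        return self.spec.dof

    @property
    def bic(self) -> float:
        return compute_bic(self.mse, self.dof, self.n)

    def params(self) -> dict:
        out = {f"k_{c.lower()}": self.weights.get(c, 0.0) for c in ALL_COMPONENTS}
        out.update({f"d_{c.lower()}": self.decays.get(c, np.nan) for c in ALL_COMPONENTS})
        return out

    def to_dict(self) -> dict:
        d = {
            "model": self.spec.label,
            "components": list(self.spec.components),
            "decay": self.spec.decay,
            "dof": self.dof,
            "mse": self.mse,
            "n": self.n,
            "bic": self.bic,
            "converged": self.converged,
            "seed": self.seed,
        }
        d.update(self.params())
        if self.variance_explained is not None:
            d["variance_explained"] = list(map(float, self.variance_explained))
        return d


def predict_mixture(
    spec: MixtureSpec,
    weights: np.ndarray,
    decays: np.ndarray | None,
    component_matrix: np.ndarray,
    distance_matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Per-movement model prediction for given parameters.

    ``component_matrix`` is (n_movements, p) in the order of
    ``spec.components``; ``distance_matrix`` the matching squared distances
    (required when decay is on).
    """
    p = len(spec.components)
    if p == 0:
        return np.zeros(component_matrix.shape[0] if component_matrix is not None else 0)
    weights = np.asarray(weights, float)
    if np.any(weights < -1e-12):
        raise ValueError("mixture weights must be nonnegative")
    gain = component_matrix * weights[None, :]
    if spec.decay:
        if distance_matrix is None:
            raise ValueError("decay model needs a distance matrix")
        decays = np.asarray(decays, float)
        if np.any(decays < 0):
            raise ValueError("decay rates must be nonnegative")
        gain = gain * np.exp(-distance_matrix * decays[None, :])
    return gain.sum(axis=1)


def _mse(pred_per_movement: np.ndarray, values: np.ndarray) -> float:
    # values: (n_subjects, n_movements); every subject shares the prediction
    resid = values - pred_per_movement[None, :]
    return float(np.mean(resid**2))


def fit_mixture(
    dataset: GeneralizationDataset,
    spec: MixtureSpec,
    n_restarts: int = 10,
    seed: int = 0,
) -> FitResult:
    """Constrained least-squares fit of a mixture (± decay) model.

    Minimizes the MSE over all concatenated subject x movement points,
    with weights on the simplex of the included components and nonnegative
    decay rates.  SLSQP from ``n_restarts`` seeded random starting points
    (Dirichlet weights, log-uniform rates); the best converged solution
    wins.
    """
    values = dataset.values.to_numpy()
    n = values.size
    p = len(spec.components)
    if p == 0:
        return FitResult(spec, {}, {}, mse=float(np.mean(values**2)), n=n, seed=seed)
    n_free = (p - 1) + (p if spec.decay else 0)
    if len(dataset.movement_ids) < max(n_free, 1):
        raise ValueError("dataset covers fewer movements than free parameters")

    X = dataset.component_matrix(spec.components)
    D = dataset.distance_matrix(spec.components) if spec.decay else None

    def unpack(z):
        w = z[:p]
        d = z[p:] if spec.decay else None
        return w, d

    def objective(z):
        w, d = unpack(z)
        pred = predict_mixture(spec, np.abs(w), d, X, D)
        return _mse(pred, values)

    if p == 1 and not spec.decay:
        w = np.ones(1)
        pred = predict_mixture(spec, w, None, X, None)
        return FitResult(
            spec,
            {spec.components[0]: 1.0},
            {},
            mse=_mse(pred, values),
            n=n,
            seed=seed,
        )

    rng = np.random.default_rng(seed)
    bounds = [(0.0, 1.0)] * p
    if spec.decay:
        bounds += [DECAY_BOUNDS] * p
    constraints = [{"type": "eq", "fun": lambda z: np.sum(z[:p]) - 1.0}]

    best = None
    any_converged = False
    for r in range(n_restarts):
        if r == 0:
            w0 = np.full(p, 1.0 / p)
            d0 = np.ones(p)
        else:
            w0 = rng.dirichlet(np.ones(p))
            d0 = 10.0 ** rng.uniform(*DECAY_LOG_RANGE, size=p)
        z0 = np.concatenate([w0, d0]) if spec.decay else w0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(
                objective,
                z0,
                method="SLSQP",
                bounds=bounds,
                constraints=constraints,
                options={"maxiter": 500, "ftol": 1e-12},
            )
        if best is None or res.fun < best.fun - 1e-15:
            best = res
            any_converged = res.success
        elif res.success and abs(res.fun - best.fun) <= 1e-12:
            any_converged = True

    w, d = unpack(best.x)
    w = np.clip(w, 0.0, None)
    w = w / w.sum()
    weights = dict(zip(spec.components, map(float, w)))
    decays = (
        dict(zip(spec.components, map(float, np.clip(d, 0.0, None)))) if spec.decay else {}
    )
    pred = predict_mixture(spec, w, d if spec.decay else None, X, D)
    return FitResult(
        spec,
        weights,
        decays,
        mse=_mse(pred, values),
        n=n,
        converged=bool(any_converged),
        seed=seed,
    )


def compute_bic(mse: float, dof: int, n: int) -> float:
    """BIC = n·ln(MSE) + dof·ln(n); lower is better."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if mse < 0:
        raise ValueError("MSE must be nonnegative")
    if mse == 0:
        warnings.warn("MSE is exactly zero; BIC is -inf", stacklevel=2)
        return -np.inf
    return float(n * np.log(mse) + dof * np.log(n))


def compare_models(
    results: list[FitResult], reference: FitResult | None = None
) -> pd.DataFrame:
    """Rank fits by BIC with ΔBIC, approximate log Bayes factors, and the
    improvement over a no-generalization reference (prediction ≡ 0).

    All results must come from the same dataset (equal n).  Ties on BIC
    break toward fewer dof, then lexicographic component order.
    """
    if not results:
        raise ValueError("no results to compare")
    ns = {r.n for r in results} | ({reference.n} if reference is not None else set())
    if len(ns) != 1:
        raise ValueError(f"results fit on different n: {sorted(ns)}")
    rows = sorted(results, key=lambda r: (r.bic, r.dof, r.spec.components))
    best_bic = rows[0].bic
    table = pd.DataFrame(
        {
            "model": [r.spec.label for r in rows],
            "dof": [r.dof for r in rows],
            "mse": [r.mse for r in rows],
            "bic": [r.bic for r in rows],
        }
    )
    table["delta_bic"] = table["bic"] - best_bic
    table["log_bayes_factor"] = 0.5 * table["delta_bic"]
    if reference is not None:
        table["bic_improvement"] = reference.bic - table["bic"]
    return table


def loocv(
    dataset: GeneralizationDataset,
    spec: MixtureSpec,
    n_restarts: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Leave-one-subject-out variance explained.

    For each subject the model is fit to the across-remaining-subjects
    average per movement, and the fit predicts the held-out subject:
    VE = 1 − SSE/SST (negative when the model predicts worse than the
    subject's own mean).
    """
    if dataset.n_subjects < 3:
        raise ValueError("leave-one-out needs at least 3 subjects")
    values = dataset.values
    out = np.empty(dataset.n_subjects)
    for i, subject in enumerate(values.index):
        rest = values.drop(index=subject)
        avg = pd.DataFrame(
            rest.to_numpy().mean(axis=0, keepdims=True), columns=values.columns
        )
        fit = fit_mixture(
            GeneralizationDataset(avg, dataset.predictions, dataset.distances),
            spec,
            n_restarts=n_restarts,
            seed=seed + i,
        )
        X = dataset.component_matrix(spec.components) if spec.components else None
        D = dataset.distance_matrix(spec.components) if spec.decay else None
        if spec.components:
            w = np.array([fit.weights[c] for c in spec.components])
            d = np.array([fit.decays[c] for c in spec.components]) if spec.decay else None
            pred = predict_mixture(spec, w, d, X, D)
        else:
            pred = np.zeros(len(values.columns))
        y = values.loc[subject].to_numpy()
        sst = float(np.sum((y - y.mean()) ** 2))
        if sst == 0:
            warnings.warn(f"subject {subject!r} has constant data; VE undefined", stacklevel=2)
            out[i] = np.nan
            continue
        sse = float(np.sum((y - pred) ** 2))
        out[i] = 1.0 - sse / sst
    return out
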