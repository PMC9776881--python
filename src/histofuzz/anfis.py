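"""First-order Sugeno ANFIS classifier with HBO-tuned membership functions.

The model is the classical five-layer adaptive neuro-fuzzy inference
system: (1) Gaussian membership functions fuzzify each input, (2) rules
take the product of their antecedent degrees as firing strength, (3)
strengths are normalized to sum to one, (4) each rule contributes a linear
(first-order Sugeno) consequent ``f = p*x1 + q*x2 + ... + r`` weighted by
its normalized strength, and (5) the weighted contributions are summed.
Rules form a full grid partition: with ``m`` membership functions per input
and ``d`` inputs there are ``m^d`` rules.

Multi-class handling: one consequent coefficient set per class (parallel
Sugeno outputs sharing the antecedents); the predicted class is the argmax
of the class scores.

Training is hybrid: the antecedent parameters (centers and widths) are
tuned by the honey badger optimizer, while for each candidate antecedent
the consequent coefficients are solved in closed form by least squares.
The classification fitness is the mean misclassification rate over
stratified cross-validation folds, so the tuner optimizes generalization
rather than training fit.  High-dimensional CNN features are first reduced
to a small number of ANFIS inputs by a standardized PCA projection, since
the grid partition grows exponentially with input count.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import warnings

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from histofuzz import hbo

__all__ = [
    "MembershipFunction",
    "FuzzyRule",
    "ANFISModel",
    "ANFISConfig",
    "FeatureProjector",
    "fuzzify",
    "rule_firing_strengths",
    "normalize_firings",
    "anfis_forward",
    "fit_consequents_lse",
    "mf_fitness",
    "regression_fitness",
    "tune_with_hbo",
    "tune_regression_with_hbo",
]

#: below this total firing mass, normalization falls back to uniform
_ZERO_FIRING = 1e-300


@dataclasses.dataclass(frozen=True)
class MembershipFunction:
    """Gaussian fuzzy set ``mu(x) = exp(-(x - c)^2 / (2 sigma^2))``."""

    center: float
    width: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("membership function width must be > 0")

    def __call__(self, x) -> np.ndarray:
        return np.exp(-((np.asarray(x, dtype=float) - self.center) ** 2)
                      / (2.0 * self.width**2))


def fuzzify(x: float, mf: MembershipFunction) -> float:
    """Membership degree of ``x`` in ``mf``; 1 at the center, in (0, 1]."""
    return float(mf(x))


@dataclasses.dataclass(frozen=True)
class FuzzyRule:
    """Antecedent MF index per input plus per-class linear consequents."""

    antecedent: tuple[int, ...]
    consequents: np.ndarray  # (n_classes, n_inputs + 1), intercept last

    def __post_init__(self) -> None:
        if self.consequents.shape[1] != len(self.antecedent) + 1:
            raise ValueError("consequent length must be n_inputs + 1")


@dataclasses.dataclass
class ANFISModel:
    """Grid-partition Sugeno model: MF grid + per-class consequent matrices.

    ``centers`` and ``widths`` have shape ``(n_inputs, mfs_per_input)``;
    ``consequents`` has shape ``(n_classes, n_rules, n_inputs + 1)`` with
    the intercept in the last column.
    """

    centers: np.ndarray
    widths: np.ndarray
    consequents: np.ndarray
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.consequents = np.asarray(self.consequents, dtype=float)
        if self.centers.shape != self.widths.shape:
            raise ValueError("centers and widths must have equal shapes")
        if np.any(self.widths <= 0):
            raise ValueError("all widths must be > 0")
        d, m = self.centers.shape
        if self.consequents.shape[1:] != (m**d, d + 1):
            raise ValueError(
                f"consequents must have shape (n_classes, {m**d}, {d + 1}), "
                f"got {self.consequents.shape}"
            )

    @property
    def n_inputs(self) -> int:
        return self.centers.shape[0]

    @property
    def mfs_per_input(self) -> int:
        return self.centers.shape[1]

    @property
    def n_classes(self) -> int:
        return self.consequents.shape[0]

    @property
    def rule_index(self) -> np.ndarray:
        """(n_rules, n_inputs) MF index per input, row-major grid order."""
        return np.array(
            list(itertools.product(range(self.mfs_per_input), repeat=self.n_inputs)),
            dtype=int,
        )

    def rules(self) -> list[FuzzyRule]:
        return [
            FuzzyRule(tuple(idx), self.consequents[:, r, :])
            for r, idx in enumerate(self.rule_index)
        ]

    def membership_functions(self) -> list[list[MembershipFunction]]:
        labels = "ABCDEFGH"
        return [
            [
                MembershipFunction(self.centers[i, j], self.widths[i, j],
                                   f"{labels[i % len(labels)]}{j + 1}")
                for j in range(self.mfs_per_input)
            ]
            for i in range(self.n_inputs)
        ]


def _memberships(X: np.ndarray, centers: np.ndarray, widths: np.ndarray) -> np.ndarray:
    """(N, d, m) membership degrees."""
    diff = X[:, :, None] - centers[None, :, :]
    return np.exp(-(diff**2) / (2.0 * widths[None, :, :] ** 2))


def _strengths(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    mem = _memberships(X, model.centers, model.widths)  # (N, d, m)
    rules = model.rule_index
    out = np.ones((X.shape[0], rules.shape[0]))
    for i in range(model.n_inputs):
        out *= mem[:, i, rules[:, i]]
    return out


def rule_firing_strengths(inputs: np.ndarray, model: ANFISModel) -> np.ndarray:
    """Layer-2 output: product of antecedent degrees for every rule."""
    x = np.asarray(inputs, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(f"expected {model.n_inputs} inputs, got shape {x.shape}")
    return _strengths(x[None], model)[0]


def normalize_firings(strengths: np.ndarray) -> np.ndarray:
    """Layer-3 output: strengths scaled to sum to one.

    If the total mass underflows (an input far outside every fuzzy set),
    returns the uniform vector 1/R instead of NaN.
    """
    s = np.asarray(strengths, dtype=float)
    total = s.sum(axis=-1, keepdims=True)
    uniform = np.full_like(s, 1.0 / s.shape[-1])
    with np.errstate(invalid="ignore"):
        out = np.where(total < _ZERO_FIRING, uniform, s / np.where(total == 0, 1, total))
    return out


def _design_matrix(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    """(N, R*(d+1)) LSE design: normalized strength x augmented input."""
    norm = normalize_firings(_strengths(X, model))  # (N, R)
    aug = np.concatenate([X, np.ones((X.shape[0], 1))], axis=1)  # (N, d+1)
    return (norm[:, :, None] * aug[:, None, :]).reshape(X.shape[0], -1)


def anfis_forward_batch(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    """(N, n_classes) Sugeno outputs for a batch of inputs."""
    X = np.asarray(X, dtype=float)
    design = _design_matrix(X, model)
    coef = model.consequents.reshape(model.n_classes, -1)  # (C, R*(d+1))
    return design @ coef.T


def anfis_forward(inputs: np.ndarray, model: ANFISModel) -> tuple[np.ndarray, int]:
    """Per-class scores and the argmax class for one input vector."""
    x = np.asarray(inputs, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(f"expected {model.n_inputs} inputs, got shape {x.shape}")
    scores = anfis_forward_batch(x[None], model)[0]
    return scores, int(np.argmax(scores))


def predict(X: np.ndarray, model: ANFISModel) -> np.ndarray:
    return np.argmax(anfis_forward_batch(X, model), axis=1)


def fit_consequents_lse(
    model: ANFISModel, X: np.ndarray, targets: np.ndarray
) -> tuple[ANFISModel, float]:
    """Solve the consequent coefficients by least squares, antecedents fixed.

    ``targets`` is (N, n_outputs) — one-hot labels for classification or
    continuous Sugeno outputs for regression.  Rank-deficient designs fall
    back to the minimum-norm solution with a warning.  Returns the updated
    model and the residual RMS.
    """
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if targets.ndim == 1:
        targets = targets[:, None]
    design = _design_matrix(X, model)
    if X.shape[0] < design.shape[1]:
        warnings.warn(
            f"{X.shape[0]} rows for {design.shape[1]} consequent coefficients; "
            "solution is minimum-norm", stacklevel=2)
    coef, _, rank, _ = np.linalg.lstsq(design, targets, rcond=None)
    if rank < design.shape[1]:
        warnings.warn("rank-deficient consequent design; using minimum-norm solution",
                      stacklevel=2)
    n_out = targets.shape[1]
    consequents = coef.T.reshape(n_out, -1, model.n_inputs + 1)
    fitted = dataclasses.replace(model, consequents=consequents)
    residual = float(np.sqrt(np.mean((design @ coef - targets) ** 2)))
    return fitted, residual


# ---------------------------------------------------------------------------
# antecedent parameter vector <-> model


def decode_mf_parameters(
    theta: np.ndarray, n_inputs: int, mfs_per_input: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split a flat parameter vector into centers and widths.

    Layout: all ``d*m`` centers first, then all ``d*m`` widths (row-major
    over inputs).
    """
    theta = np.asarray(theta, dtype=float)
    k = n_inputs * mfs_per_input
    if theta.size != 2 * k:
        raise ValueError(f"expected {2 * k} parameters, got {theta.size}")
    centers = theta[:k].reshape(n_inputs, mfs_per_input)
    widths = theta[k:].reshape(n_inputs, mfs_per_input)
    return centers, widths


def _blank_model(centers: np.ndarray, widths: np.ndarray, n_outputs: int) -> ANFISModel:
    d, m = centers.shape
    return ANFISModel(centers, widths,
                      np.zeros((n_outputs, m**d, d + 1)))


def mf_fitness(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    n_classes: int,
    mfs_per_input: int = 2,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Cross-validated misclassification rate of an antecedent candidate.

    Decodes ``theta`` into MF centers/widths, fits the consequents by LSE
    on each training fold and scores the held-out fold; returns the mean
    error over stratified folds.  Non-positive widths are penalized with
    the worst fitness 1.0 instead of raising, so the optimizer can wander
    freely.  Deterministic given ``seed`` (fold assignment).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    centers, widths = decode_mf_parameters(theta, X.shape[1], mfs_per_input)
    if np.any(widths <= 0):
        return 1.0
    onehot = np.eye(n_classes)[y]
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for train_idx, val_idx in skf.split(X, y):
            model = _blank_model(centers, widths, n_classes)
            model, _ = fit_consequents_lse(model, X[train_idx], onehot[train_idx])
            pred = predict(X[val_idx], model)
            errors.append(np.mean(pred != y[val_idx]))
    return float(np.mean(errors))


def regression_fitness(
    theta: np.ndarray,
    X: np.ndarray,
    targets: np.ndarray,
    mfs_per_input: int = 2,
) -> float:
    """Training RMSE of the LSE-fit Sugeno model for an antecedent candidate."""
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    centers, widths = decode_mf_parameters(theta, X.shape[1], mfs_per_input)
    if np.any(widths <= 0):
        return float(np.sqrt(np.mean(targets**2)) + 1.0)
    model = _blank_model(centers, widths, 1 if targets.ndim == 1 else targets.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, residual = fit_consequents_lse(model, X, targets)
    return residual


# ---------------------------------------------------------------------------
# HBO tuning


@dataclasses.dataclass(frozen=True)
class ANFISConfig:
    n_inputs: int = 4
    mfs_per_input: int = 2
    folds: int = 5
    seed: int = 0
    width_box: tuple[float, float] = (0.25, 1.5)  # multiples of feature std


def mf_search_space(X: np.ndarray, config: ANFISConfig) -> hbo.SearchSpace:
    """Box for the MF parameters: centers within each input's data range,
    widths within ``width_box`` multiples of each input's standard deviation."""
    X = np.asarray(X, dtype=float)
    lo, hi = X.min(axis=0), X.max(axis=0)
    span = np.maximum(hi - lo, 1e-6)
    std = np.maximum(X.std(axis=0), 1e-6)
    m = config.mfs_per_input
    center_lo = np.repeat(lo, m)
    center_hi = np.repeat(hi, m)
    # degenerate (constant) inputs still need a nonempty box
    center_hi = np.maximum(center_hi, center_lo + 1e-6 * np.repeat(span, m))
    width_lo = np.repeat(config.width_box[0] * std, m)
    width_hi = np.repeat(config.width_box[1] * std, m)
    return hbo.SearchSpace(
        np.concatenate([center_lo, width_lo]),
        np.concatenate([center_hi, width_hi]),
    )


def tune_with_hbo(
    X: np.ndarray,
    y: np.ndarray,
    anfis_config: ANFISConfig | None = None,
    hbo_config: hbo.HBOConfig | None = None,
    class_names: tuple[str, ...] = (),
) -> tuple[ANFISModel, np.ndarray]:
    """Tune MF centers/widths by HBO, then refit consequents on all data.

    Returns the tuned model and the (non-increasing) fitness history.
    """
    anfis_config = anfis_config or ANFISConfig()
    hbo_config = hbo_config or hbo.HBOConfig(population_size=20, max_iterations=100)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n_classes = int(y.max()) + 1
    space = mf_search_space(X, anfis_config)

    def objective(theta: np.ndarray) -> float:
        return mf_fitness(theta, X, y, n_classes, anfis_config.mfs_per_input,
                          anfis_config.folds, anfis_config.seed)

    result = hbo.optimize(objective, space, hbo_config)
    centers, widths = decode_mf_parameters(
        result.best_position, X.shape[1], anfis_config.mfs_per_input)
    model = _blank_model(centers, widths, n_classes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, _ = fit_consequents_lse(model, X, np.eye(n_classes)[y])
    model.class_names = tuple(class_names)
    return model, result.history


def tune_regression_with_hbo(
    X: np.ndarray,
    targets: np.ndarray,
    anfis_config: ANFISConfig | None = None,
    hbo_config: hbo.HBOConfig | None = None,
) -> tuple[ANFISModel, np.ndarray]:
    """Regression variant: HBO minimizes the LSE residual RMSE."""
    anfis_config = anfis_config or ANFISConfig(n_inputs=2)
    hbo_config = hbo_config or hbo.HBOConfig(population_size=20, max_iterations=100)
    X = np.asarray(X, dtype=float)
    targets = np.asarray(targets, dtype=float)
    space = mf_search_space(X, anfis_config)

    def objective(theta: np.ndarray) -> float:
        return regression_fitness(theta, X, targets, anfis_config.mfs_per_input)

    result = hbo.optimize(objective, space, hbo_config)
    centers, widths = decode_mf_parameters(
        result.best_position, X.shape[1], anfis_config.mfs_per_input)
    n_out = 1 if targets.ndim == 1 else targets.shape[1]
    model = _blank_model(centers, widths, n_out)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model, _ = fit_consequents_lse(model, X, targets)
    return model, result.history


# ---------------------------------------------------------------------------
# feature projection and serialization


@dataclasses.dataclass
class FeatureProjector:
    """Standardized PCA map reducing CNN features to ANFIS inputs."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (n_inputs, n_features)

    @classmethod
    def fit(cls, features: np.ndarray, n_inputs: int = 4) -> "FeatureProjector":
        feats = np.asarray(features, dtype=float)
        mean = feats.mean(axis=0)
        scale = np.maximum(feats.std(axis=0), 1e-8)
        standardized = (feats - mean) / scale
        n_comp = min(n_inputs, feats.shape[1], max(feats.shape[0] - 1, 1))
        pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
        pca.fit(standardized)
        components = pca.components_
        # sign convention: largest-magnitude loading positive, for determinism
        flip = np.sign(components[np.arange(n_comp),
                                  np.abs(components).argmax(axis=1)])
        return cls(mean=mean, scale=scale, components=components * flip[:, None])

    def transform(self, features: np.ndarray) -> np.ndarray:
        feats = np.asarray(features, dtype=float)
        return ((feats - self.mean) / self.scale) @ self.components.T


def save_model(model: ANFISModel, path, projector: FeatureProjector | None = None,
               metadata: dict | None = None) -> None:
    """Serialize the model (and optional projector) as JSON."""
    blob = {
        "centers": model.centers.tolist(),
        "widths": model.widths.tolist(),
        "consequents": model.consequents.tolist(),
        "class_names": list(model.class_names),
        "metadata": metadata or {},
    }
    if projector is not None:
        blob["projector"] = {
            "mean": projector.mean.tolist(),
            "scale": projector.scale.tolist(),
            "components": projector.components.tolist(),
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(blob, fh, indent=1, sort_keys=True)


def load_model(path) -> tuple[ANFISModel, FeatureProjector | None]:
    with open(path, encoding="utf-8") as fh:
        blob = json.load(fh)
    model = ANFISModel(
        np.array(blob["centers"]), np.array(blob["widths"]),
        np.array(blob["consequents"]), tuple(blob.get("class_names", ())))
    projector = None
    if "projector" in blob:
        p = blob["projector"]
        projector = FeatureProjector(np.array(p["mean"]), np.array(p["scale"]),
                                     np.array(p["components"]))
    return model, projector
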