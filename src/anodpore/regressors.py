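"""Pore-diameter surrogates: OLS multiple linear regression and a
64-32-16 feed-forward network, with the evaluation metrics and 5-fold
cross-validation comparison used to judge them.

The network is trained with scikit-learn's MLPRegressor (Adam, ReLU,
mini-batches, early stopping on an internal 15% validation split); the
fitted weights are extracted into a self-contained :class:`NetworkModel`
whose forward pass is implemented here, so saved models need no estimator
object. Under one-hot encoding the MLR design uses reference-cell coding
(the sulphuric-acid indicator is dropped and an intercept added) to keep
the design full rank; the network consumes all indicator columns.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset_io import (REFERENCE_LEVEL, ColumnInfo, FeatureMatrix, encode)

__all__ = [
    "NetworkConfig", "LinearModel", "NetworkModel", "Metrics", "CVReport",
    "fit_mlr", "fit_ann", "predict", "evaluate", "kfold_cv", "cv_aggregate",
    "save_model", "load_model",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Fixed network hyperparameters (no search): funnel 64-32-16 ReLU MLP
    trained by Adam with early stopping."""

    hidden_sizes: tuple = (64, 32, 16)
    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    batch_size: int = 32
    max_epochs: int = 1000
    early_stop_patience: int = 50
    validation_fraction: float = 0.15
    l2_penalty: float = 0.0001
    seed: int = 42

    def __post_init__(self):
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        for name in ("learning_rate", "batch_size", "max_epochs",
                     "early_stop_patience", "l2_penalty"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LinearModel:
    """OLS fit: prediction = intercept + X[design columns] @ coefficients."""

    intercept: float
    coefficients: dict[str, float]
    stderr: dict[str, float]
    intercept_stderr: float
    column_map: list[ColumnInfo]
    mode: str
    reference_level: str | None
    n: int

    @property
    def design_columns(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class NetworkModel:
    """Fitted MLP: weight matrices (inputs x units orientation per layer),
    biases, training history and the config used."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: NetworkConfig
    column_map: list[ColumnInfo]
    n_epochs: int
    loss_curve: list[float]

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = np.asarray(X, dtype=float)
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = np.maximum(a @ W + b, 0.0)  # ReLU; derivative at 0 taken as 0
        return (a @ self.weights[-1] + self.biases[-1]).ravel()


@dataclass(frozen=True)
class Metrics:
    r2: float
    rmse: float
    mae: float
    n: int


@dataclass(frozen=True)
class CVReport:
    fold_scores: list[float]
    fold_sizes: list[int]
    mean: float
    sd: float
    seed: int
    model: str

    @property
    def k(self) -> int:
        return len(self.fold_scores)


def _mlr_design(fm: FeatureMatrix):
    """Design columns for OLS: drop the reference indicator under one-hot."""
    keep = []
    for i, c in enumerate(fm.column_map):
        if fm.mode == "onehot" and c.level == REFERENCE_LEVEL:
            continue
        keep.append(i)
    names = [fm.column_map[i].name for i in keep]
    X = fm.X[:, keep]
    A = np.column_stack([np.ones(len(X)), X])
    return A, names


def fit_mlr(fm: FeatureMatrix) -> LinearModel:
    """Ordinary least squares via a rank-checked lstsq solve."""
    A, names = _mlr_design(fm)
    n, p = A.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than parameters ({p})")
    rank = np.linalg.matrix_rank(A)
    if rank < p:
        # name the columns implicated in the collinearity
        bad = [names[j - 1] for j in range(1, p)
               if np.linalg.matrix_rank(np.delete(A, j, axis=1)) == rank]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(A, fm.y, rcond=None)
    resid = fm.y - A @ beta
    s2 = float(resid @ resid) / (n - p)
    cov = s2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    return LinearModel(
        intercept=float(beta[0]),
        coefficients=dict(zip(names, map(float, beta[1:]))),
        stderr=dict(zip(names, map(float, se[1:]))),
        intercept_stderr=float(se[0]),
        column_map=list(fm.column_map),
        mode=fm.mode,
        reference_level=REFERENCE_LEVEL if fm.mode == "onehot" else None,
        n=n,
    )


def fit_ann(fm: FeatureMatrix, config: NetworkConfig = NetworkConfig()) -> NetworkModel:
    """Train the MLP; seeded init and shuffling make runs reproducible."""
    from sklearn.neural_network import MLPRegressor

    n = len(fm.y)
    if n < config.batch_size:
        warnings.warn(f"n={n} below batch_size={config.batch_size}; "
                      "batches are clipped to the sample count", stacklevel=2)
    est = MLPRegressor(
        hidden_layer_sizes=config.hidden_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=config.learning_rate,
        beta_1=config.beta1,
        beta_2=config.beta2,
        epsilon=config.epsilon,
        batch_size=min(config.batch_size, n),
        max_iter=config.max_epochs,
        early_stopping=True,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.early_stop_patience,
        alpha=config.l2_penalty,
        random_state=config.seed,
        shuffle=True,
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(fm.X, fm.y)
    if not np.isfinite(est.loss_):
        raise ArithmeticError(f"non-finite training loss at epoch {est.n_iter_}")
    return NetworkModel(
        weights=[np.array(W) for W in est.coefs_],
        biases=[np.array(b) for b in est.intercepts_],
        config=config,
        column_map=list(fm.column_map),
        n_epochs=int(est.n_iter_),
        loss_curve=[float(v) for v in est.loss_curve_],
    )


def predict(model, fm: FeatureMatrix) -> np.ndarray:
    """Predicted pore diameters (nm); unclamped, may exceed the data range."""
    if [c.name for c in model.column_map] != fm.column_names:
        raise ValueError("feature-matrix columns do not match the model's")
    if isinstance(model, LinearModel):
        A, names = _mlr_design(fm)
        if names != model.design_columns:
            raise ValueError("design columns do not match the fitted model")
        beta = np.array([model.intercept] + [model.coefficients[c] for c in names])
        return A @ beta
    if isinstance(model, NetworkModel):
        return model.forward(fm.X)
    raise TypeError(f"unsupported model type {type(model).__name__}")


def evaluate(y, y_pred) -> Metrics:
    """R² (about the mean of y), RMSE and MAE."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError("y and y_pred must have equal length")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    resid = y - y_pred
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("zero-variance y; R² undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    return Metrics(
        r2=r2,
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        mae=float(np.mean(np.abs(resid))),
        n=len(y),
    )


def cv_aggregate(fold_scores) -> tuple[float, float]:
    """Mean and population SD (divisor k) of per-fold scores."""
    scores = np.asarray(fold_scores, dtype=float)
    return float(scores.mean()), float(np.std(scores))


def kfold_cv(model_spec, fm: FeatureMatrix, k: int = 5, seed: int = 0) -> CVReport:
    """Seeded, unstratified k-fold CV with the scaler refit inside each fold.

    model_spec is ``"mlr"`` or a :class:`NetworkConfig`. Folds are near-equal
    (sizes differ by at most 1); each fold's held-out R² is reported along
    with their mean and population SD.
    """
    n = len(fm.y)
    if k < 2 or n < k:
        raise ValueError("need k >= 2 and n >= k")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
    if min(sizes) < 2:
        raise ValueError("a fold would hold fewer than 2 samples")
    raw = fm.raw_frame()
    scores, start = [], 0
    for size in sizes:
        hold = order[start:start + size]
        start += size
        train = raw.drop(raw.index[hold])
        test = raw.iloc[hold]
        train_fm, test_fm = encode(train, test, mode=fm.mode)
        if model_spec == "mlr":
            model = fit_mlr(train_fm)
            label = "mlr"
        elif isinstance(model_spec, NetworkConfig):
            model = fit_ann(train_fm, model_spec)
            label = "ann"
        else:
            raise ValueError(f"unknown model spec {model_spec!r}")
        scores.append(evaluate(test_fm.y, predict(model, test_fm)).r2)
    mean, sd = cv_aggregate(scores)
    return CVReport(fold_scores=scores, fold_sizes=sizes, mean=mean, sd=sd,
                    seed=seed, model=label)


def save_model(model, path) -> None:
    """Serialize a fitted model to portable JSON (config + parameters)."""
    common = {"column_map": [asdict(c) for c in model.column_map]}
    if isinstance(model, LinearModel):
        payload = {
            "kind": "linear",
            "intercept": model.intercept,
            "coefficients": model.coefficients,
            "stderr": model.stderr,
            "intercept_stderr": model.intercept_stderr,
            "mode": model.mode,
            "reference_level": model.reference_level,
            "n": model.n,
            **common,
        }
    elif isinstance(model, NetworkModel):
        payload = {
            "kind": "network",
            "weights": [W.tolist() for W in model.weights],
            "biases": [b.tolist() for b in model.biases],
            "config": asdict(model.config),
            "n_epochs": model.n_epochs,
            "loss_curve": model.loss_curve,
            **common,
        }
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    column_map = [ColumnInfo(**c) for c in payload["column_map"]]
    if payload["kind"] == "linear":
        return LinearModel(
            intercept=payload["intercept"],
            coefficients=payload["coefficients"],
            stderr=payload["stderr"],
            intercept_stderr=payload["intercept_stderr"],
            column_map=column_map,
            mode=payload["mode"],
            reference_level=payload["reference_level"],
            n=payload["n"],
        )
    cfg = payload["config"]
    cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
    return NetworkModel(
        weights=[np.array(W) for W in payload["weights"]],
        biases=[np.array(b) for b in payload["biases"]],
        config=NetworkConfig(**cfg),
        column_map=column_map,
        n_epochs=payload["n_epochs"],
        loss_curve=payload["loss_curve"],
    )
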