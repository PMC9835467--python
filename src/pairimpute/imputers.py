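"""Pluggable per-gene imputation learners.

Every strategy in this package imputes one missing gene at a time by
regressing the gene on a pool of shared feature genes in the studies that
observe it.  The default learner is the lasso, either with linear terms or
with a per-feature polynomial expansion; random-forest, support-vector and
multiple-imputation learners plug into the same fit/predict contract for
sensitivity analyses.

Features and target are standardized to zero mean / unit variance on the
training data inside the learner (penalized regression is scale sensitive);
predictions are returned on the original target scale.  The penalty weight
is chosen by seeded k-fold cross-validation by default and can be fixed for
exact tests; a fixed penalty of 0 gives ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, LassoCV, BayesianRidge
from sklearn.model_selection import KFold
from sklearn.svm import SVR
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

__all__ = [
    "LearnerSpec",
    "FittedImputer",
    "expand_polynomial",
    "fit_imputer",
    "predict_imputer",
    "LEARNER_FAMILIES",
]

LEARNER_FAMILIES = (
    "lasso_linear",
    "lasso_polynomial",
    "random_forest",
    "svm",
    "multiple_imputation",
)


@dataclass(frozen=True)
class LearnerSpec:
    """Declarative description of an imputation learner.

    Parameters
    ----------
    family
        One of :data:`LEARNER_FAMILIES`.
    degree
        Per-feature polynomial degree; only used by ``lasso_polynomial``
        (pure powers x, x^2, ..., x^degree — no interaction terms).
    lambda_policy
        ``"cv"`` selects the lasso penalty by k-fold cross-validation
        minimizing mean squared error; ``"fixed"`` uses ``lambda_value``.
    lambda_value
        Penalty weight when ``lambda_policy="fixed"``; 0 means ordinary
        least squares.
    cv_folds
        Number of cross-validation folds (default 10).
    seed
        Governs the CV fold split and any learner-internal randomness;
        identical seeds give bit-identical fits.
    n_alphas
        Resolution of the automatically generated penalty grid searched by
        cross-validation (50 log-spaced values by default).
    """

    family: str = "lasso_linear"
    degree: int = 2
    lambda_policy: str = "cv"
    lambda_value: Optional[float] = None
    cv_folds: int = 10
    seed: int = 0
    n_alphas: int = 50

    def __post_init__(self) -> None:
        if self.family not in LEARNER_FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")
        if self.family == "lasso_polynomial" and self.degree < 2:
            raise ValueError("degree must be >= 2 for lasso_polynomial")
        if self.lambda_policy not in ("cv", "fixed"):
            raise ValueError(f"lambda_policy must be 'cv' or 'fixed', got {self.lambda_policy!r}")
        if self.lambda_policy == "fixed":
            if self.lambda_value is None or self.lambda_value < 0:
                raise ValueError("lambda_policy='fixed' requires lambda_value >= 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "LearnerSpec":
        return cls(**d)


@dataclass
class FittedImputer:
    """A fitted per-gene model; predicts exactly ``feature_genes`` in order."""

    target_gene: str
    feature_genes: tuple[str, ...]
    spec: LearnerSpec
    model_state: dict
    training_rows: int


def expand_polynomial(X: np.ndarray, degree: int) -> np.ndarray:
    """Per-feature power expansion: for each column x, emit x, x^2, ..., x^degree.

    No cross-feature interaction terms.  Output column order is input column
    order, ascending power within a column.
    """
    if degree < 2:
        raise ValueError("degree must be >= 2")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be 2-D with at least one column")
    blocks = [X[:, j:j + 1] ** p for j in range(X.shape[1]) for p in range(1, degree + 1)]
    return np.hstack(blocks)


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)  # constant columns map to all-zeros
    return (X - mu) / sd_safe, mu, sd_safe


def _design(X: np.ndarray, spec: LearnerSpec) -> np.ndarray:
    if spec.family == "lasso_polynomial":
        return expand_polynomial(X, spec.degree)
    return X


def fit_imputer(train: pd.DataFrame, target: np.ndarray, spec: LearnerSpec,
                target_gene: str = "") -> FittedImputer:
    """Fit one per-gene imputation model.

    ``train`` holds the feature genes (columns) for the samples observing
    the target gene; ``target`` is that gene's expression vector.  Fits are
    deterministic given ``spec.seed``.

    Degenerate inputs: a zero-variance target, or a single training row,
    falls back to an intercept-only model predicting the training mean.
    """
    if not isinstance(train, pd.DataFrame):
        raise TypeError("train must be a DataFrame with gene-ID columns")
    y = np.asarray(target, dtype=float)
    if y.ndim != 1 or len(y) != train.shape[0]:
        raise ValueError("target length must equal number of training rows")
    feature_genes = tuple(str(c) for c in train.columns)
    n = len(y)

    y_mu, y_sd = float(y.mean()), float(y.std())
    intercept_only = n < 2 or y_sd == 0.0
    if intercept_only:
        if y_sd == 0.0 and n >= 2 and spec.lambda_policy == "cv":
            warnings.warn(
                f"zero-variance target {target_gene or '<gene>'}: intercept-only fallback",
                stacklevel=2,
            )
        state = {"kind": "intercept", "y_mean": y_mu}
        return FittedImputer(target_gene, feature_genes, spec, state, n)

    X = _design(train.to_numpy(dtype=float), spec)
    Xs, x_mu, x_sd = _standardize_fit(X)
    ys = (y - y_mu) / y_sd

    if spec.family in ("lasso_linear", "lasso_polynomial"):
        coef = _fit_lasso_coef(Xs, ys, spec, n)
        state = {"kind": "linear", "coef": coef, "x_mean": x_mu, "x_scale": x_sd,
                 "y_mean": y_mu, "y_scale": y_sd}
    elif spec.family == "random_forest":
        model = RandomForestRegressor(n_estimators=100, random_state=spec.seed)
        model.fit(Xs, ys)
        state = {"kind": "sklearn", "model": model, "x_mean": x_mu, "x_scale": x_sd,
                 "y_mean": y_mu, "y_scale": y_sd}
    elif spec.family == "svm":
        model = SVR(kernel="rbf")
        model.fit(Xs, ys)
        state = {"kind": "sklearn", "model": model, "x_mean": x_mu, "x_scale": x_sd,
                 "y_mean": y_mu, "y_scale": y_sd}
    elif spec.family == "multiple_imputation":
        # chained-equations draws: the target is treated as the missing
        # column of [features | target]; m posterior draws are averaged at
        # prediction time.
        state = {"kind": "mice", "train_X": Xs, "train_y": ys,
                 "x_mean": x_mu, "x_scale": x_sd, "y_mean": y_mu, "y_scale": y_sd,
                 "m": 5}
    else:  # pragma: no cover - guarded by LearnerSpec
        raise ValueError(spec.family)
    return FittedImputer(target_gene, feature_genes, spec, state, n)


def _fit_lasso_coef(Xs: np.ndarray, ys: np.ndarray, spec: LearnerSpec, n: int) -> np.ndarray:
    if spec.lambda_policy == "fixed":
        lam = float(spec.lambda_value)
        if lam == 0.0:
            coef, *_ = np.linalg.lstsq(Xs, ys, rcond=None)  # minimum-norm OLS
            return coef
        model = Lasso(alpha=lam, fit_intercept=False, max_iter=50_000)
        model.fit(Xs, ys)
        return model.coef_
    folds = min(spec.cv_folds, n)
    if folds < spec.cv_folds:
        warnings.warn(
            f"only {n} training rows: reducing CV folds from {spec.cv_folds} to {folds}",
            stacklevel=3,
        )
    kf = KFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    model = LassoCV(cv=kf, fit_intercept=False, alphas=spec.n_alphas, max_iter=50_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-fold convergence chatter
        model.fit(Xs, ys)
    return model.coef_


def predict_imputer(model: FittedImputer, newdata: pd.DataFrame) -> np.ndarray:
    """Predict the target gene for new samples.

    ``newdata`` must contain every feature gene of the model; columns are
    aligned by gene ID (order-insensitive input, deterministic alignment).
    """
    state = model.model_state
    if state["kind"] == "intercept":
        return np.full(newdata.shape[0], state["y_mean"], dtype=float)
    missing = [g for g in model.feature_genes if g not in newdata.columns]
    if missing:
        raise KeyError(
            f"newdata lacks feature genes {sorted(missing)} required to impute "
            f"{model.target_gene!r}"
        )
    X = _design(newdata.loc[:, list(model.feature_genes)].to_numpy(dtype=float), model.spec)
    Xs = (X - state["x_mean"]) / state["x_scale"]
    if state["kind"] == "linear":
        ys_hat = Xs @ state["coef"]
    elif state["kind"] == "sklearn":
        ys_hat = state["model"].predict(Xs)
    elif state["kind"] == "mice":
        ys_hat = _predict_mice(state, Xs, model.spec.seed)
    else:  # pragma: no cover
        raise ValueError(state["kind"])
    return state["y_mean"] + state["y_scale"] * ys_hat


def _predict_mice(state: dict, Xs_new: np.ndarray, seed: int) -> np.ndarray:
    n_train = state["train_X"].shape[0]
    full = np.vstack([
        np.column_stack([state["train_X"], state["train_y"]]),
        np.column_stack([Xs_new, np.full(Xs_new.shape[0], np.nan)]),
    ])
    draws = []
    for m in range(state["m"]):
        imp = IterativeImputer(
            estimator=BayesianRidge(), sample_posterior=True,
            random_state=seed + m, max_iter=10,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            completed = imp.fit_transform(full)
        draws.append(completed[n_train:, -1])
    return np.mean(draws, axis=0)
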