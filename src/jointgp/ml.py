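"""Configured machine-learning regressors and classifiers.

Thin, uniformly-configured wrappers over scikit-learn estimators:

* regression — KNN (k = 5, Euclidean, uniform weights), support-vector
  regression with an RBF kernel whose free parameter is
  ``theta = 1 / (p * var(Z))``, random forest (100 trees, depth capped at
  the locus count), and AdaBoost with a decision-tree base and linear loss;
* classification — SVC, random forest, multilayer perceptron and Gaussian
  naive Bayes at library defaults (baseline scores for interval prediction).

``theta`` is always computed from the *training* genotype matrix, with
``var(Z)`` the pooled variance over all matrix entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import AdaBoostRegressor, RandomForestClassifier, RandomForestRegressor
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeRegressor

from .genodata import GenotypeMatrix

__all__ = ["MLConfig", "PredictorModel", "rbf_theta", "fit_predictor", "predict"]

REGRESSORS = ("knn", "svr", "rf", "adaboost")
CLASSIFIERS = ("svc", "rf-c", "mlp", "gnb")


def rbf_theta(Z: np.ndarray, per_column: bool = False) -> float:
    """RBF free parameter theta = 1 / (p * var(Z)).

    ``var(Z)`` is the pooled variance over every entry of the training
    matrix by default; ``per_column=True`` averages per-locus variances
    instead (exposed for sensitivity checks).
    """
    Z = np.asarray(Z, dtype=float)
    p = Z.shape[1]
    var = float(np.mean(np.var(Z, axis=0))) if per_column else float(np.var(Z))
    if var <= 0:
        raise ValueError("genotype matrix has zero variance; theta undefined")
    return 1.0 / (p * var)


@dataclass
class MLConfig:
    """Algorithm choice plus the hyperparameters fixed by the protocol."""

    algorithm: str
    seed: int = 0
    k_neighbors: int = 5
    n_trees: int = 100
    theta_per_column: bool = False

    def __post_init__(self) -> None:
        alg = self.algorithm.lower()
        if alg not in REGRESSORS + CLASSIFIERS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        self.algorithm = alg

    @property
    def task(self) -> str:
        return "regression" if self.algorithm in REGRESSORS else "classification"


@dataclass
class PredictorModel:
    config: MLConfig
    estimator: object
    n_features: int
    theta: float | None = None


def _build(config: MLConfig, Z: np.ndarray):
    alg, seed = config.algorithm, config.seed
    p = Z.shape[1]
    if alg == "knn":
        return KNeighborsRegressor(n_neighbors=config.k_neighbors, weights="uniform", metric="euclidean"), None
    if alg == "svr":
        theta = rbf_theta(Z, config.theta_per_column)
        return SVR(kernel="rbf", gamma=theta), theta
    if alg == "rf":
        # depth capped at the locus count — effectively unbounded for marker data
        return RandomForestRegressor(n_estimators=config.n_trees, max_depth=p, random_state=seed), None
    if alg == "adaboost":
        return AdaBoostRegressor(estimator=DecisionTreeRegressor(random_state=seed), loss="linear", random_state=seed), None
    if alg == "svc":
        return SVC(random_state=seed), None
    if alg == "rf-c":
        return RandomForestClassifier(random_state=seed), None
    if alg == "mlp":
        return MLPClassifier(random_state=seed), None
    if alg == "gnb":
        return GaussianNB(), None
    raise AssertionError(alg)


def fit_predictor(config: MLConfig, Z, target) -> PredictorModel:
    """Fit the configured estimator; deterministic given ``config.seed``."""
    Zm = Z.values if isinstance(Z, GenotypeMatrix) else np.asarray(Z, dtype=float)
    y = np.asarray(target)
    if y.shape[0] != Zm.shape[0]:
        raise ValueError("target length does not match genotype rows")
    if config.task == "classification" and np.unique(y).size < 2:
        raise ValueError("classification needs at least two classes")
    if config.algorithm == "knn" and config.k_neighbors > Zm.shape[0]:
        raise ValueError("k exceeds the number of training individuals")
    est, theta = _build(config, Zm)
    est.fit(Zm, y)
    return PredictorModel(config=config, estimator=est, n_features=Zm.shape[1], theta=theta)


def predict(model: PredictorModel, Z_new) -> np.ndarray:
    Zm = Z_new.values if isinstance(Z_new, GenotypeMatrix) else np.asarray(Z_new, dtype=float)
    if Zm.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: model trained on {model.n_features} markers, got {Zm.shape[1]}"
        )
    return model.estimator.predict(Zm)
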