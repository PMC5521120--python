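"""PUK-kernel SVM training, calibration and repeated cross-validation.

The Pearson VII Universal Kernel (PUK) is

    K(x, y) = 1 / [1 + (2 * ||x - y|| * sqrt(2^(1/omega) - 1) / sigma)^2]^omega

with shape ``omega`` and width ``sigma``; ``K(x, x) = 1`` and K decreases
monotonically with Euclidean distance.  Models are soft-margin SVMs over the
precomputed PUK Gram matrix, with features z-scored using training
statistics (PUK distances are scale-sensitive) and an optional Platt-style
logistic calibration of the decision values fitted on out-of-fold
predictions.

The evaluation protocol is repeated stratified k-fold cross-validation:
each run redraws the folds with a different seed, per-run accuracy is pooled
over folds, and the report gives mean +/- standard deviation across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .matrix import DescriptorMatrix

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SVMParams:
    """Penalty and PUK kernel parameters."""

    C: float = 1.0
    omega: float = 1.0
    sigma: float = 1.0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.C <= 0 or self.omega <= 0 or self.sigma <= 0:
            raise ValueError("C, omega and sigma must all be positive")


def puk_kernel(x: np.ndarray, y: np.ndarray, omega: float = 1.0, sigma: float = 1.0) -> float:
    """PUK similarity of two feature vectors, in (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dimension mismatch")
    if omega <= 0 or sigma <= 0:
        raise ValueError("omega and sigma must be positive")
    d = float(np.linalg.norm(x - y))
    return float(
        1.0 / (1.0 + (2.0 * d * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma) ** 2) ** omega
    )


def puk_gram(
    X: np.ndarray, Y: np.ndarray | None = None, omega: float = 1.0, sigma: float = 1.0
) -> np.ndarray:
    """PUK Gram matrix between the rows of X and Y (Y defaults to X)."""
    if omega <= 0 or sigma <= 0:
        raise ValueError("omega and sigma must be positive")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    d = cdist(X, Y, metric="euclidean")
    scaled = (2.0 * d * np.sqrt(2.0 ** (1.0 / omega) - 1.0) / sigma) ** 2
    return 1.0 / (1.0 + scaled) ** omega


@dataclass
class _Scaler:
    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, enabled: bool) -> "_Scaler":
        if not enabled:
            return cls(np.zeros(X.shape[1]), np.ones(X.shape[1]))
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0   # constant columns pass through unscaled
        return cls(mean, scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class TrainedModel:
    """A fitted PUK-SVM with its preprocessing and calibration state."""

    params: SVMParams
    feature_names: list[str]
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    support_vectors: np.ndarray        # standardized training rows (support set)
    dual_coef: np.ndarray              # y_i * alpha_i for the support set
    intercept: float
    classes: tuple[int, int] = (0, 1)
    calibration: tuple[float, float] | None = None   # (a, b) of sigmoid(a*d + b)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.scaler_mean) / self.scaler_scale
        K = puk_gram(Z, self.support_vectors, self.params.omega, self.params.sigma)
        return K @ self.dual_coef + self.intercept


def _fit_svc(K: np.ndarray, y: np.ndarray, C: float) -> SVC:
    svc = SVC(C=C, kernel="precomputed")
    svc.fit(K, y)
    return svc


def train_svm(
    matrix: DescriptorMatrix,
    params: SVMParams | None = None,
    calibrate: bool = True,
    seed: int = 0,
) -> TrainedModel:
    """Fit a PUK-SVM on a labeled matrix.

    With ``calibrate`` the probability map is a logistic regression on
    decision values collected out-of-fold from an internal stratified
    5-fold split, so the calibration never sees its own training decisions.
    """
    if matrix.labels is None:
        raise ValueError("training requires a labeled matrix")
    y = matrix.labels
    if len(set(y.tolist())) < 2:
        raise ValueError("training requires both classes")
    params = params or SVMParams()
    X = matrix.values
    scaler = _Scaler.fit(X, params.standardize)
    Z = scaler.transform(X)
    K = puk_gram(Z, None, params.omega, params.sigma)
    svc = _fit_svc(K, y, params.C)

    calibration = None
    if calibrate:
        n_folds = min(5, int(np.bincount(y).min()))
        if n_folds >= 2:
            dec = np.empty(len(y))
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            for tr, te in skf.split(Z, y):
                sc = _Scaler.fit(X[tr], params.standardize)
                Ztr, Zte = sc.transform(X[tr]), sc.transform(X[te])
                Ktr = puk_gram(Ztr, None, params.omega, params.sigma)
                fold_svc = _fit_svc(Ktr, y[tr], params.C)
                Kte = puk_gram(Zte, Ztr, params.omega, params.sigma)
                dec[te] = fold_svc.decision_function(Kte)
            lr = LogisticRegression()
            lr.fit(dec[:, None], y)
            calibration = (float(lr.coef_[0, 0]), float(lr.intercept_[0]))
        else:
            logger.warning("too few instances per class to calibrate; skipping")

    sv_idx = svc.support_
    return TrainedModel(
        params=params,
        feature_names=matrix.feature_names,
        scaler_mean=scaler.mean,
        scaler_scale=scaler.scale,
        support_vectors=Z[sv_idx],
        dual_coef=svc.dual_coef_[0].copy(),
        intercept=float(svc.intercept_[0]),
        classes=(int(svc.classes_[0]), int(svc.classes_[1])),
        calibration=calibration,
    )


def predict(model: TrainedModel, matrix: DescriptorMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Classes and positive-class probabilities for new instances.

    Columns are aligned by feature name, so column order in ``matrix`` is
    irrelevant; missing columns are an error.
    """
    aligned = matrix.select(model.feature_names)
    dec = model.decision_function(aligned.values)
    classes = np.where(dec > 0, model.classes[1], model.classes[0])
    if model.calibration is not None:
        a, b = model.calibration
        prob = 1.0 / (1.0 + np.exp(-(a * dec + b)))
    else:
        prob = 1.0 / (1.0 + np.exp(-dec))   # uncalibrated logistic squash
    return classes, prob


@dataclass
class CVReport:
    """Per-run and aggregate metrics of repeated cross-validation."""

    run_accuracies: list[float]          # percent, pooled over folds per run
    run_f1: list[float]                  # positive-class F1 per run
    folds: int
    n_runs: int
    seeds: list[int]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.run_accuracies))

    @property
    def sd_accuracy(self) -> float:
        if len(self.run_accuracies) < 2:
            return 0.0
        return float(np.std(self.run_accuracies, ddof=1))

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.run_f1))

    def summary(self) -> str:
        return (
            f"{self.mean_accuracy:.2f} ± {self.sd_accuracy:.2f}% accuracy "
            f"({self.n_runs} x {self.folds}-fold CV; positive-class F1 "
            f"{self.mean_f1:.3f})"
        )


def _cv_single_run(
    X: np.ndarray, y: np.ndarray, params: SVMParams, folds: int, seed: int
) -> tuple[float, float]:
    """One CV run: pooled accuracy (%) and positive-class F1."""
    pred = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        scaler = _Scaler.fit(X[tr], params.standardize)
        Ztr = scaler.transform(X[tr])
        Zte = scaler.transform(X[te])
        Ktr = puk_gram(Ztr, None, params.omega, params.sigma)
        svc = _fit_svc(Ktr, y[tr], params.C)
        Kte = puk_gram(Zte, Ztr, params.omega, params.sigma)
        pred[te] = svc.predict(Kte)
    acc = 100.0 * float((pred == y).mean())
    f1 = float(f1_score(y, pred, pos_label=1, zero_division=0))
    return acc, f1


def crossvalidate(
    matrix: DescriptorMatrix,
    params: SVMParams | None = None,
    folds: int = 10,
    n_runs: int = 10,
    base_seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold CV with per-run reseeding.

    Run ``r`` draws its folds with seed ``base_seed + r``; standardization
    is refitted inside every training fold (no leakage).  Fold count is
    auto-reduced with a warning when a class has fewer members than folds.
    """
    if matrix.labels is None:
        raise ValueError("cross-validation requires a labeled matrix")
    y = matrix.labels
    if len(set(y.tolist())) < 2:
        raise ValueError("cross-validation requires both classes")
    min_class = int(np.bincount(y).min())
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min_class < folds:
        logger.warning(
            "reducing folds from %d to %d (smallest class has %d members)",
            folds, min_class, min_class,
        )
        folds = min_class
        if folds < 2:
            raise ValueError("smallest class too small for cross-validation")
    params = params or SVMParams()
    X = matrix.values
    seeds = [base_seed + r for r in range(n_runs)]
    accs: list[float] = []
    f1s: list[float] = []
    for seed in seeds:
        acc, f1 = _cv_single_run(X, y, params, folds, seed)
        accs.append(acc)
        f1s.append(f1)
    return CVReport(run_accuracies=accs, run_f1=f1s, folds=folds, n_runs=n_runs, seeds=seeds)


def grid_tune(
    matrix: DescriptorMatrix,
    C_grid: Sequence[float] = (0.5, 1, 2, 8, 64),
    omega_grid: Sequence[float] = (1, 7, 21),
    sigma_grid: Sequence[float] = (1, 7),
    folds: int = 10,
    n_runs: int = 1,
    base_seed: int = 0,
    standardize: bool = True,
) -> tuple[SVMParams, float]:
    """Exhaustive grid search maximizing mean CV accuracy.

    Ties break toward smaller C, then smaller omega, then smaller sigma.
    Returns the winning parameters and their mean accuracy.
    """
    if not (C_grid and omega_grid and sigma_grid):
        raise ValueError("empty grid")
    best: tuple[float, float, float, float] | None = None   # (-acc, C, omega, sigma)
    for C in C_grid:
        for omega in omega_grid:
            for sigma in sigma_grid:
                params = SVMParams(C=C, omega=omega, sigma=sigma, standardize=standardize)
                report = crossvalidate(
                    matrix, params, folds=folds, n_runs=n_runs, base_seed=base_seed
                )
                key = (-report.mean_accuracy, C, omega, sigma)
                if best is None or key < best:
                    best = key
    assert best is not None
    return SVMParams(C=best[1], omega=best[2], sigma=best[3], standardize=standardize), -best[0]


# ---------------------------------------------------------------------------
# Portable model archive (JSON; arrays as nested lists)

def save_model(model: TrainedModel, path: str | Path, feature_recipe: dict | None = None) -> None:
    """Write a versioned, text-only model archive.

    ``feature_recipe`` optionally records how to regenerate the model's
    features from raw sequences (used by the CLI predict command).
    """
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "params": asdict(model.params),
        "feature_names": model.feature_names,
        "scaler_mean": model.scaler_mean.tolist(),
        "scaler_scale": model.scaler_scale.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coef": model.dual_coef.tolist(),
        "intercept": model.intercept,
        "classes": list(model.classes),
        "calibration": list(model.calibration) if model.calibration else None,
        "feature_recipe": feature_recipe,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[TrainedModel, dict | None]:
    """Read a model archive; returns the model and its feature recipe."""
    payload = json.loads(Path(path).read_text())
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model archive version {version!r}")
    model = TrainedModel(
        params=SVMParams(**payload["params"]),
        feature_names=list(payload["feature_names"]),
        scaler_mean=np.array(payload["scaler_mean"], dtype=float),
        scaler_scale=np.array(payload["scaler_scale"], dtype=float),
        support_vectors=np.array(payload["support_vectors"], dtype=float),
        dual_coef=np.array(payload["dual_coef"], dtype=float),
        intercept=float(payload["intercept"]),
        classes=tuple(payload["classes"]),
        calibration=tuple(payload["calibration"]) if payload["calibration"] else None,
    )
    return model, payload.get("feature_recipe")
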