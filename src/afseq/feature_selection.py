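"""Three-stage supervised feature selection.

1. **Information-gain filter** — each descriptor is discretized into
   equal-frequency bins and scored by the mutual information between its
   bins and the binary class, IG = H(X) - H(X|Y) in bits.  Features whose
   IG reaches a fraction (default 15%) of the class entropy H(X) survive.
2. **Redundancy reduction** — surviving features are clustered by
   single linkage on the Spearman rank correlation (|rho| >= 0.95 links a
   pair); each cluster contributes the member closest to its centroid in
   z-scored column space.
3. **Genetic-search wrapper** — a seeded genetic algorithm over feature
   bitmasks, each candidate subset scored by the positive-class F1 of a
   PUK-SVM in stratified 5-fold cross-validation.

Stage outputs are nested, so subset sizes are non-increasing along the
pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.stats import rankdata
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold

from .matrix import DescriptorMatrix
from .svm_model import SVMParams, _Scaler, _fit_svc, puk_gram

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IGResult:
    """Information gain of one (binned) feature against the class."""

    feature_name: str
    ig: float
    class_entropy: float


@dataclass
class FeatureSubset:
    """Ordered surviving feature names with stage provenance."""

    names: list[str]
    stage: str                      # "ig" | "redundancy" | "wrapper" | "all"
    fitness: float | None = None    # wrapper stage: best F1

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature subset contains duplicates")

    def __len__(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# Information gain

def discretize(column: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Equal-frequency binning; ties share the lower bin.

    Bin ids are in ``[0, n_bins)``; a constant column collapses to a single
    bin.  Deterministic: bin of value x depends only on its min-rank.
    """
    v = np.asarray(column, dtype=float)
    if v.size == 0:
        raise ValueError("empty column")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    ranks = rankdata(v, method="min")            # ties -> lowest rank -> lower bin
    bins = np.floor((ranks - 1) * n_bins / v.size).astype(int)
    return np.clip(bins, 0, n_bins - 1)


def _entropy_from_counts(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def class_entropy(labels: np.ndarray) -> float:
    """Shannon entropy H(X) of the binary class distribution, in bits."""
    y = np.asarray(labels, dtype=int)
    return _entropy_from_counts(np.bincount(y, minlength=2))


def information_gain(binned: np.ndarray, labels: np.ndarray) -> IGResult:
    """IG = H(X) - sum_j P(y_j) H(X | y_j), all logarithms base 2.

    ``binned`` holds integer bin ids for one feature; empty contingency
    cells contribute zero.
    """
    b = np.asarray(binned, dtype=int)
    y = np.asarray(labels, dtype=int)
    if b.size != y.size or b.size == 0:
        raise ValueError("binned values and labels must be equal-length and nonempty")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary (0/1)")
    h_x = class_entropy(y)
    n = y.size
    cond = 0.0
    for bin_id in np.unique(b):
        mask = b == bin_id
        weight = mask.sum() / n
        cond += weight * _entropy_from_counts(np.bincount(y[mask], minlength=2))
    ig = max(0.0, h_x - cond)   # clamp -0.0 artifacts
    return IGResult(feature_name="", ig=ig, class_entropy=h_x)


def ig_scores(matrix: DescriptorMatrix, n_bins: int = 10) -> list[IGResult]:
    """Per-feature IG of a labeled matrix, in column order."""
    if matrix.labels is None:
        raise ValueError("information gain requires a labeled matrix")
    X = matrix.values
    y = matrix.labels
    results = []
    for j, name in enumerate(matrix.feature_names):
        res = information_gain(discretize(X[:, j], n_bins=n_bins), y)
        results.append(IGResult(feature_name=name, ig=res.ig, class_entropy=res.class_entropy))
    return results


def ig_filter(
    matrix: DescriptorMatrix, fraction: float = 0.15, n_bins: int = 10
) -> FeatureSubset:
    """Keep features with IG >= fraction * H(X), ordered by descending IG."""
    scores = ig_scores(matrix, n_bins=n_bins)
    if not scores:
        return FeatureSubset(names=[], stage="ig")
    threshold = fraction * scores[0].class_entropy
    kept = [s for s in scores if s.ig >= threshold]
    kept.sort(key=lambda s: -s.ig)   # stable: ties keep column order
    if not kept:
        logger.warning("ig_filter: no feature reaches %.3f bits; empty subset", threshold)
    return FeatureSubset(names=[s.feature_name for s in kept], stage="ig")


# ---------------------------------------------------------------------------
# Redundancy reduction

def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise Spearman rank correlation of columns (constant columns -> 0)."""
    ranks = rankdata(X, axis=0, method="average")
    centered = ranks - ranks.mean(axis=0)
    norms = np.sqrt((centered**2).sum(axis=0))
    safe = norms.copy()
    safe[safe == 0.0] = 1.0
    Z = centered / safe
    rho = Z.T @ Z
    rho[norms == 0.0, :] = 0.0
    rho[:, norms == 0.0] = 0.0
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def redundancy_reduce(
    matrix: DescriptorMatrix,
    subset: FeatureSubset,
    rho: float = 0.95,
    absolute: bool = True,
) -> FeatureSubset:
    """Single-linkage clustering at |rho_spearman| >= rho; one centroid
    representative per cluster.

    Clusters are the connected components of the graph linking feature pairs
    at or above the cutoff (single linkage, so correlation can chain).  The
    representative minimizes the Euclidean distance to the cluster's mean
    column after z-scoring; anticorrelated duplicates count as redundant
    when ``absolute`` is set.  Output keeps the input subset's order.
    """
    if len(subset) == 0:
        return FeatureSubset(names=[], stage="redundancy")
    X = matrix.select(subset.names).values
    rho_m = spearman_matrix(X)
    sim = np.abs(rho_m) if absolute else rho_m
    adj = sim >= rho
    np.fill_diagonal(adj, False)
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0.0] = 1.0
    Z = (X - mean) / std

    representatives: list[int] = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        if members.size == 1:
            representatives.append(int(members[0]))
            continue
        centroid = Z[:, members].mean(axis=1)
        dist = np.linalg.norm(Z[:, members] - centroid[:, None], axis=0)
        representatives.append(int(members[int(np.argmin(dist))]))   # ties: first
    representatives.sort()   # preserve input order
    return FeatureSubset(names=[subset.names[i] for i in representatives], stage="redundancy")


# ---------------------------------------------------------------------------
# Genetic-search wrapper

@dataclass(frozen=True)
class GAParams:
    """Genetic-search settings (population-based bitmask search)."""

    population: int = 20
    generations: int = 20
    crossover: float = 0.6
    mutation: float = 0.033
    cv_folds: int = 5

    def __post_init__(self) -> None:
        if self.population < 1 or self.generations < 0:
            raise ValueError("population >= 1 and generations >= 0 required")
        if not (0 <= self.crossover <= 1 and 0 <= self.mutation <= 1):
            raise ValueError("crossover and mutation are probabilities")


def _subset_f1(
    X: np.ndarray, y: np.ndarray, params: SVMParams, folds: int, seed: int
) -> float:
    """Positive-class F1 of a PUK-SVM in stratified k-fold CV."""
    pred = np.empty(len(y), dtype=int)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        scaler = _Scaler.fit(X[tr], params.standardize)
        Ztr = scaler.transform(X[tr])
        Zte = scaler.transform(X[te])
        svc = _fit_svc(puk_gram(Ztr, None, params.omega, params.sigma), y[tr], params.C)
        pred[te] = svc.predict(puk_gram(Zte, Ztr, params.omega, params.sigma))
    return float(f1_score(y, pred, pos_label=1, zero_division=0))


def ga_wrapper_select(
    matrix: DescriptorMatrix,
    subset: FeatureSubset,
    ga: GAParams | None = None,
    svm: SVMParams | None = None,
    seed: int = 0,
) -> FeatureSubset:
    """Genetic search over feature bitmasks scored by CV F1.

    Fitness-proportional selection with single-elite carryover, single-point
    crossover and per-bit mutation; the best-ever chromosome is returned.
    Fully reproducible given ``seed`` (which also seeds the CV folds).
    """
    if matrix.labels is None:
        raise ValueError("wrapper selection requires a labeled matrix")
    if len(subset) == 0:
        raise ValueError("wrapper selection requires a nonempty candidate subset")
    ga = ga or GAParams()
    svm = svm or SVMParams()
    y = matrix.labels
    X = matrix.select(subset.names).values
    m = len(subset)

    folds = ga.cv_folds
    min_class = int(np.bincount(y).min())
    if min_class < folds:
        folds = min_class
        logger.warning("wrapper CV folds reduced to %d (single-class-fold guard)", folds)
        if folds < 2:
            raise ValueError("smallest class too small for wrapper cross-validation")

    rng = np.random.default_rng(seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            if not mask.any():
                cache[key] = 0.0
            else:
                cache[key] = _subset_f1(X[:, mask], y, svm, folds, seed)
        return cache[key]

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask[rng.integers(m)] = True
        return mask

    pop = [repair(rng.random(m) < 0.5) for _ in range(ga.population)]
    fits = np.array([fitness(c) for c in pop])
    best_idx = int(np.argmax(fits))
    best_mask, best_fit = pop[best_idx].copy(), float(fits[best_idx])

    for _ in range(ga.generations):
        new_pop = [best_mask.copy()]   # elitism
        total = fits.sum()
        probs = fits / total if total > 0 else np.full(len(pop), 1.0 / len(pop))
        while len(new_pop) < ga.population:
            i, j = rng.choice(len(pop), size=2, p=probs)
            a, b = pop[i].copy(), pop[j].copy()
            if m > 1 and rng.random() < ga.crossover:
                point = int(rng.integers(1, m))
                a[point:], b[point:] = pop[j][point:], pop[i][point:]
            for child in (a, b):
                flip = rng.random(m) < ga.mutation
                child[flip] = ~child[flip]
                new_pop.append(repair(child))
        pop = new_pop[: ga.population]
        fits = np.array([fitness(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_mask, best_fit = pop[gen_best].copy(), float(fits[gen_best])

    names = [subset.names[i] for i in np.flatnonzero(best_mask)]
    return FeatureSubset(names=names, stage="wrapper", fitness=best_fit)


def selection_report(
    matrix: DescriptorMatrix,
    ig_subset: FeatureSubset,
    red_subset: FeatureSubset,
    wrapper_subset: FeatureSubset | None = None,
    n_bins: int = 10,
) -> "pd.DataFrame":
    """Per-feature TSV-ready report: IG, and the last stage each survived."""
    import pandas as pd

    scores = {s.feature_name: s.ig for s in ig_scores(matrix, n_bins=n_bins)}
    in_red = set(red_subset.names)
    in_wrap = set(wrapper_subset.names) if wrapper_subset else set()
    rows = []
    for name in matrix.feature_names:
        if name in in_wrap:
            stage = "wrapper"
        elif name in in_red:
            stage = "redundancy"
        elif name in set(ig_subset.names):
            stage = "ig"
        else:
            stage = "none"
        rows.append({"feature": name, "ig": scores.get(name, 0.0), "stage_survived": stage})
    return pd.DataFrame(rows)
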