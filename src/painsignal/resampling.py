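"""Minority-class oversampling: SMOTE, Borderline-SMOTE and ADASYN.

All three generate G = (n_maj - n_min) * beta synthetic minority points by
linear interpolation between a minority seed point x_i and one of its k
nearest minority neighbors x_z:  x_new = x_i + lambda * (x_z - x_i) with
lambda ~ U(0, 1).  They differ only in how G is allocated across seeds:

* SMOTE          — uniformly across all minority points;
* Borderline-SMOTE — uniformly across the "danger" points only (minority
  points whose k-NN majority fraction lies in [0.5, 1.0); points surrounded
  entirely by majority are treated as noise and never seed synthesis);
* ADASYN         — proportionally to each minority point's normalized local
  majority density r_i = (majority among k NN) / k, so harder regions
  receive more synthesis.

Original rows are preserved and come first in the output; no majority row is
ever created or removed; every synthetic point is a convex combination of
two minority rows.  Results are a pure function of (data, config, seed).

Neighbor searches use Euclidean distance on the features as assembled (the
leveled fluctuation features are already roughly commensurate); set
``standardize=True`` to z-score a copy of the features for the distance
computation only — synthesis always happens in the original space.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .errors import ConfigurationError, ResamplingError

logger = logging.getLogger(__name__)

_METHODS = ("smote", "borderline_smote", "adasyn")


@dataclass(frozen=True)
class ResampleConfig:
    method: str = "adasyn"
    k_neighbors: int = 5
    balance_ratio: float = 1.0        # beta: target minority/majority ratio
    standardize: bool = False         # z-score features for the k-NN distances
    seed: int = 0

    def __post_init__(self):
        if self.method not in _METHODS:
            raise ConfigurationError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.k_neighbors < 1:
            raise ConfigurationError(f"k_neighbors must be >= 1, got {self.k_neighbors}")
        if not (math.isfinite(self.balance_ratio) and 0.0 < self.balance_ratio <= 1.0):
            raise ConfigurationError(f"balance_ratio must lie in (0, 1], got {self.balance_ratio}")

    @classmethod
    def from_dict(cls, d: dict) -> "ResampleConfig":
        return cls(**d)


def _setup(features, labels, config):
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ResamplingError("features must be 2-D with one label per row")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ResamplingError(
            f"oversampling requires exactly two classes, got {classes.size}")
    minority_label = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == 1:
        raise ResamplingError(
            "the minority class has a single sample, so no minority neighbor "
            "exists for interpolation; collect more minority data or duplicate "
            "the point explicitly before oversampling")
    G = int(round((n_maj - n_min) * config.balance_ratio))
    min_idx = np.flatnonzero(y == minority_label)
    return X, y, minority_label, min_idx, G


def _distance_space(X: np.ndarray, standardize: bool) -> np.ndarray:
    if not standardize:
        return X
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _majority_fraction(X, y, minority_label, min_idx, k, standardize):
    """Fraction of majority points among the k nearest neighbors (over all
    points, self excluded) of each minority point."""
    D = _distance_space(X, standardize)
    k_eff = min(k, X.shape[0] - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(D)
    _, idx = nn.kneighbors(D[min_idx])
    frac = np.empty(min_idx.size)
    for row, i in enumerate(min_idx):
        neigh = [j for j in idx[row] if j != i][:k_eff]
        frac[row] = np.mean(y[neigh] != minority_label)
    return frac


def _minority_neighbors(X, min_idx, k, standardize):
    """Indices (into min_idx) of each minority point's k nearest minority
    neighbors, self excluded."""
    D = _distance_space(X, standardize)[min_idx]
    k_eff = min(k, min_idx.size - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(D)
    _, idx = nn.kneighbors(D)
    out = np.empty((min_idx.size, k_eff), dtype=int)
    for row in range(min_idx.size):
        out[row] = [j for j in idx[row] if j != row][:k_eff]
    return out


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights`` (sum
    preserved exactly; deterministic ties by index order)."""
    if total <= 0 or weights.sum() == 0:
        return np.zeros(weights.size, dtype=int)
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(int)
    remainder = total - alloc.sum()
    if remainder > 0:
        order = np.argsort(-(quota - alloc), kind="stable")
        alloc[order[:remainder]] += 1
    return alloc


def _synthesize(X, min_idx, neighbors, alloc, rng):
    points = []
    for row, g in enumerate(alloc):
        if g == 0:
            continue
        xi = X[min_idx[row]]
        zs = rng.integers(0, neighbors.shape[1], size=g)
        lams = rng.random(g)
        for z, lam in zip(zs, lams):
            xz = X[min_idx[neighbors[row, z]]]
            points.append(xi + lam * (xz - xi))
    return np.asarray(points) if points else np.empty((0, X.shape[1]))


def _assemble(X, y, synth, minority_label):
    if synth.shape[0] == 0:
        return X.copy(), y.copy()
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(synth.shape[0], minority_label, dtype=y.dtype)])
    return X_out, y_out


def smote(features, labels, config: ResampleConfig):
    """SMOTE: G synthetic points allocated uniformly across minority points."""
    X, y, m_label, min_idx, G = _setup(features, labels, config)
    if G <= 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(config.seed)
    neighbors = _minority_neighbors(X, min_idx, config.k_neighbors, config.standardize)
    alloc = _largest_remainder(np.ones(min_idx.size), G)
    synth = _synthesize(X, min_idx, neighbors, alloc, rng)
    return _assemble(X, y, synth, m_label)


def borderline_smote(features, labels, config: ResampleConfig):
    """Borderline-SMOTE: only danger points (k-NN majority fraction in
    [0.5, 1.0)) seed synthesis; no danger points means no synthesis."""
    X, y, m_label, min_idx, G = _setup(features, labels, config)
    if G <= 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(config.seed)
    frac = _majority_fraction(X, y, m_label, min_idx, config.k_neighbors, config.standardize)
    danger = (frac >= 0.5) & (frac < 1.0)
    if not danger.any():
        logger.warning("borderline_smote: no danger points found; returning the "
                       "input unchanged")
        return X.copy(), y.copy()
    neighbors = _minority_neighbors(X, min_idx, config.k_neighbors, config.standardize)
    alloc = _largest_remainder(danger.astype(float), G)
    synth = _synthesize(X, min_idx, neighbors, alloc, rng)
    return _assemble(X, y, synth, m_label)


def adasyn(features, labels, config: ResampleConfig):
    """ADASYN: allocation proportional to each minority point's normalized
    k-NN majority fraction; uniform when every neighborhood is pure minority."""
    X, y, m_label, min_idx, G = _setup(features, labels, config)
    if G <= 0:
        return X.copy(), y.copy()
    rng = np.random.default_rng(config.seed)
    frac = _majority_fraction(X, y, m_label, min_idx, config.k_neighbors, config.standardize)
    if frac.sum() == 0:
        logger.info("adasyn: no majority neighbors anywhere; falling back to "
                    "uniform allocation")
        frac = np.ones_like(frac)
    neighbors = _minority_neighbors(X, min_idx, config.k_neighbors, config.standardize)
    alloc = _largest_remainder(frac, G)
    synth = _synthesize(X, min_idx, neighbors, alloc, rng)
    return _assemble(X, y, synth, m_label)


def resample(features, labels, config: ResampleConfig):
    """Dispatch to the oversampler named by ``config.method``."""
    fn = {"smote": smote, "borderline_smote": borderline_smote, "adasyn": adasyn}[config.method]
    return fn(features, labels, config)
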