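"""Spatial stratified-heterogeneity analysis (factor and interaction detector).

The factor detector measures how much of an outcome's spatial variance a
categorical factor explains:

    q = 1 - (sum_h n_h * sigma_h^2) / (n * sigma^2)

with population (divide-by-n) variances over the L strata of the factor.
By the law of total variance q always lies in [0, 1]: q = 0 means the factor
explains nothing, q = 1 means the outcome is constant within every stratum
(the factor completely controls the spatial variation).

The interaction detector computes q for the cross-classification of two
factors and assigns one of five categories by comparing q(X1 n X2) with
q(X1), q(X2) and their sum:

    nonlinear weakening                q12 < min(q1, q2)
    single-factor nonlinear weakening  min(q1, q2) < q12 < max(q1, q2)
    bifactor enhancement               q12 > max(q1, q2)
    independent                        q12 = q1 + q2     (within tolerance)
    nonlinear enhancement              q12 > q1 + q2

Population variances are used throughout; with sample variances q can leave
[0, 1] when strata are tiny. Singleton strata contribute zero within-stratum
variance and are kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .errors import ConfigError, StatisticError
from .grid import LabelRaster, Raster

INTERACTION_CATEGORIES = (
    "nonlinear_weakening",
    "single_factor_nonlinear_weakening",
    "bifactor_enhancement",
    "independent",
    "nonlinear_enhancement",
)


@dataclass
class FactorLayer:
    """A stratified (categorical) explanatory layer on the outcome grid."""

    strata: np.ndarray          # int array; 0 marks nodata
    n_levels: int
    name: str = ""

    def __post_init__(self) -> None:
        self.strata = np.asarray(self.strata)
        if self.n_levels < 1:
            raise ConfigError("a factor needs at least one level")
        labs = self.strata[self.strata != 0]
        if labs.size and (labs.min() < 1 or labs.max() > self.n_levels):
            raise ConfigError("stratum labels must lie in [1, n_levels]")


@dataclass
class FactorResult:
    """q-statistic plus per-stratum diagnostics."""

    name: str
    q: float
    n: int
    variance: float
    stratum_sizes: dict[int, int]
    stratum_variances: dict[int, float]


def discretize_factor(raster: Raster, n_classes: int = 5,
                      method: str = "quantile") -> FactorLayer:
    """Stratify a continuous raster into ``n_classes`` levels.

    Methods: ``quantile`` (near-equal stratum sizes), ``equal_interval``
    (uniform value bins), ``natural_breaks`` (1-D k-means clustering of the
    values, a Jenks-style optimization). Already-categorical rasters can be
    wrapped directly with :func:`categorical_factor` instead.
    """
    if n_classes < 2:
        raise ConfigError("need at least 2 classes")
    vals = raster.valid_values()
    if np.unique(vals).size < n_classes:
        raise StatisticError("raster has fewer distinct values than classes")
    if method == "quantile":
        edges = np.quantile(vals, np.linspace(0, 1, n_classes + 1)[1:-1])
    elif method == "equal_interval":
        edges = np.linspace(vals.min(), vals.max(), n_classes + 1)[1:-1]
    elif method == "natural_breaks":
        km = KMeans(n_clusters=n_classes, n_init=10, random_state=0)
        km.fit(vals.reshape(-1, 1))
        centers = np.sort(km.cluster_centers_.ravel())
        edges = (centers[:-1] + centers[1:]) / 2.0
    else:
        raise ConfigError(f"unknown discretization method {method!r}")
    strata = np.zeros(raster.values.shape, dtype=np.int64)
    strata[raster.mask] = np.searchsorted(edges, vals, side="right") + 1
    return FactorLayer(strata, n_classes, name=method)


def categorical_factor(labels: LabelRaster, name: str = "") -> FactorLayer:
    """Wrap an already-categorical raster as a FactorLayer (identity pass)."""
    labs = labels.labels
    uniq = np.unique(labs[labels.mask])
    remap = {int(u): i + 1 for i, u in enumerate(uniq)}
    strata = np.zeros(labs.shape, dtype=np.int64)
    for u, s in remap.items():
        strata[labs == u] = s
    return FactorLayer(strata, len(uniq), name=name)


def _q_from_groups(values: np.ndarray, strata: np.ndarray):
    """Core q computation from flat valid values and positive stratum codes."""
    n = values.size
    if n < 2:
        raise StatisticError("q needs at least two valid cells")
    var = values.var()  # population variance
    if var <= 0:
        raise StatisticError("q is undefined for a constant outcome")
    codes, inv = np.unique(strata, return_inverse=True)
    n_h = np.bincount(inv)
    sums = np.bincount(inv, weights=values)
    means = sums / n_h
    ss_within = np.bincount(inv, weights=(values - means[inv]) ** 2)
    if len(codes) == 1:
        # single stratum: within-variance equals global variance identically
        q = 0.0
    elif ss_within.sum() == 0.0:
        # outcome constant within every stratum: full control
        q = 1.0
    else:
        q = 1.0 - ss_within.sum() / (n * var)
    sizes = {int(c): int(k) for c, k in zip(codes, n_h)}
    variances = {int(c): float(ss / k)
                 for c, ss, k in zip(codes, ss_within, n_h)}
    return float(q), n, float(var), sizes, variances


def factor_q(outcome: Raster, factor: FactorLayer) -> FactorResult:
    """Factor-detector q of a stratification on an outcome raster."""
    if factor.strata.shape != outcome.values.shape:
        raise ConfigError("factor and outcome must share a grid")
    valid = outcome.mask & (factor.strata != 0)
    q, n, var, sizes, variances = _q_from_groups(
        outcome.values[valid], factor.strata[valid])
    return FactorResult(factor.name, q, n, var, sizes, variances)


def interaction_q(outcome: Raster, f1: FactorLayer, f2: FactorLayer) -> float:
    """q of the cross-classification of two factors (nonempty (h1,h2) pairs)."""
    if f1.strata.shape != f2.strata.shape:
        raise ConfigError("factors must share a grid")
    valid = outcome.mask & (f1.strata != 0) & (f2.strata != 0)
    cross = f1.strata[valid] * (f2.n_levels + 1) + f2.strata[valid]
    q, *_ = _q_from_groups(outcome.values[valid], cross)
    return q


def classify_interaction(q1: float, q2: float, q12: float,
                         tol: float = 1e-9) -> str:
    """Assign one of the five interaction categories.

    The equality branch (independent) is tested within ``tol`` before the
    enhancement inequalities; the weakening branches are strict. Values must
    lie in [0, 1].
    """
    for v in (q1, q2, q12):
        if not -tol <= v <= 1 + tol:
            raise ConfigError("q values must lie in [0, 1]")
    if abs(q12 - (q1 + q2)) <= tol:
        return "independent"
    if q12 > q1 + q2:
        return "nonlinear_enhancement"
    if q12 > max(q1, q2):
        return "bifactor_enhancement"
    if q12 < min(q1, q2):
        return "nonlinear_weakening"
    return "single_factor_nonlinear_weakening"


class GeoDetector(BaseEstimator):
    """Factor and interaction detector over a set of explanatory layers.

    Parameters
    ----------
    n_classes : int
        Strata per continuous factor (categorical factors keep their levels).
    method : {'quantile', 'equal_interval', 'natural_breaks'}
        Discretization for continuous factors.
    interactions : bool
        Whether to evaluate all factor pairs with the interaction detector.

    After ``fit(factors, outcome)``:

    Attributes
    ----------
    results_ : dict[str, FactorResult]
    q_ : pandas.Series of q by factor, descending
    interactions_ : pandas.DataFrame with q1, q2, q12 and category per pair
        (empty unless ``interactions=True``).
    """

    def __init__(self, n_classes: int = 5, method: str = "quantile",
                 interactions: bool = True):
        self.n_classes = n_classes
        self.method = method
        self.interactions = interactions

    def _as_layer(self, name: str, layer) -> FactorLayer:
        if isinstance(layer, FactorLayer):
            return FactorLayer(layer.strata, layer.n_levels, name)
        if isinstance(layer, LabelRaster):
            return categorical_factor(layer, name)
        # rasters with fewer distinct values than classes (e.g. binary
        # indicators) are effectively categorical already
        vals = layer.valid_values()
        if np.unique(vals).size < self.n_classes:
            uniq = np.unique(vals)
            strata = np.zeros(layer.values.shape, dtype=np.int64)
            strata[layer.mask] = np.searchsorted(uniq, vals) + 1
            return FactorLayer(strata, len(uniq), name)
        fl = discretize_factor(layer, self.n_classes, self.method)
        fl.name = name
        return fl

    def fit(self, factors: Mapping[str, Raster | LabelRaster | FactorLayer],
            outcome: Raster):
        layers = {name: self._as_layer(name, lay)
                  for name, lay in factors.items()}
        self.layers_ = layers
        self.results_ = {name: factor_q(outcome, lay)
                         for name, lay in layers.items()}
        self.q_ = pd.Series({n: r.q for n, r in self.results_.items()}
                            ).sort_values(ascending=False)
        rows = []
        if self.interactions:
            for a, b in itertools.combinations(layers, 2):
                q1, q2 = self.results_[a].q, self.results_[b].q
                q12 = interaction_q(outcome, layers[a], layers[b])
                rows.append((a, b, q1, q2, q12,
                             classify_interaction(q1, q2, q12)))
        self.interactions_ = pd.DataFrame(
            rows, columns=["factor1", "factor2", "q1", "q2", "q12",
                           "category"])
        return self
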