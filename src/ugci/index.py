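"""Diagnosis step: min-max normalization, entropy weighting, the composite
index, and quartile-based management levels.

The Urban Green Carbon Index of grid cell ``i`` is the linear combination
``UGCI_i = sum_j X'_ij W_j`` of the min-max-normalized components
``X'_ij = (X_ij - X_j_min) / (X_j_max - X_j_min)`` with entropy-based
weights: each component's value shares ``P_ij = X'_ij / sum_i X'_ij`` give
a Shannon entropy ``E_j = -(1/ln n) sum_i P_ij ln P_ij`` (``0 ln 0 := 0``),
and the information utilities ``1 - E_j`` are renormalized into weights.
Spatially uniform components carry no information (``E_j = 1``) and get
weight zero.

The core is exposed both as scikit-learn estimators
(:class:`EntropyWeightedIndex`, :class:`QuartileLevelClassifier`) and as
the plain functions they wrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .grids import COMPONENT_NAMES, ComponentStack

__all__ = [
    "MANAGEMENT_LEVELS",
    "NormalizedMatrix",
    "WeightVector",
    "IndexResult",
    "EntropyWeightedIndex",
    "QuartileLevelClassifier",
    "normalize_minmax",
    "entropy_weights",
    "compute_ugci",
    "classify_quartiles",
    "select_top_components",
]

#: Management levels from worst to best quartile.
MANAGEMENT_LEVELS = ("extremely_low", "low", "moderate", "high")


@dataclass
class NormalizedMatrix:
    """Min-max-normalized component matrix with its inversion metadata."""

    values: np.ndarray  # (n, m) in [0, 1]
    mins: np.ndarray  # (m,)
    maxs: np.ndarray  # (m,)
    degenerate: np.ndarray  # (m,) bool; spatially constant components
    component_names: tuple[str, ...] = COMPONENT_NAMES

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]


@dataclass
class WeightVector:
    """Entropy-weighting artefacts: entropies, utilities, weights."""

    entropies: np.ndarray  # E_j in [0, 1]
    weights: np.ndarray  # W_j >= 0, summing to 1
    proportions: np.ndarray  # P_ij
    k: float  # 1 / ln(n)
    component_names: tuple[str, ...] = COMPONENT_NAMES

    @property
    def utilities(self) -> np.ndarray:
        """Information utility 1 - E_j of each component."""
        return 1.0 - self.entropies


@dataclass
class IndexResult:
    """Per-grid index values with quartile thresholds and levels."""

    ugci: np.ndarray  # (n,) in [0, 1]
    thresholds: tuple[float, float, float]  # Q1, Q2, Q3
    levels: np.ndarray  # (n,) int codes into MANAGEMENT_LEVELS

    def level_names(self) -> np.ndarray:
        return np.asarray(MANAGEMENT_LEVELS, dtype=object)[self.levels]


def _as_matrix(data: ComponentStack | np.ndarray) -> np.ndarray:
    if isinstance(data, ComponentStack):
        return data.matrix()
    return np.asarray(data, dtype=float)


def normalize_minmax(data: ComponentStack | np.ndarray) -> NormalizedMatrix:
    """Scale each component to [0, 1] over the valid-grid population.

    Spatially constant (degenerate) components cannot be scaled; they are
    flagged, set to 0 everywhere, and warned about — downstream they carry
    weight zero so they cannot perturb the index.
    """
    X = _as_matrix(data)
    if X.ndim != 2:
        raise ValueError(f"expected an (n, m) matrix, got shape {X.shape}")
    n, m = X.shape
    if n < 2:
        raise ValueError(f"min-max normalization needs n >= 2 valid grids, got n={n}")
    mins = X.min(axis=0)
    maxs = X.max(axis=0)
    span = maxs - mins
    degenerate = span == 0
    if degenerate.any():
        names = [COMPONENT_NAMES[j] if m == len(COMPONENT_NAMES) else str(j)
                 for j in np.flatnonzero(degenerate)]
        warnings.warn(
            f"spatially constant component(s) {names} set to 0 and flagged degenerate",
            stacklevel=2,
        )
    safe_span = np.where(degenerate, 1.0, span)
    Xn = (X - mins) / safe_span
    Xn[:, degenerate] = 0.0
    names = COMPONENT_NAMES if m == len(COMPONENT_NAMES) else tuple(
        f"component_{j}" for j in range(m)
    )
    return NormalizedMatrix(values=Xn, mins=mins, maxs=maxs,
                            degenerate=degenerate, component_names=names)


def entropy_weights(norm: NormalizedMatrix) -> WeightVector:
    """Entropy-based component weights from a normalized matrix.

    ``P_ij = X'_ij / sum_i X'_ij``; ``E_j = -(1/ln n) sum_i P_ij ln P_ij``
    with ``0 ln 0 := 0``; ``W_j = (1 - E_j) / sum_j (1 - E_j)``.
    Degenerate components get ``E_j = 1`` hence ``W_j = 0``.
    """
    Xn = norm.values
    n, m = Xn.shape
    if n < 2:
        raise ValueError("entropy weights need n >= 2 grids")
    k = 1.0 / np.log(n)
    col_sums = Xn.sum(axis=0)
    zero_info = (col_sums == 0) | norm.degenerate
    if zero_info.all():
        raise ValueError("all components are degenerate: no information to weight")
    safe_sums = np.where(col_sums == 0, 1.0, col_sums)
    P = Xn / safe_sums
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    E = -k * plogp.sum(axis=0)
    E[zero_info] = 1.0
    utilities = 1.0 - E
    W = utilities / utilities.sum()
    return WeightVector(entropies=E, weights=W, proportions=P, k=k,
                        component_names=norm.component_names)


def compute_ugci(norm: NormalizedMatrix, w: WeightVector) -> np.ndarray:
    """Linear weighted index ``UGCI_i = sum_j X'_ij W_j``, bounded in [0, 1]."""
    if norm.m != w.weights.shape[0]:
        raise ValueError(
            f"component count mismatch: matrix has {norm.m}, weights {w.weights.shape[0]}"
        )
    return norm.values @ w.weights


def classify_quartiles(values: np.ndarray) -> IndexResult:
    """Assign quartile-based management levels to index values.

    Thresholds are the 25th/50th/75th percentiles (linear interpolation
    between order statistics); levels are the half-open intervals
    ``[min, Q1) / [Q1, Q2) / [Q2, Q3) / [Q3, max]``, so a value exactly on
    a threshold belongs to the upper level.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D array of index values")
    if v.size < 4:
        raise ValueError(f"quartile classification needs >= 4 values, got {v.size}")
    q1, q2, q3 = np.percentile(v, [25, 50, 75])
    if q1 == q3:
        raise ValueError(
            "index values are (almost) all identical; quartile levels undefined"
        )
    levels = np.digitize(v, [q1, q2, q3], right=False)
    return IndexResult(ugci=v, thresholds=(float(q1), float(q2), float(q3)),
                       levels=levels)


def select_top_components(w: WeightVector, count: int = 3) -> list[int]:
    """Indices of the ``count`` highest-weight components, descending.

    Ties keep the canonical component order (stable sort), so the result is
    deterministic.
    """
    m = w.weights.shape[0]
    if count > m:
        raise ValueError(f"cannot select {count} of {m} components")
    order = np.argsort(-w.weights, kind="stable")
    return [int(j) for j in order[:count]]


class EntropyWeightedIndex(TransformerMixin, BaseEstimator):
    """Entropy-weighted min-max composite index, scikit-learn style.

    ``fit`` learns the per-component min/max and the entropy weights from
    the grid population; ``transform`` maps raw component rows to index
    scores in [0, 1] (values outside the fitted range are clipped).

    Attributes (after fit)
    ----------------------
    mins_, maxs_ : per-component normalization bounds
    degenerate_ : mask of spatially constant components
    entropies_ : per-component Shannon entropy ``E_j``
    weights_ : entropy weights ``W_j`` (nonnegative, sum to 1)
    """

    def __init__(self, clip: bool = True):
        self.clip = clip

    def fit(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        norm = normalize_minmax(X)
        w = entropy_weights(norm)
        self.n_features_in_ = X.shape[1]
        self.mins_ = norm.mins
        self.maxs_ = norm.maxs
        self.degenerate_ = norm.degenerate
        self.entropies_ = w.entropies
        self.weights_ = w.weights
        return self

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        span = np.where(self.degenerate_, 1.0, self.maxs_ - self.mins_)
        Xn = (X - self.mins_) / span
        Xn[:, self.degenerate_] = 0.0
        if self.clip:
            Xn = np.clip(Xn, 0.0, 1.0)
        return Xn

    def transform(self, X) -> np.ndarray:
        """Index score of each row (1-D array)."""
        check_is_fitted(self, "weights_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} components, expected {self.n_features_in_}"
            )
        return self._normalize(X) @ self.weights_


class QuartileLevelClassifier(BaseEstimator):
    """Quartile-based management-level classifier for index scores.

    ``fit`` learns the 25/50/75th-percentile thresholds of the score
    population; ``predict`` assigns integer levels 0..3 (see
    :data:`MANAGEMENT_LEVELS`), upper level inclusive at thresholds.
    """

    def fit(self, X, y=None):
        v = np.asarray(X, dtype=float).ravel()
        result = classify_quartiles(v)
        self.thresholds_ = result.thresholds
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        v = np.asarray(X, dtype=float).ravel()
        return np.digitize(v, list(self.thresholds_), right=False)

    def predict_names(self, X) -> np.ndarray:
        return np.asarray(MANAGEMENT_LEVELS, dtype=object)[self.predict(X)]
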