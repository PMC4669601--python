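"""Adjacent-marker LD and its loess regression on physical distance.

LD between two markers is the absolute Pearson correlation of their 0/1
allele columns across all haplotypes. Per chromosome, the LD of every
consecutive marker pair is regressed on the inter-marker distance (Kb) with
loess — locally weighted quadratic regression under a tricube kernel — and
the span (the fraction of pairs entering each local fit) is selected from a
candidate grid by 3-fold cross-validated mean squared prediction error.

No installed package offers degree-2 loess, so the local regression is
implemented here directly: for a query point the ``ceil(span * n)`` nearest
training distances are tricube-weighted by their distance to the query
(scaled by the window radius) and a weighted quadratic polynomial is solved
by least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .panel import HaplotypePanel

__all__ = ["LDPairs", "LoessLDCurve", "consecutive_ld", "fit_loess", "predict_rho"]

DEFAULT_SPAN_GRID = tuple(np.round(np.arange(0.25, 1.0001, 0.05), 2))


@dataclass(frozen=True)
class LDPairs:
    """Adjacent-pair training data for one chromosome."""

    distances_kb: np.ndarray
    abs_correlations: np.ndarray
    chromosome: str

    def __post_init__(self) -> None:
        d = np.asarray(self.distances_kb, dtype=float)
        r = np.asarray(self.abs_correlations, dtype=float)
        if d.shape != r.shape or d.ndim != 1:
            raise ValueError("distances and correlations must be equal-length vectors")
        if np.any(d <= 0):
            raise ValueError("inter-marker distances must be positive")
        if np.any((r < 0) | (r > 1 + 1e-12)):
            raise ValueError("absolute correlations must lie in [0, 1]")
        object.__setattr__(self, "distances_kb", d)
        object.__setattr__(self, "abs_correlations", np.clip(r, 0.0, 1.0))

    def __len__(self) -> int:
        return self.distances_kb.size


def consecutive_ld(panel: HaplotypePanel, chromosome: str) -> LDPairs:
    """Distance and |Pearson r| for every consecutive marker pair."""
    cols = panel.chromosome_alleles(chromosome).astype(float)
    pos = panel.map.positions(chromosome)
    ids = panel.map.marker_ids[panel.map.chromosome_index(chromosome)]
    if cols.shape[1] < 2:
        raise ValueError(f"chromosome {chromosome!r} has fewer than 2 markers")
    sd = cols.std(axis=0)
    if np.any(sd == 0):
        k = int(np.argmax(sd == 0))
        raise ValueError(
            f"marker {ids[k]!r} is monomorphic: adjacent correlation undefined"
        )
    centered = cols - cols.mean(axis=0)
    num = np.sum(centered[:, :-1] * centered[:, 1:], axis=0)
    den = cols.shape[0] * sd[:-1] * sd[1:]
    rho = np.abs(num / den)
    return LDPairs(np.diff(pos), rho, str(chromosome))


def _local_quadratic(
    x_train: np.ndarray,
    y_train: np.ndarray,
    x0: float,
    k: int,
    degree: int,
) -> float:
    """Tricube-weighted degree-``degree`` polynomial fit, evaluated at x0."""
    d = np.abs(x_train - x0)
    if k < x_train.size:
        idx = np.argpartition(d, k - 1)[:k]
    else:
        idx = np.arange(x_train.size)
    dk = d[idx]
    radius = dk.max()
    if radius == 0:  # all selected points coincide with the query
        return float(y_train[idx].mean())
    w = (1.0 - np.minimum(dk / radius, 1.0) ** 3) ** 3
    # points exactly at the window edge get weight 0; keep at least the query
    if w.sum() == 0:
        w = np.ones_like(w)
    t = x_train[idx] - x0
    deg = min(degree, np.unique(x_train[idx]).size - 1)
    X = np.vander(t, deg + 1, increasing=True)
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y_train[idx] * sw, rcond=None)
    return float(coef[0])


class LoessLDCurve(BaseEstimator, RegressorMixin):
    """Loess regression of adjacent-marker |correlation| on distance (Kb).

    Parameters
    ----------
    span : float or None
        Fraction of training pairs in each local fit. ``None`` (default)
        selects the span from ``span_grid`` by ``cv``-fold cross-validated
        MSE; ties favour the larger (smoother) span.
    span_grid : sequence of float
        Candidate spans, default 0.25..1.00 in steps of 0.05.
    degree : int
        Local polynomial degree (default 2).
    cv : int
        Number of CV folds (default 3); folds are a seeded random partition.
    min_pairs : int
        Below this many training pairs, CV is skipped with a warning and the
        largest candidate span is used.
    random_state : int

    Attributes
    ----------
    span_ : float
        Selected (or fixed) span.
    cv_error_ : float or None
        CV MSE at ``span_``; None when CV was not run.
    cv_errors_ : dict
        CV MSE per candidate span.
    x_, y_ : ndarray
        Stored training data (loess is a memory-based smoother).
    """

    def __init__(
        self,
        span: float | None = None,
        span_grid: tuple = DEFAULT_SPAN_GRID,
        degree: int = 2,
        cv: int = 3,
        min_pairs: int = 30,
        random_state: int = 0,
    ) -> None:
        self.span = span
        self.span_grid = span_grid
        self.degree = degree
        self.cv = cv
        self.min_pairs = min_pairs
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y) -> "LoessLDCurve":
        x = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if x.size != y.size:
            raise ValueError("X and y lengths differ")
        if x.size < 3:
            raise ValueError(f"need at least 3 pairs to fit a loess curve, got {x.size}")
        self.x_, self.y_ = x, y
        self.cv_errors_ = {}
        if self.span is not None:
            self.span_ = float(self.span)
            self.cv_error_ = None
        elif x.size < self.min_pairs:
            warnings.warn(
                f"only {x.size} pairs (< {self.min_pairs}): skipping span CV, "
                f"using largest candidate span",
                stacklevel=2,
            )
            self.span_ = float(max(self.span_grid))
            self.cv_error_ = None
        else:
            rng = np.random.default_rng(self.random_state)
            fold = rng.permutation(x.size) % self.cv
            best_span, best_err = None, np.inf
            for span in self.span_grid:
                sq_err = 0.0
                for f in range(self.cv):
                    tr, te = fold != f, fold == f
                    pred = self._predict_raw(x[te], x[tr], y[tr], span)
                    sq_err += float(np.sum((pred - y[te]) ** 2))
                mse = sq_err / x.size
                self.cv_errors_[float(span)] = mse
                if mse < best_err - 1e-15 or (
                    abs(mse - best_err) <= 1e-15 and span > best_span
                ):
                    best_span, best_err = float(span), mse
            self.span_, self.cv_error_ = best_span, best_err
        return self

    def _predict_raw(
        self, x_new: np.ndarray, x_train: np.ndarray, y_train: np.ndarray, span: float
    ) -> np.ndarray:
        k = max(int(np.ceil(span * x_train.size)), self.degree + 2)
        k = min(k, x_train.size)
        lo, hi = x_train.min(), x_train.max()
        x_new = np.clip(x_new, lo, hi)  # no extrapolation beyond training range
        return np.array(
            [_local_quadratic(x_train, y_train, x0, k, self.degree) for x0 in x_new]
        )

    # -- prediction --------------------------------------------------------

    def predict(self, X) -> np.ndarray:
        """Loess prediction clamped to [0, 1] (it estimates an |correlation|)."""
        x_new = np.asarray(X, dtype=float).ravel()
        raw = self._predict_raw(x_new, self.x_, self.y_, self.span_)
        return np.clip(raw, 0.0, 1.0)

    def predict_one(self, distance_kb: float) -> float:
        if distance_kb <= 0:
            raise ValueError(f"distance must be positive, got {distance_kb}")
        return float(self.predict([distance_kb])[0])


def fit_loess(pairs: LDPairs, random_state: int = 0) -> LoessLDCurve:
    """Fit the LD-vs-distance loess curve with CV span selection."""
    return LoessLDCurve(random_state=random_state).fit(
        pairs.distances_kb, pairs.abs_correlations
    )


def predict_rho(curve: LoessLDCurve, distance_kb: float) -> float:
    """Predicted |correlation| at ``distance_kb``, clamped to [0, 1]."""
    return curve.predict_one(distance_kb)
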