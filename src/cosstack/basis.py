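"""Trend and confounding-adjustment bases.

Three basis families are supported for the process mean and for the outcome
regression:

* ``monthly_indicator`` — an intercept plus indicators of months 2..12 (month
  ``v`` is the interval ``(v-1, v)``); for interval-aggregated supports the
  indicators are averaged analytically as overlap fractions.
* ``fourier`` — an intercept plus sine/cosine pairs at chosen periods;
  interval averages use the exact trigonometric integrals.
* ``rbf_tensor`` — a tensor product of Gaussian radial basis functions in
  space (knots from k-means on block centroids) and time (evenly spaced
  knots), evaluated at block centroids and interval midpoints.  This is the
  basis used to absorb unmeasured spatial-temporal confounding, optionally
  orthogonalised against the covariates (restricted spatial regression).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist, pdist
from sklearn.cluster import KMeans

from .supports import BlockSupport, PointSupport, PredPoint

__all__ = [
    "BasisSpec",
    "monthly_indicator_spec",
    "fourier_spec",
    "fit_rbf_tensor",
    "build_basis",
    "rsr_adjust",
    "relative_effects",
]


@dataclass
class BasisSpec:
    kind: str
    n_months: int = 12
    periods: tuple = (4.0, 5.0, 6.0, 7.0)
    Ks: int = 0
    Kt: int = 0
    spatial_knots: np.ndarray | None = field(default=None, repr=False)
    temporal_knots: np.ndarray | None = field(default=None, repr=False)
    r1: float = 0.0
    r2: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("monthly_indicator", "fourier", "rbf_tensor"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "monthly_indicator" and self.n_months < 1:
            raise ValueError("n_months must be >= 1")
        if self.kind == "fourier" and (len(self.periods) == 0 or min(self.periods) <= 0):
            raise ValueError("fourier periods must be positive")

    @property
    def r(self) -> int:
        if self.kind == "monthly_indicator":
            return self.n_months  # intercept + (n_months - 1) indicators
        if self.kind == "fourier":
            return 1 + 2 * len(self.periods)
        return self.Ks * self.Kt


def monthly_indicator_spec(n_months: int = 12) -> BasisSpec:
    return BasisSpec(kind="monthly_indicator", n_months=n_months)


def fourier_spec(periods: Sequence[float] = (4.0, 5.0, 6.0, 7.0)) -> BasisSpec:
    return BasisSpec(kind="fourier", periods=tuple(float(p) for p in periods))


def fit_rbf_tensor(
    blocks: Sequence[BlockSupport],
    Ks: int,
    Kt: int,
    seed: int = 0,
) -> BasisSpec:
    """Fit the knots and scales of the space-time RBF tensor basis.

    Spatial knots come from k-means (10 restarts, fixed seed) on the block
    centroids, sorted lexicographically for determinism; temporal knots are
    evenly spaced over the span of the block intervals.  Both bandwidths are
    the median pairwise distance between the respective knots.
    """
    cents = np.array([(b.polygon.centroid.x, b.polygon.centroid.y) for b in blocks])
    distinct = np.unique(cents, axis=0)
    if Ks > len(distinct):
        raise ValueError(
            f"Ks={Ks} exceeds the number of distinct block centroids ({len(distinct)})"
        )
    if Ks < 1 or Kt < 1:
        raise ValueError("Ks and Kt must be >= 1")
    km = KMeans(n_clusters=Ks, n_init=10, random_state=seed).fit(cents)
    knots = km.cluster_centers_[np.lexsort(km.cluster_centers_.T[::-1])]
    r1 = float(np.median(pdist(knots))) if Ks > 1 else 1.0
    lo = min(b.interval.a for b in blocks)
    hi = max(b.interval.b for b in blocks)
    mids = np.array([b.interval.midpoint() for b in blocks])
    if Kt > 1:
        tk = np.linspace(lo, hi, Kt)
        r2 = float(np.median(pdist(tk[:, None])))
    else:
        tk = np.array([0.5 * (lo + hi)])
        r2 = 1.0
    del mids
    return BasisSpec(
        kind="rbf_tensor", Ks=Ks, Kt=Kt,
        spatial_knots=knots, temporal_knots=tk, r1=r1, r2=r2,
    )


def _interval_arrays(targets) -> tuple[np.ndarray, np.ndarray]:
    a = np.array([t.interval.a for t in targets])
    b = np.array([t.interval.b for t in targets])
    return a, b


def _monthly_columns(a: np.ndarray, b: np.ndarray, n_months: int) -> np.ndarray:
    length = b - a
    cols = [np.ones_like(a)]
    for v in range(2, n_months + 1):
        overlap = np.clip(np.minimum(b, v) - np.maximum(a, v - 1), 0.0, None)
        cols.append(overlap / length)
    return np.column_stack(cols)


def _monthly_columns_at(t: np.ndarray, n_months: int) -> np.ndarray:
    cols = [np.ones_like(t)]
    month = np.ceil(t).astype(int)
    for v in range(2, n_months + 1):
        cols.append((month == v).astype(float))
    return np.column_stack(cols)


def _fourier_columns(a: np.ndarray, b: np.ndarray, periods) -> np.ndarray:
    length = b - a
    cols = [np.ones_like(a)]
    for p in periods:
        w = 2.0 * np.pi / p
        cols.append((np.cos(w * a) - np.cos(w * b)) / (w * length))  # avg sin
        cols.append((np.sin(w * b) - np.sin(w * a)) / (w * length))  # avg cos
    return np.column_stack(cols)


def _fourier_columns_at(t: np.ndarray, periods) -> np.ndarray:
    cols = [np.ones_like(t)]
    for p in periods:
        w = 2.0 * np.pi / p
        cols.append(np.sin(w * t))
        cols.append(np.cos(w * t))
    return np.column_stack(cols)


def _rbf_columns(spec: BasisSpec, sites: np.ndarray, times: np.ndarray) -> np.ndarray:
    xi = np.exp(-cdist(sites, spec.spatial_knots) ** 2 / spec.r1**2)  # (n, Ks)
    if spec.Kt == 1:
        eta = np.ones((len(times), 1))  # single temporal knot: component omitted
    else:
        eta = np.exp(-((times[:, None] - spec.temporal_knots[None, :]) ** 2) / spec.r2**2)
    return (xi[:, :, None] * eta[:, None, :]).reshape(len(sites), -1)


def build_basis(spec: BasisSpec, targets) -> np.ndarray:
    """Evaluate the basis design matrix at point supports, blocks or points.

    Temporal bases are interval-averaged analytically for interval supports;
    the RBF tensor basis is evaluated at block centroids and interval
    midpoints.
    """
    targets = list(targets)
    if len(targets) == 0:
        raise ValueError("no targets to evaluate the basis at")
    first = targets[0]
    if spec.kind == "rbf_tensor":
        if spec.spatial_knots is None:
            raise ValueError("rbf_tensor basis must be fitted first (fit_rbf_tensor)")
        if isinstance(first, BlockSupport):
            sites = np.array(
                [(t.polygon.centroid.x, t.polygon.centroid.y) for t in targets]
            )
            times = np.array([t.interval.midpoint() for t in targets])
        elif isinstance(first, PointSupport):
            sites = np.array([t.site for t in targets])
            times = np.array([t.interval.midpoint() for t in targets])
        else:
            sites = np.array([t.site for t in targets])
            times = np.array([t.time for t in targets])
        return _rbf_columns(spec, sites, times)
    if isinstance(first, PredPoint):
        t = np.array([p.time for p in targets])
        if spec.kind == "monthly_indicator":
            return _monthly_columns_at(t, spec.n_months)
        return _fourier_columns_at(t, spec.periods)
    a, b = _interval_arrays(targets)
    if spec.kind == "monthly_indicator":
        return _monthly_columns(a, b, spec.n_months)
    return _fourier_columns(a, b, spec.periods)


def rsr_adjust(basis: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project basis columns onto the orthogonal complement of the covariates.

    Restricted spatial regression: returns ``(I - P_W) B`` where ``P_W`` is
    the orthogonal projector onto the column space of ``covariates``.
    """
    basis = np.atleast_2d(np.asarray(basis, dtype=float))
    W = np.atleast_2d(np.asarray(covariates, dtype=float))
    if np.linalg.matrix_rank(W) < W.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    Q, _ = np.linalg.qr(W)
    return basis - Q @ (Q.T @ basis)


def relative_effects(beta_draws: np.ndarray, contrast) -> dict:
    """Posterior draws and summaries of ``exp(c^T beta)`` for a contrast ``c``.

    ``contrast`` is either a coefficient index, a list of indices (summed), or
    a full weight vector.  Returns draws, posterior median and the central
    95% interval; by monotonicity the median of the ratio is the
    exponentiated median of the linear combination.
    """
    beta_draws = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    q = beta_draws.shape[1]
    c = np.zeros(q)
    if np.isscalar(contrast):
        c[int(contrast)] = 1.0
    else:
        contrast = np.asarray(contrast)
        if contrast.ndim == 1 and len(contrast) == q and contrast.dtype.kind == "f":
            c = contrast.astype(float)
        else:
            for idx in np.atleast_1d(contrast).astype(int):
                c[idx] += 1.0
    draws = np.exp(beta_draws @ c)
    lo, med, hi = np.quantile(draws, [0.025, 0.5, 0.975])
    return {"draws": draws, "median": float(med), "ci95": (float(lo), float(hi))}
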