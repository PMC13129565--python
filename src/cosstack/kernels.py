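"""Separable spatial-temporal correlation and change-of-support covariances.

The latent process has a separable correlation ``C(l, l') = C_s(s, s') *
C_t(t, t')`` with an isotropic Matérn spatial factor and an exponential
temporal factor ``exp(-phi2 |t - t'|)``.  Observations are averages of the
process over supports (site x interval, or polygon x interval), so covariance
matrices between observed quantities are averages of the kernel:

* temporal double/single integrals of the exponential factor admit closed
  forms dispatched over the disjoint / overlapping / nested interval cases;
* spatial integrals over irregular polygons are Monte-Carlo averages over a
  fixed uniform within-polygon sample, cached per polygon and reused for
  every matrix entry so the assembled block covariance is an exact covariance
  of finite averages.
"""

from __future__ import annotations

import warnings
import zlib
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammaln, kve

from .supports import (
    BlockSupport,
    KernelParams,
    PointSupport,
    PolygonSampleCache,
    PredPoint,
    TimeInterval,
)

try:  # fused distance+kernel loops for the big double averages
    import numba as _numba
except ImportError:  # pragma: no cover
    _numba = None

__all__ = [
    "matern_correlation",
    "temporal_block_integral",
    "temporal_point_integral",
    "polygon_mc_average",
    "GeometryCache",
    "build_cov_points",
    "build_cov_cross",
    "build_cov_blocks",
    "build_cov_pred",
    "check_min_eigenvalue",
    "clip_to_psd",
]


# ---------------------------------------------------------------------------
# correlation functions
# ---------------------------------------------------------------------------

def matern_correlation(d, phi1: float, nu: float):
    """Isotropic Matérn correlation ``(phi1 d)^nu K_nu(phi1 d) / (2^{nu-1} Gamma(nu))``.

    Returns 1 at zero distance (the Bessel limit is handled explicitly) and
    floors hard underflow at large ``phi1 * d`` to 0.  ``nu`` of 1/2, 3/2 and
    5/2 use the exponential-family closed forms.
    """
    if phi1 <= 0 or nu <= 0:
        raise ValueError("phi1 and nu must be strictly positive")
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("distances must be non-negative")
    x = phi1 * d_arr
    if nu == 0.5:
        out = np.exp(-x)
    elif nu == 1.5:
        out = (1.0 + x) * np.exp(-x)
    elif nu == 2.5:
        out = (1.0 + x + x * x / 3.0) * np.exp(-x)
    else:
        out = np.empty_like(x)
        small = x < 1e-12
        out[small] = 1.0
        xs = x[~small]
        with np.errstate(over="ignore", under="ignore"):
            # K_nu(x) = kve(nu, x) exp(-x); assemble in log space for stability
            log_pref = (1.0 - nu) * np.log(2.0) - gammaln(nu)
            vals = np.exp(log_pref + nu * np.log(xs) - xs) * kve(nu, xs)
        out[~small] = np.nan_to_num(vals, nan=0.0, posinf=0.0, neginf=0.0)
    out = np.clip(out, 0.0, 1.0)
    return out if out.ndim else float(out)


def _exp_leq0(arg: np.ndarray) -> np.ndarray:
    # all exponents of the closed forms are <= 0 in their applicable branch;
    # clipping keeps the inapplicable branches of np.where from overflowing
    return np.exp(np.minimum(arg, 0.0))


def _ct_block_matrix(ab1: np.ndarray, ab2: np.ndarray, phi2: float) -> np.ndarray:
    """Raw double integrals of ``exp(-phi2 |t - t'|)`` over interval pairs.

    ``ab1`` is ``(m, 2)``, ``ab2`` is ``(n, 2)``; returns ``(m, n)``.  The
    closed forms assume the first interval starts no later than the second,
    so interval pairs are canonically ordered first (the integral is
    symmetric in its arguments).  Each of the three interval configurations
    (disjoint / overlapping / nested) is evaluated in a cancellation-free
    ``expm1`` rearrangement: the textbook difference-of-exponentials form
    loses all precision when interval widths are tiny relative to 1/phi2.
    """
    a = ab1[:, 0][:, None]
    b = ab1[:, 1][:, None]
    c = ab2[:, 0][None, :]
    d = ab2[:, 1][None, :]
    swap = a > c
    a, c = np.where(swap, c, a), np.where(swap, a, c)
    b, d = np.where(swap, d, b), np.where(swap, b, d)

    def em(x):
        # 1 - exp(-phi2 x) for x >= 0, stable near 0
        return -np.expm1(-phi2 * np.clip(x, 0.0, None))

    def G(x):
        # phi2 x + exp(-phi2 x) - 1 >= 0, stable near 0
        x = np.clip(x, 0.0, None)
        return phi2 * x + np.expm1(-phi2 * x)

    disjoint = b <= c
    overlapping = (~disjoint) & (b <= d)
    # disjoint, gap = c - b: (1 - E(b-a)) E(gap) (1 - E(d-c))
    val_disjoint = em(b - a) * _exp_leq0(-phi2 * (c - b)) * em(d - c)
    # overlapping, offsets u = c - a, v = d - b, overlap L = b - c
    u, v, Lov = c - a, d - b, b - c
    val_overlap = 2.0 * G(Lov) + em(u) * em(v) + em(Lov) * em(u + v)
    # (c, d) nested in (a, b): u = c - a, M = d - c, v = b - d
    M, vn = d - c, b - d
    val_nested = 2.0 * G(M) + em(M) * (em(u) + em(vn))
    out = np.where(disjoint, val_disjoint, np.where(overlapping, val_overlap, val_nested))
    return out / (phi2 * phi2)


def temporal_block_integral(I1: TimeInterval, I2: TimeInterval, phi2: float) -> float:
    """Closed-form ``\\int_{I2}\\int_{I1} exp(-phi2 |t - t'|) dt dt'``."""
    if phi2 <= 0:
        raise ValueError("phi2 must be strictly positive")
    ab1 = np.array([[I1.a, I1.b]])
    ab2 = np.array([[I2.a, I2.b]])
    return float(_ct_block_matrix(ab1, ab2, phi2)[0, 0])


def _ct_point_matrix(t0: np.ndarray, ab: np.ndarray, phi2: float) -> np.ndarray:
    """Raw single integrals ``\\int_a^b exp(-phi2 |t0 - t|) dt``; (m,) x (n,2) -> (m,n)."""
    t = np.asarray(t0, dtype=float)[:, None]
    a = ab[:, 0][None, :]
    b = ab[:, 1][None, :]
    below = t <= a
    above = t >= b
    val_below = (_exp_leq0(-phi2 * (a - t)) - _exp_leq0(-phi2 * (b - t))) / phi2
    val_above = (_exp_leq0(-phi2 * (t - b)) - _exp_leq0(-phi2 * (t - a))) / phi2
    val_inside = (2.0 - _exp_leq0(-phi2 * (t - a)) - _exp_leq0(-phi2 * (b - t))) / phi2
    return np.where(below, val_below, np.where(above, val_above, val_inside))


def temporal_point_integral(t0: float, I: TimeInterval, phi2: float) -> float:
    """Closed-form ``\\int_I exp(-phi2 |t0 - t|) dt``."""
    if phi2 <= 0:
        raise ValueError("phi2 must be strictly positive")
    return float(_ct_point_matrix(np.array([t0]), np.array([[I.a, I.b]]), phi2)[0, 0])


# ---------------------------------------------------------------------------
# Monte Carlo spatial averaging
# ---------------------------------------------------------------------------

def polygon_mc_average(f, B, n_mc: int = 500, seed: int = 0) -> float:
    """Monte-Carlo average of a kernel over a polygon or a polygon pair.

    For a single polygon ``B``, approximates ``|B|^{-1} \\int_B f(s) ds`` by
    the mean of ``f`` over a cached uniform within-polygon sample; ``f`` maps
    an ``(n, 2)`` point array to ``n`` values.  For a pair ``(B1, B2)``,
    approximates the double average; ``f`` then maps two point arrays to an
    ``(n, m)`` matrix of kernel evaluations.
    """
    if isinstance(B, (tuple, list)):
        B1, B2 = B
        c1 = PolygonSampleCache(B1, seed=seed, n_mc=n_mc)
        c2 = PolygonSampleCache(B2, seed=seed + 1, n_mc=n_mc)
        return float(np.mean(f(c1.points, c2.points)))
    cache = PolygonSampleCache(B, seed=seed, n_mc=n_mc)
    return float(np.mean(f(cache.points)))


if _numba is not None:

    @_numba.njit(fastmath=True, cache=False)
    def _pair_avg_halfint(pts, offsets, phi1, half_order):  # pragma: no cover
        """Block-pair double averages for half-integer Matérn (0.5/1.5/2.5).

        Fusing the distance and kernel evaluation avoids materialising the
        (total points)^2 distance matrix, which dominates the cost of the
        block-block covariance at realistic block counts.
        """
        K = len(offsets) - 1
        out = np.empty((K, K))
        for k1 in range(K):
            for k2 in range(k1, K):
                acc = 0.0
                for i in range(offsets[k1], offsets[k1 + 1]):
                    x1 = pts[i, 0]
                    y1 = pts[i, 1]
                    for j in range(offsets[k2], offsets[k2 + 1]):
                        dx = x1 - pts[j, 0]
                        dy = y1 - pts[j, 1]
                        x = phi1 * np.sqrt(dx * dx + dy * dy)
                        if half_order == 0:
                            acc += np.exp(-x)
                        elif half_order == 1:
                            acc += (1.0 + x) * np.exp(-x)
                        else:
                            acc += (1.0 + x + x * x / 3.0) * np.exp(-x)
                n1 = offsets[k1 + 1] - offsets[k1]
                n2 = offsets[k2 + 1] - offsets[k2]
                out[k1, k2] = acc / (n1 * n2)
                out[k2, k1] = out[k1, k2]
        return out


# ---------------------------------------------------------------------------
# geometry cache and covariance assembly
# ---------------------------------------------------------------------------

def _unique_rows(arr: np.ndarray):
    uniq, inv = np.unique(arr, axis=0, return_inverse=True)
    return uniq, inv.ravel()


def _derive_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([int(master), int(index)]).generate_state(1)[0])


def _polygon_seed(master: int, poly) -> int:
    # seed from the geometry itself: identical polygons share their sample,
    # so duplicated block supports yield exactly equal covariance entries
    digest = zlib.crc32(poly.wkb) % (2**31)
    return _derive_seed(master, digest)


class GeometryCache:
    """Caches geometry-dependent pieces of the covariance constructions.

    Sites and intervals of point supports usually repeat heavily (the same
    stations observed over many months), so spatial and temporal factors are
    computed on the unique sets and expanded by indexing.  Spatial factors
    depend only on ``(phi1, nu)`` and temporal factors only on ``phi2``;
    both are memoised so a grid of candidate models shares them.
    """

    def __init__(
        self,
        supports: Sequence[PointSupport] | None = None,
        blocks: Sequence[BlockSupport] | None = None,
        n_mc: int = 500,
        seed: int = 0,
    ):
        self.n_mc = int(n_mc)
        self.seed = int(seed)
        if supports is not None and len(supports) > 0:
            self.sites = np.array([s.site for s in supports], dtype=float)
            self.ab = np.array(
                [[s.interval.a, s.interval.b] for s in supports], dtype=float
            )
            self.lengths = self.ab[:, 1] - self.ab[:, 0]
            self.usites, self.site_inv = _unique_rows(self.sites)
            self.uab, self.ab_inv = _unique_rows(self.ab)
            self._usite_dist = cdist(self.usites, self.usites)
        else:
            self.sites = None
        self.blocks = list(blocks) if blocks is not None else None
        if self.blocks:
            self.block_caches = [
                PolygonSampleCache(
                    blk.polygon, seed=_polygon_seed(self.seed, blk.polygon), n_mc=self.n_mc
                )
                for blk in self.blocks
            ]
            self.block_ab = np.array(
                [[blk.interval.a, blk.interval.b] for blk in self.blocks], dtype=float
            )
            self.block_lengths = self.block_ab[:, 1] - self.block_ab[:, 0]
            self.block_areas = np.array([blk.area for blk in self.blocks])
            self._cross_dists = None
        self._spatial_pp: dict = {}
        self._spatial_pb: dict = {}
        self._spatial_bb: dict = {}
        self._temporal: dict = {}

    # -- spatial factors ----------------------------------------------------

    def spatial_points(self, phi1: float, nu: float) -> np.ndarray:
        key = (phi1, nu)
        if key not in self._spatial_pp:
            self._spatial_pp[key] = matern_correlation(self._usite_dist, phi1, nu)
        return self._spatial_pp[key]

    def _cross_distances(self):
        # unique sites x (block, mc sample) distances, computed once
        if self._cross_dists is None:
            self._cross_dists = [
                cdist(self.usites, c.points) for c in self.block_caches
            ]
        return self._cross_dists

    def spatial_cross(self, phi1: float, nu: float) -> np.ndarray:
        """Unique-site x block matrix of within-polygon kernel averages."""
        key = (phi1, nu)
        if key not in self._spatial_pb:
            cols = [
                matern_correlation(d, phi1, nu).mean(axis=1)
                for d in self._cross_distances()
            ]
            self._spatial_pb[key] = np.column_stack(cols)
        return self._spatial_pb[key]

    def spatial_blocks(self, phi1: float, nu: float) -> np.ndarray:
        """Block x block matrix of double within-polygon kernel averages."""
        key = (phi1, nu)
        if key in self._spatial_bb:
            return self._spatial_bb[key]
        K = len(self.blocks)
        pts = [c.points for c in self.block_caches]
        counts = np.array([len(p) for p in pts])
        allpts = np.vstack(pts)
        offsets = np.concatenate([[0], np.cumsum(counts)])
        if _numba is not None and nu in (0.5, 1.5, 2.5):
            half = {0.5: 0, 1.5: 1, 2.5: 2}[nu]
            out = _pair_avg_halfint(allpts, offsets.astype(np.int64), phi1, half)
            self._spatial_bb[key] = out
            return out
        out = np.empty((K, K))
        for k in range(K):
            tail = allpts[offsets[k] :]
            vals = matern_correlation(cdist(pts[k], tail), phi1, nu)
            starts = offsets[k:-1] - offsets[k]
            seg_sums = np.add.reduceat(vals, starts, axis=1)
            row = seg_sums.sum(axis=0) / (counts[k] * counts[k:])
            out[k, k:] = row
            out[k:, k] = row
        self._spatial_bb[key] = out
        return out

    # -- temporal factors ---------------------------------------------------

    def _temporal_entry(self, phi2: float) -> dict:
        if phi2 not in self._temporal:
            self._temporal[phi2] = {}
        return self._temporal[phi2]

    def temporal_points(self, phi2: float) -> np.ndarray:
        ent = self._temporal_entry(phi2)
        if "pp" not in ent:
            ulen = self.uab[:, 1] - self.uab[:, 0]
            raw = _ct_block_matrix(self.uab, self.uab, phi2)
            ent["pp"] = raw / np.outer(ulen, ulen)
        return ent["pp"]

    def temporal_cross(self, phi2: float) -> np.ndarray:
        ent = self._temporal_entry(phi2)
        if "pb" not in ent:
            ulen = self.uab[:, 1] - self.uab[:, 0]
            raw = _ct_block_matrix(self.uab, self.block_ab, phi2)
            ent["pb"] = raw / np.outer(ulen, self.block_lengths)
        return ent["pb"]

    def temporal_blocks(self, phi2: float) -> np.ndarray:
        ent = self._temporal_entry(phi2)
        if "bb" not in ent:
            raw = _ct_block_matrix(self.block_ab, self.block_ab, phi2)
            ent["bb"] = raw / np.outer(self.block_lengths, self.block_lengths)
        return ent["bb"]

    # -- assembled covariances ---------------------------------------------

    def cov_points(self, kp: KernelParams) -> np.ndarray:
        """N x N correlation matrix of the interval-averaged process at supports."""
        Cs = self.spatial_points(kp.phi1, kp.nu)[np.ix_(self.site_inv, self.site_inv)]
        Ct = self.temporal_points(kp.phi2)[np.ix_(self.ab_inv, self.ab_inv)]
        C = Cs * Ct
        return 0.5 * (C + C.T)

    def cov_cross(self, kp: KernelParams) -> np.ndarray:
        """N x K cross-covariance between point supports and blocks."""
        Cs = self.spatial_cross(kp.phi1, kp.nu)[self.site_inv, :]
        Ct = self.temporal_cross(kp.phi2)[self.ab_inv, :]
        return Cs * Ct

    def cov_blocks(self, kp: KernelParams) -> np.ndarray:
        """K x K covariance of block-and-interval averages of the process."""
        C = self.spatial_blocks(kp.phi1, kp.nu) * self.temporal_blocks(kp.phi2)
        return 0.5 * (C + C.T)

    def cov_pred(self, kp: KernelParams, pred: Sequence[PredPoint]):
        """(N* x N cross matrix, N* x N* exact-kernel matrix) for point prediction."""
        psites = np.array([p.site for p in pred], dtype=float)
        ptimes = np.array([p.time for p in pred], dtype=float)
        Cs_pp = matern_correlation(cdist(psites, psites), kp.phi1, kp.nu)
        Ct_pp = np.exp(-kp.phi2 * np.abs(ptimes[:, None] - ptimes[None, :]))
        C_pred = Cs_pp * Ct_pp
        np.fill_diagonal(C_pred, 1.0)
        Cs_px = matern_correlation(cdist(psites, self.usites), kp.phi1, kp.nu)[
            :, self.site_inv
        ]
        Ct_px = (_ct_point_matrix(ptimes, self.uab, kp.phi2) / (self.uab[:, 1] - self.uab[:, 0]))[
            :, self.ab_inv
        ]
        return Cs_px * Ct_px, C_pred


def _check_supports(supports):
    if len(supports) == 0:
        raise ValueError("need at least one support")


def build_cov_points(supports: Sequence[PointSupport], kp: KernelParams) -> np.ndarray:
    """Covariance (correlation-scale) matrix of interval-averaged point supports."""
    _check_supports(supports)
    C = GeometryCache(supports=supports).cov_points(kp)
    if len(supports) > 1:
        sign, logdet = np.linalg.slogdet(C + 1e-12 * np.eye(len(C)))
        if sign <= 0 or not np.isfinite(logdet):
            warnings.warn("covariance matrix is singular (duplicate supports?)")
    return C


def build_cov_cross(
    supports: Sequence[PointSupport],
    blocks: Sequence[BlockSupport],
    kp: KernelParams,
    n_mc: int = 500,
    seed: int = 0,
) -> np.ndarray:
    _check_supports(supports)
    _check_supports(blocks)
    cache = GeometryCache(supports=supports, blocks=blocks, n_mc=n_mc, seed=seed)
    return cache.cov_cross(kp)


def build_cov_blocks(
    blocks: Sequence[BlockSupport],
    kp: KernelParams,
    n_mc: int = 500,
    seed: int = 0,
) -> np.ndarray:
    _check_supports(blocks)
    cache = GeometryCache(blocks=blocks, n_mc=n_mc, seed=seed)
    return cache.cov_blocks(kp)


def build_cov_pred(
    pred: Sequence[PredPoint],
    supports: Sequence[PointSupport],
    kp: KernelParams,
):
    _check_supports(pred)
    _check_supports(supports)
    return GeometryCache(supports=supports).cov_pred(kp, pred)


# ---------------------------------------------------------------------------
# PSD utilities
# ---------------------------------------------------------------------------

def check_min_eigenvalue(mat: np.ndarray, rtol: float = 1e-8) -> float:
    """Smallest eigenvalue; raises if below ``-rtol`` times the spectral norm."""
    w = np.linalg.eigvalsh(0.5 * (mat + mat.T))
    lo, hi = w[0], max(abs(w[-1]), 1.0)
    if lo < -rtol * hi:
        raise np.linalg.LinAlgError(
            f"matrix not PSD within tolerance: min eig {lo:.3e} vs norm {hi:.3e}"
        )
    return float(lo)


def clip_to_psd(mat: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Zero slightly negative eigenvalues; error if negativity exceeds tolerance.

    Monte-Carlo-estimated cross-covariances can break positive definiteness
    marginally; eigenvalues in ``(-rtol * lambda_max, 0)`` are clipped to 0,
    anything more negative signals an inconsistent covariance and raises.
    """
    sym = 0.5 * (mat + mat.T)
    w, V = np.linalg.eigh(sym)
    hi = max(abs(w[-1]), 1e-300)
    if w[0] < -rtol * hi:
        raise np.linalg.LinAlgError(
            f"conditional covariance has eigenvalue {w[0]:.3e} beyond tolerance"
        )
    w = np.clip(w, 0.0, None)
    return (V * w) @ V.T
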