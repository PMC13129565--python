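"""Cut-model conjugate hierarchical Gaussian-process regression.

The hierarchy has two modules.  Module 2 regresses interval-averaged noisy
point measurements ``X`` on a latent separable GP with basis-function trend
``Psi gamma`` and conjugate Normal-Inverse-Gamma priors ``(gamma, sigma2)``;
its posterior is available in closed form for fixed kernel parameters.
Module 1 is a weighted Bayesian linear regression of block outcomes ``Y`` on
confounders and the block-averaged latent process ``Z_L``, with conjugate
``(beta, tau2)``.  Inference is *modular* (a cut model): the outcome never
feeds back into the latent process, so Module 2 is fit from ``X`` alone and
its uncertainty is propagated into Module 1 by refitting the regression for
every posterior draw of ``Z_L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as sla

from .kernels import GeometryCache, clip_to_psd
from .supports import BlockSupport, KernelParams, PointSupport, PredPoint

__all__ = [
    "PriorConfig",
    "ExposureData",
    "OutcomeData",
    "Module2Posterior",
    "Module2Draws",
    "OutcomeFit",
    "fit_module2",
    "sample_module2",
    "predict_blocks",
    "predict_points",
    "fit_module1",
]


def _chol_spd(mat: np.ndarray, what: str) -> np.ndarray:
    try:
        return sla.cholesky(mat, lower=True)
    except sla.LinAlgError as exc:
        raise sla.LinAlgError(f"Cholesky factorization of {what} failed: {exc}") from exc


@dataclass
class PriorConfig:
    """Fixed hyperparameters of the conjugate priors.

    ``beta | tau2 ~ N(mu_beta, tau2 V_beta)``, ``tau2 ~ IG(a_tau, b_tau)``,
    ``gamma | sigma2 ~ N(mu_gamma, sigma2 V_gamma)``, ``sigma2 ~ IG(a_sigma,
    b_sigma)``.  The default is a weakly informative choice: zero means,
    ``V = 1000 I`` and ``IG(2, 0.1)`` for both variances.
    """

    mu_beta: np.ndarray
    V_beta: np.ndarray
    mu_gamma: np.ndarray
    V_gamma: np.ndarray
    a_tau: float = 2.0
    b_tau: float = 0.1
    a_sigma: float = 2.0
    b_sigma: float = 0.1

    def __post_init__(self) -> None:
        self.mu_beta = np.atleast_1d(np.asarray(self.mu_beta, dtype=float))
        self.mu_gamma = np.atleast_1d(np.asarray(self.mu_gamma, dtype=float))
        self.V_beta = np.atleast_2d(np.asarray(self.V_beta, dtype=float))
        self.V_gamma = np.atleast_2d(np.asarray(self.V_gamma, dtype=float))
        for name, V in (("V_beta", self.V_beta), ("V_gamma", self.V_gamma)):
            if not np.allclose(V, V.T):
                raise ValueError(f"{name} must be symmetric")
            _chol_spd(V, name)
        for name in ("a_tau", "b_tau", "a_sigma", "b_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def default(cls, r: int, p: int = 1, scale: float = 1e3,
                a: float = 2.0, b: float = 0.1) -> "PriorConfig":
        return cls(
            mu_beta=np.zeros(p + 1),
            V_beta=scale * np.eye(p + 1),
            mu_gamma=np.zeros(r),
            V_gamma=scale * np.eye(r),
            a_tau=a, b_tau=b, a_sigma=a, b_sigma=b,
        )


@dataclass
class ExposureData:
    """Point-referenced interval-aggregated observations of the exposure.

    Missing records are simply absent rows (the design is unbalanced, never
    imputed).  ``d_weights`` holds the reciprocal interval lengths that scale
    the measurement-error variance.
    """

    supports: list
    x: np.ndarray
    basis: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float).ravel()
        self.basis = np.atleast_2d(np.asarray(self.basis, dtype=float))
        n = len(self.supports)
        if self.basis.shape[0] != n or self.x.shape[0] != n:
            raise ValueError("supports, x and basis must have matching lengths")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("x contains non-finite values; drop missing rows instead")
        self.lengths = np.array([s.interval.length() for s in self.supports])
        self.d_weights = 1.0 / self.lengths

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class OutcomeData:
    """Block-referenced outcomes with confounders.

    The noise variance of outcome ``k`` is ``tau2 / (|B_k| |I_k|)`` (block
    volume) by default, or ``tau2 / |B_k|`` with ``variance_form="area"``.
    Raw map areas are rescaled to mean 1 so that ``tau2`` stays on the scale
    of the outcome.
    """

    blocks: list
    y: np.ndarray
    W: np.ndarray
    basis: np.ndarray | None = None
    variance_form: str = "volume"
    rescale_areas: bool = True

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        K = len(self.blocks)
        if self.y.shape[0] != K or self.W.shape[0] != K:
            raise ValueError("blocks, y and W must have matching lengths")
        if np.linalg.matrix_rank(self.W) < self.W.shape[1]:
            raise ValueError("confounder matrix W is rank deficient")
        areas = np.array([b.area for b in self.blocks])
        if self.rescale_areas:
            areas = areas / areas.mean()
        lengths = np.array([b.interval.length() for b in self.blocks])
        if self.variance_form == "volume":
            self.volumes = areas * lengths
        elif self.variance_form == "area":
            self.volumes = areas
        else:
            raise ValueError("variance_form must be 'volume' or 'area'")
        # D_L = diag(1 / volume); its inverse (the precision weights) is `volumes`
        self.d_weights = 1.0 / self.volumes

    @property
    def k(self) -> int:
        return len(self.y)


@dataclass
class Module2Posterior:
    """Closed-form posterior factors of the exposure module for one candidate."""

    kp: KernelParams
    chol_VX: np.ndarray
    M_gamma: np.ndarray
    m_gamma: np.ndarray
    gamma_mean: np.ndarray
    chol_M_gamma: np.ndarray
    Mz: np.ndarray
    chol_Mz: np.ndarray
    a_sigma_star: float
    b_sigma_star: float
    _chol_C: np.ndarray | None = field(default=None, repr=False)

    def chol_C(self, C: np.ndarray) -> np.ndarray:
        """Cholesky of the latent covariance, cached on first use."""
        if self._chol_C is None:
            jitter = 1e-10 * np.trace(C) / len(C)
            try:
                self._chol_C = sla.cholesky(C, lower=True)
            except sla.LinAlgError:
                self._chol_C = sla.cholesky(
                    C + jitter * 1e2 * np.eye(len(C)), lower=True
                )
        return self._chol_C


@dataclass
class Module2Draws:
    """Composition-sampled posterior draws from the exposure module."""

    sigma2: np.ndarray
    gamma: np.ndarray
    z: np.ndarray
    model: str = ""
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 draws must be positive")
        B = len(self.sigma2)
        if self.gamma.shape[0] != B or self.z.shape[0] != B:
            raise ValueError("draw arrays have inconsistent first dimension")

    @property
    def n_draws(self) -> int:
        return len(self.sigma2)


@dataclass
class OutcomeFit:
    """Per-draw conjugate regression posterior of the outcome module."""

    tau2: np.ndarray
    beta: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        if np.any(self.tau2 <= 0):
            raise ValueError("tau2 draws must be positive")


def fit_module2(
    data: ExposureData,
    kp: KernelParams,
    priors: PriorConfig,
    cache: GeometryCache | None = None,
) -> Module2Posterior:
    """Closed-form posterior of the exposure module for fixed kernel parameters.

    All factors are computed once: the Cholesky of ``V_X = C + delta2 D``,
    the Gaussian factor ``(M_gamma, m_gamma)`` of the trend coefficients, the
    inverse-gamma update ``(a*, b*)`` of the process variance, and the latent
    conditional covariance ``M_z`` obtained through the identity
    ``M_z = delta2 D V_X^{-1} C``.
    """
    N, r = data.basis.shape
    if N < r:
        raise ValueError("need at least as many observations as basis columns")
    if cache is None:
        cache = GeometryCache(supports=data.supports)
    C = cache.cov_points(kp)
    V = C.copy()
    idx = np.diag_indices(N)
    V[idx] += kp.delta2 * data.d_weights
    try:
        L = sla.cholesky(V, lower=True)
    except sla.LinAlgError as exc:
        raise sla.LinAlgError(
            f"V_X ill-conditioned for candidate ({kp.label()}): {exc}"
        ) from exc
    Vi_Psi = sla.cho_solve((L, True), data.basis)
    Vi_X = sla.cho_solve((L, True), data.x)
    Lg = _chol_spd(priors.V_gamma, "V_gamma")
    Vg_inv = sla.cho_solve((Lg, True), np.eye(r))
    Mg_inv = data.basis.T @ Vi_Psi + Vg_inv
    L_Mg_inv = _chol_spd(Mg_inv, "M_gamma^{-1}")
    M_gamma = sla.cho_solve((L_Mg_inv, True), np.eye(r))
    M_gamma = 0.5 * (M_gamma + M_gamma.T)
    m_gamma = data.basis.T @ Vi_X + Vg_inv @ priors.mu_gamma
    gamma_mean = sla.cho_solve((L_Mg_inv, True), m_gamma)
    a_star = priors.a_sigma + N / 2.0
    b_star = priors.b_sigma + 0.5 * (
        data.x @ Vi_X
        + priors.mu_gamma @ (Vg_inv @ priors.mu_gamma)
        - m_gamma @ gamma_mean
    )
    if b_star <= 0:
        raise ValueError(f"non-positive b_sigma* for candidate ({kp.label()})")
    Mz = kp.delta2 * data.d_weights[:, None] * sla.cho_solve((L, True), C)
    Mz = 0.5 * (Mz + Mz.T)
    try:
        L_Mz = sla.cholesky(Mz, lower=True)
    except sla.LinAlgError:
        L_Mz = sla.cholesky(Mz + 1e-10 * np.trace(Mz) / N * np.eye(N), lower=True)
    return Module2Posterior(
        kp=kp,
        chol_VX=L,
        M_gamma=M_gamma,
        m_gamma=m_gamma,
        gamma_mean=gamma_mean,
        chol_M_gamma=_chol_spd(M_gamma, "M_gamma"),
        Mz=Mz,
        chol_Mz=L_Mz,
        a_sigma_star=a_star,
        b_sigma_star=float(b_star),
    )


def sample_module2(
    post: Module2Posterior,
    data: ExposureData,
    B: int,
    seed: int,
) -> Module2Draws:
    """Composition sampling: ``sigma2``, then ``gamma | sigma2``, then
    ``Z | gamma, sigma2`` with ``m_z = (X - Psi gamma) / delta2``."""
    if B < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    N = data.n
    r = data.basis.shape[1]
    sigma2 = post.b_sigma_star / rng.gamma(post.a_sigma_star, 1.0, size=B)
    sd = np.sqrt(sigma2)
    gamma = (
        post.gamma_mean[None, :]
        + sd[:, None] * (rng.standard_normal((B, r)) @ post.chol_M_gamma.T)
    )
    trend = gamma @ data.basis.T  # (B, N)
    # full conditional mean of Z: trend + M_z D^{-1} (X - trend) / delta2;
    # M_z is symmetric so the per-draw products are row-vector multiplies
    mz = (data.lengths[None, :] * (data.x[None, :] - trend)) / post.kp.delta2
    z_mean = trend + mz @ post.Mz
    z = z_mean + sd[:, None] * (rng.standard_normal((B, N)) @ post.chol_Mz.T)
    return Module2Draws(sigma2=sigma2, gamma=gamma, z=z, model=post.kp.label(), seed=seed)


def _conditional_factor(cond: np.ndarray, rtol: float = 1e-8) -> np.ndarray:
    """Square-root factor of a conditional covariance, after PSD clipping."""
    sym = clip_to_psd(cond, rtol=rtol)
    w, V = np.linalg.eigh(sym)
    return V * np.sqrt(np.clip(w, 0.0, None))


def predict_blocks(
    draws: Module2Draws,
    post: Module2Posterior,
    data: ExposureData,
    blocks: Sequence[BlockSupport],
    block_basis: np.ndarray,
    cache: GeometryCache,
    seed: int,
) -> np.ndarray:
    """Per-draw sampling of the block-averaged latent process ``Z_L``.

    The conditional moments follow the joint law of the process at the two
    resolutions; the conditional covariance is computed once per candidate
    and clipped to PSD (Monte-Carlo spatial averaging can leave it very
    slightly indefinite).  Returns a ``(B, K)`` array.
    """
    if len(blocks) == 0 or draws.n_draws == 0:
        raise ValueError("need draws and at least one block")
    kp = post.kp
    C = cache.cov_points(kp)
    C_cross = cache.cov_cross(kp)
    C_blk = cache.cov_blocks(kp)
    Lc = post.chol_C(C)
    A = sla.cho_solve((Lc, True), C_cross)  # C^{-1} C_cross, (N, K)
    cond = C_blk - C_cross.T @ A
    F = _conditional_factor(cond)
    block_basis = np.atleast_2d(block_basis)
    resid = draws.z - draws.gamma @ data.basis.T  # (B, N)
    mu = draws.gamma @ block_basis.T + resid @ A  # (B, K)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((draws.n_draws, len(blocks))) @ F.T
    return mu + np.sqrt(draws.sigma2)[:, None] * noise


def predict_points(
    draws: Module2Draws,
    post: Module2Posterior,
    data: ExposureData,
    pred: Sequence[PredPoint],
    point_basis: np.ndarray,
    cache: GeometryCache,
    seed: int,
) -> np.ndarray:
    """Per-draw sampling of the latent process at exact space-time points."""
    if len(pred) == 0 or draws.n_draws == 0:
        raise ValueError("need draws and at least one prediction point")
    kp = post.kp
    C = cache.cov_points(kp)
    C_cross, C_pred = cache.cov_pred(kp, pred)  # (N*, N), (N*, N*)
    Lc = post.chol_C(C)
    A = sla.cho_solve((Lc, True), C_cross.T)  # (N, N*)
    cond = C_pred - C_cross @ A
    F = _conditional_factor(cond)
    point_basis = np.atleast_2d(point_basis)
    resid = draws.z - draws.gamma @ data.basis.T
    mu = draws.gamma @ point_basis.T + resid @ A
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((draws.n_draws, len(pred))) @ F.T
    return mu + np.sqrt(draws.sigma2)[:, None] * noise


def fit_module1(
    outcome: OutcomeData,
    zl_draws: np.ndarray,
    priors: PriorConfig,
    extra_basis: np.ndarray | None = None,
    rsr: bool = False,
    seed: int = 0,
) -> OutcomeFit:
    """Outcome regression refit for every draw of the block-level process.

    For each draw ``b`` the design is ``[W, Z_L(b)]``, optionally augmented
    with confounding-adjustment basis columns (orthogonalised against the
    covariates per draw when ``rsr=True``), and the conjugate
    Normal-Inverse-Gamma update is applied with precision weights given by
    the block volumes.  Sampling ``(tau2, beta)`` once per ``Z_L`` draw
    propagates the latent-process uncertainty modularly.
    """
    zl_draws = np.atleast_2d(zl_draws)
    B, K = zl_draws.shape
    if K != outcome.k:
        raise ValueError("Z_L draws do not match the number of blocks")
    W = outcome.W
    p = W.shape[1]
    q = 0 if extra_basis is None else np.atleast_2d(extra_basis).shape[1]
    ncol = p + 1 + q
    if K <= ncol:
        raise ValueError("need more blocks than regression columns")
    # extend the beta prior block-diagonally over any basis columns, using the
    # same prior scale
    Vb = priors.V_beta
    if Vb.shape[0] != p + 1:
        raise ValueError("V_beta must be (p+1) x (p+1) for W with p columns")
    scale = float(np.mean(np.diag(Vb)))
    V_full = np.zeros((ncol, ncol))
    V_full[: p + 1, : p + 1] = Vb
    if q:
        V_full[p + 1 :, p + 1 :] = scale * np.eye(q)
    mu_full = np.zeros(ncol)
    mu_full[: p + 1] = priors.mu_beta
    Lv = _chol_spd(V_full, "V_beta (extended)")
    Vb_inv = sla.cho_solve((Lv, True), np.eye(ncol))
    prior_quad = mu_full @ (Vb_inv @ mu_full)
    vol = outcome.volumes  # D_L^{-1} diagonal
    y = outcome.y
    y_quad = y @ (vol * y)
    a_star = priors.a_tau + K / 2.0

    rng = np.random.default_rng(seed)
    tau2 = np.empty(B)
    beta = np.empty((B, ncol))
    basis = None if extra_basis is None else np.atleast_2d(np.asarray(extra_basis, float))
    from .basis import rsr_adjust  # local import to avoid a cycle

    for b in range(B):
        Wt = np.column_stack([W, zl_draws[b]])
        if basis is not None:
            cols = rsr_adjust(basis, Wt) if rsr else basis
            Wfull = np.column_stack([Wt, cols])
        else:
            Wfull = Wt
        Mb_inv = (Wfull * vol[:, None]).T @ Wfull + Vb_inv
        try:
            Lm = sla.cholesky(Mb_inv, lower=True)
        except sla.LinAlgError as exc:
            raise sla.LinAlgError(
                f"rank-deficient outcome design at draw {b}: {exc}"
            ) from exc
        m_b = Wfull.T @ (vol * y) + Vb_inv @ mu_full
        mean_b = sla.cho_solve((Lm, True), m_b)
        b_star = priors.b_tau + 0.5 * (y_quad + prior_quad - m_b @ mean_b)
        tau2[b] = b_star / rng.gamma(a_star, 1.0)
        # beta | tau2 ~ N(M m, tau2 M); sample via the factor of M_b^{-1}
        zvec = rng.standard_normal(ncol)
        beta[b] = mean_b + np.sqrt(tau2[b]) * sla.solve_triangular(
            Lm, zvec, lower=True, trans="T"
        )
    columns = (
        [f"w{i}" for i in range(1, p + 1)]
        + ["z_block"]
        + [f"basis{i}" for i in range(1, q + 1)]
    )
    return OutcomeFit(tau2=tau2, beta=beta, columns=columns)
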