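"""Synthetic data with the structure of misaligned exposure/outcome studies.

The generator emulates a monitoring-network design: a latent separable GP is
sampled daily at randomly placed sites over a year, with a smooth periodic
temporal mean; daily values plus measurement noise are aggregated to monthly
site means, a fraction of which is discarded at random.  Block supports are
quarterly Voronoi tessellations of the unit square, the block-level latent
truth is drawn from its exact conditional law given the simulated fine grid,
and block outcomes add confounders, an unmeasured spatially-structured field
with controlled correlation to the exposure, and heteroskedastic noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla
from scipy.spatial import Voronoi
from scipy.spatial.distance import cdist
from shapely.geometry import Polygon, box

from .kernels import GeometryCache, _ct_point_matrix, clip_to_psd, matern_correlation
from .supports import BlockSupport, KernelParams, PointSupport, TimeInterval

__all__ = ["SimConfig", "SimDataset", "simulate_exposure", "make_blocks", "simulate_outcome"]


@dataclass
class SimConfig:
    """Study-design parameters of the reference simulation.

    Defaults reproduce the reference design: 100 sites, 360 daily time points
    over 12 months on the unit square, exponential-in-space (phi1=4, nu=0.5)
    and exponential-in-time (phi2=0.6) kernel with unit process variance,
    unit daily measurement-error variance, a periodic GP temporal mean
    (level 5, variance 4, period 7, decay 0.1), 10% missing monthly records,
    and quarterly Voronoi block counts (40, 50, 30, 60).
    """

    ns: int = 100
    nt: int = 360
    t_max: float = 12.0
    phi1: float = 4.0
    nu: float = 0.5
    phi2: float = 0.6
    sigma2: float = 1.0
    noise_var: float = 1.0
    mean_level: float = 5.0
    mean_var: float = 4.0
    period: float = 7.0
    lam: float = 0.1
    periodic_convention: str = "printed"  # exp(-2 lam^2 sin^2); "standard": exp(-2 sin^2 / lam^2)
    missing_frac: float = 0.1
    blocks_per_quarter: tuple = (40, 50, 30, 60)
    beta1: tuple = (1.0, 1.0)
    beta2: float = 1.0
    rho: float = 0.5
    outcome_sd: float = 0.5
    block_noise: bool = False
    n_mc: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ns < 1 or self.nt < 1:
            raise ValueError("ns and nt must be >= 1")
        if not 0.0 <= self.missing_frac < 1.0:
            raise ValueError("missing_frac must be in [0, 1)")
        if not -1.0 < self.rho < 1.0:
            raise ValueError("rho must be in (-1, 1)")
        if any(c < 1 for c in self.blocks_per_quarter):
            raise ValueError("block counts must be positive")
        if self.periodic_convention not in ("printed", "standard"):
            raise ValueError("periodic_convention must be 'printed' or 'standard'")

    @property
    def n_months(self) -> int:
        m = int(round(self.t_max))
        if self.nt % m != 0:
            raise ValueError("nt must be a multiple of the number of months")
        return m

    @property
    def days_per_month(self) -> int:
        return self.nt // self.n_months

    @property
    def true_kernel(self) -> KernelParams:
        """Kernel truth with the noise ratio implied by monthly aggregation.

        Averaging ``d`` daily noise draws of variance ``noise_var`` gives a
        monthly measurement-error variance ``noise_var / d``, i.e. an
        effective ``delta2 = noise_var / (d sigma2)`` for unit-length monthly
        intervals.
        """
        d2 = self.noise_var / (self.days_per_month * self.sigma2)
        return KernelParams(phi1=self.phi1, nu=self.nu, phi2=self.phi2, delta2=d2)


@dataclass
class SimDataset:
    cfg: SimConfig
    sites: np.ndarray = None
    times: np.ndarray = None
    mu_t: np.ndarray = None
    z_daily: np.ndarray = None
    x_daily: np.ndarray = None
    z_monthly: np.ndarray = None
    x_monthly: np.ndarray = None
    keep_mask: np.ndarray = None
    supports: list = None
    x: np.ndarray = None
    site_index: np.ndarray = None
    month_index: np.ndarray = None
    chol_spatial: np.ndarray = None
    chol_temporal: np.ndarray = None
    blocks: list = None
    z_blocks: np.ndarray = None
    mu_blocks: np.ndarray = None
    y: np.ndarray = None
    W: np.ndarray = None
    g: np.ndarray = None
    seeds: dict = field(default_factory=dict)


def _child_seed(master: int, tag: str) -> np.random.Generator:
    # deterministic across processes (unlike builtin hash of strings)
    h = zlib.crc32(tag.encode()) % (2**31)
    return np.random.default_rng(np.random.SeedSequence([int(master), h]))


def simulate_exposure(cfg: SimConfig) -> SimDataset:
    """Simulate daily exposure, aggregate to monthly means, thin at random.

    Monthly values are exactly the arithmetic means of their daily
    constituents, and the retained-record count is
    ``round((1 - missing_frac) * ns * n_months)``.
    """
    ds = SimDataset(cfg=cfg)
    months = cfg.n_months
    dpm = cfg.days_per_month
    rng_sites = _child_seed(cfg.seed, "sites")
    rng_mean = _child_seed(cfg.seed, "mean")
    rng_field = _child_seed(cfg.seed, "field")
    rng_noise = _child_seed(cfg.seed, "noise")
    rng_miss = _child_seed(cfg.seed, "missing")

    ds.sites = rng_sites.uniform(size=(cfg.ns, 2))
    ds.times = np.arange(1, cfg.nt + 1) * (cfg.t_max / cfg.nt)

    dt = np.abs(ds.times[:, None] - ds.times[None, :])
    s = np.sin(np.pi * dt / cfg.period) ** 2
    if cfg.periodic_convention == "printed":
        R = np.exp(-2.0 * cfg.lam**2 * s)
    else:
        R = np.exp(-2.0 * s / cfg.lam**2)
    Lr = sla.cholesky(cfg.mean_var * R + 1e-8 * np.eye(cfg.nt), lower=True)
    ds.mu_t = cfg.mean_level + Lr @ rng_mean.standard_normal(cfg.nt)

    Cs = matern_correlation(cdist(ds.sites, ds.sites), cfg.phi1, cfg.nu)
    Ct = np.exp(-cfg.phi2 * dt)
    try:
        Ls = sla.cholesky(Cs + 1e-10 * np.eye(cfg.ns), lower=True)
        Lt = sla.cholesky(Ct + 1e-10 * np.eye(cfg.nt), lower=True)
    except (sla.LinAlgError, MemoryError) as exc:  # pragma: no cover
        raise RuntimeError(
            "grids too large for dense factorization; reduce ns/nt "
            "(sampling uses the spatial (x) temporal Kronecker structure)"
        ) from exc
    G = rng_field.standard_normal((cfg.ns, cfg.nt))
    detr = np.sqrt(cfg.sigma2) * (Ls @ G @ Lt.T)
    ds.z_daily = ds.mu_t[None, :] + detr
    ds.x_daily = ds.z_daily + np.sqrt(cfg.noise_var) * rng_noise.standard_normal(
        (cfg.ns, cfg.nt)
    )
    ds.chol_spatial, ds.chol_temporal = Ls, Lt

    ds.z_monthly = ds.z_daily.reshape(cfg.ns, months, dpm).mean(axis=2)
    ds.x_monthly = ds.x_daily.reshape(cfg.ns, months, dpm).mean(axis=2)

    total = cfg.ns * months
    n_keep = int(round((1.0 - cfg.missing_frac) * total))
    kept = np.sort(rng_miss.choice(total, size=n_keep, replace=False))
    mask = np.zeros(total, dtype=bool)
    mask[kept] = True
    ds.keep_mask = mask.reshape(cfg.ns, months)

    site_idx, month_idx = np.nonzero(ds.keep_mask)
    ds.site_index, ds.month_index = site_idx, month_idx
    ds.supports = [
        PointSupport(site=tuple(ds.sites[i]), interval=TimeInterval(v, v + 1.0))
        for i, v in zip(site_idx, month_idx)
    ]
    ds.x = ds.x_monthly[site_idx, month_idx]
    return ds


def _voronoi_polygons(seeds: np.ndarray) -> list[Polygon]:
    """Clipped Voronoi tessellation of the unit square.

    Generator points are mirrored across all four edges so every cell
    touching the square is bounded, then cells are clipped to the square.
    """
    pts = np.asarray(seeds, dtype=float)
    reflections = [
        pts * [-1.0, 1.0],
        pts * [1.0, -1.0],
        np.column_stack([2.0 - pts[:, 0], pts[:, 1]]),
        np.column_stack([pts[:, 0], 2.0 - pts[:, 1]]),
    ]
    if len(pts) == 1:
        return [box(0.0, 0.0, 1.0, 1.0)]
    vor = Voronoi(np.vstack([pts] + reflections))
    square = box(0.0, 0.0, 1.0, 1.0)
    cells = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(square)
        cells.append(poly)
    return cells


def make_blocks(cfg: SimConfig, return_seeds: bool = False):
    """Quarterly Voronoi block supports on the unit square.

    Each quarter (three-month interval) gets its own tessellation from the
    stated number of uniformly sampled generator points; duplicated seeds
    are resampled.  With ``return_seeds=True`` the generator points are
    returned alongside the blocks.
    """
    rng = _child_seed(cfg.seed, "blocks")
    months_per_quarter = 3.0
    blocks: list[BlockSupport] = []
    all_seeds: list[np.ndarray] = []
    for q, count in enumerate(cfg.blocks_per_quarter):
        while True:
            seeds = rng.uniform(size=(count, 2))
            if len(np.unique(seeds, axis=0)) == count:
                break
        interval = TimeInterval(q * months_per_quarter, (q + 1) * months_per_quarter)
        for poly, seed_pt in zip(_voronoi_polygons(seeds), seeds):
            blocks.append(BlockSupport(polygon=poly, interval=interval))
            all_seeds.append(seed_pt)
    if return_seeds:
        return blocks, np.array(all_seeds)
    return blocks


def simulate_outcome(
    cfg: SimConfig,
    exposure: SimDataset,
    blocks: list[BlockSupport],
    cache: GeometryCache | None = None,
) -> SimDataset:
    """Draw block-level truth and confounded outcomes.

    The block-averaged latent process is drawn from its exact conditional law
    given the simulated site-by-day field (the site/time Kronecker structure
    makes the conditioning cheap); spatial block integrals use the cached
    Monte-Carlo polygon samples.  The unmeasured confounder ``g`` is built
    from an independent draw of the same block-level kernel so that its
    correlation with the exposure equals ``rho`` by construction, and the
    outcome noise is heteroskedastic in the block volume.
    """
    cfg_kp = cfg.true_kernel
    if cache is None:
        cache = GeometryCache(blocks=blocks, n_mc=cfg.n_mc, seed=cfg.seed)
    rng_block = _child_seed(cfg.seed, "block-truth")
    rng_out = _child_seed(cfg.seed, "outcome")

    K = len(blocks)
    sites, times = exposure.sites, exposure.times
    Ls, Lt = exposure.chol_spatial, exposure.chol_temporal
    block_ab = cache.block_ab
    block_len = cache.block_lengths

    # single averages: spatial (ns x K) and normalized temporal (nt x K)
    a_mat = np.column_stack(
        [
            matern_correlation(cdist(sites, c.points), cfg.phi1, cfg.nu).mean(axis=1)
            for c in cache.block_caches
        ]
    )
    b_mat = _ct_point_matrix(times, block_ab, cfg.phi2) / block_len[None, :]

    As = sla.cho_solve((Ls, True), a_mat)  # Cs^{-1} a
    Bt = sla.cho_solve((Lt, True), b_mat)  # Ct^{-1} b
    Zc = exposure.z_daily - exposure.mu_t[None, :]
    cond_mean = np.einsum("ik,ik->k", As, Zc @ Bt)

    C_blk = cache.cov_blocks(cfg_kp)
    cond_corr = C_blk - (a_mat.T @ As) * (b_mat.T @ Bt)
    cond_cov = cfg.sigma2 * clip_to_psd(cond_corr, rtol=1e-6)
    w, V = np.linalg.eigh(cond_cov)
    F = V * np.sqrt(np.clip(w, 0.0, None))

    # mean function averaged over each block interval (discretized daily)
    mu_blocks = np.array(
        [
            exposure.mu_t[(times > ab[0] + 1e-12) & (times <= ab[1] + 1e-12)].mean()
            for ab in block_ab
        ]
    )
    z_blocks = mu_blocks + cond_mean + F @ rng_block.standard_normal(K)
    if cfg.block_noise:
        areas = cache.block_areas / cache.block_areas.mean()
        vol = areas * block_len
        z_blocks = z_blocks + np.sqrt(cfg.noise_var / vol) * rng_block.standard_normal(K)

    exposure.blocks = list(blocks)
    exposure.z_blocks = z_blocks
    exposure.mu_blocks = mu_blocks

    # confounded outcome
    W = np.column_stack([np.ones(K), rng_out.standard_normal(K)])
    wb, Vb = np.linalg.eigh(cfg.sigma2 * clip_to_psd(C_blk, rtol=1e-6))
    g_indep = (Vb * np.sqrt(np.clip(wb, 0.0, None))) @ rng_out.standard_normal(K)

    def _std(v):
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    g = cfg.rho * _std(z_blocks) + np.sqrt(1.0 - cfg.rho**2) * _std(g_indep)
    areas = cache.block_areas / cache.block_areas.mean()
    vol = areas * block_len
    eps = cfg.outcome_sd / np.sqrt(vol) * rng_out.standard_normal(K)
    y = W @ np.asarray(cfg.beta1) + cfg.beta2 * z_blocks + g + eps

    exposure.y = y
    exposure.W = W
    exposure.g = g
    return exposure
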