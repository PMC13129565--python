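"""Predictive-performance metrics for posterior draws."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = ["waic", "bayesian_mse", "block_mse", "outcome_pointwise_logdens"]


def waic(pointwise_logdens: np.ndarray) -> float:
    """Widely applicable information criterion, ``-2 (lppd - p_waic)``.

    ``pointwise_logdens`` is a K x B matrix of per-observation, per-draw log
    densities.  ``lppd`` is the summed log of the draw-averaged densities
    (computed with log-sum-exp stabilisation) and the effective number of
    parameters ``p_waic`` is the summed across-draw variance of the log
    densities.
    """
    ld = np.atleast_2d(np.asarray(pointwise_logdens, dtype=float))
    if not np.all(np.isfinite(ld)):
        raise ValueError("pointwise log densities must be finite")
    if ld.shape[1] < 2:
        raise ValueError("WAIC needs at least two posterior draws")
    B = ld.shape[1]
    lppd = float(np.sum(logsumexp(ld, axis=1) - np.log(B)))
    p_waic = float(np.sum(np.var(ld, axis=1, ddof=1)))
    return -2.0 * (lppd - p_waic)


def bayesian_mse(draws: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Mean squared deviation of posterior draws from the truth, per parameter.

    Equals posterior variance plus squared bias of the posterior mean.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    truth = np.atleast_1d(np.asarray(truth, dtype=float))
    if draws.shape[1] != truth.shape[0]:
        raise ValueError("draws and truth have mismatched dimensions")
    return np.mean((draws - truth[None, :]) ** 2, axis=0)


def block_mse(zl_draws: np.ndarray, truth: np.ndarray) -> float:
    """Mean over draws and blocks of the squared block-prediction error."""
    zl_draws = np.atleast_2d(np.asarray(zl_draws, dtype=float))
    truth = np.atleast_1d(np.asarray(truth, dtype=float))
    if zl_draws.shape[1] != truth.shape[0]:
        raise ValueError("draws and truth have mismatched dimensions")
    return float(np.mean((zl_draws - truth[None, :]) ** 2))


def outcome_pointwise_logdens(
    y: np.ndarray,
    mean_draws: np.ndarray,
    tau2_draws: np.ndarray,
    volumes: np.ndarray,
) -> np.ndarray:
    """K x B matrix of outcome log densities ``N(y_k | mean_k(b), tau2(b)/vol_k)``."""
    y = np.asarray(y, dtype=float)[:, None]
    mean_draws = np.asarray(mean_draws, dtype=float).T  # (K, B)
    v = np.asarray(tau2_draws, dtype=float)[None, :] / np.asarray(volumes, dtype=float)[:, None]
    return -0.5 * (np.log(2.0 * np.pi * v) + (y - mean_draws) ** 2 / v)
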