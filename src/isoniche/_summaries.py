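"""Posterior-draw summaries shared across modules."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class PosteriorSummary:
    mean: float
    mode: float
    q025: float
    q05: float
    q95: float
    q975: float


def kde_mode(draws: np.ndarray) -> float:
    """Mode of a draw vector: Gaussian KDE (Silverman bandwidth), 512-point grid."""
    draws = np.asarray(draws, float)
    lo, hi = draws.min(), draws.max()
    if lo == hi:
        return float(lo)
    grid = np.linspace(lo, hi, 512)
    density = stats.gaussian_kde(draws, bw_method="silverman")(grid)
    return float(grid[np.argmax(density)])


def summarize_posterior(draws: np.ndarray) -> PosteriorSummary:
    """Mean, KDE mode and empirical (linear-interpolation) quantiles of draws."""
    draws = np.asarray(draws, float)
    if draws.size == 0:
        raise ValueError("empty draw vector")
    q025, q05, q95, q975 = np.quantile(draws, [0.025, 0.05, 0.95, 0.975])
    return PosteriorSummary(
        mean=float(draws.mean()),
        mode=kde_mode(draws),
        q025=float(q025), q05=float(q05), q95=float(q95), q975=float(q975),
    )
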