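"""Bayesian multivariate-normal niche model.

A species' niche on d axes is modelled as N(μ, Σ). Under the standard
non-informative prior π(μ, Σ) ∝ |Σ|^{−(d+1)/2}, the posterior given n
samples with mean x̄ and centered sum-of-squares S is

    Σ | data  ~  Inverse-Wishart(scale = S, dof = n − 1)
    μ | Σ     ~  Normal(x̄, Σ / n)

The niche region at level α is the α-probability ellipsoid of N(μ, Σ); its
hypervolume ("niche size") is

    V = [2 π^{d/2} / (d Γ(d/2))] · (χ²_{d,α})^{d/2} · |Σ|^{1/2}

and directional overlap of group A onto group B is the probability that a
point drawn from A's distribution falls inside B's α-niche region,
estimated by Monte Carlo per paired posterior draw. Overlap is asymmetric
by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from ._summaries import PosteriorSummary, summarize_posterior

DEFAULT_K = 100_000
DEFAULT_ALPHA = 0.95
DEFAULT_N_MC = 1_000


class NicheModelError(ValueError):
    pass


@dataclass(frozen=True)
class NichePosterior:
    """Posterior draws of a group's niche centroid and covariance."""

    group: str
    axis_names: tuple[str, ...]
    mu_draws: np.ndarray      # K×d
    sigma_draws: np.ndarray   # K×d×d
    seed: int | None = None

    @property
    def K(self) -> int:
        return self.mu_draws.shape[0]

    @property
    def d(self) -> int:
        return self.mu_draws.shape[1]

    @classmethod
    def from_fixed(cls, mu, sigma, K: int, group: str = "fixed",
                   axis_names: tuple[str, ...] | None = None) -> "NichePosterior":
        """Degenerate posterior: every draw equals the given (μ, Σ)."""
        mu = np.atleast_1d(np.asarray(mu, float))
        sigma = np.atleast_2d(np.asarray(sigma, float))
        d = mu.shape[0]
        names = axis_names or tuple(f"axis{i + 1}" for i in range(d))
        return cls(group, names,
                   np.tile(mu, (K, 1)), np.tile(sigma, (K, 1, 1)))


def sample_posterior(
    coords: np.ndarray,
    K: int = DEFAULT_K,
    seed: int = 0,
    group: str = "group",
    axis_names: tuple[str, ...] | None = None,
) -> NichePosterior:
    """Draw K (μ, Σ) pairs from the non-informative conjugate posterior.

    Requires n ≥ d + 2 observations for a proper d-dimensional posterior.
    Deterministic given ``seed``.
    """
    x = np.asarray(coords, float)
    if x.ndim == 1:
        x = x[:, None]
    n, d = x.shape
    if n <= d + 1:
        raise NicheModelError(
            f"group {group!r}: insufficient samples for a proper "
            f"{d}-dimensional posterior (n={n}, need n >= {d + 2})")
    names = tuple(axis_names) if axis_names else tuple(f"axis{i + 1}" for i in range(d))
    xbar = x.mean(axis=0)
    centered = x - xbar
    S = centered.T @ centered
    rng = np.random.default_rng(seed)
    sigma = stats.invwishart.rvs(df=n - 1, scale=S, size=K, random_state=rng)
    sigma = np.asarray(sigma, float).reshape(K, d, d)
    chol = np.linalg.cholesky(sigma / n)
    z = rng.standard_normal((K, d))
    mu = xbar + np.einsum("kij,kj->ki", chol, z)
    return NichePosterior(group, names, mu, sigma, seed=seed)


def niche_size(sigma: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray | float:
    """Hypervolume of the α-probability ellipsoid of N(·, Σ).

    Accepts a single d×d matrix or a stack K×d×d; returns a scalar or a
    K-vector accordingly, in axis-unitsᵈ.
    """
    if not 0 < alpha < 1:
        raise NicheModelError("alpha must be in (0, 1)")
    sig = np.asarray(sigma, float)
    single = sig.ndim == 2
    if single:
        sig = sig[None]
    d = sig.shape[-1]
    det = np.linalg.det(sig)
    if (det <= 0).any() or (np.linalg.eigvalsh(sig).min(axis=-1) <= 0).any():
        raise NicheModelError("covariance must be positive definite")
    r2 = stats.chi2.ppf(alpha, df=d)
    log_ball = np.log(2.0) + (d / 2) * np.log(np.pi) - np.log(d) - gammaln(d / 2)
    vol = np.exp(log_ball + (d / 2) * np.log(r2) + 0.5 * np.log(det))
    return float(vol[0]) if single else vol


@dataclass(frozen=True)
class NicheSizeSummary:
    group: str
    approach: str
    size_draws: np.ndarray
    summary: PosteriorSummary

    @classmethod
    def from_posterior(cls, posterior: NichePosterior, alpha: float = DEFAULT_ALPHA,
                       approach: str = "") -> "NicheSizeSummary":
        draws = niche_size(posterior.sigma_draws, alpha)
        return cls(posterior.group, approach, draws, summarize_posterior(draws))


@dataclass(frozen=True)
class OverlapResult:
    """Directional overlap of ``from_group`` onto ``onto_group``'s niche region."""

    from_group: str
    onto_group: str
    alpha: float
    overlap_draws: np.ndarray  # K-vector of probabilities
    summary: PosteriorSummary


def niche_overlap(
    frm: NichePosterior,
    onto: NichePosterior,
    alpha: float = DEFAULT_ALPHA,
    n_mc: int = DEFAULT_N_MC,
    seed: int = 0,
    chunk: int = 512,
) -> OverlapResult:
    """Posterior of P(X ∈ onto's α-region) for X ~ from's distribution.

    Per paired posterior draw k, ``n_mc`` Monte-Carlo points are drawn from
    N(μ_from,k, Σ_from,k) and the fraction falling inside
    {x : (x−μ_onto,k)ᵀ Σ_onto,k⁻¹ (x−μ_onto,k) ≤ χ²_{d,α}} is recorded.
    """
    if frm.axis_names != onto.axis_names:
        raise NicheModelError(
            f"axis mismatch: {frm.axis_names} vs {onto.axis_names}")
    if frm.K != onto.K:
        raise NicheModelError(f"draw-count mismatch: {frm.K} vs {onto.K}")
    if n_mc < 100:
        raise NicheModelError("n_mc must be >= 100")
    K, d = frm.K, frm.d
    r2 = stats.chi2.ppf(alpha, df=d)
    rng = np.random.default_rng(seed)
    overlap = np.empty(K)
    for start in range(0, K, chunk):
        stop = min(start + chunk, K)
        m = stop - start
        chol = np.linalg.cholesky(frm.sigma_draws[start:stop])
        z = rng.standard_normal((m, n_mc, d))
        points = frm.mu_draws[start:stop, None, :] + z @ chol.transpose(0, 2, 1)
        inv = np.linalg.inv(onto.sigma_draws[start:stop])
        y = points - onto.mu_draws[start:stop, None, :]
        maha = np.einsum("mnd,mde,mne->mn", y, inv, y)
        overlap[start:stop] = (maha <= r2).mean(axis=1)
    return OverlapResult(frm.group, onto.group, alpha, overlap,
                         summarize_posterior(overlap))
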