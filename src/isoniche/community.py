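"""Layman community metrics generalized to n dimensions.

The classic biplot descriptors — centroid distance (CD), nearest-neighbour
distance (NND), its standard deviation (SDNND) and per-axis range — are
computed on the posterior draws of each species' niche centroid, so each
metric has a full posterior distribution rather than a point value.
Per draw k, with centroid μ_s,k for species s:

    CD    = mean over s of ‖μ_s,k − c_k‖₂, c_k the unweighted mean centroid
    NND   = mean over s of min_{t≠s} ‖μ_s,k − μ_t,k‖₂
    SDNND = population sd of those per-species minima
    range = per-axis max − min of centroid coordinates

CD measures species spread in niche space, NND the density of species
packing, SDNND the evenness of that packing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._summaries import PosteriorSummary, summarize_posterior
from .niche import NichePosterior

__all__ = ["LaymanDraws", "layman_metrics", "summarize_posterior", "PosteriorSummary"]


class CommunityError(ValueError):
    pass


@dataclass(frozen=True)
class LaymanDraws:
    """Posterior draws and summaries of the community metrics."""

    groups: tuple[str, ...]
    axis_names: tuple[str, ...]
    cd: np.ndarray                 # K-vector
    nnd: np.ndarray                # K-vector
    sdnnd: np.ndarray              # K-vector
    range_per_axis: np.ndarray     # K×d
    summaries: dict[str, PosteriorSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, summ in self.summaries.items():
            rows.append({"metric": metric, "mean": summ.mean, "mode": summ.mode,
                         "q025": summ.q025, "q975": summ.q975})
        return pd.DataFrame(rows)


def layman_metrics(posteriors: list[NichePosterior]) -> LaymanDraws:
    """Community metrics over aligned posterior centroid draws.

    All posteriors must share axis names and draw count; at least two
    species are required (with exactly two, SDNND is identically 0 and
    NND = 2·CD).
    """
    if len(posteriors) < 2:
        raise CommunityError("need at least 2 species for community metrics")
    axis_names = posteriors[0].axis_names
    K = posteriors[0].K
    for p in posteriors[1:]:
        if p.axis_names != axis_names:
            raise CommunityError(
                f"axis mismatch: {p.group} has {p.axis_names}, expected {axis_names}")
        if p.K != K:
            raise CommunityError(
                f"draw-count mismatch: {p.group} has K={p.K}, expected {K}")
    centroids = np.stack([p.mu_draws for p in posteriors])     # S×K×d
    S = centroids.shape[0]
    community = centroids.mean(axis=0)                         # K×d
    cd = np.linalg.norm(centroids - community, axis=2).mean(axis=0)
    diff = centroids[:, None] - centroids[None, :]             # S×S×K×d
    dist = np.linalg.norm(diff, axis=3)                        # S×S×K
    dist[np.arange(S), np.arange(S)] = np.inf
    nearest = dist.min(axis=1)                                 # S×K
    nnd = nearest.mean(axis=0)
    sdnnd = nearest.std(axis=0)                                # population sd
    rng_axis = centroids.max(axis=0) - centroids.min(axis=0)   # K×d
    summaries = {"CD": summarize_posterior(cd),
                 "NND": summarize_posterior(nnd),
                 "SDNND": summarize_posterior(sdnnd)}
    for j, name in enumerate(axis_names):
        summaries[f"range_{name}"] = summarize_posterior(rng_axis[:, j])
    return LaymanDraws(tuple(p.group for p in posteriors), axis_names,
                       cd, nnd, sdnnd, rng_axis, summaries)
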