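"""Posterior-comparison statistics and the two-period temporal analysis.

Two groups' posteriors are compared three ways:

* Bhattacharyya coefficient BC = Σ√(p·q) over a shared equal-width binning
  of two draw vectors — the probability-scale overlap of two posterior
  distributions, applied per niche axis (marginal centroid draws) and to
  the niche-size posteriors.
* A conservative centroid-difference probability: each group's centroid
  draws are split into equal null/test halves by one seeded permutation and
  p = P(d_between − d_a,within − d_b,within > 0), where d_between is the
  distance between the two groups' test draws and d_within the distance
  between a group's test and null draws. Under identical niches the within
  distances are as large as the between distance and p stays near 0.
* The posterior mean Euclidean distance between paired centroid draws.

The temporal analysis splits one species into two collection periods,
shares a single PCA basis across periods (so centroid shifts are
identifiable), and reports sizes, directional overlaps and the statistics
above per dimensional approach.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dimensions import build_dimension_space, complete_case_filter
from .io import IsotopeDataset
from .niche import (DEFAULT_ALPHA, DEFAULT_N_MC, NichePosterior,
                    NicheSizeSummary, OverlapResult, niche_overlap, niche_size,
                    sample_posterior)

log = logging.getLogger("isoniche")

DEFAULT_N_BINS = 100


class ComparisonError(ValueError):
    pass


def bhattacharyya(draws_a: np.ndarray, draws_b: np.ndarray,
                  n_bins: int = DEFAULT_N_BINS) -> float:
    """Bhattacharyya coefficient of two draw vectors on a shared binning.

    Returns Σ√(p·q) ∈ [0, 1] with p, q the normalized bin frequencies over
    ``n_bins`` equal-width bins spanning the union range. A degenerate
    union range (every value identical) returns 1.0 by convention.
    """
    a = np.asarray(draws_a, float).ravel()
    b = np.asarray(draws_b, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ComparisonError("empty draw vector")
    if n_bins < 2:
        raise ComparisonError("n_bins must be >= 2")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    if lo == hi:
        log.info("bhattacharyya: degenerate union range at %g, returning 1.0", lo)
        return 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(a, bins=edges)[0] / a.size
    q = np.histogram(b, bins=edges)[0] / b.size
    return float(np.sqrt(p * q).sum())


def centroid_difference_test(mu_a: np.ndarray, mu_b: np.ndarray,
                             seed: int = 0) -> tuple[float, float]:
    """Conservative probability that two groups' centroids differ.

    Returns ``(p, centroid_distance)``. Draws are truncated to a common even
    count; one seeded permutation (shared by both groups, so a group
    compared with itself gives p = 0 exactly) defines the null/test halves.
    """
    a = np.atleast_2d(np.asarray(mu_a, float))
    b = np.atleast_2d(np.asarray(mu_b, float))
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ComparisonError("mu draws must be K×d with matching d")
    K = min(a.shape[0], b.shape[0]) // 2 * 2
    if K < 4:
        raise ComparisonError("need at least 4 posterior draws")
    a, b = a[:K], b[:K]
    perm = np.random.default_rng(seed).permutation(K)
    test, null = perm[: K // 2], perm[K // 2:]
    d_between = np.linalg.norm(a[test] - b[test], axis=1)
    d_a = np.linalg.norm(a[test] - a[null], axis=1)
    d_b = np.linalg.norm(b[test] - b[null], axis=1)
    p = float((d_between - d_a - d_b > 0).mean())
    centroid_distance = float(np.linalg.norm(a - b, axis=1).mean())
    return p, centroid_distance


@dataclass(frozen=True)
class ComparisonResult:
    group_a: str
    group_b: str
    axis_names: tuple[str, ...]
    bc_per_axis: dict[str, float]
    bc_size: float
    p_centroid_diff: float
    centroid_distance: float

    def to_frame(self) -> pd.DataFrame:
        row = {"group_a": self.group_a, "group_b": self.group_b,
               "p_centroid_diff": self.p_centroid_diff,
               "centroid_distance": self.centroid_distance,
               "bc_size": self.bc_size}
        row.update({f"bc_{axis}": v for axis, v in self.bc_per_axis.items()})
        return pd.DataFrame([row])


def compare_groups(
    post_a: NichePosterior,
    post_b: NichePosterior,
    sizes_a: np.ndarray | None = None,
    sizes_b: np.ndarray | None = None,
    seed: int = 0,
    n_bins: int = DEFAULT_N_BINS,
    alpha: float = DEFAULT_ALPHA,
) -> ComparisonResult:
    """Full posterior comparison of two groups on matching axes."""
    if post_a.axis_names != post_b.axis_names:
        raise ComparisonError(
            f"axis mismatch: {post_a.axis_names} vs {post_b.axis_names}")
    if sizes_a is None:
        sizes_a = niche_size(post_a.sigma_draws, alpha)
    if sizes_b is None:
        sizes_b = niche_size(post_b.sigma_draws, alpha)
    bc_axis = {
        axis: bhattacharyya(post_a.mu_draws[:, j], post_b.mu_draws[:, j], n_bins)
        for j, axis in enumerate(post_a.axis_names)
    }
    bc_size = bhattacharyya(sizes_a, sizes_b, n_bins)
    p, dist = centroid_difference_test(post_a.mu_draws, post_b.mu_draws, seed)
    return ComparisonResult(post_a.group, post_b.group, post_a.axis_names,
                            bc_axis, bc_size, p, dist)


@dataclass(frozen=True)
class PeriodSplit:
    """Two disjoint, inclusive year ranges defining the collection periods."""

    period1: tuple[int, int] = (1970, 1989)
    period2: tuple[int, int] = (1990, 2006)

    def __post_init__(self) -> None:
        lo1, hi1 = self.period1
        lo2, hi2 = self.period2
        if lo1 > hi1 or lo2 > hi2:
            raise ComparisonError("empty period range")
        if max(lo1, lo2) <= min(hi1, hi2):
            raise ComparisonError("period ranges overlap")

    def label(self, year: int) -> str | None:
        if self.period1[0] <= year <= self.period1[1]:
            return "period1"
        if self.period2[0] <= year <= self.period2[1]:
            return "period2"
        return None

    def name(self, which: str) -> str:
        lo, hi = self.period1 if which == "period1" else self.period2
        return f"{lo}-{hi}"


@dataclass
class TemporalApproachResult:
    approach: str
    estimable: bool
    reason: str = ""
    sizes: dict[str, NicheSizeSummary] = field(default_factory=dict)
    overlaps: dict[tuple[str, str], OverlapResult] = field(default_factory=dict)
    comparison: ComparisonResult | None = None


@dataclass
class TemporalResult:
    species: str
    split: PeriodSplit
    per_approach: dict[str, TemporalApproachResult]

    def sizes_table(self) -> pd.DataFrame:
        """Per period × approach niche-size summary (mode, 5% and 95% quantiles)."""
        rows = []
        for appr, res in self.per_approach.items():
            for period, summ in (res.sizes or {}).items():
                rows.append({"species": self.species, "approach": appr,
                             "period": period, "mode": summ.summary.mode,
                             "q05": summ.summary.q05, "q95": summ.summary.q95,
                             "mean": summ.summary.mean})
            if not res.estimable:
                rows.append({"species": self.species, "approach": appr,
                             "period": "not estimable", "mode": np.nan,
                             "q05": np.nan, "q95": np.nan, "mean": np.nan})
        return pd.DataFrame(rows)

    def tests_table(self) -> pd.DataFrame:
        """Per approach centroid-difference probability and distance."""
        rows = []
        for appr, res in self.per_approach.items():
            if res.comparison is None:
                rows.append({"species": self.species, "approach": appr,
                             "p": np.nan, "distance": np.nan,
                             "note": res.reason or "not estimable"})
            else:
                rows.append({"species": self.species, "approach": appr,
                             "p": res.comparison.p_centroid_diff,
                             "distance": res.comparison.centroid_distance,
                             "note": ""})
        return pd.DataFrame(rows)

    def overlap_table(self) -> pd.DataFrame:
        """Directional overlap (%) between periods per approach."""
        rows = []
        for appr, res in self.per_approach.items():
            for (frm, onto), ov in (res.overlaps or {}).items():
                rows.append({"species": self.species, "approach": appr,
                             "from": frm, "onto": onto,
                             "overlap_mean_pct": 100 * ov.summary.mean,
                             "overlap_mode_pct": 100 * ov.summary.mode})
        return pd.DataFrame(rows)


def temporal_analysis(
    dataset: IsotopeDataset,
    species: str,
    split: PeriodSplit | None = None,
    approaches: tuple[str, ...] = ("2D", "3D", "5D"),
    K: int = 10_000,
    alpha: float = DEFAULT_ALPHA,
    n_mc: int = DEFAULT_N_MC,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
) -> TemporalResult:
    """Compare one species' niche between two collection periods.

    Dimension spaces are built once on the full complete-case dataset so
    both periods share the PCA basis; the species' rows are then split by
    year. Approaches for which either period has too few samples are
    flagged "not estimable" and the rest proceed.
    """
    split = split or PeriodSplit()
    filtered = complete_case_filter(dataset)
    if species not in set(filtered.species):
        raise ComparisonError(f"species {species!r} not present after filtering")
    seeds = np.random.SeedSequence(seed).generate_state(4 * len(approaches))
    results: dict[str, TemporalApproachResult] = {}
    for ia, approach in enumerate(approaches):
        space, _, _ = build_dimension_space(filtered, approach)
        mask = np.asarray([s == species for s in space.species])
        coords = space.coords[mask]
        years = np.asarray(space.year)[mask]
        labels = np.asarray([split.label(int(y)) or "" for y in years])
        d = space.d
        period_coords = {p: coords[labels == p] for p in ("period1", "period2")}
        too_small = [p for p, c in period_coords.items() if len(c) <= d + 1]
        if too_small:
            reason = "; ".join(
                f"{split.name(p)}: n={len(period_coords[p])} <= d+1={d + 1}"
                for p in too_small)
            log.warning("temporal %s %s not estimable (%s)", species, approach, reason)
            results[approach] = TemporalApproachResult(approach, False, reason)
            continue
        posts: dict[str, NichePosterior] = {}
        sizes: dict[str, NicheSizeSummary] = {}
        for ip, p in enumerate(("period1", "period2")):
            post = sample_posterior(period_coords[p], K=K,
                                    seed=int(seeds[4 * ia + ip]),
                                    group=f"{species} {split.name(p)}",
                                    axis_names=space.axis_names)
            posts[p] = post
            sizes[split.name(p)] = NicheSizeSummary.from_posterior(post, alpha, approach)
        overlaps = {}
        for frm, onto, s_off in (("period1", "period2", 2), ("period2", "period1", 3)):
            ov = niche_overlap(posts[frm], posts[onto], alpha=alpha, n_mc=n_mc,
                               seed=int(seeds[4 * ia + s_off]))
            overlaps[(split.name(frm), split.name(onto))] = ov
        comparison = compare_groups(posts["period1"], posts["period2"],
                                    sizes[split.name("period1")].size_draws,
                                    sizes[split.name("period2")].size_draws,
                                    seed=int(seeds[4 * ia]), n_bins=n_bins,
                                    alpha=alpha)
        results[approach] = TemporalApproachResult(
            approach, True, sizes=sizes, overlaps=overlaps, comparison=comparison)
    return TemporalResult(species, split, results)
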