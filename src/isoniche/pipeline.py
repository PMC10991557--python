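"""End-to-end orchestration of the four dimensional approaches.

`run_pipeline` executes complete-case filtering, dimension-space
construction, per-species posteriors, niche sizes, all pairwise directional
overlaps, community metrics and all pairwise comparisons — optionally a
two-period temporal analysis for selected species — and writes plain-CSV
tables plus a JSON manifest (config echo, seed, config hash, versions, row
counts) to the output directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import permutations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .community import layman_metrics
from .compare import PeriodSplit, compare_groups, temporal_analysis
from .dimensions import (APPROACH_AXES, build_dimension_space,
                         complete_case_filter, trophic_indices,
                         validate_proxies)
from .io import IsotopeDataset, read_dataset, write_dataset
from .niche import NicheSizeSummary, niche_overlap, sample_posterior
from .synthetic import default_community

log = logging.getLogger("isoniche")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; YAML-serializable."""

    input_path: str | None = None      # canonical CSV; None → synthetic
    synthetic_seed: int | None = None  # used when input_path is None
    approaches: tuple[str, ...] = ("1D", "2D", "3D", "5D")
    K: int = 100_000                   # posterior draws per group
    alpha: float = 0.95                # niche-region probability level
    n_mc: int = 1_000                  # MC points per draw for overlap
    n_bins: int = 100                  # Bhattacharyya bins
    seed: int = 0
    temporal_species: tuple[str, ...] = ()
    period1: tuple[int, int] = (1970, 1989)
    period2: tuple[int, int] = (1990, 2006)
    output_dir: str = "isoniche-out"
    #: which stages to compute; "dims" is always implied
    stages: tuple[str, ...] = ("fit", "overlap", "layman", "compare")

    def __post_init__(self) -> None:
        self.approaches = tuple(self.approaches)
        self.stages = tuple(self.stages)
        bad = [s for s in self.stages if s not in ("fit", "overlap", "layman", "compare")]
        if bad:
            raise PipelineError(f"unknown stage(s): {', '.join(bad)}")
        self.temporal_species = tuple(self.temporal_species)
        self.period1 = tuple(self.period1)
        self.period2 = tuple(self.period2)
        if self.K < 100:
            raise PipelineError("K must be >= 100")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must be in (0, 1)")
        if not self.approaches:
            raise PipelineError("approaches must be non-empty")
        unknown = [a for a in self.approaches if a not in APPROACH_AXES]
        if unknown:
            raise PipelineError(f"unknown approach(es): {', '.join(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    output_dir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _load_input(config: PipelineConfig) -> IsotopeDataset:
    if config.input_path is not None:
        dataset, report = read_dataset(config.input_path)
        if not report.ok:
            raise PipelineError(f"invalid input: duplicates {report.duplicate_ids}")
        return dataset
    seed = config.synthetic_seed if config.synthetic_seed is not None else config.seed
    log.info("generating default synthetic community with seed %d", seed)
    return default_community(seed)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = _load_input(config)
    write_dataset(dataset, out / "dataset.csv")
    filtered = complete_case_filter(dataset)
    species_names = filtered.species_names()
    words = np.random.SeedSequence(config.seed).generate_state(len(species_names) + 2)
    species_seeds = {name: int(s) for name, s in zip(species_names, words)}
    overlap_seed, compare_seed = int(words[-2]), int(words[-1])

    tables: dict[str, pd.DataFrame] = {}
    size_rows, overlap_rows, layman_frames, compare_frames, corr_frames = [], [], [], [], []
    indices = trophic_indices(filtered)
    tables["trophic_indices"] = indices

    for approach in config.approaches:
        space, pca_c, pca_n = build_dimension_space(filtered, approach)
        tables[f"space_{approach}"] = space.to_frame()
        if approach == config.approaches[0]:
            tables["pca_c_contributions"] = pca_c.contributions_frame()
            tables["pca_n_contributions"] = pca_n.contributions_frame()
            tables["pca_c_loadings"] = pca_c.loadings_frame()
            tables["pca_n_loadings"] = pca_n.loadings_frame()
        corr = validate_proxies(space, filtered, indices)
        corr.insert(0, "approach", approach)
        corr_frames.append(corr)

        if not any(s in config.stages for s in ("fit", "overlap", "layman", "compare")):
            continue
        posteriors = {}
        for name in species_names:
            coords = space.group_coords(name)
            if len(coords) <= space.d + 1:
                size_rows.append({"species": name, "approach": approach,
                                  "mode": np.nan, "q05": np.nan, "q95": np.nan,
                                  "mean": np.nan, "q025": np.nan, "q975": np.nan,
                                  "note": "not estimable"})
                log.warning("%s %s: not estimable (n=%d, d=%d)",
                            name, approach, len(coords), space.d)
                continue
            post = sample_posterior(coords, K=config.K, seed=species_seeds[name],
                                    group=name, axis_names=space.axis_names)
            posteriors[name] = post
            summ = NicheSizeSummary.from_posterior(post, config.alpha, approach)
            s = summ.summary
            size_rows.append({"species": name, "approach": approach,
                              "mode": s.mode, "q05": s.q05, "q95": s.q95,
                              "mean": s.mean, "q025": s.q025, "q975": s.q975,
                              "note": ""})

        if "overlap" not in config.stages:
            overlap_iter = []
        else:
            overlap_iter = list(permutations(posteriors, 2))
        for i, (a, b) in enumerate(overlap_iter):
            ov = niche_overlap(posteriors[a], posteriors[b], alpha=config.alpha,
                               n_mc=config.n_mc, seed=overlap_seed + i)
            overlap_rows.append({
                "approach": approach, "from": a, "onto": b,
                "overlap_mean_pct": 100 * ov.summary.mean,
                "overlap_mode_pct": 100 * ov.summary.mode,
                "q025_pct": 100 * ov.summary.q025,
                "q975_pct": 100 * ov.summary.q975,
            })

        if len(posteriors) >= 2 and "layman" in config.stages:
            lay = layman_metrics(list(posteriors.values()))
            lf = lay.to_frame()
            lf.insert(0, "approach", approach)
            layman_frames.append(lf)
        if len(posteriors) >= 2 and "compare" in config.stages:
            for i, (a, b) in enumerate(
                    (x, y) for x in posteriors for y in posteriors if x < y):
                cmp_res = compare_groups(posteriors[a], posteriors[b],
                                         seed=compare_seed + i,
                                         n_bins=config.n_bins, alpha=config.alpha)
                cf = cmp_res.to_frame()
                cf.insert(0, "approach", approach)
                compare_frames.append(cf)

    tables["niche_size"] = pd.DataFrame(size_rows)
    tables["overlap"] = pd.DataFrame(overlap_rows)
    if layman_frames:
        tables["layman"] = pd.concat(layman_frames, ignore_index=True)
    if compare_frames:
        tables["comparisons"] = pd.concat(compare_frames, ignore_index=True)
    tables["proxy_correlations"] = pd.concat(corr_frames, ignore_index=True)

    split = PeriodSplit(config.period1, config.period2)
    for sp in config.temporal_species:
        t_appr = tuple(a for a in config.approaches if a != "1D")
        res = temporal_analysis(dataset, sp, split, approaches=t_appr,
                                K=config.K, alpha=config.alpha, n_mc=config.n_mc,
                                n_bins=config.n_bins, seed=config.seed)
        tables[f"temporal_{sp}_sizes"] = res.sizes_table()
        tables[f"temporal_{sp}_tests"] = res.tests_table()
        tables[f"temporal_{sp}_overlap"] = res.overlap_table()

    manifest = {
        "package": "isoniche",
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_samples_input": len(dataset),
        "n_samples_complete": len(filtered),
        "species": species_names,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "tables": sorted(tables),
    }
    for name, frame in tables.items():
        keep_index = name.startswith("pca_")
        frame.to_csv(out / f"{name}.csv", index=keep_index, lineterminator="\n")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    log.info("pipeline wrote %d tables to %s", len(tables), out)
    return PipelineResult(out, tables, manifest)
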