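"""Dimension spaces for the four model approaches.

The niche axes are built from a scaled (correlation-matrix) PCA fitted
independently to the amino-acid δ13C and δ15N blocks, plus the standardized
bulk δ34S value (stdDeltaS):

    1D  →  (PC1-Nss,)
    2D  →  (PC1-Css, PC1-Nss)
    3D  →  (PC1-Css, PC1-Nss, stdDeltaS)
    5D  →  (PC1-Css, PC1-Nss, stdDeltaS, PC2-Css, PC2-Nss)

PC1 of the δ15N amino acids tracks the nitrogen baseline; PC2 tracks
trophic position; PC1 of the δ13C amino acids is a carbon-source proxy.
Component orientation is fixed deterministically (largest-|loading| entry
positive) since a correlation PCA is sign-indeterminate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AA_C_COLUMNS, AA_N_COLUMNS, AA_ORDER, IsotopeDataset

log = logging.getLogger("isoniche")

APPROACH_AXES: dict[str, tuple[str, ...]] = {
    "1D": ("PC1-Nss",),
    "2D": ("PC1-Css", "PC1-Nss"),
    "3D": ("PC1-Css", "PC1-Nss", "stdDeltaS"),
    "5D": ("PC1-Css", "PC1-Nss", "stdDeltaS", "PC2-Css", "PC2-Nss"),
}

#: Default trophic-position constants (‰) for the Glx−Phe formulation:
#: β is the producer-level Glx−Phe offset, TDF the per-step enrichment.
DEFAULT_BETA = 3.4
DEFAULT_TDF = 7.6

DEFAULT_TROPHIC_SET = ("ala", "asp", "glx", "ile", "leu", "pro", "val")
DEFAULT_SOURCE_SET = ("gly", "phe", "lys")


class DimensionError(ValueError):
    pass


@dataclass(frozen=True)
class PcaModel:
    """Correlation-matrix PCA of one 10-variable amino-acid block."""

    variable_names: tuple[str, ...]
    center: np.ndarray            # per-variable mean, ‰
    scale: np.ndarray             # per-variable sample sd, ‰
    loadings: np.ndarray          # p×p orthonormal, columns = components
    explained_fraction: np.ndarray
    contributions_pct: np.ndarray  # 100·loading², columns sum to 100

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        """Project (already in original units) onto all components."""
        z = (np.asarray(matrix, float) - self.center) / self.scale
        return z @ self.loadings

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=list(self.variable_names), columns=cols)

    def contributions_frame(self) -> pd.DataFrame:
        cols = [f"PC{j + 1}" for j in range(self.loadings.shape[1])]
        return pd.DataFrame(self.contributions_pct, index=list(self.variable_names),
                            columns=cols)


@dataclass(frozen=True)
class DimensionSpace:
    """Per-sample niche coordinates for one model approach."""

    approach: str
    axis_names: tuple[str, ...]
    coords: np.ndarray            # n_samples × d
    sample_ids: tuple[str, ...]
    species: tuple[str, ...]
    year: tuple[int, ...]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def group_coords(self, name: str) -> np.ndarray:
        mask = np.asarray([s == name for s in self.species])
        return self.coords[mask]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({
            "sample_id": self.sample_ids,
            "species": self.species,
            "year": self.year,
        })
        for j, name in enumerate(self.axis_names):
            frame[name] = self.coords[:, j]
        return frame


def complete_case_filter(dataset: IsotopeDataset) -> IsotopeDataset:
    """Keep rows with all 20 amino-acid values and bulk δ34S present and finite.

    Order is preserved; the dropped-row count is logged. Raises
    :class:`DimensionError` if no rows survive.
    """
    if len(dataset) == 0:
        raise DimensionError("empty dataset")
    required = list(AA_C_COLUMNS) + list(AA_N_COLUMNS) + ["bulk_s"]
    values = dataset.frame[required].to_numpy(float)
    keep = np.isfinite(values).all(axis=1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("complete-case filter dropped %d of %d rows", dropped, len(dataset))
    if not keep.any():
        raise DimensionError("no complete-case rows survive filtering")
    return dataset.subset(keep)


def fit_pca(matrix: np.ndarray, variable_names: tuple[str, ...] | None = None) -> PcaModel:
    """Correlation-matrix PCA with a deterministic sign convention.

    Each column is centered and divided by its sample sd; components are the
    eigenvectors of the resulting correlation structure, ordered by
    decreasing variance explained. The sign of each component is fixed so
    its largest-|loading| entry is positive. Per-variable contributions to a
    component are ``100·loading²`` (each column sums to 100).
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DimensionError("need an n×p matrix with n >= 2")
    if not np.isfinite(x).all():
        raise DimensionError("missing values: run complete_case_filter first")
    n, p = x.shape
    names = tuple(variable_names) if variable_names is not None else tuple(
        f"var{i + 1}" for i in range(p))
    center = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    zero_var = np.flatnonzero(scale == 0)
    if zero_var.size:
        raise DimensionError(
            "zero-variance column(s): " + ", ".join(names[i] for i in zero_var))
    z = (x - center) / scale
    corr = z.T @ z / (n - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    loadings = eigvecs[:, order]
    for j in range(p):
        i_star = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_star, j] < 0:
            loadings[:, j] = -loadings[:, j]
    explained = eigvals / eigvals.sum()
    contributions = 100.0 * loadings ** 2
    return PcaModel(names, center, scale, loadings, explained, contributions)


def build_dimension_space(
    dataset: IsotopeDataset,
    approach: str,
) -> tuple[DimensionSpace, PcaModel, PcaModel]:
    """Assemble one approach's niche space; returns the two fitted PCAs too.

    The dataset must already be complete-case filtered. Both PCAs are always
    fitted (on the δ13C and δ15N blocks respectively) so the returned models
    are identical across approaches on the same data.
    """
    if approach not in APPROACH_AXES:
        raise DimensionError(
            f"unknown approach {approach!r}; valid: {', '.join(APPROACH_AXES)}")
    pca_c = fit_pca(dataset.aa_d13c.to_numpy(), AA_C_COLUMNS)
    pca_n = fit_pca(dataset.aa_d15n.to_numpy(), AA_N_COLUMNS)
    scores_c = pca_c.transform(dataset.aa_d13c.to_numpy())
    scores_n = pca_n.transform(dataset.aa_d15n.to_numpy())
    sulphur = dataset.frame["bulk_s"].to_numpy(float)
    sd = sulphur.std(ddof=1)
    if sd == 0:
        raise DimensionError("bulk_s has zero variance; stdDeltaS undefined")
    std_s = (sulphur - sulphur.mean()) / sd
    columns = {
        "PC1-Css": scores_c[:, 0],
        "PC2-Css": scores_c[:, 1],
        "PC1-Nss": scores_n[:, 0],
        "PC2-Nss": scores_n[:, 1],
        "stdDeltaS": std_s,
    }
    axes = APPROACH_AXES[approach]
    coords = np.column_stack([columns[a] for a in axes])
    space = DimensionSpace(
        approach=approach,
        axis_names=axes,
        coords=coords,
        sample_ids=tuple(dataset.sample_ids),
        species=tuple(dataset.species),
        year=tuple(int(y) for y in dataset.year),
    )
    return space, pca_c, pca_n


def trophic_indices(
    dataset: IsotopeDataset,
    beta: float = DEFAULT_BETA,
    tdf: float = DEFAULT_TDF,
    trophic_set: tuple[str, ...] = DEFAULT_TROPHIC_SET,
    source_set: tuple[str, ...] = DEFAULT_SOURCE_SET,
) -> pd.DataFrame:
    """Per-sample trophic indices from the amino-acid δ15N values.

    glx_minus_lys and glx_minus_phe are raw ‰ spreads. tp_single is the
    single-amino-acid trophic position (glx_minus_phe − β)/TDF + 1; tp_mean
    uses mean(trophic set) − mean(source set) in place of Glx − Phe.
    """
    if tdf == 0:
        raise DimensionError("tdf must be non-zero")
    unknown = [a for a in tuple(trophic_set) + tuple(source_set) if a not in AA_ORDER]
    if unknown:
        raise DimensionError(f"unknown amino acid(s): {', '.join(unknown)}")
    n15 = dataset.aa_d15n
    glx = n15["glx_n"]
    gm_lys = glx - n15["lys_n"]
    gm_phe = glx - n15["phe_n"]
    trophic_mean = n15[[f"{a}_n" for a in trophic_set]].mean(axis=1)
    source_mean = n15[[f"{a}_n" for a in source_set]].mean(axis=1)
    return pd.DataFrame({
        "sample_id": dataset.sample_ids,
        "glx_minus_lys": gm_lys,
        "glx_minus_phe": gm_phe,
        "tp_single": (gm_phe - beta) / tdf + 1.0,
        "tp_mean": (trophic_mean - source_mean - beta) / tdf + 1.0,
    })


def validate_proxies(
    space: DimensionSpace,
    dataset: IsotopeDataset,
    indices: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Pearson correlations between niche axes and bulk values / trophic indices.

    Returns a tidy table (axis, target, r, n). A correlation-PCA component's
    orientation is a package convention, so the magnitude |r| is the
    comparable quantity; the sign column reports the orientation actually
    obtained.
    """
    if len(dataset) < 3:
        raise DimensionError("need at least 3 samples to correlate")
    if tuple(dataset.sample_ids) != space.sample_ids:
        raise DimensionError("space and dataset are not aligned on sample_id")
    targets: dict[str, np.ndarray] = {
        "bulk_c": dataset.frame["bulk_c"].to_numpy(float),
        "bulk_n": dataset.frame["bulk_n"].to_numpy(float),
    }
    if indices is not None:
        for col in ("glx_minus_lys", "glx_minus_phe", "tp_single", "tp_mean"):
            targets[col] = indices[col].to_numpy(float)
    rows = []
    for j, axis in enumerate(space.axis_names):
        for target, values in targets.items():
            ok = np.isfinite(values)
            r = stats.pearsonr(space.coords[ok, j], values[ok]).statistic if ok.sum() >= 3 else np.nan
            rows.append({"axis": axis, "target": target, "r": r,
                         "abs_r": abs(r), "n": int(ok.sum())})
    return pd.DataFrame(rows)
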