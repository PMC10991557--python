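"""Canonical tabular format for per-sample isotope measurements.

One row per (possibly pooled) egg sample. Columns, in canonical order:
``sample_id, species, year, site`` followed by the ten amino-acid δ13C
columns (``ala_c`` … ``lys_c``), the ten amino-acid δ15N columns
(``ala_n`` … ``lys_n``) and the three bulk values ``bulk_c, bulk_n,
bulk_s``. All δ values are in ‰. UTF-8, comma delimiter, period decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("isoniche")

#: Fixed amino-acid order used everywhere in the package.
AA_ORDER: tuple[str, ...] = (
    "ala", "val", "gly", "ile", "leu", "pro", "asp", "phe", "glx", "lys",
)

AA_FULL_NAMES: dict[str, str] = {
    "ala": "alanine", "val": "valine", "gly": "glycine",
    "ile": "isoleucine", "leu": "leucine", "pro": "proline",
    "asp": "aspartic acid", "phe": "phenylalanine",
    "glx": "glutamic acid (Glx)", "lys": "lysine",
}

AA_C_COLUMNS: tuple[str, ...] = tuple(f"{aa}_c" for aa in AA_ORDER)
AA_N_COLUMNS: tuple[str, ...] = tuple(f"{aa}_n" for aa in AA_ORDER)
BULK_COLUMNS: tuple[str, ...] = ("bulk_c", "bulk_n", "bulk_s")
META_COLUMNS: tuple[str, ...] = ("sample_id", "species", "year", "site")
CANONICAL_COLUMNS: tuple[str, ...] = (
    META_COLUMNS + AA_C_COLUMNS + AA_N_COLUMNS + BULK_COLUMNS
)
TRACER_COLUMNS: tuple[str, ...] = AA_C_COLUMNS + AA_N_COLUMNS + BULK_COLUMNS


class DatasetError(ValueError):
    """Raised when a table does not satisfy the canonical-schema contract."""


@dataclass
class ValidationReport:
    """What `read_dataset` noticed while typing a table."""

    n_rows: int = 0
    n_missing_cells: int = 0
    duplicate_ids: list[str] = field(default_factory=list)
    species_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.duplicate_ids


@dataclass(frozen=True)
class IsotopeDataset:
    """Typed wrapper around the canonical per-sample isotope table.

    The underlying frame always carries the canonical columns in canonical
    order; missing measurements are NaN (they survive until
    :func:`isoniche.dimensions.complete_case_filter` removes them).
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.frame.columns]
        if missing:
            raise DatasetError(f"missing mandatory column(s): {', '.join(missing)}")
        dup = self.frame["sample_id"][self.frame["sample_id"].duplicated()]
        if len(dup):
            raise DatasetError(f"duplicate sample_id(s): {sorted(set(dup))}")
        frame = self.frame[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        frame = frame.astype({c: float for c in TRACER_COLUMNS} | {"year": int})
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def species(self) -> pd.Series:
        return self.frame["species"]

    @property
    def sample_ids(self) -> pd.Series:
        return self.frame["sample_id"]

    @property
    def year(self) -> pd.Series:
        return self.frame["year"]

    @property
    def aa_d13c(self) -> pd.DataFrame:
        """n×10 amino-acid δ13C block (‰), canonical amino-acid order."""
        return self.frame[list(AA_C_COLUMNS)]

    @property
    def aa_d15n(self) -> pd.DataFrame:
        """n×10 amino-acid δ15N block (‰), canonical amino-acid order."""
        return self.frame[list(AA_N_COLUMNS)]

    @property
    def bulk(self) -> pd.DataFrame:
        return self.frame[list(BULK_COLUMNS)]

    def subset(self, mask) -> "IsotopeDataset":
        return IsotopeDataset(self.frame[np.asarray(mask)].reset_index(drop=True))

    def species_names(self) -> list[str]:
        return list(dict.fromkeys(self.frame["species"]))


def read_dataset(path: str | Path) -> tuple[IsotopeDataset, ValidationReport]:
    """Read a canonical CSV, returning the typed dataset and a validation report.

    Raises :class:`DatasetError` naming the column if a mandatory column is
    absent, or listing duplicate ``sample_id`` values.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    dataset = IsotopeDataset(frame)
    tracers = dataset.frame[list(TRACER_COLUMNS)]
    report = ValidationReport(
        n_rows=len(dataset),
        n_missing_cells=int(tracers.isna().sum().sum()),
        species_counts=dataset.species.value_counts().to_dict(),
    )
    log.info("read %d samples (%d missing cells) from %s",
             report.n_rows, report.n_missing_cells, path)
    return dataset, report


def write_dataset(dataset: IsotopeDataset, path: str | Path) -> None:
    """Write the canonical CSV dialect (byte-stable under read/write cycles)."""
    dataset.frame.to_csv(path, index=False, lineterminator="\n")
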