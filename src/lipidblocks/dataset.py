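"""The samples x species abundance container with its sample metadata.

A :class:`LipidomeDataset` couples a wide non-negative abundance matrix
(rows = individual fish samples, columns = lipid species in shorthand) with
per-sample metadata (tissue, life stage, diet group, day, tank, fish) and
parsed species annotations.  Delimited-text round-trip is provided so every
pipeline stage can be audited from files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .nomenclature import LipidSpecies, parse_lipid_name

#: Metadata columns every dataset must carry.
META_COLUMNS = ("tissue", "stage", "diet_group", "day", "tank", "fish")

#: The eight diet-group levels of the switch design.  ``D5/6`` is a single
#: nominal level: the freshwater trial sampled day 5, the seawater trial
#: day 6.
DIET_GROUPS = (
    "D0_FO", "D1_FOVO", "D5/6_FOVO", "D20_FOVO",
    "D0_VO", "D1_VOFO", "D5/6_VOFO", "D20_VOFO",
)

TISSUES = ("gut", "liver", "muscle")
STAGES = ("FW", "SW")


class DatasetError(ValueError):
    """Raised when abundance matrix and metadata disagree."""


@dataclass
class LipidomeDataset:
    abundance: pd.DataFrame
    sample_meta: pd.DataFrame
    species: list[LipidSpecies] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = [parse_lipid_name(c) for c in self.abundance.columns]
        names = [s.name for s in self.species]
        if list(self.abundance.columns) != names:
            raise DatasetError("abundance columns do not match species annotations")
        if not self.abundance.index.equals(self.sample_meta.index):
            raise DatasetError("abundance rows do not match sample metadata index")
        missing = set(META_COLUMNS) - set(self.sample_meta.columns)
        if missing:
            raise DatasetError(f"sample metadata missing columns: {sorted(missing)}")
        if (self.abundance.to_numpy() < 0).any():
            raise DatasetError("abundances must be non-negative")

    # -- convenience ------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_species(self) -> int:
        return self.abundance.shape[1]

    def subset_tissue(self, tissue: str) -> "LipidomeDataset":
        mask = self.sample_meta["tissue"] == tissue
        if not mask.any():
            raise DatasetError(f"no samples for tissue {tissue!r}")
        return LipidomeDataset(
            self.abundance.loc[mask].copy(),
            self.sample_meta.loc[mask].copy(),
            list(self.species),
        )

    def with_abundance(self, abundance: pd.DataFrame) -> "LipidomeDataset":
        return LipidomeDataset(abundance, self.sample_meta.copy(), list(self.species))

    def check_balanced(self, n_per_cell: int | None = None) -> int:
        """Verify the diet-group x stage design is balanced within each tissue;
        returns the common per-cell n."""
        sizes = set()
        for _, sub in self.sample_meta.groupby("tissue", observed=True):
            counts = sub.groupby(["diet_group", "stage"], observed=True).size()
            sizes.update(counts.tolist())
        if len(sizes) != 1:
            raise DatasetError(f"unbalanced design: cell sizes {sorted(sizes)}")
        n = sizes.pop()
        if n_per_cell is not None and n != n_per_cell:
            raise DatasetError(f"expected n={n_per_cell} per cell, found n={n}")
        return n

    # -- delimited-text round trip ---------------------------------------

    def to_csv(self, abundance_path: str | Path, meta_path: str | Path) -> None:
        self.abundance.to_csv(abundance_path, index_label="sample_id", float_format="%.10g")
        self.sample_meta.to_csv(meta_path, index_label="sample_id")

    @classmethod
    def from_csv(cls, abundance_path: str | Path, meta_path: str | Path) -> "LipidomeDataset":
        ab = pd.read_csv(abundance_path, index_col="sample_id")
        meta = pd.read_csv(meta_path, index_col="sample_id")
        meta = meta.loc[ab.index]
        return cls(ab, meta)

    def species_table(self) -> pd.DataFrame:
        """Species annotation table: name, class, carbons, double_bonds."""
        return pd.DataFrame(
            {
                "name": [s.name for s in self.species],
                "class": [s.lipid_class for s in self.species],
                "carbons": [s.carbons for s in self.species],
                "double_bonds": [s.double_bonds for s in self.species],
            }
        ).set_index("name")


def log2_safe(values: np.ndarray | pd.DataFrame) -> np.ndarray | pd.DataFrame:
    """log2 that raises on non-positive entries instead of emitting -inf."""
    arr = values.to_numpy() if isinstance(values, pd.DataFrame) else np.asarray(values)
    if (arr <= 0).any():
        raise DatasetError("log2 requires strictly positive abundances")
    return np.log2(values)
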