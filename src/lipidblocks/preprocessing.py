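"""Sample normalization and the multiblock centering/scaling chain.

The chain mirrors standard chemometric practice for class-partitioned
lipidomes:

1. per-sample normalization — each sample is divided by a scalar size
   factor so abundances are comparable across injections.  The default is
   the median of log ratios to a reference sample ("normalize to all
   compounds"); a simple total-sum alternative is available.
2. autoscaling — every species column is mean-centered and divided by its
   standard deviation (ddof=1), per block;
3. block weighting — each class block is divided by the square root of its
   total sum of squares, so all five blocks enter the consensus model with
   equal total SS regardless of how many species they contain.

All transform parameters are retained, making the chain invertible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import LipidomeDataset
from .nomenclature import BlockPartition, DEFAULT_PARTITION, assign_block


class NormalizationError(ValueError):
    """Raised when a sample cannot be normalized against the reference."""


class ScalingError(ValueError):
    """Raised for zero-variance columns or empty blocks."""


MIN_SHARED_SPECIES = 10


# ---------------------------------------------------------------------------
# Per-sample normalization

def _auto_reference(abundance: pd.DataFrame) -> str:
    """Sample whose log total abundance is the median (lower median for even n)."""
    totals = abundance.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise NormalizationError(f"samples with zero total abundance: {bad}")
    order = np.argsort(np.log(totals.to_numpy()), kind="stable")
    return str(abundance.index[order[(len(order) - 1) // 2]])

def normalize_to_all(
    dataset: LipidomeDataset,
    reference: str = "auto",
    mode: str = "median_ratio",
) -> tuple[LipidomeDataset, pd.Series]:
    """Scale every sample by a scalar factor; returns (dataset, factors).

    ``median_ratio`` (default): factor_s = exp(median of log(x_s / x_ref))
    over species nonzero in both the sample and the reference; zeros are
    treated as missing, never logged.  ``total_sum``: factor_s =
    total_s / total_ref.  Factors are relative to the reference, whose own
    factor is exactly 1.
    """
    ab = dataset.abundance
    ref = _auto_reference(ab) if reference == "auto" else reference
    if ref not in ab.index:
        raise NormalizationError(f"reference sample {ref!r} not in dataset")
    ref_vals = ab.loc[ref].to_numpy()

    factors = {}
    if mode == "median_ratio":
        for sid in ab.index:
            vals = ab.loc[sid].to_numpy()
            shared = (vals > 0) & (ref_vals > 0)
            if shared.sum() < MIN_SHARED_SPECIES:
                raise NormalizationError(
                    f"sample {sid!r} shares only {int(shared.sum())} nonzero species "
                    f"with reference {ref!r} (need >= {MIN_SHARED_SPECIES})"
                )
            factors[sid] = float(
                np.exp(np.median(np.log(vals[shared] / ref_vals[shared])))
            )
    elif mode == "total_sum":
        ref_total = ref_vals.sum()
        for sid in ab.index:
            factors[sid] = float(ab.loc[sid].sum() / ref_total)
    else:
        raise NormalizationError(f"unknown normalization mode {mode!r}")

    fac = pd.Series(factors, name="factor").loc[ab.index]
    normalized = ab.div(fac, axis=0)
    return dataset.with_abundance(normalized), fac


# ---------------------------------------------------------------------------
# Blocks

@dataclass
class Block:
    """One preprocessed class block with its stored transform parameters."""

    data: pd.DataFrame          # samples x species, centered/scaled/weighted
    means: pd.Series            # per-species column means
    sds: pd.Series              # per-species column sds (ddof=1)
    weight: float = 1.0         # scalar divisor applied block-wise

    @property
    def total_ss(self) -> float:
        return float(np.sum(self.data.to_numpy() ** 2))

    def inverse(self) -> pd.DataFrame:
        """Undo weighting, scaling and centering."""
        return self.data * self.weight * self.sds + self.means


@dataclass
class BlockSet:
    """The five class blocks sharing one sample dimension."""

    blocks: dict[str, Block]

    def __post_init__(self) -> None:
        indexes = [b.data.index for b in self.blocks.values()]
        if any(not idx.equals(indexes[0]) for idx in indexes[1:]):
            raise ScalingError("blocks do not share the sample dimension")

    @property
    def sample_index(self) -> pd.Index:
        return next(iter(self.blocks.values())).data.index

    @property
    def labels(self) -> list[str]:
        return list(self.blocks)

    def concatenated(self) -> pd.DataFrame:
        return pd.concat([b.data for b in self.blocks.values()], axis=1)

    def total_ss(self) -> dict[str, float]:
        return {label: b.total_ss for label, b in self.blocks.items()}


def center_and_scale(block: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Autoscale columns to mean 0, sd 1 (ddof=1); returns (matrix, means, sds)."""
    if block.shape[0] < 2:
        raise ScalingError("need >= 2 samples to scale")
    means = block.mean(axis=0)
    sds = block.std(axis=0, ddof=1)
    zero_var = sds[sds == 0].index.tolist()
    if zero_var:
        raise ScalingError(f"zero-variance species cannot be scaled: {zero_var}")
    return (block - means) / sds, means, sds


def blockwise_ss_scale(blocks: BlockSet) -> BlockSet:
    """Divide each block by the square root of its total sum of squares.

    Afterwards every block has total SS exactly 1, giving each lipid class
    equal weight in the consensus model.
    """
    scaled: dict[str, Block] = {}
    for label, b in blocks.blocks.items():
        if b.data.shape[1] == 0:
            raise ScalingError(f"block {label!r} is empty")
        ss = b.total_ss
        if ss == 0:
            raise ScalingError(f"block {label!r} has zero total sum of squares")
        divisor = float(np.sqrt(ss))
        scaled[label] = Block(b.data / divisor, b.means, b.sds, b.weight * divisor)
    return BlockSet(scaled)


def partition_columns(
    dataset: LipidomeDataset, partition: BlockPartition = DEFAULT_PARTITION
) -> dict[str, list[str]]:
    """Group species column names by analysis block, preserving column order."""
    groups: dict[str, list[str]] = {}
    for sp in dataset.species:
        groups.setdefault(assign_block(sp, partition), []).append(sp.name)
    return groups


def build_blocks(
    dataset: LipidomeDataset,
    partition: BlockPartition = DEFAULT_PARTITION,
) -> BlockSet:
    """Partition a (normalized) dataset into blocks and run the full
    centering / autoscaling / block-SS-weighting chain."""
    groups = partition_columns(dataset, partition)
    blocks: dict[str, Block] = {}
    for label, cols in groups.items():
        mat, means, sds = center_and_scale(dataset.abundance[cols])
        blocks[label] = Block(mat, means, sds)
    return blockwise_ss_scale(BlockSet(blocks))
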