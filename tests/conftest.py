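from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from lipidblocks.preprocessing import Block, BlockSet, blockwise_ss_scale, center_and_scale
from lipidblocks.simulate import SimulationConfig, generate_experiment

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def small_sim_config(**overrides) -> SimulationConfig:
    """A reduced synthetic experiment: one tissue, 40 species, n=4 per cell."""
    defaults = dict(
        n_species={"TG": 12, "PC": 10, "PE": 8, "DG": 5, "Other": 5},
        tissues=("gut",),
        k={("SW", "gut"): 0.6, ("FW", "gut"): 0.3},
        seed=11,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def make_blockset(
    rng: np.random.Generator, n_samples: int, widths: list[int]
) -> BlockSet:
    """Random centered/autoscaled/SS-weighted blocks sharing a sample index."""
    index = pd.Index([f"s{i}" for i in range(n_samples)], name="sample_id")
    blocks = {}
    for b, width in enumerate(widths):
        raw = pd.DataFrame(
            rng.normal(size=(n_samples, width)),
            index=index,
            columns=[f"b{b}v{j}" for j in range(width)],
        )
        mat, means, sds = center_and_scale(raw)
        blocks[f"B{b}"] = Block(mat, means, sds)
    return blockwise_ss_scale(BlockSet(blocks))


@pytest.fixture(scope="session")
def small_experiment():
    return generate_experiment(small_sim_config())


@pytest.fixture(scope="session")
def gut_normalized(small_experiment):
    from lipidblocks.preprocessing import normalize_to_all

    dataset, _ = small_experiment
    ds_norm, _ = normalize_to_all(dataset.subset_tissue("gut"))
    return ds_norm
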