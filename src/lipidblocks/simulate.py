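"""Synthetic diet-switch lipidome experiments with known ground truth.

The generator emulates the statistical design the analysis expects: three
tissues x two life stages (freshwater FW, seawater SW) x eight diet groups
(day-0 fish-oil and vegetable-oil controls plus days 1, 5/6 and 20 after
switching in either direction) x four fish per cell (two per tank, two
tanks), with roughly 300 lipid species across TG/PC/PE/DG/Other classes.

Remodeling follows first-order kinetics on the log scale: after a switch at
day 0 the expected log2 abundance relaxes exponentially from the source
diet's steady state toward the target diet's,

    y(t) = y_target + (y_source - y_target) * exp(-k t),

with a rate constant k per (stage, tissue) — faster in the seawater gut.
Life-stage offsets are concentrated in phospholipid species, tanks share a
small additive log-scale effect, and measurement noise is log-normal.  The
nominal "day 5" level is sampled at t=5 in FW and t=6 in SW but coded as a
single factor level, as in the real design.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .dataset import DIET_GROUPS, LipidomeDataset, STAGES, TISSUES
from .nomenclature import LipidSpecies

LN2 = float(np.log(2.0))


class SimulationConfigError(ValueError):
    pass


def _default_n_species() -> dict[str, int]:
    return {"TG": 120, "PC": 80, "PE": 50, "DG": 20, "Other": 30}


def _default_k() -> dict[tuple[str, str], float]:
    # 1/day; SW gut remodels fastest, muscle far from steady state by day 20
    return {
        ("SW", "gut"): 0.60, ("FW", "gut"): 0.30,
        ("SW", "liver"): 0.35, ("FW", "liver"): 0.30,
        ("SW", "muscle"): 0.06, ("FW", "muscle"): 0.05,
    }


@dataclass
class SimulationConfig:
    """Design and effect-size parameters of the synthetic experiment.

    Baseline log2 abundances put TG/PC/PE far above the minor classes so the
    three dominant classes carry >90% of total abundance.  ``noise_cv`` is
    the multiplicative coefficient of variation of a single measurement;
    ``tank_sd_log2`` the s.d. of the shared per-tank offset.  Diet effects
    (log2 difference between fish-oil and vegetable-oil steady states) hit a
    configurable fraction of species, signed by unsaturation: highly
    unsaturated species are richer under fish oil.  Stage offsets hit a
    fraction of PC/PE species, mostly lower in seawater.
    """

    n_species: dict[str, int] = field(default_factory=_default_n_species)
    tissues: tuple[str, ...] = TISSUES
    stages: tuple[str, ...] = STAGES
    days: tuple[int, ...] = (0, 1, 5, 20)
    n_tanks: int = 2
    n_fish_per_tank: int = 2
    k: dict[tuple[str, str], float] = field(default_factory=_default_k)
    base_log2: dict[str, float] = field(
        default_factory=lambda: {"TG": 10.0, "PC": 9.3, "PE": 8.6, "DG": 6.0, "Other": 5.3}
    )
    base_scatter_log2: float = 1.2
    diet_effect_fraction: float = 0.5
    diet_effect_mean_log2: float = 1.8
    diet_effect_sd_log2: float = 0.5
    high_db_threshold: int = 8      # DB >= threshold => higher under fish oil
    stage_offset_fraction: float = 0.4   # of PC/PE species
    stage_offset_log2: float = 1.5
    stage_offset_positive_fraction: float = 0.1  # few PL species higher in SW
    noise_cv: float = 0.15
    tank_sd_log2: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_tanks < 1 or self.n_fish_per_tank < 1:
            raise SimulationConfigError("need at least one tank and one fish per tank")
        if self.noise_cv <= 0:
            raise SimulationConfigError("noise_cv must be positive")
        if any(v < 0 for v in self.k.values()):
            raise SimulationConfigError("rate constants must be non-negative")
        missing = [
            (s, t) for s in self.stages for t in self.tissues if (s, t) not in self.k
        ]
        if missing:
            raise SimulationConfigError(f"rate constants missing for {missing}")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated experiment.

    ``species_params`` holds, per species, the fish-oil and vegetable-oil
    steady-state log2 means, the stage offset, and null/effect labels;
    ``k`` is the (stage, tissue) rate-constant table.  Expected noise-free
    cell values follow from these via the generator's kinetic model.
    """

    species_params: pd.DataFrame
    k: Mapping[tuple[str, str], float]
    config: SimulationConfig

    def expected_log2(self, tissue: str, stage: str, diet_group: str) -> pd.Series:
        """Noise-free expected log2 abundance per species for one design cell."""
        p = self.species_params
        history, switched, t = _decode_group(diet_group, stage)
        y_src = p["mu_FO"] if history == "FO" else p["mu_VO"]
        y_tgt = p["mu_VO"] if history == "FO" else p["mu_FO"]
        if switched:
            y = y_tgt + (y_src - y_tgt) * np.exp(-self.k[(stage, tissue)] * t)
        else:
            y = y_src.copy()
        if stage == "SW":
            y = y + p["stage_offset_log2"]
        y.name = f"{tissue}|{stage}|{diet_group}"
        return y

    def expected_cell_table(self, tissue: str) -> pd.DataFrame:
        """Species x (stage|diet_group) table of expected log2 abundances."""
        cols = {
            f"{s}|{g}": self.expected_log2(tissue, s, g)
            for s in self.config.stages
            for g in DIET_GROUPS
        }
        return pd.DataFrame(cols)

    def truth_contrast_table(self, tissue: str, contrast: str) -> pd.Series:
        """Expected log2 fold change per species for a named contrast.

        Contrasts: ``"stage:<diet_group>"`` (SW minus FW within a diet
        group) or ``"switch:<stage>:<switched_group>:<control_group>"``.
        """
        parts = contrast.split(":")
        if parts[0] == "stage" and len(parts) == 2:
            g = parts[1]
            if g not in DIET_GROUPS:
                raise KeyError(f"unknown diet group {g!r}")
            return (
                self.expected_log2(tissue, "SW", g)
                - self.expected_log2(tissue, "FW", g)
            ).rename(contrast)
        if parts[0] == "switch" and len(parts) == 4:
            _, stage, ga, gb = parts
            return (
                self.expected_log2(tissue, stage, ga)
                - self.expected_log2(tissue, stage, gb)
            ).rename(contrast)
        raise KeyError(f"unknown contrast {contrast!r}")

    def to_csv(self, path) -> None:
        df = self.species_params.copy()
        df.to_csv(path, index_label="species", float_format="%.10g")


def _decode_group(diet_group: str, stage: str) -> tuple[str, bool, float]:
    """Decode a diet-group label into (starting diet, switched?, time in days)."""
    if diet_group not in DIET_GROUPS:
        raise KeyError(f"unknown diet group {diet_group!r}")
    day_part, diet_part = diet_group.split("_")
    if diet_part in ("FO", "VO"):
        return diet_part, False, 0.0
    history = diet_part[:2]  # FOVO -> FO start, VOFO -> VO start
    day = day_part.lstrip("D")
    t = 6.0 if (day == "5/6" and stage == "SW") else float(day.replace("5/6", "5"))
    return history, True, t


# ---------------------------------------------------------------------------
# Species catalogue

#: (class, carbon grid, double-bond grid, acyl-chain count); the chain count
#: caps double bonds at roughly (C - 2*chains)/3, the polyunsaturation
#: ceiling of natural fatty acyls (DHA-level, ~1 double bond per 3 carbons)
_CLASS_GRIDS = {
    "TG": ("TG", range(44, 70, 2), range(0, 19), 3),
    "PC": ("PC", range(30, 46, 2), range(0, 13), 2),
    "PE": ("PE", range(30, 46, 2), range(0, 13), 2),
    "DG": ("DG", range(28, 45, 2), range(0, 9), 2),
}
_OTHER_CLASSES = [
    ("SM", range(32, 45, 2), range(1, 4)),
    ("LPC", range(16, 23), range(0, 7)),
    ("CER", range(32, 45, 2), range(0, 3)),
    ("MG", range(16, 23), range(0, 7)),
    ("CE", range(16, 23), range(0, 7)),
]


def _draw_species(rng: np.random.Generator, block: str, count: int) -> list[LipidSpecies]:
    if block in _CLASS_GRIDS:
        cls, c_range, db_range, chains = _CLASS_GRIDS[block]
        grid = [
            (cls, c, d)
            for c in c_range
            for d in db_range
            if d <= (c - 2 * chains) // 3
        ]
    else:
        grid = [
            (cls, c, d)
            for cls, c_range, db_range in _OTHER_CLASSES
            for c in c_range
            for d in db_range
            if d <= (c - 2) // 2
        ]
    if count > len(grid):
        raise SimulationConfigError(
            f"cannot draw {count} distinct {block} species from a grid of {len(grid)}"
        )
    idx = rng.choice(len(grid), size=count, replace=False)
    chosen = sorted(grid[i] for i in idx)
    return [LipidSpecies(cls, c, d) for cls, c, d in chosen]


# ---------------------------------------------------------------------------
# Generation

def generate_experiment(config: SimulationConfig) -> tuple[LipidomeDataset, SyntheticTruth]:
    """Generate one full diet-switch experiment plus its ground truth.

    Identical configs (including seed) give bit-identical datasets.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    species: list[LipidSpecies] = []
    for block, count in config.n_species.items():
        species.extend(_draw_species(rng, block, count))
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise SimulationConfigError("species catalogue contains duplicates")
    n_sp = len(species)

    cls = np.array([s.lipid_class for s in species])
    db = np.array([s.double_bonds for s in species])
    base_block = np.array(
        [
            config.base_log2.get(s.lipid_class, config.base_log2["Other"])
            for s in species
        ]
    )
    base = base_block + rng.normal(0.0, config.base_scatter_log2, n_sp)

    responsive = rng.random(n_sp) < config.diet_effect_fraction
    magnitude = np.abs(
        rng.normal(config.diet_effect_mean_log2, config.diet_effect_sd_log2, n_sp)
    )
    sign = np.where(db >= config.high_db_threshold, 1.0, -1.0)
    delta = np.where(responsive, sign * magnitude, 0.0)  # mu_FO - mu_VO

    is_pl = np.isin(cls, ("PC", "PE"))
    offset_candidate = is_pl & (rng.random(n_sp) < config.stage_offset_fraction)
    offset_sign = np.where(
        rng.random(n_sp) < config.stage_offset_positive_fraction, 1.0, -1.0
    )
    stage_offset = np.where(offset_candidate, offset_sign * config.stage_offset_log2, 0.0)

    params = pd.DataFrame(
        {
            "class": cls,
            "double_bonds": db,
            "base_log2": base,
            "mu_FO": base + delta / 2.0,
            "mu_VO": base - delta / 2.0,
            "diet_delta_log2": delta,
            "stage_offset_log2": stage_offset,
            "is_diet_responsive": responsive,
            "is_stage_offset": offset_candidate,
            "is_null": ~(responsive | offset_candidate),
        },
        index=pd.Index(names, name="species"),
    )
    truth = SyntheticTruth(params, dict(config.k), config)

    # tank offsets shared across tissues and species within (stage, group, tank)
    tank_offset = {
        (s, g, tk): rng.normal(0.0, config.tank_sd_log2)
        for s in config.stages
        for g in DIET_GROUPS
        for tk in range(1, config.n_tanks + 1)
    }

    sigma_ln = float(np.sqrt(np.log1p(config.noise_cv**2)))

    rows_meta = []
    rows_ab = []
    for tissue in config.tissues:
        for stage in config.stages:
            for g in DIET_GROUPS:
                mu = truth.expected_log2(tissue, stage, g).to_numpy()
                for tk in range(1, config.n_tanks + 1):
                    for f in range(1, config.n_fish_per_tank + 1):
                        sid = f"{tissue}-{stage}-{g.replace('/', '.')}-t{tk}-f{f}"
                        eps = rng.normal(0.0, sigma_ln, n_sp)
                        log2_val = mu + tank_offset[(stage, g, tk)] + eps / LN2
                        rows_ab.append(np.exp2(log2_val))
                        rows_meta.append(
                            {
                                "sample_id": sid,
                                "tissue": tissue,
                                "stage": stage,
                                "diet_group": g,
                                "day": _decode_group(g, stage)[2],
                                "tank": f"{stage}-{g}-tank{tk}",
                                "fish": f"{stage}-{g}-t{tk}-f{f}",
                            }
                        )

    meta = pd.DataFrame(rows_meta).set_index("sample_id")
    abundance = pd.DataFrame(np.vstack(rows_ab), index=meta.index, columns=names)
    dataset = LipidomeDataset(abundance, meta, species)
    return dataset, truth
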