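"""End-to-end orchestration: generate/ingest -> normalize -> blocks -> CPCA
-> differential abundance -> reports.

Every stage is a pure function of (inputs, config, seed); outputs are
delimited text with fixed float formatting, so a rerun with the same config
is byte-identical, and the run manifest records a config hash plus a SHA-256
checksum per output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import cpca as cpca_mod
from . import differential as da_mod
from . import preprocessing as pre_mod
from .dataset import LipidomeDataset
from .simulate import SimulationConfig, generate_experiment

log = logging.getLogger("lipidblocks")

FLOAT_FMT = "%.10g"


class PipelineConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run.

    Either ``simulation`` (a :class:`SimulationConfig`) or the pair
    ``abundance_path``/``metadata_path`` must be provided.
    """

    outdir: str = "results/pipeline"
    seed: int = 0
    simulation: SimulationConfig | None = None
    abundance_path: str | None = None
    metadata_path: str | None = None
    tissues: tuple[str, ...] | None = None     # None = all tissues present
    normalization_mode: str = "median_ratio"
    normalization_reference: str = "auto"
    n_components: int = 2
    cpca_tol: float = 1e-10
    cpca_max_iter: int = 5000
    p_source: str = "tukey"
    lfc_threshold: float = 1.0
    p_threshold: float = 0.05
    n_cluster_groups: int = 4
    write_plots: bool = False

    def __post_init__(self) -> None:
        if self.lfc_threshold <= 0 or not (0 < self.p_threshold < 1):
            raise PipelineConfigError("thresholds must be positive (p in (0,1))")
        if self.simulation is None and not (self.abundance_path and self.metadata_path):
            raise PipelineConfigError(
                "provide either a simulation config or abundance+metadata paths"
            )

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.pop("simulation", None)
        if sim is not None and not isinstance(sim, SimulationConfig):
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(sim) - sim_known
            if sim_unknown:
                raise PipelineConfigError(
                    f"unknown simulation config keys: {sorted(sim_unknown)}"
                )
            if "k" in sim and isinstance(sim["k"], dict):
                sim["k"] = {
                    tuple(key.split("|")) if isinstance(key, str) else tuple(key): v
                    for key, v in sim["k"].items()
                }
            if "n_species" in sim:
                sim["n_species"] = dict(sim["n_species"])
            sim = SimulationConfig(**sim)
        if "tissues" in raw and raw["tissues"] is not None:
            raw["tissues"] = tuple(raw["tissues"])
        return cls(simulation=sim, **raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        raw = yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise PipelineConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(raw)

    def to_jsonable(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            sim = dataclasses.asdict(self.simulation)
            sim["k"] = {"|".join(key): v for key, v in self.simulation.k.items()}
            d["simulation"] = sim
        return d

    def config_hash(self) -> str:
        # the hash identifies the analysis, not where it is stored
        payload = {k: v for k, v in self.to_jsonable().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index_label: str) -> None:
    df.to_csv(path, index_label=index_label, float_format=FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages per tissue; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    warnings_seen: list[str] = []

    if config.simulation is not None:
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        log.info("simulate: generating synthetic experiment (seed=%d)", config.seed)
        dataset, truth = generate_experiment(sim)
        dataset.to_csv(outdir / "abundance.csv", outdir / "sample_meta.csv")
        truth.to_csv(outdir / "truth_species.csv")
        outputs += [outdir / "abundance.csv", outdir / "sample_meta.csv",
                    outdir / "truth_species.csv"]
    else:
        log.info("ingest: %s", config.abundance_path)
        dataset = LipidomeDataset.from_csv(config.abundance_path, config.metadata_path)

    tissues = (
        list(config.tissues)
        if config.tissues
        else sorted(dataset.sample_meta["tissue"].unique())
    )
    log.info("dataset: %d samples x %d species; tissues=%s",
             dataset.n_samples, dataset.n_species, tissues)

    da_counts: dict[str, int] = {}
    for tissue in tissues:
        tdir = outdir / tissue
        tdir.mkdir(exist_ok=True)
        ds_t = dataset.subset_tissue(tissue)

        ds_norm, factors = pre_mod.normalize_to_all(
            ds_t, reference=config.normalization_reference, mode=config.normalization_mode
        )
        _write_csv(factors.to_frame(), tdir / "normalization_factors.csv", "sample_id")
        _write_csv(ds_norm.abundance, tdir / "normalized_abundance.csv", "sample_id")
        log.info("%s: normalized %d samples (mode=%s)", tissue, ds_norm.n_samples,
                 config.normalization_mode)

        blocks = pre_mod.build_blocks(ds_norm)
        model = cpca_mod.fit_cpca(
            blocks, config.n_components, tol=config.cpca_tol,
            max_iter=config.cpca_max_iter,
        )
        if not all(model.converged):
            msg = f"{tissue}: CPCA non-convergence in components " \
                  f"{[i + 1 for i, ok in enumerate(model.converged) if not ok]}"
            warnings_seen.append(msg)
            log.warning(msg)
        _write_csv(model.global_scores, tdir / "global_scores.csv", "sample_id")
        _write_csv(model.super_weights, tdir / "super_weights.csv", "block")
        _write_csv(model.ev_block, tdir / "explained_variance_block.csv", "block")
        _write_csv(model.ev_global.to_frame(), tdir / "explained_variance.csv", "component")
        for lab in blocks.labels:
            _write_csv(model.block_scores[lab], tdir / f"block_scores_{lab}.csv", "sample_id")
            _write_csv(model.block_loadings[lab], tdir / f"block_loadings_{lab}.csv", "species")
        loadings = cpca_mod.correlation_loadings(model, ds_norm.abundance)
        _write_csv(loadings.to_frame(), tdir / "correlation_loadings.csv", "species")
        log.info("%s: CPCA EV per component: %s", tissue,
                 [round(v, 3) for v in model.ev_global])

        da = da_mod.run_differential(
            ds_norm,
            lfc_threshold=config.lfc_threshold,
            p_threshold=config.p_threshold,
            p_source=config.p_source,
            n_cluster_groups=config.n_cluster_groups,
        )
        _write_csv(da, tdir / "da_results.csv", "species")
        da_counts[tissue] = int(da["significant"].sum())
        log.info("%s: %d / %d species significant (|log2FC|>%g and p<%g)",
                 tissue, da_counts[tissue], len(da), config.lfc_threshold,
                 config.p_threshold)

        if config.write_plots:
            from . import plotting
            plotting.global_score_plot(model, ds_norm.sample_meta,
                                       tdir / "global_score_plot.png")
            plotting.block_score_plots(model, ds_norm.sample_meta,
                                       tdir / "block_score_plots.png")
            plotting.correlation_loading_plot(loadings, tdir / "correlation_loadings.png")
            flagged = da.index[da["significant"]]
            if len(flagged) >= 2:
                plotting.da_heatmap(ds_norm, da, tdir / "da_heatmap.png")

        outputs += sorted(tdir.glob("*.csv"))

    counts = pd.Series(da_counts, name="n_significant")
    _write_csv(counts.to_frame(), outdir / "summary_counts.csv", "tissue")
    outputs.append(outdir / "summary_counts.csv")

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tissues": tissues,
        "n_samples": dataset.n_samples,
        "n_species": dataset.n_species,
        "significant_per_tissue": da_counts,
        "warnings": warnings_seen,
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(outputs))
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
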