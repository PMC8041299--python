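#!/usr/bin/env python
"""Consensus PCA of each tissue's five class blocks.

Writes global/block scores, explained variance and correlation loadings
under results/cpca/<tissue>/, plus the three figure types (global score
plot, block score plots, correlation-loading circle plot), and prints which
axes separate diet histories and life stages.
"""

from pathlib import Path

from lipidblocks import plotting
from lipidblocks.cpca import correlation_loadings, fit_cpca
from lipidblocks.dataset import LipidomeDataset, TISSUES
from lipidblocks.preprocessing import build_blocks

SYN = Path("results/synthetic")
PRE = Path("results/preprocessing")
OUT = Path("results/cpca")


def main() -> None:
    for tissue in TISSUES:
        ds = LipidomeDataset.from_csv(
            PRE / tissue / "normalized_abundance.csv", SYN / "sample_meta.csv"
        )
        blocks = build_blocks(ds)
        model = fit_cpca(blocks, 2)
        tdir = OUT / tissue
        tdir.mkdir(parents=True, exist_ok=True)
        model.global_scores.to_csv(tdir / "global_scores.csv",
                                   index_label="sample_id", float_format="%.10g")
        model.ev_global.to_frame().to_csv(tdir / "explained_variance.csv",
                                          index_label="component", float_format="%.10g")
        loadings = correlation_loadings(model, ds.abundance)
        loadings.to_frame().to_csv(tdir / "correlation_loadings.csv",
                                   index_label="species", float_format="%.10g")
        plotting.global_score_plot(model, ds.sample_meta, tdir / "global_score_plot.png")
        plotting.block_score_plots(model, ds.sample_meta, tdir / "block_score_plots.png")
        plotting.correlation_loading_plot(loadings, tdir / "correlation_loadings.png")

        ev = model.ev_global
        # which axis separates the two diet histories / the two stages?
        scores = model.global_scores.join(ds.sample_meta[["diet_group", "stage"]])
        history = scores["diet_group"].str.split("_").str[-1].str[:2]
        sep_diet = (scores.groupby(history)["PC1"].mean().diff().abs().iloc[-1]
                    / scores["PC1"].std())
        sep_stage = (scores.groupby("stage")["PC2"].mean().diff().abs().iloc[-1]
                     / scores["PC2"].std())
        print(f"{tissue}: EV1={100 * ev.iloc[0]:.1f}% EV2={100 * ev.iloc[1]:.1f}%; "
              f"diet separation on PC1 {sep_diet:.2f} sd; "
              f"stage separation on PC2 {sep_stage:.2f} sd")


if __name__ == "__main__":
    main()
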