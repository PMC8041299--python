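#!/usr/bin/env python
"""Remodeling kinetics and acyl-composition inference.

Refits the first-order remodeling rate constant k per (stage, tissue) from
the simulated group means and compares it to the planted truth — the
headline contrast being the faster seawater gut — then enumerates the
fatty-acyl compositions consistent with a few highly unsaturated marker
species.  Writes results/kinetics/rate_constants.csv and
results/kinetics/acyl_compositions.csv.
"""

from pathlib import Path

import pandas as pd

from lipidblocks.dataset import LipidomeDataset, STAGES, TISSUES
from lipidblocks.kinetics import fit_switch_rate
from lipidblocks.nomenclature import enumerate_compositions, parse_lipid_name
from lipidblocks.simulate import SimulationConfig

SYN = Path("results/synthetic")
OUT = Path("results/kinetics")

MARKERS = ["TG-66:18", "TG-64:17", "TG-54:9", "PC-44:12", "PE-40:9", "PC-38:8"]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = LipidomeDataset.from_csv(SYN / "abundance.csv", SYN / "sample_meta.csv")
    k_true = SimulationConfig().k

    rows = []
    for tissue in TISSUES:
        for stage in STAGES:
            k_hat = fit_switch_rate(dataset, tissue, stage)
            rows.append({
                "tissue": tissue, "stage": stage,
                "k_fit_per_day": k_hat, "k_true_per_day": k_true[(stage, tissue)],
            })
    rates = pd.DataFrame(rows)
    rates.to_csv(OUT / "rate_constants.csv", index=False, float_format="%.6g")
    print("refitted remodeling rate constants (1/day):")
    for r in rates.itertuples(index=False):
        print(f"  {r.tissue:>6} {r.stage}: k = {r.k_fit_per_day:.3f} "
              f"(truth {r.k_true_per_day:.2f})")
    gut = rates.set_index(["tissue", "stage"])
    ratio = (gut.loc[("gut", "SW"), "k_fit_per_day"]
             / gut.loc[("gut", "FW"), "k_fit_per_day"])
    print(f"seawater gut remodels {ratio:.1f}x faster than freshwater gut")

    comp_rows = []
    for name in MARKERS:
        combos = enumerate_compositions(parse_lipid_name(name))
        comp_rows.append({
            "species": name,
            "n_candidates": len(combos),
            "compositions": "; ".join(
                " + ".join(str(a) for a in combo) for combo in combos
            ),
        })
    comps = pd.DataFrame(comp_rows)
    comps.to_csv(OUT / "acyl_compositions.csv", index=False)
    print("\nacyl compositions consistent with the default pool:")
    for r in comps.itertuples(index=False):
        print(f"  {r.species}: {r.compositions or '(none)'}")


if __name__ == "__main__":
    main()
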