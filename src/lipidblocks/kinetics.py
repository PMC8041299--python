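"""Refitting the remodeling rate constant from observed diet-switch data.

The generator (and, under the analysis' working model, the real experiment)
assumes first-order relaxation of each species' log2 abundance toward the
new diet's steady state, with one rate constant k per (stage, tissue).
:func:`fit_switch_rate` re-estimates that shared k by nonlinear least
squares over the switched-group means of all diet-responsive species,
anchoring each species' source and target steady states at the day-0
control means.  :func:`estimate_stage_log2fc` estimates a species'
life-stage effect from the pre-switch (day-0) cells, where both stages sit
at their diet steady states and the contrast is uncontaminated by kinetics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .dataset import LipidomeDataset, log2_safe


class KineticsError(ValueError):
    pass


_SWITCH_SCHEDULE = {
    # diet_group -> (history, day label)
    "D1_FOVO": ("FO", 1.0), "D5/6_FOVO": ("FO", 5.0), "D20_FOVO": ("FO", 20.0),
    "D1_VOFO": ("VO", 1.0), "D5/6_VOFO": ("VO", 5.0), "D20_VOFO": ("VO", 20.0),
}


def _group_mean_log2(ab: pd.DataFrame, meta: pd.DataFrame, stage: str) -> pd.DataFrame:
    sub = meta["stage"] == stage
    logv = pd.DataFrame(
        np.asarray(log2_safe(ab.loc[sub])), index=ab.index[sub], columns=ab.columns
    )
    return logv.groupby(meta.loc[sub, "diet_group"], observed=True).mean()


def fit_switch_rate(
    dataset: LipidomeDataset,
    tissue: str,
    stage: str,
    min_delta_log2: float = 0.5,
    k_max: float = 20.0,
) -> float:
    """Estimate the shared relaxation rate k (1/day) for one stage x tissue.

    Species whose day-0 steady states differ by less than ``min_delta_log2``
    carry no kinetic signal and are excluded.  The day "5/6" level is taken
    at t=5 for FW fish and t=6 for SW fish.
    """
    ds = dataset.subset_tissue(tissue)
    means = _group_mean_log2(ds.abundance, ds.sample_meta, stage)
    needed = {"D0_FO", "D0_VO", *(_SWITCH_SCHEDULE)}
    missing = needed - set(means.index)
    if missing:
        raise KineticsError(f"missing diet groups for rate fit: {sorted(missing)}")

    y_fo = means.loc["D0_FO"]
    y_vo = means.loc["D0_VO"]
    keep = (y_fo - y_vo).abs() > min_delta_log2
    if keep.sum() < 3:
        raise KineticsError(
            f"only {int(keep.sum())} diet-responsive species; cannot fit a rate"
        )

    obs, src, tgt, times = [], [], [], []
    for group, (history, day) in _SWITCH_SCHEDULE.items():
        t = 6.0 if (day == 5.0 and stage == "SW") else day
        y_s = (y_fo if history == "FO" else y_vo)[keep]
        y_t = (y_vo if history == "FO" else y_fo)[keep]
        obs.append(means.loc[group][keep].to_numpy())
        src.append(y_s.to_numpy())
        tgt.append(y_t.to_numpy())
        times.append(np.full(int(keep.sum()), t))
    obs_v = np.concatenate(obs)
    src_v = np.concatenate(src)
    tgt_v = np.concatenate(tgt)
    t_v = np.concatenate(times)

    def residuals(params: np.ndarray) -> np.ndarray:
        k = params[0]
        return tgt_v + (src_v - tgt_v) * np.exp(-k * t_v) - obs_v

    fit = least_squares(residuals, x0=[0.2], bounds=([0.0], [k_max]))
    return float(fit.x[0])


def estimate_stage_log2fc(dataset: LipidomeDataset, tissue: str) -> pd.Series:
    """Per-species SW-minus-FW log2 fold change from the day-0 control cells.

    Means are taken on the normalized (linear) scale within each stage over
    both day-0 diet controls, then log2-ratioed.  Pooling the two diet
    histories doubles the fish per stage and cancels diet effects that are
    symmetric across the histories.
    """
    ds = dataset.subset_tissue(tissue)
    meta = ds.sample_meta
    d0 = meta["diet_group"].isin(["D0_FO", "D0_VO"])
    out = {}
    for stage in ("FW", "SW"):
        sel = d0 & (meta["stage"] == stage)
        if not sel.any():
            raise KineticsError(f"no day-0 samples for stage {stage!r}")
        # average log2 within each diet control first, then across diets,
        # so a diet effect cannot leak into the stage contrast
        logv = pd.DataFrame(
            np.asarray(log2_safe(ds.abundance.loc[sel])),
            index=ds.abundance.index[sel],
            columns=ds.abundance.columns,
        )
        out[stage] = logv.groupby(meta.loc[sel, "diet_group"], observed=True).mean().mean(axis=0)
    return (out["SW"] - out["FW"]).rename("stage_log2fc")
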