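"""Per-species differential abundance across diet groups and life stages.

Each lipid species is tested with a balanced fixed-effects two-way ANOVA
(8 diet-group levels x 2 life stages, n fish per cell) on log-transformed
normalized abundance, followed by Tukey's HSD over the 16 cell means.  The
reported contrasts are freshwater vs seawater within each diet group.  A
species is called significant when, on some reported contrast, the Tukey
p-value is below 0.05 and the |log2 fold change| of cell means (on the
normalized, untransformed scale) exceeds 1.  Flagged species are row-scaled
and hierarchically clustered into a configured number of temporal groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster import hierarchy

from .dataset import DIET_GROUPS, LipidomeDataset, STAGES, log2_safe

P_THRESHOLD_DEFAULT = 0.05
LFC_THRESHOLD_DEFAULT = 1.0


class DesignError(ValueError):
    """Raised for empty cells or unbalanced designs."""


# ---------------------------------------------------------------------------
# Two-way ANOVA (balanced)

@dataclass
class AnovaTable:
    p_diet: float
    p_stage: float
    p_interaction: float
    mse: float
    df_error: int
    ss: dict[str, float] = field(default_factory=dict)
    degenerate: bool = False


def _check_design(diet: np.ndarray, stage: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    d_levels, d_codes = np.unique(diet, return_inverse=True)
    s_levels, s_codes = np.unique(stage, return_inverse=True)
    counts = np.zeros((len(d_levels), len(s_levels)), dtype=int)
    np.add.at(counts, (d_codes, s_codes), 1)
    if (counts == 0).any():
        di, si = np.argwhere(counts == 0)[0]
        raise DesignError(f"empty design cell: diet={d_levels[di]!r}, stage={s_levels[si]!r}")
    if counts.min() != counts.max():
        raise DesignError(f"unbalanced design: cell sizes {counts.min()}..{counts.max()}")
    n = int(counts[0, 0])
    if n < 2:
        raise DesignError("need n >= 2 per cell")
    return d_codes, s_codes, n


def two_way_anova_matrix(
    Y: np.ndarray, diet: Sequence, stage: Sequence
) -> dict[str, np.ndarray]:
    """Vectorized balanced two-way ANOVA over the columns of ``Y``.

    ``Y`` is observations x species.  Returns arrays (one entry per species)
    of p-values, sums of squares, MSE and a degenerate-data flag (zero error
    SS: p-values are NaN).  The classical balanced decomposition is exact:
    SS_total = SS_diet + SS_stage + SS_interaction + SS_error.
    """
    Y = np.asarray(Y, dtype=float)
    diet = np.asarray(diet)
    stage = np.asarray(stage)
    d_codes, s_codes, n = _check_design(diet, stage)
    D = d_codes.max() + 1
    S = s_codes.max() + 1
    n_obs, n_sp = Y.shape

    grand = Y.mean(axis=0)
    cell_sum = np.zeros((D, S, n_sp))
    np.add.at(cell_sum, (d_codes, s_codes), Y)
    cell_mean = cell_sum / n
    diet_mean = cell_mean.mean(axis=1)    # D x n_sp
    stage_mean = cell_mean.mean(axis=0)   # S x n_sp

    ss_diet = n * S * ((diet_mean - grand) ** 2).sum(axis=0)
    ss_stage = n * D * ((stage_mean - grand) ** 2).sum(axis=0)
    ss_cells = n * ((cell_mean - grand) ** 2).sum(axis=(0, 1))
    ss_int = ss_cells - ss_diet - ss_stage
    ss_err = ((Y - cell_mean[d_codes, s_codes, :]) ** 2).sum(axis=0)

    df_diet, df_stage = D - 1, S - 1
    df_int = df_diet * df_stage
    df_err = n_obs - D * S
    mse = ss_err / df_err
    degenerate = np.isclose(ss_err, 0.0)

    def _p(ss_effect: np.ndarray, df_effect: int) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_effect / df_effect) / mse
        p = stats.f.sf(F, df_effect, df_err)
        return np.where(degenerate, np.nan, p)

    return {
        "p_diet": _p(ss_diet, df_diet),
        "p_stage": _p(ss_stage, df_stage),
        "p_interaction": _p(ss_int, df_int),
        "ss_diet": ss_diet,
        "ss_stage": ss_stage,
        "ss_interaction": ss_int,
        "ss_error": ss_err,
        "mse": mse,
        "df_error": df_err,
        "n_per_cell": n,
        "degenerate": degenerate,
        "cell_means": cell_mean,
    }


def two_way_anova(values: Sequence[float], diet: Sequence, stage: Sequence) -> AnovaTable:
    """Balanced two-way fixed-effects ANOVA with interaction for one species."""
    res = two_way_anova_matrix(np.asarray(values, dtype=float)[:, None], diet, stage)
    return AnovaTable(
        p_diet=float(res["p_diet"][0]),
        p_stage=float(res["p_stage"][0]),
        p_interaction=float(res["p_interaction"][0]),
        mse=float(res["mse"][0]),
        df_error=int(res["df_error"]),
        ss={
            "diet": float(res["ss_diet"][0]),
            "stage": float(res["ss_stage"][0]),
            "interaction": float(res["ss_interaction"][0]),
            "error": float(res["ss_error"][0]),
        },
        degenerate=bool(res["degenerate"][0]),
    )


# ---------------------------------------------------------------------------
# Tukey's HSD

def studentized_range_sf(
    q: np.ndarray | float, k: int, df: int, n_z: int = 121, n_s: int = 101
) -> np.ndarray:
    """Survival function of the studentized range Q_{k, df}, vectorized in q.

    Evaluates the classical double integral

        P(Q > q) = 1 - int_0^inf f_s(s) [ k int phi(z)
                   (Phi(z) - Phi(z - q s))^{k-1} dz ] ds,

    where s is a chi_{df}/sqrt(df) variate, by Gauss-Legendre quadrature on
    both axes.  All q values at a common (k, df) share the quadrature grid,
    which makes thousands of Tukey p-values essentially free; agreement with
    ``scipy.stats.studentized_range.sf`` is at the 1e-12 level at the
    default node counts.
    """
    q_arr = np.atleast_1d(np.asarray(q, dtype=float))
    out = np.full(q_arr.shape, np.nan)
    out[np.isposinf(q_arr)] = 0.0
    out[q_arr <= 0] = 1.0
    todo = np.isfinite(q_arr) & (q_arr > 0)
    if todo.any():
        qv = q_arr[todo]
        zs, wz = np.polynomial.legendre.leggauss(n_z)
        z = 9.0 * zs
        wz = 9.0 * wz
        ss, ws = np.polynomial.legendre.leggauss(n_s)
        smax = 1.0 + 10.0 / np.sqrt(2.0 * df)
        s = 0.5 * smax * (ss + 1.0)
        ws = 0.5 * smax * ws
        log_c = (
            0.5 * df * np.log(df)
            - special.gammaln(df / 2.0)
            - (df / 2.0 - 1.0) * np.log(2.0)
        )
        f_s = np.exp(log_c + (df - 1.0) * np.log(s) - df * s**2 / 2.0)
        phi_w = np.exp(-z**2 / 2.0) / np.sqrt(2.0 * np.pi) * wz
        Phi = special.ndtr(z)
        cdf = np.zeros_like(qv)
        for s_j, w_j, f_j in zip(s, ws, f_s):
            inner = (Phi[None, :] - special.ndtr(z[None, :] - (qv * s_j)[:, None])) ** (
                k - 1
            )
            cdf += w_j * f_j * k * (inner * phi_w[None, :]).sum(axis=1)
        out[todo] = np.clip(1.0 - cdf, 0.0, 1.0)
    return out if np.ndim(q) else float(out[0])


def tukey_hsd(
    cell_means: pd.Series,
    mse: float,
    df_error: int,
    n_per_cell: int,
    contrasts: Sequence[tuple[str, str]] | None = None,
    k_family: int | None = None,
) -> pd.Series:
    """Tukey-adjusted p-values from the studentized range distribution.

    ``cell_means`` is indexed by cell label; the family size ``k`` defaults
    to the number of cells (all-pairs family).  For a contrast (a, b) the
    statistic is q = |m_a - m_b| / sqrt(MSE / n) and
    p = P(Q_{k, df} > q).  Adjusted p is non-decreasing in k, and is never
    below the unadjusted two-sample p for the same contrast.
    """
    if n_per_cell < 2:
        raise DesignError("Tukey's HSD needs n >= 2 per cell")
    k = k_family if k_family is not None else len(cell_means)
    if contrasts is None:
        labels = list(cell_means.index)
        contrasts = [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
    se = np.sqrt(mse / n_per_cell)
    out = {}
    for a, b in contrasts:
        if mse == 0:
            out[(a, b)] = np.nan if cell_means[a] != cell_means[b] else 1.0
            continue
        q = abs(cell_means[a] - cell_means[b]) / se
        out[(a, b)] = float(studentized_range_sf(q, k, df_error))
    return pd.Series(out, name="p_tukey")


def log2_fold_change(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """log2 of the ratio of group means, on the normalized (linear) scale.

    Returns NaN (undefined fold change) when either mean is non-positive.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DesignError("fold change needs non-empty groups")
    ma, mb = a.mean(), b.mean()
    if ma <= 0 or mb <= 0:
        return float("nan")
    return float(np.log2(ma / mb))


def significance_filter(
    results: pd.DataFrame,
    lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    lfc_col: str = "log2fc",
    p_col: str = "p",
) -> tuple[pd.DataFrame, pd.Series]:
    """Flag rows with |log2FC| > threshold AND p < threshold.

    Returns (flagged subset, per-tissue counts).  Rows with NaN in either
    column are never flagged.
    """
    lfc = results[lfc_col]
    p = results[p_col]
    mask = (lfc.abs() > lfc_threshold) & (p < p_threshold)
    mask &= lfc.notna() & p.notna()
    flagged = results.loc[mask]
    if "tissue" in results.columns:
        counts = flagged.groupby("tissue", observed=True).size()
    else:
        counts = pd.Series({"all": int(mask.sum())})
    counts.name = "n_significant"
    return flagged, counts


# ---------------------------------------------------------------------------
# Heatmap cluster groups

def heatmap_groups(
    matrix: pd.DataFrame, n_groups: int = 4
) -> tuple[pd.Series, pd.DataFrame]:
    """Row-scale a species x group-mean matrix and cut an average-linkage tree.

    Rows are scaled to mean 0 / sd 1 across the columns, clustered with
    average linkage on Euclidean distance, and the dendrogram is cut into
    ``n_groups`` clusters.  Labels ("A", "B", ...) are deterministic,
    ordered by first appearance along the dendrogram leaf order.
    """
    if matrix.shape[0] < 2:
        labels = pd.Series(["A"] * matrix.shape[0], index=matrix.index, name="cluster_group")
        return labels, matrix.copy()
    sds = matrix.std(axis=1, ddof=1)
    sds = sds.where(sds > 0, 1.0)  # constant rows scale to all-zero
    scaled = matrix.sub(matrix.mean(axis=1), axis=0).div(sds, axis=0)
    n_groups = min(n_groups, matrix.shape[0])
    Z = hierarchy.linkage(scaled.to_numpy(), method="average", metric="euclidean")
    raw = hierarchy.fcluster(Z, t=n_groups, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(Z)
    relabel: dict[int, str] = {}
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    for leaf in leaf_order:
        c = raw[leaf]
        if c not in relabel:
            relabel[c] = alphabet[len(relabel) % 26]
    labels = pd.Series([relabel[c] for c in raw], index=matrix.index, name="cluster_group")
    return labels, scaled


# ---------------------------------------------------------------------------
# Whole-tissue driver

def run_differential(
    dataset: LipidomeDataset,
    lfc_threshold: float = LFC_THRESHOLD_DEFAULT,
    p_threshold: float = P_THRESHOLD_DEFAULT,
    p_source: str = "tukey",
    n_cluster_groups: int = 4,
) -> pd.DataFrame:
    """Differential abundance for every species of a single-tissue dataset.

    For each species: two-way ANOVA on log2 normalized abundance, Tukey HSD
    over the 16 diet x stage cells, and per-diet-group FW-vs-SW log2 fold
    changes on the normalized scale.  ``p_source`` selects whether the
    significance rule uses the Tukey-adjusted contrast p (default) or the
    ANOVA stage main-effect p.  Returns a tidy per-species table including
    a heatmap cluster-group label for the flagged species.
    """
    tissues = dataset.sample_meta["tissue"].unique()
    if len(tissues) != 1:
        raise DesignError(f"run_differential works per tissue; got {sorted(tissues)}")
    tissue = tissues[0]
    if p_source not in ("tukey", "anova"):
        raise DesignError(f"unknown p_source {p_source!r}")

    ab = dataset.abundance
    meta = dataset.sample_meta
    diet = meta["diet_group"].to_numpy()
    stage = meta["stage"].to_numpy()
    logY = np.asarray(log2_safe(ab))
    res = two_way_anova_matrix(logY, diet, stage)
    d_levels = np.unique(diet)
    s_levels = np.unique(stage)
    n = res["n_per_cell"]

    if "SW" not in s_levels or "FW" not in s_levels:
        raise DesignError(f"need both FW and SW stages, found {list(s_levels)}")
    si_sw = int(np.where(s_levels == "SW")[0][0])
    si_fw = int(np.where(s_levels == "FW")[0][0])
    cm = res["cell_means"]  # D x S x species, on the log2 scale

    # Tukey q statistics for the FW-vs-SW contrast within each diet group;
    # one vectorized studentized-range evaluation for all species x groups
    k_family = len(d_levels) * len(s_levels)
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(res["mse"] / n)  # per species
        q_mat = np.abs(cm[:, si_sw, :] - cm[:, si_fw, :]) / se[None, :]
    p_tukey_mat = studentized_range_sf(q_mat, k_family, int(res["df_error"]))
    p_tukey_mat = np.where(res["degenerate"][None, :], np.nan, p_tukey_mat)

    # linear-scale cell means for the reported log2 fold changes
    lin_cell_sum = np.zeros_like(cm)
    d_codes = np.searchsorted(d_levels, diet)
    s_codes = np.searchsorted(s_levels, stage)
    np.add.at(lin_cell_sum, (d_codes, s_codes), ab.to_numpy(dtype=float))
    lin_cell_mean = lin_cell_sum / n
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc_mat = np.log2(lin_cell_mean[:, si_sw, :] / lin_cell_mean[:, si_fw, :])
    lfc_mat = np.where(
        (lin_cell_mean[:, si_sw, :] <= 0) | (lin_cell_mean[:, si_fw, :] <= 0),
        np.nan,
        lfc_mat,
    )

    p_contrast = (
        p_tukey_mat if p_source == "tukey" else np.tile(res["p_stage"], (len(d_levels), 1))
    )
    hit = (
        ~np.isnan(p_contrast)
        & ~np.isnan(lfc_mat)
        & (np.abs(lfc_mat) > lfc_threshold)
        & (p_contrast < p_threshold)
    )

    out = pd.DataFrame(
        {
            "tissue": tissue,
            "p_diet": res["p_diet"],
            "p_stage": res["p_stage"],
            "p_interaction": res["p_interaction"],
            "degenerate": res["degenerate"],
        },
        index=pd.Index(ab.columns, name="species"),
    )
    for di, d in enumerate(d_levels):
        out[f"log2fc_{d}"] = lfc_mat[di]
        out[f"p_{d}"] = p_contrast[di]

    best_p = np.where(hit, p_contrast, np.inf).min(axis=0)
    best_di = np.where(hit, p_contrast, np.inf).argmin(axis=0)
    any_hit = hit.any(axis=0)
    out["p"] = np.where(any_hit, best_p, np.nan)
    out["log2fc"] = np.where(any_hit, lfc_mat[best_di, np.arange(lfc_mat.shape[1])], np.nan)
    out["contrast"] = np.where(any_hit, d_levels[best_di], None)
    out["significant"] = any_hit

    flagged = out.index[out["significant"]]
    out["cluster_group"] = pd.NA
    if len(flagged) >= 1:
        # cluster on log-scale cell means (columns = 16 diet x stage cells)
        cm = res["cell_means"]
        cell_cols = [f"{d}|{s}" for d in d_levels for s in s_levels]
        mat = pd.DataFrame(
            cm.reshape(len(d_levels) * len(s_levels), -1).T,
            index=ab.columns,
            columns=cell_cols,
        ).loc[flagged]
        labels, _ = heatmap_groups(mat, n_groups=n_cluster_groups)
        out.loc[flagged, "cluster_group"] = labels
    return out
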