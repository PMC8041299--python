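"""Consensus principal component analysis (CPCA) on a multiblock dataset.

CPCA extracts, one component at a time, a *global* (super) score shared by
all blocks together with per-block scores and loadings.  With deflation
taken with respect to the super score, the global solution coincides with
ordinary PCA of the column-concatenated block-weighted matrix — that
equivalence is the module's primary correctness oracle.  The NIPALS-style
iteration is kept because it exposes the block-level quantities (block
scores, super weights) that the concatenated SVD does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocessing import BlockSet

DEFAULT_TOL = 1e-10
DEFAULT_MAX_ITER = 5000


class CPCAError(ValueError):
    pass


class ConvergenceWarning(UserWarning):
    pass


@dataclass
class CPCAModel:
    """Fitted consensus-PCA model.

    ``global_scores`` are the super scores t (samples x components);
    ``super_weights`` (blocks x components, unit-norm columns) say how much
    each block contributes to the consensus; ``block_scores`` /
    ``block_loadings`` are per-block.  Explained variance is reported as a
    fraction of the preprocessed total SS, globally and per block.
    """

    n_components: int
    global_scores: pd.DataFrame
    super_weights: pd.DataFrame
    block_scores: dict[str, pd.DataFrame]
    block_loadings: dict[str, pd.DataFrame]
    ev_global: pd.Series
    ev_block: pd.DataFrame            # blocks x components
    iterations: list[int] = field(default_factory=list)
    final_change: list[float] = field(default_factory=list)
    converged: list[bool] = field(default_factory=list)
    total_ss: float = 0.0

    @property
    def component_labels(self) -> list[str]:
        return list(self.global_scores.columns)


def _component_labels(k: int) -> list[str]:
    return [f"PC{i + 1}" for i in range(k)]


def fit_cpca(
    blocks: BlockSet,
    n_components: int = 2,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> CPCAModel:
    """Fit CPCA by the NIPALS consensus iteration with super-score deflation.

    Per component: initialize the super score t as the concatenated-matrix
    column of maximal variance, then iterate block loadings
    ``p_b = X_b' t / t't`` and the consensus super score
    ``t = sum_b X_b p_b`` until the relative change of t falls below
    ``tol``.  This consensus update weights each block's score by the sum of
    squares of its loading vector, which makes the extraction exactly the
    NIPALS iteration for PCA of the column-concatenated matrix — the
    equivalence the oracle tests assert.  (Normalizing the super weight
    ``T't/t't`` instead, as some formulations do, weights every block
    equally at each step and converges to a different direction, breaking
    that equivalence.)  Block scores ``t_b = X_b p_b / p_b'p_b`` and the
    unit-norm super weight (entries proportional to ``p_b'p_b``) are
    recorded for the block-level plots.  Every block is then deflated by the
    super score.  Non-convergence raises a warning recorded in the model,
    not an error.
    """
    labels = blocks.labels
    sample_index = blocks.sample_index
    X = {lab: blocks.blocks[lab].data.to_numpy(dtype=float).copy() for lab in labels}
    columns = {lab: blocks.blocks[lab].data.columns for lab in labels}
    n = len(sample_index)
    total_vars = sum(x.shape[1] for x in X.values())
    if n_components > min(n - 1, total_vars):
        raise CPCAError(
            f"n_components={n_components} exceeds min(samples-1, variables)="
            f"{min(n - 1, total_vars)}"
        )
    total_ss = float(sum(np.sum(x**2) for x in X.values()))

    comp_labels = _component_labels(n_components)
    T_global = np.zeros((n, n_components))
    W_super = np.zeros((len(labels), n_components))
    Tb = {lab: np.zeros((n, n_components)) for lab in labels}
    Pb = {lab: np.zeros((X[lab].shape[1], n_components)) for lab in labels}
    ev_global = np.zeros(n_components)
    ev_block = np.zeros((len(labels), n_components))
    iterations, final_change, converged = [], [], []

    for a in range(n_components):
        concat = np.hstack([X[lab] for lab in labels])
        # start from the concatenated column of maximal variance
        t = concat[:, int(np.argmax(concat.var(axis=0)))].copy()
        if not np.any(t):
            t = concat[:, 0] + 1e-12
        change = np.inf
        it = 0
        for it in range(1, max_iter + 1):
            tt = float(t @ t)
            p = {lab: X[lab].T @ t / tt for lab in labels}
            # joint (concatenated) unit-norm loading stabilizes the scale
            p_norm = float(np.sqrt(sum(pb @ pb for pb in p.values())))
            t_new = np.sum([X[lab] @ p[lab] for lab in labels], axis=0) / p_norm
            change = float(np.linalg.norm(t_new - t) / np.linalg.norm(t_new))
            t = t_new
            if change < tol:
                break
        ok = change < tol
        if not ok:
            warnings.warn(
                f"CPCA component {a + 1} did not converge in {max_iter} iterations "
                f"(final relative change {change:.2e})",
                ConvergenceWarning,
                stacklevel=2,
            )
        iterations.append(it)
        final_change.append(change)
        converged.append(ok)

        # deterministic sign: largest-|loading| entry of the concatenated
        # loading vector is made positive
        tt = float(t @ t)
        p = {lab: X[lab].T @ t / tt for lab in labels}
        p_concat = np.concatenate([p[lab] for lab in labels])
        sign = 1.0 if p_concat[int(np.argmax(np.abs(p_concat)))] >= 0 else -1.0
        t = sign * t
        tt = float(t @ t)
        p = {lab: X[lab].T @ t / tt for lab in labels}
        tb = np.column_stack(
            [X[lab] @ p[lab] / float(p[lab] @ p[lab]) for lab in labels]
        )
        w = np.array([float(p[lab] @ p[lab]) for lab in labels])
        w = w / np.linalg.norm(w)

        T_global[:, a] = t
        W_super[:, a] = w
        for bi, lab in enumerate(labels):
            Tb[lab][:, a] = tb[:, bi]
            Pb[lab][:, a] = p[lab]
            ev_block[bi, a] = tt * float(p[lab] @ p[lab]) / blocks.blocks[lab].total_ss
        ev_global[a] = tt * float(p_concat @ p_concat) / total_ss

        for lab in labels:
            X[lab] -= np.outer(t, p[lab])

    return CPCAModel(
        n_components=n_components,
        global_scores=pd.DataFrame(T_global, index=sample_index, columns=comp_labels),
        super_weights=pd.DataFrame(W_super, index=labels, columns=comp_labels),
        block_scores={
            lab: pd.DataFrame(Tb[lab], index=sample_index, columns=comp_labels)
            for lab in labels
        },
        block_loadings={
            lab: pd.DataFrame(Pb[lab], index=columns[lab], columns=comp_labels)
            for lab in labels
        },
        ev_global=pd.Series(ev_global, index=comp_labels, name="explained_variance"),
        ev_block=pd.DataFrame(ev_block, index=labels, columns=comp_labels),
        iterations=iterations,
        final_change=final_change,
        converged=converged,
        total_ss=total_ss,
    )


def concatenated_svd_scores(blocks: BlockSet, n_components: int) -> np.ndarray:
    """PCA scores of the column-concatenated block matrix (independent route).

    Returned with the same sign convention as :func:`fit_cpca` (largest-|v|
    loading entry positive) so oracle comparisons are sign-free.
    """
    concat = blocks.concatenated().to_numpy(dtype=float)
    U, s, Vt = np.linalg.svd(concat, full_matrices=False)
    scores = U[:, :n_components] * s[:n_components]
    for a in range(n_components):
        v = Vt[a]
        if v[int(np.argmax(np.abs(v)))] < 0:
            scores[:, a] *= -1
    return scores


# ---------------------------------------------------------------------------
# Correlation loadings

@dataclass
class CorrelationLoadings:
    """Pearson correlations of original variables with global score vectors.

    ``explained_variance`` is the per-variable sum of squared correlations
    over the plotted components; in a correlation-loading plot it equals the
    squared distance from the origin, so 100% EV sits on the unit circle and
    50% EV on the circle of radius sqrt(0.5).
    """

    correlations: pd.DataFrame      # variables x components
    explained_variance: pd.Series   # per variable, fraction in [0, 1]
    components: tuple[int, ...]

    def to_frame(self) -> pd.DataFrame:
        out = self.correlations.copy()
        out["explained_variance"] = self.explained_variance
        return out


def correlation_loadings(
    model: CPCAModel,
    original,
    components: tuple[int, ...] = (1, 2),
) -> CorrelationLoadings:
    """Correlate each original (normalized, pre-centering) variable with the
    requested global components (1-based indices)."""
    for c in components:
        if not 1 <= c <= model.n_components:
            raise IndexError(
                f"component {c} out of range for a {model.n_components}-component model"
            )
    data = original.abundance if hasattr(original, "abundance") else original
    data = data.loc[model.global_scores.index]
    X = data.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    x_norm = np.linalg.norm(Xc, axis=0)

    cols = [f"r_PC{c}" for c in components]
    R = np.zeros((X.shape[1], len(components)))
    for j, c in enumerate(components):
        t = model.global_scores.iloc[:, c - 1].to_numpy()
        tc = t - t.mean()
        denom = x_norm * np.linalg.norm(tc)
        with np.errstate(invalid="ignore", divide="ignore"):
            R[:, j] = np.where(denom > 0, Xc.T @ tc / denom, 0.0)
    corr = pd.DataFrame(R, index=data.columns, columns=cols)
    ev = pd.Series((R**2).sum(axis=1), index=data.columns, name="explained_variance")
    return CorrelationLoadings(corr, ev, tuple(components))


def score_plot_data(
    model: CPCAModel,
    sample_meta: pd.DataFrame,
    level: str = "global",
    components: tuple[int, int] = (1, 2),
) -> pd.DataFrame:
    """Scores for a score plot, joined with sample metadata.

    ``level`` is ``"global"`` or a block label; ``components`` are 1-based.
    """
    for c in components:
        if not 1 <= c <= model.n_components:
            raise IndexError(
                f"component {c} out of range for a {model.n_components}-component model"
            )
    if level == "global":
        scores = model.global_scores
    elif level in model.block_scores:
        scores = model.block_scores[level]
    else:
        raise KeyError(f"unknown score level {level!r}; use 'global' or one of "
                       f"{list(model.block_scores)}")
    cols = [f"PC{c}" for c in components]
    out = scores[cols].copy()
    return out.join(sample_meta.loc[out.index, ["diet_group", "stage"]])
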