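"""Per-gene differential expression, BH-FDR, top-DEG ranking and PCA.

Differential expression for a named group-vs-group contrast uses the
pooled-variance two-sample t-test on log2 expression: the log2 fold change
is the difference of group means and the t statistic has ``nA + nB − 2``
degrees of freedom.  With three pooled samples per group a gene can have
zero within-group variance; the pooled SD is then floored at 1e-8 and the
gene flagged ``degenerate``.  DEGs are called at unadjusted p < α (default
0.05) with the Benjamini–Hochberg q-value reported alongside.

PCA operates on per-gene centered (unscaled) log2 data with samples as
observations; explained-variance fractions come from the squared singular
values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import CountMatrix, DesignTable

_SD_FLOOR = 1e-8


@dataclass
class DEResult:
    """Per-gene statistics for one contrast (numerator vs denominator)."""

    contrast: tuple
    table: pd.DataFrame  # log2fc, t, df, p, q, degenerate per gene
    alpha: float = 0.05

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.alpha]


@dataclass
class PcaResult:
    scores: pd.DataFrame      # samples × components
    loadings: pd.DataFrame    # genes × components
    var_frac: np.ndarray      # all components, sums to 1


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini–Hochberg q-values: step-up minimum of p·m/rank, clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def de_test(
    matrix: CountMatrix,
    design: DesignTable,
    contrast: tuple,
    alpha: float = 0.05,
) -> DEResult:
    """Pooled-variance two-sample t-test per gene for ``contrast``.

    ``contrast`` is a pair of design cells, each a tuple of factor levels in
    design factor order, numerator first: log2FC > 0 means higher in the
    numerator group.
    """
    if matrix.scale != "log2":
        raise ValueError("de_test expects a log2 matrix")
    num_cell, den_cell = contrast
    a = design.samples_in(tuple(num_cell))
    b = design.samples_in(tuple(den_cell))
    if not a or not b:
        raise ValueError(f"empty contrast group in {contrast}")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both contrast groups need ≥2 samples")

    xa = matrix.values[a].to_numpy(dtype=float)
    xb = matrix.values[b].to_numpy(dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    ss = xa.var(axis=1, ddof=1) * (na - 1) + xb.var(axis=1, ddof=1) * (nb - 1)
    df = na + nb - 2
    pooled_sd = np.sqrt(ss / df)
    degenerate = pooled_sd < _SD_FLOOR
    pooled_sd = np.maximum(pooled_sd, _SD_FLOOR)
    t = log2fc / (pooled_sd * np.sqrt(1.0 / na + 1.0 / nb))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": t,
            "df": df,
            "p": p,
            "q": bh_fdr(p),
            "degenerate": degenerate,
        },
        index=matrix.values.index,
    )
    return DEResult(contrast=(tuple(num_cell), tuple(den_cell)), table=table, alpha=alpha)


def top_degs(de: DEResult, n: int, by: str = "abs_log2fc") -> list:
    """The top ``n`` DEGs ranked by |log2FC| (descending) or p (ascending).

    Ties break lexicographically on gene name.  Asking for more DEGs than
    exist returns them all (the truncation is reported by length).
    """
    degs = de.degs
    if by == "abs_log2fc":
        ranked = sorted(degs.index, key=lambda g: (-abs(degs.at[g, "log2fc"]), g))
    elif by == "p":
        ranked = sorted(degs.index, key=lambda g: (degs.at[g, "p"], g))
    else:
        raise ValueError(f"unknown ranking {by!r}")
    return ranked[: max(n, 0)]


def pca(
    matrix: CountMatrix,
    genes=None,
    n_components: int | None = None,
) -> PcaResult:
    """PCA of samples on per-gene centered log2 expression.

    ``var_frac`` covers every component and sums to 1; a constant matrix
    (zero total variance) is an error.
    """
    sub = matrix.subset(list(genes)) if genes is not None else matrix
    if len(sub.samples) < 2:
        raise ValueError("PCA needs ≥2 samples")
    x = sub.values.to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError("matrix has zero total variance")
    # samples × genes; left singular vectors give sample scores
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)
    var = s**2
    var_frac = var / var.sum()
    k = len(s) if n_components is None else min(n_components, len(s))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=sub.samples, columns=comp_names)
    loadings = pd.DataFrame(vt[:k].T, index=sub.genes, columns=comp_names)
    return PcaResult(scores=scores, loadings=loadings, var_frac=var_frac)
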