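"""The three panel scoring engines: first-PC pathway scores, directed and
undirected global significance scores, and cell-type profiling.

**Pathway scoring** summarises a gene set per sample by the first principal
component of its (per-gene centered) log2 submatrix, oriented so that a
higher score means higher overall expression of the set; scores average to
zero across samples by construction.

**Gene set analysis** summarises the evidence that a set responds to a
covariate: per-gene t statistics come from the additive two-factor linear
model (log2 expression ~ factorA + factorB over all samples), and the
directed global significance score is the signed square root of the mean
signed squared t over the set's genes, with ±1.3 as the conventional
flagging cutoff.  The undirected companion drops the signs, so
``|directed| ≤ undirected`` always.

**Cell-type profiling** scores a cell type per sample as the arithmetic
mean of its marker genes' log2 values, and validates the marker set by
comparing the mean pairwise Pearson correlation among markers with that of
randomly drawn gene sets of the same size (add-one permutation p-value).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import CountMatrix, DesignTable, GeneSet

#: conventional cutoff on |directed GSS| for calling a set changed
GSS_CUTOFF = 1.3
#: sets with fewer measured genes than this are skipped by pathway scoring
MIN_PATHWAY_GENES = 5


@dataclass
class PathwayScoreResult:
    """One pathway's per-sample scores plus orientation diagnostics."""

    name: str
    scores: pd.Series            # per sample, mean 0
    loadings: pd.Series          # per measured gene
    orientation: int             # ±1 applied to the raw first PC
    pc1_var_frac: float
    genes_used: list


@dataclass
class PathwayScores:
    """Pathway × sample score matrix plus per-pathway diagnostics."""

    scores: pd.DataFrame
    orientation: dict
    pc1_var_frac: dict
    skipped: dict  # pathway → reason


@dataclass
class CellTypeProfile:
    name: str
    markers: list
    score: pd.Series
    qc_p: float | None = None
    mean_marker_corr: float | None = None
    mean_pairwise_slope: float | None = None
    qc_flag: str = ""


# ---------------------------------------------------------------------------
# pathway scoring
# ---------------------------------------------------------------------------


def pathway_score(matrix: CountMatrix, gene_set: GeneSet) -> PathwayScoreResult:
    """First-PC score of ``gene_set`` per sample, oriented with expression.

    The set's measured genes are centered per gene; the per-sample score is
    the projection on the first right singular vector, sign-flipped so the
    sum of gene loadings is positive (an exact zero sum falls back to the
    sign of the correlation with the set's per-sample mean expression).
    """
    genes = gene_set.measured(matrix)
    if len(genes) < 2:
        raise ValueError(f"gene set {gene_set.name!r} has <2 measured genes")
    if len(matrix.samples) < 3:
        raise ValueError("pathway scoring needs ≥3 samples")
    x = matrix.values.loc[genes].to_numpy(dtype=float)
    centered = x - x.mean(axis=1, keepdims=True)
    if not np.any(centered):
        raise ValueError(f"gene set {gene_set.name!r} has zero variance")
    u, s, vt = np.linalg.svd(centered.T, full_matrices=False)  # samples × genes
    raw_scores = u[:, 0] * s[0]
    loadings = vt[0]
    load_sum = loadings.sum()
    if load_sum != 0.0:
        orientation = 1 if load_sum > 0 else -1
    else:
        set_mean = centered.mean(axis=0)
        corr = float(np.dot(raw_scores, set_mean))
        orientation = 1 if corr >= 0 else -1
    scores = pd.Series(orientation * raw_scores, index=matrix.samples, name=gene_set.name)
    return PathwayScoreResult(
        name=gene_set.name,
        scores=scores,
        loadings=pd.Series(orientation * loadings, index=genes),
        orientation=orientation,
        pc1_var_frac=float(s[0] ** 2 / (s**2).sum()),
        genes_used=genes,
    )


def score_pathways(
    matrix: CountMatrix,
    gene_sets,
    min_genes: int = MIN_PATHWAY_GENES,
) -> PathwayScores:
    """Score every gene set with ≥ ``min_genes`` measured genes.

    Sets with too few detected genes are skipped and reported, mirroring
    the practice of dropping sparsely measured pathways from scoring.
    """
    sets = gene_sets.values() if isinstance(gene_sets, dict) else gene_sets
    rows, orientation, var_frac, skipped = {}, {}, {}, {}
    for gs in sets:
        measured = gs.measured(matrix)
        if len(measured) < min_genes:
            skipped[gs.name] = f"{len(measured)} measured genes < {min_genes}"
            continue
        res = pathway_score(matrix, gs)
        rows[gs.name] = res.scores
        orientation[gs.name] = res.orientation
        var_frac[gs.name] = res.pc1_var_frac
    scores = pd.DataFrame(rows).T if rows else pd.DataFrame(columns=matrix.samples)
    return PathwayScores(scores=scores, orientation=orientation,
                         pc1_var_frac=var_frac, skipped=skipped)


# ---------------------------------------------------------------------------
# gene set analysis
# ---------------------------------------------------------------------------


def covariate_t(
    matrix: CountMatrix,
    design: DesignTable,
    covariate: str,
    adjust: bool = True,
) -> pd.Series:
    """Per-gene t statistic of ``covariate`` from the additive two-factor
    model log2 expression ~ factorA + factorB (df = n − 3).

    ``adjust=False`` drops the other factor and fits the univariate model
    (df = n − 2) instead.
    """
    if covariate not in design.factors:
        raise ValueError(f"unknown covariate {covariate!r}; design has {design.factors}")
    design.check_covers(matrix.samples)
    sub = design.table.loc[matrix.samples]
    factors = design.factors if adjust else (covariate,)
    cols = []
    for f in factors:
        ref, alt = design.levels[f]
        ind = (sub[f] == alt).to_numpy(dtype=float)
        if ind.min() == ind.max():
            raise ValueError(f"factor {f!r} has a single level among these samples")
        cols.append(ind)
    X = np.column_stack([np.ones(len(sub)), *cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("confounded design: factor columns are aliased")
    n, k = X.shape
    if n <= k:
        raise ValueError("not enough samples for the two-factor model")
    Y = matrix.values[list(sub.index)].to_numpy(dtype=float).T  # samples × genes
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ Y
    resid = Y - X @ beta
    dof = n - k
    sigma2 = (resid**2).sum(axis=0) / dof
    j = 1 + factors.index(covariate)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 1e-300))
    t = beta[j] / se
    return pd.Series(t, index=matrix.values.index, name=f"t_{covariate}")


def directed_gss(gene_t, gene_set: GeneSet) -> float:
    """Signed sqrt of the mean signed squared t over the set's genes."""
    t = _set_t(gene_t, gene_set)
    m = float(np.mean(np.sign(t) * t**2))
    return float(np.sign(m) * np.sqrt(abs(m)))


def undirected_gss(gene_t, gene_set: GeneSet) -> float:
    """Root mean squared t over the set's genes (magnitude only)."""
    t = _set_t(gene_t, gene_set)
    return float(np.sqrt(np.mean(t**2)))


def _set_t(gene_t, gene_set: GeneSet) -> np.ndarray:
    if isinstance(gene_t, pd.Series):
        gene_t = gene_t.to_dict()
    t = np.asarray([gene_t[g] for g in gene_set.genes if g in gene_t], dtype=float)
    if t.size == 0:
        raise ValueError(f"no measured genes for set {gene_set.name!r}")
    return t


def gss_table(
    matrix: CountMatrix,
    design: DesignTable,
    gene_sets,
    cutoff: float = GSS_CUTOFF,
    covariates=None,
    adjust: bool = True,
) -> pd.DataFrame:
    """Directed + undirected GSS per (gene set, covariate) with flags.

    A set is flagged ``up`` when directed GSS ≥ cutoff and ``down`` when
    ≤ −cutoff; otherwise the flag is empty.  ``adjust`` selects the
    two-factor (default) vs univariate t-statistic model.
    """
    sets = list(gene_sets.values()) if isinstance(gene_sets, dict) else list(gene_sets)
    covariates = list(design.factors) if covariates is None else list(covariates)
    rows = []
    for cov in covariates:
        t = covariate_t(matrix, design, cov, adjust=adjust)
        for gs in sets:
            measured = gs.measured(matrix)
            if not measured:
                continue
            d = directed_gss(t, gs)
            u = undirected_gss(t, gs)
            flag = "up" if d >= cutoff else ("down" if d <= -cutoff else "")
            rows.append(
                {
                    "gene_set": gs.name,
                    "covariate": cov,
                    "n_genes": len(measured),
                    "directed_gss": d,
                    "undirected_gss": u,
                    "flag": flag,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cell-type profiling
# ---------------------------------------------------------------------------


def celltype_score(matrix: CountMatrix, markers: GeneSet) -> pd.Series:
    """Per-sample arithmetic mean of the marker genes' log2 values."""
    genes = markers.measured(matrix)
    if not genes:
        raise ValueError(f"no measured markers for cell type {markers.name!r}")
    return matrix.values.loc[genes].mean(axis=0).rename(markers.name)


def _mean_pairwise_corr(x: np.ndarray) -> float:
    """Mean off-diagonal Pearson correlation among the rows of ``x``."""
    c = np.corrcoef(x)
    iu = np.triu_indices_from(c, k=1)
    vals = c[iu]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else np.nan


def _mean_pairwise_slope(x: np.ndarray) -> float:
    """Mean regression slope over ordered marker pairs (descriptive only)."""
    slopes = []
    for i in range(x.shape[0]):
        for j in range(x.shape[0]):
            if i == j:
                continue
            vi = x[i] - x[i].mean()
            vj = x[j] - x[j].mean()
            denom = float(vi @ vi)
            if denom > 0:
                slopes.append(float(vi @ vj) / denom)
    return float(np.mean(slopes)) if slopes else np.nan


def celltype_qc(
    matrix: CountMatrix,
    markers: GeneSet,
    n_random: int = 999,
    seed: int | np.random.Generator = 0,
) -> CellTypeProfile:
    """Validate a marker set against random gene sets of the same size.

    The statistic is the mean pairwise Pearson correlation among markers
    across samples; the null draws ``n_random`` same-size sets (without
    replacement) from the measured non-marker genes, and the p-value is the
    add-one permutation estimate ``(1 + #{null ≥ observed}) / (1 + R)``.
    A single-marker set has no defined co-correlation: qc_p = 1, flagged.
    """
    genes = markers.measured(matrix)
    score = celltype_score(matrix, markers)
    if len(genes) < 2:
        return CellTypeProfile(
            name=markers.name, markers=genes, score=score, qc_p=1.0,
            mean_marker_corr=np.nan, qc_flag="undefined: <2 markers",
        )
    if n_random < 99:
        raise ValueError("n_random must be ≥ 99 for a stable permutation p")
    pool = [g for g in matrix.genes if g not in set(genes)]
    if len(pool) < len(genes):
        raise ValueError("not enough non-marker genes to draw null sets")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    x = matrix.values.loc[genes].to_numpy(dtype=float)
    observed = _mean_pairwise_corr(x)
    all_vals = matrix.values.loc[pool].to_numpy(dtype=float)
    null = np.empty(n_random)
    for r in range(n_random):
        idx = rng.choice(len(pool), size=len(genes), replace=False)
        null[r] = _mean_pairwise_corr(all_vals[idx])
    qc_p = (1.0 + np.sum(null >= observed)) / (1.0 + n_random)
    return CellTypeProfile(
        name=markers.name,
        markers=genes,
        score=score,
        qc_p=float(qc_p),
        mean_marker_corr=observed,
        mean_pairwise_slope=_mean_pairwise_slope(x),
    )


def profile_celltypes(
    matrix: CountMatrix,
    marker_sets,
    n_random: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Cell-type scores + QC for every marker set; tidy one-row-per-type."""
    sets = list(marker_sets.values()) if isinstance(marker_sets, dict) else list(marker_sets)
    rng = np.random.default_rng(seed)
    rows = []
    for gs in sets:
        prof = celltype_qc(matrix, gs, n_random=n_random, seed=rng)
        row = {
            "celltype": prof.name,
            "n_markers": len(prof.markers),
            "qc_p": prof.qc_p,
            "mean_marker_corr": prof.mean_marker_corr,
            "qc_flag": prof.qc_flag,
        }
        row.update(prof.score.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("celltype")
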