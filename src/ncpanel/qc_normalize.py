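"""Lane QC, background thresholding, geNorm housekeeping selection and
normalization to a log2 expression matrix.

The QC rules mirror the standard digital-count system checks: imaging
(percent fields of view counted, strictly > 75 by default), binding density
(within [0.1, 2.25] spots/µm² inclusive), positive-control linearity
(R² of log2 count on log2 concentration, strictly > 0.95) and a limit of
detection rule (the 0.5 fM positive probe must exceed the negative-control
mean plus two standard deviations, per lane).

Background is a single pooled threshold — arithmetic mean of all negative
control counts across all lanes plus ``lod_sd_mult`` sample standard
deviations — and a gene is dropped when it falls below threshold in strictly
more than an observation-frequency fraction of samples.  Housekeeping genes
are chosen by geNorm stability (mean standard deviation of pairwise log
ratios, least stable removed iteratively).  Sample (n−1) standard deviation
is used everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel_io import CountMatrix, SampleLane, positive_concentrations


@dataclass(frozen=True)
class QCThresholds:
    """Lane QC thresholds (defaults per the standard system QC)."""

    fov_min: float = 75.0
    bd_min: float = 0.1
    bd_max: float = 2.25
    poslin_r2_min: float = 0.95
    lod_sd_mult: float = 2.0

    def __post_init__(self) -> None:
        if not self.bd_min < self.bd_max:
            raise ValueError("bd_min must be < bd_max")
        if not 0 < self.poslin_r2_min <= 1:
            raise ValueError("poslin_r2_min must be in (0, 1]")


@dataclass
class QCReport:
    """Per-sample QC flags; ``overall_pass`` is the conjunction of all four."""

    table: pd.DataFrame

    @property
    def overall_pass(self) -> pd.Series:
        return self.table["overall_pass"]

    def all_passed(self) -> bool:
        return bool(self.table["overall_pass"].all())


@dataclass
class BackgroundFilter:
    threshold: float
    obs_freq: float
    kept: list
    removed: list


@dataclass
class GeNormResult:
    """geNorm output: stability M per candidate, the selection and the
    elimination order (least stable first)."""

    stability: dict
    selected: list
    removal_order: list


# ---------------------------------------------------------------------------
# lane QC
# ---------------------------------------------------------------------------


def pos_control_r2(counts: Mapping[float, float]) -> float:
    """R² of the positive-control titration.

    Simple linear regression of log2 count on log2 concentration; a flat
    response returns 0, an exact power law returns exactly 1.  A +0.5
    offset is applied only when a zero count would make the log undefined.
    """
    concs = np.asarray(list(counts), dtype=float)
    if len(np.unique(concs)) < 3:
        raise ValueError("need ≥3 distinct positive-control concentrations")
    raw = np.asarray([counts[c] for c in counts], dtype=float)
    y = np.log2(raw if (raw > 0).all() else raw + 0.5)
    x = np.log2(concs)
    xc = x - x.mean()
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        return 0.0
    beta = float(xc @ yc) / float(xc @ xc)
    ss_res = float(((yc - beta * xc) ** 2).sum())
    return 1.0 - ss_res / ss_y


def lane_qc(
    lanes: Sequence[SampleLane],
    thresholds: QCThresholds = QCThresholds(),
    concentrations: Mapping[str, float] | None = None,
) -> QCReport:
    """Apply the four system QC rules to every lane.

    Positive-probe concentrations are taken from ``concentrations`` or
    parsed from probe names like ``POS_A(128)``.
    """
    rows = []
    for lane in lanes:
        pos = lane.probes("Positive")
        neg = lane.probes("Negative")
        if not pos or not neg:
            raise ValueError(f"lane {lane.sample_id!r} lacks positive or negative probes")
        conc = dict(concentrations) if concentrations else positive_concentrations(pos)
        missing = [p for p in pos if p not in conc]
        if missing:
            raise ValueError(f"no concentration known for positive probes {missing}")
        titration = {conc[p]: lane.counts[p] for p in pos}
        r2 = pos_control_r2(titration)

        neg_counts = np.asarray([lane.counts[p] for p in neg], dtype=float)
        lod_limit = neg_counts.mean() + thresholds.lod_sd_mult * neg_counts.std(ddof=1)
        lod_probe_conc = min(conc.values(), key=lambda c: abs(c - 0.5))
        lod_count = titration[lod_probe_conc]

        fov_pass = lane.fov_counted_pct > thresholds.fov_min
        bd_pass = thresholds.bd_min <= lane.binding_density <= thresholds.bd_max
        poslin_pass = r2 > thresholds.poslin_r2_min
        lod_pass = lod_count > lod_limit
        rows.append(
            {
                "sample_id": lane.sample_id,
                "fov": lane.fov_counted_pct,
                "fov_pass": fov_pass,
                "binding_density": lane.binding_density,
                "bd_pass": bd_pass,
                "poslin_r2": r2,
                "poslin_pass": poslin_pass,
                "lod_count": lod_count,
                "lod_limit": lod_limit,
                "lod_pass": lod_pass,
                "overall_pass": fov_pass and bd_pass and poslin_pass and lod_pass,
            }
        )
    return QCReport(pd.DataFrame(rows).set_index("sample_id"))


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------


def background_threshold(neg_counts: Sequence[float]) -> float:
    """Pooled background: mean + 2·SD (sample SD) of all negative counts."""
    x = np.asarray(neg_counts, dtype=float)
    if x.size < 2:
        raise ValueError("need ≥2 negative-control observations")
    return float(x.mean() + 2.0 * x.std(ddof=1))


def background_thresholds_per_lane(matrix: CountMatrix) -> pd.Series:
    """Per-lane alternative to the single pooled threshold."""
    neg = matrix.of_class("Negative").values
    if neg.shape[0] < 2:
        raise ValueError("need ≥2 negative-control probes per lane")
    return neg.mean(axis=0) + 2.0 * neg.std(axis=0, ddof=1)


def filter_background(
    matrix: CountMatrix, threshold: float, obs_freq: float = 0.5
) -> BackgroundFilter:
    """Drop genes below ``threshold`` in strictly more than ``obs_freq`` of
    samples.  Only Endogenous and Housekeeping probes are candidates;
    controls are never filtered.
    """
    if matrix.scale != "raw":
        raise ValueError("background filtering operates on the raw matrix")
    if matrix.code_classes is not None:
        candidates = matrix.of_class("Endogenous", "Housekeeping")
    else:
        candidates = matrix
    below = (candidates.values < threshold).mean(axis=1)
    removed = list(below.index[below > obs_freq])
    kept = [g for g in candidates.genes if g not in set(removed)]
    return BackgroundFilter(threshold=threshold, obs_freq=obs_freq, kept=kept, removed=removed)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------


def _genorm_m(log2_counts: np.ndarray) -> np.ndarray:
    """Stability M per gene: mean over partners of SD of pairwise log ratios.

    ``log2_counts`` is genes × samples on the log2 scale.
    """
    k = log2_counts.shape[0]
    m = np.empty(k)
    for j in range(k):
        ratios = log2_counts[j] - log2_counts  # partners × samples
        sds = ratios.std(axis=1, ddof=1)
        m[j] = sds[np.arange(k) != j].mean()
    return m


def genorm_select(hk_matrix: CountMatrix, n_select: int, offset: float = 0.5) -> GeNormResult:
    """Iterative geNorm selection of the ``n_select`` most stable genes.

    At each step the gene with the largest stability M (mean SD of its
    pairwise log2 ratios) is removed and M is recomputed, until ``n_select``
    genes remain.  Ties break lexicographically on gene name.  Zero counts
    are shifted by ``offset`` before taking logs (``offset=0`` raises on
    zeros).
    """
    genes = list(hk_matrix.genes)
    if len(genes) < n_select:
        raise ValueError(f"only {len(genes)} candidates for n_select={n_select}")
    if len(genes) < 2:
        raise ValueError("geNorm needs ≥2 candidates")
    counts = hk_matrix.values.to_numpy(dtype=float)
    if (counts <= 0).any():
        if offset <= 0:
            raise ValueError("zero counts among housekeeping candidates and no offset")
        counts = counts + offset
    logs = np.log2(counts)

    stability: dict = {}
    removal_order: list = []
    active = list(range(len(genes)))
    while True:
        m = _genorm_m(logs[active])
        for idx, mj in zip(active, m):
            stability[genes[idx]] = float(mj)
        if len(active) <= n_select:
            break
        # remove the least stable; ties → lexicographically last name goes
        # first so the kept set is deterministic
        worst = max(range(len(active)), key=lambda i: (m[i], genes[active[i]]))
        removal_order.append(genes[active[worst]])
        del active[worst]
    selected = [genes[i] for i in active]
    return GeNormResult(stability=stability, selected=selected, removal_order=removal_order)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def positive_factors(matrix: CountMatrix) -> pd.Series:
    """Per-lane positive-control scaling: mean lane positive sum / lane sum."""
    pos = matrix.of_class("Positive").values
    sums = pos.sum(axis=0).astype(float)
    if (sums == 0).any():
        raise ValueError("a lane has zero total positive-control counts")
    return sums.mean() / sums


def normalize(
    matrix: CountMatrix,
    genorm: GeNormResult,
    pos_norm: bool = True,
    offset: float = 0.5,
) -> CountMatrix:
    """Scale lanes by positive-control and housekeeping factors, return log2.

    Per lane *i*: optional positive factor ``p_i`` (mean positive sum over
    lanes / lane positive sum), then housekeeping factor
    ``h_i = mean_j(g_j) / g_i`` with ``g_i`` the geometric mean of the
    selected housekeeping counts after positive scaling.  Values are
    returned as ``log2(count·p_i·h_i + offset)`` with control probes
    dropped.
    """
    if matrix.scale != "raw":
        raise ValueError("normalize expects a raw matrix")
    if matrix.code_classes is None:
        raise ValueError("normalize needs code-class annotation")
    missing = [g for g in genorm.selected if g not in matrix.values.index]
    if missing:
        raise ValueError(f"selected housekeeping genes absent from matrix: {missing}")

    p = positive_factors(matrix) if pos_norm else pd.Series(1.0, index=matrix.values.columns)

    hk = matrix.values.loc[genorm.selected].astype(float).mul(p, axis=1)
    if (hk.to_numpy() <= 0).any():
        if offset <= 0:
            raise ValueError("zero housekeeping count with offset disabled")
        hk = hk + offset
    g = np.exp(np.log(hk).mean(axis=0))
    h = g.mean() / g

    keep = matrix.code_classes[matrix.code_classes.isin(["Endogenous", "Housekeeping"])].index
    scaled = matrix.values.loc[keep].astype(float).mul(p * h, axis=1)
    values = np.log2(scaled + offset)
    return CountMatrix(values, scale="log2", code_classes=matrix.code_classes.loc[keep])
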