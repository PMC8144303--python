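"""Synthetic lane-data generator emulating a 12-lane targeted panel study.

The generator reproduces the *structure* of a pooled-sample neuropathology
panel experiment: ~770 endogenous genes plus housekeeping candidates, six
positive controls on a four-fold fM titration, eight negative controls,
and 12 lanes in four groups of three crossed over two binary genotype
factors.  Endogenous counts are negative-binomial around a log2 baseline
with additive (log2-scale) group effects and a per-lane scale factor;
housekeeping candidates are high-abundance and nearly Poisson, carrying
only a gene-specific per-lane stability deviation (decoy candidates a
larger one, so stability ranking has something to find);
controls are Poisson, with the positive titration scaled by the lane factor
so positive-control normalization is exercisable.

The default effect template mirrors the study qualitatively — the amyloid
factor spikes inflammation/AD-risk/autophagy sets, the arginase factor
spikes myelination/lipid sets with smaller effects — purely so every
pipeline stage has signal to find; it is not a numeric fidelity claim.
No attempt is made to match any real series' count distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import panel as panel_mod
from .panel_io import (
    CountMatrix,
    DesignTable,
    GeneSet,
    SampleLane,
    assemble_matrix,
    write_rcc,
)

FACTORS = ("APP", "Arg1")
LEVELS = {"APP": ("nTg", "APP"), "Arg1": ("Arg1_suff", "Arg1_insuff")}


@dataclass(frozen=True)
class Effect:
    """A spiked log2 fold change on a gene set for one design factor."""

    gene_set: object  # pathway name (str) or explicit gene sequence
    factor: str
    log2fc: float

    def resolve(self, pathways: dict) -> list:
        if isinstance(self.gene_set, str):
            if self.gene_set not in pathways:
                raise ValueError(f"effect references unknown gene set {self.gene_set!r}")
            return list(pathways[self.gene_set].genes)
        return list(self.gene_set)


def default_effects() -> list:
    return [
        Effect("activated microglia", "APP", 1.0),
        Effect("AD causal risk pathway", "APP", 0.8),
        Effect("autophagy", "APP", 0.8),
        Effect("myelination", "Arg1", 0.4),
        Effect("lipid metabolism", "Arg1", 0.35),
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    ``dispersion`` is the negative-binomial size parameter (larger → closer
    to Poisson); ``lane_scale_sd`` the SD of the per-lane log2 scale factor;
    ``hk_stability_sd`` / ``hk_decoy_sd`` the per-lane log2 deviation of the
    stable housekeeping genes and their decoy candidates; ``neg_mean`` the
    Poisson mean of negative controls; ``pos_counts_per_fm`` the capture
    factor turning fM into expected positive counts.
    """

    n_genes: int = 770
    n_hk_candidates: int = 10
    n_pos: int = 6
    n_neg: int = 8
    n_per_cell: int = 3
    baseline_log2_mean_range: tuple = (2.0, 11.0)
    dispersion: float = 15.0
    lane_scale_sd: float = 0.15
    effects: tuple = field(default_factory=lambda: tuple(default_effects()))
    hk_baseline_log2_range: tuple = (8.0, 11.0)
    hk_dispersion: float = 300.0
    hk_stability_sd: float = 0.05
    hk_decoy_sd: float = 0.35
    neg_mean: float = 5.0
    pos_titration: tuple = panel_mod.POS_TITRATION
    pos_counts_per_fm: float = 40.0
    seed: int = 0

    def null(self) -> "SimConfig":
        """Same conditions with every spiked effect removed."""
        return replace(self, effects=())


@dataclass
class GroundTruth:
    """What the generator actually injected."""

    log2fc: pd.DataFrame          # genes × factors, true additive effects
    lane_log2_scale: pd.Series    # per lane
    spiked_sets: dict             # factor → {set name/genes → log2fc}


def _build_design(config: SimConfig) -> DesignTable:
    rows = []
    idx = 0
    for a in LEVELS["APP"]:
        for b in LEVELS["Arg1"]:
            for _ in range(config.n_per_cell):
                idx += 1
                rows.append(
                    {
                        "sample_id": f"S{idx:02d}_{a}_{b}",
                        "APP": a,
                        "Arg1": b,
                        "sex": "M" if idx % 2 else "F",
                        "pool_size": 2,
                    }
                )
    table = pd.DataFrame(rows).set_index("sample_id")
    return DesignTable(table, FACTORS, dict(LEVELS))


def simulate_matrix(config: SimConfig = SimConfig()):
    """Generate (raw CountMatrix, DesignTable, GroundTruth) under ``config``.

    One root seed; gene-level parameters come from a panel-wide substream
    and each lane draws its counts from its own substream, so lanes are
    independent given the seed.
    """
    probes = panel_mod.default_panel(config.n_genes, config.n_hk_candidates)
    pathways = panel_mod.default_pathways(probes)
    endo = [p.gene_id for p in probes if p.code_class == "Endogenous"]
    hk = [p.gene_id for p in probes if p.code_class == "Housekeeping"]
    pos = [p.gene_id for p in probes if p.code_class == "Positive"][: config.n_pos]
    neg = [p.gene_id for p in probes if p.code_class == "Negative"][: config.n_neg]
    pos_conc = {p.gene_id: p.concentration for p in probes if p.code_class == "Positive"}
    design = _build_design(config)
    samples = design.samples

    root = np.random.SeedSequence(config.seed)
    panel_seq, *lane_seqs = root.spawn(1 + len(samples))
    panel_rng = np.random.default_rng(panel_seq)

    lo, hi = config.baseline_log2_mean_range
    hk_lo, hk_hi = config.hk_baseline_log2_range
    baseline = pd.Series(
        np.concatenate([
            panel_rng.uniform(lo, hi, size=len(endo)),
            panel_rng.uniform(hk_lo, hk_hi, size=len(hk)),
        ]),
        index=endo + hk,
    )

    # additive true log2 effects per gene × factor
    log2fc = pd.DataFrame(0.0, index=endo + hk, columns=list(FACTORS))
    spiked: dict = {f: {} for f in FACTORS}
    for eff in config.effects:
        if eff.factor not in FACTORS:
            raise ValueError(f"effect factor {eff.factor!r} not in {FACTORS}")
        genes = eff.resolve(pathways)
        unknown = [g for g in genes if g not in log2fc.index]
        if unknown:
            raise ValueError(f"effect references unknown genes {unknown[:5]}")
        log2fc.loc[genes, eff.factor] += eff.log2fc
        label = eff.gene_set if isinstance(eff.gene_set, str) else ",".join(genes[:3]) + "…"
        spiked[eff.factor][label] = eff.log2fc
    log2fc.loc[hk] = 0.0  # housekeeping genes never respond to the design

    decoys = set(panel_mod.HOUSEKEEPING_DECOYS)
    hk_sd = np.array([config.hk_decoy_sd if g in decoys else config.hk_stability_sd
                      for g in hk])

    x = {f: design.indicator(f).to_numpy() for f in FACTORS}
    endo_base = baseline.loc[endo].to_numpy()
    endo_fx = log2fc.loc[endo].to_numpy()  # genes × factors
    hk_base = baseline.loc[hk].to_numpy()

    columns = {}
    lane_scale = {}
    for i, (sample, seq) in enumerate(zip(samples, lane_seqs)):
        rng = np.random.default_rng(seq)
        s_i = rng.normal(0.0, config.lane_scale_sd)
        lane_scale[sample] = s_i
        shift = sum(endo_fx[:, j] * x[f][i] for j, f in enumerate(FACTORS))
        mu_endo = 2.0 ** (endo_base + shift + s_i)
        counts_endo = _nbinom(rng, mu_endo, config.dispersion)
        mu_hk = 2.0 ** (hk_base + s_i + rng.normal(0.0, hk_sd))
        counts_hk = _nbinom(rng, mu_hk, config.hk_dispersion)
        counts_pos = rng.poisson(
            np.array([config.pos_counts_per_fm * pos_conc[p] for p in pos]) * 2.0**s_i
        )
        counts_neg = rng.poisson(config.neg_mean, size=len(neg))
        columns[sample] = np.concatenate([counts_endo, counts_hk, counts_pos, counts_neg])

    index = endo + hk + pos + neg
    values = pd.DataFrame(columns, index=index)
    cc = pd.Series(
        ["Endogenous"] * len(endo) + ["Housekeeping"] * len(hk)
        + ["Positive"] * len(pos) + ["Negative"] * len(neg),
        index=index,
    )
    matrix = CountMatrix(values, scale="raw", code_classes=cc)
    truth = GroundTruth(
        log2fc=log2fc,
        lane_log2_scale=pd.Series(lane_scale),
        spiked_sets=spiked,
    )
    return matrix, design, truth


def _nbinom(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial with given mean and size (overdispersion) parameter."""
    p = size_param / (size_param + np.asarray(mean, dtype=float))
    return rng.negative_binomial(size_param, p)


def simulate_panel(config: SimConfig = SimConfig()):
    """Generate RCC-style lanes plus design table and ground truth.

    Lane attributes (FOV percent, binding density) are drawn inside the
    system-QC pass bands so a default simulation passes QC.
    """
    matrix, design, truth = simulate_matrix(config)
    attr_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA77]))
    lanes = []
    for sample in matrix.samples:
        lanes.append(
            SampleLane(
                sample_id=sample,
                counts={g: int(matrix.values.at[g, sample]) for g in matrix.genes},
                fov_counted_pct=float(attr_rng.uniform(90.0, 100.0)),
                binding_density=float(attr_rng.uniform(0.5, 1.5)),
                code_classes=matrix.code_classes.to_dict(),
                group_labels={f: design.table.at[sample, f] for f in design.factors},
            )
        )
    return lanes, design, truth


__all__ = [
    "Effect",
    "SimConfig",
    "GroundTruth",
    "default_effects",
    "simulate_matrix",
    "simulate_panel",
    "write_rcc",
    "assemble_matrix",
]
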