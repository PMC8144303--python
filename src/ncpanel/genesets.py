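"""Amyloid-associated glial signature curation, overlap decomposition and
composite scoring.

Seven glial transcriptomic signatures describe how microglia, astrocytes and
oligodendrocytes respond to amyloid-β plaques:

* **PIGs** – plaque-induced genes and **OLIGs** – plaque-correlated
  oligodendrocyte genes (spatial transcriptomics WGCNA modules);
* **DAM** – disease-associated microglia and **HM** – homeostatic microglia
  (single-cell contrasts of activated vs resting microglia);
* **MGnD** – microglial neurodegenerative phenotype and **M0** – tolerogenic
  microglia (bulk sorted-microglia contrasts);
* **DAA** – disease-associated astrocytes.

Each signature is curated from a ranked reference list (sorted by p-value or
fold change) by thresholding the statistic and intersecting with the genes a
targeted panel actually measures.  The composite amyloid-β glial signature
score is the per-sample average of the seven individual signature scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel_io import GeneSet

# ---------------------------------------------------------------------------
# shipped default signatures
# ---------------------------------------------------------------------------

#: The 17 plaque-induced genes measured by the mouse neuropathology panel,
#: as printed in the source study's overlap decomposition.
PIGS_GENES = (
    "Apoe", "Trem2", "C4a", "Cd9", "Grn", "Gusb", "Npc2",
    "C1qa", "C1qb", "C1qc", "Csf1r", "Cx3cr1", "Hexb", "Fcrls",
    "Clu", "Gfap", "Man2b1",
)

# The six lists below are synthetic stand-ins of the published sizes
# (DAM 15 / HM 9 / MGnD 20 / M0 25 / DAA 15 / OLIGs 30).  Their overlap with
# PIGs reproduces the published decomposition exactly; padding genes are
# well-known members of the respective literature signatures, but the full
# published panel-intersected lists live in a figure table that is not
# machine-readable, so these lists are stand-ins, not transcriptions.
DAM_GENES = (
    "Apoe", "Trem2", "Cd9", "Grn", "Gusb", "Npc2",
    "Cst7", "Lpl", "Itgax", "Clec7a", "Axl", "Tyrobp", "Ctsb", "Ctsd", "Cd63",
)
HM_GENES = (
    "C1qa", "C1qb", "C1qc", "Csf1r", "Cx3cr1", "Hexb", "Fcrls",
    "P2ry12", "Tmem119",
)
MGND_GENES = (
    "Apoe", "Trem2", "C4a", "Cd9", "Grn",
    "Axl", "Itgax", "Clec7a", "Spp1", "Gpnmb", "Lgals3", "Fabp5",
    "Ccl2", "Csf1", "Lyz2", "Ctsz", "Cst7", "Lpl", "Cd63", "Ctsb",
)
M0_GENES = (
    "P2ry12", "Tmem119", "Cx3cr1", "Hexb", "Csf1r", "C1qa", "C1qb", "C1qc",
    "Fcrls", "Selplg", "Siglech", "Olfml3", "Gpr34", "P2ry13", "Tgfbr1",
    "Mef2a", "Sall1", "Mafb", "Maf", "Jun", "Fos", "Egr1", "Klf2", "Txnip",
    "Marcks",
)
DAA_GENES = (
    "Gfap", "Clu", "Serpina3n", "Vim", "Osmr", "Mt1", "Mt2", "A2m",
    "Aqp4", "S100b", "Id3", "Fxyd1", "Slc38a1", "Sparcl1", "Gja1",
)
OLIGS_GENES = (
    "Mog", "Pllp", "Plxnb3", "Gsn", "Fa2h", "Mag", "Mbp", "Plp1", "Mobp",
    "Cnp", "Mal", "Opalin", "Cldn11", "Sox10", "Olig1", "Olig2", "Ugt8a",
    "Gal3st1", "Ermn", "Gjb1", "Gjc2", "Aspa", "Trf", "Car2", "Qdpr",
    "Tppp", "Sirt2", "Cryab", "Sept4", "Pdgfra",
)

SIGNATURE_NAMES = ("PIGs", "OLIGs", "DAM", "HM", "MGnD", "M0", "DAA")

_DEFAULT_LISTS = {
    "PIGs": (PIGS_GENES, "spatial WGCNA plaque module"),
    "OLIGs": (OLIGS_GENES, "spatial WGCNA oligodendrocyte module (synthetic stand-in)"),
    "DAM": (DAM_GENES, "scRNA-seq activated-microglia contrast (synthetic stand-in)"),
    "HM": (HM_GENES, "scRNA-seq homeostatic-microglia contrast (synthetic stand-in)"),
    "MGnD": (MGND_GENES, "sorted-microglia amyloid contrast (synthetic stand-in)"),
    "M0": (M0_GENES, "sorted-microglia tolerogenic contrast (synthetic stand-in)"),
    "DAA": (DAA_GENES, "scRNA-seq disease-associated astrocyte contrast (synthetic stand-in)"),
}


def default_signatures() -> dict:
    """The seven shipped glial signatures as name → :class:`GeneSet`."""
    return {
        name: GeneSet(name, genes, theme="amyloid-associated glia", provenance=prov)
        for name, (genes, prov) in _DEFAULT_LISTS.items()
    }


# ---------------------------------------------------------------------------
# curation from ranked references
# ---------------------------------------------------------------------------

STAT_KINDS = ("neglog10_p", "log2_fc")


@dataclass(frozen=True)
class RankedReference:
    """A reference gene ranking: (gene, statistic) pairs plus semantics.

    ``stat_kind`` is ``neglog10_p`` (−log10 p, always thresholded from
    above) or ``log2_fc``.  ``direction`` records whether the listed genes
    are the up- or down-regulated side of the source contrast; for
    ``log2_fc`` rankings it decides the inequality used at the cutoff.
    """

    name: str
    entries: tuple
    stat_kind: str
    direction: str = "up"

    def __post_init__(self) -> None:
        if self.stat_kind not in STAT_KINDS:
            raise ValueError(f"unknown stat kind {self.stat_kind!r}")
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        object.__setattr__(self, "entries", tuple((g, float(s)) for g, s in self.entries))


def curate_signature(
    ref: RankedReference,
    cutoff: float,
    panel_genes: Sequence[str],
    stat_kind: str | None = None,
    name: str | None = None,
) -> GeneSet | None:
    """Threshold a ranked reference and intersect with the panel.

    Genes passing the cutoff (``≥`` for −log10 p and up-regulated fold
    changes, ``≤`` for down-regulated fold changes) and measured by the
    panel are returned in reference order.  Returns ``None`` (with no set)
    when the intersection is empty.
    """
    if stat_kind is not None and stat_kind != ref.stat_kind:
        raise ValueError(
            f"cutoff stat kind {stat_kind!r} does not match reference {ref.stat_kind!r}"
        )
    if not panel_genes:
        raise ValueError("panel gene list is empty")
    if ref.stat_kind == "neglog10_p" or ref.direction == "up":
        passing = [g for g, s in ref.entries if s >= cutoff]
    else:
        passing = [g for g, s in ref.entries if s <= cutoff]
    panel = set(panel_genes)
    selected = [g for g in passing if g in panel]
    if not selected:
        return None
    return GeneSet(name or ref.name, tuple(selected), provenance=f"curated from {ref.name}")


def read_ranked_reference(path, name, stat_kind, direction="up") -> RankedReference:
    """Read a two-column TSV (gene, stat) into a :class:`RankedReference`."""
    df = pd.read_csv(path, sep="\t", header=0)
    gene_col, stat_col = df.columns[:2]
    entries = tuple(zip(df[gene_col].astype(str), df[stat_col].astype(float)))
    return RankedReference(name, entries, stat_kind, direction)


# ---------------------------------------------------------------------------
# overlap decomposition
# ---------------------------------------------------------------------------


def _largest_remainder_percents(counts: Sequence[int], total: int) -> list:
    """Integer percentages summing to 100 (largest-remainder apportionment)."""
    raw = [100.0 * c / total for c in counts]
    floors = [int(np.floor(r)) for r in raw]
    shortfall = 100 - sum(floors)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - floors[i], raw[i]), reverse=True)
    for i in order[:shortfall]:
        floors[i] += 1
    return floors


def signature_overlap(base: GeneSet, partitions: Mapping[str, Sequence[GeneSet]]) -> pd.DataFrame:
    """Decompose ``base`` over named signature groups.

    Each base gene is assigned to the first group (in the given order) whose
    union contains it; unassigned genes fall into ``others``.  Percentages
    are integers reconciled to a 100 total by largest remainder.
    """
    if len(base) == 0:
        raise ValueError("empty base gene set")
    group_genes = {
        name: set().union(*(set(s.genes) for s in sets)) for name, sets in partitions.items()
    }
    assignment: dict = {name: [] for name in partitions}
    assignment["others"] = []
    for g in base.genes:
        for name in partitions:
            if g in group_genes[name]:
                assignment[name].append(g)
                break
        else:
            assignment["others"].append(g)
    names = list(assignment)
    counts = [len(assignment[n]) for n in names]
    pcts = _largest_remainder_percents(counts, len(base))
    return pd.DataFrame(
        {
            "group": names,
            "n_genes": counts,
            "percent": pcts,
            "genes": [",".join(assignment[n]) for n in names],
        }
    ).set_index("group")


def composite_signature_score(signature_scores: Mapping[str, pd.Series]) -> pd.Series:
    """Average the seven per-sample glial signature scores.

    ``signature_scores`` must contain every name in
    :data:`SIGNATURE_NAMES`, each a Series over an identical sample index.
    """
    missing = [n for n in SIGNATURE_NAMES if n not in signature_scores]
    if missing:
        raise ValueError(f"missing signature scores: {missing}")
    frame = pd.DataFrame({n: signature_scores[n] for n in SIGNATURE_NAMES})
    if frame.isna().any().any():
        raise ValueError("signature scores are not aligned over identical samples")
    return frame.mean(axis=1).rename("composite")
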