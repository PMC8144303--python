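"""Shipped default panel: a 770-gene mouse neuropathology-style annotation.

The panel mirrors the structure of a targeted neuropathology expression
codeset: ~770 endogenous probes annotated into 25 pathways under seven
themes, housekeeping candidates, six positive controls on a four-fold fM
titration and eight negative controls, plus cell-type marker annotations.

Only the genes that the source study names (the 15-gene AD causal risk set,
the autophagy anchors, housekeeping genes, cell-type markers, glial
signature genes and the named differentially expressed genes) are real; the
remaining endogenous gene names are synthetic filler (``Syn0001`` …) used to
bring the panel to its nominal size.  The filler is distributed round-robin
over the pathways so every pathway is scoreable.
"""

from __future__ import annotations

from itertools import cycle

from . import genesets
from .panel_io import GeneSet, ProbeDefinition

#: four-fold titration of the positive spike-in probes, in fM
POS_TITRATION = (128.0, 32.0, 8.0, 2.0, 0.5, 0.125)

#: the 15 genome-wide-association AD causal/risk genes annotated as a
#: custom pathway on the panel
AD_CAUSAL_RISK_GENES = (
    "Cntnap2", "Cd33", "Psen2", "Mapt", "Psmb9", "App", "Psen1", "Apoe",
    "Trem2", "Adam10", "Psmb8", "Spi1", "Sorl1", "Clu", "C4a",
)

#: housekeeping genes selected in the source study by geNorm
HOUSEKEEPING_SELECTED = ("Aars", "Ccdc127", "Cnot10", "Csnk2a2", "Lars", "Mto1")
#: extra candidates so housekeeping selection has something to reject
HOUSEKEEPING_DECOYS = ("Hkc1", "Hkc2", "Hkc3", "Hkc4")

#: cell-type marker panels (microglia/oligodendrocyte lists as published;
#: the remaining cell types use canonical literature markers)
CELLTYPE_MARKERS = {
    "microglia_macrophages": ("Fcrls", "Itgam", "Trem2", "Irf8", "Cd68", "Hexb", "Cx3cr1"),
    "oligodendrocytes": ("Mog", "Pllp", "Plxnb3", "Gsn", "Fa2h", "Mag"),
    "astrocytes": ("Gfap", "Aqp4", "Slc1a3", "Aldh1l1", "Slc1a2"),
    "endothelial_cells": ("Cldn5", "Flt1", "Pecam1", "Slc2a1", "Emcn"),
    "neurotransmitter_neurons": ("Slc17a7", "Gad1", "Gad2", "Slc6a1", "Syt1"),
    "mature_neurons": ("Rbfox3", "Nefl", "Snap25", "Map2", "Eno2"),
}

#: 25 pathways mapped into seven themes (one disease theme, six functional)
PATHWAY_THEMES = {
    "AD causal risk pathway": "neurodegeneration disease association",
    "disease association": "neurodegeneration disease association",
    "neuronal cytoskeleton": "compartmentalization & structural integrity",
    "axon and dendrite structure": "compartmentalization & structural integrity",
    "tissue integrity": "compartmentalization & structural integrity",
    "autophagy": "metabolism",
    "lipid metabolism": "metabolism",
    "carbohydrate metabolism": "metabolism",
    "oxidative stress": "metabolism",
    "activated microglia": "neuroinflammation",
    "cytokines": "neuroinflammation",
    "inflammatory signaling": "neuroinflammation",
    "matrix remodeling": "neuroinflammation",
    "angiogenesis": "neuroplasticity, development & aging",
    "apoptosis": "neuroplasticity, development & aging",
    "growth factor signaling": "neuroplasticity, development & aging",
    "neural plasticity": "neuroplasticity, development & aging",
    "transcription and splicing": "neuroplasticity, development & aging",
    "myelination": "neuron-glia interaction",
    "astrocyte function": "neuron-glia interaction",
    "neuron-glia adhesion": "neuron-glia interaction",
    "transmitter synthesis and storage": "neurotransmission",
    "transmitter release": "neurotransmission",
    "transmitter response and reuptake": "neurotransmission",
    "vesicle trafficking": "neurotransmission",
}

#: real gene → pathway seeds (genes may belong to several pathways)
_PATHWAY_SEEDS = {
    "AD causal risk pathway": AD_CAUSAL_RISK_GENES,
    "autophagy": ("Atg5", "Becn1", "Mapk8", "Sirt1", "Tsc2", "Gba", "Hmox1", "Ctsd", "Ctsb"),
    "activated microglia": (
        "Cd68", "Irf8", "Fcrls", "Itgam", "Cx3cr1", "Hexb", "Trem2", "C4a", "Cd33",
        "Tyrobp", "Clec7a", "Itgax", "Cst7", "Csf1r", "C1qa", "C1qb", "C1qc", "Stab1",
        "Grn", "Gusb", "Man2b1", "Lyz2", "Spi1",
    ),
    "cytokines": ("Il6", "Il4ra", "Osmr", "Tgfbr2", "Ccl2", "Csf1", "Il5", "Rela", "Stat1"),
    "inflammatory signaling": ("Rela", "Stat1", "Mapk8", "Tgfbr1", "Jun", "Fos", "Spp1"),
    "myelination": genesets.OLIGS_GENES,
    "lipid metabolism": ("Apoe", "Clu", "Lpl", "Npc2", "Gba", "Cers4", "Soat1", "Fabp5", "Fa2h"),
    "neuronal cytoskeleton": ("Mapt", "Nefl", "Map2", "Tppp", "Sirt2", "Mta2", "Ncl"),
    "disease association": ("App", "Mapt", "Apoe", "Psen1", "Psen2", "Gfap", "Ache", "Nos1", "C3"),
    "astrocyte function": genesets.DAA_GENES,
    "angiogenesis": ("Flt1", "Pecam1", "Emcn", "Cldn5", "Epha3", "Slc2a1", "Vim"),
    "apoptosis": ("Bcl2", "Fas", "Casp6", "Creb1", "Pten", "Akt2"),
    "transmitter synthesis and storage": ("Gad1", "Gad2", "Slc17a7", "Slc6a1", "Ache", "Nos1"),
    "transmitter release": ("Snap25", "Syt1", "Stx1b", "Gnao1"),
    "transmitter response and reuptake": ("Grin1", "Grin2d", "Gabrb3", "Slc1a2", "Slc1a3", "Lpar1"),
    "growth factor signaling": ("Tgfbr2", "Tgfbr1", "Raf1", "Notch1", "Il4ra", "Pdgfra"),
    "neural plasticity": ("Creb1", "Grin1", "Calb2", "Egr1", "Mef2a"),
    "vesicle trafficking": ("Syt1", "Stx1b", "Snap25", "Cd9", "Cd63", "U2af2"),
    "matrix remodeling": ("A2m", "Sparcl1", "Gja1", "Lgals3"),
    "oxidative stress": ("Hmox1", "Mt1", "Mt2", "Txnip", "Qdpr"),
    "carbohydrate metabolism": ("Slc2a1", "Gusb", "Car2", "Gpnmb"),
    "axon and dendrite structure": ("Nefl", "Map2", "Cntnap2", "Plxnb3", "Ermn"),
    "tissue integrity": ("Cldn11", "Cldn5", "Gjb1", "Gjc2", "Aqp4", "Fxyd1"),
    "neuron-glia adhesion": ("Cntnap2", "Mag", "Mog", "Sema4d", "Selplg"),
    "transcription and splicing": ("Spi1", "U2af2", "Mef2a", "Sall1", "Mafb", "Maf", "Jun", "Fos", "Id3", "Sox10", "Olig1", "Olig2"),
}


def _real_endogenous_genes() -> list:
    seen: dict = {}
    sources = (
        AD_CAUSAL_RISK_GENES,
        *(_PATHWAY_SEEDS[p] for p in _PATHWAY_SEEDS),
        *(CELLTYPE_MARKERS[c] for c in CELLTYPE_MARKERS),
        genesets.PIGS_GENES, genesets.DAM_GENES, genesets.HM_GENES,
        genesets.MGND_GENES, genesets.M0_GENES, genesets.DAA_GENES,
        genesets.OLIGS_GENES,
    )
    for source in sources:
        for g in source:
            seen[g] = None
    return list(seen)


def default_panel(n_genes: int = 770, n_hk_candidates: int = 10) -> list:
    """Build the shipped default panel as a list of :class:`ProbeDefinition`.

    ``n_genes`` endogenous probes (real named genes first, synthetic filler
    after), ``n_hk_candidates`` housekeeping candidates, six positive and
    eight negative controls.
    """
    real = _real_endogenous_genes()
    if n_genes < len(real):
        raise ValueError(f"n_genes must be ≥ {len(real)} to hold the named genes")
    gene_names = real + [f"Syn{i:04d}" for i in range(1, n_genes - len(real) + 1)]

    pathways_of: dict = {g: set() for g in gene_names}
    for pathway, seeds in _PATHWAY_SEEDS.items():
        for g in seeds:
            pathways_of[g].add(pathway)
    # the AD causal risk pathway is a fixed 15-gene curation — no filler
    filler_cycle = cycle(sorted(p for p in PATHWAY_THEMES
                                if p != "AD causal risk pathway"))
    for g in gene_names:
        if not pathways_of[g]:
            pathways_of[g].add(next(filler_cycle))

    celltypes_of: dict = {g: set() for g in gene_names}
    for celltype, markers in CELLTYPE_MARKERS.items():
        for g in markers:
            celltypes_of[g].add(celltype)

    probes = [
        ProbeDefinition(g, "Endogenous",
                        annotations=frozenset(pathways_of[g]),
                        celltypes=frozenset(celltypes_of[g]))
        for g in gene_names
    ]
    hk = list(HOUSEKEEPING_SELECTED) + list(HOUSEKEEPING_DECOYS)
    if n_hk_candidates > len(hk):
        hk += [f"Hkc{i}" for i in range(len(HOUSEKEEPING_DECOYS) + 1,
                                        n_hk_candidates - len(HOUSEKEEPING_SELECTED) + 1)]
    probes += [ProbeDefinition(g, "Housekeeping") for g in hk[:n_hk_candidates]]
    probes += [
        ProbeDefinition(f"POS_{chr(65 + i)}({conc:g})", "Positive", concentration=conc)
        for i, conc in enumerate(POS_TITRATION)
    ]
    probes += [ProbeDefinition(f"NEG_{chr(65 + i)}", "Negative") for i in range(8)]
    return probes


def default_pathways(probes=None) -> dict:
    """Pathway name → GeneSet for the default panel, with themes attached."""
    from .panel_io import pathway_sets

    probes = default_panel() if probes is None else probes
    sets = pathway_sets(probes)
    return {
        name: GeneSet(name, s.genes, theme=PATHWAY_THEMES.get(name, ""))
        for name, s in sets.items()
    }
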