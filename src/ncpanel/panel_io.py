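"""Readers, writers and in-memory containers for targeted expression panels.

The lane format is a plain-text RCC dialect as produced by digital-count
instruments: bracketed sections (``<Header>``, ``<Sample_Attributes>``,
``<Lane_Attributes>``, ``<Code_Summary>``) holding comma-separated records.
Probe annotations, design tables and count matrices travel as tab-separated
tables; gene sets additionally as GMT.

Gene identity is case-sensitive exact string match throughout; probe names
on a fixed panel are stable, so no alias resolution is attempted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

CODE_CLASSES = ("Endogenous", "Housekeeping", "Positive", "Negative")

#: regex extracting the spike-in concentration (fM) from a positive-probe
#: name such as ``POS_A(128)``
_POS_CONC_RE = re.compile(r"\(([\d.]+)\)\s*$")


class PanelFormatError(ValueError):
    """A panel file violates the expected dialect."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProbeDefinition:
    """One probe of the panel: identity, class and annotations.

    ``concentration`` is the spike-in amount in fM and is mandatory for
    Positive probes and forbidden for Negative probes.  ``annotations`` are
    pathway names, ``celltypes`` the cell types the probe marks.
    """

    gene_id: str
    code_class: str
    concentration: float | None = None
    annotations: frozenset = field(default_factory=frozenset)
    celltypes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.code_class not in CODE_CLASSES:
            raise ValueError(f"unknown code class {self.code_class!r}")
        if self.code_class == "Positive":
            if self.concentration is None or self.concentration <= 0:
                raise ValueError(
                    f"positive probe {self.gene_id!r} needs a positive concentration"
                )
        elif self.code_class == "Negative" and self.concentration is not None:
            raise ValueError(f"negative probe {self.gene_id!r} must not carry a concentration")


@dataclass
class SampleLane:
    """Raw counts of one lane plus its imaging attributes.

    ``fov_counted_pct`` is the percentage of attempted fields of view that
    were counted; ``binding_density`` is in spots/µm².  ``code_classes``
    mirrors the Code_Summary section's CodeClass column.
    """

    sample_id: str
    counts: dict
    fov_counted_pct: float
    binding_density: float
    code_classes: dict = field(default_factory=dict)
    group_labels: dict = field(default_factory=dict)

    def probes(self, code_class: str) -> list:
        return [g for g, c in self.code_classes.items() if c == code_class]


@dataclass
class CountMatrix:
    """Genes × samples matrix with a scale tag.

    ``values`` is a DataFrame indexed by gene with one column per sample.
    ``scale`` is one of raw / normalized / log2.  ``code_classes`` is an
    optional per-gene Series aligned to the index.
    """

    values: pd.DataFrame
    scale: str = "raw"
    code_classes: pd.Series | None = None

    SCALES = ("raw", "normalized", "log2")

    def __post_init__(self) -> None:
        if self.scale not in self.SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "raw":
            v = self.values.to_numpy()
            if (v < 0).any() or not np.allclose(v, np.round(v)):
                raise ValueError("raw matrix must hold non-negative integers")
        elif not np.isfinite(self.values.to_numpy()).all():
            raise ValueError(f"{self.scale} matrix must be finite")

    @property
    def genes(self) -> list:
        return list(self.values.index)

    @property
    def samples(self) -> list:
        return list(self.values.columns)

    def subset(self, genes: Sequence[str]) -> "CountMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing}")
        cc = self.code_classes.loc[list(genes)] if self.code_classes is not None else None
        return CountMatrix(self.values.loc[list(genes)], self.scale, cc)

    def of_class(self, *code_classes: str) -> "CountMatrix":
        if self.code_classes is None:
            raise ValueError("matrix carries no code-class annotation")
        keep = self.code_classes[self.code_classes.isin(code_classes)].index
        return CountMatrix(self.values.loc[keep], self.scale, self.code_classes.loc[keep])


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered, duplicate-free gene list."""

    name: str
    genes: tuple
    theme: str = ""
    provenance: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", tuple(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    def measured(self, matrix: CountMatrix) -> list:
        present = set(matrix.values.index)
        return [g for g in self.genes if g in present]


@dataclass
class DesignTable:
    """Sample → factor-level assignment for a crossed two-factor design.

    ``table`` is indexed by sample id with one column per factor (plus any
    extra columns such as sex or pool_size).  ``levels`` fixes the
    (reference, alternative) order per factor, which defines the sign of
    every downstream contrast and covariate coding.
    """

    table: pd.DataFrame
    factors: tuple
    levels: dict

    def __post_init__(self) -> None:
        for f in self.factors:
            if f not in self.table.columns:
                raise ValueError(f"design table lacks factor column {f!r}")
            seen = set(self.table[f])
            if not seen <= set(self.levels[f]):
                raise ValueError(f"factor {f!r} has levels {seen} outside {self.levels[f]}")

    @property
    def samples(self) -> list:
        return list(self.table.index)

    def group_key(self, sample: str) -> tuple:
        return tuple(self.table.loc[sample, f] for f in self.factors)

    def samples_in(self, cell: tuple) -> list:
        mask = np.ones(len(self.table), dtype=bool)
        for f, lev in zip(self.factors, cell):
            mask &= (self.table[f] == lev).to_numpy()
        return list(self.table.index[mask])

    def indicator(self, factor: str) -> pd.Series:
        """0/1 coding of ``factor`` (reference level → 0)."""
        ref, alt = self.levels[factor]
        return (self.table[factor] == alt).astype(float)

    def check_covers(self, samples: Iterable[str]) -> None:
        missing = [s for s in samples if s not in self.table.index]
        if missing:
            raise ValueError(f"samples without a design row: {missing}")


# ---------------------------------------------------------------------------
# RCC lane files
# ---------------------------------------------------------------------------

_SECTION_RE = re.compile(r"^<(/?)([A-Za-z_]+)>\s*$")


def _parse_sections(text: str, path: str) -> dict:
    sections: dict = {}
    current = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        m = _SECTION_RE.match(line)
        if m:
            closing, name = m.groups()
            if closing:
                current = None
            else:
                current = name
                sections.setdefault(name, [])
            continue
        if current is not None and line.strip():
            sections[current].append((lineno, line))
    if "Code_Summary" not in sections:
        raise PanelFormatError(f"{path}: missing Code_Summary section")
    return sections


def _kv(section: list) -> dict:
    out = {}
    for _, line in section:
        key, _, value = line.partition(",")
        out[key] = value
    return out


def read_rcc(path) -> SampleLane:
    """Parse one RCC-dialect lane file into a :class:`SampleLane`.

    Counts must be integers; a fractional count is a format error naming the
    offending line.  FOV (percent counted) and binding density come from the
    Lane_Attributes section.
    """
    path = Path(path)
    sections = _parse_sections(path.read_text(), str(path))

    sample_attrs = _kv(sections.get("Sample_Attributes", []))
    lane_attrs = _kv(sections.get("Lane_Attributes", []))
    sample_id = sample_attrs.get("ID", path.stem)
    group_labels = {
        k[len("Group_"):]: v for k, v in sample_attrs.items() if k.startswith("Group_")
    }
    try:
        fov = float(lane_attrs["FovCounted"])
        bd = float(lane_attrs["BindingDensity"])
    except KeyError as exc:
        raise PanelFormatError(f"{path}: Lane_Attributes lacks {exc.args[0]}") from None

    counts: dict = {}
    code_classes: dict = {}
    for lineno, line in sections["Code_Summary"]:
        fields = line.split(",")
        if fields[0] == "CodeClass":  # header row
            continue
        if len(fields) != 4:
            raise PanelFormatError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
        code_class, name, _accession, count_str = fields
        try:
            count = int(count_str)
        except ValueError:
            raise PanelFormatError(
                f"{path}:{lineno}: non-integer count {count_str!r} for probe {name!r}"
            ) from None
        if count < 0:
            raise PanelFormatError(f"{path}:{lineno}: negative count for probe {name!r}")
        if name in counts:
            raise PanelFormatError(f"{path}:{lineno}: duplicate probe {name!r}")
        counts[name] = count
        code_classes[name] = code_class
    return SampleLane(
        sample_id=sample_id,
        counts=counts,
        fov_counted_pct=fov,
        binding_density=bd,
        code_classes=code_classes,
        group_labels=group_labels,
    )


def write_rcc(lane: SampleLane, path) -> None:
    """Emit ``lane`` in the RCC dialect read back by :func:`read_rcc`."""
    lines = ["<Header>", "FileVersion,1.7", "SoftwareVersion,ncpanel", "</Header>", ""]
    lines += ["<Sample_Attributes>", f"ID,{lane.sample_id}"]
    for factor, level in lane.group_labels.items():
        lines.append(f"Group_{factor},{level}")
    lines += ["</Sample_Attributes>", ""]
    lines += [
        "<Lane_Attributes>",
        "ID,1",
        f"FovCounted,{lane.fov_counted_pct:g}",
        f"BindingDensity,{lane.binding_density:g}",
        "</Lane_Attributes>",
        "",
    ]
    lines += ["<Code_Summary>", "CodeClass,Name,Accession,Count"]
    for gene, count in lane.counts.items():
        cc = lane.code_classes.get(gene, "Endogenous")
        lines.append(f"{cc},{gene},NA,{int(count)}")
    lines += ["</Code_Summary>", ""]
    Path(path).write_text("\n".join(lines))


def assemble_matrix(lanes: Sequence[SampleLane]) -> CountMatrix:
    """Stack lanes into a raw genes × samples matrix, sample order = lane order."""
    if not lanes:
        raise ValueError("no lanes given")
    universe = list(lanes[0].counts)
    uset = set(universe)
    for lane in lanes[1:]:
        if set(lane.counts) != uset:
            diff = sorted(set(lane.counts) ^ uset)
            raise PanelFormatError(
                f"lane {lane.sample_id!r} probe universe mismatch: {diff}"
            )
    data = {lane.sample_id: [lane.counts[g] for g in universe] for lane in lanes}
    values = pd.DataFrame(data, index=universe)
    cc = pd.Series({g: lanes[0].code_classes.get(g, "Endogenous") for g in universe})
    return CountMatrix(values, scale="raw", code_classes=cc.loc[values.index])


def positive_concentrations(probe_names: Iterable[str]) -> dict:
    """Extract fM concentrations from positive-probe names like ``POS_A(128)``."""
    out = {}
    for name in probe_names:
        m = _POS_CONC_RE.search(name)
        if m:
            out[name] = float(m.group(1))
    return out


# ---------------------------------------------------------------------------
# probe annotation tables
# ---------------------------------------------------------------------------


def read_probe_annotations(path) -> list:
    """Read a tab-separated probe annotation table.

    Columns: gene_id, code_class, concentration (blank unless Positive),
    pathways (``;``-separated), celltypes (``;``-separated).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"gene_id", "code_class"}
    if df.empty and not required <= set(df.columns):
        return []
    if not required <= set(df.columns):
        raise PanelFormatError(f"{path}: annotation table needs columns {sorted(required)}")
    dupes = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dupes:
        raise PanelFormatError(f"{path}: duplicate gene ids {sorted(set(dupes))}")
    probes = []
    for _, row in df.iterrows():
        conc_raw = row.get("concentration", "")
        conc = float(conc_raw) if conc_raw not in ("", "NA") else None
        ann = frozenset(p for p in row.get("pathways", "").split(";") if p)
        cts = frozenset(c for c in row.get("celltypes", "").split(";") if c)
        try:
            probes.append(
                ProbeDefinition(row["gene_id"], row["code_class"], conc, ann, cts)
            )
        except ValueError as exc:
            raise PanelFormatError(f"{path}: {exc}") from None
    return probes


def write_probe_annotations(probes: Sequence[ProbeDefinition], path) -> None:
    rows = [
        {
            "gene_id": p.gene_id,
            "code_class": p.code_class,
            "concentration": "" if p.concentration is None else f"{p.concentration:g}",
            "pathways": ";".join(sorted(p.annotations)),
            "celltypes": ";".join(sorted(p.celltypes)),
        }
        for p in probes
    ]
    pd.DataFrame(rows, columns=["gene_id", "code_class", "concentration", "pathways", "celltypes"]).to_csv(
        path, sep="\t", index=False
    )


def pathway_sets(probes: Sequence[ProbeDefinition]) -> dict:
    """Invert probe annotations into pathway-name → GeneSet (panel order)."""
    names: dict = {}
    for p in probes:
        for a in p.annotations:
            names.setdefault(a, []).append(p.gene_id)
    return {n: GeneSet(n, genes) for n, genes in names.items()}


def celltype_sets(probes: Sequence[ProbeDefinition]) -> dict:
    names: dict = {}
    for p in probes:
        for c in p.celltypes:
            names.setdefault(c, []).append(p.gene_id)
    return {n: GeneSet(n, genes) for n, genes in names.items()}


# ---------------------------------------------------------------------------
# gene sets (GMT + two-column TSV), matrices, design tables
# ---------------------------------------------------------------------------


def read_gmt(path) -> list:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise PanelFormatError(f"{path}: GMT line needs name, description, ≥1 gene")
        theme, _, provenance = fields[1].partition("|")
        sets.append(GeneSet(fields[0], tuple(fields[2:]), theme=theme, provenance=provenance))
    return sets


def write_gmt(sets: Sequence[GeneSet], path) -> None:
    lines = [
        "\t".join([s.name, f"{s.theme}|{s.provenance}", *s.genes]) for s in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_matrix(path) -> CountMatrix:
    """Read a TSV count matrix (genes in rows; ``# scale:`` comment honoured)."""
    path = Path(path)
    scale = "raw"
    with path.open() as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("# scale:"):
        scale = first.partition(":")[2].strip()
        skip = 1
    df = pd.read_csv(path, sep="\t", index_col=0, skiprows=skip)
    df.index.name = None
    cc = None
    if "code_class" in df.columns:
        cc = df.pop("code_class")
    if scale == "raw":
        df = df.astype(int)
    return CountMatrix(df, scale=scale, code_classes=cc)


def write_matrix(matrix: CountMatrix, path) -> None:
    df = matrix.values.copy()
    if matrix.code_classes is not None:
        df.insert(0, "code_class", matrix.code_classes)
    with Path(path).open("w") as fh:
        fh.write(f"# scale: {matrix.scale}\n")
        df.to_csv(fh, sep="\t", index_label="gene")


def read_design(path, factors: Sequence[str] = ("APP", "Arg1")) -> DesignTable:
    """Read a design TSV (sample_id + one column per factor + extras).

    Level order per factor is order of first appearance, which fixes the
    reference level for contrasts.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    levels = {}
    for f in factors:
        if f not in df.columns:
            raise PanelFormatError(f"{path}: design lacks factor column {f!r}")
        seen = list(dict.fromkeys(df[f]))
        if len(seen) != 2:
            raise PanelFormatError(f"{path}: factor {f!r} must have exactly 2 levels, got {seen}")
        levels[f] = tuple(seen)
    return DesignTable(df, tuple(factors), levels)


def write_design(design: DesignTable, path) -> None:
    design.table.to_csv(path, sep="\t", index_label="sample_id")
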