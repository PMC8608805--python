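"""Star-allele haplotype definitions and translation tables.

A star allele is a named haplotype of a pharmacogene, defined by a vector of
variant states over the panel sites plus, for CYP2D6, a structural class:
an ordinary full gene, the whole-gene deletion (*5), or a CYP2D7/CYP2D6
fusion ("hybrid") whose sequence switches origin inside a stated interval
between CNV probe regions. Hybrids occur both alone and in cis with a full
gene ("hybrid tandems", e.g. *13 + *2 or *36 + *10).

Translation tables are plain TSV files (one row per haplotype, one column
per panel site); the built-in tables encode the haplotypes interrogated by
the supported genotyping platforms.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import IO, Iterable, Optional, Union

from .sites import Gene, ProbeRegion, VariantSite, resolve_site, sites_for

#: Per-site state codes. Sites not listed on a haplotype are REF. ABSENT
#: marks a site that the haplotype does not carry in interrogable form
#: (CYP2D7-derived or uncharacterized sequence in a hybrid): such a unit
#: contributes neither a reference nor a variant signal at that site.
REF = "ref"
VAR = "var"
ABSENT = "absent"
_STATES = {REF, VAR, ABSENT}


class StructuralKind(str, Enum):
    FULL_GENE = "full_gene"
    DELETION = "deletion"
    HYBRID_2D6_2D7 = "hybrid_2D6_2D7"  # CYP2D6-derived 5', CYP2D7-derived 3'
    HYBRID_2D7_2D6 = "hybrid_2D7_2D6"  # CYP2D7-derived 5', CYP2D6-derived 3'

    @property
    def is_hybrid(self) -> bool:
        return self in (StructuralKind.HYBRID_2D6_2D7, StructuralKind.HYBRID_2D7_2D6)


@dataclass(frozen=True)
class StructuralClass:
    """Structural character of one gene unit.

    ``switch_interval`` is the ordered pair of probe-region boundaries
    (lo, hi) within which a hybrid's sequence origin changes; it is present
    iff the kind is a hybrid. A hybrid contributes one copy exactly to the
    probe regions on its CYP2D6-derived side of the interval.
    """

    kind: StructuralKind
    switch_interval: Optional[tuple[ProbeRegion, ProbeRegion]] = None

    def __post_init__(self) -> None:
        if self.kind.is_hybrid:
            if self.switch_interval is None:
                raise ValueError(f"{self.kind.value} requires a switch_interval")
            lo, hi = self.switch_interval
            if lo.order >= hi.order:
                raise ValueError("switch_interval must be ordered 5'->3'")
        elif self.switch_interval is not None:
            raise ValueError("switch_interval is only meaningful for hybrids")

    def region_copies(self, region: ProbeRegion) -> int:
        """Copies this unit contributes to a CNV probe region (0 or 1)."""
        if self.kind is StructuralKind.DELETION:
            return 0
        if self.kind is StructuralKind.FULL_GENE:
            return 1
        lo, hi = self.switch_interval  # type: ignore[misc]
        if self.kind is StructuralKind.HYBRID_2D7_2D6:
            return 1 if region.order >= hi.order else 0
        return 1 if region.order <= lo.order else 0


FULL_GENE = StructuralClass(StructuralKind.FULL_GENE)
DELETION = StructuralClass(StructuralKind.DELETION)

#: Activity value for haplotypes whose functional effect is not established.
UNCERTAIN = "uncertain"


def core_star(star_name: str) -> str:
    """Core star group of a (sub-)allele name: *2.001 -> *2, *13[EU093102] -> *13."""
    name = star_name.split("[", 1)[0]
    return name.split(".", 1)[0]


@dataclass(frozen=True)
class HaplotypeDef:
    """One star allele (or sub-allele) of a pharmacogene."""

    star_name: str
    gene: Gene
    states: dict[str, str] = field(default_factory=dict)  # canonical site id -> VAR/ABSENT
    structural: StructuralClass = FULL_GENE
    tandem_partners: frozenset[str] = field(default_factory=frozenset)
    activity: Union[float, str] = UNCERTAIN

    def __post_init__(self) -> None:
        for site_id, state in self.states.items():
            if state not in (VAR, ABSENT):
                raise ValueError(
                    f"{self.star_name}: state for {site_id} must be "
                    f"{VAR!r} or {ABSENT!r} (ref is implicit), got {state!r}"
                )

    @property
    def core_star(self) -> str:
        return core_star(self.star_name)

    @property
    def suballele_depth(self) -> int:
        return len(self.star_name.split(".")) - 1 + ("[" in self.star_name)

    def state_at(self, site: Union[str, VariantSite]) -> str:
        site_id = site.canonical_id if isinstance(site, VariantSite) else site
        return self.states.get(site_id, REF)

    @property
    def numeric_activity(self) -> Optional[float]:
        return None if self.activity == UNCERTAIN else float(self.activity)


class TableError(ValueError):
    """Malformed haplotype-table input."""


_COLUMNS = ("star_name", "gene", "structural_kind", "switch_interval",
            "tandem_partners", "activity")


@dataclass
class HaplotypeTable:
    """Validated set of haplotype definitions for one gene."""

    gene: Gene
    entries: dict[str, HaplotypeDef]
    provenance: str = ""

    def __post_init__(self) -> None:
        ref = self.entries.get("*1")
        if ref is None or ref.states or ref.structural.kind is not StructuralKind.FULL_GENE:
            raise TableError("table must contain the reference haplotype *1 "
                             "with no variant states and a full gene structure")

    def __getitem__(self, star_name: str) -> HaplotypeDef:
        return self.entries[star_name]

    def __contains__(self, star_name: str) -> bool:
        return star_name in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def reference(self) -> HaplotypeDef:
        return self.entries["*1"]

    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.canonical_id for s in sites_for(self.gene))

    def resolve_star(self, name: str) -> HaplotypeDef:
        """Look up a star name, accepting the xN duplication suffix."""
        base = name.replace("×", "x")
        if base.endswith("xN"):
            base = base[:-2]
        if base in self.entries:
            return self.entries[base]
        if core_star(base) in self.entries:
            return self.entries[core_star(base)]
        raise KeyError(f"star allele {name!r} not in the {self.gene.value} table")

    def with_activities(self, overrides: dict[str, Union[float, str]]) -> "HaplotypeTable":
        """Return a copy with per-star activity overrides applied."""
        entries = {}
        for name, hap in self.entries.items():
            if name in overrides:
                hap = HaplotypeDef(hap.star_name, hap.gene, hap.states, hap.structural,
                                   hap.tandem_partners, overrides[name])
            entries[name] = hap
        return HaplotypeTable(self.gene, entries, self.provenance)


def _parse_switch(text: str) -> Optional[tuple[ProbeRegion, ProbeRegion]]:
    if not text:
        return None
    try:
        lo, hi = text.split("..")
        return (ProbeRegion(lo.strip()), ProbeRegion(hi.strip()))
    except ValueError as exc:
        raise TableError(f"bad switch_interval {text!r}; expected e.g. "
                         "'intron2..intron6'") from exc


def parse_haplotype_table(stream: Union[str, IO[str]], provenance: str = "") -> HaplotypeTable:
    """Parse a haplotype translation table from TSV text.

    Dialect: UTF-8 TSV with ``#`` comment lines; header columns
    ``star_name, gene, structural_kind, switch_interval, tandem_partners,
    activity`` followed by one column per panel site (canonical id or legacy
    alias). Site cells hold ``var``/``absent``; an empty cell means the
    reference state. Unknown site columns are rejected, not dropped.
    """
    if isinstance(stream, str):
        stream = _io.StringIO(stream)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise TableError("empty haplotype table")
    header = lines[0].split("\t")
    if tuple(header[: len(_COLUMNS)]) != _COLUMNS:
        raise TableError(f"header must start with columns {', '.join(_COLUMNS)}")
    site_labels = header[len(_COLUMNS):]

    entries: dict[str, HaplotypeDef] = {}
    gene: Optional[Gene] = None
    site_ids: list[str] = []
    for row_no, line in enumerate(lines[1:], start=2):
        cells = line.split("\t")
        cells += [""] * (len(header) - len(cells))
        star, gene_txt, kind_txt, switch_txt, partners_txt, activity_txt = (
            c.strip() for c in cells[: len(_COLUMNS)]
        )
        if gene is None:
            gene = Gene(gene_txt)
            # Validate site columns against this gene's registry once.
            for label in site_labels:
                site_ids.append(resolve_site(label, gene).canonical_id)
            if len(set(site_ids)) != len(site_ids):
                raise TableError("two site columns resolve to the same canonical site")
        elif Gene(gene_txt) is not gene:
            raise TableError(f"row {row_no} ({star}): mixed genes in one table")
        if star in entries:
            raise TableError(f"row {row_no}: duplicate star_name {star!r}")
        try:
            structural = StructuralClass(StructuralKind(kind_txt or "full_gene"),
                                         _parse_switch(switch_txt))
        except ValueError as exc:
            raise TableError(f"row {row_no} ({star}): {exc}") from exc
        partners = frozenset(p.strip() for p in partners_txt.split(",") if p.strip())
        activity: Union[float, str]
        if activity_txt in ("", UNCERTAIN):
            activity = UNCERTAIN
        else:
            activity = float(activity_txt)
            if activity < 0:
                raise TableError(f"row {row_no} ({star}): negative activity")
        states: dict[str, str] = {}
        for site_id, cell in zip(site_ids, cells[len(_COLUMNS):]):
            cell = cell.strip()
            if not cell or cell == REF:
                continue
            if cell not in _STATES:
                raise TableError(f"row {row_no} ({star}): unknown state code {cell!r} "
                                 f"for site {site_id}")
            states[site_id] = cell
        entries[star] = HaplotypeDef(star, gene, states, structural, partners, activity)
    assert gene is not None
    return HaplotypeTable(gene, entries, provenance)


def write_table(table: HaplotypeTable, stream: Optional[IO[str]] = None) -> str:
    """Serialize a table in the TSV dialect read by :func:`parse_haplotype_table`."""
    site_ids = table.site_ids()
    out = ["\t".join(_COLUMNS + site_ids)]
    for hap in table:
        switch = ""
        if hap.structural.switch_interval:
            lo, hi = hap.structural.switch_interval
            switch = f"{lo.value}..{hi.value}"
        activity = hap.activity if hap.activity == UNCERTAIN else repr(float(hap.activity))
        row = [hap.star_name, hap.gene.value, hap.structural.kind.value, switch,
               ",".join(sorted(hap.tandem_partners)), str(activity)]
        row += [hap.states.get(site_id, "") for site_id in site_ids]
        text_row = "\t".join(row)
        out.append(text_row)
    text = "\n".join(out) + "\n"
    if stream is not None:
        stream.write(text)
    return text


_BUILTIN_CACHE: dict[Gene, HaplotypeTable] = {}

_BUILTIN_FILES = {
    Gene.CYP2D6: "cyp2d6_haplotypes.tsv",
    Gene.CYP2C19: "cyp2c19_haplotypes.tsv",
}


def builtin_table(gene: Union[Gene, str]) -> HaplotypeTable:
    """The built-in, curated haplotype table for a gene."""
    gene = Gene(gene)
    if gene not in _BUILTIN_CACHE:
        text = resources.files("starcall.data").joinpath(_BUILTIN_FILES[gene]).read_text()
        _BUILTIN_CACHE[gene] = parse_haplotype_table(text, provenance=f"built-in {gene.value}")
    return _BUILTIN_CACHE[gene]


def iter_star_names(names: Iterable[str]) -> list[str]:
    return sorted(names)
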