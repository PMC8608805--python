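"""Panel variant sites for CYP2D6 and CYP2C19.

Star alleles of the CYP2D pharmacogenes are defined over a small panel of
single-nucleotide variants and short indels. Historically these sites are
named by their position on the M33388 reference sequence, and two off-by-one
dialects of that numbering circulate in the literature (e.g. the *2-defining
variant rs16947 appears as both "2850C>T" and "2851C>T"). Each site here has
one canonical id (the dbSNP rsID where one exists unambiguously, else a
normalized legacy label) plus the full set of legacy aliases, so that data
from any platform resolves to the same internal site.

CYP2D6 sites additionally carry a gene segment locating them relative to the
copy-number probe regions (intron 2, intron 6, exon 9); hybrid-gene logic
needs this to decide which probe regions a CYP2D7/2D6 fusion contributes to.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Gene(str, Enum):
    CYP2D6 = "CYP2D6"
    CYP2C19 = "CYP2C19"


class ProbeRegion(str, Enum):
    """CNV probe regions along CYP2D6, ordered 5' -> 3'."""

    FIVE_PRIME_FLANK = "five_prime_flank"
    INTRON2 = "intron2"
    INTRON6 = "intron6"
    EXON9 = "exon9"
    THREE_PRIME_FLANK = "three_prime_flank"

    @property
    def order(self) -> int:
        return _REGION_ORDER[self]


_REGION_ORDER = {
    ProbeRegion.FIVE_PRIME_FLANK: 0,
    ProbeRegion.INTRON2: 1,
    ProbeRegion.INTRON6: 2,
    ProbeRegion.EXON9: 3,
    ProbeRegion.THREE_PRIME_FLANK: 4,
}

#: Regions assayed by the standard TaqMan three-probe set.
TAQMAN_REGIONS = (ProbeRegion.INTRON2, ProbeRegion.INTRON6, ProbeRegion.EXON9)


class GeneSegment(str, Enum):
    """Segments of CYP2D6 bounded by the CNV probe positions, 5' -> 3'.

    A variant site in segment EXON1_INTRON2 lies between the 5'-flank probe
    and the intron-2 probe, and so on. Hybrid switch intervals are expressed
    in terms of the probe boundaries that flank a segment.
    """

    FIVE_PRIME_FLANK = "five_prime_flank"
    EXON1_INTRON2 = "exon1_intron2"
    INTRON2_INTRON6 = "intron2_intron6"
    INTRON6_EXON9 = "intron6_exon9"
    THREE_PRIME_FLANK = "three_prime_flank"

    @property
    def order(self) -> int:
        return _SEGMENT_ORDER[self]


_SEGMENT_ORDER = {
    GeneSegment.FIVE_PRIME_FLANK: 0,
    GeneSegment.EXON1_INTRON2: 1,
    GeneSegment.INTRON2_INTRON6: 2,
    GeneSegment.INTRON6_EXON9: 3,
    GeneSegment.THREE_PRIME_FLANK: 4,
}


@dataclass(frozen=True)
class VariantSite:
    """One panel site, identified by canonical id with legacy aliases."""

    canonical_id: str
    gene: Gene
    legacy_labels: frozenset[str] = field(default_factory=frozenset)
    #: M33388-style position, used only for 5'->3' ordering of sites.
    position: int = 0
    segment: Optional[GeneSegment] = None
    ref_state: str = "ref"
    var_state: str = "var"

    def __post_init__(self) -> None:
        if self.gene is Gene.CYP2D6 and self.segment is None:
            raise ValueError(
                f"CYP2D6 site {self.canonical_id} requires a gene segment "
                "(needed by hybrid logic)"
            )

    @property
    def labels(self) -> frozenset[str]:
        return self.legacy_labels | {self.canonical_id}


class UnknownSiteError(KeyError):
    """Raised when a label does not resolve to any registered site."""

    def __init__(self, label: str, suggestions: list[str]):
        self.label = label
        self.suggestions = suggestions
        hint = f"; did you mean {', '.join(suggestions)}?" if suggestions else ""
        super().__init__(f"unknown variant site label {label!r}{hint}")


def _d6(canonical: str, aliases: tuple[str, ...], pos: int, seg: GeneSegment) -> VariantSite:
    return VariantSite(canonical, Gene.CYP2D6, frozenset(aliases), pos, seg)


def _c19(canonical: str, aliases: tuple[str, ...], pos: int) -> VariantSite:
    return VariantSite(canonical, Gene.CYP2C19, frozenset(aliases), pos)


_SEG = GeneSegment

# CYP2D6 panel sites. Positions are M33388 legacy coordinates; where two
# off-by-one dialects exist both are aliases of the same site.
CYP2D6_SITES: tuple[VariantSite, ...] = (
    _d6("rs1080985", ("-1584C>G",), -1584, _SEG.FIVE_PRIME_FLANK),
    _d6("rs769258", ("31G>A",), 31, _SEG.EXON1_INTRON2),
    _d6("rs1065852", ("100C>T",), 100, _SEG.EXON1_INTRON2),
    _d6("rs5030867", ("124G>A",), 124, _SEG.EXON1_INTRON2),
    _d6("137_138insT", ("138insT",), 137, _SEG.EXON1_INTRON2),
    _d6("rs5030863", ("883G>C", "882G>C"), 883, _SEG.EXON1_INTRON2),
    _d6("rs28371706", ("1023C>T",), 1023, _SEG.EXON1_INTRON2),
    _d6("rs61736512", ("1659G>A", "1660G>A"), 1659, _SEG.INTRON2_INTRON6),
    _d6("rs5030655", ("1707delT", "1708delT"), 1707, _SEG.INTRON2_INTRON6),
    # 1758G>T (*8) and 1758G>A (*14) share one rsID; keep legacy labels
    # canonical so the two variant alleles stay distinct sites.
    _d6("1758G>T", ("1759G>T",), 1758, _SEG.INTRON2_INTRON6),
    _d6("1758G>A", ("1759G>A",), 1758, _SEG.INTRON2_INTRON6),
    _d6("rs3892097", ("1846G>A", "1847G>A"), 1846, _SEG.INTRON2_INTRON6),
    _d6("rs72549356", ("1863_1864ins(TTTCGCCCC)2",), 1863, _SEG.INTRON2_INTRON6),
    _d6("1863insTTTCGCCCC", (), 1864, _SEG.INTRON2_INTRON6),
    _d6("rs72549354", ("1973insG",), 1973, _SEG.INTRON2_INTRON6),
    _d6("rs72549353", ("2539_2542delAACT",), 2539, _SEG.INTRON2_INTRON6),
    _d6("rs35742686", ("2549delA", "2550delA"), 2549, _SEG.INTRON2_INTRON6),
    _d6("rs5030656", ("2613_2615delAGA",), 2613, _SEG.INTRON2_INTRON6),
    _d6("rs16947", ("2850C>T", "2851C>T"), 2850, _SEG.INTRON2_INTRON6),
    _d6("rs5030862", ("2935A>C", "2936A>C"), 2935, _SEG.INTRON2_INTRON6),
    _d6("rs28371725", ("2988G>A", "2989G>A"), 2988, _SEG.INTRON2_INTRON6),
    _d6("rs59421388", ("3183G>A", "3184G>A"), 3183, _SEG.INTRON6_EXON9),
    _d6("3198C>G", (), 3198, _SEG.INTRON6_EXON9),
    _d6("3277T>C", (), 3277, _SEG.INTRON6_EXON9),
    _d6("4042G>A", (), 4042, _SEG.INTRON6_EXON9),
    _d6("rs1135840", ("4180G>C", "4181G>C"), 4180, _SEG.INTRON6_EXON9),
)

# CYP2C19 panel sites (positions on the legacy CYP2C19 coding reference).
CYP2C19_SITES: tuple[VariantSite, ...] = (
    _c19("rs12248560", ("-806C>T",), -806),  # *17
    _c19("rs28399504", ("1A>G",), 1),  # *4
    _c19("rs12769205", ("12662A>G",), 99),  # on *2.002
    _c19("rs41291556", ("358T>C",), 358),  # *8
    _c19("rs72552267", ("395G>A",), 395),  # *6
    _c19("rs17884712", ("431G>A",), 431),  # *9
    _c19("rs4986893", ("636G>A",), 636),  # *3
    _c19("rs6413438", ("680C>T",), 680),  # *10
    _c19("rs4244285", ("681G>A",), 681),  # *2
    _c19("rs72558186", ("819+2T>A", "IVS5+2T>A"), 819),  # *7
    _c19("rs56337013", ("1297C>T",), 1297),  # *5
)

ALL_SITES: tuple[VariantSite, ...] = CYP2D6_SITES + CYP2C19_SITES

_REGISTRY: dict[tuple[Gene, str], VariantSite] = {}
for _site in ALL_SITES:
    for _label in _site.labels:
        key = (_site.gene, _label)
        if key in _REGISTRY:  # pragma: no cover - guarded by construction
            raise RuntimeError(f"duplicate site label {_label} for {_site.gene}")
        _REGISTRY[key] = _site


def sites_for(gene: Gene) -> tuple[VariantSite, ...]:
    """All registered sites for a gene, ordered 5' -> 3'."""
    return tuple(sorted((s for s in ALL_SITES if s.gene is gene), key=lambda s: s.position))


def resolve_site(label: str, gene: Gene | str) -> VariantSite:
    """Resolve a legacy position label or rsID to its canonical site.

    Dialect-variant labels ("2850C>T" vs "2851C>T") resolve to the same
    site. Unknown labels raise :class:`UnknownSiteError` listing the nearest
    known labels.
    """
    gene = Gene(gene)
    site = _REGISTRY.get((gene, label))
    if site is not None:
        return site
    known = [lab for (g, lab) in _REGISTRY if g is gene]
    suggestions = difflib.get_close_matches(label, known, n=3, cutoff=0.5)
    raise UnknownSiteError(label, suggestions)
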