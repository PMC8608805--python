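"""Built-in genotyping platform panels.

Each panel records which panel sites a platform interrogates, which star
alleles its translation content can distinguish, which CNV probe regions it
reads, and whether it can represent hybrids, the *5 whole-gene deletion and
xN duplications. Panels are immutable values; their coverage gaps are what
drive the collapse model (e.g. the AmpliChip cannot detect CYP2C19*17,
*6 or *8, nor CYP2D6 hybrids, and has a documented sensitivity problem for
the *5 deletion).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .haplotypes import builtin_table, core_star
from .sites import Gene, ProbeRegion, sites_for

#: Evidence tiers used for consensus tie-breaking.
TIER_SCREENING = 1      # single-platform screening arrays (AmpliChip)
TIER_MULTIPLEX = 2      # multiplex SNV + CNV platforms
TIER_SEQUENCING = 3     # Sanger / amplicon-level evidence


@dataclass(frozen=True)
class PlatformPanel:
    name: str
    gene: Gene
    sites_assayed: frozenset[str]
    haplotypes_distinguishable: frozenset[str]
    cnv_regions: tuple[ProbeRegion, ...] = ()
    detects_hybrids: bool = False
    detects_deletion: bool = True
    detects_duplication: bool = True
    evidence_tier: int = TIER_MULTIPLEX
    assay_metadata: Mapping[str, str] = field(default_factory=dict)

    def covers_star(self, star_name: str) -> bool:
        """True if the panel's translation content represents this star
        allele (exactly, or at core-star resolution)."""
        if star_name in self.haplotypes_distinguishable:
            return True
        core = core_star(star_name)
        return core in {core_star(h.replace("×", "x").removesuffix("xN"))
                        for h in self.haplotypes_distinguishable}

    def covers_xn(self, star_name: str) -> bool:
        """True if the panel reports xN duplications of this star allele."""
        if not self.detects_duplication:
            return False
        xn_entries = {h.replace("×", "x") for h in self.haplotypes_distinguishable
                      if h.replace("×", "x").endswith("xN")}
        if not xn_entries:
            return True  # duplication reported generically (CNV-based panels)
        return f"{core_star(star_name)}xN" in xn_entries


class UnknownPlatformError(KeyError):
    pass


def _ids(gene: Gene, *, exclude: tuple[str, ...] = ()) -> frozenset[str]:
    return frozenset(s.canonical_id for s in sites_for(gene)) - frozenset(exclude)


_R = ProbeRegion

# The 32 CYP2D6 variant haplotypes identified by the AmpliChip CYP450 test.
AMPLICHIP_CYP2D6_HAPLOTYPES = frozenset({
    "*2", "*3", "*4", "*5", "*6", "*7", "*8", "*9", "*10", "*11", "*14",
    "*15", "*17", "*19", "*20", "*25", "*26", "*29", "*30", "*31", "*35",
    "*36", "*40", "*41", "*114",
    "*1xN", "*2xN", "*4xN", "*10xN", "*17xN", "*35xN", "*41xN",
})

_LUMINEX_D6_HAPS = frozenset({
    # kit content: *2-*12 (incl. the *5 deletion), *14, *15, *17, *29, *35,
    # *41 and gene duplication ...
    "*2", "*3", "*4", "*5", "*6", "*7", "*8", "*9", "*10", "*11", "*12",
    "*14", "*15", "*17", "*29", "*35", "*41",
    # ... plus translator-derived haplotypes, sub-alleles, hybrids and
    # hybrid tandems.
    "*20", "*39.001", "*39.002", "*69", "*70", "*107", "*114", "*2.001",
    "*4.013", "*13", "*13[EU093102]", "*13[GQ162807]", "*36", "*57", "*61",
    "*63", "*68", "*83",
})

_AMPLISEQ_D6_HAPS = frozenset({
    "*2", "*2.001", "*3", "*4", "*4.013", "*5", "*6", "*7", "*8", "*9",
    "*10", "*11", "*12", "*13", "*13[EU093102]", "*13[GQ162807]", "*14",
    "*15", "*17", "*29", "*35", "*36", "*41", "*68", "*69", "*114",
})

_PSCAN_D6_HAPS = frozenset({
    "*2", "*2.001", "*3", "*4", "*5", "*6", "*7", "*8", "*9", "*10", "*11",
    "*12", "*14", "*15", "*17", "*19", "*20", "*25", "*26", "*29", "*30",
    "*31", "*35", "*39.001", "*39.002", "*40", "*41", "*69", "*70", "*114",
})

_TAQMAN_D6_SITES = frozenset({
    "rs16947",      # *2
    "rs35742686",   # *3
    "rs3892097",    # *4
    "rs5030655",    # *6
    "rs1065852",    # *10
    "rs769258",     # *35
    "rs28371725",   # *41
})

_TAQMAN_SNV_ASSAYS = {
    "rs16947": "C_27102425_10", "rs35742686": "C_32407232_50",
    "rs3892097": "C_27102431_D0", "rs5030655": "C_32407243_20",
    "rs769258": "C_27102444_F0", "rs28371725": "C_34816116_20",
    "rs1065852": "C__11484460_40", "rs4244285": "C__25986767_70",
}

_TAQMAN_CNV_ASSAYS = {
    "intron2": "Hs04083572_cn", "intron6": "Hs04502391_cn",
    "exon9": "Hs00010001_cn",
}


def _build_panels() -> dict[tuple[str, Gene], PlatformPanel]:
    d6, c19 = Gene.CYP2D6, Gene.CYP2C19
    panels = [
        PlatformPanel(
            "AmpliChip", d6,
            sites_assayed=_ids(d6, exclude=("rs1080985",)),
            haplotypes_distinguishable=AMPLICHIP_CYP2D6_HAPLOTYPES,
            cnv_regions=(),
            detects_hybrids=False,
            # Sensitivity problem for *5 detection; the deletion is in the
            # nominal content but unreliable, so the collapse model treats
            # it as undetected.
            detects_deletion=False,
            detects_duplication=True,
            evidence_tier=TIER_SCREENING,
        ),
        PlatformPanel(
            "AmpliChip", c19,
            sites_assayed=frozenset({"rs4244285", "rs4986893"}),
            haplotypes_distinguishable=frozenset({"*2", "*3"}),
            detects_duplication=False,
            evidence_tier=TIER_SCREENING,
        ),
        PlatformPanel(
            "LuminexXTAGv3", d6,
            sites_assayed=_ids(d6, exclude=(
                "rs72549353", "rs72549356", "1863insTTTCGCCCC",
                "3198C>G", "3277T>C", "4042G>A")),
            haplotypes_distinguishable=_LUMINEX_D6_HAPS,
            detects_hybrids=True,
            detects_deletion=True,
        ),
        PlatformPanel(
            "LuminexXTAGv3", c19,
            sites_assayed=_ids(c19),
            haplotypes_distinguishable=frozenset({
                "*2", "*2.002", "*3", "*4", "*5", "*6", "*7", "*8", "*9",
                "*10", "*17"}),
            detects_duplication=False,
        ),
        PlatformPanel(
            "TaqMan", d6,
            sites_assayed=_TAQMAN_D6_SITES,
            haplotypes_distinguishable=frozenset({
                "*2", "*3", "*4", "*5", "*6", "*10", "*35", "*41"}),
            cnv_regions=(_R.INTRON2, _R.INTRON6, _R.EXON9),
            detects_hybrids=True,
            assay_metadata={**_TAQMAN_SNV_ASSAYS, **_TAQMAN_CNV_ASSAYS},
        ),
        PlatformPanel(
            "TaqMan", c19,
            sites_assayed=frozenset({"rs4244285", "rs12248560"}),
            haplotypes_distinguishable=frozenset({"*2", "*17"}),
            detects_duplication=False,
            assay_metadata={"rs4244285": "C__25986767_70",
                            "rs12248560": "C_469857_10"},
        ),
        PlatformPanel(
            "AmpliSeq", d6,
            # 20 CYP2D6 variant sites
            sites_assayed=_ids(d6, exclude=(
                "rs72549353", "rs72549354", "rs72549356",
                "1863insTTTCGCCCC", "3198C>G", "3277T>C")),
            haplotypes_distinguishable=_AMPLISEQ_D6_HAPS,
            cnv_regions=(_R.INTRON2, _R.EXON9),  # gene-level + exon-9 CNV
            detects_hybrids=True,
        ),
        PlatformPanel(
            "AmpliSeq", c19,
            sites_assayed=_ids(c19),  # 11 CYP2C19 variant sites
            haplotypes_distinguishable=frozenset({
                "*2", "*2.002", "*3", "*4", "*5", "*6", "*7", "*8", "*9",
                "*10", "*17"}),
            detects_duplication=False,
        ),
        PlatformPanel(
            "PharmacoScan", d6,
            sites_assayed=_ids(d6),
            haplotypes_distinguishable=_PSCAN_D6_HAPS,
            cnv_regions=(_R.FIVE_PRIME_FLANK, _R.EXON9, _R.THREE_PRIME_FLANK),
            detects_hybrids=False,
        ),
        PlatformPanel(
            "PharmacoScan", c19,
            sites_assayed=_ids(c19),
            haplotypes_distinguishable=frozenset({
                "*2", "*2.002", "*3", "*4", "*5", "*6", "*7", "*8", "*9",
                "*10", "*17"}),
            detects_duplication=False,
        ),
        PlatformPanel(
            "Agena", c19,
            sites_assayed=frozenset({
                "rs4244285", "rs4986893", "rs28399504", "rs56337013",
                "rs72552267", "rs72558186", "rs41291556", "rs12248560"}),
            haplotypes_distinguishable=frozenset({
                "*2", "*3", "*4", "*5", "*6", "*7", "*8", "*17"}),
            detects_duplication=False,
        ),
    ]
    return {(p.name, p.gene): p for p in panels}


_PANELS = _build_panels()
PLATFORM_NAMES = tuple(sorted({name for name, _ in _PANELS}))


def panel_of(name: str, gene: Union[Gene, str, None] = None) -> PlatformPanel:
    """Return the built-in panel for a platform.

    ``gene`` defaults to CYP2D6 where the platform covers it, else to the
    platform's only gene (Agena is CYP2C19-only).
    """
    if gene is not None:
        gene = Gene(gene)
        panel = _PANELS.get((name, gene))
        if panel is None:
            _raise_unknown(name, gene)
        return panel
    for g in (Gene.CYP2D6, Gene.CYP2C19):
        panel = _PANELS.get((name, g))
        if panel is not None:
            return panel
    _raise_unknown(name, None)


def _raise_unknown(name: str, gene: Optional[Gene]) -> None:
    if name not in PLATFORM_NAMES:
        raise UnknownPlatformError(
            f"unknown platform {name!r}; supported: {', '.join(PLATFORM_NAMES)}")
    raise UnknownPlatformError(
        f"platform {name!r} has no {gene.value if gene else ''} panel")


def validate_panels() -> None:
    """Check that every distinguishable haplotype resolves in the built-in
    table for its gene (xN entries resolve via their core star)."""
    for (name, gene), panel in _PANELS.items():
        table = builtin_table(gene)
        for star in panel.haplotypes_distinguishable:
            table.resolve_star(star)  # raises KeyError if unresolvable
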