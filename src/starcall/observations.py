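"""Observation containers shared by the caller, simulator and readers.

Multiplex genotyping platforms report site genotypes as categories (WT /
HET / MUT), not phased alleles or dosages; CNV probes report integer copy
calls with a confidence; TaqMan SNV assays additionally expose raw
wild-type/variant signal pairs usable for allelic-ratio phasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Optional

from .cnv import CnvProbeVector
from .sites import Gene

if TYPE_CHECKING:  # pragma: no cover
    from .phasing import SignalPair


class Category(str, Enum):
    """Site genotype category as reported by a multiplex assay."""

    WT = "WT"
    HET = "HET"
    MUT = "MUT"
    NOCALL = "NOCALL"
    #: A failed/low-intensity well: treated as NOCALL but flagged distinctly.
    LOW_SIGNAL = "LOW_SIGNAL"

    @property
    def is_nocall(self) -> bool:
        return self in (Category.NOCALL, Category.LOW_SIGNAL)


_CATEGORY_ALIASES = {
    "WT": Category.WT, "HET": Category.HET, "MUT": Category.MUT,
    "NOCALL": Category.NOCALL, "NO CALL": Category.NOCALL,
    "NO_CALL": Category.NOCALL, "LOW SIGNAL": Category.LOW_SIGNAL,
    "LOW_SIGNAL": Category.LOW_SIGNAL,
}


def parse_category(text: str) -> Category:
    try:
        return _CATEGORY_ALIASES[text.strip().upper()]
    except KeyError:
        raise ValueError(f"unknown genotype category {text!r}; expected one of "
                         f"{sorted(set(_CATEGORY_ALIASES))}") from None


@dataclass(frozen=True)
class SiteGenotype:
    """Genotype category at one panel site (canonical id)."""

    site: str
    category: Category


@dataclass
class PlatformObservation:
    """Everything one platform reported for one sample."""

    platform: str
    gene: Gene
    snv: dict[str, Category] = field(default_factory=dict)
    cnv: Optional[CnvProbeVector] = None
    signals: dict[str, list["SignalPair"]] = field(default_factory=dict)

    def genotypes(self) -> list[SiteGenotype]:
        return [SiteGenotype(site, cat) for site, cat in self.snv.items()]


@dataclass
class ObservationSet:
    """Per-platform observations for one sample, plus structural side
    constraints established by follow-up work (e.g. ``deletion_present``
    from haplotype phasing against a deletion)."""

    sample_id: str
    gene: Gene
    platforms: dict[str, PlatformObservation] = field(default_factory=dict)
    structural_constraints: frozenset[str] = frozenset()

    def cnv_vectors(self) -> list[CnvProbeVector]:
        return [p.cnv for p in self.platforms.values() if p.cnv is not None]

    def all_genotypes(self) -> list[SiteGenotype]:
        out = []
        for p in self.platforms.values():
            out.extend(p.genotypes())
        return out

    @property
    def is_empty(self) -> bool:
        return all(not p.snv and p.cnv is None and not p.signals
                   for p in self.platforms.values())
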