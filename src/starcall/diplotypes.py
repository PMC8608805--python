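"""Chromosome configurations and diplotypes.

A chromosome configuration is an ordered list of gene units, each a
haplotype with a repeat count: this covers ordinary single genes, xN
duplications/multiplications (*1x2, *41x3), the whole-gene deletion (*5),
and hybrid tandems such as *13 + *2 or *36x2 + *10. A diplotype is an
unordered pair of chromosome configurations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Iterator

from .haplotypes import HaplotypeDef, HaplotypeTable, StructuralKind, core_star


@dataclass(frozen=True)
class ChromosomeConfig:
    """Ordered gene units on one chromosome: tuples of (haplotype, repeat >= 1)."""

    units: tuple[tuple[HaplotypeDef, int], ...]

    def __post_init__(self) -> None:
        if not self.units:
            raise ValueError("a chromosome configuration needs at least one unit")
        for hap, rep in self.units:
            if rep < 1:
                raise ValueError(f"repeat count must be >= 1, got {rep} for {hap.star_name}")
        n_del = sum(1 for hap, _ in self.units
                    if hap.structural.kind is StructuralKind.DELETION)
        if n_del and (n_del > 1 or len(self.units) > 1):
            raise ValueError("a deletion must be the only unit on its chromosome")

    @property
    def n_units(self) -> int:
        return sum(rep for _, rep in self.units)

    @property
    def is_deletion(self) -> bool:
        return self.units[0][0].structural.kind is StructuralKind.DELETION

    def iter_units(self) -> Iterator[HaplotypeDef]:
        """Expand repeats into individual gene units."""
        for hap, rep in self.units:
            for _ in range(rep):
                yield hap

    def format(self) -> str:
        return " + ".join(
            f"{hap.star_name}x{rep}" if rep > 1 else hap.star_name
            for hap, rep in self.units
        )

    def format_core(self) -> str:
        return " + ".join(
            f"{core_star(hap.star_name)}x{rep}" if rep > 1 else core_star(hap.star_name)
            for hap, rep in self.units
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of chromosome configurations (a/b equals b/a)."""

    chrom_a: ChromosomeConfig
    chrom_b: ChromosomeConfig

    @cached_property
    def chromosomes(self) -> tuple[ChromosomeConfig, ChromosomeConfig]:
        """The two configurations in canonical (sorted) order."""
        return tuple(sorted((self.chrom_a, self.chrom_b), key=ChromosomeConfig.format))

    @property
    def n_units(self) -> int:
        return self.chrom_a.n_units + self.chrom_b.n_units

    def iter_units(self) -> Iterator[HaplotypeDef]:
        yield from self.chrom_a.iter_units()
        yield from self.chrom_b.iter_units()

    def format(self) -> str:
        return "/".join(c.format() for c in self.chromosomes)

    def format_core(self) -> str:
        return "/".join(sorted(c.format_core() for c in self.chromosomes))

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.format()

    def __eq__(self, other) -> bool:
        if not isinstance(other, Diplotype):
            return NotImplemented
        return self.format() == other.format()

    def __hash__(self) -> int:
        return hash(self.format())

    @property
    def structural_event_count(self) -> int:
        """Departures from the two-full-gene baseline: hybrids, deletions,
        extra tandem copies, extra units in cis."""
        events = 0
        for chrom in (self.chrom_a, self.chrom_b):
            events += len(chrom.units) - 1
            for hap, rep in chrom.units:
                events += rep - 1
                if hap.structural.kind is StructuralKind.DELETION:
                    events += 1
                elif hap.structural.kind.is_hybrid:
                    events += 1
        return events

    @property
    def uses_novel_tandem(self) -> bool:
        """True when a hybrid sits in cis with a full gene outside its known
        tandem partner set."""
        for chrom in (self.chrom_a, self.chrom_b):
            if len(chrom.units) < 2:
                continue
            for (hap, _), (nxt, _) in zip(chrom.units, chrom.units[1:]):
                if hap.structural.kind.is_hybrid:
                    partners = {core_star(p) for p in hap.tandem_partners}
                    if core_star(nxt.star_name) not in partners and \
                            nxt.star_name not in hap.tandem_partners:
                        return True
        return False

    @property
    def suballele_depth(self) -> int:
        return sum(hap.suballele_depth for hap in self.iter_units())


_UNIT_RE = re.compile(r"^(?P<star>\*[^x]+?)(?:x(?P<rep>\d+))?$")


def parse_diplotype(text: str, table: HaplotypeTable) -> Diplotype:
    """Parse a diplotype string like ``*1/*2``, ``*41x3/*1`` or ``*13 + *4/*5``."""
    halves = text.split("/")
    if len(halves) != 2:
        raise ValueError(f"diplotype {text!r} must have exactly two chromosomes")
    chroms = []
    for half in halves:
        units = []
        for token in half.split("+"):
            token = token.strip().replace("×", "x")
            m = _UNIT_RE.match(token)
            if not m:
                raise ValueError(f"cannot parse gene unit {token!r} in {text!r}")
            star = m.group("star").strip()
            if star not in table:
                raise KeyError(f"star allele {star!r} not in the {table.gene.value} table")
            units.append((table[star], int(m.group("rep") or 1)))
        chroms.append(ChromosomeConfig(tuple(units)))
    return Diplotype(chroms[0], chroms[1])


def make_diplotype(table: HaplotypeTable, *chrom_specs: Iterable[str]) -> Diplotype:
    """Build a diplotype from two iterables of unit specs, e.g.
    ``make_diplotype(table, ["*13", "*4"], ["*5"])``."""
    if len(chrom_specs) != 2:
        raise ValueError("exactly two chromosome specs required")
    chroms = []
    for spec in chrom_specs:
        units = []
        for token in spec:
            m = _UNIT_RE.match(token.replace("×", "x"))
            if not m:
                raise ValueError(f"cannot parse gene unit {token!r}")
            units.append((table[m.group("star")], int(m.group("rep") or 1)))
        chroms.append(ChromosomeConfig(tuple(units)))
    return Diplotype(chroms[0], chroms[1])
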