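"""Haplotype phasing of duplications from allelic signal ratios, and
automated duplicate-run comparison.

For a sample with n > 2 gene copies that is heterozygous at a site, the
fraction of variant-probe signal is expected to sit near a lattice point
m/n, where m is the number of gene copies carrying the variant. Replicate
wild-type/variant signal pairs are reduced to var/(var+wt) fractions and
the nearest lattice point decides which haplotype carries the extra copies
(e.g. a fraction near 2/3 in a three-copy sample puts the duplication on
the variant haplotype; near 3/4 in a four-copy sample it indicates a
variant multiplication such as *41x3). Estimates not clearly attributable
to one lattice point — including the single-probe-amplifying case, where
copy configurations like C/C, CC/C, CC/- and C/- cannot be told apart —
come back as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .observations import Category, SiteGenotype

#: Absolute tolerance around a lattice point; estimates must also be closer
#: to the chosen point than half-way to any competing point.
DEFAULT_TOLERANCE = 0.12


@dataclass(frozen=True)
class SignalPair:
    """Raw wild-type/variant probe signals from one replicate well."""

    wt_signal: float
    var_signal: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.wt_signal < 0 or self.var_signal < 0:
            raise ValueError("signals must be non-negative")

    @property
    def failed(self) -> bool:
        return self.wt_signal == 0 and self.var_signal == 0

    @property
    def var_fraction(self) -> float:
        return self.var_signal / (self.var_signal + self.wt_signal)


class PhaseOutcome(str, Enum):
    DUP_ON_REF_HAPLOTYPE = "dup_on_ref_haplotype"
    DUP_ON_VAR_HAPLOTYPE = "dup_on_var_haplotype"
    AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class PhaseAssignment:
    outcome: PhaseOutcome
    estimated_var_fraction: float
    supporting_replicates: int
    #: Estimated number of gene copies carrying the variant (None when no
    #: lattice point is attributable).
    var_copies: Optional[int] = None
    flags: frozenset[str] = frozenset()


def phase_xn(site: str, pairs: Sequence[SignalPair], total_copies: int,
             tolerance: float = DEFAULT_TOLERANCE,
             control_fractions: Optional[dict[int, float]] = None
             ) -> PhaseAssignment:
    """Assign a duplication/multiplication to the reference or variant
    haplotype from replicate allelic signal ratios.

    ``control_fractions`` optionally re-centers the m/n lattice using
    measured fractions from samples of known copy configuration.
    """
    if total_copies < 3:
        raise ValueError("phasing applies to samples with at least 3 copies")
    live = [p for p in pairs if not p.failed]
    if not live:
        raise ValueError(f"all replicates failed for site {site}")
    est = sum(p.var_fraction for p in live) / len(live)

    lattice = {m: (control_fractions or {}).get(m, m / total_copies)
               for m in range(1, total_copies)}
    best_m = min(lattice, key=lambda m: (abs(est - lattice[m]), m))
    err = abs(est - lattice[best_m])
    competitors = [abs(est - f) for m, f in lattice.items() if m != best_m]
    half_gap = (min(abs(lattice[best_m] - f) for m, f in lattice.items()
                    if m != best_m) / 2) if competitors else float("inf")

    flags = set()
    if all(p.var_signal == 0 for p in live) or all(p.wt_signal == 0 for p in live):
        flags.add("single_probe_amplified")
    if err >= min(tolerance, half_gap) or "single_probe_amplified" in flags:
        return PhaseAssignment(PhaseOutcome.AMBIGUOUS, est, len(live),
                               None, frozenset(flags | {"off_lattice"}
                                               if err >= min(tolerance, half_gap)
                                               else flags))
    m = best_m
    ref_copies = total_copies - m
    if m >= 2 and ref_copies == 1:
        outcome = PhaseOutcome.DUP_ON_VAR_HAPLOTYPE
    elif ref_copies >= 2 and m == 1:
        outcome = PhaseOutcome.DUP_ON_REF_HAPLOTYPE
    else:
        # both haplotypes multiplied (e.g. 2+2 of 4): lattice point found
        # but the extra copy cannot be attributed to one haplotype.
        outcome = PhaseOutcome.AMBIGUOUS
        flags.add("both_haplotypes_duplicated")
    return PhaseAssignment(outcome, est, len(live), m, frozenset(flags))


class DuplicateVerdict(str, Enum):
    PASS = "pass"
    REPEAT_NEEDED = "repeat_needed"
    FAIL = "fail"


def compare_duplicates(run1: Sequence[SiteGenotype],
                       run2: Sequence[SiteGenotype]
                       ) -> dict[str, DuplicateVerdict]:
    """Automated comparison of duplicate genotyping runs, per site:
    identical informative categories pass, a one-sided no-call requests a
    repeat, contradictory categories fail."""
    g1 = {g.site: g.category for g in run1}
    g2 = {g.site: g.category for g in run2}
    if set(g1) != set(g2):
        missing = set(g1) ^ set(g2)
        raise ValueError(f"duplicate runs cover different sites: {sorted(missing)}")
    report = {}
    for site in g1:
        a, b = g1[site], g2[site]
        if a.is_nocall or b.is_nocall:
            report[site] = DuplicateVerdict.REPEAT_NEEDED
        elif a is b:
            report[site] = DuplicateVerdict.PASS
        else:
            report[site] = DuplicateVerdict.FAIL
    return report
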