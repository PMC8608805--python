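"""Copy-number probe model for CYP2D6 structural variation.

Forward direction: a diplotype's expected integer copy number at each CNV
probe region is the sum of per-unit contributions (a full gene contributes
one copy everywhere, the *5 deletion none, a CYP2D7/2D6 hybrid one copy
only on its CYP2D6-derived side of the switch interval). Equal calls across
regions therefore indicate a standard two-copy sample, a deletion carrier
(<2) or an xN carrier (>2); calls that rise 5'->3' indicate a CYP2D7-2D6
hybrid (e.g. 1,2,2 for a *13 tandem with a deletion in trans) and falling
calls a CYP2D6-2D7 hybrid, with the switch region bracketed by the step.

Inverse direction: :func:`classify_cnv` turns observed probe vectors from
one or more platforms into a structural hypothesis. Calls below the
confidence floor (0.95, matching clinical practice for quadruplicate
real-time PCR CNV calls) are flagged and excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence

from .diplotypes import Diplotype
from .sites import ProbeRegion, TAQMAN_REGIONS

#: Minimum per-region confidence for a call to be used unflagged.
MIN_CONFIDENCE = 0.95


@dataclass(frozen=True)
class CnvProbeVector:
    """Integer copy calls per probe region, with per-region confidence."""

    calls: dict[ProbeRegion, int]
    confidence: dict[ProbeRegion, float] = field(default_factory=dict)
    platform: str = ""

    def __post_init__(self) -> None:
        for region, call in self.calls.items():
            if call < 0:
                raise ValueError(f"negative copy call at {region.value}")

    def confidence_at(self, region: ProbeRegion) -> float:
        return self.confidence.get(region, 1.0)

    def confident_calls(self, floor: float = MIN_CONFIDENCE) -> dict[ProbeRegion, int]:
        """Calls meeting the confidence floor, in 5'->3' region order."""
        usable = {r: c for r, c in self.calls.items() if self.confidence_at(r) >= floor}
        return dict(sorted(usable.items(), key=lambda rc: rc[0].order))

    def flagged_regions(self, floor: float = MIN_CONFIDENCE) -> tuple[ProbeRegion, ...]:
        return tuple(r for r in self.calls if self.confidence_at(r) < floor)

    def ordered_calls(self) -> tuple[tuple[ProbeRegion, int], ...]:
        return tuple(sorted(self.calls.items(), key=lambda rc: rc[0].order))


class HypothesisKind(str, Enum):
    STANDARD_TWO_COPY = "standard_two_copy"
    DELETION_PRESENT = "deletion_present"
    XN_PRESENT = "xN_present"
    HYBRID_2D7_2D6_PRESENT = "hybrid_2D7_2D6_present"
    HYBRID_2D6_2D7_PRESENT = "hybrid_2D6_2D7_present"
    CONFLICT = "conflict"

    @property
    def is_hybrid(self) -> bool:
        return self in (HypothesisKind.HYBRID_2D7_2D6_PRESENT,
                        HypothesisKind.HYBRID_2D6_2D7_PRESENT)


class ExtraGene(str, Enum):
    NONE = "none"
    IN_CIS = "in_cis"
    IN_TRANS = "in_trans"
    UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class StructuralHypothesis:
    """Structural reading of one or more observed CNV probe vectors."""

    kind: HypothesisKind
    switch_interval: Optional[tuple[ProbeRegion, ProbeRegion]] = None
    extra_gene: ExtraGene = ExtraGene.NONE
    #: Inclusive bounds on the number of non-deleted gene units.
    total_units_bound: tuple[int, int] = (2, 2)
    #: The confident observed vectors the hypothesis is based on; candidate
    #: diplotypes are matched region-by-region against these.
    vectors: tuple[CnvProbeVector, ...] = ()
    #: On conflict, the per-platform hypotheses that disagreed.
    retained: tuple["StructuralHypothesis", ...] = ()
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind.is_hybrid and self.switch_interval is None:
            raise ValueError(f"{self.kind.value} requires a switch_interval")


def expected_cnv(diplotype: Diplotype,
                 regions: Sequence[ProbeRegion] = TAQMAN_REGIONS,
                 platform: str = "expected") -> CnvProbeVector:
    """Expected probe vector for a diplotype: per-region sum of unit copies."""
    calls = {
        region: sum(unit.structural.region_copies(region)
                    for unit in diplotype.iter_units())
        for region in regions
    }
    return CnvProbeVector(calls, {r: 1.0 for r in regions}, platform)


def matches_observed(diplotype: Diplotype, vectors: Iterable[CnvProbeVector],
                     floor: float = MIN_CONFIDENCE) -> bool:
    """True iff the diplotype's expected copies equal every confident
    observed call, region by region."""
    for vector in vectors:
        usable = vector.confident_calls(floor)
        if not usable:
            continue
        expected = expected_cnv(diplotype, tuple(usable))
        if any(expected.calls[r] != c for r, c in usable.items()):
            return False
    return True


def _classify_one(vector: CnvProbeVector,
                  floor: float) -> Optional[StructuralHypothesis]:
    usable = vector.confident_calls(floor)
    if len(usable) < 1:
        return None
    regions = list(usable)
    calls = [usable[r] for r in regions]
    flags = frozenset(f"low_confidence:{r.value}" for r in vector.flagged_regions(floor))
    if len(set(calls)) == 1:
        k = calls[0]
        if k == 2:
            kind = HypothesisKind.STANDARD_TWO_COPY
        elif k < 2:
            kind = HypothesisKind.DELETION_PRESENT
        else:
            kind = HypothesisKind.XN_PRESENT
        return StructuralHypothesis(kind, total_units_bound=(k, k + 1),
                                    vectors=(vector,), flags=flags)
    rising = all(a <= b for a, b in zip(calls, calls[1:]))
    falling = all(a >= b for a, b in zip(calls, calls[1:]))
    if rising or falling:
        if rising:
            kind = HypothesisKind.HYBRID_2D7_2D6_PRESENT
            step = next(i for i in range(len(calls) - 1) if calls[i] < calls[i + 1])
        else:
            kind = HypothesisKind.HYBRID_2D6_2D7_PRESENT
            step = next(i for i in range(len(calls) - 1) if calls[i] > calls[i + 1])
        switch = (regions[step], regions[step + 1])
        top = max(calls)
        extra = ExtraGene.UNDETERMINED if top > 2 else ExtraGene.NONE
        return StructuralHypothesis(kind, switch, extra,
                                    total_units_bound=(top, top + 1),
                                    vectors=(vector,), flags=flags)
    # Non-monotone single-platform pattern: no single hybrid explains it.
    return StructuralHypothesis(HypothesisKind.CONFLICT,
                                total_units_bound=(max(calls), max(calls) + 1),
                                vectors=(vector,),
                                flags=flags | {"non_monotone_vector"})


def _merge_switch(a: Optional[tuple[ProbeRegion, ProbeRegion]],
                  b: Optional[tuple[ProbeRegion, ProbeRegion]]
                  ) -> Optional[tuple[ProbeRegion, ProbeRegion]]:
    if a is None:
        return b
    if b is None:
        return a
    lo = max(a[0], b[0], key=lambda r: r.order)
    hi = min(a[1], b[1], key=lambda r: r.order)
    return (lo, hi) if lo.order < hi.order else None


def classify_cnv(vectors: Sequence[CnvProbeVector],
                 floor: float = MIN_CONFIDENCE) -> StructuralHypothesis:
    """Classify observed CNV probe vectors into a structural hypothesis.

    Cross-platform contradictions are not voted away: the result has kind
    ``conflict`` and retains each platform's own hypothesis, so the clinical
    workflow can route the sample to confirmation instead of guessing.
    """
    if not vectors:
        raise ValueError("classify_cnv needs at least one probe vector")
    singles = [h for h in (_classify_one(v, floor) for v in vectors) if h is not None]
    if not singles:
        raise ValueError("no probe call meets the confidence floor "
                         f"({floor:.0%}); repeat the assay")
    merged = singles[0]
    for nxt in singles[1:]:
        if nxt.kind is merged.kind:
            switch = _merge_switch(merged.switch_interval, nxt.switch_interval)
            if merged.kind.is_hybrid and switch is None:
                return _conflict(singles)
            lo = max(merged.total_units_bound[0], nxt.total_units_bound[0])
            hi = max(merged.total_units_bound[1], nxt.total_units_bound[1])
            merged = StructuralHypothesis(
                merged.kind, switch,
                merged.extra_gene if merged.extra_gene is not ExtraGene.NONE
                else nxt.extra_gene,
                (lo, hi), merged.vectors + nxt.vectors,
                flags=merged.flags | nxt.flags)
        else:
            return _conflict(singles)
    return merged


def _conflict(singles: list[StructuralHypothesis]) -> StructuralHypothesis:
    vectors = tuple(v for h in singles for v in h.vectors)
    flags = frozenset().union(*(h.flags for h in singles)) | {"cross_platform_conflict"} \
        if any(h.flags for h in singles) else frozenset({"cross_platform_conflict"})
    return StructuralHypothesis(HypothesisKind.CONFLICT, vectors=vectors,
                                retained=tuple(singles), flags=flags)
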