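"""Diplotype calling from site genotype categories and CNV evidence.

Multiplex platforms report unphased genotype *categories* per site, so a
call is a constraint-satisfaction problem: enumerate every diplotype (over
the translation table, up to a unit budget) whose presence semantics match
the observed categories and whose expected CNV probe vector matches the
observed copy calls, then rank candidates by structural parsimony. HET
means both alleles are present somewhere among the gene units, MUT that
every unit carries the variant, WT that every unit carries the reference;
deletion units and CYP2D7-derived (absent) sequence contribute no signal,
which is what makes a *X/*5 sample read as hemizygous WT or MUT and lets a
*13 hybrid hide behind a seemingly homozygous *4 call.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

from .cnv import StructuralHypothesis, matches_observed
from .diplotypes import ChromosomeConfig, Diplotype
from .haplotypes import (
    REF, VAR, ABSENT, HaplotypeDef, HaplotypeTable, StructuralKind, builtin_table,
)
from .observations import Category, SiteGenotype
from .panels import PlatformPanel
from .sites import Gene, resolve_site

DEFAULT_MAX_UNITS = 4


class Phenotype(str, Enum):
    PM = "PM"    # poor metabolizer
    IM = "IM"    # intermediate metabolizer
    NM = "NM"    # normal metabolizer
    UM = "UM"    # ultrarapid metabolizer
    INDETERMINATE = "indeterminate"


@dataclass(frozen=True)
class ActivityResult:
    score: Optional[float]
    phenotype: Phenotype


#: Activity-score cut points mapping a diplotype score to a metabolizer
#: phenotype. CYP2D6 follows the CPIC convention (0 poor; below 1.25
#: intermediate; 1.25-2.25 normal; above 2.25 ultrarapid). CYP2C19 has no
#: published activity-score system; the surrogate mirrors the standard
#: allele-function translation (two functional copies normal, one
#: loss-of-function intermediate, two poor, *17 gain above normal).
CUTPOINTS = {
    Gene.CYP2D6: ((0.0, Phenotype.PM), (1.0, Phenotype.IM),
                  (2.25, Phenotype.NM), (float("inf"), Phenotype.UM)),
    Gene.CYP2C19: ((0.0, Phenotype.PM), (1.75, Phenotype.IM),
                   (2.0, Phenotype.NM), (float("inf"), Phenotype.UM)),
}


@dataclass(frozen=True)
class CandidateCall:
    """One candidate diplotype with its deterministic rank key."""

    diplotype: Diplotype
    flags: frozenset[str] = frozenset()

    @property
    def rank_key(self) -> tuple:
        d = self.diplotype
        return (d.structural_event_count, int(d.uses_novel_tandem),
                d.suballele_depth, d.format())


def _unit_signals(diplotype: Diplotype, site_id: str) -> tuple[bool, bool, bool]:
    """(has_ref, has_var, has_absent) over the non-deleted gene units."""
    has_ref = has_var = has_absent = False
    for unit in diplotype.iter_units():
        if unit.structural.kind is StructuralKind.DELETION:
            continue
        state = unit.state_at(site_id)
        if state == VAR:
            has_var = True
        elif state == ABSENT:
            has_absent = True
        else:
            has_ref = True
    return has_ref, has_var, has_absent


def consistent(diplotype: Diplotype, genotypes: Sequence[SiteGenotype],
               panel: Optional[PlatformPanel] = None,
               gene: Optional[Gene] = None) -> bool:
    """True iff the diplotype's allele content can produce every observed
    non-NOCALL category under presence semantics."""
    gene = gene or (panel.gene if panel else next(diplotype.iter_units()).gene)
    for g in genotypes:
        site = resolve_site(g.site, gene)
        if panel is not None and site.canonical_id not in panel.sites_assayed:
            raise ValueError(f"site {g.site} is not assayed by the "
                             f"{panel.name} {gene.value} panel")
        if g.category.is_nocall:
            continue
        has_ref, has_var, _ = _unit_signals(diplotype, site.canonical_id)
        if g.category is Category.HET and not (has_ref and has_var):
            return False
        if g.category is Category.MUT and not (has_var and not has_ref):
            return False
        if g.category is Category.WT and not (has_ref and not has_var):
            return False
    return True


def chromosome_universe(table: HaplotypeTable, max_units: int,
                        haps: Optional[Iterable[HaplotypeDef]] = None
                        ) -> list[ChromosomeConfig]:
    """All chromosome configurations with up to ``max_units`` gene units:
    singles, the deletion, xN repeats of full genes, and hybrid+full-gene
    tandems (with repeats on either member)."""
    haps = list(haps if haps is not None else table)
    configs: list[ChromosomeConfig] = []
    fulls = [h for h in haps if h.structural.kind is StructuralKind.FULL_GENE]
    hybrids = [h for h in haps if h.structural.kind.is_hybrid]
    deletions = [h for h in haps if h.structural.kind is StructuralKind.DELETION]
    for h in deletions:
        configs.append(ChromosomeConfig(((h, 1),)))
    for h in fulls + hybrids:
        configs.append(ChromosomeConfig(((h, 1),)))
    for h in fulls:
        for rep in range(2, max_units + 1):
            configs.append(ChromosomeConfig(((h, rep),)))
    for hy in hybrids:
        for fu in fulls:
            for rep_h in range(1, max_units):
                for rep_f in range(1, max_units + 1 - rep_h):
                    if rep_h + rep_f < 2 or rep_h + rep_f > max_units:
                        continue
                    configs.append(ChromosomeConfig(((hy, rep_h), (fu, rep_f))))
    return configs


def _prefilter(table: HaplotypeTable, genotypes: Sequence[SiteGenotype],
               gene: Gene) -> list[HaplotypeDef]:
    """Drop haplotypes that can never appear in a consistent diplotype:
    any unit with the reference state at a MUT site, or the variant state
    at a WT site, is excluded outright (absent states constrain nothing)."""
    excluded_if = []
    for g in genotypes:
        if g.category in (Category.MUT, Category.WT):
            site_id = resolve_site(g.site, gene).canonical_id
            bad = REF if g.category is Category.MUT else VAR
            excluded_if.append((site_id, bad))
    out = []
    for hap in table:
        if hap.structural.kind is StructuralKind.DELETION:
            out.append(hap)
            continue
        if any(hap.state_at(site_id) == bad for site_id, bad in excluded_if):
            continue
        out.append(hap)
    return out


def enumerate_diplotypes(genotypes: Sequence[SiteGenotype],
                         cnv_hypothesis: Optional[StructuralHypothesis] = None,
                         table: Optional[HaplotypeTable] = None,
                         panel: Optional[PlatformPanel] = None,
                         max_units: int = DEFAULT_MAX_UNITS,
                         gene: Union[Gene, str] = Gene.CYP2D6
                         ) -> list[CandidateCall]:
    """All diplotypes (up to ``max_units`` gene units) consistent with the
    observed genotype categories and CNV evidence, ranked by parsimony:
    fewest structural events, known tandem arrangements before novel ones,
    core alleles before sub-alleles, then name order. An empty list is a
    valid "no call" outcome.
    """
    if max_units < 2:
        raise ValueError("max_units must be at least 2")
    gene = Gene(gene)
    if table is None:
        table = builtin_table(gene)
    if panel is not None:
        for g in genotypes:
            if resolve_site(g.site, gene).canonical_id not in panel.sites_assayed:
                raise ValueError(f"site {g.site} is not assayed by the "
                                 f"{panel.name} {gene.value} panel")
    haps = _prefilter(table, genotypes, gene)
    configs = chromosome_universe(table, max_units - 1, haps)
    vectors = cnv_hypothesis.vectors if cnv_hypothesis is not None else ()

    flags = frozenset(
        {f"nocall:{g.site}" for g in genotypes if g.category is Category.NOCALL}
        | {f"low_signal:{g.site}" for g in genotypes
           if g.category is Category.LOW_SIGNAL}
        | (cnv_hypothesis.flags if cnv_hypothesis is not None else frozenset())
    )
    seen: set[str] = set()
    out: list[CandidateCall] = []
    for ca, cb in itertools.combinations_with_replacement(configs, 2):
        if ca.n_units + cb.n_units > max_units:
            continue
        dip = Diplotype(ca, cb)
        key = dip.format()
        if key in seen:
            continue
        seen.add(key)
        if vectors and not matches_observed(dip, vectors):
            continue
        if not consistent(dip, genotypes, panel=None, gene=gene):
            continue
        out.append(CandidateCall(dip, flags))
    out.sort(key=lambda c: c.rank_key)
    return out


class MixedAmpliconError(ValueError):
    """An amplicon expected to be single-haplotype shows heterozygous calls;
    use detect_mixed_amplicon to localize the co-amplification boundary."""


def match_amplicon(hemizygous_calls: Sequence[SiteGenotype],
                   table: Optional[HaplotypeTable] = None,
                   gene: Union[Gene, str] = Gene.CYP2D6) -> list[str]:
    """Match a single-haplotype (hemizygous) amplicon genotype vector to
    star alleles, most specific first.

    A long-range PCR amplicon interrogates one haplotype, so every call
    must be WT or MUT; NOCALL/LOW_SIGNAL cells are wildcards, and a
    haplotype whose sequence is absent at a site (CYP2D7-derived region)
    can only produce a NOCALL/low-signal cell there.
    """
    gene = Gene(gene)
    if table is None:
        table = builtin_table(gene)
    het = [g.site for g in hemizygous_calls if g.category is Category.HET]
    if het:
        raise MixedAmpliconError(
            f"heterozygous calls at {', '.join(het)}: amplicon contains more "
            "than one template; run detect_mixed_amplicon")
    calls = {resolve_site(g.site, gene).canonical_id: g.category
             for g in hemizygous_calls}
    matches: list[tuple[tuple, str]] = []
    for hap in table:
        if hap.structural.kind is StructuralKind.DELETION:
            continue
        ok = True
        n_var = n_absent = 0
        for site_id, cat in calls.items():
            state = hap.state_at(site_id)
            if cat.is_nocall:
                n_absent += state == ABSENT
                continue
            if state == ABSENT:
                ok = False
                break
            if (cat is Category.MUT) != (state == VAR):
                ok = False
                break
            n_var += state == VAR
        if ok:
            # Most specific first: most variant sites explained, then the
            # fewest wildcarded absences, then stable name order.
            matches.append(((-n_var, -n_absent, hap.suballele_depth,
                             hap.star_name), hap.star_name))
    matches.sort()
    return [name for _, name in matches]


@dataclass(frozen=True)
class MixedAmpliconBoundary:
    """Interval after which heterozygous calls begin on an amplicon,
    bounded by the last clean (WT/MUT) site upstream, if any."""

    last_clean_site: Optional[str]
    first_het_site: str


def detect_mixed_amplicon(ordered_calls: Sequence[SiteGenotype],
                          gene: Union[Gene, str] = Gene.CYP2D6
                          ) -> Optional[MixedAmpliconBoundary]:
    """Scan 5'->3' for the point where an amplicon stops looking
    single-template: WT/MUT-only upstream, HET-containing downstream.
    Returns None when no HET call is present."""
    gene = Gene(gene)
    calls = sorted(ordered_calls, key=lambda g: resolve_site(g.site, gene).position)
    last_clean: Optional[str] = None
    for g in calls:
        if g.category is Category.HET:
            return MixedAmpliconBoundary(last_clean, g.site)
        if not g.category.is_nocall:
            last_clean = g.site
    return None


def activity_score(diplotype: Diplotype,
                   score_table: Optional[dict[str, float]] = None,
                   gene: Optional[Gene] = None,
                   cutpoints=None) -> ActivityResult:
    """Sum of per-unit activity values times repeat counts, mapped to a
    metabolizer phenotype through gene-specific cut points. Any unit of
    uncertain activity makes the result indeterminate."""
    units = list(diplotype.iter_units())
    gene = gene or units[0].gene
    total = 0.0
    for unit in units:
        value = (score_table or {}).get(unit.star_name, unit.numeric_activity)
        if value is None:
            return ActivityResult(None, Phenotype.INDETERMINATE)
        total += float(value)
    cuts = cutpoints or CUTPOINTS[gene]
    for upper, pheno in cuts:
        if total <= upper:
            return ActivityResult(total, pheno)
    return ActivityResult(total, cuts[-1][1])  # pragma: no cover
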