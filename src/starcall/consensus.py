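"""Cross-platform consensus calling, concordance tables and revision
reporting.

Different platforms see different slices of a sample: a hybrid-blind array
reports *13 + *4/*5 as *4/*4, a panel without *17 content reports *1/*17 as
*1/*1. Consensus derivation therefore asks for the diplotype that is
consistent with every platform's call *after* applying that platform's own
limitations (the collapse model), together with all raw SNV/CNV/phasing
observations — no majority voting. Concordance is tabulated the way
clinical cross-validation studies print it: percent of platform calls equal
to the consensus genotype, with no-calls counted in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .caller import CandidateCall, activity_score, enumerate_diplotypes
from .cnv import classify_cnv
from .diplotypes import ChromosomeConfig, Diplotype
from .haplotypes import HaplotypeTable, StructuralKind, builtin_table, core_star
from .observations import Category, ObservationSet, SiteGenotype
from .panels import PlatformPanel, panel_of
from .sites import Gene

#: Structural side-constraint tokens accepted in
#: ObservationSet.structural_constraints.
DELETION_PRESENT = "deletion_present"
DUPLICATION_PRESENT = "duplication_present"
HYBRID_PRESENT = "hybrid_present"


@dataclass(frozen=True)
class PlatformCall:
    """One platform's reported diplotype (or no-call) for a sample."""

    sample_id: str
    platform: str
    gene: Gene
    diplotype: Optional[Diplotype] = None
    #: Alternative calls as diplotype strings; "UNK" is a wildcard
    #: chromosome (e.g. "*4/UNK").
    alternatives: tuple[str, ...] = ()
    evidence_tier: Optional[int] = None

    @property
    def is_nocall(self) -> bool:
        return self.diplotype is None

    def tier(self) -> int:
        if self.evidence_tier is not None:
            return self.evidence_tier
        return panel_of(self.platform, self.gene).evidence_tier


@dataclass(frozen=True)
class CollapsedCall:
    """A diplotype as a limited panel would report it."""

    diplotype: Optional[Diplotype]
    unrepresentable: bool = False
    flags: frozenset[str] = frozenset()


def collapse_call(diplotype: Diplotype, panel: PlatformPanel,
                  table: Optional[HaplotypeTable] = None) -> CollapsedCall:
    """Project a diplotype through a panel's coverage limitations.

    Haplotypes outside the panel's translation content map to a covered
    ancestor sub-allele when one exists, else to the reference *1;
    structurally undetectable features are dropped: hybrids vanish from a
    hybrid-blind panel, and a deletion on a deletion-blind panel leaves the
    remaining allele looking homozygous. Idempotent by construction.
    """
    table = table or builtin_table(panel.gene)
    flags: set[str] = set()
    unrepresentable = False
    new_chroms: list[Optional[ChromosomeConfig]] = []
    for chrom in diplotype.chromosomes:
        units = []
        for hap, rep in chrom.units:
            kind = hap.structural.kind
            if kind is StructuralKind.DELETION:
                if panel.detects_deletion:
                    units.append((hap, 1))
                else:
                    flags.add("deletion_masked")
                    unrepresentable = True
                continue
            if kind.is_hybrid and not panel.detects_hybrids:
                flags.add(f"hybrid_dropped:{hap.star_name}")
                unrepresentable = True
                continue
            if hap.star_name in panel.haplotypes_distinguishable:
                mapped = hap
            elif core_star(hap.star_name) in panel.haplotypes_distinguishable:
                mapped = table[core_star(hap.star_name)]
                flags.add(f"suballele_collapsed:{hap.star_name}")
            else:
                mapped = table.reference
                flags.add(f"substituted:{hap.star_name}")
            if rep > 1 and not panel.covers_xn(mapped.star_name):
                flags.add(f"xn_collapsed:{mapped.star_name}")
                rep = 1
            units.append((mapped, rep))
        new_chroms.append(ChromosomeConfig(tuple(units)) if units else None)

    a, b = new_chroms
    if a is None and b is None:
        return CollapsedCall(None, True, frozenset(flags | {"unrepresentable"}))
    if a is None:
        a = b  # the surviving allele appears homozygous
    if b is None:
        b = a
    return CollapsedCall(Diplotype(a, b), unrepresentable, frozenset(flags))


def _chrom_core(chrom: ChromosomeConfig) -> str:
    return chrom.format_core()


def _match_pattern(diplotype: Diplotype, pattern: str) -> bool:
    """Match a diplotype against a call string at core-star resolution;
    'UNK' matches any chromosome."""
    halves = [h.strip() for h in pattern.replace("×", "x").split("/")]
    if len(halves) != 2:
        return False
    cand = [_chrom_core(c) for c in diplotype.chromosomes]

    def norm(text: str) -> str:
        units = [u.strip() for u in text.split("+")]
        return " + ".join(
            f"{core_star(u.split('x')[0])}x{u.split('x')[1]}" if "x" in u
            else core_star(u)
            for u in units)

    for p1, p2 in (halves, halves[::-1]):
        ok1 = p1 == "UNK" or norm(p1) == cand[0]
        ok2 = p2 == "UNK" or norm(p2) == cand[1]
        if ok1 and ok2:
            return True
    return False


def _compatible(candidate: Diplotype, call: PlatformCall,
                table: HaplotypeTable) -> bool:
    panel = panel_of(call.platform, call.gene)
    collapsed = collapse_call(candidate, panel, table)
    if collapsed.diplotype is None:
        return call.is_nocall
    if call.diplotype is not None:
        if collapsed.diplotype.format_core() == call.diplotype.format_core():
            return True
        return any(_match_pattern(collapsed.diplotype, alt)
                   for alt in call.alternatives)
    if call.alternatives:
        return any(_match_pattern(collapsed.diplotype, alt)
                   for alt in call.alternatives)
    return True  # plain no-call constrains nothing


@dataclass
class ConsensusResult:
    sample_id: str
    consensus: Optional[Diplotype]
    candidates: tuple[CandidateCall, ...]
    contributing_platforms: tuple[str, ...]
    discordant_platforms: tuple[str, ...]
    rationale: tuple[str, ...]

    @property
    def resolved(self) -> bool:
        return self.consensus is not None


def _merge_genotypes(observations: ObservationSet) -> list[SiteGenotype]:
    """Highest-tier informative category per site; same-tier disagreement
    drops the site (it constrains nothing and is flagged in the trail)."""
    by_site: dict[str, list[tuple[int, Category]]] = {}
    for name, plat in observations.platforms.items():
        tier = panel_of(name, observations.gene).evidence_tier
        for site, cat in plat.snv.items():
            by_site.setdefault(site, []).append((tier, cat))
    merged = []
    for site, entries in sorted(by_site.items()):
        informative = [(t, c) for t, c in entries if not c.is_nocall]
        if not informative:
            merged.append(SiteGenotype(site, Category.NOCALL))
            continue
        top = max(t for t, _ in informative)
        cats = {c for t, c in informative if t == top}
        if len(cats) == 1:
            merged.append(SiteGenotype(site, cats.pop()))
        # else: discordant at equal tier -> unconstrained
    return merged


def _satisfies_constraints(d: Diplotype, constraints: frozenset[str]) -> bool:
    kinds = [u.structural.kind for u in d.iter_units()]
    if DELETION_PRESENT in constraints and StructuralKind.DELETION not in kinds:
        return False
    if HYBRID_PRESENT in constraints and not any(k.is_hybrid for k in kinds):
        return False
    if DUPLICATION_PRESENT in constraints and d.n_units <= 2:
        return False
    return True


def derive_consensus(calls: Sequence[PlatformCall],
                     observations: ObservationSet,
                     table: Optional[HaplotypeTable] = None,
                     max_units: int = 4) -> ConsensusResult:
    """Derive the consensus diplotype: the unique candidate consistent with
    all raw observations and with every platform's call after collapse
    through that platform's panel; ties break toward the highest evidence
    tier, else the sample is flagged unresolved with the surviving set."""
    gene = observations.gene
    table = table or builtin_table(gene)
    rationale: list[str] = []

    genotypes = _merge_genotypes(observations)
    vectors = observations.cnv_vectors()
    hypothesis = classify_cnv(vectors) if vectors else None
    if hypothesis is not None:
        rationale.append(f"CNV hypothesis: {hypothesis.kind.value}")

    candidates = enumerate_diplotypes(genotypes, hypothesis, table,
                                      max_units=max_units, gene=gene)
    rationale.append(f"{len(candidates)} candidates from raw observations")

    if observations.structural_constraints:
        candidates = [c for c in candidates
                      if _satisfies_constraints(c.diplotype,
                                                observations.structural_constraints)]
        rationale.append(
            f"{len(candidates)} after constraints "
            f"{sorted(observations.structural_constraints)}")

    for call in sorted(calls, key=lambda c: -c.tier()):
        kept = [c for c in candidates if _compatible(c.diplotype, call, table)]
        rationale.append(
            f"{len(kept)} compatible with {call.platform} "
            f"({call.diplotype.format() if call.diplotype else 'no call'})")
        candidates = kept

    consensus: Optional[Diplotype] = None
    if len(candidates) == 1:
        consensus = candidates[0].diplotype
    elif len(candidates) > 1:
        # strictly best-ranked candidate, then highest-tier exact call
        best = candidates[0]
        if best.rank_key < candidates[1].rank_key:
            consensus = best.diplotype
            rationale.append("unique best-ranked candidate")
        else:
            top_calls = sorted((c for c in calls if not c.is_nocall),
                               key=lambda c: -c.tier())
            for call in top_calls:
                exact = [c for c in candidates
                         if c.diplotype.format_core()
                         == call.diplotype.format_core()]
                if len(exact) == 1:
                    consensus = exact[0].diplotype
                    rationale.append(f"tie broken by {call.platform} "
                                     f"(tier {call.tier()})")
                    break

    contributing, discordant = [], []
    for call in calls:
        if consensus is not None and _compatible(consensus, call, table):
            contributing.append(call.platform)
        else:
            discordant.append(call.platform)
    if consensus is None:
        rationale.append("unresolved: no unique consistent diplotype")
    return ConsensusResult(observations.sample_id, consensus,
                           tuple(candidates), tuple(contributing),
                           tuple(discordant), tuple(rationale))


@dataclass(frozen=True)
class ConcordanceCell:
    concordant: int
    assayed: int

    @property
    def percent(self) -> float:
        return 100.0 * self.concordant / self.assayed if self.assayed else float("nan")

    def format(self, group_n: Optional[int] = None) -> str:
        """Render as printed in cross-validation tables: plain '100' when
        everything assayed agreed, else 'P (c/n)' with one decimal."""
        if self.assayed == 0:
            return "NA"
        if self.concordant == self.assayed and (group_n is None
                                                or self.assayed == group_n):
            return "100"
        pct = self.percent
        text = f"{pct:.1f}".rstrip("0").rstrip(".")
        return f"{text} ({self.concordant}/{self.assayed})"


@dataclass
class ConcordanceTable:
    """Rows keyed by consensus genotype group; cells per platform."""

    rows: dict[str, dict[str, ConcordanceCell]]
    group_n: dict[str, int]
    platforms: tuple[str, ...]

    def overall(self, platform: str) -> ConcordanceCell:
        c = sum(r[platform].concordant for r in self.rows.values() if platform in r)
        n = sum(r[platform].assayed for r in self.rows.values() if platform in r)
        return ConcordanceCell(c, n)


def concordance_table(calls: Sequence[PlatformCall],
                      consensus_list: Sequence[ConsensusResult],
                      group_by: str = "core") -> ConcordanceTable:
    """Per consensus-genotype-group, per-platform percentage concordance.
    A platform call counts as concordant iff it equals the consensus
    diplotype (at core-star resolution for the default grouping); no-calls
    stay in the denominator."""
    consensus_by_sample = {r.sample_id: r for r in consensus_list}
    for call in calls:
        if call.sample_id not in consensus_by_sample:
            raise ValueError(f"sample {call.sample_id} has no consensus result")

    def group_key(d: Diplotype) -> str:
        return d.format_core() if group_by == "core" else d.format()

    platforms = tuple(sorted({c.platform for c in calls}))
    rows: dict[str, dict[str, ConcordanceCell]] = {}
    group_n: dict[str, int] = {}
    counts: dict[tuple[str, str], list[int]] = {}
    for res in consensus_list:
        if res.consensus is None:
            continue
        group_n[group_key(res.consensus)] = group_n.get(group_key(res.consensus), 0) + 1
    for call in calls:
        res = consensus_by_sample[call.sample_id]
        if res.consensus is None:
            continue
        key = (group_key(res.consensus), call.platform)
        c_n = counts.setdefault(key, [0, 0])
        c_n[1] += 1
        if call.diplotype is not None and \
                group_key(call.diplotype) == group_key(res.consensus):
            c_n[0] += 1
    for (group, platform), (c, n) in counts.items():
        rows.setdefault(group, {})[platform] = ConcordanceCell(c, n)
    return ConcordanceTable(rows, group_n, platforms)


@dataclass
class RevisionReport:
    n_changed: int
    n_total: int
    transitions: dict[tuple[str, str], int]

    @property
    def fraction_changed(self) -> float:
        return self.n_changed / self.n_total if self.n_total else 0.0


def revision_report(prior_calls: dict[str, Optional[Diplotype]],
                    consensus_list: Sequence[ConsensusResult],
                    score_table: Optional[dict[str, float]] = None,
                    gene: Gene = Gene.CYP2D6) -> RevisionReport:
    """Count samples whose assigned activity score changes between prior
    and consensus genotypes; prior no-calls that gain a genotype count as
    changed. Also returns the phenotype transition matrix."""
    consensus_by_sample = {r.sample_id: r.consensus for r in consensus_list}
    if set(prior_calls) != set(consensus_by_sample):
        raise ValueError("prior and consensus must cover the same samples")
    changed = 0
    transitions: dict[tuple[str, str], int] = {}
    for sample, prior in prior_calls.items():
        cons = consensus_by_sample[sample]
        prior_act = activity_score(prior, score_table, gene) if prior else None
        cons_act = activity_score(cons, score_table, gene) if cons else None
        p_ph = prior_act.phenotype.value if prior_act else "indeterminate"
        c_ph = cons_act.phenotype.value if cons_act else "indeterminate"
        transitions[(p_ph, c_ph)] = transitions.get((p_ph, c_ph), 0) + 1
        if prior is None and cons is not None:
            changed += 1
        elif prior is not None and cons is not None:
            if (prior_act.score is None) != (cons_act.score is None) or \
                    (prior_act.score is not None
                     and prior_act.score != cons_act.score):
                changed += 1
    return RevisionReport(changed, len(prior_calls), transitions)
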