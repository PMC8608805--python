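"""Clinical workflow state machine for CYP2D6 genotyping.

Given the evidence accumulated so far for one sample, recommend the next
laboratory step: after the initial multiplex SNV + two-probe CNV screen,
unequal probe calls trigger the third (intron 6) CNV probe; a confirmed
unequal pattern triggers hybrid-specific long-range PCR with multiplex
genotyping of the amplicon; a flat copy number above two with heterozygous
sites triggers allelic-ratio phasing of the duplication; and a sample that
still has no unique best candidate goes to Sanger confirmation and finally
to manual review. Every recommendation is deterministic in the state, and
a genotype is only reported when exactly one best-ranked candidate remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

from .caller import CandidateCall, enumerate_diplotypes, match_amplicon
from .cnv import CnvProbeVector, HypothesisKind, StructuralHypothesis, classify_cnv
from .haplotypes import HaplotypeTable, builtin_table, core_star
from .observations import Category, SiteGenotype
from .phasing import DuplicateVerdict, PhaseAssignment
from .sites import Gene, ProbeRegion

#: The two-probe screen; the intron 6 probe is only run on unequal calls.
SCREEN_REGIONS = (ProbeRegion.INTRON2, ProbeRegion.EXON9)

#: Downstream full genes for which the CYP2D6-2D7 hybrid-specific amplicon
#: can also be generated from CYP2D7 itself (false-positive caveat).
AMPLICON_G_CROSSREACTIVE = frozenset({"*1", "*4", "*41"})


class Action(str, Enum):
    REPORT_DIPLOTYPE = "report_diplotype"
    RUN_THIRD_CNV_PROBE = "run_third_cnv_probe"
    GENERATE_HYBRID_AMPLICON_AND_GENOTYPE = "generate_hybrid_amplicon_and_genotype"
    PHASE_DUPLICATION = "phase_duplication"
    SANGER_CONFIRM = "sanger_confirm"
    REPEAT_ASSAY = "repeat_assay"
    MANUAL_REVIEW = "manual_review"


@dataclass(frozen=True)
class WorkflowAction:
    action: Action
    warnings: tuple[str, ...] = ()
    candidates: tuple[CandidateCall, ...] = ()


@dataclass(frozen=True)
class WorkflowState:
    """Evidence accumulated for one sample."""

    gene: Gene = Gene.CYP2D6
    genotypes: tuple[SiteGenotype, ...] = ()
    cnv_vectors: tuple[CnvProbeVector, ...] = ()
    phase_results: tuple[tuple[str, PhaseAssignment], ...] = ()
    #: Each amplicon result is the hemizygous genotype vector of one
    #: long-range PCR product.
    amplicon_results: tuple[tuple[SiteGenotype, ...], ...] = ()
    duplicate_verdicts: tuple[tuple[str, DuplicateVerdict], ...] = ()
    sanger_done: bool = False
    flags: frozenset[str] = frozenset()

    @property
    def is_empty(self) -> bool:
        return not self.genotypes and not self.cnv_vectors

    def with_observations(self, **changes) -> "WorkflowState":
        return replace(self, **changes)


def _hypothesis(state: WorkflowState) -> Optional[StructuralHypothesis]:
    if not state.cnv_vectors:
        return None
    return classify_cnv(state.cnv_vectors)


def _candidates(state: WorkflowState,
                table: HaplotypeTable) -> list[CandidateCall]:
    hyp = _hypothesis(state)
    cands = enumerate_diplotypes(state.genotypes, hyp, table, gene=state.gene)
    for amp in state.amplicon_results:
        stars = set(match_amplicon(amp, table, state.gene))
        if not stars:
            continue
        cands = [c for c in cands
                 if any(u.star_name in stars for u in c.diplotype.iter_units())]
    return cands


def _warnings(state: WorkflowState, hyp: Optional[StructuralHypothesis],
              cands: Sequence[CandidateCall]) -> tuple[str, ...]:
    warns = []
    if hyp is not None and hyp.kind is HypothesisKind.HYBRID_2D6_2D7_PRESENT:
        cores = {core_star(u.star_name)
                 for c in cands for u in c.diplotype.iter_units()
                 if not u.structural.kind.is_hybrid}
        hits = sorted(cores & AMPLICON_G_CROSSREACTIVE)
        if hits:
            warns.append(
                "amplicon G can also amplify CYP2D7 when the downstream "
                f"CYP2D6 gene is {', '.join(hits)}: confirm before calling "
                "a hybrid from this amplicon alone")
    if hyp is not None and hyp.kind.is_hybrid and len(state.cnv_vectors) == 1:
        warns.append(
            "hybrid hypothesis supported by a single platform: sequence "
            "variation under the intron 2/6 probes can mimic copy loss; "
            "confirm on a second platform or by amplicon work")
    return tuple(warns)


def next_action(state: WorkflowState,
                table: Optional[HaplotypeTable] = None) -> WorkflowAction:
    """Deterministic next step for the sample's current evidence."""
    if state.is_empty:
        raise ValueError("workflow requires at least the initial multiplex "
                         "SNV + CNV screen")
    table = table or builtin_table(state.gene)

    if any(v is DuplicateVerdict.FAIL for _, v in state.duplicate_verdicts):
        return WorkflowAction(Action.REPEAT_ASSAY,
                              ("duplicate runs contradict each other",))

    hyp = _hypothesis(state)
    probed = {r for vec in state.cnv_vectors for r in vec.calls}

    if hyp is not None and hyp.kind is not HypothesisKind.STANDARD_TWO_COPY:
        unequal = hyp.kind.is_hybrid or hyp.kind is HypothesisKind.CONFLICT
        if unequal and ProbeRegion.INTRON6 not in probed:
            return WorkflowAction(Action.RUN_THIRD_CNV_PROBE)
        if unequal and not state.amplicon_results:
            cands = _candidates(state, table)
            return WorkflowAction(Action.GENERATE_HYBRID_AMPLICON_AND_GENOTYPE,
                                  _warnings(state, hyp, cands), tuple(cands))
        if hyp.kind is HypothesisKind.XN_PRESENT:
            het_sites = [g.site for g in state.genotypes
                         if g.category is Category.HET]
            phased = {site for site, _ in state.phase_results}
            if het_sites and not (set(het_sites) & phased):
                return WorkflowAction(Action.PHASE_DUPLICATION)

    cands = _candidates(state, table)
    unique = len(cands) == 1 or (
        len(cands) > 1 and cands[0].rank_key < cands[1].rank_key)
    if cands and unique:
        return WorkflowAction(Action.REPORT_DIPLOTYPE,
                              _warnings(state, hyp, cands[:1]),
                              (cands[0],))
    if not state.sanger_done:
        return WorkflowAction(Action.SANGER_CONFIRM,
                              _warnings(state, hyp, cands), tuple(cands))
    return WorkflowAction(Action.MANUAL_REVIEW,
                          ("no unique candidate after confirmation",),
                          tuple(cands))
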