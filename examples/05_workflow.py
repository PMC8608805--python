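"""Walk the clinical workflow for a hybrid sample.

Starting from the initial multiplex SNV + two-probe CNV screen, the state
machine recommends each next assay until the diplotype can be reported:
unequal screen probes -> third CNV probe -> hybrid-specific long-range PCR
with multiplex genotyping of the amplicon -> report.
"""

from starcall import Category, SiteGenotype, builtin_table, parse_diplotype
from starcall.cnv import expected_cnv
from starcall.panels import panel_of
from starcall.sites import TAQMAN_REGIONS
from starcall.synthetic import simulate_observations
from starcall.workflow import Action, SCREEN_REGIONS, WorkflowState, next_action

table = builtin_table("CYP2D6")
truth = parse_diplotype("*13 + *2/*1", table)  # known only to the simulator
panel = panel_of("LuminexXTAGv3", "CYP2D6")

obs = simulate_observations(truth, [panel], table=table)
state = WorkflowState(
    genotypes=tuple(obs.platforms[panel.name].genotypes()),
    cnv_vectors=(expected_cnv(truth, SCREEN_REGIONS, "TaqMan"),))

for step in range(1, 7):
    action = next_action(state)
    print(f"step {step}: {action.action.value}")
    for warning in action.warnings:
        print(f"    warning: {warning}")
    if action.action is Action.RUN_THIRD_CNV_PROBE:
        state = state.with_observations(
            cnv_vectors=(expected_cnv(truth, TAQMAN_REGIONS, "TaqMan"),))
    elif action.action is Action.GENERATE_HYBRID_AMPLICON_AND_GENOTYPE:
        hybrid = next(u for u in truth.iter_units()
                      if u.structural.kind.is_hybrid)
        amplicon = tuple(
            SiteGenotype(s, {"var": Category.MUT,
                             "absent": Category.NOCALL}
                         .get(hybrid.state_at(s), Category.WT))
            for s in sorted(panel.sites_assayed))
        state = state.with_observations(
            amplicon_results=state.amplicon_results + (amplicon,))
    elif action.action in (Action.REPORT_DIPLOTYPE, Action.MANUAL_REVIEW):
        if action.candidates:
            print(f"    reported: {action.candidates[0].diplotype.format()}")
        break
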