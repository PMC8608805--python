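"""Assign a multiplication to a haplotype from allelic signal ratios.

A sample with flat CNV calls of 4 across all probes is heterozygous at the
*41-defining intron 6 site. Which haplotype carries the extra copies?
Replicate wild-type/variant probe signals put the variant fraction near
3/4, so three of the four gene copies carry the *41 variant: a *41x3/*1
configuration.
"""

from starcall import SignalPair, activity_score, builtin_table, parse_diplotype
from starcall.phasing import phase_xn

pairs = [SignalPair(wt_signal=102.0, var_signal=308.0, replicate_id="rep1"),
         SignalPair(wt_signal=97.0, var_signal=301.0, replicate_id="rep2")]

result = phase_xn("rs28371725", pairs, total_copies=4)
print(f"estimated variant fraction: {result.estimated_var_fraction:.3f}")
print(f"variant copies: {result.var_copies} of 4 -> {result.outcome.value}")

table = builtin_table("CYP2D6")
act = activity_score(parse_diplotype("*41x3/*1", table))
print(f"*41x3/*1 activity score: {act.score} -> {act.phenotype.value}")
print("\nThree decreased-function copies (3 x 0.25) plus one normal copy")
print("sum to 1.75, still a normal metabolizer under the standard cut-offs.")
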