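"""Cross-platform consensus for a sample no single platform gets right.

A hybrid-blind screening array reports *4/*4; a second array gives a
no-call with alternatives *4/UNK; TaqMan probes read copies 1, 2, 2; and
allelic-ratio phasing shows the *4 sits opposite a deletion. No platform
saw the whole picture, but only one diplotype is consistent with all of
them after each panel's limitations are applied: *13 + *4/*5.
"""

from starcall import Category, CnvProbeVector, PlatformCall, ProbeRegion, \
    builtin_table, derive_consensus, parse_diplotype
from starcall.consensus import DELETION_PRESENT
from starcall.observations import ObservationSet, PlatformObservation
from starcall.sites import Gene

table = builtin_table("CYP2D6")

observations = ObservationSet(
    "sample-042", Gene.CYP2D6,
    structural_constraints=frozenset({DELETION_PRESENT}))  # from phasing
observations.platforms["TaqMan"] = PlatformObservation(
    "TaqMan", Gene.CYP2D6,
    snv={"rs3892097": Category.MUT},
    cnv=CnvProbeVector({ProbeRegion.INTRON2: 1, ProbeRegion.INTRON6: 2,
                        ProbeRegion.EXON9: 2}, platform="TaqMan"))

calls = [
    PlatformCall("sample-042", "AmpliChip", Gene.CYP2D6,
                 parse_diplotype("*4/*4", table)),
    PlatformCall("sample-042", "PharmacoScan", Gene.CYP2D6, None,
                 alternatives=("*4/UNK", "*4.009/UNK")),
]

result = derive_consensus(calls, observations, table)
print(f"consensus: {result.consensus.format()}")
print("rationale:")
for step in result.rationale:
    print(f"  - {step}")
print("\nThe seemingly homozygous *4/*4 is the hybrid tandem *13 + *4 over")
print("a whole-gene deletion: the array cannot see the hybrid or the")
print("deletion, so the *4 signal is all it reports.")
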