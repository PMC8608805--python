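"""Reproduce cross-platform concordance from a consensus distribution.

Project the built-in consensus CYP2C19 genotype distribution (93 samples)
through each platform's coverage limitations and tabulate how often the
platform call equals the consensus. A panel restricted to *2 and *3
mis-genotypes every *17, *6 and *8 carrier; panels covering *2-*10 and
*17 agree perfectly.
"""

from starcall import builtin_table, panel_of
from starcall.synthetic import CohortSpec, simulate_platform_limited_cohort

table = builtin_table("CYP2C19")
spec = CohortSpec()
print(f"cohort: {spec.n_samples} samples, "
      f"{len(spec.groups)} consensus genotype groups\n")

for platform in ("AmpliChip", "LuminexXTAGv3", "PharmacoScan", "Agena"):
    pairs = simulate_platform_limited_cohort(
        spec, panel_of(platform, "CYP2C19"), table)
    concordant = sum(1 for truth, call in pairs
                     if call is not None
                     and call.format_core() == truth.format_core())
    pct = 100.0 * concordant / len(pairs)
    print(f"{platform:15s} {pct:5.1f} % ({concordant}/{len(pairs)})")

print("\nThe limited panel's 66.7 % comes entirely from haplotypes outside")
print("its content collapsing to *1 (24x *1/*17, 4x *2/*17, 1x *17/*17,")
print("1x *1/*8, 1x *2/*6).")
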