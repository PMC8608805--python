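# starcall

Star-allele diplotype calling for **CYP2D6** and **CYP2C19** from
multi-platform SNV and CNV-probe data, including structural variation:
the *5 whole-gene deletion, xN duplications/multiplications, CYP2D7/2D6
**hybrid genes** and **hybrid tandems** (e.g. `*13 + *2`, `*36 + *10`).

## Who this is for

CYP2D6 and CYP2C19 metabolize many antidepressants, antipsychotics and
other commonly prescribed drugs, and prescribing guidelines keyed to their
star alleles exist. Clinical genotyping of CYP2D6 is hard: the gene sits
next to the highly homologous CYP2D7 pseudogene, producing deletions,
duplications and fusion ("hybrid") genes that most multiplex platforms
cannot represent directly. `starcall` is a library (plus a thin CLI) for
laboratories and method developers who combine evidence across platforms —
multiplex SNV genotyping, real-time PCR CNV probes, arrays, amplicon
genotyping of long-range PCR products — and need automated, reproducible
translation of that evidence into diplotypes, activity scores and
metabolizer phenotypes.

## The model

**Haplotype translation.** A star allele is a vector of variant states
over panel sites plus a structural class. A hybrid's class carries a
*switch interval* — the pair of CNV probe boundaries between which its
sequence origin changes. Each gene unit contributes integer copies to each
CNV probe region: a full gene contributes 1 everywhere, the deletion 0,
and a hybrid 1 exactly on its CYP2D6-derived side. For a chromosome pair
the expected probe vector is the sum over units, so

```
*13[switch in (intron2, intron6]] + *4   /   *5
(0,1,1)                + (1,1,1)      +  (0,0,0)  =  (1, 2, 2)
```

over the probes (intron 2, intron 6, exon 9). Inversely, flat observed
calls mean a standard, deletion or xN sample; calls rising 5'→3' indicate
a CYP2D7-2D6 hybrid and falling calls a CYP2D6-2D7 hybrid, with the switch
region bracketed by the step.

**Calling is constraint satisfaction.** Multiplex platforms report site
categories, not phased alleles: HET means both alleles present somewhere
among the units, MUT that all units carry the variant, WT that all carry
the reference; deletion units and CYP2D7-derived sequence contribute no
signal. The caller enumerates every diplotype (up to a unit budget)
consistent with the categories and the CNV evidence, ranked by structural
parsimony.

**Phasing.** For n > 2 copies heterozygous at a site, replicate
wild-type/variant signal fractions cluster near lattice points m/n; the
nearest point assigns the duplication to a haplotype (activity score of a
diplotype = Σ unit activity × repeat, mapped to PM/IM/NM/UM).

**Consensus.** The consensus diplotype is the unique candidate consistent
with every platform's call *after* applying that platform's coverage
limitations (hybrids vanish from hybrid-blind panels; a missed deletion
makes the surviving allele look homozygous) — no majority voting.

## Worked example

`examples/03_consensus_deduction.py` reconciles four kinds of evidence for
one sample — a screening array reporting `*4/*4`, an array no-call with
alternatives `*4/UNK`, TaqMan CNV probes reading copies 1, 2, 2, and
phasing showing the *4 opposite a deletion:

```
consensus: *13 + *4/*5
rationale:
  - CNV hypothesis: hybrid_2D7_2D6_present
  - 5 candidates from raw observations
  - 1 after constraints ['deletion_present']
  - 1 compatible with PharmacoScan (no call)
  - 1 compatible with AmpliChip (*4/*4)
```

The seemingly homozygous `*4/*4` is actually a CYP2D7-2D6 hybrid tandem
over a whole-gene deletion; all three alleles are null, so the sample is a
poor metabolizer either way. `examples/04_platform_concordance.py`
projects the built-in 93-sample consensus CYP2C19 genotype distribution
through each panel's limitation model:

```
AmpliChip        66.7 % (62/93)
LuminexXTAGv3   100.0 % (93/93)
PharmacoScan    100.0 % (93/93)
```

— the restricted panel (CYP2C19 *2/*3 only) silently converts every *17,
*6 and *8 carrier to *1, while panels covering *2–*10 and *17 agree with
the consensus on every sample.

The other examples cover candidate enumeration for a hidden hybrid
(`01`), allelic-ratio phasing of a *41×3 multiplication (`02`) and the
clinical workflow state machine (`05`). A thin CLI mirrors the library:
`starcall call`, `consensus`, `concordance`, `simulate`, `workflow`,
`panel show`.

## Layout

- `src/starcall/` — `sites`, `haplotypes`, `panels` (definitions and
  built-in tables), `cnv` (forward model + classifier), `caller`
  (enumeration, amplicon matching, activity), `phasing`, `consensus`,
  `workflow`, `synthetic` (forward simulator), `io`, `cli`.
- `src/starcall/data/` — curated haplotype translation tables (TSV).
- `docs/methods.md` — model details, defaults, numerical choices and
  limitations.
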