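# Methods

## Scope and data model

`starcall` operates on the evidence types that clinical pharmacogenetic
laboratories actually produce for CYP2D6 and CYP2C19: per-site genotype
*categories* (WT/HET/MUT, plus NOCALL and LOW_SIGNAL) from multiplex
assays, integer copy-number calls with confidences from CNV probes, raw
wild-type/variant signal pairs from replicate TaqMan wells, and
single-haplotype genotype vectors from long-range PCR amplicons. It does
not process reads, traces or instrument-native files; those upstream steps
are the instrument software's job and their outputs are this package's
inputs.

Sites are registered under one canonical id — the dbSNP rsID where one
exists unambiguously, else a normalized legacy label — with all legacy
M33388-dialect spellings (the off-by-one pairs such as 2850C>T/2851C>T)
as aliases. The two variant alleles at position 1758 (G>T defining *8,
G>A defining *14) share a single rsID, so they keep legacy labels as
canonical ids to remain distinct sites.

## Structural model

Each haplotype has a structural class: full gene, whole-gene deletion, or
a hybrid with an orientation (CYP2D7-derived 5' / CYP2D6-derived 3', or
the reverse) and a **switch interval** — an ordered pair of CNV probe
boundaries within which the sequence origin changes. The per-region copy
contribution is 1 on the CYP2D6-derived side of the interval and 0
elsewhere; expected probe vectors are sums of unit contributions. This
single rule generates all the observable patterns: flat vectors for
standard/deletion/xN samples, monotone steps for hybrids, and mixed
heights for hybrid tandems.

The inverse classifier reads confident calls in fixed 5'→3' region order
(5'-flank < intron 2 < intron 6 < exon 9 < 3'-flank). Calls below the
0.95 confidence floor (the conventional threshold for quadruplicate
real-time PCR CNV calling) are flagged and excluded; if nothing clears
the floor the classifier demands a repeat rather than guessing.
Cross-platform contradictions produce a `conflict` hypothesis that
retains each platform's own reading — conflicts are routed to the
workflow, never voted away. Vectors from platforms with different region
sets merge by intersecting hybrid switch intervals (a 2-region array
vector brackets the switch loosely; a 3-probe vector narrows it).

## Calling

Presence semantics: at each site, HET requires both a reference-carrying
and a variant-carrying unit somewhere in the diplotype; MUT requires all
carrying units variant; WT all reference. Deletion units and sites marked
`absent` on a haplotype (CYP2D7-derived or uncharacterized hybrid
sequence) carry nothing — which is exactly why a `*X/*5` sample reads
hemizygous and why a *13 hybrid can hide behind an apparently homozygous
*4. With three or more copies the categories are interpreted as presence,
not dosage; dosage refinement is phasing's job.

Enumeration builds the chromosome-configuration universe from the
translation table — singles, the deletion, xN repeats of full genes, and
hybrid+full tandems — up to a default budget of 4 gene units per
diplotype (covering `*13 + *2 / *41x3`-scale configurations at tractable
cost). Candidates must match every confident observed CNV call region by
region. Ranking is by structural parsimony: fewest structural events
(hybrids, deletions, extra copies, extra in-cis units), then known tandem
arrangements before novel ones, then core alleles before sub-alleles,
then name order. All candidates are reported; an empty list is a valid
no-call. Two consequences worth knowing:

- A configuration observationally identical to a simpler one (e.g.
  `*1x2/*5` versus `*1/*1` at flat copy 2) appears in the candidate list
  but never outranks the simpler call.
- When a panel does not assay a defining site, alleles differing only
  there are genuinely indistinguishable and tie; adding a platform that
  covers the site resolves the tie. The ranking never invents evidence.

Amplicon matching treats a long-range PCR product as one haplotype: every
call must be WT or MUT, `absent` haplotype sites can only produce
no-signal cells, and matches order most-specific first (most variant
sites explained). Heterozygous calls raise a mixed-amplicon error; the
boundary scanner then localizes where heterozygosity begins, which is how
a co-amplified pseudogene copy plus a hybrid is recognized.

## Activity and phenotype

Diplotype score = Σ activity × repeat over all units. CYP2D6 activity
defaults follow the published CPIC values (normal alleles 1, decreased
0.25–0.5, null 0) and are fully overridable per haplotype via the table
file or a score-table argument; every *13 entry is 0 (the exon 1
frameshift insertion terminates translation regardless of sub-identity).
Cut-points for CYP2D6: 0 → PM, (0, 1] → IM, (1, 2.25] → NM, > 2.25 → UM
(scores move in quarter steps, so this places 1.25–2.25 in NM as CPIC
does). CYP2C19 has no published activity-score system; the package uses
an additive surrogate (loss-of-function 0, *9/*10 0.5, *1 1, *17 1.5)
with cut-points 0 → PM, (0, 2) → IM, 2 → NM, > 2 → UM, which reproduces
the standard allele-function phenotype translation for all common
diplotypes (the increased-function *1/*17 and *17/*17 map to UM; a
distinct "rapid" category is not modeled). Any unit of uncertain activity
makes the result indeterminate.

## Phasing

For a site called HET on genomic DNA in a sample with n ≥ 3 copies, the
variant-signal fraction var/(var+wt), averaged over non-failed replicate
wells, is compared to the lattice m/n (m = 1..n−1). A lattice point is
accepted only if the estimate is within 0.12 absolute **and** closer than
half-way to any competing point; otherwise the assignment is ambiguous.
The 0.12 default acknowledges that ratio clustering carries real
uncertainty without quantifying a distribution the data do not provide;
shrinking the tolerance can only move outcomes toward ambiguous, never
flip them. The single-probe-amplifying case (one signal ≈ 0) is
ambiguous by construction — copy configurations like C/C, CC/C, CC/− and
C/− produce the same one-sided signal. Optional control fractions from
known-genotype samples re-center the lattice. Duplicate-run comparison is
a three-way rule per site: identical informative categories pass, a
one-sided no-call requests a repeat, contradictions fail the site.

## Collapse and consensus

`collapse_call` projects a diplotype through a panel's limitations:
haplotypes outside the panel's content map to a covered ancestor
sub-allele or to *1; hybrids are dropped on hybrid-blind panels; a
deletion on a deletion-blind panel leaves the surviving chromosome
mirrored (the sample looks homozygous). The built-in AmpliChip panel is
modeled deletion-blind — its *5 content is nominal but unreliable — which
is what makes a hybrid tandem over a deletion collapse to an apparently
homozygous call. Collapse is idempotent.

Consensus requires consistency, not majority: candidates are enumerated
from the merged raw observations (highest evidence tier wins per site;
equal-tier contradictions drop the site), filtered by structural side
constraints established in follow-up work (e.g. `deletion_present` from
phasing), then filtered by every platform's call after collapse through
that platform's panel ("UNK" in an alternative call is a wildcard
chromosome). Evidence tiers (amplicon/Sanger 3 > multiplex SNV+CNV 2 >
screening array 1) break residual ties; otherwise the sample is flagged
unresolved with the surviving candidate set and rationale trail.

Concordance tables count a platform call as concordant only if it equals
the consensus genotype at core-star resolution (sub-alleles merged),
with no-calls in the denominator; cells render as `P (c/n)` exactly as
such tables are printed, or plain `100` when everything assayed agreed.

## Workflow state machine

Priorities, in order: contradictory duplicates → repeat; two-probe CNV
inequality without an intron 6 call → run the third probe; confirmed
inequality without amplicon data → generate the hybrid-specific amplicon
and genotype it; flat copies > 2 with unphased heterozygous sites →
phase the duplication; a unique best-ranked candidate → report; else
Sanger confirmation once, then manual review. Two caveats surface as
warnings rather than actions: the CYP2D6-2D7 amplicon primer pair also
amplifies CYP2D7 when the downstream gene is *1, *4 or *41, and a hybrid
hypothesis supported by a single platform may reflect sequence variation
under the intron 2/6 probes mimicking copy loss. A report is only emitted
when exactly one best-ranked candidate remains, and every trajectory
reaches report or manual review within six recommendations.

## Forward simulator

The simulator emulates the conditions of a multi-platform cross-validation cohort: per-panel site categories
from the exact presence semantics, CNV vectors from the forward model,
and replicate signal pairs at ideal m/n fractions. The default cohort
specification is a 93-sample consensus CYP2C19 genotype
distribution across 8 genotype groups, and the platform-limitation model
is deterministic collapse — which is sufficient to reproduce the printed
overall concordances (62/93 = 66.7 % for the restricted screening panel,
93/93 for fully covering panels). Optional noise: per-site no-call
probability, per-region ±1 CNV miscount probability, and lognormal signal
scatter (CV 0.08 by default — a typical replicate qPCR spread; no signal
distribution is published) applied when a noise model with nonzero rates
is supplied. All randomness flows through one `numpy` generator seeded
explicitly; zero rates reproduce the deterministic model bitwise.

What the simulator does **not** emulate: allele dropout from primer-site
variants, batch effects, reference-sample calibration drift, or
rare/novel variants outside the panel — so passing round-trip tests show
the inference machinery is self-consistent under the stated semantics,
not that any platform's wet-lab error modes are covered.

## Built-in tables and problem sizes

The shipped translation tables encode the haplotypes and sites the
supported panels interrogate (42 CYP2D6 entries including the *13 group,
*4.013, *36, *57, *61, *63, *68, *83 hybrids and one representative
sub-allele per mechanism; 12 CYP2C19 entries). The two deposited *13
reference sequences are encoded from their printed amplicon genotypes;
the generic `*13` group entry marks sites between the intron 2 and
intron 6 probes `absent` because the group's sub-identity (and hence its
sequence there) is unresolved. Sites of hybrids not characterized in the
sources are likewise `absent`, and a handful of rare alleles
(*25, *26, *30, *57, *70, *107) carry `uncertain` activity.

Test problem sizes are chosen for exhaustiveness where the space is
small and representativeness where it is not: oracle-equivalence checks
run the full CYP2C19 table and the full CYP2D6 table at ≤ 4 units
against an independent brute-force filter for a panel of genotype/CNV
inputs; round-trip recovery is exhaustive over all two-unit CYP2C19
diplotypes and covers a curated CYP2D6 archetype set spanning every
structural mechanism; the forward/inverse CNV consistency sweep is
exhaustive over ≤ 4-unit diplotypes from an 11-haplotype representative
subset (> 500 distinct configurations).

## Known limitations

- Rare and novel variants are out of scope; the caller can only return
  haplotypes present in its translation table.
- CYP2C19 structural variants are not modeled (the workflow machinery is
  gene-agnostic enough to extend, but no CYP2C19 CNV content ships).
- The quantitative false-positive behavior of the intron 2/6 probes under
  local sequence variation is unknown; it is handled as a workflow
  warning, not a likelihood model.
- Panels encode the haplotype content stated for each platform, not the
  vendors' full proprietary translation files; coverage of alleles not
  named in the sources is conservative.
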