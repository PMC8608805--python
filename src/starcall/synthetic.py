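"""Forward simulator of platform observations from ground-truth diplotypes.

The simulator inverts the caller: given a true diplotype it produces, per
platform panel, the site genotype categories that presence semantics
predict (restricted to the panel's assayed sites), the expected CNV probe
vector, and replicate allelic signal pairs for heterozygous sites on
multi-copy samples. With all noise rates at zero the output is the exact
deterministic forward model, so simulate -> call round trips are testable;
optional noise injects no-calls, CNV miscounts of one copy, and lognormal
scatter on signal fractions. It also emulates platform coverage gaps
(collapse of a truth diplotype to what a limited panel can report), which
is what reproduces printed cross-platform concordance figures from a
consensus genotype distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .cnv import expected_cnv
from .consensus import collapse_call
from .diplotypes import Diplotype, parse_diplotype
from .haplotypes import ABSENT, HaplotypeTable, StructuralKind, VAR, builtin_table
from .observations import Category, ObservationSet, PlatformObservation
from .panels import PlatformPanel
from .phasing import SignalPair
from .sites import Gene


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise. All-zero rates reproduce the deterministic
    forward model exactly."""

    nocall_rate: float = 0.0
    cnv_miscount_rate: float = 0.0
    #: Coefficient of variation of replicate signal intensities.
    signal_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.nocall_rate <= 1 and 0 <= self.cnv_miscount_rate <= 1):
            raise ValueError("noise rates must be in [0, 1]")
        if self.signal_cv <= 0:
            raise ValueError("signal_cv must be positive")


NOISELESS = NoiseModel()

#: 93-sample European-ancestry consensus CYP2C19 genotype distribution
#: used as the default cohort specification.
CYP2C19_CONSENSUS_COHORT: tuple[tuple[str, int], ...] = (
    ("*1/*1", 44), ("*1/*17", 24), ("*1/*2", 16), ("*17/*17", 1),
    ("*2/*17", 4), ("*2/*2", 2), ("*1/*8", 1), ("*2/*6", 1),
)


@dataclass(frozen=True)
class CohortSpec:
    """List of (diplotype string, count) pairs defining a cohort."""

    groups: tuple[tuple[str, int], ...] = CYP2C19_CONSENSUS_COHORT
    gene: Gene = Gene.CYP2C19

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort specification must be non-empty")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.groups)

    def diplotypes(self, table: Optional[HaplotypeTable] = None
                   ) -> list[Diplotype]:
        table = table or builtin_table(self.gene)
        out = []
        for text, count in self.groups:
            d = parse_diplotype(text, table)
            out.extend([d] * count)
        return out


def _true_category(truth: Diplotype, site_id: str) -> Category:
    has_ref = has_var = has_absent = False
    for unit in truth.iter_units():
        if unit.structural.kind is StructuralKind.DELETION:
            continue
        state = unit.state_at(site_id)
        if state == VAR:
            has_var = True
        elif state == ABSENT:
            has_absent = True
        else:
            has_ref = True
    if has_ref and has_var:
        return Category.HET
    if has_var:
        return Category.MUT
    if has_ref:
        return Category.WT
    # no interrogable template at this site
    return Category.LOW_SIGNAL if has_absent else Category.NOCALL


def simulate_observations(truth: Diplotype,
                          panels: Sequence[PlatformPanel],
                          noise: NoiseModel = NOISELESS,
                          seed: Optional[int] = None,
                          table: Optional[HaplotypeTable] = None
                          ) -> ObservationSet:
    """Simulate one sample's per-platform observations from a ground-truth
    diplotype. Identical (truth, panels, noise, seed) gives bitwise
    identical output."""
    gene = next(truth.iter_units()).gene
    table = table or builtin_table(gene)
    for unit in truth.iter_units():
        if unit.star_name not in table:
            raise KeyError(f"truth haplotype {unit.star_name} missing from table")
    rng = np.random.default_rng(noise.seed if seed is None else seed)
    noisy = noise.nocall_rate > 0 or noise.cnv_miscount_rate > 0

    obs = ObservationSet(sample_id="sim", gene=gene)
    for panel in panels:
        if panel.gene is not gene:
            raise ValueError(f"panel {panel.name} is for {panel.gene.value}, "
                             f"not {gene.value}")
        snv: dict[str, Category] = {}
        for site_id in sorted(panel.sites_assayed):
            cat = _true_category(truth, site_id)
            if noise.nocall_rate and rng.random() < noise.nocall_rate:
                cat = Category.NOCALL
            snv[site_id] = cat
        cnv = None
        if panel.cnv_regions:
            cnv = expected_cnv(truth, panel.cnv_regions, platform=panel.name)
            if noise.cnv_miscount_rate:
                calls = dict(cnv.calls)
                for region in calls:
                    if rng.random() < noise.cnv_miscount_rate:
                        calls[region] = max(0, calls[region]
                                            + int(rng.choice((-1, 1))))
                cnv = type(cnv)(calls, dict(cnv.confidence), cnv.platform)
        signals: dict[str, list[SignalPair]] = {}
        total_units = truth.n_units
        if total_units >= 3:
            for site_id, cat in snv.items():
                if cat is not Category.HET:
                    continue
                m = sum(1 for u in truth.iter_units()
                        if u.structural.kind is not StructuralKind.DELETION
                        and u.state_at(site_id) == VAR)
                n = sum(1 for u in truth.iter_units()
                        if u.structural.kind is not StructuralKind.DELETION
                        and u.state_at(site_id) != ABSENT)
                reps = []
                for rep in range(2):
                    wt, var = float(n - m), float(m)
                    if noisy:
                        sigma = np.sqrt(np.log1p(noise.signal_cv ** 2))
                        wt *= float(rng.lognormal(0.0, sigma))
                        var *= float(rng.lognormal(0.0, sigma))
                    reps.append(SignalPair(wt, var, f"rep{rep + 1}"))
                signals[site_id] = reps
        obs.platforms[panel.name] = PlatformObservation(panel.name, gene,
                                                        snv, cnv, signals)
    return obs


def simulate_platform_limited_cohort(spec: CohortSpec, panel: PlatformPanel,
                                     table: Optional[HaplotypeTable] = None
                                     ) -> list[tuple[Diplotype, Optional[Diplotype]]]:
    """Deterministically project each cohort truth diplotype through one
    panel's coverage limitations: (truth, platform call) pairs."""
    table = table or builtin_table(spec.gene)
    if panel.gene is not spec.gene:
        raise ValueError(f"panel {panel.name} is for {panel.gene.value}")
    out = []
    for truth in spec.diplotypes(table):
        collapsed = collapse_call(truth, panel, table)
        out.append((truth, collapsed.diplotype))
    return out
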