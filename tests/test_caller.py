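"""Caller tests, including an independent brute-force oracle for the
diplotype enumeration."""

import itertools

import pytest

from starcall.caller import (
    MixedAmpliconError, activity_score, consistent, detect_mixed_amplicon,
    enumerate_diplotypes, match_amplicon, Phenotype,
)
from starcall.cnv import classify_cnv, CnvProbeVector
from starcall.diplotypes import ChromosomeConfig, Diplotype, parse_diplotype
from starcall.haplotypes import ABSENT, REF, VAR, StructuralKind
from starcall.observations import Category, SiteGenotype, parse_category
from starcall.panels import panel_of
from starcall.sites import Gene, ProbeRegion as R, resolve_site

from conftest import genotypes


def cnv(platform="TaqMan", **calls):
    return CnvProbeVector({R(k): n for k, n in calls.items()}, {}, platform)


# ---------------------------------------------------------------- oracle --

def oracle_universe(table, max_units):
    """Independent chromosome-configuration enumeration: singles, the
    deletion, xN repeats of full genes, hybrid+full tandems."""
    fulls, hybrids, dels = [], [], []
    for hap in table:
        kind = hap.structural.kind
        (dels if kind is StructuralKind.DELETION
         else hybrids if kind.is_hybrid else fulls).append(hap)
    configs = [((d, 1),) for d in dels]
    for f in fulls:
        for rep in range(1, max_units + 1):
            configs.append(((f, rep),))
    for h in hybrids:
        configs.append(((h, 1),))
        for rh in range(1, max_units):
            for f in fulls:
                for rf in range(1, max_units - rh + 1):
                    configs.append(((h, rh), (f, rf)))
    return [ChromosomeConfig(c) for c in configs]


def oracle_consistent(dip, gts, gene):
    """Presence semantics re-derived from first principles."""
    for g in gts:
        if g.category.is_nocall:
            continue
        site = resolve_site(g.site, gene).canonical_id
        states = [u.state_at(site) for u in dip.iter_units()
                  if u.structural.kind is not StructuralKind.DELETION]
        states = [s for s in states if s != ABSENT]
        want = {Category.WT: states and all(s == REF for s in states),
                Category.MUT: states and all(s == VAR for s in states),
                Category.HET: REF in states and VAR in states}[g.category]
        if not want:
            return False
    return True


def oracle_enumerate(gts, vectors, table, gene, max_units=4):
    from starcall.cnv import expected_cnv
    out = set()
    configs = oracle_universe(table, max_units - 1)
    for ca, cb in itertools.combinations_with_replacement(configs, 2):
        if ca.n_units + cb.n_units > max_units:
            continue
        dip = Diplotype(ca, cb)
        if not oracle_consistent(dip, gts, gene):
            continue
        ok = True
        for v in vectors:
            usable = v.confident_calls()
            exp = expected_cnv(dip, tuple(usable))
            if any(exp.calls[r] != c for r, c in usable.items()):
                ok = False
                break
        if ok:
            out.add(dip.format())
    return out


# ----------------------------------------------------------- consistent --

class TestConsistent:
    def test_hemizygous_mut_with_deletion_in_trans(self, d6_table):
        d = parse_diplotype("*4/*5", d6_table)
        assert consistent(d, genotypes({"rs3892097": "MUT"}), gene=Gene.CYP2D6)
        assert not consistent(d, genotypes({"rs3892097": "HET"}), gene=Gene.CYP2D6)

    def test_reference_diplotype_rejects_het_anywhere(self, d6_table):
        d = parse_diplotype("*1/*1", d6_table)
        for site in ("rs16947", "rs1065852", "rs3892097"):
            assert not consistent(d, genotypes({site: "HET"}), gene=Gene.CYP2D6)

    def test_multiplication_keeps_both_alleles_visible(self, d6_table):
        d = parse_diplotype("*41x3/*1", d6_table)
        assert consistent(d, genotypes({"rs28371725": "HET"}), gene=Gene.CYP2D6)

    def test_nocall_and_low_signal_impose_no_constraint(self, d6_table):
        d = parse_diplotype("*1/*1", d6_table)
        assert consistent(d, genotypes({"rs16947": "NOCALL",
                                        "rs1065852": "LOW_SIGNAL"}),
                          gene=Gene.CYP2D6)

    def test_site_outside_panel_is_an_error(self, d6_table):
        d = parse_diplotype("*1/*1", d6_table)
        with pytest.raises(ValueError, match="not assayed"):
            consistent(d, genotypes({"rs1080985": "WT"}),
                       panel=panel_of("TaqMan", Gene.CYP2D6))

    def test_chromosome_swap_symmetry(self, d6_table):
        gts = genotypes({"rs3892097": "HET", "rs1065852": "HET"})
        a = parse_diplotype("*4/*1", d6_table)
        b = parse_diplotype("*1/*4", d6_table)
        assert consistent(a, gts, gene=Gene.CYP2D6) == \
            consistent(b, gts, gene=Gene.CYP2D6)
        assert a == b


# ------------------------------------------------------------ enumerate --

class TestEnumerate:
    def test_cyp2c19_het_het_top_candidate(self, c19_table):
        gts = genotypes({"rs4244285": "HET", "rs12248560": "HET"})
        cands = enumerate_diplotypes(gts, None, c19_table, gene=Gene.CYP2C19)
        assert cands[0].diplotype == parse_diplotype("*2/*17", c19_table)

    def test_all_wt_flat_two_has_reference_as_unique_best(self, d6_table):
        from starcall.sites import sites_for
        gts = [SiteGenotype(s.canonical_id, Category.WT)
               for s in sites_for(Gene.CYP2D6)]
        hyp = classify_cnv([cnv(intron2=2, intron6=2, exon9=2)])
        cands = enumerate_diplotypes(gts, hyp, d6_table)
        assert cands[0].diplotype == parse_diplotype("*1/*1", d6_table)
        if len(cands) > 1:  # e.g. *1x2/*5 mimics a flat two
            assert cands[0].rank_key < cands[1].rank_key

    def test_hybrid_tandem_with_deletion_is_a_candidate(self, d6_table):
        hyp = classify_cnv([cnv(intron2=1, intron6=2, exon9=2)])
        cands = enumerate_diplotypes(genotypes({"rs3892097": "MUT"}), hyp,
                                     d6_table)
        names = [c.diplotype.format() for c in cands]
        assert parse_diplotype("*13 + *4/*5", d6_table).format() in names

    def test_no_call_is_an_empty_list_not_an_error(self, d6_table):
        # MUT at two sites that no single diplotype can satisfy with a
        # flat-two vector restricted to 2 units
        gts = genotypes({"rs35742686": "MUT", "rs5030655": "MUT"})
        hyp = classify_cnv([cnv(intron2=2, intron6=2, exon9=2)])
        cands = enumerate_diplotypes(gts, hyp, d6_table, max_units=2)
        assert cands == []

    def test_input_row_order_is_irrelevant(self, c19_table):
        gts = genotypes({"rs4244285": "HET", "rs12248560": "HET",
                         "rs4986893": "WT"})
        a = enumerate_diplotypes(gts, None, c19_table, gene=Gene.CYP2C19)
        b = enumerate_diplotypes(gts[::-1], None, c19_table, gene=Gene.CYP2C19)
        assert [c.diplotype.format() for c in a] == \
            [c.diplotype.format() for c in b]

    def test_collapsing_to_nocall_only_grows_the_candidate_set(self, c19_table):
        gts = genotypes({"rs4244285": "HET", "rs12248560": "WT",
                         "rs4986893": "WT"})
        full = {c.diplotype.format()
                for c in enumerate_diplotypes(gts, None, c19_table,
                                              gene=Gene.CYP2C19)}
        for i in range(len(gts)):
            relaxed = list(gts)
            relaxed[i] = SiteGenotype(gts[i].site, Category.NOCALL)
            bigger = {c.diplotype.format()
                      for c in enumerate_diplotypes(relaxed, None, c19_table,
                                                    gene=Gene.CYP2C19)}
            assert full <= bigger

    def test_max_units_below_two_rejected(self, d6_table):
        with pytest.raises(ValueError):
            enumerate_diplotypes([], None, d6_table, max_units=1)

    @pytest.mark.parametrize("gts,vectors", [
        ({"rs4244285": "HET", "rs12248560": "HET"}, []),
        ({"rs4244285": "MUT"}, []),
        ({"rs4244285": "WT", "rs12248560": "WT", "rs4986893": "HET"}, []),
    ])
    def test_oracle_equivalence_cyp2c19(self, c19_table, gts, vectors):
        gts = genotypes(gts)
        cands = enumerate_diplotypes(gts, None, c19_table, gene=Gene.CYP2C19)
        assert {c.diplotype.format() for c in cands} == \
            oracle_enumerate(gts, vectors, c19_table, Gene.CYP2C19)

    @pytest.mark.parametrize("gts,calls", [
        ({"rs3892097": "MUT"}, dict(intron2=1, intron6=2, exon9=2)),
        ({"rs1065852": "HET", "rs16947": "HET", "rs1135840": "HET"},
         dict(intron2=2, intron6=2, exon9=2)),
        ({"rs28371725": "HET", "rs16947": "MUT", "rs1135840": "MUT"},
         dict(intron2=4, intron6=4, exon9=4)),
        ({"rs1065852": "MUT"}, dict(intron2=2, intron6=2, exon9=1)),
    ])
    def test_oracle_equivalence_cyp2d6(self, d6_table, gts, calls):
        gts = genotypes(gts)
        vectors = [cnv(**calls)]
        hyp = classify_cnv(vectors)
        cands = enumerate_diplotypes(gts, hyp, d6_table)
        assert {c.diplotype.format() for c in cands} == \
            oracle_enumerate(gts, vectors, d6_table, Gene.CYP2D6)


# ------------------------------------------------------- amplicon logic --

AMPLICON_PANEL_SITES = ["31G>A", "100C>T", "124G>A", "137_138insT", "882G>C",
                  "1660G>A", "1708delT", "1847G>A", "2550delA", "2851C>T",
                  "2936A>C", "2989G>A", "3184G>A", "4181G>C"]


def amplicon(overrides):
    base = {s: "WT" for s in AMPLICON_PANEL_SITES}
    base.update(overrides)
    return [SiteGenotype(s, parse_category(c)) for s, c in base.items()]


class TestMatchAmplicon:
    def test_sample1_pattern_matches_eu093102(self, d6_table):
        calls = amplicon({"31G>A": "MUT", "137_138insT": "MUT",
                          "4181G>C": "MUT", "2989G>A": "LOW SIGNAL"})
        assert match_amplicon(calls, d6_table) == ["*13[EU093102]"]

    def test_sample3_pattern_matches_gq162807(self, d6_table):
        calls = amplicon({"31G>A": "MUT", "137_138insT": "MUT",
                          "2851C>T": "MUT", "4181G>C": "MUT"})
        assert match_amplicon(calls, d6_table) == ["*13[GQ162807]"]

    def test_all_wt_amplicon_matches_reference_first(self, d6_table):
        calls = amplicon({})
        result = match_amplicon(calls, d6_table)
        assert result[0] == "*1"

    def test_het_calls_raise_mixed_amplicon_error(self, d6_table):
        calls = amplicon({"2851C>T": "HET"})
        with pytest.raises(MixedAmpliconError, match="detect_mixed_amplicon"):
            match_amplicon(calls, d6_table)


class TestDetectMixedAmplicon:
    def test_het_downstream_of_intron2_bounds_the_switch(self, d6_table):
        calls = amplicon({"2851C>T": "HET", "2989G>A": "HET",
                          "4181G>C": "HET"})
        boundary = detect_mixed_amplicon(calls)
        assert boundary is not None
        assert boundary.first_het_site == "2851C>T"
        assert resolve_site(boundary.last_clean_site, Gene.CYP2D6).position < \
            resolve_site("2851C>T", Gene.CYP2D6).position

    def test_no_het_returns_none(self, d6_table):
        assert detect_mixed_amplicon(amplicon({})) is None

    def test_het_from_the_start_has_open_upstream_bound(self, d6_table):
        calls = [SiteGenotype(s, Category.HET) for s in AMPLICON_PANEL_SITES]
        boundary = detect_mixed_amplicon(calls)
        assert boundary.last_clean_site is None
        assert boundary.first_het_site == "31G>A"


# ------------------------------------------------------- activity score --

class TestActivityScore:
    @pytest.mark.parametrize("text,score,pheno", [
        ("*13/*13", 0.0, Phenotype.PM),
        ("*1/*1", 2.0, Phenotype.NM),
        ("*41x3/*1", 1.75, Phenotype.NM),
        ("*4/*5", 0.0, Phenotype.PM),
        ("*1/*41", 1.25, Phenotype.NM),
        ("*4/*41", 0.25, Phenotype.IM),
        ("*1x3/*2", 4.0, Phenotype.UM),
        ("*13 + *4/*5", 0.0, Phenotype.PM),
    ])
    def test_cyp2d6_scores_and_phenotypes(self, d6_table, text, score, pheno):
        result = activity_score(parse_diplotype(text, d6_table))
        assert result.score == pytest.approx(score)
        assert result.phenotype is pheno

    @pytest.mark.parametrize("text,pheno", [
        ("*2/*2", Phenotype.PM), ("*1/*2", Phenotype.IM),
        ("*1/*1", Phenotype.NM), ("*1/*17", Phenotype.UM),
        ("*2/*17", Phenotype.IM),
    ])
    def test_cyp2c19_phenotypes(self, c19_table, text, pheno):
        result = activity_score(parse_diplotype(text, c19_table))
        assert result.phenotype is pheno

    def test_uncertain_activity_is_indeterminate(self, d6_table):
        result = activity_score(parse_diplotype("*25/*1", d6_table))
        assert result.score is None
        assert result.phenotype is Phenotype.INDETERMINATE

    def test_score_table_override(self, d6_table):
        result = activity_score(parse_diplotype("*25/*1", d6_table),
                                score_table={"*25": 1.0})
        assert result.score == 2.0
        assert result.phenotype is Phenotype.NM
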