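import pytest

from starcall.cnv import CnvProbeVector
from starcall.consensus import (
    DELETION_PRESENT, ConcordanceCell, ConsensusResult, PlatformCall,
    collapse_call, concordance_table, derive_consensus, revision_report,
)
from starcall.diplotypes import parse_diplotype
from starcall.observations import Category, ObservationSet, PlatformObservation
from starcall.panels import panel_of
from starcall.sites import Gene, ProbeRegion as R


def obs(sample, gene, platform, snv=None, cnv_calls=None, constraints=()):
    o = ObservationSet(sample, gene,
                       structural_constraints=frozenset(constraints))
    vector = None
    if cnv_calls:
        vector = CnvProbeVector({R(k): v for k, v in cnv_calls.items()},
                                {}, platform)
    o.platforms[platform] = PlatformObservation(
        platform, gene, {k: Category(v) for k, v in (snv or {}).items()},
        vector)
    return o


class TestCollapse:
    def test_star17_vanishes_on_amplichip(self, c19_table):
        panel = panel_of("AmpliChip", Gene.CYP2C19)
        result = collapse_call(parse_diplotype("*1/*17", c19_table), panel,
                               c19_table)
        assert result.diplotype == parse_diplotype("*1/*1", c19_table)

    def test_covered_diplotype_is_unchanged(self, c19_table):
        for name in ("AmpliChip", "LuminexXTAGv3", "Agena"):
            panel = panel_of(name, Gene.CYP2C19)
            d = parse_diplotype("*2/*2", c19_table)
            assert collapse_call(d, panel, c19_table).diplotype == d

    def test_hybrid_tandem_is_unrepresentable_on_amplichip(self, d6_table):
        panel = panel_of("AmpliChip", Gene.CYP2D6)
        result = collapse_call(parse_diplotype("*13 + *2/*1", d6_table), panel,
                               d6_table)
        assert result.unrepresentable
        assert any(f.startswith("hybrid_dropped") for f in result.flags)
        # the fallback is what the platform would actually report
        assert result.diplotype == parse_diplotype("*2/*1", d6_table)

    def test_deletion_blind_panel_reports_pseudo_homozygote(self, d6_table):
        panel = panel_of("AmpliChip", Gene.CYP2D6)
        result = collapse_call(parse_diplotype("*13 + *4/*5", d6_table), panel,
                               d6_table)
        assert result.diplotype == parse_diplotype("*4/*4", d6_table)
        assert "deletion_masked" in result.flags

    def test_suballele_collapses_to_core_star(self, c19_table):
        panel = panel_of("Agena", Gene.CYP2C19)  # covers *2, not *2.002
        result = collapse_call(parse_diplotype("*1/*2.002", c19_table), panel,
                               c19_table)
        assert result.diplotype == parse_diplotype("*1/*2", c19_table)

    def test_collapse_is_idempotent(self, d6_table, c19_table):
        cases = [(d6_table, "AmpliChip", "*13 + *4/*5"),
                 (d6_table, "PharmacoScan", "*13/*1"),
                 (d6_table, "TaqMan", "*2.001/*41"),
                 (c19_table, "AmpliChip", "*2/*17"),
                 (c19_table, "Agena", "*1/*2.002")]
        for table, platform, text in cases:
            panel = panel_of(platform, table.gene)
            once = collapse_call(parse_diplotype(text, table), panel, table)
            twice = collapse_call(once.diplotype, panel, table)
            assert twice.diplotype == once.diplotype


class TestDeriveConsensus:
    def test_agreement_passes_through(self, c19_table):
        observations = obs("S1", Gene.CYP2C19, "LuminexXTAGv3",
                           snv={"rs4244285": "HET", "rs12248560": "WT",
                                "rs4986893": "WT", "rs28399504": "WT",
                                "rs41291556": "WT", "rs72552267": "WT",
                                "rs72558186": "WT", "rs17884712": "WT",
                                "rs6413438": "WT", "rs56337013": "WT",
                                "rs12769205": "WT"})
        d = parse_diplotype("*1/*2", c19_table)
        calls = [PlatformCall("S1", "LuminexXTAGv3", Gene.CYP2C19, d),
                 PlatformCall("S1", "Agena", Gene.CYP2C19, d)]
        result = derive_consensus(calls, observations, c19_table)
        assert result.consensus == d
        assert set(result.contributing_platforms) == {"LuminexXTAGv3", "Agena"}

    def test_hybrid_deduction_from_conflicting_platforms(self, d6_table):
        """A hybrid-blind *4/*4, a no-call with *4/UNK alternatives, a
        rising CNV vector and phasing showing a deletion in trans resolve
        to the hybrid tandem over the deletion."""
        observations = obs("S1", Gene.CYP2D6, "TaqMan",
                           snv={"rs3892097": "MUT"},
                           cnv_calls={"intron2": 1, "intron6": 2, "exon9": 2},
                           constraints=[DELETION_PRESENT])
        calls = [
            PlatformCall("S1", "AmpliChip", Gene.CYP2D6,
                         parse_diplotype("*4/*4", d6_table)),
            PlatformCall("S1", "PharmacoScan", Gene.CYP2D6, None,
                         alternatives=("*4/UNK", "*4.009/UNK")),
        ]
        result = derive_consensus(calls, observations, d6_table)
        assert result.consensus == parse_diplotype("*13 + *4/*5", d6_table)
        assert set(result.contributing_platforms) == {"AmpliChip", "PharmacoScan"}

    def test_incompatible_equal_tier_calls_stay_unresolved(self, c19_table):
        observations = obs("S1", Gene.CYP2C19, "LuminexXTAGv3",
                           snv={"rs4244285": "HET"})
        calls = [PlatformCall("S1", "LuminexXTAGv3", Gene.CYP2C19,
                              parse_diplotype("*1/*2", c19_table)),
                 PlatformCall("S1", "Agena", Gene.CYP2C19,
                              parse_diplotype("*2/*2", c19_table))]
        result = derive_consensus(calls, observations, c19_table)
        assert not result.resolved
        assert result.consensus is None


class TestConcordance:
    def consensus_fixture(self, c19_table, n, genotype="*1/*1"):
        return [ConsensusResult(f"S{i}", parse_diplotype(genotype, c19_table),
                                (), (), (), ()) for i in range(n)]

    def test_cell_formatting_matches_printed_tables(self):
        assert ConcordanceCell(42, 43).format(44).startswith("97.7 (42/43)")
        assert ConcordanceCell(40, 42).format(44) == "95.2 (40/42)"
        assert ConcordanceCell(22, 22).format(24) == "100 (22/22)"
        assert ConcordanceCell(16, 16).format(16) == "100"

    def test_no_calls_stay_in_the_denominator(self, c19_table):
        results = self.consensus_fixture(c19_table, 43)
        d = parse_diplotype("*1/*1", c19_table)
        calls = [PlatformCall(f"S{i}", "AmpliSeq", Gene.CYP2C19, d)
                 for i in range(42)]
        calls.append(PlatformCall("S42", "AmpliSeq", Gene.CYP2C19, None))
        table = concordance_table(calls, results)
        cell = table.rows["*1/*1"]["AmpliSeq"]
        assert (cell.concordant, cell.assayed) == (42, 43)
        assert cell.percent == pytest.approx(97.7, abs=0.05)

    def test_full_concordance_is_100(self, c19_table):
        results = self.consensus_fixture(c19_table, 5)
        d = parse_diplotype("*1/*1", c19_table)
        calls = [PlatformCall(f"S{i}", "Agena", Gene.CYP2C19, d)
                 for i in range(5)]
        cell = concordance_table(calls, results).rows["*1/*1"]["Agena"]
        assert cell.percent == 100.0
        assert cell.format(5) == "100"

    def test_percentages_bounded_and_100_only_when_perfect(self, c19_table):
        results = self.consensus_fixture(c19_table, 10)
        d_ok = parse_diplotype("*1/*1", c19_table)
        d_bad = parse_diplotype("*1/*2", c19_table)
        calls = [PlatformCall(f"S{i}", "Agena", Gene.CYP2C19,
                              d_ok if i % 3 else d_bad) for i in range(10)]
        cell = concordance_table(calls, results).rows["*1/*1"]["Agena"]
        assert 0 <= cell.percent <= 100
        assert cell.percent < 100

    def test_call_without_consensus_is_an_error(self, c19_table):
        with pytest.raises(ValueError, match="no consensus"):
            concordance_table(
                [PlatformCall("SX", "Agena", Gene.CYP2C19, None)],
                self.consensus_fixture(c19_table, 1))


class TestRevisionReport:
    def result(self, c19_table, sample, text):
        d = parse_diplotype(text, c19_table) if text else None
        return ConsensusResult(sample, d, (), (), (), ())

    def test_identical_prior_and_consensus_changes_nothing(self, c19_table):
        prior = {"S0": parse_diplotype("*1/*1", c19_table)}
        report = revision_report(prior, [self.result(c19_table, "S0", "*1/*1")],
                                 gene=Gene.CYP2C19)
        assert report.n_changed == 0
        assert report.n_total == 1

    def test_transition_matrix_sums_to_sample_count(self, c19_table):
        prior = {"S0": parse_diplotype("*1/*1", c19_table),
                 "S1": parse_diplotype("*1/*1", c19_table),
                 "S2": parse_diplotype("*1/*2", c19_table),
                 "S3": parse_diplotype("*2/*2", c19_table)}
        consensus = [self.result(c19_table, "S0", "*1/*17"),  # NM -> UM
                     self.result(c19_table, "S1", "*1/*1"),
                     self.result(c19_table, "S2", "*2/*2"),   # IM -> PM
                     self.result(c19_table, "S3", "*2/*2")]
        report = revision_report(prior, consensus, gene=Gene.CYP2C19)
        assert report.n_changed == 2
        assert sum(report.transitions.values()) == 4
        assert report.transitions[("NM", "UM")] == 1
        assert report.transitions[("IM", "PM")] == 1

    def test_prior_nocall_gaining_a_genotype_counts_as_changed(self, d6_table):
        prior = {"S0": None}
        consensus = [ConsensusResult(
            "S0", parse_diplotype("*13/*1", d6_table), (), (), (), ())]
        report = revision_report(prior, consensus, gene=Gene.CYP2D6)
        assert report.n_changed == 1
        assert report.transitions[("indeterminate", "IM")] == 1

    def test_mismatched_sample_sets_rejected(self, c19_table):
        with pytest.raises(ValueError):
            revision_report({"S0": None},
                            [self.result(c19_table, "S1", "*1/*1")],
                            gene=Gene.CYP2C19)
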