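"""Cohort screening arithmetic, the rule-table classifier, reporting."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import triomap as tm
from triomap.classify import (EvidenceProfile, RuleTable, classify,
                              classify_case_variant_table, count_homozygotes, read_report,
                              report, screen_cohorts, write_report)
from triomap.datamodel import CohortCounts

from oracles import allele_frequency_exact

GRID1 = "28:40526902:G:T"
TYR = "29:6343738:G:A"
NSMF = "NSMF:case3"


@pytest.fixture(scope="module")
def case_variant_table():
    return tm.load_case_variant_counts()


class TestScreenCohorts:
    def test_grid1_simmental_allele_frequency(self, case_variant_table):
        """Combined WGS + array Simmental cohorts, case included."""
        s = screen_cohorts(GRID1, case_variant_table, breed="Simmental", include_case=True)
        assert round(s.allele_frequency, 4) == 0.0187
        assert s.breed_specific

    def test_tyr_absent_from_genotyped_simmental(self, case_variant_table):
        s = screen_cohorts(TYR, case_variant_table,
                           populations=["Simmental_array"])
        assert s.n_varvar == 0 and s.n_refvar == 0
        assert s.n_refref >= 1200
        assert s.allele_frequency == 0.0

    def test_all_ref_population_frequency_zero(self):
        df = pd.DataFrame([{"variant_id": "v", "population": "b_wgs",
                            "n_varvar": 0, "n_refvar": 0, "n_refref": 10,
                            "includes_case": 0}])
        s = screen_cohorts("v", CohortCounts(df))
        assert s.allele_frequency == 0.0

    def test_zero_total_rejected(self):
        df = pd.DataFrame([{"variant_id": "v", "population": "b_wgs",
                            "n_varvar": 0, "n_refvar": 0, "n_refref": 0,
                            "includes_case": 0}])
        with pytest.raises(tm.TriomapError):
            screen_cohorts("v", CohortCounts(df))

    @given(st.integers(0, 50), st.integers(0, 500), st.integers(0, 5000))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_matches_exact_rational_formula(self, vv, rv, rr):
        if vv + rv + rr == 0:
            return
        df = pd.DataFrame([{"variant_id": "v", "population": "b_wgs",
                            "n_varvar": vv, "n_refvar": rv, "n_refref": rr,
                            "includes_case": 0}])
        s = screen_cohorts("v", CohortCounts(df))
        assert s.allele_frequency == pytest.approx(
            float(allele_frequency_exact(vv, rv, rr)), rel=1e-12)

    def test_frequency_invariant_to_population_splitting(self, case_variant_table):
        """Splitting a population's counts into sub-cohorts is neutral."""
        row = case_variant_table.rows(GRID1, ["Simmental_array"]).iloc[0]
        merged = pd.DataFrame([row])
        split = pd.DataFrame([
            {**row, "n_varvar": 0, "n_refvar": 10, "n_refref": 300,
             "population": "Simmental_arrayA"},
            {**row, "n_varvar": 0, "n_refvar": row.n_refvar - 10,
             "n_refref": row.n_refref - 300, "population": "Simmental_arrayB"},
        ])
        f1 = screen_cohorts(GRID1, CohortCounts(merged)).allele_frequency
        f2 = screen_cohorts(GRID1, CohortCounts(split)).allele_frequency
        assert f1 == pytest.approx(f2)


class TestCountHomozygotes:
    def test_nsmf_noncase_simmental_homozygotes(self, case_variant_table):
        assert count_homozygotes(NSMF, case_variant_table, breed="Simmental",
                                 exclude_case=True) == 3

    def test_grid1_no_additional_homozygotes(self, case_variant_table):
        assert count_homozygotes(GRID1, case_variant_table, breed="Simmental",
                                 exclude_case=True) == 0

    def test_equals_hand_summation(self, case_variant_table):
        for vid in case_variant_table.variant_ids():
            sub = case_variant_table.df[case_variant_table.df.variant_id == vid]
            expected = int(sub.n_varvar.sum()) - int(sub.includes_case.sum())
            assert count_homozygotes(vid, case_variant_table, exclude_case=True) == expected


class TestClassifier:
    def test_candidate_gene_full_evidence_is_pathogenic(self):
        profile = EvidenceProfile(votes=5, known_candidate_gene=True,
                                  segregation_consistent=True,
                                  control_hom_count=0, breed_specific=True)
        cls = classify(profile)
        assert cls.label == "likely_pathogenic"
        assert "gene:known_candidate" in cls.fired_rules

    def test_no_votes_with_unaffected_homozygotes_is_benign(self):
        profile = EvidenceProfile(votes=0, known_candidate_gene=False,
                                  segregation_consistent=True,
                                  control_hom_count=3)
        assert classify(profile).label == "likely_benign"

    def test_unscorable_lof_with_carrier_in_controls_is_uncertain(self):
        """A frameshift (no predictor votes, one outside homozygote) stays
        a variant of uncertain significance."""
        profile = EvidenceProfile(votes=0, known_candidate_gene=False,
                                  segregation_consistent=True,
                                  control_hom_count=1, loss_of_function=True)
        assert classify(profile).label == "uncertain_significance"

    def test_votes_exceeding_tool_count_rejected(self):
        profile = EvidenceProfile(votes=6, known_candidate_gene=False,
                                  segregation_consistent=True,
                                  control_hom_count=0)
        with pytest.raises(tm.TriomapError):
            classify(profile)

    _profiles = st.builds(
        EvidenceProfile,
        votes=st.integers(0, 5),
        known_candidate_gene=st.booleans(),
        segregation_consistent=st.booleans(),
        control_hom_count=st.integers(0, 10),
        control_het_count=st.integers(0, 100),
        breed_specific=st.booleans(),
        loss_of_function=st.booleans())

    RANK = {"likely_benign": 0, "uncertain_significance": 1,
            "likely_pathogenic": 2}

    @given(_profiles)
    @settings(deadline=None, derandomize=True, max_examples=300)
    def test_monotone_in_votes_and_homozygote_count(self, profile):
        """More in-silico support or fewer unaffected homozygotes never
        moves the label toward benign."""
        base = self.RANK[classify(profile).label]
        if profile.votes < 5:
            up = EvidenceProfile(**{**vars(profile),
                                    "votes": profile.votes + 1})
            assert self.RANK[classify(up).label] >= base
        if profile.control_hom_count > 0:
            down = EvidenceProfile(**{**vars(profile),
                                      "control_hom_count":
                                      profile.control_hom_count - 1})
            assert self.RANK[classify(down).label] >= base


class TestCaseVariantTableClassification:
    def test_headline_variants(self):
        tab = classify_case_variant_table().set_index("gene")
        assert tab.loc["TYR", "classification"] == "likely_pathogenic"
        assert tab.loc["GRID1", "classification"] == "likely_pathogenic"
        assert tab.loc["RAD54B", "classification"] == "uncertain_significance"
        assert tab.loc["NSMF", "classification"] == "likely_benign"

    def test_label_split(self):
        counts = classify_case_variant_table()["classification"].value_counts()
        assert counts["likely_pathogenic"] == 2
        assert counts["uncertain_significance"] == 5
        assert counts["likely_benign"] == 4


class TestReport:
    def test_empty_candidate_list_is_valid(self, tmp_path):
        df = report([])
        assert len(df) == 0
        write_report(df, tmp_path / "r.tsv", tmp_path / "r.txt")
        assert "0 candidate" in (tmp_path / "r.txt").read_text()

    def test_simulated_run_single_pathogenic_row_and_round_trip(
            self, recessive_sim, tmp_path):
        res = recessive_sim
        ana = tm.run_trio_analysis(res.matrix, res.pedigree, res.evidence,
                                   genome_denominator_bp=res.genome_denominator_bp)
        rep = ana.report
        patho = rep[rep.classification == "likely_pathogenic"]
        truth = res.truth.entries[0]
        assert list(patho.variant_id) == [truth.variant_id]
        assert patho.iloc[0].roh_length_bp > 0
        write_report(rep, tmp_path / "r.tsv", tmp_path / "r.txt")
        back = read_report(tmp_path / "r.tsv")
        pd.testing.assert_frame_equal(back, rep, check_dtype=False)
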