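"""Scoring-engine behaviour: component scores, totals, ranking, properties."""

from __future__ import annotations

import dataclasses
import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from targetrank import (
    CandidateTarget,
    DrugEvidence,
    ExpressionProfile,
    Family,
    Tissue,
    WeightConfig,
    rank_targets,
    score_drug,
    score_essentiality,
    score_expression,
    score_total,
    score_and_rank,
    table2_fixture,
)

from conftest import candidate, drug_evidence
from oracles import drug_score_oracle


@pytest.mark.parametrize(
    "codes, expected",
    [(["L", "B", "K"], 0.3), ([], 0.0), (list("HLBKTOP"), 0.7)],
)
def test_expression_score_counts_tissues_above_threshold(codes, expected):
    profile = ExpressionProfile.from_codes(codes)
    assert score_expression(profile, WeightConfig()) == pytest.approx(expected)


def test_expression_threshold_is_strict():
    profile = ExpressionProfile({Tissue.LIVER: 10.0, Tissue.BRAIN: 10.0001})
    assert score_expression(profile, WeightConfig()) == pytest.approx(0.1)


@pytest.mark.parametrize(
    "essential, w, expected", [(True, 0.1, 0.1), (False, 0.1, 0.0), (True, 0.2, 0.2)]
)
def test_essentiality_score_is_linear_in_weight(essential, w, expected):
    cfg = WeightConfig().replace(w_essential=w)
    assert score_essentiality(essential, cfg) == pytest.approx(expected)


class TestDrugScore:
    def test_stacked_tiers_example(self):
        ev = DrugEvidence(
            drugbank_approved_hits=1,
            ttd_successful_hits=1,
            lead_compound=True,
            chembl_hit=True,
        )
        assert score_drug(ev, Family.KINASE, WeightConfig()) == pytest.approx(4.25)

    def test_no_evidence_scores_zero(self):
        assert score_drug(DrugEvidence(), Family.OTHER, WeightConfig()) == 0.0

    def test_drug_domain_without_lead_scores_fifth_of_unit(self):
        ev = DrugEvidence(drug_domain=True)
        assert score_drug(ev, Family.OTHER, WeightConfig()) == pytest.approx(0.2)

    def test_lead_compound_suppresses_drug_domain_branch(self):
        ev = DrugEvidence(lead_compound=True, drug_domain=True)
        assert score_drug(ev, Family.OTHER, WeightConfig()) == pytest.approx(1.0)

    def test_clinical_only_branch(self):
        ev = DrugEvidence(drugbank_clinical_only=True)
        assert score_drug(ev, Family.OTHER, WeightConfig()) == pytest.approx(0.25)

    def test_ttd_compound_branch_only_without_successful(self):
        cfg = WeightConfig()
        assert score_drug(DrugEvidence(ttd_compound_hits=3), cfg=cfg) == pytest.approx(0.25)
        assert score_drug(
            DrugEvidence(ttd_successful_hits=1, ttd_compound_hits=3), cfg=cfg
        ) == pytest.approx(1.0)

    def test_family_bonus_applies_once_for_gpcr_and_kinase(self):
        ev = DrugEvidence()
        assert score_drug(ev, Family.GPCR, WeightConfig()) == pytest.approx(1.0)
        assert score_drug(ev, Family.KINASE, WeightConfig()) == pytest.approx(1.0)
        assert score_drug(ev, Family.PROTEASE, WeightConfig()) == 0.0

    def test_count_weighted_mode_multiplies_hits(self):
        cfg = WeightConfig().replace(count_weighted=True)
        ev = DrugEvidence(drugbank_approved_hits=3, ttd_successful_hits=2)
        assert score_drug(ev, Family.OTHER, cfg) == pytest.approx(3 + 2)

    @settings(max_examples=300, derandomize=True)
    @given(ev=drug_evidence(), family=st.sampled_from(list(Family)))
    def test_matches_max_branch_oracle_under_defaults(self, ev, family):
        cfg = WeightConfig()
        assert score_drug(ev, family, cfg) == pytest.approx(
            drug_score_oracle(ev, family, cfg), abs=1e-12
        )

    def test_exhaustive_boolean_flag_enumeration_matches_oracle(self):
        """Every combination of the boolean evidence flags and count
        indicators agrees with the brute-force tier enumerator."""
        cfg = WeightConfig()
        bool_fields = [
            "chembl_hit",
            "chembl_druggable",
            "chembl_tractable",
            "drugbank_clinical_only",
            "lead_compound",
            "drug_domain",
        ]
        count_fields = [
            "drugbank_approved_hits",
            "drugbank_experimental_hits",
            "ttd_successful_hits",
            "ttd_compound_hits",
        ]
        n_cases = 0
        for bools in itertools.product([False, True], repeat=len(bool_fields)):
            for counts in itertools.product([0, 1], repeat=len(count_fields)):
                kwargs = dict(zip(bool_fields, bools)) | dict(zip(count_fields, counts))
                if kwargs["drugbank_clinical_only"] and kwargs["drugbank_approved_hits"]:
                    continue  # violates the evidence invariant
                ev = DrugEvidence(**kwargs)
                for family in (Family.OTHER, Family.GPCR):
                    assert score_drug(ev, family, cfg) == pytest.approx(
                        drug_score_oracle(ev, family, cfg), abs=1e-12
                    )
                    n_cases += 1
        # 2^10 flag combinations minus the 2^5 * 2^3 invalid clinical/approved ones
        assert n_cases == 2 * (2**10 - 2**5 * 2**3)


class TestTotalScore:
    @pytest.mark.parametrize(
        "drug, codes, essential, expected",
        [
            (4.22, ["L", "B", "K"], True, 4.62),
            (4.09, ["L", "K", "T"], False, 4.39),
            (4.23, [], True, 4.33),
        ],
    )
    def test_published_top_target_rows(self, drug, codes, essential, expected):
        c = CandidateTarget(
            gene_id="G",
            expression=ExpressionProfile.from_codes(codes),
            essential=essential,
            precomputed_drug_score=drug,
        )
        st_ = score_total(c, WeightConfig())
        assert round(st_.total_score, 2) == pytest.approx(expected)

    @settings(max_examples=300, derandomize=True)
    @given(c=candidate())
    def test_additivity_of_components(self, c):
        st_ = score_total(c, WeightConfig())
        assert st_.total_score - st_.drug_score == pytest.approx(
            st_.essentiality_score + st_.expression_score, abs=1e-9
        )

    @settings(max_examples=300, derandomize=True)
    @given(c=candidate())
    def test_default_upper_bounds(self, c):
        st_ = score_total(c, WeightConfig())
        assert st_.drug_score <= 5.25 + 1e-9
        assert st_.total_score <= 5.25 + 0.7 + 0.1 + 1e-9
        assert 0.0 <= st_.expression_score <= 0.7 + 1e-9

    @settings(max_examples=200, derandomize=True)
    @given(c=candidate(), data=st.data())
    def test_monotone_in_evidence_flags(self, c, data):
        """Turning any single false flag true never decreases the total."""
        base = score_total(c, WeightConfig()).total_score
        flags = [
            f.name
            for f in dataclasses.fields(DrugEvidence)
            if not getattr(c.evidence, f.name)
        ]
        if not flags:
            return
        name = data.draw(st.sampled_from(flags))
        value = True if isinstance(getattr(c.evidence, name), bool) else 1
        if name == "drugbank_clinical_only" and c.evidence.drugbank_approved_hits:
            return  # would violate the evidence invariant
        if name == "drugbank_approved_hits" and c.evidence.drugbank_clinical_only:
            return
        bumped = dataclasses.replace(
            c, evidence=dataclasses.replace(c.evidence, **{name: value})
        )
        assert score_total(bumped, WeightConfig()).total_score >= base - 1e-9

    @settings(max_examples=200, derandomize=True)
    @given(c=candidate(), tissue=st.sampled_from(list(Tissue)))
    def test_monotone_in_expression(self, c, tissue):
        """Raising one tissue across the FPKM threshold never decreases the total."""
        base = score_total(c, WeightConfig()).total_score
        raised = dataclasses.replace(
            c,
            expression=ExpressionProfile(c.expression.fpkm | {tissue: 1000.0}),
        )
        assert score_total(raised, WeightConfig()).total_score >= base - 1e-9


class TestRanking:
    def test_fixture_totals_and_top_rank(self):
        cands, expected = table2_fixture()
        scored = score_and_rank(cands)
        assert scored[0].candidate.gene_id == "XLOC_015532"
        assert scored[0].rank == 1
        by_id = {s.candidate.gene_id: s for s in scored}
        for e in expected:
            assert round(by_id[e.candidate.gene_id].total_score, 2) == pytest.approx(
                e.total_score
            )

    def test_ranks_are_a_permutation_of_1_to_n(self):
        cands, _ = table2_fixture()
        scored = score_and_rank(cands)
        assert sorted(s.rank for s in scored) == list(range(1, 21))

    def test_single_candidate_gets_rank_one(self):
        scored = score_and_rank([CandidateTarget(gene_id="G1")])
        assert scored[0].rank == 1

    def test_full_ties_preserve_input_order(self):
        """Candidates with identical total and drug scores keep input order,
        under every permutation of a small distinguishable set."""
        import itertools as it

        base = [
            CandidateTarget(gene_id=f"G{i}", precomputed_drug_score=2.0)
            for i in range(4)
        ]
        for perm in it.permutations(base):
            scored = score_and_rank(list(perm))
            assert [s.candidate.gene_id for s in scored] == [c.gene_id for c in perm]

    def test_total_ties_break_by_drug_score(self):
        a = CandidateTarget(gene_id="A", precomputed_drug_score=2.0, essential=True)
        b = CandidateTarget(gene_id="B", precomputed_drug_score=2.1)
        # totals: A = 2.1, B = 2.1; drug scores differ
        scored = score_and_rank([a, b])
        assert [s.candidate.gene_id for s in scored] == ["B", "A"]

    def test_random_ranking_matches_sorted_oracle(self):
        rng = random.Random(7)
        cands = [
            CandidateTarget(
                gene_id=f"G{i}",
                precomputed_drug_score=rng.choice([1.0, 2.0, 3.0]),
                essential=rng.random() < 0.5,
            )
            for i in range(50)
        ]
        scored = score_and_rank(cands)
        totals = [s.total_score for s in scored]
        assert totals == sorted(totals, reverse=True)
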