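"""Shared strategies and fixtures for the test suite."""

from __future__ import annotations

import pytest
from hypothesis import strategies as st

from targetrank import (
    CandidateTarget,
    DrugEvidence,
    ExpressionProfile,
    Family,
    Tissue,
    WeightConfig,
)


@pytest.fixture
def default_cfg() -> WeightConfig:
    return WeightConfig()


@st.composite
def drug_evidence(draw) -> DrugEvidence:
    approved = draw(st.integers(min_value=0, max_value=3))
    return DrugEvidence(
        chembl_hit=draw(st.booleans()),
        chembl_druggable=draw(st.booleans()),
        chembl_tractable=draw(st.booleans()),
        drugbank_approved_hits=approved,
        drugbank_experimental_hits=draw(st.integers(min_value=0, max_value=3)),
        drugbank_clinical_only=(approved == 0 and draw(st.booleans())),
        ttd_successful_hits=draw(st.integers(min_value=0, max_value=3)),
        ttd_compound_hits=draw(st.integers(min_value=0, max_value=3)),
        lead_compound=draw(st.booleans()),
        drug_domain=draw(st.booleans()),
    )


@st.composite
def expression_profile(draw) -> ExpressionProfile:
    return ExpressionProfile(
        {
            t: draw(
                st.floats(min_value=0.0, max_value=1000.0, allow_nan=False)
            )
            for t in Tissue
        }
    )


@st.composite
def candidate(draw, gene_id: str | None = None) -> CandidateTarget:
    return CandidateTarget(
        gene_id=gene_id or draw(st.from_regex(r"XLOC_[0-9]{6}", fullmatch=True)),
        annotation=draw(st.text(max_size=10)),
        n_isoforms=draw(st.integers(min_value=1, max_value=12)),
        family=draw(st.sampled_from(list(Family))),
        evidence=draw(drug_evidence()),
        expression=draw(expression_profile()),
        essential=draw(st.booleans()),
    )
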