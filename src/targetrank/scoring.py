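"""Weighted-profile scoring and ranking of candidate drug targets.

The total score of candidate *i* is additive over three components,

    S_total(i) = eps_i + S_drug(i) + E_i

where ``eps_i`` is the essentiality score (a fixed weight if the mouse
ortholog knockout is lethal), ``E_i`` is the tissue-expression score (a
fixed weight per tissue whose FPKM exceeds the threshold), and
``S_drug(i)`` sums the drug-evidence criteria. Expression and essentiality
never enter the drug score.

The drug score combines five structured terms:

* a DrugBank tier — the approved-target weight if any approved-drug hit
  exists, else the clinical-data weight if only clinical data are
  available, else 0;
* a TTD tier — the successful-target weight if any successful-drug hit
  exists, else the compound-target weight if any compound hit exists;
* ChEMBL literature flags — hit, druggable and tractable weights stack,
  scaled by the aggregate ChEMBL weight;
* a lead tier — the lead-compound weight, else the drug-domain weight
  when a drug-binding domain is present without a lead;
* a family bonus, applied at most once, for GPCRs and protein kinases.

Within each tier exactly one branch contributes, so with non-negative
weights every score is monotone in the evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .evidence import (
    CandidateTarget,
    DrugEvidence,
    ExpressionProfile,
    Family,
    WeightConfig,
)

__all__ = [
    "ScoredTarget",
    "score_expression",
    "score_essentiality",
    "score_drug",
    "score_total",
    "rank_targets",
    "score_and_rank",
]


@dataclass(frozen=True)
class ScoredTarget:
    """A candidate with its computed score components and (optional) rank."""

    candidate: CandidateTarget
    essentiality_score: float
    expression_score: float
    drug_score: float
    total_score: float
    rank: int | None = None


def score_expression(profile: ExpressionProfile, cfg: WeightConfig | None = None) -> float:
    """Expression score E: one tissue weight per tissue with FPKM > threshold."""
    cfg = cfg or WeightConfig()
    return cfg.w_fpkm_per_tissue * len(profile.tissues_above(cfg.fpkm_threshold))


def score_essentiality(essential: bool, cfg: WeightConfig | None = None) -> float:
    """Essentiality score eps: the essentiality weight if the flag is set."""
    cfg = cfg or WeightConfig()
    return cfg.w_essential if essential else 0.0


def score_drug(
    ev: DrugEvidence,
    family: Family = Family.OTHER,
    cfg: WeightConfig | None = None,
) -> float:
    """Drug score S_drug from database evidence and family, per the tiers above.

    With ``cfg.count_weighted`` the DrugBank and TTD tiers multiply their
    weight by the hit count instead of treating it as an indicator.
    """
    cfg = cfg or WeightConfig()
    ia, ie = ev.drugbank_approved_hits, ev.drugbank_experimental_hits
    is_, ic = ev.ttd_successful_hits, ev.ttd_compound_hits

    mult = (lambda n: n) if cfg.count_weighted else (lambda n: 1)

    if ia > 0:
        drugbank = cfg.w_drugbank_approved * mult(ia)
    elif ev.drugbank_clinical_only:
        drugbank = cfg.w_drugbank_clinical
    else:
        drugbank = 0.0
    drugbank += cfg.w_drugbank_experimental * mult(ie) * (1 if ie > 0 else 0)

    if is_ > 0:
        ttd = cfg.w_ttd_successful * mult(is_)
    elif ic > 0:
        ttd = cfg.w_ttd_compound * mult(ic)
    else:
        ttd = 0.0

    chembl = cfg.w_chembl * (
        cfg.w_chembl_hit * ev.chembl_hit
        + cfg.w_chembl_druggable * ev.chembl_druggable
        + cfg.w_chembl_tractable * ev.chembl_tractable
    )

    if ev.lead_compound:
        lead = cfg.w_lead_compound
    elif ev.drug_domain:
        lead = cfg.w_drug_domain_no_lead
    else:
        lead = 0.0

    family_bonus = cfg.w_gpcr_or_kinase if family in (Family.GPCR, Family.KINASE) else 0.0

    return drugbank + ttd + chembl + lead + family_bonus


def score_total(c: CandidateTarget, cfg: WeightConfig | None = None) -> ScoredTarget:
    """Score one candidate; rank is left unset.

    If the candidate carries a ``precomputed_drug_score`` it is used as
    S_drug verbatim (the evidence fields are ignored for scoring).
    """
    cfg = cfg or WeightConfig()
    eps = score_essentiality(c.essential, cfg)
    e = score_expression(c.expression, cfg)
    if c.precomputed_drug_score is not None:
        s_drug = float(c.precomputed_drug_score)
    else:
        s_drug = score_drug(c.evidence, c.family, cfg)
    return ScoredTarget(
        candidate=c,
        essentiality_score=eps,
        expression_score=e,
        drug_score=s_drug,
        total_score=eps + s_drug + e,
    )


def rank_targets(targets: Sequence[ScoredTarget]) -> list[ScoredTarget]:
    """Assign ranks 1..N by total score descending.

    Ties on total score are broken by drug score descending, then by input
    order (stable). Every rank 1..N is used exactly once; equal scores do
    not share a rank.
    """
    ordered = sorted(
        targets, key=lambda st: (-st.total_score, -st.drug_score)
    )  # sorted() is stable: input order breaks remaining ties
    return [replace(st, rank=i) for i, st in enumerate(ordered, start=1)]


def score_and_rank(
    candidates: Sequence[CandidateTarget], cfg: WeightConfig | None = None
) -> list[ScoredTarget]:
    """Score every candidate and return the ranked list."""
    cfg = cfg or WeightConfig()
    return rank_targets([score_total(c, cfg) for c in candidates])
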