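"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the drug-score
oracle takes the max over applicable branch weights per evidence tier,
and the AUC oracle counts concordant positive/negative pairs directly.
"""

from __future__ import annotations

from typing import Mapping

from targetrank import DrugEvidence, Family, WeightConfig


def drug_score_oracle(ev: DrugEvidence, family: Family, cfg: WeightConfig) -> float:
    """Max-of-applicable-branch-weights drug score (indicator mode only)."""
    db_branches = [0.0]
    if ev.drugbank_approved_hits > 0:
        db_branches.append(cfg.w_drugbank_approved)
    if ev.drugbank_clinical_only:
        db_branches.append(cfg.w_drugbank_clinical)
    db = max(db_branches)
    if ev.drugbank_experimental_hits > 0:
        db += cfg.w_drugbank_experimental

    ttd_branches = [0.0]
    if ev.ttd_successful_hits > 0:
        ttd_branches.append(cfg.w_ttd_successful)
    if ev.ttd_compound_hits > 0:
        ttd_branches.append(cfg.w_ttd_compound)
    ttd = max(ttd_branches)

    chembl = cfg.w_chembl * (
        cfg.w_chembl_hit * ev.chembl_hit
        + cfg.w_chembl_druggable * ev.chembl_druggable
        + cfg.w_chembl_tractable * ev.chembl_tractable
    )

    lead_branches = [0.0]
    if ev.lead_compound:
        lead_branches.append(cfg.w_lead_compound)
    if ev.drug_domain and not ev.lead_compound:
        lead_branches.append(cfg.w_drug_domain_no_lead)
    lead = max(lead_branches)

    fam = cfg.w_gpcr_or_kinase if family in (Family.GPCR, Family.KINASE) else 0.0
    return db + ttd + chembl + lead + fam


def auc_pairs(scores: Mapping[str, float], positives: set[str]) -> float:
    """Mann-Whitney AUC: fraction of positive/negative pairs ranked correctly,
    ties counted 1/2. O(n_pos * n_neg)."""
    pos = [scores[i] for i in scores if i in positives]
    neg = [scores[i] for i in scores if i not in positives]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
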