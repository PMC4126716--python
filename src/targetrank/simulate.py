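"""Synthetic candidate tables and the packaged worked-example fixture.

The generator emulates the statistical shape of a transcriptome-scale
candidate set: a mixture over seven druggable protein families, sparse
independent drug-evidence flags, per-tissue FPKM drawn from a two-part
model (a Bernoulli "expressed above threshold" indicator and a log-normal
magnitude), and a Bernoulli essentiality flag. It also plants
ortholog-score deltas with a chosen higher/comparable/lower split so that
the cross-species comparison can be exercised with a known ground truth.

The worked-example fixture packages the published top-20 target table:
gene ids, annotations, isoform counts, thresholded tissue sets, printed
drug scores (injected as precomputed drug scores, since the underlying
per-target evidence rows were never published) and essentiality flags
reconstructed from the score arithmetic (the printed totals force every
flag; exactly one of the twenty rows is non-essential).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .evidence import (
    CandidateTarget,
    DrugEvidence,
    ExpressionProfile,
    Family,
    Tissue,
    ValidationError,
    WeightConfig,
    read_candidates,
)
from .scoring import ScoredTarget, score_and_rank

__all__ = [
    "SimulationConfig",
    "simulate_candidates",
    "simulate_ortholog_scores",
    "table2_fixture",
]

# default per-flag probabilities: drug evidence is sparse in a real
# candidate set (most loci have no database support)
_DEFAULT_FLAG_PROBS: dict[str, float] = {
    "chembl_hit": 0.30,
    "chembl_druggable": 0.10,
    "chembl_tractable": 0.15,
    "drugbank_approved": 0.10,
    "drugbank_experimental": 0.10,
    "drugbank_clinical_only": 0.05,
    "ttd_successful": 0.10,
    "ttd_compound": 0.10,
    "lead_compound": 0.10,
    "drug_domain": 0.20,
}

# family mixture loosely matching the relative sizes of the seven
# annotated families in a mammalian transcriptome-wide candidate set
# (kinases and GPCRs largest, neuropeptides smallest)
_DEFAULT_FAMILY_MIX: dict[Family, float] = {
    Family.GPCR: 0.15,
    Family.KINASE: 0.18,
    Family.ION_CHANNEL: 0.08,
    Family.IMMUNE: 0.20,
    Family.NEUROPEPTIDE: 0.02,
    Family.PROTEASE: 0.12,
    Family.NUCLEAR_RECEPTOR: 0.03,
    Family.OTHER: 0.22,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic candidate generator.

    ``p_tissue_expressed`` is the probability that a tissue's FPKM exceeds
    the threshold; above-threshold magnitudes are threshold + LogNormal
    (``lognorm_mu``, ``lognorm_sigma`` on the log scale), below-threshold
    values are uniform on [0, threshold]. ``ortholog_split`` is the planted
    (higher, comparable, lower) fraction triple for ortholog comparisons.
    """

    n_candidates: int = 1000
    seed: int = 0
    family_mix: Mapping[Family, float] = field(
        default_factory=lambda: dict(_DEFAULT_FAMILY_MIX)
    )
    flag_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FLAG_PROBS)
    )
    p_tissue_expressed: float = 0.35
    lognorm_mu: float = 3.0
    lognorm_sigma: float = 1.0
    p_essential: float = 0.25
    fpkm_threshold: float = 10.0
    ortholog_split: tuple[float, float, float] = (0.575, 0.175, 0.25)
    ortholog_delta_scale: float = 0.5

    def __post_init__(self) -> None:
        if self.n_candidates < 0:
            raise ValidationError("n_candidates must be >= 0")
        probs = [self.p_tissue_expressed, self.p_essential, *self.flag_probs.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValidationError("all probabilities must lie in [0, 1]")
        if abs(sum(self.family_mix.values()) - 1.0) > 1e-9:
            raise ValidationError("family mixture proportions must sum to 1")
        if abs(sum(self.ortholog_split) - 1.0) > 1e-9:
            raise ValidationError("ortholog split fractions must sum to 1")


def _draw_evidence(rng: np.random.Generator, p: Mapping[str, float]) -> DrugEvidence:
    flags = {k: bool(rng.random() < p[k]) for k in _DEFAULT_FLAG_PROBS}
    # hit counts: 1 + Poisson extra hits when the tier fires
    def count(flag: bool) -> int:
        return int(1 + rng.poisson(0.5)) if flag else 0

    approved = count(flags["drugbank_approved"])
    # clinical-only is incompatible with an approved hit by definition
    clinical_only = flags["drugbank_clinical_only"] and approved == 0
    return DrugEvidence(
        chembl_hit=flags["chembl_hit"],
        chembl_druggable=flags["chembl_druggable"],
        chembl_tractable=flags["chembl_tractable"],
        drugbank_approved_hits=approved,
        drugbank_experimental_hits=count(flags["drugbank_experimental"]),
        drugbank_clinical_only=clinical_only,
        ttd_successful_hits=count(flags["ttd_successful"]),
        ttd_compound_hits=count(flags["ttd_compound"]),
        lead_compound=flags["lead_compound"],
        drug_domain=flags["drug_domain"],
    )


def _draw_expression(rng: np.random.Generator, cfg: SimulationConfig) -> ExpressionProfile:
    fpkm = {}
    for t in Tissue:
        if rng.random() < cfg.p_tissue_expressed:
            fpkm[t] = cfg.fpkm_threshold + rng.lognormal(cfg.lognorm_mu, cfg.lognorm_sigma)
        else:
            fpkm[t] = rng.uniform(0.0, cfg.fpkm_threshold)
    return ExpressionProfile(fpkm)


def simulate_candidates(cfg: SimulationConfig) -> list[CandidateTarget]:
    """Draw a synthetic candidate table; deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    families = list(cfg.family_mix)
    mix = np.array([cfg.family_mix[f] for f in families], dtype=float)
    mix = mix / mix.sum()
    out: list[CandidateTarget] = []
    for i in range(cfg.n_candidates):
        family = families[int(rng.choice(len(families), p=mix))]
        out.append(
            CandidateTarget(
                gene_id=f"SYN_{i:06d}",
                annotation=f"synthetic candidate {i}",
                n_isoforms=int(1 + rng.poisson(1.2)),
                family=family,
                evidence=_draw_evidence(rng, cfg.flag_probs),
                expression=_draw_expression(rng, cfg),
                essential=bool(rng.random() < cfg.p_essential),
            )
        )
    return out


def simulate_ortholog_scores(
    own: Mapping[str, float], cfg: SimulationConfig
) -> dict[str, float]:
    """Plant ortholog scores realizing ``cfg.ortholog_split`` exactly.

    The first ``round(n * f_higher)`` ids (in map order, after a seeded
    shuffle) get ortholog scores strictly below their own score, the next
    block equal scores, the rest strictly above; at tolerance 0 the
    comparison recovers the planted split exactly (up to rounding of the
    block sizes). Delta magnitudes are Exponential(``ortholog_delta_scale``).
    """
    rng = np.random.default_rng(cfg.seed + 1)
    ids = list(own)
    rng.shuffle(ids)
    n = len(ids)
    f_hi, f_cmp, _ = cfg.ortholog_split
    n_hi = round(n * f_hi)
    n_cmp = round(n * f_cmp)
    other: dict[str, float] = {}
    for j, i in enumerate(ids):
        gap = float(rng.exponential(cfg.ortholog_delta_scale)) + 1e-6
        if j < n_hi:
            other[i] = own[i] - gap
        elif j < n_hi + n_cmp:
            other[i] = own[i]
        else:
            other[i] = own[i] + gap
    return other


def table2_fixture() -> tuple[list[CandidateTarget], list[ScoredTarget]]:
    """The packaged top-20 worked example.

    Returns the 20 candidates (printed drug scores injected as
    ``precomputed_drug_score``, essentiality reconstructed from the score
    arithmetic) together with the expected scored-and-ranked list whose
    totals and ranks match the published table.
    """
    resource = importlib.resources.files("targetrank").joinpath("data/table2_top20.tsv")
    with importlib.resources.as_file(resource) as p:
        candidates = read_candidates(p, dialect="codes")
        expected_df = pd.read_csv(p, sep="\t", keep_default_na=False)

    scored = score_and_rank(candidates, WeightConfig())
    by_id = {st.candidate.gene_id: st for st in scored}
    expected = [
        ScoredTarget(
            candidate=by_id[row.gene_id].candidate,
            essentiality_score=by_id[row.gene_id].essentiality_score,
            expression_score=by_id[row.gene_id].expression_score,
            drug_score=float(row.drug_score),
            total_score=float(row.expected_total),
            rank=int(row.expected_rank),
        )
        for row in expected_df.itertuples()
    ]
    return candidates, expected
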