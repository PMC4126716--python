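"""Evaluation of target rankings: ROC/AUC and cross-species score comparison.

A ranking is assessed two ways. First, against a reference positive list
(e.g. known DrugBank targets) with a receiver operating characteristic:
the score threshold is swept over the observed values and the area under
the curve is computed by the trapezoidal rule, which for a step-function
ROC equals the Mann-Whitney pair statistic (ties counted 1/2). Second,
per-target drug scores are compared with those of orthologs in a
comparator species (e.g. mouse or human), classifying each shared target
as higher, comparable or lower within a stated tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_curve

__all__ = ["EvaluationResult", "OrthologComparison", "compute_roc", "compare_orthologs"]


class EvaluationError(ValueError):
    """The evaluation is undefined for the given inputs."""


@dataclass(frozen=True)
class EvaluationResult:
    """ROC points, AUC and the problem sizes they were computed over."""

    auc: float
    roc_points: tuple[tuple[float, float], ...]
    n_candidates: int
    n_positives: int


@dataclass(frozen=True)
class OrthologComparison:
    """Score deltas vs a comparator species and their higher/comparable/lower split.

    ``deltas`` maps each shared target id to own score minus ortholog score.
    A target counts as *higher* when its delta exceeds ``tolerance``, *lower*
    when it is below ``-tolerance``, and *comparable* otherwise; the three
    fractions are over the shared-id set and sum to 1.
    """

    deltas: Mapping[str, float]
    fraction_higher: float
    fraction_comparable: float
    fraction_lower: float
    tolerance: float
    n_shared: int = field(default=0)


def compute_roc(scores: Mapping[str, float], positives: set[str]) -> EvaluationResult:
    """ROC curve and AUC of a score map against a reference positive set.

    Parameters
    ----------
    scores
        Candidate id -> score; higher scores should indicate positives.
    positives
        The reference standard; must be a non-empty proper subset of the
        scored ids.

    Raises
    ------
    EvaluationError
        if there are no positives, no negatives, or ids outside ``scores``.
    """
    ids = list(scores)
    unknown = set(positives) - set(ids)
    if unknown:
        raise EvaluationError(f"positive id(s) not in scores: {sorted(unknown)[:5]}")
    y = np.array([i in positives for i in ids], dtype=int)
    s = np.array([scores[i] for i in ids], dtype=float)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(ids):
        raise EvaluationError(
            "AUC is undefined: need at least one positive and one negative"
        )
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return EvaluationResult(
        auc=auc,
        roc_points=tuple(zip(fpr.tolist(), tpr.tolist())),
        n_candidates=len(ids),
        n_positives=n_pos,
    )


def compare_orthologs(
    own: Mapping[str, float], other: Mapping[str, float], tolerance: float = 0.05
) -> OrthologComparison:
    """Compare per-target scores with their orthologs in another species.

    Only ids present in both maps are compared (the orthology mapping is
    assumed already applied, i.e. shared ids pair orthologous genes).

    Raises
    ------
    EvaluationError
        if the maps share no ids or ``tolerance`` is negative.
    """
    if tolerance < 0:
        raise EvaluationError(f"tolerance must be >= 0, got {tolerance}")
    shared = [i for i in own if i in other]
    if not shared:
        raise EvaluationError("no shared ids between the two score maps")
    deltas = {i: own[i] - other[i] for i in shared}
    n = len(shared)
    n_higher = sum(d > tolerance for d in deltas.values())
    n_lower = sum(d < -tolerance for d in deltas.values())
    n_comparable = n - n_higher - n_lower
    return OrthologComparison(
        deltas=deltas,
        fraction_higher=n_higher / n,
        fraction_comparable=n_comparable / n,
        fraction_lower=n_lower / n,
        tolerance=tolerance,
        n_shared=n,
    )
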