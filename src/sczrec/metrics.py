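"""Evaluation metrics: RMSE, MAP@3, overlap and coverage.

"Relevant" arms for MAP@3 are treatments the patient actually received
whose observed affinity exceeds 0.5; consultations with no relevant arm are
skipped (average precision is undefined there) and counted separately.
Overlap is the fraction of consultations whose actually prescribed therapy
appears in the top-3 list; coverage is its complement.
"""

from __future__ import annotations

import numpy as np

from .errors import EmptyPairsError, NoEvaluableConsultationError


def rmse(predicted, observed) -> float:
    """Root-mean-square error between paired predictions and observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted/observed length mismatch")
    if predicted.size == 0:
        raise EmptyPairsError("RMSE of zero pairs")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def average_precision_at_3(ranked: list[str], relevant: set[str]) -> float:
    """AP@3 = sum_{k<=3} precision@k * rel(k) / min(3, |relevant|)."""
    if not relevant:
        raise NoEvaluableConsultationError("AP undefined for an empty relevant set")
    top = list(ranked[:3])
    hits = 0
    score = 0.0
    for k, arm in enumerate(top, start=1):
        if arm in relevant:
            hits += 1
            score += hits / k
    return score / min(3, len(relevant))


def map_at_3(
    ranked_lists: list[list[str]],
    relevant_sets: list[set[str]],
) -> tuple[float, int, int]:
    """Mean AP@3 over consultations with a non-empty relevant set.

    Returns (MAP@3, n_evaluated, n_skipped). Raises when nothing is
    evaluable.
    """
    if len(ranked_lists) != len(relevant_sets):
        raise ValueError("ranked/relevant length mismatch")
    scores = []
    skipped = 0
    for ranked, relevant in zip(ranked_lists, relevant_sets):
        if not relevant:
            skipped += 1
            continue
        scores.append(average_precision_at_3(ranked, relevant))
    if not scores:
        raise NoEvaluableConsultationError("every consultation had an empty relevant set")
    return float(np.mean(scores)), len(scores), skipped


def overlap_and_coverage(
    top3_lists: list[list[str]],
    actual_therapies: list[str],
) -> tuple[float, float]:
    """(overlap, coverage = 1 - overlap), computed exactly."""
    if len(top3_lists) != len(actual_therapies):
        raise ValueError("length mismatch")
    if not actual_therapies:
        raise EmptyPairsError("overlap of zero consultations")
    hits = sum(1 for top3, actual in zip(top3_lists, actual_therapies) if actual in top3)
    overlap = hits / len(actual_therapies)
    return overlap, 1.0 - overlap
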