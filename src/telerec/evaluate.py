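"""Evaluation surface: Pre@N / Rec@N, relevance, activity, rationality scoring.

A recommended specialist counts as correct when their expertise labels
intersect the target patient's disease labels. Precision and recall at
N follow the usual confusion-matrix definitions; relevance is the mean
cosine similarity between the target EMR vector and each recommended
specialist's aggregate document vector; the rationality score combines
a rank prior with mean human ratings of each slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .patient_model import DocVector, cosine_similarity


@dataclass
class EvalResult:
    n: int
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    mean_relevance: float | None = None
    mean_activity: float | None = None


def correctness(recommended: Sequence[str], target_labels: set[str],
                profiles: Mapping[str, set[str]]) -> list[bool]:
    """Per-item flags: true iff the specialist's labels meet the target's."""
    flags = []
    for sid in recommended:
        if sid not in profiles:
            raise KeyError(f"no profile labels for specialist {sid!r}")
        flags.append(bool(target_labels & profiles[sid]))
    return flags


def precision_recall_at_n(correct_flags: Sequence[bool],
                          total_relevant: int) -> EvalResult:
    n = len(correct_flags)
    tp = sum(bool(f) for f in correct_flags)
    if total_relevant < tp:
        raise ValueError(f"total_relevant={total_relevant} smaller than tp={tp}")
    fp = n - tp
    fn = total_relevant - tp
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    return EvalResult(n, tp, fp, fn, precision, recall)


def relevance(recommended: Sequence[DocVector], target: DocVector) -> float:
    """Mean cosine similarity of recommended specialists' vectors to the target."""
    if not recommended:
        raise ValueError("empty recommendation list")
    return float(np.mean([cosine_similarity(r.vector, target.vector)
                          for r in recommended]))


@dataclass
class RationalityScore:
    rank: int                   # 0-based position in the list
    prior: float
    ratings: list[int] = field(default_factory=list)
    score_r: float = 0.0


def rationality(rank_ratings: Sequence[Sequence[int]], list_size: int = 10,
                normalized_prior: bool = False) -> list[RationalityScore]:
    """Priority-weighted mean rating per list slot.

    prior_r = (list_size - r) / sum_{r=0}^{list_size-1} r, as printed
    in the source formula (for a 10-item list the denominator is 45,
    so the priors do not sum to 1); with ``normalized_prior`` the
    denominator is sum(list_size - r) instead, which does normalize.
    score_r = prior_r * mean(ratings at rank r), ratings on a 1..5 scale.
    """
    if len(rank_ratings) != list_size:
        raise ValueError("one rating list per rank is required")
    denom = (sum(list_size - r for r in range(list_size)) if normalized_prior
             else sum(range(list_size)))
    out = []
    for r, ratings in enumerate(rank_ratings):
        for v in ratings:
            if not 1 <= v <= 5:
                raise ValueError(f"rating {v} outside 1..5")
        prior = (list_size - r) / denom
        mean = sum(ratings) / len(ratings) if ratings else 0.0
        out.append(RationalityScore(r, prior, list(ratings), prior * mean))
    return out
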