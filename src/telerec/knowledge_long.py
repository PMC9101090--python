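"""Long-term specialist knowledge: attribute matrix, imputation, cold-start repair.

A specialist's long-term knowledge is a binary row over disease/
expertise attributes. Missing cells are filled by column frequency:
a cell becomes 1 iff at least half of the observed cells in its column
are 1. Similarity between rows is a weighted Jaccard coefficient, and
newly registered specialists (fewer than three consultations) whose
knowledge view resembles a current candidate's (similarity >= 0.7)
receive an updated recommendation index

    ini_score'_j = ini_score_j + (1/q) * sum_h ini_score_h * SimKnowledge(j, h)

and join the candidate set, mitigating the cold-start problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .patient_model import PROV_COLD_START, CandidateEntry, CandidateSet

COLD_START_THRESHOLD = 0.7
NEWCOMER_MAX_CONSULTATIONS = 3  # strictly fewer than this => newly registered


@dataclass
class KnowledgeMatrix:
    """Binary specialist x attribute expertise matrix with optional missingness.

    ``values`` holds 0.0 / 1.0 with NaN marking missing cells before
    imputation. ``weights`` are per-attribute nonnegative importances
    (uniform by default).
    """

    specialists: list[str]
    attributes: list[str]
    values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.specialists), len(self.attributes)):
            raise ValueError("matrix shape does not match id lists")
        if self.weights is None:
            self.weights = np.ones(len(self.attributes))
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("attribute weights must be nonnegative")
        if self.weights.sum() <= 0:
            raise ValueError("attribute weights must have positive sum")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def row(self, specialist_id: str) -> np.ndarray:
        try:
            return self.values[self.specialists.index(specialist_id)]
        except ValueError:
            raise KeyError(f"specialist {specialist_id!r} not in knowledge matrix")

    @classmethod
    def from_csv(cls, path, weights: Sequence[float] | None = None) -> "KnowledgeMatrix":
        df = pd.read_csv(path, dtype={"specialist_id": str})
        if df.columns[0] != "specialist_id":
            raise ValueError("first column must be specialist_id")
        specialists = df["specialist_id"].tolist()
        attrs = list(df.columns[1:])
        values = df[attrs].to_numpy(dtype=float)  # empty cells -> NaN
        return cls(specialists, attrs, values, weights)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.attributes)
        df.insert(0, "specialist_id", self.specialists)
        # integer-format observed cells, keep missing ones empty
        for a in self.attributes:
            df[a] = df[a].map(lambda v: "" if np.isnan(v) else str(int(v)))
        df.to_csv(path, index=False)


def impute_matrix(matrix: KnowledgeMatrix) -> KnowledgeMatrix:
    """Fill missing cells by the observed column frequency (>= 0.5 -> 1).

    The frequency is taken over observed entries only: counting missing
    cells as zeros would bias filling toward 0, defeating the fairness
    intent of frequency filling. A column with no observations imputes
    to 0 (no evidence of expertise).
    """
    values = matrix.values.copy()
    mask = np.isnan(values)
    for p in range(values.shape[1]):
        col_missing = mask[:, p]
        if not col_missing.any():
            continue
        observed = values[~col_missing, p]
        fill = 1.0 if observed.size and observed.mean() >= 0.5 else 0.0
        values[col_missing, p] = fill
    return KnowledgeMatrix(list(matrix.specialists), list(matrix.attributes),
                           values, matrix.weights.copy())


def rarity_weights(matrix: KnowledgeMatrix) -> np.ndarray:
    """Optional attribute weighting: rarer expertise counts more.

    w_p = ln(n / (1 + sum_j a_jp)) floored at a small positive value.
    """
    if matrix.missing_mask.any():
        raise ValueError("impute the matrix before computing weights")
    n = len(matrix.specialists)
    w = np.log(n / (1.0 + matrix.values.sum(axis=0)))
    return np.maximum(w, 1e-6)


def weighted_jaccard(row_j: np.ndarray, row_h: np.ndarray,
                     weights: np.ndarray) -> float:
    """Weighted Jaccard similarity sum(w*min) / sum(w*max) over binary rows."""
    row_j = np.asarray(row_j, dtype=float)
    row_h = np.asarray(row_h, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (row_j.shape == row_h.shape == weights.shape):
        raise ValueError("rows and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be nonnegative")
    if np.any(np.isnan(row_j)) or np.any(np.isnan(row_h)):
        raise ValueError("rows must be imputed before comparison")
    denom = float(np.sum(weights * np.maximum(row_j, row_h)))
    if denom == 0.0:
        return 0.0  # both rows all-zero
    return float(np.sum(weights * np.minimum(row_j, row_h)) / denom)


@dataclass
class ColdStartUpdate:
    """Audit record of one newly-registered specialist's index update."""

    specialist_id: str
    old_ini_score: float
    similar: list[tuple[str, float, float]] = field(default_factory=list)
    new_ini_score: float = 0.0


def update_cold_start(candidates: CandidateSet, matrix: KnowledgeMatrix,
                      newly_registered: Sequence[str],
                      threshold: float = COLD_START_THRESHOLD,
                      ) -> tuple[CandidateSet, list[ColdStartUpdate]]:
    """Raise newly registered specialists' indices via knowledge similarity.

    For each newly registered specialist j, the candidate-set members h
    with SimKnowledge(j, h) >= threshold contribute; with q >= 1 such
    members, j's index becomes ini_score_j + (1/q) * sum ini_score_h *
    Sim(j, h) and j joins the pool (provenance cold-start). Existing
    members are never removed or down-scored. Returns the re-sorted set
    and the per-newcomer audit trail.
    """
    if matrix.missing_mask.any():
        raise ValueError("knowledge matrix must be imputed before cold-start update")
    out = candidates.copy()
    members = [e for e in candidates.entries]  # similarity pool: incoming members
    updates: list[ColdStartUpdate] = []
    for sid in newly_registered:
        row_j = matrix.row(sid)  # KeyError with the id if absent
        existing = out.get(sid)
        old = existing.ini_score if existing is not None else 0.0
        upd = ColdStartUpdate(sid, old)
        for h in members:
            if h.specialist_id == sid:
                continue
            sim = weighted_jaccard(row_j, matrix.row(h.specialist_id), matrix.weights)
            if sim >= threshold:
                upd.similar.append((h.specialist_id, sim, h.ini_score))
        if upd.similar:
            q = len(upd.similar)
            upd.new_ini_score = old + sum(s * i for _, s, i in upd.similar) / q
            if existing is not None:
                existing.ini_score = upd.new_ini_score
                existing.provenance = PROV_COLD_START
            else:
                out.entries.append(CandidateEntry(sid, upd.new_ini_score,
                                                  PROV_COLD_START))
        else:
            upd.new_ini_score = old
        updates.append(upd)
    return out.sorted_by("ini"), updates


def newly_registered_from_counts(counts: dict[str, int],
                                 max_consultations: int = NEWCOMER_MAX_CONSULTATIONS,
                                 ) -> list[str]:
    """Specialists with fewer than ``max_consultations`` logged consultations."""
    return sorted(sid for sid, c in counts.items() if c < max_consultations)
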