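"""Activity, preference weights, QoS feedback and the fused hybrid ranking.

A specialist's activity is a time-decayed share of platform
consultations, AC_j = sum_t N_j(t) e^{-t} / N(t), normalized by the
most active specialist (LAC_j = AC_j / AC_max). The professional index
is prof_score = LAC * ini_score * short_score. Patients' subjective
preferences (a five-category Likert answer per strategy) fix the fusion
weights, and the objective per-specialist service ratings form a
normalized qos_score; the final ranking follows

    compre_score = w_p * prof_score' + w_q * qos_score,

with prof_score' normalized by the maximum within the candidate pool.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .patient_model import CandidateSet

DEFAULT_HORIZON = 12        # periods (calendar months) of history considered
DEFAULT_QOS_SCALE = (0.0, 5.0)

# Likert categories -> numbers used to build preference weights
PREFERENCE_SCALE = {
    "extremely like": 4,
    "like": 3,
    "fair": 2,
    "dislike": 1,
    "extremely dislike": 0,
}


# ---------------------------------------------------------------------------
# Activity


@dataclass
class ActivityLedger:
    """Monthly consultation counts per specialist.

    ``counts`` maps (specialist_id, period age t) -> N_j(t), t = 0 for
    the current period. Totals N(t) are derived, so the ledger is
    consistent by construction.
    """

    counts: dict[tuple[str, int], int]
    horizon: int = DEFAULT_HORIZON

    def __post_init__(self):
        for key, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative consultation count for {key}")

    def total(self, t: int) -> int:
        return sum(c for (_, tt), c in self.counts.items() if tt == t)

    def specialists(self) -> list[str]:
        return sorted({sid for sid, _ in self.counts})

    @classmethod
    def from_records(cls, records, horizon: int = DEFAULT_HORIZON,
                     current: datetime.date | None = None) -> "ActivityLedger":
        """Build the ledger from consultation records (period = calendar month)."""
        if current is None:
            current = max(r.date for r in records)
        counts: dict[tuple[str, int], int] = {}
        for r in records:
            t = (current.year - r.date.year) * 12 + (current.month - r.date.month)
            if 0 <= t <= horizon:
                key = (r.specialist_id, t)
                counts[key] = counts.get(key, 0) + 1
        return cls(counts, horizon)


@dataclass
class ActivityScore:
    specialist_id: str
    ac: float
    lac: float | None = None


def activity(ledger: ActivityLedger, specialist_id: str) -> float:
    """AC_j = sum over periods of N_j(t) e^{-t} / N(t)."""
    ac = 0.0
    for t in range(ledger.horizon + 1):
        n_t = ledger.total(t)
        if n_t == 0:
            continue
        n_jt = ledger.counts.get((specialist_id, t), 0)
        ac += n_jt * math.exp(-t) / n_t
    return ac


def activity_scores(ledger: ActivityLedger,
                    specialists: Sequence[str] | None = None) -> list[ActivityScore]:
    ids = list(specialists) if specialists is not None else ledger.specialists()
    return [ActivityScore(sid, activity(ledger, sid)) for sid in ids]


def normalized_activity(scores: Sequence[ActivityScore]) -> list[ActivityScore]:
    """LAC_j = AC_j / AC_max; the most active specialist gets 1."""
    ac_max = max((s.ac for s in scores), default=0.0)
    if ac_max <= 0.0:
        raise ValueError("no activity signal: all AC values are zero")
    return [replace(s, lac=s.ac / ac_max) for s in scores]


# ---------------------------------------------------------------------------
# Professional score and preference weights


def professional_score(lac: float, ini_score: float, short_score: float) -> float:
    """prof_score = LAC * ini_score * short_score, all components in [0, 1]."""
    for name, v in (("lac", lac), ("ini_score", ini_score),
                    ("short_score", short_score)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return lac * ini_score * short_score


@dataclass(frozen=True)
class PreferenceWeights:
    omega_p: float
    omega_q: float

    def __post_init__(self):
        if not (0.0 <= self.omega_p <= 1.0 and 0.0 <= self.omega_q <= 1.0):
            raise ValueError("preference weights must lie in [0, 1]")
        if abs(self.omega_p + self.omega_q - 1.0) > 1e-9:
            raise ValueError("preference weights must sum to 1")


def preference_weights(prof_choice: str, qos_choice: str) -> PreferenceWeights:
    """Map two Likert answers to fusion weights (a/(a+b), b/(a+b)).

    When both answers map to 0 ("Extremely dislike" twice) the weights
    fall back to (0.5, 0.5) so the fusion constraint still holds.
    """
    def lookup(choice: str) -> int:
        key = choice.strip().lower()
        if key not in PREFERENCE_SCALE:
            raise ValueError(f"unknown preference {choice!r}; valid: "
                             + ", ".join(sorted(PREFERENCE_SCALE)))
        return PREFERENCE_SCALE[key]

    a, b = lookup(prof_choice), lookup(qos_choice)
    if a + b == 0:
        return PreferenceWeights(0.5, 0.5)
    return PreferenceWeights(a / (a + b), b / (a + b))


# ---------------------------------------------------------------------------
# QoS feedback


@dataclass
class QosState:
    """Running objective service-quality feedback for one specialist."""

    specialist_id: str
    ratings: list[float] = field(default_factory=list)
    scale: tuple[float, float] = DEFAULT_QOS_SCALE
    qos_score: float | None = None

    @property
    def qos(self) -> float:
        return sum(self.ratings) / len(self.ratings) if self.ratings else 0.0


def update_qos(state: QosState, new_rating: float) -> QosState:
    """Append a rating; the running qos is the mean over all ratings."""
    lo, hi = state.scale
    if not lo <= new_rating <= hi:
        raise ValueError(f"rating {new_rating} outside scale [{lo}, {hi}]")
    return QosState(state.specialist_id, state.ratings + [new_rating],
                    state.scale, None)


def qos_scores(states: Sequence[QosState]) -> list[QosState]:
    """qos_score_j = qos_j / qos_max over the supplied specialists."""
    qos_max = max((s.qos for s in states), default=0.0)
    if qos_max <= 0.0:
        raise ValueError("no QoS signal: all ratings are zero")
    return [QosState(s.specialist_id, list(s.ratings), s.scale, s.qos / qos_max)
            for s in states]


# ---------------------------------------------------------------------------
# Hybrid ranking


@dataclass
class RecommendationEntry:
    specialist_id: str
    ini_score: float
    short_score: float
    lac: float
    prof_score: float
    prof_score_normalized: float
    qos_score: float
    compre_score: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "specialist_id", "ini_score", "short_score", "lac", "prof_score",
            "prof_score_normalized", "qos_score", "compre_score")}


@dataclass
class Recommendation:
    entries: list[RecommendationEntry]
    weights: PreferenceWeights

    def __len__(self):
        return len(self.entries)

    def ids(self) -> list[str]:
        return [e.specialist_id for e in self.entries]

    def to_json(self) -> dict:
        return {"weights": {"omega_p": self.weights.omega_p,
                            "omega_q": self.weights.omega_q},
                "entries": [e.to_dict() for e in self.entries]}


def hybrid_rank(candidates: CandidateSet,
                activity_by_id: Mapping[str, float],
                qos_by_id: Mapping[str, float],
                weights: PreferenceWeights, n: int = 10) -> Recommendation:
    """Fuse professional and QoS indices and return the top-n breakdown.

    ``activity_by_id`` maps specialist -> LAC, ``qos_by_id`` maps
    specialist -> normalized qos_score. Candidates never compared in
    topic space (short_score unset) are not penalized: their
    short_score is taken as 1. prof_score is normalized by the maximum
    within the candidate pool.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    rows = []
    for e in candidates.entries:
        if e.specialist_id not in activity_by_id:
            raise KeyError(f"no activity score for {e.specialist_id!r}")
        if e.specialist_id not in qos_by_id:
            raise KeyError(f"no qos score for {e.specialist_id!r}")
        short = 1.0 if e.short_score is None else e.short_score
        lac = activity_by_id[e.specialist_id]
        prof = professional_score(lac, min(e.ini_score, 1.0), short)
        rows.append((e, lac, short, prof))
    prof_max = max(r[3] for r in rows)
    entries = []
    for e, lac, short, prof in rows:
        prof_norm = prof / prof_max if prof_max > 0 else 0.0
        qos = qos_by_id[e.specialist_id]
        compre = weights.omega_p * prof_norm + weights.omega_q * qos
        entries.append(RecommendationEntry(
            e.specialist_id, e.ini_score, short, lac, prof, prof_norm, qos, compre))
    entries.sort(key=lambda r: (-r.compre_score, r.specialist_id))
    return Recommendation(entries[:n], weights)
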