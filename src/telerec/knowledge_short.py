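"""Short-term specialist knowledge: Gibbs LDA, perplexity, JS similarity, extension.

Each specialist's recently diagnosed EMRs (concatenated into one
document) are modeled with latent Dirichlet allocation fitted by
collapsed Gibbs sampling. The specialist's document-topic row is their
short-term knowledge profile; profiles are compared with the
Jensen-Shannon divergence (base-2 logs, so D_JS is in [0, 1]) and
similarity = 1 - D_JS. Specialists whose profiles resemble a current
candidate's extend the candidate set at the semantic level, carrying
that similarity as their ``short_score``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._kernels import lda_gibbs
from .patient_model import PROV_TOPIC, CandidateEntry, CandidateSet
from .preprocess import Corpus

logger = logging.getLogger(__name__)

DEFAULT_BETA = 0.01
DEFAULT_ITERATIONS = 500
DEFAULT_MIN_SIM = 0.8
DEFAULT_PER_SEED_CAP = 10


def default_alpha(n_topics: int) -> float:
    """Symmetric document-topic hyperparameter, the common 50/K heuristic."""
    return 50.0 / n_topics


# ---------------------------------------------------------------------------
# Model


@dataclass
class TopicModel:
    """Fitted LDA parameters: smoothed topic-word and doc-topic distributions."""

    n_topics: int
    alpha: float
    beta: float
    topic_word: np.ndarray      # K x V, rows sum to 1
    doc_topic: np.ndarray       # D x K, rows sum to 1
    vocabulary: list[str]
    doc_ids: list[str]
    iterations: int
    seed: int

    @property
    def vocab_index(self) -> dict[str, int]:
        return {w: i for i, w in enumerate(self.vocabulary)}

    def theta(self, doc_id: str) -> np.ndarray:
        return self.doc_topic[self.doc_ids.index(doc_id)]

    def top_words(self, topic: int, n: int = 10) -> list[tuple[str, float]]:
        row = self.topic_word[topic]
        order = np.argsort(-row)[:n]
        return [(self.vocabulary[i], float(row[i])) for i in order]

    def to_json(self, path) -> None:
        payload = {
            "n_topics": self.n_topics, "alpha": self.alpha, "beta": self.beta,
            "iterations": self.iterations, "seed": self.seed,
            "vocabulary": self.vocabulary, "doc_ids": self.doc_ids,
            "topic_word": self.topic_word.tolist(),
            "doc_topic": self.doc_topic.tolist(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "TopicModel":
        with open(path, encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(p["n_topics"], p["alpha"], p["beta"],
                   np.asarray(p["topic_word"]), np.asarray(p["doc_topic"]),
                   p["vocabulary"], p["doc_ids"], p["iterations"], p["seed"])


class GibbsLda(BaseEstimator):
    """LDA fitted by collapsed Gibbs sampling, deterministic under a fixed seed.

    Parameter estimates are taken from the final sweep's counts with
    Dirichlet smoothing: phi = (n_kw + beta) / (n_k + V*beta), theta =
    (n_dk + alpha) / (n_d + K*alpha), so every entry is positive.
    """

    def __init__(self, n_topics: int = 10, alpha: float | None = None,
                 beta: float = DEFAULT_BETA, iterations: int = DEFAULT_ITERATIONS,
                 seed: int = 0):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.iterations = iterations
        self.seed = seed

    def fit(self, docs: Sequence[tuple[str, Sequence[str]]]) -> "GibbsLda":
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if len(docs) < 1:
            raise ValueError("need at least one document")
        vocab: dict[str, int] = {}
        doc_arr: list[int] = []
        word_arr: list[int] = []
        for d, (_, tokens) in enumerate(docs):
            for tok in tokens:
                doc_arr.append(d)
                word_arr.append(vocab.setdefault(tok, len(vocab)))
        if not word_arr:
            raise ValueError("documents contain no tokens")
        alpha = default_alpha(self.n_topics) if self.alpha is None else self.alpha
        ndk, nkw, z = lda_gibbs(
            np.asarray(doc_arr, np.int32), np.asarray(word_arr, np.int32),
            len(docs), len(vocab), self.n_topics, float(alpha), float(self.beta),
            int(self.iterations), int(self.seed) % (2 ** 31))
        if int(ndk.sum()) != len(word_arr):  # sampler must conserve tokens
            raise AssertionError("Gibbs counts out of sync with token count")
        v = len(vocab)
        phi = (nkw + self.beta) / (nkw.sum(axis=1, keepdims=True) + v * self.beta)
        theta = (ndk + alpha) / (ndk.sum(axis=1, keepdims=True) + self.n_topics * alpha)
        self.model_ = TopicModel(self.n_topics, float(alpha), float(self.beta),
                                 phi, theta, list(vocab),
                                 [doc_id for doc_id, _ in docs],
                                 int(self.iterations), int(self.seed))
        self.components_ = phi
        self.doc_topic_ = theta
        self.vocabulary_ = list(vocab)
        self.assignments_ = z
        return self


def fit_lda(docs: Sequence[tuple[str, Sequence[str]]], n_topics: int,
            alpha: float | None = None, beta: float = DEFAULT_BETA,
            iterations: int = DEFAULT_ITERATIONS, seed: int = 0) -> TopicModel:
    est = GibbsLda(n_topics=n_topics, alpha=alpha, beta=beta,
                   iterations=iterations, seed=seed)
    return est.fit(docs).model_


def perplexity(model: TopicModel, docs: Sequence[tuple[str, Sequence[str]]]) -> float:
    """exp(-mean token log-likelihood) with P(w|d) = sum_t P(w|t) P(t|d)."""
    index = model.vocab_index
    log_lik = 0.0
    n_tokens = 0
    for doc_id, tokens in docs:
        theta = model.theta(doc_id)
        pw = theta @ model.topic_word  # P(w | d) over the vocabulary
        for tok in tokens:
            if tok not in index:
                raise KeyError(f"token {tok!r} outside model vocabulary")
            log_lik += np.log(pw[index[tok]])
            n_tokens += 1
    if n_tokens == 0:
        raise ValueError("no tokens to evaluate")
    return float(np.exp(-log_lik / n_tokens))


def topic_count_table(docs: Sequence[tuple[str, Sequence[str]]],
                      k_grid: Sequence[int], seed: int = 0,
                      alpha: float | None = None, beta: float = DEFAULT_BETA,
                      iterations: int = DEFAULT_ITERATIONS,
                      ) -> list[tuple[int, float]]:
    """Fit one model per grid value; return (K, training perplexity) pairs."""
    if not k_grid:
        raise ValueError("empty topic-count grid")
    table = []
    for k in k_grid:
        model = fit_lda(docs, k, alpha=alpha, beta=beta,
                        iterations=iterations, seed=seed)
        table.append((k, perplexity(model, docs)))
    return table


def _elbow(table: Sequence[tuple[int, float]]) -> int:
    """Knee of the perplexity curve: the grid point farthest above the
    chord joining the curve's endpoints (Kneedle construction)."""
    kk = np.asarray([k for k, _ in table], dtype=float)
    pp = np.asarray([p for _, p in table], dtype=float)
    if pp.max() == pp.min():
        return int(kk[0])
    x = (kk - kk[0]) / (kk[-1] - kk[0])
    y = (pp - pp.min()) / (pp.max() - pp.min())
    return int(kk[int(np.argmax((1.0 - x) - y))])


def select_topic_count(docs: Sequence[tuple[str, Sequence[str]]],
                       k_grid: Sequence[int], seed: int = 0,
                       alpha: float | None = None, beta: float = DEFAULT_BETA,
                       iterations: int = DEFAULT_ITERATIONS,
                       method: str = "elbow") -> int:
    """Choose the topic count from the training-perplexity curve.

    Training perplexity decreases (near-)monotonically in K, so the
    default picks the curve's elbow, where adding topics stops paying;
    ``method="min"`` takes the plain minimum instead. Grids too short
    to have an interior elbow (fewer than three points), and exact
    perplexity ties, resolve to the smallest qualifying K.
    """
    if sorted(k_grid) != list(k_grid):
        raise ValueError("topic-count grid must be ascending")
    table = topic_count_table(docs, k_grid, seed, alpha, beta, iterations)
    for k, perp in table:
        logger.info("topic-count selection: K=%d perplexity=%.4f", k, perp)
    if method == "elbow" and len(table) >= 3:
        return _elbow(table)
    best_k, _ = min(table, key=lambda kp: (kp[1], kp[0]))
    return best_k


# ---------------------------------------------------------------------------
# Jensen-Shannon similarity


class ShortScore(NamedTuple):
    djs: float
    similarity: float


def js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """Base-2 Jensen-Shannon divergence, bounded in [0, 1]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have the same length")
    for v in (p, q):
        if np.any(v < 0) or abs(v.sum() - 1.0) > 1e-6:
            raise ValueError("inputs must be probability distributions")
    m = 0.5 * (p + q)

    def kl(a, b):
        nz = a > 0
        return float(np.sum(a[nz] * np.log2(a[nz] / b[nz])))

    return min(0.5 * kl(p, m) + 0.5 * kl(q, m), 1.0)


def js_similarity(p: np.ndarray, q: np.ndarray) -> ShortScore:
    d = js_divergence(p, q)
    return ShortScore(d, 1.0 - d)


# ---------------------------------------------------------------------------
# Specialist profiles and candidate extension


@dataclass
class SpecialistTopicProfile:
    """A specialist's aggregated document-topic distribution."""

    specialist_id: str
    topic_distribution: np.ndarray
    top_words: list[tuple[str, float]]


def specialist_documents(corpus: Corpus) -> list[tuple[str, list[str]]]:
    """Concatenate each specialist's diagnosed EMRs into one training document."""
    grouped: dict[str, list[str]] = {}
    for doc_id, tokens in corpus.documents:
        sid = corpus.doc_meta[doc_id][1]
        grouped.setdefault(sid, []).extend(tokens)
    return sorted(grouped.items())


def specialist_profiles(model: TopicModel,
                        all_specialists: Sequence[str] | None = None,
                        ) -> dict[str, SpecialistTopicProfile]:
    """Profiles from a model fitted on per-specialist documents.

    Specialists without any diagnosed EMR (possible for the newly
    registered) get the symmetric-prior mean, i.e. a uniform topic
    distribution: with no data the posterior is the prior.
    """
    profiles: dict[str, SpecialistTopicProfile] = {}
    for sid in model.doc_ids:
        theta = model.theta(sid)
        dominant = int(np.argmax(theta))
        profiles[sid] = SpecialistTopicProfile(sid, theta, model.top_words(dominant))
    if all_specialists is not None:
        uniform = np.full(model.n_topics, 1.0 / model.n_topics)
        for sid in all_specialists:
            if sid not in profiles:
                profiles[sid] = SpecialistTopicProfile(sid, uniform.copy(), [])
    return profiles


def extend_candidates(candidates: CandidateSet,
                      profiles: Mapping[str, SpecialistTopicProfile],
                      min_sim: float = DEFAULT_MIN_SIM,
                      per_seed_cap: int = DEFAULT_PER_SEED_CAP) -> CandidateSet:
    """Extend the pool with topic-space neighbors of current candidates.

    Incoming members keep their entries and get short_score = 1. For
    each member (seed), non-member specialists with JS similarity >=
    ``min_sim`` (at most ``per_seed_cap`` per seed, by similarity) are
    added with provenance topic-extension, short_score = similarity and
    the seed's ini_score. A specialist reachable from several seeds
    keeps the assignment maximizing ini_score * short_score.
    """
    out = candidates.copy()
    member_ids = set(out.ids())
    for e in out.entries:
        e.short_score = 1.0
    additions: dict[str, CandidateEntry] = {}
    for seed_entry in candidates.entries:
        sid = seed_entry.specialist_id
        if sid not in profiles:
            raise KeyError(f"no topic profile for candidate {sid!r}")
        seed_theta = profiles[sid].topic_distribution
        scored = []
        for other_id, prof in profiles.items():
            if other_id in member_ids or other_id == sid:
                continue
            sim = js_similarity(seed_theta, prof.topic_distribution).similarity
            if sim >= min_sim:
                scored.append((other_id, sim))
        scored.sort(key=lambda t: (-t[1], t[0]))
        for other_id, sim in scored[:per_seed_cap]:
            cand = CandidateEntry(other_id, seed_entry.ini_score, PROV_TOPIC, sim)
            prev = additions.get(other_id)
            if prev is None or cand.governing > prev.governing:
                additions[other_id] = cand
    out.entries.extend(additions[k] for k in sorted(additions))
    return out.sorted_by("governing")
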