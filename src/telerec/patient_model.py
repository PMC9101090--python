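"""Patient feature modeling: embeddings, TF-IDF weights, EMR vectors, candidates.

An EMR is represented as the TF-IDF-weighted average of the word
vectors of its distinct feature words,

    d_i = (1/f) * sum_k v_k * tfidf(w_k, d_i),

and two EMRs are compared with cosine similarity. The specialists who
treated the most similar patients form the initial candidate set; each
specialist's initial recommendation index (``ini_score``) is the
highest similarity among the patients they treated, and the top-n
specialists by that index are kept. No similarity threshold is applied
at this stage: telemedicine patients often present uncommon diseases,
and thresholding would unduly restrict the pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._kernels import sgns_train
from .preprocess import Corpus

PROV_PATIENT = "patient-similarity"
PROV_COLD_START = "cold-start"
PROV_TOPIC = "topic-extension"


# ---------------------------------------------------------------------------
# Embeddings


@dataclass
class EmbeddingModel:
    """Word vectors keyed by token, all of the same dimension."""

    dimension: int
    vectors: dict[str, np.ndarray]
    training_seed: int

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __contains__(self, token: str) -> bool:
        return token in self.vectors


class SkipGramEmbedding(BaseEstimator):
    """Word2vec-style skip-gram embedding with negative sampling.

    Single-threaded SGD over (center, context) pairs with a dynamic
    window and a unigram^0.75 negative-sampling table, so a fixed seed
    yields identical vectors on every run.

    Parameters
    ----------
    dimension : embedding size p (default 100).
    window : maximum context distance (default 5).
    negative : negatives per positive pair (default 5).
    epochs : passes over the corpus (default 5).
    learning_rate : initial SGD step, linearly decayed (default 0.025).
    seed : RNG seed for init, window sizes and negative draws.
    """

    def __init__(self, dimension: int = 100, window: int = 5, negative: int = 5,
                 epochs: int = 5, learning_rate: float = 0.025, seed: int = 0):
        self.dimension = dimension
        self.window = window
        self.negative = negative
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.seed = seed

    def fit(self, documents: Sequence[Sequence[str]]) -> "SkipGramEmbedding":
        vocab: dict[str, int] = {}
        counts: list[int] = []
        for doc in documents:
            for tok in doc:
                j = vocab.setdefault(tok, len(vocab))
                if j == len(counts):
                    counts.append(0)
                counts[j] += 1
        if len(vocab) < 1:
            raise ValueError("cannot train embeddings on an empty vocabulary")
        v = len(vocab)
        rng = np.random.RandomState(self.seed)
        w_in = (rng.rand(v, self.dimension) - 0.5) / self.dimension
        w_out = np.zeros((v, self.dimension))
        freq = np.asarray(counts, dtype=np.float64) ** 0.75
        freq /= freq.sum()
        table_size = max(10_000, 10 * v)
        neg_table = rng.choice(v, size=table_size, p=freq).astype(np.int32)
        tokens = np.fromiter((vocab[t] for doc in documents for t in doc),
                             dtype=np.int32)
        offsets = np.zeros(len(documents) + 1, dtype=np.int64)
        for i, doc in enumerate(documents):
            offsets[i + 1] = offsets[i] + len(doc)
        sgns_train(tokens, offsets, w_in, w_out, neg_table, self.window,
                   self.negative, self.epochs, self.learning_rate,
                   self.seed % (2 ** 31))
        self.vocabulary_ = list(vocab)
        self.vectors_ = {tok: w_in[j].copy() for tok, j in vocab.items()}
        return self

    def to_model(self) -> EmbeddingModel:
        return EmbeddingModel(self.dimension, self.vectors_, self.seed)


def train_embeddings(corpus: Corpus, dimension: int = 100, window: int = 5,
                     seed: int = 0, **kwargs) -> EmbeddingModel:
    """Train word vectors over a corpus; deterministic for a fixed seed."""
    est = SkipGramEmbedding(dimension=dimension, window=window, seed=seed, **kwargs)
    est.fit([toks for _, toks in corpus.documents])
    return est.to_model()


# ---------------------------------------------------------------------------
# TF-IDF


@dataclass
class TfidfTable:
    """tf-idf(w, d) = (count(w,d)/|d|) * ln(N/df(w)), unsmoothed."""

    weights: dict[tuple[str, str], float]
    doc_freq: dict[str, int]
    n_docs: int

    def idf(self, token: str) -> float:
        return math.log(self.n_docs / self.doc_freq[token])

    def weight(self, token: str, doc_id: str) -> float:
        return self.weights.get((token, doc_id), 0.0)

    def external_weights(self, tokens: Sequence[str]) -> dict[str, float]:
        """tf-idf weights for an out-of-corpus document (the target EMR).

        Term frequency comes from the token list itself; idf from the
        corpus. Tokens unseen in the corpus are skipped (df = 0 leaves
        idf undefined and the token has no embedding anyway).
        """
        n = len(tokens)
        out: dict[str, float] = {}
        for tok in set(tokens):
            if tok in self.doc_freq:
                out[tok] = tokens.count(tok) / n * self.idf(tok)
        return out


def tfidf_weights(corpus: Corpus) -> TfidfTable:
    doc_freq: dict[str, int] = {}
    for _, toks in corpus.documents:
        for tok in set(toks):
            doc_freq[tok] = doc_freq.get(tok, 0) + 1
    n = len(corpus.documents)
    weights: dict[tuple[str, str], float] = {}
    for doc_id, toks in corpus.documents:
        size = len(toks)
        for tok in set(toks):
            weights[(tok, doc_id)] = toks.count(tok) / size * math.log(n / doc_freq[tok])
    return TfidfTable(weights, doc_freq, n)


# ---------------------------------------------------------------------------
# Document vectors and similarity


@dataclass
class DocVector:
    doc_id: str
    vector: np.ndarray
    f: int  # number of distinct feature words


def document_vector(doc: tuple[str, Sequence[str]], emb: EmbeddingModel,
                    tfidf: TfidfTable) -> DocVector:
    """Aggregate a document into the weighted mean of its distinct word vectors."""
    doc_id, tokens = doc
    distinct = list(dict.fromkeys(tokens))
    if not distinct:
        raise ValueError(f"document {doc_id!r} has no tokens to embed")
    acc = np.zeros(emb.dimension)
    for tok in distinct:
        acc += emb[tok] * tfidf.weight(tok, doc_id)
    return DocVector(doc_id, acc / len(distinct), len(distinct))


def document_vector_from_weights(doc_id: str, tokens: Sequence[str],
                                 weights: Mapping[str, float],
                                 emb: EmbeddingModel) -> DocVector:
    """Document vector with explicitly supplied per-token weights."""
    distinct = [t for t in dict.fromkeys(tokens) if t in weights and t in emb]
    if not distinct:
        raise ValueError(f"document {doc_id!r} has no embeddable tokens")
    acc = np.zeros(emb.dimension)
    for tok in distinct:
        acc += emb[tok] * weights[tok]
    return DocVector(doc_id, acc / len(distinct), len(distinct))


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have the same length")
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero vectors")
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# Candidate set


@dataclass
class CandidateEntry:
    specialist_id: str
    ini_score: float
    provenance: str = PROV_PATIENT
    short_score: float | None = None

    @property
    def governing(self) -> float:
        return self.ini_score if self.short_score is None \
            else self.ini_score * self.short_score

    def to_dict(self) -> dict:
        return {"specialist_id": self.specialist_id,
                "ini_score": self.ini_score,
                "provenance": self.provenance,
                "short_score": self.short_score}


@dataclass
class CandidateSet:
    """Ordered pool of recommendable specialists with component indices."""

    entries: list[CandidateEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def ids(self) -> list[str]:
        return [e.specialist_id for e in self.entries]

    def get(self, specialist_id: str) -> CandidateEntry | None:
        for e in self.entries:
            if e.specialist_id == specialist_id:
                return e
        return None

    def sorted_by(self, key: str = "ini") -> "CandidateSet":
        if key == "ini":
            fn = lambda e: (-e.ini_score, e.specialist_id)
        elif key == "governing":
            fn = lambda e: (-e.governing, e.specialist_id)
        else:
            raise ValueError(key)
        return CandidateSet(sorted(self.entries, key=fn))

    def copy(self) -> "CandidateSet":
        return CandidateSet([replace(e) for e in self.entries])

    def to_json(self) -> list[dict]:
        return [e.to_dict() for e in self.entries]


def generate_candidates(target: DocVector, corpus_vectors: Sequence[DocVector],
                        meta: Mapping[str, str], n: int = 10) -> CandidateSet:
    """Initial candidate set: per-specialist max EMR similarity, top-n.

    ``meta`` maps doc_id -> specialist_id. Documents sharing the
    target's doc_id are excluded; documents whose aggregate vector is
    zero carry no feature signal and are skipped.
    """
    if not corpus_vectors:
        raise ValueError("empty corpus")
    best: dict[str, float] = {}
    for dv in corpus_vectors:
        if dv.doc_id == target.doc_id:
            continue
        if not np.any(dv.vector):
            continue
        sim = cosine_similarity(target.vector, dv.vector)
        sid = meta[dv.doc_id]
        if sid not in best or sim > best[sid]:
            best[sid] = sim
    # ini_score is an index in [0, 1]; anti-similar documents carry no
    # recommendation signal, so negative cosines are floored at zero.
    entries = [CandidateEntry(sid, max(score, 0.0), PROV_PATIENT)
               for sid, score in best.items()]
    ranked = CandidateSet(entries).sorted_by("ini")
    return CandidateSet(ranked.entries[:n])
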