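"""Four-stage recommendation pipeline behind one estimator.

Stages: (1) initial candidates from patient-EMR similarity, (2)
cold-start repair of newly registered specialists via long-term
knowledge similarity, (3) semantic extension through short-term topic
profiles, (4) activity-weighted professional scoring fused with QoS
feedback under the patient's preference weights. The stage log records
the candidate set after every stage so each score component is
auditable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml
from sklearn.base import BaseEstimator

from . import knowledge_long, knowledge_short, patient_model, scoring
from .preprocess import (Dictionaries, build_corpus, normalize_text,
                         read_consultations_csv, tokenize)


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults follow the method's stated values
    (top-10 candidates, knowledge-similarity threshold 0.7, 500 Gibbs
    iterations) where one exists."""

    n_candidates: int = 10
    embedding_dim: int = 100
    embedding_window: int = 5
    embedding_epochs: int = 5
    n_topics: int = 10
    k_grid: list[int] | None = None
    alpha: float | None = None
    beta: float = knowledge_short.DEFAULT_BETA
    iterations: int = knowledge_short.DEFAULT_ITERATIONS
    sim_knowledge_threshold: float = knowledge_long.COLD_START_THRESHOLD
    min_topic_sim: float = knowledge_short.DEFAULT_MIN_SIM
    per_seed_cap: int = knowledge_short.DEFAULT_PER_SEED_CAP
    activity_horizon: int = scoring.DEFAULT_HORIZON
    qos_scale: tuple[float, float] = scoring.DEFAULT_QOS_SCALE
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["qos_scale"] = list(self.qos_scale)
        Path(path).write_text(yaml.safe_dump(d), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "qos_scale" in d:
            d["qos_scale"] = tuple(d["qos_scale"])
        return cls(**d)


class SpecialistRecommender(BaseEstimator):
    """Content-based telemedicine specialist recommender.

    ``fit`` ingests the consultation log, specialist profiles and the
    long-term knowledge matrix; ``recommend`` ranks specialists for a
    target EMR. Deterministic under a fixed ``seed``.
    """

    def __init__(self, n_candidates: int = 10, embedding_dim: int = 100,
                 embedding_window: int = 5, embedding_epochs: int = 5,
                 n_topics: int = 10, k_grid: list[int] | None = None,
                 alpha: float | None = None,
                 beta: float = knowledge_short.DEFAULT_BETA,
                 iterations: int = knowledge_short.DEFAULT_ITERATIONS,
                 sim_knowledge_threshold: float = knowledge_long.COLD_START_THRESHOLD,
                 min_topic_sim: float = knowledge_short.DEFAULT_MIN_SIM,
                 per_seed_cap: int = knowledge_short.DEFAULT_PER_SEED_CAP,
                 activity_horizon: int = scoring.DEFAULT_HORIZON,
                 qos_scale: tuple[float, float] = scoring.DEFAULT_QOS_SCALE,
                 seed: int = 0):
        self.n_candidates = n_candidates
        self.embedding_dim = embedding_dim
        self.embedding_window = embedding_window
        self.embedding_epochs = embedding_epochs
        self.n_topics = n_topics
        self.k_grid = k_grid
        self.alpha = alpha
        self.beta = beta
        self.iterations = iterations
        self.sim_knowledge_threshold = sim_knowledge_threshold
        self.min_topic_sim = min_topic_sim
        self.per_seed_cap = per_seed_cap
        self.activity_horizon = activity_horizon
        self.qos_scale = qos_scale
        self.seed = seed

    @classmethod
    def from_config(cls, config: PipelineConfig) -> "SpecialistRecommender":
        return cls(**dataclasses.asdict(config))

    # ------------------------------------------------------------------
    def fit(self, records, knowledge: knowledge_long.KnowledgeMatrix,
            profiles: list[dict],
            dictionaries: Dictionaries | None = None) -> "SpecialistRecommender":
        self.dictionaries_ = dictionaries or Dictionaries()
        self.corpus_ = build_corpus(records, self.dictionaries_)

        docs = [toks for _, toks in self.corpus_.documents]
        emb = patient_model.SkipGramEmbedding(
            dimension=self.embedding_dim, window=self.embedding_window,
            epochs=self.embedding_epochs, seed=self.seed).fit(docs)
        self.embedding_ = emb.to_model()
        self.tfidf_ = patient_model.tfidf_weights(self.corpus_)
        self.doc_vectors_ = [
            patient_model.document_vector(doc, self.embedding_, self.tfidf_)
            for doc in self.corpus_.documents]
        self.doc_specialist_ = {doc_id: meta[1]
                                for doc_id, meta in self.corpus_.doc_meta.items()}

        spec_docs = knowledge_short.specialist_documents(self.corpus_)
        if self.k_grid:
            k = knowledge_short.select_topic_count(
                spec_docs, self.k_grid, seed=self.seed + 1, alpha=self.alpha,
                beta=self.beta, iterations=self.iterations)
        else:
            k = self.n_topics
        self.n_topics_ = k
        self.lda_ = knowledge_short.fit_lda(
            spec_docs, k, alpha=self.alpha, beta=self.beta,
            iterations=self.iterations, seed=self.seed + 1)

        all_specialists = sorted(
            set(knowledge.specialists)
            | {p["specialist_id"] for p in profiles}
            | {sid for _, sid in self.doc_specialist_.items()})
        self.topic_profiles_ = knowledge_short.specialist_profiles(
            self.lda_, all_specialists)

        self.knowledge_ = knowledge_long.impute_matrix(knowledge)
        counts = {sid: 0 for sid in all_specialists}
        for r in records:
            counts[r.specialist_id] = counts.get(r.specialist_id, 0) + 1
        self.consultation_counts_ = counts
        self.newly_registered_ = [
            sid for sid in knowledge_long.newly_registered_from_counts(counts)
            if sid in set(self.knowledge_.specialists)]

        ledger = scoring.ActivityLedger.from_records(
            records, horizon=self.activity_horizon)
        raw = scoring.normalized_activity(
            scoring.activity_scores(ledger, ledger.specialists()))
        self.lac_ = {sid: 0.0 for sid in all_specialists}
        self.lac_.update({s.specialist_id: s.lac for s in raw})

        states = [scoring.QosState(p["specialist_id"], [float(p["rating"])],
                                   self.qos_scale)
                  for p in profiles]
        self.qos_ = {s.specialist_id: s.qos_score
                     for s in scoring.qos_scores(states)}
        self.profile_labels_ = {p["specialist_id"]: set(p.get("labels", []))
                                for p in profiles}
        return self

    # ------------------------------------------------------------------
    def target_vector(self, target_text: str) -> patient_model.DocVector:
        tokens = tokenize(normalize_text(target_text, self.dictionaries_.synonyms),
                          self.dictionaries_)
        weights = self.tfidf_.external_weights(tokens)
        return patient_model.document_vector_from_weights(
            "target", tokens, weights, self.embedding_)

    def recommend(self, target_text: str,
                  preference: tuple[str, str] | None = None,
                  weights: scoring.PreferenceWeights | None = None,
                  top_n: int = 10) -> scoring.Recommendation:
        """Rank specialists for a target EMR; the stage log lands in
        ``stage_log_``."""
        if weights is None:
            prof_choice, qos_choice = preference or ("Fair", "Fair")
            weights = scoring.preference_weights(prof_choice, qos_choice)
        target = self.target_vector(target_text)

        stage_log: dict = {}
        cand = patient_model.generate_candidates(
            target, self.doc_vectors_, self.doc_specialist_, n=self.n_candidates)
        stage_log["initial"] = cand.to_json()

        cand, updates = knowledge_long.update_cold_start(
            cand, self.knowledge_, self.newly_registered_,
            threshold=self.sim_knowledge_threshold)
        stage_log["cold_start"] = cand.to_json()
        stage_log["cold_start_updates"] = [
            {"specialist_id": u.specialist_id, "old": u.old_ini_score,
             "new": u.new_ini_score,
             "similar": [{"id": h, "sim": s, "ini": i} for h, s, i in u.similar]}
            for u in updates]

        cand = knowledge_short.extend_candidates(
            cand, self.topic_profiles_, min_sim=self.min_topic_sim,
            per_seed_cap=self.per_seed_cap)
        stage_log["extension"] = cand.to_json()

        rec = scoring.hybrid_rank(cand, self.lac_, self.qos_, weights, n=top_n)
        stage_log["fused"] = rec.to_json()
        self.stage_log_ = stage_log
        return rec


def load_inputs(paths: dict) -> dict:
    """Read the external-interface files into pipeline inputs.

    ``paths`` carries consultations / profiles / knowledge and
    optionally stopwords / synonyms / user_terms file paths.
    """
    records = read_consultations_csv(paths["consultations"])
    with open(paths["profiles"], encoding="utf-8") as fh:
        profiles = json.load(fh)
    knowledge = knowledge_long.KnowledgeMatrix.from_csv(paths["knowledge"])
    dictionaries = Dictionaries.from_paths(
        stopwords=paths.get("stopwords"), synonyms=paths.get("synonyms"),
        user_terms=paths.get("user_terms"))
    return {"records": records, "profiles": profiles, "knowledge": knowledge,
            "dictionaries": dictionaries}


def run_pipeline(config: PipelineConfig, paths: dict, target_text: str,
                 preference: tuple[str, str] = ("Fair", "Fair"),
                 top_n: int = 10):
    """Load inputs, fit the recommender and rank for one target EMR.

    Returns (recommendation, stage_log).
    """
    inputs = load_inputs(paths)
    est = SpecialistRecommender.from_config(config)
    est.fit(inputs["records"], inputs["knowledge"], inputs["profiles"],
            inputs["dictionaries"])
    rec = est.recommend(target_text, preference=preference, top_n=top_n)
    return rec, est.stage_log_
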