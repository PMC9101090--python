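"""Self-contained synthetic telemedicine world with known ground truth.

The generator emulates the statistical shape of a telemedicine
consultation log: each specialist has a latent Dirichlet topic mixture
(most mass on one or two disease topics), every consultation's EMR
text is sampled token-by-token through topic-then-word draws from a
planted topic-word matrix phi*, the knowledge-attribute matrix marks a
specialist as expert in a disease topic when their mixture mass on it
is high, monthly consultation volumes differ across specialists, and
service ratings are noisy draws around a latent quality that is
independent of topical relevance. Tokens are synthetic symbols
(``w0001`` ...), so no language-specific segmentation is needed.

Everything, including the designated target patient and the
ground-truth best-match specialists, is reproducible from one seed.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .knowledge_long import KnowledgeMatrix
from .preprocess import ConsultationRecord, Dictionaries, write_consultations_csv


@dataclass
class WorldConfig:
    """Generation parameters; defaults define the package's study conditions."""

    n_specialists: int = 50
    n_patients: int = 1000
    n_topics: int = 5
    vocab_size: int = 300
    doc_length_mean: int = 30
    missing_rate: float = 0.2
    months: int = 12
    rating_noise: float = 0.5
    seed: int = 0
    planted_match: bool = False
    n_newly_registered: int = 4
    topic_word_concentration: float = 0.08
    mixture_concentration: float = 0.15
    attribute_threshold: float = 0.2
    n_stopwords: int = 5
    stopword_rate: float = 0.08
    n_synonyms: int = 10
    synonym_rate: float = 0.5

    def validate(self) -> None:
        for name in ("n_specialists", "n_patients", "n_topics", "vocab_size",
                     "doc_length_mean", "months"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.vocab_size < self.n_topics:
            raise ValueError("vocab_size must be >= n_topics")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_newly_registered >= self.n_specialists:
            raise ValueError("too many newly registered specialists")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    phi: np.ndarray                      # planted K x V topic-word matrix
    mixtures: dict[str, np.ndarray]      # specialist -> topic mixture
    records: list[ConsultationRecord]
    knowledge: KnowledgeMatrix           # with NaN for masked cells
    profiles: list[dict]
    dictionaries: Dictionaries
    ratings: dict[str, float]
    target_text: str
    target_topic: int
    best_match: list[str]
    relevant_specialists: list[str]
    newly_registered: list[str]
    planted_newcomer: str | None = None
    planted_template: str | None = None
    attribute_names: list[str] = field(default_factory=list)

    @property
    def target_labels(self) -> set[str]:
        return {f"disease_{self.target_topic}"}

    def label_sets(self) -> dict[str, set[str]]:
        return {p["specialist_id"]: set(p["labels"]) for p in self.profiles}


def _word(i: int) -> str:
    return f"w{i:04d}"


def _sample_tokens(rng: np.random.Generator, mixture: np.ndarray,
                   phi: np.ndarray, length: int, cfg: WorldConfig,
                   decorate: bool = True) -> list[str]:
    """Draw a document: topic-then-word, with synonym variants and stop words."""
    topics = rng.choice(cfg.n_topics, size=length, p=mixture)
    tokens: list[str] = []
    for t in topics:
        w = int(rng.choice(cfg.vocab_size, p=phi[t]))
        name = _word(w)
        if decorate and w < cfg.n_synonyms and rng.random() < cfg.synonym_rate:
            name = name + "v"  # variant spelling, mapped back by the synonym file
        tokens.append(name)
        if decorate and rng.random() < cfg.stopword_rate:
            tokens.append(f"s{rng.integers(cfg.n_stopwords)}")
    return tokens


def generate_world(config: WorldConfig) -> SyntheticWorld:
    config.validate()
    rng = np.random.default_rng(config.seed)
    k, v = config.n_topics, config.vocab_size
    sids = [f"S{i:03d}" for i in range(1, config.n_specialists + 1)]
    newcomers = sids[-config.n_newly_registered:]
    veterans = sids[:-config.n_newly_registered]

    phi = rng.dirichlet([config.topic_word_concentration] * v, size=k)
    mixtures = {sid: rng.dirichlet([config.mixture_concentration] * k)
                for sid in sids}

    target_topic = int(rng.integers(k))
    planted_newcomer = planted_template = None
    if config.planted_match:
        planted_template = max(veterans, key=lambda s: mixtures[s][target_topic])
        planted_newcomer = newcomers[-1]
        mixtures[planted_newcomer] = mixtures[planted_template].copy()

    # --- consultation assignment: newcomers get < 3, veterans share the rest
    patient_ids = [f"P{i:04d}" for i in range(1, config.n_patients + 1)]
    assignment: list[tuple[str, str]] = []
    cursor = 0
    for sid in newcomers:
        # the planted newcomer has long-term expertise but no platform
        # history yet: only long-term knowledge similarity can surface it
        n_consults = 0 if sid == planted_newcomer else int(rng.integers(1, 3))
        for _ in range(n_consults):
            if cursor < len(patient_ids):
                assignment.append((patient_ids[cursor], sid))
                cursor += 1
    # every veteran has some consultation history; volumes beyond that are
    # heterogeneous (skewed Dirichlet shares)
    for sid in veterans:
        if cursor < len(patient_ids):
            assignment.append((patient_ids[cursor], sid))
            cursor += 1
    vet_weights = rng.dirichlet([0.5] * len(veterans))
    for pid in patient_ids[cursor:]:
        assignment.append((pid, veterans[int(rng.choice(len(veterans),
                                                        p=vet_weights))]))

    records = []
    for pid, sid in assignment:
        month = int(rng.integers(1, config.months + 1))
        day = int(rng.integers(1, 29))
        length = max(5, int(rng.poisson(config.doc_length_mean)))
        tokens = _sample_tokens(rng, mixtures[sid], phi, length, config)
        dominant = int(np.argmax(mixtures[sid]))
        records.append(ConsultationRecord(
            pid, sid, f"dept_{dominant}", datetime.date(2020, month, day),
            " ".join(tokens)))

    # --- knowledge attribute matrix: attribute p <-> dominance of topic p
    attributes = [f"disease_{p}" for p in range(k)]
    values = np.zeros((len(sids), k))
    for i, sid in enumerate(sids):
        mix = mixtures[sid]
        values[i] = (mix >= config.attribute_threshold).astype(float)
        values[i, int(np.argmax(mix))] = 1.0  # the dominant topic is always expertise
    truth_values = values.copy()
    protected = {planted_newcomer, planted_template}
    for i, sid in enumerate(sids):
        if sid in protected:
            continue
        mask = rng.random(k) < config.missing_rate
        values[i, mask] = np.nan
    knowledge = KnowledgeMatrix(list(sids), attributes, values)

    # --- ratings: latent quality independent of topical relevance
    ratings = {}
    for sid in sids:
        quality = rng.uniform(2.5, 5.0)
        ratings[sid] = float(np.clip(rng.normal(quality, config.rating_noise),
                                     0.0, 5.0))

    profiles = []
    for i, sid in enumerate(sids):
        labels = [attributes[p] for p in range(k) if truth_values[i, p] == 1.0]
        profiles.append({
            "specialist_id": sid,
            "profile_text": " ".join(labels),
            "labels": labels,
            "registered": "2020-12" if sid in newcomers else "2019-01",
            "rating": round(ratings[sid], 4),
        })

    dictionaries = Dictionaries(
        stopwords={f"s{i}" for i in range(config.n_stopwords)},
        synonyms={_word(i) + "v": _word(i) for i in range(config.n_synonyms)},
        user_terms=set())

    one_hot = np.zeros(k)
    one_hot[target_topic] = 1.0
    target_tokens = _sample_tokens(rng, one_hot, phi,
                                   2 * config.doc_length_mean, config)
    best_match = [sid for sid in sids
                  if int(np.argmax(mixtures[sid])) == target_topic]
    relevant = [p["specialist_id"] for p in profiles
                if f"disease_{target_topic}" in p["labels"]]

    return SyntheticWorld(
        config=config, phi=phi, mixtures=mixtures, records=records,
        knowledge=knowledge, profiles=profiles, dictionaries=dictionaries,
        ratings=ratings, target_text=" ".join(target_tokens),
        target_topic=target_topic, best_match=best_match,
        relevant_specialists=relevant,
        newly_registered=list(newcomers), planted_newcomer=planted_newcomer,
        planted_template=planted_template, attribute_names=attributes)


def write_fixture(world: SyntheticWorld, directory) -> dict[str, Path]:
    """Write the exact external-interface files the pipeline consumes.

    ``truth.json`` carries the ground truth (never read by the
    pipeline itself, only by evaluation).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in [
        ("consultations", "consultations.csv"), ("profiles", "profiles.json"),
        ("knowledge", "knowledge.csv"), ("stopwords", "stopwords.txt"),
        ("synonyms", "synonyms.tsv"), ("user_terms", "user_terms.txt"),
        ("target_emr", "target_emr.txt"), ("truth", "truth.json")]}
    write_consultations_csv(world.records, paths["consultations"])
    with open(paths["profiles"], "w", encoding="utf-8") as fh:
        json.dump(world.profiles, fh, indent=1)
    world.knowledge.to_csv(paths["knowledge"])
    paths["stopwords"].write_text(
        "".join(f"{w}\n" for w in sorted(world.dictionaries.stopwords)),
        encoding="utf-8")
    paths["synonyms"].write_text(
        "".join(f"{a}\t{b}\n" for a, b in sorted(world.dictionaries.synonyms.items())),
        encoding="utf-8")
    paths["user_terms"].write_text(
        "".join(f"{t}\n" for t in sorted(world.dictionaries.user_terms)),
        encoding="utf-8")
    paths["target_emr"].write_text(world.target_text + "\n", encoding="utf-8")
    truth = {
        "seed": world.config.seed,
        "target_topic": world.target_topic,
        "target_labels": sorted(world.target_labels),
        "best_match_specialists": world.best_match,
        "relevant_specialists": world.relevant_specialists,
        "newly_registered": world.newly_registered,
        "planted_newcomer": world.planted_newcomer,
        "planted_template": world.planted_template,
        "specialist_mixtures": {sid: mix.tolist()
                                for sid, mix in sorted(world.mixtures.items())},
        "topic_word": world.phi.tolist(),
    }
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=1)
    return paths
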