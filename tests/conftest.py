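import pytest

from telerec.pipeline import SpecialistRecommender
from telerec.preprocess import Dictionaries
from telerec.synthetic import WorldConfig, generate_world

SMALL = dict(n_specialists=12, n_patients=80, n_topics=3, vocab_size=60,
             doc_length_mean=15, months=6, n_newly_registered=2, seed=11,
             planted_match=True)

SMALL_PIPELINE = dict(n_topics=6, embedding_dim=32, embedding_epochs=3,
                      iterations=150, seed=11)


@pytest.fixture(scope="session")
def small_world():
    return generate_world(WorldConfig(**SMALL))


@pytest.fixture(scope="session")
def fitted_small(small_world):
    est = SpecialistRecommender(**SMALL_PIPELINE)
    est.fit(small_world.records, small_world.knowledge, small_world.profiles,
            small_world.dictionaries)
    return est


@pytest.fixture
def dicts():
    return Dictionaries(stopwords={"with", "the"},
                        synonyms={"HBV": "hepatitis_B"},
                        user_terms={"type 2 diabetes"})
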