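import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from telerec import knowledge_short as ks
from telerec.patient_model import CandidateEntry, CandidateSet
from telerec.preprocess import build_corpus


def two_cluster_docs(n_per=20, seed=0):
    """Documents over two disjoint vocabularies -> two clean topics."""
    rng = np.random.default_rng(seed)
    docs = []
    for i in range(n_per):
        docs.append((f"a{i}", [f"va{rng.integers(10)}" for _ in range(25)]))
        docs.append((f"b{i}", [f"vb{rng.integers(10)}" for _ in range(25)]))
    return docs


class TestGibbsLda:
    def test_deterministic_for_fixed_seed(self):
        docs = two_cluster_docs(5)
        m1 = ks.fit_lda(docs, 2, iterations=50, seed=4)
        m2 = ks.fit_lda(docs, 2, iterations=50, seed=4)
        np.testing.assert_array_equal(m1.topic_word, m2.topic_word)
        np.testing.assert_array_equal(m1.doc_topic, m2.doc_topic)

    def test_rows_are_distributions(self):
        m = ks.fit_lda(two_cluster_docs(5), 3, iterations=50, seed=0)
        np.testing.assert_allclose(m.topic_word.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(m.doc_topic.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(m.topic_word > 0) and np.all(m.doc_topic > 0)

    def test_disjoint_vocabularies_separate(self):
        docs = two_cluster_docs(20, seed=1)
        m = ks.fit_lda(docs, 2, alpha=0.5, iterations=200, seed=2)
        for (doc_id, _), theta in zip(docs, m.doc_topic):
            assert theta.max() >= 0.9, doc_id

    def test_assignment_count_conserved(self):
        docs = two_cluster_docs(5)
        est = ks.GibbsLda(n_topics=2, iterations=20, seed=0).fit(docs)
        assert est.assignments_.shape[0] == sum(len(t) for _, t in docs)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            ks.fit_lda(two_cluster_docs(2), 0)

    def test_json_round_trip(self, tmp_path):
        m = ks.fit_lda(two_cluster_docs(3), 2, iterations=20, seed=1)
        path = tmp_path / "model.json"
        m.to_json(path)
        back = ks.TopicModel.from_json(path)
        np.testing.assert_allclose(back.topic_word, m.topic_word)
        assert back.vocabulary == m.vocabulary
        assert back.doc_ids == m.doc_ids


class TestPerplexity:
    def degenerate(self, phi, theta, vocab):
        return ks.TopicModel(len(theta[0]), 1.0, 0.01, np.asarray(phi, float),
                             np.asarray(theta, float), vocab, ["d0"], 0, 0)

    def test_certain_model_has_perplexity_one(self):
        m = self.degenerate([[1.0]], [[1.0]], ["w"])
        assert ks.perplexity(m, [("d0", ["w", "w"])]) == pytest.approx(1.0)

    def test_uniform_model_has_perplexity_v(self):
        v = 8
        m = self.degenerate([np.full(v, 1 / v)], [[1.0]],
                            [f"w{i}" for i in range(v)])
        assert ks.perplexity(m, [("d0", ["w0", "w3"])]) == pytest.approx(v)

    def test_matched_topic_count_beats_k1(self):
        docs = two_cluster_docs(20, seed=3)
        p1 = ks.perplexity(ks.fit_lda(docs, 1, iterations=100, seed=5), docs)
        p2 = ks.perplexity(ks.fit_lda(docs, 2, iterations=100, seed=5), docs)
        assert p2 < p1

    def test_unknown_token_rejected(self):
        m = self.degenerate([[1.0]], [[1.0]], ["w"])
        with pytest.raises(KeyError):
            ks.perplexity(m, [("d0", ["unknown"])])


class TestSelectTopicCount:
    def test_singleton_grid(self):
        assert ks.select_topic_count(two_cluster_docs(3), [2],
                                     iterations=20, seed=0) == 2

    def test_tie_resolves_to_smaller_k(self, monkeypatch):
        monkeypatch.setattr(ks, "topic_count_table",
                            lambda *a, **k: [(3, 50.0), (5, 50.0)])
        assert ks.select_topic_count(two_cluster_docs(2), [3, 5]) == 3

    def test_elbow_of_hockey_stick_curve(self, monkeypatch):
        table = [(2, 200.0), (3, 180.0), (4, 120.0), (5, 60.0), (6, 58.0),
                 (7, 57.0), (8, 56.0)]
        monkeypatch.setattr(ks, "topic_count_table", lambda *a, **k: table)
        assert ks.select_topic_count(two_cluster_docs(2),
                                     [k for k, _ in table]) == 5

    def test_min_method_returns_argmin(self, monkeypatch):
        table = [(2, 200.0), (3, 120.0), (4, 70.0)]
        monkeypatch.setattr(ks, "topic_count_table", lambda *a, **k: table)
        assert ks.select_topic_count(two_cluster_docs(2), [2, 3, 4],
                                     method="min") == 4

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            ks.select_topic_count(two_cluster_docs(2), [])


class TestJsSimilarity:
    def test_closed_forms(self):
        p = np.array([0.2, 0.3, 0.5])
        assert ks.js_similarity(p, p) == (0.0, 1.0)
        d, s = ks.js_similarity([1.0, 0.0], [0.0, 1.0])
        assert d == pytest.approx(1.0) and s == pytest.approx(0.0)
        d, _ = ks.js_similarity([0.5, 0.5], [1.0, 0.0])
        assert d == pytest.approx(0.311278, abs=1e-6)

    def test_matches_scipy_oracle_on_random_pairs(self):
        rng = np.random.default_rng(29)
        for _ in range(1000):
            p = rng.dirichlet(np.ones(5))
            q = rng.dirichlet(np.ones(5))
            expect = jensenshannon(p, q, base=2) ** 2
            d = ks.js_divergence(p, q)
            assert d == pytest.approx(expect, abs=1e-12)
            assert d == pytest.approx(ks.js_divergence(q, p), abs=1e-12)
            assert 0.0 <= d <= 1.0

    def test_validation(self):
        with pytest.raises(ValueError):
            ks.js_divergence([0.5, 0.5], [0.5, 0.25, 0.25])
        with pytest.raises(ValueError):
            ks.js_divergence([0.9, 0.3], [0.5, 0.5])


class TestExtendCandidates:
    def profiles(self, thetas):
        return {sid: ks.SpecialistTopicProfile(sid, np.asarray(t, float), [])
                for sid, t in thetas.items()}

    def test_identical_theta_added_with_seed_ini(self):
        profiles = self.profiles({"SEED": [0.7, 0.3], "TWIN": [0.7, 0.3],
                                  "FAR": [0.0, 1.0]})
        cands = CandidateSet([CandidateEntry("SEED", 0.6)])
        out = ks.extend_candidates(cands, profiles, min_sim=0.8)
        twin = out.get("TWIN")
        assert twin.short_score == pytest.approx(1.0)
        assert twin.ini_score == pytest.approx(0.6)
        assert twin.provenance == "topic-extension"
        assert out.get("FAR") is None

    def test_below_threshold_not_added(self):
        profiles = self.profiles({"SEED": [1.0, 0.0], "OTHER": [0.2, 0.8]})
        cands = CandidateSet([CandidateEntry("SEED", 0.6)])
        out = ks.extend_candidates(cands, profiles, min_sim=0.8)
        assert out.ids() == ["SEED"]

    def test_empty_candidate_set(self):
        assert len(ks.extend_candidates(CandidateSet([]), {})) == 0

    def test_members_keep_scores_and_get_short_one(self):
        profiles = self.profiles({"A": [1.0, 0.0], "B": [0.0, 1.0]})
        cands = CandidateSet([CandidateEntry("A", 0.9), CandidateEntry("B", 0.4)])
        out = ks.extend_candidates(cands, profiles, min_sim=0.8)
        assert {e.specialist_id: e.short_score for e in out} == {"A": 1.0, "B": 1.0}
        assert out.get("A").ini_score == 0.9

    def test_multi_seed_reachability_keeps_best_product(self):
        profiles = self.profiles({"S1": [1.0, 0.0], "S2": [0.9, 0.1],
                                  "X": [0.9, 0.1]})
        cands = CandidateSet([CandidateEntry("S1", 0.5), CandidateEntry("S2", 0.9)])
        out = ks.extend_candidates(cands, profiles, min_sim=0.5)
        # X is identical to S2 (sim 1.0, product 0.9) and close to S1
        assert out.get("X").ini_score == pytest.approx(0.9)
        assert out.get("X").short_score == pytest.approx(1.0)

    def test_per_seed_cap(self):
        thetas = {"SEED": [1.0, 0.0]}
        thetas.update({f"N{i}": [1.0, 0.0] for i in range(5)})
        cands = CandidateSet([CandidateEntry("SEED", 0.5)])
        out = ks.extend_candidates(cands, self.profiles(thetas),
                                   min_sim=0.8, per_seed_cap=3)
        assert len(out) == 4

    def test_missing_profile_error_names_specialist(self):
        cands = CandidateSet([CandidateEntry("SEED", 0.5)])
        with pytest.raises(KeyError, match="SEED"):
            ks.extend_candidates(cands, {})


def test_specialist_documents_concatenate_per_specialist(small_world):
    corpus = build_corpus(small_world.records, small_world.dictionaries)
    docs = dict(ks.specialist_documents(corpus))
    by_hand = {}
    for doc_id, toks in corpus.documents:
        by_hand.setdefault(corpus.doc_meta[doc_id][1], []).extend(toks)
    assert docs == by_hand


def test_profiles_for_absent_specialists_are_uniform():
    model = ks.fit_lda(two_cluster_docs(3), 2, iterations=20, seed=1)
    profs = ks.specialist_profiles(model, all_specialists=["a0", "GHOST"])
    np.testing.assert_allclose(profs["GHOST"].topic_distribution, [0.5, 0.5])
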