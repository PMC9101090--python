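import datetime
import math

import pytest

from telerec.patient_model import CandidateEntry, CandidateSet
from telerec.preprocess import ConsultationRecord
from telerec.scoring import (ActivityLedger, ActivityScore, PreferenceWeights,
                             QosState, activity, hybrid_rank,
                             normalized_activity, preference_weights,
                             professional_score, qos_scores, update_qos)


class TestActivity:
    def test_sole_specialist_current_period(self):
        ledger = ActivityLedger({("S1", 0): 3})
        assert activity(ledger, "S1") == pytest.approx(1.0)

    def test_share_of_period(self):
        ledger = ActivityLedger({("S1", 0): 2, ("S2", 0): 2})
        assert activity(ledger, "S1") == pytest.approx(0.5)

    def test_decay_factor(self):
        ledger = ActivityLedger({("S1", 1): 2, ("S2", 1): 2})
        assert activity(ledger, "S1") == pytest.approx(0.5 * math.exp(-1))

    def test_decay_monotone_in_period_shift(self):
        for t in range(5):
            now = activity(ActivityLedger({("S1", t): 2, ("S2", t): 2}), "S1")
            later = activity(ActivityLedger({("S1", t + 1): 2, ("S2", t + 1): 2}), "S1")
            assert later < now

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ActivityLedger({("S1", 0): -1})

    def test_from_records_uses_month_age(self):
        recs = [ConsultationRecord("p1", "S1", "d", datetime.date(2020, 12, 5), "x"),
                ConsultationRecord("p2", "S1", "d", datetime.date(2020, 10, 20), "x"),
                ConsultationRecord("p3", "S2", "d", datetime.date(2020, 12, 1), "x")]
        ledger = ActivityLedger.from_records(recs)
        assert ledger.counts == {("S1", 0): 1, ("S1", 2): 1, ("S2", 0): 1}


class TestNormalizedActivity:
    def test_values(self):
        out = normalized_activity([ActivityScore("A", 2.0), ActivityScore("B", 1.0)])
        assert [s.lac for s in out] == [1.0, 0.5]

    def test_single_specialist(self):
        assert normalized_activity([ActivityScore("A", 0.3)])[0].lac == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            normalized_activity([ActivityScore("A", 0.0)])


class TestProfessionalScore:
    @pytest.mark.parametrize("args,expected", [
        ((1.0, 1.0, 1.0), 1.0),
        ((0.5, 0.4, 1.0), 0.2),
        ((0.0, 0.9, 0.9), 0.0),
        ((0.9, 0.0, 0.9), 0.0),
    ])
    def test_product(self, args, expected):
        assert professional_score(*args) == pytest.approx(expected)

    def test_range_validated(self):
        with pytest.raises(ValueError):
            professional_score(1.2, 0.5, 0.5)


class TestPreferenceWeights:
    def test_worked_example(self):
        w = preference_weights("Extremely like", "Like")
        assert (w.omega_p, w.omega_q) == (pytest.approx(4 / 7), pytest.approx(3 / 7))

    def test_fair_fair(self):
        w = preference_weights("Fair", "Fair")
        assert (w.omega_p, w.omega_q) == (0.5, 0.5)

    def test_double_extreme_dislike_fallback(self):
        w = preference_weights("Extremely dislike", "Extremely dislike")
        assert (w.omega_p, w.omega_q) == (0.5, 0.5)

    def test_unknown_category_lists_valid_ones(self):
        with pytest.raises(ValueError, match="extremely like"):
            preference_weights("Adore", "Fair")

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            PreferenceWeights(0.7, 0.7)


class TestQos:
    def test_mean_updates(self):
        s = QosState("S1", [4.0, 4.0])
        assert update_qos(s, 4.0).qos == pytest.approx(4.0)
        assert update_qos(QosState("S1", [5.0, 3.0]), 4.0).qos == pytest.approx(4.0)
        assert update_qos(QosState("S1", []), 4.0).qos == pytest.approx(4.0)

    def test_permutation_invariant(self):
        a = QosState("S1", [1.0, 5.0, 3.0])
        b = QosState("S1", [3.0, 1.0, 5.0])
        assert a.qos == pytest.approx(b.qos)

    def test_out_of_scale_rejected(self):
        with pytest.raises(ValueError):
            update_qos(QosState("S1", []), 5.5)

    def test_normalization(self):
        out = qos_scores([QosState("A", [4.5]), QosState("B", [3.0])])
        assert out[0].qos_score == pytest.approx(1.0)
        assert out[1].qos_score == pytest.approx(3.0 / 4.5)

    def test_single_specialist_gets_one(self):
        assert qos_scores([QosState("A", [2.0])])[0].qos_score == 1.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            qos_scores([QosState("A", [0.0])])


class TestHybridRank:
    def pool(self):
        cands = CandidateSet([CandidateEntry("A", 1.0, short_score=1.0),
                              CandidateEntry("B", 0.5, short_score=1.0)])
        lac = {"A": 1.0, "B": 1.0}
        qos = {"A": 0.5, "B": 1.0}
        return cands, lac, qos

    def test_hand_computed_fusion(self):
        cands, lac, qos = self.pool()
        rec = hybrid_rank(cands, lac, qos, PreferenceWeights(0.6, 0.4))
        assert rec.ids() == ["A", "B"]
        assert rec.entries[0].compre_score == pytest.approx(0.80)
        assert rec.entries[1].compre_score == pytest.approx(0.70)

    def test_professional_only_ranking(self):
        cands, lac, qos = self.pool()
        rec = hybrid_rank(cands, lac, qos, PreferenceWeights(1.0, 0.0))
        assert rec.ids() == ["A", "B"]
        assert [e.compre_score for e in rec.entries] == [1.0, 0.5]

    def test_qos_only_ranking(self):
        cands, lac, qos = self.pool()
        rec = hybrid_rank(cands, lac, qos, PreferenceWeights(0.0, 1.0))
        assert rec.ids() == ["B", "A"]

    def test_equal_qos_reduces_to_professional_order_for_any_weight(self):
        cands, lac, _ = self.pool()
        qos = {"A": 0.8, "B": 0.8}
        for wp in (0.0, 0.3, 0.7, 1.0):
            rec = hybrid_rank(cands, lac, qos, PreferenceWeights(wp, 1 - wp))
            if wp > 0:
                assert rec.ids() == ["A", "B"]
        # at wp = 0 scores tie; the id tie-break keeps a total order
        rec = hybrid_rank(cands, lac, qos, PreferenceWeights(0.0, 1.0))
        assert rec.ids() == ["A", "B"]

    def test_compre_bounded_and_monotone_in_wp(self):
        cands, lac, qos = self.pool()
        prev = None
        for wp in [0.0, 0.25, 0.5, 0.75, 1.0]:
            rec = hybrid_rank(cands, lac, qos, PreferenceWeights(wp, 1 - wp))
            top_a = next(e for e in rec.entries if e.specialist_id == "A")
            assert 0.0 <= top_a.compre_score <= 1.0
            if prev is not None:     # A has prof' 1.0 > qos 0.5: rising in wp
                assert top_a.compre_score >= prev
            prev = top_a.compre_score

    def test_missing_component_errors(self):
        cands, lac, qos = self.pool()
        with pytest.raises(KeyError):
            hybrid_rank(cands, {"A": 1.0}, qos, PreferenceWeights(0.5, 0.5))
        with pytest.raises(KeyError):
            hybrid_rank(cands, lac, {"A": 0.5}, PreferenceWeights(0.5, 0.5))
        with pytest.raises(ValueError):
            hybrid_rank(CandidateSet([]), lac, qos, PreferenceWeights(0.5, 0.5))

    def test_top_n_truncation(self):
        cands = CandidateSet([CandidateEntry(f"S{i}", 0.5 + 0.01 * i)
                              for i in range(15)])
        lac = {f"S{i}": 1.0 for i in range(15)}
        qos = {f"S{i}": 1.0 for i in range(15)}
        rec = hybrid_rank(cands, lac, qos, PreferenceWeights(0.5, 0.5), n=10)
        assert len(rec) == 10
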