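"""Validation statistics: confusion counts, F1, weighted averages, kappa,
adjudication and score match rates."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score

from migrascore import (
    EncounterFeatures,
    EvalCounts,
    EvaluationError,
    Feature,
    FeatureMetrics,
    adjudicate,
    cohen_kappa,
    encounter_confusion,
    f1_score,
    feature_metrics,
    match_rates,
    round_percent,
    weighted_summary,
)


def ef(eid, features=()):
    return EncounterFeatures(encounter_id=eid, features=frozenset(features))


def universe(asserted, ids=("e1", "e2", "e3", "e4")):
    return {eid: ef(eid, (Feature.NAUSEA,) if eid in asserted else ()) for eid in ids}


class TestEncounterConfusion:
    def test_identical_sets_no_errors(self):
        auto = universe({"e1", "e3"})
        counts = encounter_confusion(auto, dict(auto), Feature.NAUSEA.value)
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 0)

    def test_partial_overlap_set_algebra(self):
        # reference asserts {e1,e2}, automated asserts {e2,e3}
        counts = encounter_confusion(
            universe({"e2", "e3"}), universe({"e1", "e2"}), Feature.NAUSEA.value
        )
        assert (counts.tp, counts.fp, counts.fn) == (1, 1, 1)

    def test_feature_asserted_nowhere(self):
        counts = encounter_confusion(universe(()), universe(()), Feature.NAUSEA.value)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 0)

    def test_universe_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            encounter_confusion(
                universe((), ids=("e1",)), universe((), ids=("e2",)), "nausea"
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            EvalCounts(tp=-1, fp=0, fn=0)


class TestFeatureMetrics:
    def test_counts_to_rates(self):
        m = feature_metrics(EvalCounts(tp=90, fp=10, fn=10), occurrence=100)
        assert m.recall == pytest.approx(0.9)
        assert m.precision == pytest.approx(0.9)
        assert m.f1 == pytest.approx(0.9)
        assert m.included

    def test_no_predictions_gives_na_precision_and_f1(self):
        m = feature_metrics(EvalCounts(tp=0, fp=0, fn=25), occurrence=25)
        assert m.recall == 0.0
        assert m.precision is None and m.f1 is None

    def test_zero_occurrence_gives_na_recall(self):
        m = feature_metrics(EvalCounts(tp=0, fp=3, fn=0), occurrence=0)
        assert m.recall is None and m.precision == 0.0
        assert not m.included

    def test_rare_feature_excluded(self):
        assert not feature_metrics(EvalCounts(tp=10, fp=0, fn=9), occurrence=19).included
        assert feature_metrics(EvalCounts(tp=20, fp=0, fn=0), occurrence=20).included

    @given(
        st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
    )
    def test_f1_between_recall_and_precision(self, tp, fp, fn):
        m = feature_metrics(EvalCounts(tp=tp, fp=fp, fn=fn), occurrence=tp + fn)
        if m.recall is not None and m.precision is not None and m.f1 is not None:
            assert min(m.recall, m.precision) - 1e-12 <= m.f1 <= max(m.recall, m.precision) + 1e-12
            if m.recall == m.precision:
                assert m.f1 == pytest.approx(m.recall)


def metric(feature, occurrence, f1):
    return FeatureMetrics(
        feature=feature, occurrence=occurrence, recall=f1, precision=f1, f1=f1, included=occurrence >= 20
    )


class TestWeightedSummary:
    def test_single_feature_is_identity(self):
        summary = weighted_summary([metric("nausea", 100, 0.93)])
        assert summary.f1 == pytest.approx(0.93)

    def test_equal_weights_symmetric_values(self):
        summary = weighted_summary([metric("a", 100, 1.0), metric("b", 100, 0.0)])
        assert summary.f1 == pytest.approx(0.5)

    def test_equal_weights_equal_unweighted_mean(self):
        # oracle: with equal weights the weighted mean is the plain mean
        values = [0.1, 0.4, 0.9, 0.75]
        summary = weighted_summary([metric(f"f{i}", 50, v) for i, v in enumerate(values)])
        assert summary.f1 == pytest.approx(sum(values) / len(values))

    def test_undefined_values_excluded_from_average(self):
        rows = [
            metric("a", 100, 0.8),
            FeatureMetrics(feature="b", occurrence=100, recall=0.0, precision=None, f1=None, included=True),
        ]
        summary = weighted_summary(rows)
        assert summary.f1 == pytest.approx(0.8)  # only the defined F1
        assert summary.recall == pytest.approx(0.4)  # both recalls defined

    def test_no_included_features_is_an_error(self):
        with pytest.raises(EvaluationError):
            weighted_summary([metric("rare", 5, 1.0)])


class TestCohenKappa:
    def test_identical_nonconstant_sequences(self):
        labels = [0, 1, 0, 1, 1]
        assert cohen_kappa(labels, labels).kappa == pytest.approx(1.0)

    def test_two_by_two_contingency_example(self):
        # 4 agreements on each class, 1 disagreement each way:
        # po = 0.8, marginals 5/5 both sides -> pe = 0.5, kappa = 0.6
        a = [1, 1, 1, 1, 0, 0, 0, 0, 1, 0]
        b = [1, 1, 1, 1, 0, 0, 0, 0, 0, 1]
        result = cohen_kappa(a, b)
        assert result.po == pytest.approx(0.8)
        assert result.pe == pytest.approx(0.5)
        assert result.kappa == pytest.approx(0.6)
        assert not result.adequate

    def test_independent_random_labels_near_zero(self):
        rng = np.random.default_rng(12345)
        a = rng.integers(0, 2, size=10_000).tolist()
        b = rng.integers(0, 2, size=10_000).tolist()
        assert abs(cohen_kappa(a, b).kappa) < 0.05

    @given(
        st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2)), min_size=2, max_size=60)
    )
    def test_matches_contingency_oracle_and_sklearn(self, pairs):
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        result = cohen_kappa(a, b)
        # brute-force oracle from the full contingency table
        n = len(a)
        po = sum(x == y for x, y in zip(a, b)) / n
        pe = sum(
            (a.count(c) / n) * (b.count(c) / n) for c in set(a) | set(b)
        )
        if pe >= 1.0:
            assert result.kappa is None and result.po == 1.0
        else:
            assert result.kappa == pytest.approx((po - pe) / (1 - pe))
            assert result.kappa == pytest.approx(cohen_kappa_score(a, b))
            assert result.kappa <= result.po + 1e-12

    def test_relabeling_invariance(self):
        a = [0, 1, 2, 1, 0, 2, 2, 1]
        b = [0, 2, 2, 1, 1, 2, 0, 1]
        relabel = {0: "x", 1: "y", 2: "z"}
        ra = [relabel[v] for v in a]
        rb = [relabel[v] for v in b]
        assert cohen_kappa(a, b).kappa == pytest.approx(cohen_kappa(ra, rb).kappa)

    def test_constant_identical_sequences_degenerate(self):
        result = cohen_kappa([1, 1, 1], [1, 1, 1])
        assert result.kappa is None
        assert result.po == 1.0

    def test_adequacy_gate(self):
        labels = [0, 1] * 20
        assert cohen_kappa(labels, labels).adequate


class TestAdjudicate:
    def test_identical_sets_finalize_immediately(self):
        ann = {"e1": {"nausea"}, "e2": set()}
        result = adjudicate(ann, {"e1": {"nausea"}, "e2": set()})
        assert result.finalized
        assert result.worksheet == ()
        assert result.consensus == {"e1": frozenset({"nausea"}), "e2": frozenset()}

    def test_disagreement_blocks_until_resolved(self):
        a = {"e1": {"nausea", "headache"}}
        b = {"e1": {"headache"}}
        unresolved = adjudicate(a, b)
        assert not unresolved.finalized
        assert len(unresolved.worksheet) == 1
        resolved = adjudicate(a, b, resolutions={("e1", "nausea"): True})
        assert resolved.finalized
        assert "nausea" in resolved.consensus["e1"]
        dropped = adjudicate(a, b, resolutions={("e1", "nausea"): False})
        assert dropped.finalized
        assert "nausea" not in dropped.consensus["e1"]

    def test_resolution_for_unknown_item_rejected(self):
        a = {"e1": {"nausea"}}
        with pytest.raises(EvaluationError):
            adjudicate(a, dict(a), resolutions={("e1", "vomiting"): True})


class TestMatchRates:
    def test_identical_scores(self):
        scores = {"e1": 5, "e2": 8}
        rates = match_rates(scores, dict(scores))
        assert rates.exact_rate == rates.close_rate == 1.0
        assert rates.success

    def test_direct_count_example(self):
        auto = {"e1": 5, "e2": 5, "e3": 5, "e4": 5}
        reference = {"e1": 5, "e2": 6, "e3": 7, "e4": 5}
        rates = match_rates(auto, reference)
        assert rates.exact_rate == pytest.approx(0.5)
        assert rates.close_rate == pytest.approx(0.75)

    def test_single_gross_mismatch_fails_gate(self):
        rates = match_rates({"e1": 3}, {"e1": 5})
        assert rates.exact_rate == 0.0 and rates.close_rate == 0.0
        assert not rates.success

    @given(
        st.lists(st.tuples(st.integers(1, 10), st.integers(1, 10)), min_size=1, max_size=40)
    )
    def test_exact_rate_never_exceeds_close_rate(self, pairs):
        auto = {f"e{i}": a for i, (a, _) in enumerate(pairs)}
        reference = {f"e{i}": b for i, (_, b) in enumerate(pairs)}
        rates = match_rates(auto, reference)
        assert 0.0 <= rates.exact_rate <= rates.close_rate <= 1.0


class TestRounding:
    @pytest.mark.parametrize(
        "proportion, expected",
        [(0.9475, 94.8), (0.72450, 72.5), (0.919153, 91.9), (1.0, 100.0), (0.0, 0.0)],
    )
    def test_percent_half_up_one_decimal(self, proportion, expected):
        assert round_percent(proportion) == expected
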