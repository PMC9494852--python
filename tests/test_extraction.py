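"""Sentence segmentation, mention finding and context attributes."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from migrascore import (
    Descriptor,
    Feature,
    FeatureMention,
    Lexicon,
    Severity,
    Span,
    aggregate_encounter,
    extract_note,
    find_mentions,
    segment,
)
from migrascore.extraction import LexiconError, apply_context


class TestSegment:
    def test_empty_narrative(self):
        assert segment("") == []

    def test_two_sentences_with_offsets(self):
        sents = segment("Severe headache. Denies nausea.")
        assert [(s.start, s.end) for s in sents] == [(0, 16), (17, 31)]

    def test_abbreviation_does_not_split(self):
        sents = segment("Seen by Dr. Smith for HA.")
        assert len(sents) == 1

    def test_newline_run_is_boundary(self):
        sents = segment("Severe headache\n\nDenies nausea")
        assert len(sents) == 2

    @given(
        st.text(
            alphabet="abc .\n!?;Dr",
            max_size=120,
        )
    )
    def test_sentences_tile_without_overlap(self, text):
        sents = segment(text)
        for s in sents:
            assert 0 <= s.start < s.end <= len(text)
            covered = text[s.start : s.end]
            assert covered == covered.strip()
            for t in s.tokens:
                assert s.start <= t.start < t.end <= s.end
                assert text[t.start : t.end] == t.text
        for a, b in zip(sents, sents[1:]):
            assert a.end <= b.start


class TestFindMentions:
    def test_multiple_concepts_in_one_sentence(self, make_note):
        note = make_note("Pt has migraine headaches with photophobia.")
        feats = {m.feature for m in find_mentions(note)}
        assert feats == {Feature.MIGRAINE, Feature.HEADACHE, Feature.PHOTOPHOBIA}

    def test_every_span_slices_to_its_surface(self, make_note, lexicon):
        note = make_note("Pt has migraine headaches with photophobia and HA.")
        surfaces = {f.lower() for forms in lexicon.surfaces.values() for f in forms}
        for m in find_mentions(note):
            assert note.narrative[m.span.start : m.span.end].lower() in surfaces

    def test_longest_match_wins(self, make_note):
        note = make_note("Reports migraine with aura today.")
        (m,) = find_mentions(note)
        assert note.narrative[m.span.start : m.span.end] == "migraine with aura"

    def test_ambiguous_ma_blocked_without_cue(self, make_note):
        assert find_mentions(make_note("MA seen pt for vitals.")) == []

    def test_ambiguous_ma_blocked_by_blocked_cue(self, make_note):
        assert find_mentions(make_note("Seen with the medical assistant (MA) for headache.")) == [
            FeatureMention(
                encounter_id="e1", feature=Feature.HEADACHE, span=Span(start=41, end=49)
            )
        ]

    def test_ambiguous_ma_resolved_by_aura_context(self, make_note):
        note = make_note("History of MA with visual aura.")
        (m,) = find_mentions(note)
        assert m.feature is Feature.MIGRAINE
        assert note.narrative[m.span.start : m.span.end] == "MA"

    def test_lowercase_abbreviations_not_matched(self, make_note):
        assert find_mentions(make_note("She ha d a good day, ma too.")) == []

    def test_duplicate_surface_across_features_rejected(self):
        surfaces = dict(Lexicon().surfaces)
        surfaces[Feature.NAUSEA] = surfaces[Feature.NAUSEA] + ("headache",)
        with pytest.raises(LexiconError):
            Lexicon(surfaces=surfaces)


class TestApplyContext:
    def _extract(self, make_note, text):
        return {
            (m.feature, m.negated, m.severity, m.descriptor)
            for m in extract_note(make_note(text))
        }

    def test_negation_cue_shared_across_conjunction(self, make_note):
        got = self._extract(make_note, "Denies nausea or vomiting.")
        assert got == {
            (Feature.NAUSEA, True, Severity.NONE_STATED, None),
            (Feature.VOMITING, True, Severity.NONE_STATED, None),
        }

    def test_severity_and_descriptor_attach_to_headache(self, make_note):
        got = self._extract(make_note, "Severe throbbing headache.")
        assert got == {(Feature.HEADACHE, False, Severity.SEVERE, Descriptor.THROBBING)}

    def test_scope_terminated_at_but(self, make_note):
        got = self._extract(make_note, "No headache today, but reports nausea.")
        assert got == {
            (Feature.HEADACHE, True, Severity.NONE_STATED, None),
            (Feature.NAUSEA, False, Severity.NONE_STATED, None),
        }

    def test_negation_window_limits_scope(self, make_note):
        # cue is 7 tokens away from the mention: outside the default window
        got = self._extract(
            make_note, "No acute distress noted at all during today with headache."
        )
        assert got == {(Feature.HEADACHE, False, Severity.NONE_STATED, None)}

    def test_severity_window_before_limits_attachment(self, make_note):
        # "severe" sits 5 tokens before the mention: outside the 4-token window
        got = self._extract(make_note, "Severe pain in neck and also some headache.")
        assert got == {(Feature.HEADACHE, False, Severity.NONE_STATED, None)}

    def test_severity_after_mention(self, make_note):
        got = self._extract(make_note, "Headache was severe.")
        assert got == {(Feature.HEADACHE, False, Severity.SEVERE, None)}

    def test_negation_does_not_cross_sentences(self, make_note):
        got = self._extract(make_note, "Denies vomiting. Reports nausea.")
        assert got == {
            (Feature.VOMITING, True, Severity.NONE_STATED, None),
            (Feature.NAUSEA, False, Severity.NONE_STATED, None),
        }

    def test_structured_mentions_pass_through(self, make_note):
        from migrascore import MentionSource

        m = FeatureMention(
            encounter_id="e1", feature=Feature.NAUSEA, source=MentionSource.STRUCTURED
        )
        assert apply_context([m], [], Lexicon()) == [m]


class TestAggregateEncounter:
    def _mention(self, feature, negated=False, severity=Severity.NONE_STATED, descriptor=None):
        return FeatureMention(
            encounter_id="e1",
            feature=feature,
            span=Span(start=0, end=2),
            negated=negated,
            severity=severity,
            descriptor=descriptor,
        )

    def test_negated_only_feature_absent(self):
        ef = aggregate_encounter("e1", [self._mention(Feature.NAUSEA, negated=True)])
        assert Feature.NAUSEA not in ef.features

    def test_severities_union_over_mentions(self):
        ef = aggregate_encounter(
            "e1",
            [
                self._mention(Feature.HEADACHE, severity=Severity.MILD),
                self._mention(Feature.HEADACHE, severity=Severity.SEVERE),
            ],
        )
        assert ef.severities == {Severity.MILD, Severity.SEVERE}

    def test_assertion_dominates_negation(self):
        ef = aggregate_encounter(
            "e1",
            [self._mention(Feature.NAUSEA, negated=True), self._mention(Feature.NAUSEA)],
        )
        assert Feature.NAUSEA in ef.features

    def test_migraine_severity_feeds_headache_fact(self):
        ef = aggregate_encounter(
            "e1", [self._mention(Feature.MIGRAINE, severity=Severity.SEVERE)]
        )
        assert ef.features == {Feature.MIGRAINE}
        assert ef.severities == {Severity.SEVERE}

    def test_foreign_encounter_id_rejected(self):
        with pytest.raises(ValueError):
            aggregate_encounter("e2", [self._mention(Feature.NAUSEA)])

    def test_extraction_is_deterministic(self, make_note):
        note = make_note("Severe headache. Denies nausea. Reports photophobia and HA.")
        assert extract_note(note) == extract_note(note)
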