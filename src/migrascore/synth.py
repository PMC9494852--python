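"""Synthetic EHR corpora with exact ground truth.

The real study data are tertiary-care EHR narratives that cannot be shared;
this module generates corpora with the same statistical skeleton — paired
encounters per patient, migraine-feature sentences with configurable
prevalences, explicit negation cues, severity adjectives and
severe-headache descriptors, ambiguous "MA" in both its migraine and
distractor senses, and structured coding whose per-feature sensitivity can
be dialled down to the low recall typical of symptom coding.

Narratives are assembled from a template grammar, and the ground truth
(mention spans, encounter-level feature sets, outcome scores) is emitted by
construction while assembling — never re-derived by parsing the generated
text.  The truth score is computed by the generator's own arithmetic
directly from its draws, so generator/outcome-model consistency is a real
(falsifiable) invariant.

Default parameters mirror the validation study's conditions: 1,003 patients
with two evaluable encounters each at least 14 days apart, 2018–2020 dates,
feature prevalences and structured coding sensitivities matching the
published per-feature occurrence and structured-recall figures.  Narrative
style parameters (negation, abbreviation, distractor rates) have no
published values and are fixed artifact choices (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path
from typing import Optional, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .corpus import (
    CodedRecord,
    CodeSystem,
    Descriptor,
    EncounterFeatures,
    EncounterNote,
    Feature,
    FeatureMention,
    MentionSource,
    Severity,
    Span,
    write_annotations,
    write_coded,
    write_features_csv,
    write_notes,
)
from .scoring import MigraineScore, write_scores_csv

__all__ = ["ConfigError", "GeneratorConfig", "SyntheticCorpus", "generate_corpus", "code_encounters"]


class ConfigError(ValueError):
    """An invalid generator configuration."""


def _default_prevalence() -> dict[Feature, float]:
    # per-encounter asserted-feature rates matching the published
    # manual-annotation occurrence counts over 2,006 encounters
    return {
        Feature.HEADACHE: 0.995,
        Feature.MIGRAINE: 0.655,
        Feature.NAUSEA: 0.596,
        Feature.VOMITING: 0.442,
        Feature.PHOTOPHOBIA: 0.228,
        Feature.PHONOPHOBIA: 0.159,
    }


def _default_severity() -> dict[Severity, float]:
    # mild/severe rates among headache encounters from the published counts;
    # moderate occurred below the 20-occurrence reporting floor
    return {
        Severity.NONE_STATED: 0.830,
        Severity.MILD: 0.052,
        Severity.MODERATE: 0.0,
        Severity.SEVERE: 0.118,
    }


def _default_sensitivity() -> dict[Feature, float]:
    # probability a true encounter-level feature receives a diagnosis code;
    # matches the published structured-data recall deficit
    return {
        Feature.HEADACHE: 0.331,
        Feature.MIGRAINE: 0.585,
        Feature.NAUSEA: 0.025,
        Feature.VOMITING: 0.010,
        Feature.PHOTOPHOBIA: 0.0,
        Feature.PHONOPHOBIA: 0.0,
    }


class GeneratorConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(default=1003, ge=1)
    encounters_per_patient: int = Field(default=2, ge=2)
    date_start: date = date(2018, 1, 1)
    date_end: date = date(2020, 12, 31)
    feature_prevalence: dict[Feature, float] = Field(default_factory=_default_prevalence)
    negation_rate: float = 0.15
    severity_distribution: dict[Severity, float] = Field(default_factory=_default_severity)
    descriptor_probability: float = 0.136
    abbreviation_rate: float = 0.20
    distractor_rate: float = 0.30
    structured_sensitivity: dict[Feature, float] = Field(default_factory=_default_sensitivity)
    structured_false_code_rate: float = 0.01
    min_separation_days: int = Field(default=14, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _valid(self) -> "GeneratorConfig":
        probs = [
            self.negation_rate,
            self.descriptor_probability,
            self.abbreviation_rate,
            self.distractor_rate,
            self.structured_false_code_rate,
            *self.feature_prevalence.values(),
            *self.structured_sensitivity.values(),
            *self.severity_distribution.values(),
        ]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all probabilities must lie in [0, 1]")
        if abs(sum(self.severity_distribution.values()) - 1.0) > 1e-9:
            raise ConfigError("severity_distribution must sum to 1")
        if self.date_end <= self.date_start:
            raise ConfigError("date_end must follow date_start")
        return self

    @classmethod
    def zero_noise(cls, n_patients: int = 500, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Conditions under which extraction must equal truth exactly:
        no ambiguity injection, no distractors, no spurious codes."""
        kwargs = dict(
            n_patients=n_patients,
            abbreviation_rate=0.0,
            distractor_rate=0.0,
            structured_false_code_rate=0.0,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class SyntheticCorpus:
    notes: list[EncounterNote]
    coded: list[CodedRecord]
    truth_mentions: list[FeatureMention]
    truth_features: dict[str, EncounterFeatures]
    truth_scores: dict[str, MigraineScore]

    def write(self, out_dir: Union[str, Path]) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_notes(self.notes, out / "notes.jsonl")
        write_coded(self.coded, out / "coded.csv")
        write_annotations(self.truth_mentions, out / "truth_annotations.jsonl")
        write_features_csv(self.truth_features, out / "truth_features.csv")
        write_scores_csv(self.truth_scores, out / "truth_scores.csv")


# --------------------------------------------------------------------------
# Template grammar
# --------------------------------------------------------------------------

_POSITIVE_TEMPLATES = (
    "Reports {}.",
    "Patient reports {}.",
    "Complains of {}.",
    "Ongoing {} this week.",
)

_NEGATED_TEMPLATES = (
    "Denies {}.",
    "No {} today.",
    "Patient denies any {}.",
    "Negative for {}.",
)

# migraine-with-aura templates for the ambiguous abbreviation: the allowed
# cue "aura" is part of the sentence by construction
_MA_TEMPLATES = (
    "History of MA with aura.",
    "MA with aura reported today.",
)

_DISTRACTORS = (
    "Medication refill discussed.",
    "Past medical history reviewed.",
    "Vitals taken by the medical assistant.",
    "MA took vitals before the exam.",
    "Seen with the medical assistant (MA) today.",
    "Follow up in four weeks.",
)

#: Positive-sentence surface choices per feature: (form, weight).
_POSITIVE_SURFACES: dict[Feature, tuple[tuple[str, float], ...]] = {
    Feature.HEADACHE: (("headache", 0.8), ("headaches", 0.2)),
    Feature.MIGRAINE: (("migraine", 0.7), ("migraines", 0.15), ("migraine with aura", 0.15)),
    Feature.NAUSEA: (("nausea", 0.8), ("nauseated", 0.2)),
    Feature.VOMITING: (("vomiting", 0.7), ("emesis", 0.15), ("throwing up", 0.15)),
    Feature.PHOTOPHOBIA: (
        ("photophobia", 0.6),
        ("sensitive to light", 0.25),
        ("light sensitivity", 0.15),
    ),
    Feature.PHONOPHOBIA: (
        ("phonophobia", 0.6),
        ("sensitive to sound", 0.25),
        ("sound sensitivity", 0.15),
    ),
}

#: Canonical (noun) surface used in negated sentences.
_NEGATED_SURFACE = {f: f.value for f in Feature}

#: Descriptor draw weights; the last three occurred below the reporting floor.
_DESCRIPTOR_WEIGHTS: tuple[tuple[Descriptor, float], ...] = (
    (Descriptor.THROBBING, 0.45),
    (Descriptor.PULSATING, 0.29),
    (Descriptor.STABBING, 0.18),
    (Descriptor.DEBILITATING, 0.04),
    (Descriptor.DISABLING, 0.03),
    (Descriptor.PIERCING, 0.01),
)

_SEVERITY_ADJ = {Severity.MILD: "mild", Severity.MODERATE: "moderate", Severity.SEVERE: "severe"}


def _choice(rng: np.random.Generator, pairs) -> object:
    items = [p[0] for p in pairs]
    weights = np.asarray([p[1] for p in pairs], dtype=float)
    return items[int(rng.choice(len(items), p=weights / weights.sum()))]


@dataclass
class _PlannedSentence:
    text: str
    # (rel_start, rel_end, feature, negated, severity, descriptor)
    mention: Optional[tuple[int, int, Feature, bool, Severity, Optional[Descriptor]]] = None


def _positive_sentence(
    rng: np.random.Generator,
    feature: Feature,
    severity: Severity,
    descriptor: Optional[Descriptor],
    abbreviation_rate: float,
) -> _PlannedSentence:
    if feature is Feature.MIGRAINE and rng.random() < abbreviation_rate:
        template = str(rng.choice(_MA_TEMPLATES))
        rel = template.index("MA")
        return _PlannedSentence(
            text=template,
            mention=(rel, rel + 2, feature, False, Severity.NONE_STATED, None),
        )
    if feature is Feature.HEADACHE and rng.random() < abbreviation_rate:
        surface = "HA"
    else:
        surface = str(_choice(rng, _POSITIVE_SURFACES[feature]))
    prefix_parts = []
    if feature is Feature.HEADACHE:
        if severity is not Severity.NONE_STATED:
            prefix_parts.append(_SEVERITY_ADJ[severity])
        if descriptor is not None:
            prefix_parts.append(descriptor.value)
    phrase = " ".join(prefix_parts + [surface])
    template = str(rng.choice(_POSITIVE_TEMPLATES))
    text = template.format(phrase)
    text = text[0].upper() + text[1:]
    phrase_rel = text.index(phrase) if phrase in text else text.lower().index(phrase.lower())
    rel = phrase_rel + (len(phrase) - len(surface))
    sev = severity if feature is Feature.HEADACHE else Severity.NONE_STATED
    desc = descriptor if feature is Feature.HEADACHE else None
    return _PlannedSentence(text=text, mention=(rel, rel + len(surface), feature, False, sev, desc))


def _negated_sentence(rng: np.random.Generator, feature: Feature) -> _PlannedSentence:
    surface = _NEGATED_SURFACE[feature]
    template = str(rng.choice(_NEGATED_TEMPLATES))
    text = template.format(surface)
    rel = text.lower().index(surface)
    return _PlannedSentence(
        text=text, mention=(rel, rel + len(surface), feature, True, Severity.NONE_STATED, None)
    )


def _truth_score(
    asserted: set[Feature], severity: Severity, descriptor: Optional[Descriptor]
) -> MigraineScore:
    """The generator's own score arithmetic, independent of the outcome model."""
    if Feature.HEADACHE in asserted or Feature.MIGRAINE in asserted:
        if descriptor is not None and Feature.HEADACHE in asserted:
            sev_pts = 7
        else:
            sev_pts = {
                Severity.NONE_STATED: 3,
                Severity.MILD: 3,
                Severity.MODERATE: 5,
                Severity.SEVERE: 7,
            }[severity if Feature.HEADACHE in asserted else Severity.NONE_STATED]
    else:
        sev_pts = 1
    assoc = int(Feature.NAUSEA in asserted) + int(Feature.VOMITING in asserted)
    assoc += int(Feature.PHOTOPHOBIA in asserted or Feature.PHONOPHOBIA in asserted)
    return MigraineScore(severity_points=sev_pts, associated_points=assoc, total=sev_pts + assoc)


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate notes, coded records and exact ground truth.

    Deterministic given ``config.seed``.  Consecutive encounters of a
    patient are always at least ``min_separation_days`` apart.
    """
    rng = np.random.default_rng(config.seed)
    notes: list[EncounterNote] = []
    truth_mentions: list[FeatureMention] = []
    truth_features: dict[str, EncounterFeatures] = {}
    truth_scores: dict[str, MigraineScore] = {}

    span_days = (config.date_end - config.date_start).days
    max_gap = max(config.min_separation_days + 1, min(90, span_days // config.encounters_per_patient))

    for i in range(config.n_patients):
        pid = f"p{i:05d}"
        budget = max(1, span_days - (config.encounters_per_patient - 1) * max_gap)
        day = int(rng.integers(0, budget))
        for j in range(config.encounters_per_patient):
            eid = f"{pid}e{j}"
            enc_date = config.date_start + timedelta(days=day)
            day += int(rng.integers(config.min_separation_days, max_gap + 1))
            specialty = "neurology" if rng.random() < 0.6 else "primary_care"

            asserted: set[Feature] = set()
            planned: list[_PlannedSentence] = []
            severity = Severity.NONE_STATED
            descriptor: Optional[Descriptor] = None
            for feature in Feature:
                if rng.random() < config.feature_prevalence.get(feature, 0.0):
                    asserted.add(feature)
                    sev, desc = Severity.NONE_STATED, None
                    if feature is Feature.HEADACHE:
                        sev_levels = list(config.severity_distribution)
                        sev_p = np.asarray(
                            [config.severity_distribution[s] for s in sev_levels], dtype=float
                        )
                        severity = sev = sev_levels[int(rng.choice(len(sev_levels), p=sev_p / sev_p.sum()))]
                        if rng.random() < config.descriptor_probability:
                            descriptor = desc = _choice(rng, _DESCRIPTOR_WEIGHTS)  # type: ignore[assignment]
                    planned.append(
                        _positive_sentence(rng, feature, sev, desc, config.abbreviation_rate)
                    )
                elif rng.random() < config.negation_rate:
                    planned.append(_negated_sentence(rng, feature))

            n_distractors = int(rng.binomial(3, config.distractor_rate))
            for k in range(n_distractors):
                planned.append(_PlannedSentence(text=str(rng.choice(_DISTRACTORS))))

            order = rng.permutation(len(planned))
            narrative_parts: list[str] = []
            offset = 0
            for idx in order:
                sent = planned[int(idx)]
                if sent.mention is not None:
                    s, e, feat, neg, sev, desc = sent.mention
                    truth_mentions.append(
                        FeatureMention(
                            encounter_id=eid,
                            feature=feat,
                            span=Span(start=offset + s, end=offset + e),
                            negated=neg,
                            severity=sev,
                            descriptor=desc,
                            source=MentionSource.MANUAL,
                        )
                    )
                narrative_parts.append(sent.text)
                offset += len(sent.text) + 1  # single-space joined
            narrative = " ".join(narrative_parts)

            if Feature.HEADACHE in asserted:
                chief = "headache"
            else:
                chief = "follow up" if rng.random() < 0.5 else "med refill"

            notes.append(
                EncounterNote(
                    patient_id=pid,
                    encounter_id=eid,
                    date=enc_date,
                    specialty=specialty,
                    chief_complaint=chief,
                    narrative=narrative,
                )
            )
            truth_features[eid] = EncounterFeatures(
                encounter_id=eid,
                features=frozenset(asserted),
                severities=(
                    frozenset({severity})
                    if Feature.HEADACHE in asserted and severity is not Severity.NONE_STATED
                    else frozenset()
                ),
                descriptors=(
                    frozenset({descriptor})
                    if Feature.HEADACHE in asserted and descriptor is not None
                    else frozenset()
                ),
            )
            truth_scores[eid] = _truth_score(
                asserted,
                severity if Feature.HEADACHE in asserted else Severity.NONE_STATED,
                descriptor if Feature.HEADACHE in asserted else None,
            )

    coded = code_encounters(truth_features, config)
    return SyntheticCorpus(
        notes=notes,
        coded=coded,
        truth_mentions=truth_mentions,
        truth_features=truth_features,
        truth_scores=truth_scores,
    )


#: Representative ICD-10-CM code per feature for synthetic coding.
_FEATURE_CODES: dict[Feature, tuple[str, str]] = {
    Feature.HEADACHE: ("R51.9", "Headache, unspecified"),
    Feature.MIGRAINE: ("G43.909", "Migraine, unspecified, not intractable"),
    Feature.NAUSEA: ("R11.0", "Nausea"),
    Feature.VOMITING: ("R11.10", "Vomiting, unspecified"),
    Feature.PHOTOPHOBIA: ("H53.149", "Visual discomfort, unspecified eye"),
    Feature.PHONOPHOBIA: ("H93.233", "Hyperacusis, bilateral"),
}

_FILLER_CODES = (
    ("Z79.899", "Other long term (current) drug therapy"),
    ("I10", "Essential (primary) hypertension"),
    ("E11.9", "Type 2 diabetes mellitus without complications"),
)


def code_encounters(
    truth: dict[str, EncounterFeatures],
    config: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[CodedRecord]:
    """Simulate structured coding of true encounter-level features.

    Each true feature is coded independently with probability
    ``structured_sensitivity[feature]``; severity and descriptor facts are
    never coded (no codes exist for them).  Non-asserted features may draw a
    spurious code with probability ``structured_false_code_rate``, and
    unrelated filler codes are mixed in to exercise unmapped-code handling.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 17])
    coded: list[CodedRecord] = []
    for eid in truth:
        ef = truth[eid]
        for feature in Feature:
            code, desc = _FEATURE_CODES[feature]
            if feature in ef.features:
                if rng.random() < config.structured_sensitivity.get(feature, 0.0):
                    coded.append(
                        CodedRecord(
                            encounter_id=eid, code_system=CodeSystem.ICD10CM, code=code, description=desc
                        )
                    )
            elif rng.random() < config.structured_false_code_rate:
                coded.append(
                    CodedRecord(
                        encounter_id=eid, code_system=CodeSystem.ICD10CM, code=code, description=desc
                    )
                )
        if rng.random() < 0.5:
            code, desc = _FILLER_CODES[int(rng.integers(len(_FILLER_CODES)))]
            coded.append(
                CodedRecord(
                    encounter_id=eid, code_system=CodeSystem.ICD10CM, code=code, description=desc
                )
            )
    return coded
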