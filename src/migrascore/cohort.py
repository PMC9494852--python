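"""Patient- and encounter-level inclusion filters and the study split.

An encounter is *evaluable* when headache is the primary reason for the
visit (chief-complaint field contains a headache-family term) or when the
narrative mentions headache at least twice — migraine terms count as
headache mentions for this filter, and mentions are counted regardless of
negation (the filter precedes attribute analysis).

A patient is *eligible* when migraine appears somewhere in their structured
or unstructured record and they have at least two evaluable encounters; per
eligible patient the earliest evaluable encounter is paired with the first
subsequent evaluable encounter at least two weeks (14 calendar days) later.
Patients are split into training and validation partitions at patient level
so both paired encounters land on the same side.
"""

from __future__ import annotations

import random
from typing import Iterable, Mapping, Optional, Sequence

from pydantic import BaseModel, ConfigDict, Field

from .corpus import CodedRecord, EncounterNote, Feature
from .extraction import Lexicon, find_mentions, segment, _form_pattern
from .structured import CodeMap

__all__ = [
    "CohortConfig",
    "count_headache_mentions",
    "is_evaluable",
    "select_patients",
    "select_encounter_pair",
    "split_train_validation",
]


class CohortConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    min_headache_mentions: int = Field(default=2, ge=1)
    min_separation_days: int = Field(default=14, ge=0)
    validation_fraction: float = Field(default=0.5, ge=0.0, le=1.0)
    split_seed: int = 0


def _headache_family_patterns(lexicon: Lexicon):
    forms: list[str] = []
    for feat in (Feature.HEADACHE, Feature.MIGRAINE):
        forms.extend(lexicon.surfaces.get(feat, ()))
    # filter matching is deliberately coarse: case-insensitive even for
    # abbreviations, longest form first so "migraine with aura" counts once
    return [
        _form_pattern(f, case_sensitive=False) for f in sorted(forms, key=len, reverse=True)
    ]


def count_headache_mentions(text: str, lexicon: Optional[Lexicon] = None) -> int:
    """Number of non-overlapping headache/migraine surface matches in text."""
    lexicon = lexicon or Lexicon()
    taken: list[tuple[int, int]] = []
    for pattern in _headache_family_patterns(lexicon):
        for m in pattern.finditer(text):
            if not any(m.start() < e and m.end() > s for s, e in taken):
                taken.append((m.start(), m.end()))
    return len(taken)


def is_evaluable(
    note: EncounterNote,
    lexicon: Optional[Lexicon] = None,
    config: Optional[CohortConfig] = None,
) -> bool:
    """True iff headache is the visit's primary reason or is mentioned twice."""
    lexicon = lexicon or Lexicon()
    config = config or CohortConfig()
    if count_headache_mentions(note.chief_complaint, lexicon) >= 1:
        return True
    return count_headache_mentions(note.narrative, lexicon) >= config.min_headache_mentions


def _has_migraine_evidence(
    notes: Sequence[EncounterNote],
    coded_by_encounter: Mapping[str, Sequence[CodedRecord]],
    lexicon: Lexicon,
    codemap: CodeMap,
) -> bool:
    for note in notes:
        for rec in coded_by_encounter.get(note.encounter_id, ()):
            if Feature.MIGRAINE in codemap.lookup(rec.code_system, rec.code):
                return True
        if any(m.feature is Feature.MIGRAINE for m in find_mentions(note, lexicon)):
            return True
    return False


def select_patients(
    notes_by_patient: Mapping[str, Sequence[EncounterNote]],
    coded: Iterable[CodedRecord] = (),
    lexicon: Optional[Lexicon] = None,
    codemap: Optional[CodeMap] = None,
    config: Optional[CohortConfig] = None,
) -> list[str]:
    """Patients with migraine evidence and at least two evaluable encounters."""
    lexicon = lexicon or Lexicon()
    codemap = codemap or CodeMap()
    config = config or CohortConfig()
    coded_by_encounter: dict[str, list[CodedRecord]] = {}
    for rec in coded:
        coded_by_encounter.setdefault(rec.encounter_id, []).append(rec)
    eligible: list[str] = []
    for pid in sorted(notes_by_patient):
        notes = list(notes_by_patient[pid])
        n_evaluable = sum(is_evaluable(n, lexicon, config) for n in notes)
        if n_evaluable < 2:
            continue
        if _has_migraine_evidence(notes, coded_by_encounter, lexicon, codemap):
            eligible.append(pid)
    return eligible


def select_encounter_pair(
    encounters: Sequence[EncounterNote],
    lexicon: Optional[Lexicon] = None,
    config: Optional[CohortConfig] = None,
) -> Optional[tuple[str, str]]:
    """The earliest evaluable encounter paired with the first subsequent
    evaluable encounter dated ≥ ``min_separation_days`` later, or None."""
    lexicon = lexicon or Lexicon()
    config = config or CohortConfig()
    evaluable = sorted(
        (n for n in encounters if is_evaluable(n, lexicon, config)),
        key=lambda n: (n.date, n.encounter_id),
    )
    if len(evaluable) < 2:
        return None
    first = evaluable[0]
    for later in evaluable[1:]:
        if (later.date - first.date).days >= config.min_separation_days:
            return first.encounter_id, later.encounter_id
    return None


def split_train_validation(
    patient_ids: Iterable[str], config: Optional[CohortConfig] = None
) -> tuple[list[str], list[str]]:
    """Patient-level train/validation partition, deterministic given the seed.

    ``|validation| = round(fraction × n)`` with round-half-up.
    """
    config = config or CohortConfig()
    ids = sorted(set(patient_ids))
    rng = random.Random(config.split_seed)
    rng.shuffle(ids)
    n_val = int(config.validation_fraction * len(ids) + 0.5)
    validation = sorted(ids[:n_val])
    train = sorted(ids[n_val:])
    return train, validation
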