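"""Core data types and on-disk formats for encounter corpora.

An encounter is a single patient visit.  Three artifacts describe it:

* a narrative note (``EncounterNote``, stored as JSONL, one object per line),
* zero or more coded diagnosis records (``CodedRecord``, stored as CSV),
* stand-off feature annotations (``FeatureMention``, stored as JSONL with
  0-based half-open character offsets into the narrative).

Stand-off annotation keeps the narrative pristine: a mention points into the
text rather than marking it up, so ``narrative[span.start:span.end]`` always
recovers the annotated surface string.  Narratives are Unicode text,
normalised NFC on read; offsets are character (not byte) offsets.  Dates are
ISO-8601 calendar dates — the methods work at day granularity and carry no
timezone semantics.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "CorpusError",
    "ParseError",
    "Specialty",
    "CodeSystem",
    "Feature",
    "HEADACHE_TYPE",
    "ASSOCIATED_FEATURES",
    "Severity",
    "Descriptor",
    "MentionSource",
    "Span",
    "EncounterNote",
    "CodedRecord",
    "FeatureMention",
    "EncounterFeatures",
    "read_notes",
    "write_notes",
    "read_annotations",
    "write_annotations",
    "validate_annotations",
    "read_coded",
    "write_coded",
    "read_features_csv",
    "write_features_csv",
]


class CorpusError(Exception):
    """A corpus-level consistency violation (e.g. duplicate encounter id)."""


class ParseError(CorpusError):
    """A malformed record in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class Specialty(str, Enum):
    PRIMARY_CARE = "primary_care"
    NEUROLOGY = "neurology"
    OTHER = "other"


class CodeSystem(str, Enum):
    ICD10CM = "ICD10CM"
    LOCAL = "local"


class Feature(str, Enum):
    """Clinical concepts tracked at encounter level."""

    HEADACHE = "headache"
    MIGRAINE = "migraine"
    NAUSEA = "nausea"
    VOMITING = "vomiting"
    PHOTOPHOBIA = "photophobia"
    PHONOPHOBIA = "phonophobia"


#: Features that denote a headache event and may carry severity/descriptor
#: attributes.  Migraine mentions contribute severity evidence to the
#: headache fact because the modelled concept is migraine-associated headache.
HEADACHE_TYPE = frozenset({Feature.HEADACHE, Feature.MIGRAINE})

#: Symptoms that accompany a migraine attack and score associated points.
ASSOCIATED_FEATURES = (
    Feature.NAUSEA,
    Feature.VOMITING,
    Feature.PHOTOPHOBIA,
    Feature.PHONOPHOBIA,
)


class Severity(str, Enum):
    NONE_STATED = "none_stated"
    MILD = "mild"
    MODERATE = "moderate"
    SEVERE = "severe"


class Descriptor(str, Enum):
    """Adjectives treated as evidence of severe headache."""

    PULSATING = "pulsating"
    DEBILITATING = "debilitating"
    STABBING = "stabbing"
    THROBBING = "throbbing"
    DISABLING = "disabling"
    PIERCING = "piercing"


class MentionSource(str, Enum):
    TEXT = "text"
    STRUCTURED = "structured"
    MANUAL = "manual"


class Span(BaseModel):
    """0-based half-open character interval into a narrative."""

    model_config = ConfigDict(frozen=True)

    start: int = Field(ge=0)
    end: int

    @model_validator(mode="after")
    def _ordered(self) -> "Span":
        if self.end <= self.start:
            raise ValueError(f"span [{self.start},{self.end}) is empty or reversed")
        return self

    def slice(self, text: str) -> str:
        return text[self.start : self.end]


class EncounterNote(BaseModel):
    model_config = ConfigDict(frozen=True)

    patient_id: str
    encounter_id: str
    date: date
    specialty: Specialty
    chief_complaint: str = ""
    narrative: str = ""


class CodedRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    encounter_id: str
    code_system: CodeSystem
    code: str = Field(min_length=1)
    description: str = ""


class FeatureMention(BaseModel):
    """A located concept mention with its context attributes.

    Severity and descriptor only apply to headache-type mentions (headache,
    migraine); structured-source mentions carry no span.
    """

    model_config = ConfigDict(frozen=True)

    encounter_id: str
    feature: Feature
    span: Optional[Span] = None
    negated: bool = False
    severity: Severity = Severity.NONE_STATED
    descriptor: Optional[Descriptor] = None
    source: MentionSource = MentionSource.TEXT

    @model_validator(mode="after")
    def _consistent(self) -> "FeatureMention":
        if self.source is MentionSource.TEXT and self.span is None:
            raise ValueError("text-source mention requires a span")
        if self.source is MentionSource.STRUCTURED and self.span is not None:
            raise ValueError("structured-source mention must not carry a span")
        if self.feature not in HEADACHE_TYPE:
            if self.severity is not Severity.NONE_STATED:
                raise ValueError(f"severity not applicable to {self.feature.value}")
            if self.descriptor is not None:
                raise ValueError(f"descriptor not applicable to {self.feature.value}")
        return self


class EncounterFeatures(BaseModel):
    """The asserted (non-negated) feature set of one encounter.

    This is the unit the validation statistics operate on: each feature
    appears at most once, and the headache fact carries the set of documented
    severities and descriptors observed across non-negated headache-type
    mentions.
    """

    model_config = ConfigDict(frozen=True)

    encounter_id: str
    features: frozenset[Feature] = frozenset()
    severities: frozenset[Severity] = frozenset()
    descriptors: frozenset[Descriptor] = frozenset()

    @model_validator(mode="after")
    def _consistent(self) -> "EncounterFeatures":
        if Severity.NONE_STATED in self.severities:
            raise ValueError("severities holds documented severities only")
        if (self.severities or self.descriptors) and not (self.features & HEADACHE_TYPE):
            raise ValueError("severity/descriptor facts require a headache-type feature")
        return self

    def facts(self) -> frozenset[str]:
        """Binary encounter-level fact keys, one per evaluation-table row.

        Base features use their own names; severity facts are keyed
        ``headache (mild|moderate|severe)``; descriptor facts use the
        adjective itself.
        """
        keys = {f.value for f in self.features}
        keys.update(f"headache ({s.value})" for s in self.severities)
        keys.update(d.value for d in self.descriptors)
        return frozenset(keys)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

PathLike = Union[str, Path]

_NOTE_FIELDS = ("patient_id", "encounter_id", "date", "specialty", "chief_complaint", "narrative")


def read_notes(path: PathLike) -> list[EncounterNote]:
    """Read an encounter-note corpus from JSONL.

    Narratives and chief complaints are NFC-normalised; text is otherwise
    preserved byte-for-byte.  Raises :class:`ParseError` (with line number)
    for malformed records and :class:`CorpusError` for duplicate encounter
    ids.
    """
    notes: list[EncounterNote] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc}", line=lineno) from exc
            missing = [f for f in _NOTE_FIELDS[:4] if f not in raw]
            if missing:
                raise ParseError(f"missing required field(s): {', '.join(missing)}", line=lineno)
            for key in ("chief_complaint", "narrative"):
                if key in raw and isinstance(raw[key], str):
                    raw[key] = unicodedata.normalize("NFC", raw[key])
            try:
                note = EncounterNote(**{k: raw[k] for k in _NOTE_FIELDS if k in raw})
            except Exception as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if note.encounter_id in seen:
                raise CorpusError(f"duplicate encounter_id {note.encounter_id!r}")
            seen.add(note.encounter_id)
            notes.append(note)
    return notes


def write_notes(notes: Iterable[EncounterNote], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            rec = note.model_dump(mode="json")
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def write_annotations(mentions: Iterable[FeatureMention], path: PathLike) -> None:
    """Write stand-off annotations as JSONL, preserving order."""
    with open(path, "w", encoding="utf-8") as fh:
        for m in mentions:
            rec = {
                "encounter_id": m.encounter_id,
                "feature": m.feature.value,
                "start": m.span.start if m.span else None,
                "end": m.span.end if m.span else None,
                "negated": m.negated,
                "severity": m.severity.value,
                "descriptor": m.descriptor.value if m.descriptor else None,
                "source": m.source.value,
            }
            fh.write(json.dumps(rec, ensure_ascii=False) + "\n")


def read_annotations(path: PathLike) -> list[FeatureMention]:
    mentions: list[FeatureMention] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                raw = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"invalid JSON: {exc}", line=lineno) from exc
            span = None
            if raw.get("start") is not None:
                try:
                    span = Span(start=raw["start"], end=raw["end"])
                except Exception as exc:
                    raise ParseError(str(exc), line=lineno) from exc
            try:
                mentions.append(
                    FeatureMention(
                        encounter_id=raw["encounter_id"],
                        feature=raw["feature"],
                        span=span,
                        negated=raw.get("negated", False),
                        severity=raw.get("severity", Severity.NONE_STATED),
                        descriptor=raw.get("descriptor"),
                        source=raw.get("source", MentionSource.TEXT),
                    )
                )
            except KeyError as exc:
                raise ParseError(f"missing required field {exc}", line=lineno) from exc
            except Exception as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return mentions


def validate_annotations(
    mentions: Iterable[FeatureMention], notes: Iterable[EncounterNote]
) -> None:
    """Cross-check every mention span against its narrative.

    Raises :class:`CorpusError` for an unknown encounter id or a span that
    falls outside the narrative.
    """
    by_id = {n.encounter_id: n for n in notes}
    for m in mentions:
        if m.encounter_id not in by_id:
            raise CorpusError(f"mention references unknown encounter {m.encounter_id!r}")
        if m.span is not None and m.span.end > len(by_id[m.encounter_id].narrative):
            raise CorpusError(
                f"span [{m.span.start},{m.span.end}) outside narrative of "
                f"encounter {m.encounter_id!r}"
            )


_CODED_HEADER = ["encounter_id", "code_system", "code", "description"]


def read_coded(path: PathLike) -> list[CodedRecord]:
    """Read coded records from CSV.  Codes are upper-cased, dots preserved."""
    records: list[CodedRecord] = []
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or list(reader.fieldnames) != _CODED_HEADER:
            raise ParseError(
                f"expected header {','.join(_CODED_HEADER)}, got {reader.fieldnames}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                records.append(
                    CodedRecord(
                        encounter_id=row["encounter_id"],
                        code_system=row["code_system"],
                        code=(row["code"] or "").upper(),
                        description=row.get("description") or "",
                    )
                )
            except Exception as exc:
                raise ParseError(str(exc), line=lineno) from exc
    return records


def write_coded(records: Iterable[CodedRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CODED_HEADER)
        for r in records:
            writer.writerow([r.encounter_id, r.code_system.value, r.code, r.description])


def write_features_csv(
    features: Mapping[str, EncounterFeatures] | Sequence[EncounterFeatures], path: PathLike
) -> None:
    """Write encounter-level feature sets as CSV (sets joined with ';')."""
    if isinstance(features, Mapping):
        rows = [features[k] for k in features]
    else:
        rows = list(features)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["encounter_id", "features", "severities", "descriptors"])
        for ef in rows:
            writer.writerow(
                [
                    ef.encounter_id,
                    ";".join(sorted(f.value for f in ef.features)),
                    ";".join(sorted(s.value for s in ef.severities)),
                    ";".join(sorted(d.value for d in ef.descriptors)),
                ]
            )


def read_features_csv(path: PathLike) -> dict[str, EncounterFeatures]:
    out: dict[str, EncounterFeatures] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        for lineno, row in enumerate(reader, start=2):
            try:
                ef = EncounterFeatures(
                    encounter_id=row["encounter_id"],
                    features=frozenset(
                        Feature(v) for v in row["features"].split(";") if v
                    ),
                    severities=frozenset(
                        Severity(v) for v in row["severities"].split(";") if v
                    ),
                    descriptors=frozenset(
                        Descriptor(v) for v in row["descriptors"].split(";") if v
                    ),
                )
            except Exception as exc:
                raise ParseError(str(exc), line=lineno) from exc
            if ef.encounter_id in out:
                raise CorpusError(f"duplicate encounter_id {ef.encounter_id!r}")
            out[ef.encounter_id] = ef
    return out
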