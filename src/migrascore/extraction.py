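"""Rule-based concept extraction from encounter narratives.

A transparent NegEx/ConText-style engine: a lexicon of surface forms per
clinical concept, sentence segmentation, longest-match mention finding with
abbreviation disambiguation, and window-based attachment of negation,
severity and descriptor attributes.  No trained weights — every decision is
traceable to a lexicon entry and a scope rule.

Pipeline per note::

    segment -> find_mentions -> apply_context -> aggregate_encounter

Scope rules (token windows are configurable on the lexicon):

* negation — a mention is negated iff a negation cue precedes it in the same
  sentence, at most ``negation_window`` (default 6) tokens away, with no
  scope terminator ("but", "however", ".", ";") between cue and mention;
* severity — the nearest severity adjective in the same sentence within 4
  tokens before or 3 after a headache-type mention, else none stated;
* descriptor — the nearest severe-headache descriptor in the same sentence,
  attached to headache-type mentions.

Ambiguous abbreviations ("MA") are emitted only when an allowed context cue
(e.g. "aura", "headache") occurs in the same sentence and no blocked cue
(e.g. "assistant") does — the classic disambiguation of "MA" to "migraine
with aura" rather than "medical assistant".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .corpus import (
    HEADACHE_TYPE,
    Descriptor,
    EncounterFeatures,
    EncounterNote,
    Feature,
    FeatureMention,
    MentionSource,
    Severity,
    Span,
)

__all__ = [
    "LexiconError",
    "Lexicon",
    "Token",
    "Sentence",
    "segment",
    "find_mentions",
    "apply_context",
    "aggregate_encounter",
    "extract_note",
    "extract_corpus",
]


class LexiconError(ValueError):
    """An inconsistent lexicon (e.g. one surface form mapping to two features)."""


@dataclass(frozen=True)
class AmbiguousForm:
    """A surface form emitted only in a supporting context."""

    feature: Feature
    allowed: frozenset[str]  # cue words; at least one must occur in-sentence
    blocked: frozenset[str]  # any occurrence suppresses the mention


_DEFAULT_SURFACES: dict[Feature, tuple[str, ...]] = {
    Feature.HEADACHE: ("headache", "headaches", "HA", "cephalalgia"),
    Feature.MIGRAINE: ("migraine", "migraines", "migraine with aura", "MA"),
    Feature.NAUSEA: ("nausea", "nauseated", "nauseous"),
    Feature.VOMITING: ("vomiting", "vomited", "emesis", "throwing up"),
    Feature.PHOTOPHOBIA: ("photophobia", "light sensitivity", "sensitive to light"),
    Feature.PHONOPHOBIA: (
        "phonophobia",
        "sound sensitivity",
        "sensitive to sound",
        "sensitive to noise",
    ),
}


@dataclass(frozen=True)
class Lexicon:
    """Surface forms, attribute vocabularies and scope parameters.

    All forms are matched case-insensitively except the flagged abbreviations
    (``case_sensitive``), which must appear verbatim — "ha" inside running
    text is not a headache.
    """

    surfaces: dict[Feature, tuple[str, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_SURFACES)
    )
    case_sensitive: frozenset[str] = frozenset({"HA", "MA"})
    severity_terms: dict[str, Severity] = field(
        default_factory=lambda: {
            "mild": Severity.MILD,
            "moderate": Severity.MODERATE,
            "severe": Severity.SEVERE,
        }
    )
    descriptor_terms: dict[str, Descriptor] = field(
        default_factory=lambda: {d.value: d for d in Descriptor}
    )
    negation_cues: tuple[str, ...] = ("no", "denies", "denied", "without", "negative for", "not")
    scope_terminators: frozenset[str] = frozenset({"but", "however", ".", ";"})
    ambiguous: dict[str, AmbiguousForm] = field(
        default_factory=lambda: {
            "MA": AmbiguousForm(
                feature=Feature.MIGRAINE,
                allowed=frozenset(
                    {"aura", "headache", "headaches", "migraine", "migraines", "ha"}
                ),
                blocked=frozenset({"assistant", "mass", "massachusetts"}),
            )
        }
    )
    negation_window: int = 6
    severity_window_before: int = 4
    severity_window_after: int = 3

    def __post_init__(self) -> None:
        owner: dict[str, Feature] = {}
        for feat, forms in self.surfaces.items():
            for form in forms:
                key = form if form in self.case_sensitive else form.lower()
                if key in owner and owner[key] != feat and form not in self.ambiguous:
                    raise LexiconError(f"surface form {form!r} maps to two features")
                owner[key] = feat

    # -- serialisation -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "Lexicon":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "features" in raw:
            kwargs["surfaces"] = {
                Feature(k): tuple(v) for k, v in raw["features"].items()
            }
        if "case_sensitive" in raw:
            kwargs["case_sensitive"] = frozenset(raw["case_sensitive"])
        if "severity" in raw:
            kwargs["severity_terms"] = {k: Severity(v) for k, v in raw["severity"].items()}
        if "descriptors" in raw:
            kwargs["descriptor_terms"] = {d: Descriptor(d) for d in raw["descriptors"]}
        if "negation_cues" in raw:
            kwargs["negation_cues"] = tuple(raw["negation_cues"])
        if "scope_terminators" in raw:
            kwargs["scope_terminators"] = frozenset(raw["scope_terminators"])
        if "ambiguous" in raw:
            kwargs["ambiguous"] = {
                form: AmbiguousForm(
                    feature=Feature(spec["feature"]),
                    allowed=frozenset(w.lower() for w in spec.get("allowed", [])),
                    blocked=frozenset(w.lower() for w in spec.get("blocked", [])),
                )
                for form, spec in raw["ambiguous"].items()
            }
        for key in ("negation_window", "severity_window_before", "severity_window_after"):
            if key in raw:
                kwargs[key] = int(raw[key])
        return cls(**kwargs)

    def to_yaml(self, path: Union[str, Path]) -> None:
        raw = {
            "features": {f.value: list(forms) for f, forms in self.surfaces.items()},
            "case_sensitive": sorted(self.case_sensitive),
            "severity": {k: v.value for k, v in self.severity_terms.items()},
            "descriptors": sorted(self.descriptor_terms),
            "negation_cues": list(self.negation_cues),
            "scope_terminators": sorted(self.scope_terminators),
            "ambiguous": {
                form: {
                    "feature": spec.feature.value,
                    "allowed": sorted(spec.allowed),
                    "blocked": sorted(spec.blocked),
                }
                for form, spec in self.ambiguous.items()
            },
            "negation_window": self.negation_window,
            "severity_window_before": self.severity_window_before,
            "severity_window_after": self.severity_window_after,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Token:
    start: int
    end: int
    text: str


@dataclass(frozen=True)
class Sentence:
    start: int
    end: int
    tokens: tuple[Token, ...]

    def text(self, narrative: str) -> str:
        return narrative[self.start : self.end]


#: Abbreviations whose trailing period does not end a sentence.
_SAFE_ABBREVIATIONS = ("dr", "pt", "hx")

_TOKEN_RE = re.compile(r"[A-Za-z0-9]+|[^\sA-Za-z0-9]")
_BOUNDARY_RE = re.compile(r"[.!?]|\n+")
_ABBREV_RE = re.compile(
    r"(?:^|[\s(\[])(%s)$" % "|".join(_SAFE_ABBREVIATIONS), re.IGNORECASE
)


def _tokenize(narrative: str, start: int, end: int) -> tuple[Token, ...]:
    return tuple(
        Token(start=m.start() + start, end=m.end() + start, text=m.group())
        for m in _TOKEN_RE.finditer(narrative[start:end])
    )


def segment(narrative: str) -> list[Sentence]:
    """Split a narrative into sentences with offset-carrying tokens.

    Boundaries are ``.``, ``!``, ``?`` and newline runs; a period after a
    known abbreviation ("Dr.", "pt.", "hx.") does not end a sentence.
    Sentence spans are trimmed of surrounding whitespace and never overlap.
    """
    if not narrative:
        return []
    boundaries: list[int] = []  # index one past the end of each raw segment
    for m in _BOUNDARY_RE.finditer(narrative):
        if m.group().startswith(("\n",)):
            boundaries.append(m.start())
            boundaries.append(m.end())  # newline excluded from either side
        else:
            if m.group() == ".":
                tail = narrative[max(0, m.start() - 8) : m.start()]
                if _ABBREV_RE.search(tail):
                    continue
            boundaries.append(m.end())
    boundaries.append(len(narrative))
    sentences: list[Sentence] = []
    prev = 0
    for b in boundaries:
        if b <= prev:
            prev = max(prev, b)
            continue
        seg = narrative[prev:b]
        stripped = seg.strip()
        if stripped:
            s = prev + (len(seg) - len(seg.lstrip()))
            e = s + len(stripped)
            sentences.append(Sentence(start=s, end=e, tokens=_tokenize(narrative, s, e)))
        prev = b
    return sentences


# ---------------------------------------------------------------------------
# Mention finding
# ---------------------------------------------------------------------------


def _form_pattern(form: str, case_sensitive: bool) -> re.Pattern:
    # word-bounded on alphanumerics; internal spaces tolerate any whitespace run
    body = r"\s+".join(re.escape(part) for part in form.split())
    pattern = r"(?<![A-Za-z0-9])" + body + r"(?![A-Za-z0-9])"
    return re.compile(pattern, 0 if case_sensitive else re.IGNORECASE)


def _compiled_surfaces(lexicon: Lexicon) -> list[tuple[re.Pattern, Feature, str]]:
    compiled = []
    for feat, forms in lexicon.surfaces.items():
        for form in forms:
            compiled.append((_form_pattern(form, form in lexicon.case_sensitive), feat, form))
    return compiled


def _word_present(words: frozenset[str], sentence_tokens: Sequence[Token]) -> bool:
    toks = {t.text.lower() for t in sentence_tokens}
    single = {w for w in words if " " not in w}
    if toks & single:
        return True
    multi = [w.split() for w in words if " " in w]
    if multi:
        lowered = [t.text.lower() for t in sentence_tokens]
        for seq in multi:
            n = len(seq)
            if any(lowered[i : i + n] == seq for i in range(len(lowered) - n + 1)):
                return True
    return False


def find_mentions(note: EncounterNote, lexicon: Optional[Lexicon] = None) -> list[FeatureMention]:
    """Locate concept mentions in a note's narrative (attributes unset).

    Longest match wins among overlapping candidates ("migraine with aura"
    beats "migraine"); matching is case-insensitive except for flagged
    abbreviations; ambiguous forms require an allowed in-sentence cue and the
    absence of blocked cues.
    """
    lexicon = lexicon or Lexicon()
    compiled = _compiled_surfaces(lexicon)
    mentions: list[FeatureMention] = []
    for sent in segment(note.narrative):
        text = note.narrative[sent.start : sent.end]
        candidates: list[tuple[int, int, Feature, str]] = []
        for pattern, feat, form in compiled:
            for m in pattern.finditer(text):
                candidates.append((m.start() + sent.start, m.end() + sent.start, feat, form))
        candidates.sort(key=lambda c: (c[0], c[0] - c[1]))
        taken_end = -1
        for start, end, feat, form in candidates:
            if start < taken_end:
                continue
            if form in lexicon.ambiguous:
                spec = lexicon.ambiguous[form]
                other = [t for t in sent.tokens if not (t.start >= start and t.end <= end)]
                if _word_present(spec.blocked, other):
                    continue
                if not _word_present(spec.allowed, other):
                    continue
                feat = spec.feature
            mentions.append(
                FeatureMention(
                    encounter_id=note.encounter_id,
                    feature=feat,
                    span=Span(start=start, end=end),
                    source=MentionSource.TEXT,
                )
            )
            taken_end = end
    mentions.sort(key=lambda m: m.span.start)  # type: ignore[union-attr]
    return mentions


# ---------------------------------------------------------------------------
# Context attributes
# ---------------------------------------------------------------------------


def _token_range(sentence: Sentence, span: Span) -> tuple[int, int]:
    """Indices of the first and last sentence token overlapping the span."""
    idx = [
        i for i, t in enumerate(sentence.tokens) if t.start < span.end and t.end > span.start
    ]
    return (idx[0], idx[-1]) if idx else (0, -1)


def _cue_positions(tokens: Sequence[Token], cues: Iterable[str]) -> list[tuple[int, int]]:
    """(first_idx, last_idx) of every cue occurrence; cues may be multi-word."""
    lowered = [t.text.lower() for t in tokens]
    out = []
    for cue in cues:
        seq = cue.split()
        n = len(seq)
        for i in range(len(lowered) - n + 1):
            if lowered[i : i + n] == seq:
                out.append((i, i + n - 1))
    return out


def apply_context(
    mentions: Iterable[FeatureMention],
    sentences: Sequence[Sentence],
    lexicon: Optional[Lexicon] = None,
) -> list[FeatureMention]:
    """Attach negation / severity / descriptor attributes to mentions."""
    lexicon = lexicon or Lexicon()
    out: list[FeatureMention] = []
    for m in mentions:
        if m.span is None:
            out.append(m)
            continue
        sent = next(
            (s for s in sentences if s.start <= m.span.start and m.span.end <= s.end), None
        )
        if sent is None:
            out.append(m)
            continue
        lowered = [t.text.lower() for t in sent.tokens]
        i0, i1 = _token_range(sent, m.span)

        negated = False
        for c0, c1 in _cue_positions(sent.tokens, lexicon.negation_cues):
            if c1 >= i0:
                continue
            if i0 - c1 > lexicon.negation_window:
                continue
            between = lowered[c1 + 1 : i0]
            if any(t in lexicon.scope_terminators for t in between):
                continue
            negated = True
            break

        severity = Severity.NONE_STATED
        descriptor: Optional[Descriptor] = None
        if m.feature in HEADACHE_TYPE:
            best: Optional[tuple[int, int, Severity]] = None  # (distance, prefer-before, value)
            for j, tok in enumerate(lowered):
                if tok not in lexicon.severity_terms:
                    continue
                if j < i0 and i0 - j <= lexicon.severity_window_before:
                    cand = (i0 - j, 0, lexicon.severity_terms[tok])
                elif j > i1 and j - i1 <= lexicon.severity_window_after:
                    cand = (j - i1, 1, lexicon.severity_terms[tok])
                else:
                    continue
                if best is None or cand[:2] < best[:2]:
                    best = cand
            if best is not None:
                severity = best[2]

            best_d: Optional[tuple[int, int, Descriptor]] = None
            for j, tok in enumerate(lowered):
                if tok not in lexicon.descriptor_terms:
                    continue
                if j < i0:
                    cand_d = (i0 - j, 0, lexicon.descriptor_terms[tok])
                elif j > i1:
                    cand_d = (j - i1, 1, lexicon.descriptor_terms[tok])
                else:
                    continue
                if best_d is None or cand_d[:2] < best_d[:2]:
                    best_d = cand_d
            if best_d is not None:
                descriptor = best_d[2]

        out.append(
            m.model_copy(update={"negated": negated, "severity": severity, "descriptor": descriptor})
        )
    return out


# ---------------------------------------------------------------------------
# Encounter aggregation
# ---------------------------------------------------------------------------


def aggregate_encounter(
    encounter_id: str, mentions: Iterable[FeatureMention]
) -> EncounterFeatures:
    """Collapse mention-level output to the encounter-level feature set.

    A feature is asserted iff at least one non-negated mention exists
    (assertion dominates negation within an encounter — the score asks
    whether the symptom was present at the visit).  The headache fact
    carries the union of documented severities and descriptors over
    non-negated headache-type mentions.
    """
    features: set[Feature] = set()
    severities: set[Severity] = set()
    descriptors: set[Descriptor] = set()
    for m in mentions:
        if m.encounter_id != encounter_id:
            raise ValueError(
                f"mention for encounter {m.encounter_id!r} passed to aggregation of {encounter_id!r}"
            )
        if m.negated:
            continue
        features.add(m.feature)
        if m.feature in HEADACHE_TYPE:
            if m.severity is not Severity.NONE_STATED:
                severities.add(m.severity)
            if m.descriptor is not None:
                descriptors.add(m.descriptor)
    return EncounterFeatures(
        encounter_id=encounter_id,
        features=frozenset(features),
        severities=frozenset(severities),
        descriptors=frozenset(descriptors),
    )


def extract_note(
    note: EncounterNote, lexicon: Optional[Lexicon] = None
) -> list[FeatureMention]:
    """Full per-note pipeline: segment, find mentions, attach attributes."""
    lexicon = lexicon or Lexicon()
    sentences = segment(note.narrative)
    return apply_context(find_mentions(note, lexicon), sentences, lexicon)


def extract_corpus(
    notes: Iterable[EncounterNote], lexicon: Optional[Lexicon] = None
) -> tuple[list[FeatureMention], dict[str, EncounterFeatures]]:
    """Extract every note; returns (all mentions, encounter-level features)."""
    lexicon = lexicon or Lexicon()
    all_mentions: list[FeatureMention] = []
    features: dict[str, EncounterFeatures] = {}
    for note in notes:
        ms = extract_note(note, lexicon)
        all_mentions.extend(ms)
        features[note.encounter_id] = aggregate_encounter(note.encounter_id, ms)
    return all_mentions, features
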