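"""Encounter-level feature extraction from coded (structured) records.

The comparison arm: instead of reading the narrative, assert a feature
whenever any diagnosis code on the encounter maps to it.  The mapping is an
ICD-10-CM prefix table (configuration, not code); the longest matching
prefix wins.  Codes never carry severity or descriptor information — no
such codes exist — so this arm structurally cannot recover those facts,
which is exactly the deficit it is meant to expose.

Phonophobia has no dedicated ICD-10-CM code; hyperacusis (H93.23*) is used
as a documented proxy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .corpus import CodedRecord, CodeSystem, EncounterFeatures, Feature

__all__ = ["CodeMapEntry", "CodeMap", "extract_structured"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CodeMapEntry:
    code_system: CodeSystem
    prefix: str
    features: tuple[Feature, ...]


_DEFAULT_ENTRIES: tuple[CodeMapEntry, ...] = (
    CodeMapEntry(CodeSystem.ICD10CM, "G43", (Feature.MIGRAINE,)),
    CodeMapEntry(CodeSystem.ICD10CM, "R51", (Feature.HEADACHE,)),
    CodeMapEntry(CodeSystem.ICD10CM, "R11.0", (Feature.NAUSEA,)),
    CodeMapEntry(CodeSystem.ICD10CM, "R11.1", (Feature.VOMITING,)),
    CodeMapEntry(CodeSystem.ICD10CM, "R11.2", (Feature.NAUSEA, Feature.VOMITING)),
    CodeMapEntry(CodeSystem.ICD10CM, "H53.14", (Feature.PHOTOPHOBIA,)),
    CodeMapEntry(CodeSystem.ICD10CM, "H93.23", (Feature.PHONOPHOBIA,)),  # hyperacusis proxy
)


@dataclass(frozen=True)
class CodeMap:
    """Prefix → feature mapping with longest-prefix resolution."""

    entries: tuple[CodeMapEntry, ...] = _DEFAULT_ENTRIES

    def lookup(self, code_system: CodeSystem, code: str) -> tuple[Feature, ...]:
        """Features mapped by the longest matching prefix; empty if unmapped."""
        best: Optional[CodeMapEntry] = None
        for entry in self.entries:
            if entry.code_system is not code_system:
                continue
            if code.upper().startswith(entry.prefix.upper()):
                if best is None or len(entry.prefix) > len(best.prefix):
                    best = entry
        return best.features if best else ()

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "CodeMap":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or []
        return cls(
            entries=tuple(
                CodeMapEntry(
                    code_system=CodeSystem(e.get("code_system", "ICD10CM")),
                    prefix=str(e["prefix"]),
                    features=tuple(Feature(f) for f in e["features"]),
                )
                for e in raw
            )
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        raw = [
            {
                "code_system": e.code_system.value,
                "prefix": e.prefix,
                "features": [f.value for f in e.features],
            }
            for e in self.entries
        ]
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def extract_structured(
    coded: Iterable[CodedRecord],
    codemap: Optional[CodeMap] = None,
    encounter_ids: Optional[Iterable[str]] = None,
) -> dict[str, EncounterFeatures]:
    """Map coded records to encounter-level feature sets.

    A feature is asserted iff any code on the encounter maps to it; severity
    is always unstated and descriptors always absent.  Unmapped codes are
    ignored (logged at DEBUG).  ``encounter_ids`` optionally fixes the
    encounter universe so code-free encounters appear with empty feature
    sets.
    """
    codemap = codemap or CodeMap()
    asserted: dict[str, set[Feature]] = {eid: set() for eid in (encounter_ids or ())}
    for rec in coded:
        feats = codemap.lookup(rec.code_system, rec.code)
        if not feats:
            logger.debug("unmapped code %s:%s on %s", rec.code_system.value, rec.code, rec.encounter_id)
        asserted.setdefault(rec.encounter_id, set()).update(feats)
    return {
        eid: EncounterFeatures(encounter_id=eid, features=frozenset(feats))
        for eid, feats in asserted.items()
    }
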