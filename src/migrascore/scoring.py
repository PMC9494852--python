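"""The 10-point migraine outcome score.

Each encounter is scored on two additive components:

* **headache severity** (1–7 points): no headache documented → 1; mild, or a
  headache documented without severity → 3; moderate → 5; severe, or any
  severe-headache descriptor (pulsating, debilitating, stabbing, throbbing,
  disabling, piercing) → 7.  When an encounter documents multiple headache
  severities the highest one wins.
* **associated features** (0–3 points): nausea, vomiting, and
  photophobia-or-phonophobia each contribute one point when present
  (photophobia and phonophobia together still contribute a single point).

The total therefore lies in [1, 10].  Automated and manual scores are
compared per encounter: an *exact* match is a total difference of 0, a
*close* match a difference of at most 1 point.
"""

from __future__ import annotations

import csv
from enum import Enum
from itertools import chain, combinations
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator

from .corpus import (
    ASSOCIATED_FEATURES,
    HEADACHE_TYPE,
    Descriptor,
    EncounterFeatures,
    Feature,
    Severity,
)

__all__ = [
    "MigraineScore",
    "MatchClass",
    "SEVERITY_POINTS",
    "severity_points",
    "associated_points",
    "total_score",
    "classify_match",
    "enumerate_feature_states",
    "write_scores_csv",
    "read_scores_csv",
]

#: Points carried by each documented severity level.  A headache documented
#: with no severity statement scores the same as mild.
SEVERITY_POINTS: dict[Severity, int] = {
    Severity.NONE_STATED: 3,
    Severity.MILD: 3,
    Severity.MODERATE: 5,
    Severity.SEVERE: 7,
}

#: Any severe-headache descriptor counts as severe evidence.
DESCRIPTOR_POINTS = 7


class MigraineScore(BaseModel):
    model_config = ConfigDict(frozen=True)

    severity_points: int
    associated_points: int = Field(ge=0, le=3)
    total: int = Field(ge=1, le=10)

    @model_validator(mode="after")
    def _consistent(self) -> "MigraineScore":
        if self.severity_points not in (1, 3, 5, 7):
            raise ValueError(f"severity_points must be one of 1/3/5/7, got {self.severity_points}")
        if self.total != self.severity_points + self.associated_points:
            raise ValueError("total must equal severity_points + associated_points")
        return self


class MatchClass(str, Enum):
    EXACT = "exact"
    CLOSE = "close"
    MISMATCH = "mismatch"


def severity_points(features: EncounterFeatures) -> int:
    """Severity component (1/3/5/7) for one encounter.

    With no headache-type fact the encounter scores 1.  Otherwise every piece
    of severity evidence (documented severities, presence of a severe
    descriptor, the bare headache fact itself at 3) is mapped to points and
    the maximum is returned — encounters with multiple headache features take
    the highest severity represented.
    """
    if not (features.features & HEADACHE_TYPE):
        return 1
    points = [SEVERITY_POINTS[Severity.NONE_STATED]]
    points.extend(SEVERITY_POINTS[s] for s in features.severities)
    if features.descriptors:
        points.append(DESCRIPTOR_POINTS)
    return max(points)


def associated_points(features: EncounterFeatures) -> int:
    """Associated-feature component (0–3): nausea, vomiting, photo-or-phono."""
    pts = 0
    if Feature.NAUSEA in features.features:
        pts += 1
    if Feature.VOMITING in features.features:
        pts += 1
    if Feature.PHOTOPHOBIA in features.features or Feature.PHONOPHOBIA in features.features:
        pts += 1
    return pts


def total_score(features: EncounterFeatures) -> MigraineScore:
    sev = severity_points(features)
    assoc = associated_points(features)
    return MigraineScore(severity_points=sev, associated_points=assoc, total=sev + assoc)


ScoreLike = Union[MigraineScore, int]


def _total(score: ScoreLike) -> int:
    return score.total if isinstance(score, MigraineScore) else int(score)


def classify_match(auto: ScoreLike, manual: ScoreLike) -> MatchClass:
    """Exact (Δ=0), close (Δ=1) or mismatch (Δ>1) on the 10-point scale."""
    delta = abs(_total(auto) - _total(manual))
    if delta == 0:
        return MatchClass.EXACT
    if delta == 1:
        return MatchClass.CLOSE
    return MatchClass.MISMATCH


def _powerset(items: tuple) -> Iterator[frozenset]:
    return (
        frozenset(c) for c in chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))
    )


def enumerate_feature_states(encounter_id: str = "enum") -> Iterator[EncounterFeatures]:
    """Brute-force enumeration of valid encounter-feature states.

    Covers every subset of the six features; for states with a headache-type
    feature, every subset of documented severities crossed with
    descriptor-absent/descriptor-present.  Used as the enumeration oracle for
    scale bounds and attainability.
    """
    documented = (Severity.MILD, Severity.MODERATE, Severity.SEVERE)
    for feats in _powerset(tuple(Feature)):
        if feats & HEADACHE_TYPE:
            for sevs in _powerset(documented):
                for descs in (frozenset(), frozenset({Descriptor.THROBBING})):
                    yield EncounterFeatures(
                        encounter_id=encounter_id,
                        features=feats,
                        severities=sevs,
                        descriptors=descs,
                    )
        else:
            yield EncounterFeatures(encounter_id=encounter_id, features=feats)


def write_scores_csv(scores: Mapping[str, MigraineScore], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["encounter_id", "severity_points", "associated_points", "total"])
        for eid in scores:
            s = scores[eid]
            writer.writerow([eid, s.severity_points, s.associated_points, s.total])


def read_scores_csv(path: Union[str, Path]) -> dict[str, MigraineScore]:
    out: dict[str, MigraineScore] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["encounter_id"]] = MigraineScore(
                severity_points=int(row["severity_points"]),
                associated_points=int(row["associated_points"]),
                total=int(row["total"]),
            )
    return out
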