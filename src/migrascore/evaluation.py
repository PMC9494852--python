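"""Validation statistics against a manual reference standard.

Accuracy is measured at encounter level, per feature: an automated system is
credited with a feature only when it identifies it in the specific encounter
where the reference standard documents it.  Attribute facts — e.g.
"headache (severe)" or "throbbing" — are evaluated as binary encounter-level
features in their own right.

* recall = TP / (TP + FN): share of reference facts the system found;
* precision = TP / (TP + FP): share of system facts that are real;
* F1 = harmonic mean of the two.

Facts occurring in fewer than 20 reference encounters are excluded from
accuracy summaries, and summary averages are weighted by reference
occurrence counts.  Undefined values (zero denominators) are reported as NA
and excluded from the averages.  Percentages are printed to one decimal,
round-half-up.

The reference standard itself is produced by dual annotation: two blinded
annotators, inter-annotator agreement tracked per batch with Cohen's kappa
(adequacy gate 0.7), disagreements adjudicated jointly and escalated to a
third annotator when unresolved.

Score-level agreement between automated and manual extraction is summarised
as the fraction of encounters with an exact (Δ=0) and close (Δ≤1,
cumulative) match on the 10-point scale; the pre-registered success gate is
a close match on at least 70% of encounters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Iterable, Mapping, Optional, Sequence, Union

from .corpus import Descriptor, EncounterFeatures, Feature, Severity
from .scoring import MigraineScore, ScoreLike, _total

__all__ = [
    "EvaluationError",
    "EvalCounts",
    "FeatureMetrics",
    "WeightedSummary",
    "KappaResult",
    "MatchRates",
    "Disagreement",
    "Adjudication",
    "TABLE_ROWS",
    "MIN_OCCURRENCE",
    "round_percent",
    "f1_score",
    "encounter_confusion",
    "feature_metrics",
    "weighted_summary",
    "cohen_kappa",
    "adjudicate",
    "match_rates",
    "evaluate_arm",
]

#: Facts below this reference occurrence are excluded from accuracy summaries.
MIN_OCCURRENCE = 20

#: Close-match success gate on the outcome score.
CLOSE_MATCH_GATE = 0.70

#: Inter-annotator adequacy gate on Cohen's kappa.
KAPPA_GATE = 0.7

#: Canonical evaluation-table row order: base concepts, severity facts,
#: severe-headache descriptors, associated symptoms.
TABLE_ROWS: tuple[str, ...] = (
    Feature.HEADACHE.value,
    Feature.MIGRAINE.value,
    f"headache ({Severity.MILD.value})",
    f"headache ({Severity.MODERATE.value})",
    f"headache ({Severity.SEVERE.value})",
    Descriptor.THROBBING.value,
    Descriptor.STABBING.value,
    Descriptor.PULSATING.value,
    Descriptor.DEBILITATING.value,
    Descriptor.DISABLING.value,
    Descriptor.PIERCING.value,
    Feature.NAUSEA.value,
    Feature.VOMITING.value,
    Feature.PHOTOPHOBIA.value,
    Feature.PHONOPHOBIA.value,
)


class EvaluationError(ValueError):
    """Mismatched encounter universes or an unusable metric request."""


def round_percent(proportion: float) -> float:
    """A proportion as a percentage with one decimal, round-half-up."""
    return float(
        (Decimal(repr(proportion)) * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def f1_score(recall: float, precision: float) -> Optional[float]:
    """Harmonic mean of recall and precision; None when both are zero."""
    if recall + precision == 0:
        return None
    return 2 * recall * precision / (recall + precision)


@dataclass(frozen=True)
class EvalCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class FeatureMetrics:
    """Per-fact accuracy row.  None marks an undefined (NA) value."""

    feature: str
    occurrence: int
    recall: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    included: bool


@dataclass(frozen=True)
class WeightedSummary:
    recall: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    total_weight: int


@dataclass(frozen=True)
class KappaResult:
    po: float
    pe: float
    kappa: Optional[float]
    n_items: int
    adequate: bool


@dataclass(frozen=True)
class MatchRates:
    n_encounters: int
    exact_rate: float
    close_rate: float  # cumulative: includes exact
    success: bool


def encounter_confusion(
    auto: Mapping[str, EncounterFeatures],
    reference: Mapping[str, EncounterFeatures],
    fact: str,
) -> EvalCounts:
    """Encounter-level TP/FP/FN for one binary fact key."""
    if set(auto) != set(reference):
        raise EvaluationError("automated and reference encounter universes differ")
    tp = fp = fn = 0
    for eid in reference:
        in_ref = fact in reference[eid].facts()
        in_auto = fact in auto[eid].facts()
        tp += in_ref and in_auto
        fp += in_auto and not in_ref
        fn += in_ref and not in_auto
    return EvalCounts(tp=tp, fp=fp, fn=fn)


def feature_metrics(counts: EvalCounts, occurrence: int, feature: str = "") -> FeatureMetrics:
    recall = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn > 0 else None
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp > 0 else None
    f1 = f1_score(recall, precision) if recall is not None and precision is not None else None
    return FeatureMetrics(
        feature=feature,
        occurrence=occurrence,
        recall=recall,
        precision=precision,
        f1=f1,
        included=occurrence >= MIN_OCCURRENCE,
    )


def _weighted_mean(pairs: list[tuple[float, int]]) -> Optional[float]:
    total = sum(w for _, w in pairs)
    if total == 0:
        return None
    return sum(v * w for v, w in pairs) / total


def weighted_summary(metrics: Iterable[FeatureMetrics]) -> WeightedSummary:
    """Occurrence-weighted mean of each defined metric over included facts.

    Facts with an undefined value are excluded from that metric's average;
    raises :class:`EvaluationError` when no included fact has any defined
    metric.
    """
    included = [m for m in metrics if m.included]
    if not included or all(
        m.recall is None and m.precision is None and m.f1 is None for m in included
    ):
        raise EvaluationError("no included feature with a defined metric")
    return WeightedSummary(
        recall=_weighted_mean([(m.recall, m.occurrence) for m in included if m.recall is not None]),
        precision=_weighted_mean(
            [(m.precision, m.occurrence) for m in included if m.precision is not None]
        ),
        f1=_weighted_mean([(m.f1, m.occurrence) for m in included if m.f1 is not None]),
        total_weight=sum(m.occurrence for m in included),
    )


def cohen_kappa(labels_a: Sequence[Hashable], labels_b: Sequence[Hashable]) -> KappaResult:
    """Chance-corrected agreement between two parallel label sequences.

    po is the observed agreement fraction, pe the agreement expected from
    the annotators' marginal label distributions, kappa = (po−pe)/(1−pe).
    When both annotators are constant and identical pe = 1 and kappa is
    degenerate: reported as None with po = 1.
    """
    if len(labels_a) != len(labels_b):
        raise EvaluationError("label sequences differ in length")
    n = len(labels_a)
    if n == 0:
        raise EvaluationError("label sequences are empty")
    po = sum(a == b for a, b in zip(labels_a, labels_b)) / n
    ca, cb = Counter(labels_a), Counter(labels_b)
    pe = sum((ca[c] / n) * (cb[c] / n) for c in set(ca) | set(cb))
    if pe >= 1.0:
        return KappaResult(po=po, pe=pe, kappa=None, n_items=n, adequate=False)
    kappa = (po - pe) / (1 - pe)
    return KappaResult(po=po, pe=pe, kappa=kappa, n_items=n, adequate=kappa >= KAPPA_GATE)


@dataclass(frozen=True)
class Disagreement:
    encounter_id: str
    fact: str
    in_a: bool
    in_b: bool


@dataclass(frozen=True)
class Adjudication:
    consensus: dict[str, frozenset[str]]
    worksheet: tuple[Disagreement, ...]
    finalized: bool


def adjudicate(
    ann_a: Mapping[str, Iterable[str]],
    ann_b: Mapping[str, Iterable[str]],
    resolutions: Optional[Mapping[tuple[str, str], bool]] = None,
) -> Adjudication:
    """Merge two encounter-level annotation sets into a consensus reference.

    Facts both annotators agree on enter the consensus automatically;
    disagreements form a resolution worksheet.  A resolutions mapping
    ``(encounter_id, fact) -> keep`` finalizes the reference; unresolved
    items leave it unfinalized.  A resolution that references no listed
    disagreement is an error.
    """
    if set(ann_a) != set(ann_b):
        raise EvaluationError("annotator encounter universes differ")
    consensus: dict[str, set[str]] = {}
    worksheet: list[Disagreement] = []
    for eid in sorted(ann_a):
        facts_a, facts_b = set(ann_a[eid]), set(ann_b[eid])
        consensus[eid] = facts_a & facts_b
        for fact in sorted(facts_a ^ facts_b):
            worksheet.append(
                Disagreement(encounter_id=eid, fact=fact, in_a=fact in facts_a, in_b=fact in facts_b)
            )
    open_items = {(d.encounter_id, d.fact) for d in worksheet}
    if resolutions:
        unknown = set(resolutions) - open_items
        if unknown:
            raise EvaluationError(f"resolution references unknown disagreement(s): {sorted(unknown)}")
        for (eid, fact), keep in resolutions.items():
            if keep:
                consensus[eid].add(fact)
            open_items.discard((eid, fact))
    return Adjudication(
        consensus={eid: frozenset(facts) for eid, facts in consensus.items()},
        worksheet=tuple(worksheet),
        finalized=not open_items,
    )


def match_rates(
    auto_scores: Mapping[str, ScoreLike], reference_scores: Mapping[str, ScoreLike]
) -> MatchRates:
    """Exact/close agreement between automated and manual outcome scores."""
    if set(auto_scores) != set(reference_scores):
        raise EvaluationError("automated and reference encounter universes differ")
    n = len(reference_scores)
    if n == 0:
        raise EvaluationError("no encounters to compare")
    deltas = [abs(_total(auto_scores[e]) - _total(reference_scores[e])) for e in reference_scores]
    exact = sum(d == 0 for d in deltas) / n
    close = sum(d <= 1 for d in deltas) / n
    return MatchRates(n_encounters=n, exact_rate=exact, close_rate=close, success=close >= CLOSE_MATCH_GATE)


def evaluate_arm(
    auto: Mapping[str, EncounterFeatures],
    reference: Mapping[str, EncounterFeatures],
    rows: Sequence[str] = TABLE_ROWS,
) -> list[FeatureMetrics]:
    """Per-fact metrics for one extraction arm over a shared universe."""
    metrics = []
    ref_facts = {eid: reference[eid].facts() for eid in reference}
    for fact in rows:
        counts = encounter_confusion(auto, reference, fact)
        occurrence = sum(fact in facts for facts in ref_facts.values())
        metrics.append(feature_metrics(counts, occurrence, feature=fact))
    return metrics
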