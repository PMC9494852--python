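# Methods

## The outcome model

Each encounter receives a migraine outcome score on a 10-point scale built
from data elements that clinicians actually document in routine care:

* **Severity component (1–7).** No headache-type fact (headache or
  migraine) documented → 1 point. A headache-type fact with mild or no
  stated severity → 3; moderate → 5; severe → 7. Any severe-headache
  descriptor (pulsating, debilitating, stabbing, throbbing, disabling,
  piercing) is evidence of severe headache and scores 7. All severity
  evidence in the encounter is mapped to points and the **maximum** is
  taken, so conflicting statements (e.g. "mild" plus "throbbing") resolve
  to the highest severity represented.
* **Associated component (0–3).** One point each for nausea, vomiting, and
  the disjunction photophobia-or-phonophobia (both light and sound
  sensitivity together still score one point).

The components are additive; an encounter with associated symptoms but no
headache scores 1 + associated (nothing in the model forbids that
combination). Brute-force enumeration over all feature states
(`enumerate_feature_states`) confirms the total is confined to [1, 10] and
that every value on the scale, including 2 (no headache + one associated
symptom), is attainable.

Headache progression (improvement/worsening) is a documentable feature of
the clinical picture but carries no points in this scale and is not
extracted.

## Extraction

The extraction engine is deliberately rule-based and transparent — a
NegEx/ConText-style pipeline rather than a statistical model — so that
every assertion is traceable to a lexicon entry and a scope rule:

1. **Segmentation.** Sentences split on `.`, `!`, `?` and newline runs,
   with a short abbreviation guard ("Dr.", "pt.", "hx."). Tokens are
   maximal alphanumeric runs or single punctuation marks; all offsets are
   0-based half-open character offsets into the NFC-normalised narrative.
2. **Mention finding.** Case-insensitive, word-bounded surface matching per
   concept, longest match first among overlapping candidates. Flagged
   abbreviations ("HA", "MA") match case-sensitively. Ambiguous forms
   ("MA") are emitted only when an allowed cue (aura, headache, migraine,
   ...) occurs in the same sentence and no blocked cue (assistant, mass,
   Massachusetts) does.
3. **Context attributes.** A mention is negated iff a negation cue ("no",
   "denies", "without", "negative for", ...) precedes it in the same
   sentence within 6 tokens with no scope terminator ("but", "however",
   ".", ";") in between. Severity attaches from the nearest severity
   adjective within 4 tokens before or 3 after a headache-type mention
   (ties prefer the preceding term); descriptors attach from the nearest
   descriptor in the sentence. The window sizes are package choices — no
   published values exist for them — and are configurable on the lexicon.
4. **Aggregation.** A feature is asserted at encounter level iff at least
   one non-negated mention exists; assertion dominates negation because the
   score asks whether the symptom was present at the visit. The headache
   fact accumulates the union of documented severities and descriptors
   across non-negated headache-type mentions.

Severity and descriptor attributes are carried by both headache and
migraine mentions (the modelled concept is migraine-associated headache,
so "severe migraine" is severity evidence), but headache and migraine
remain separate features for accuracy evaluation.

The structured arm asserts a feature when any ICD-10-CM code on the
encounter resolves through a longest-prefix code map (G43\* → migraine,
R51\* → headache, R11.0 → nausea, R11.1\* → vomiting, R11.2 → nausea and
vomiting, H53.14\* → photophobia, H93.23\* hyperacusis as the phonophobia
proxy — phonophobia has no dedicated code). Codes cannot express severity
or descriptors, so those reference facts are structurally unreachable for
this arm (0% recall by construction whenever they occur).

## Cohort definitions

An encounter is evaluable when the chief-complaint field contains a
headache-family term, or the narrative contains at least two case-
insensitive headache-family surface matches (migraine terms count; negated
mentions count too, since the filter precedes attribute analysis). A
patient enters the study with migraine evidence anywhere in their record
(text mention or code) and at least two evaluable encounters; the earliest
evaluable encounter is paired with the first subsequent one at least 14
calendar days later. The train/validation split is by patient,
deterministic in the seed, with |validation| = round(fraction × n)
(half-up); the default fraction is 0.5.

## Validation statistics

Per binary fact (base features plus attribute rows such as "headache
(severe)" and "throbbing"), encounter-level TP/FP/FN yield recall,
precision and F1 (harmonic mean). Facts with fewer than 20 reference
occurrences are excluded from summaries; weighted averages use reference
occurrence counts as weights. Undefined values (zero denominators) are
reported as NA and excluded from the averages — with the consequence,
noted as a known limitation, that a published structured-arm weighted
average computed under an unstated convention is not reconstructible from
per-row values alone. Percentages are printed to one decimal, round-half-up.

Cohen's kappa is computed per evaluation batch from the annotators'
marginals (pe = Σ_c p_a(c)·p_b(c); kappa = (po − pe)/(1 − pe)); adequacy
gate 0.7. Two constant, identical label sequences make pe = 1 and kappa
degenerate (reported as NA with po = 1). Adjudication keeps agreed facts,
emits a disagreement worksheet, and finalizes only when a resolutions
mapping covers every item; a resolution referencing an unlisted item is an
error.

Outcome-score agreement is the fraction of encounters with exact (Δ = 0)
and close (Δ ≤ 1, cumulative — close includes exact) total-score matches;
the success gate is close ≥ 70%.

## The synthetic generator

Real migraine EHR narratives are not redistributable, so validation runs on
synthetic corpora. The generator assembles each narrative from a template
grammar — positive symptom sentences (optionally with a severity adjective
and/or descriptor adjacent to the headache surface), negated sentences
using cues from the extraction lexicon's own list, migraine-with-aura
sentences for the "MA" abbreviation, and distractor sentences including the
non-migraine senses of "MA". Ground truth (mention spans, encounter
feature sets, scores) is emitted while assembling, never re-derived by
parsing; the truth score is computed by the generator's own independent
arithmetic, which makes generator/outcome-model agreement a falsifiable
invariant rather than a tautology.

Defaults mirror the validation study's design: 1,003 patients × 2
encounters (2,006 encounters) dated 2018–2020, consecutive encounters ≥ 14
days apart, per-encounter feature prevalences set to the published manual
occurrence rates (headache 0.995, migraine 0.655, nausea 0.596, vomiting
0.442, photophobia 0.228, phonophobia 0.159), severity distribution from
the published mild/severe shares among headache encounters (mild 0.052,
severe 0.118, moderate 0 — it fell below the 20-occurrence reporting floor),
descriptor probability 0.136, and structured coding sensitivities equal to
the published structured recalls (headache 0.331, migraine 0.585, nausea
0.025, vomiting 0.010, photophobia/phonophobia 0). Narrative-style
parameters have no published values and are fixed artifact choices:
negation rate 0.15, abbreviation rate 0.20, distractor rate 0.30, spurious
code rate 0.01.

**What the generator does and does not show.** Its grammar is constructed
to be exactly coverable by the extraction rules, so zero-noise end-to-end
runs must recover truth perfectly (per-feature F1 = 1.0, close-match rate
= 1.0) — that is an internal-consistency check of the pipeline, exercised
at 1,000 encounters in the acceptance suite. It is *not* evidence about
accuracy on real clinical prose, whose lexical variety, typos, section
structure and discourse phenomena the grammar does not model; published
headline accuracies on proprietary data (e.g. 77.2% exact / 82.2% close)
are therefore not reproduction targets here. What the synthetic runs do
probe quantitatively is the statistical machinery: configured prevalences
and coding sensitivities are recovered within exact binomial 99% intervals,
kappa matches a brute-force contingency oracle, and the structured arm's
severity deficit emerges from mechanism rather than assumption.

## Numerical and degenerate-input choices

* Percent formatting: one decimal, round-half-up via `decimal.Decimal`
  (float banker's rounding would flip printed edge cases).
* F1 with recall = precision = 0 is undefined (NA), as is recall with zero
  reference occurrence and precision with zero predictions.
* Empty narratives segment to no sentences; an encounter with no mentions
  aggregates to an empty feature set and scores 1.
* Mention spans are validated (start < end, inside the narrative when
  cross-checked against notes); duplicate encounter ids are corpus errors.
* All randomness flows through explicit seeds (numpy `default_rng` in the
  generator, `random.Random` in the split); reports are byte-stable for a
  fixed configuration, and timings are logged rather than written into
  reports.

## Problem sizes

The test and acceptance suites run the end-to-end pipeline at 1,000–2,000
synthetic encounters — the same order as the 2,006-encounter validation
design — which is ample for the binomial-interval checks while keeping the
full suite under a minute on one CPU.
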