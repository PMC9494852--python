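# migrascore

Migraine is a "soft-outcome" condition: how a patient is doing lives in the
free-text narrative a clinician writes, not in billing codes. Real-world
evidence studies that want to track migraine status from electronic health
records therefore need (1) an outcome model built only from data elements
routinely documented in clinic notes, (2) automated extraction of those
elements from unstructured text, and (3) a validation framework that
measures the automation against a manually annotated reference standard.

`migrascore` implements that whole workflow as a transparent, rule-based,
fully testable toolkit:

* **10-point migraine outcome score.** Per encounter,
  `total = severity + associated`, where severity ∈ {1, 3, 5, 7}
  (no headache documented → 1; mild or severity not documented → 3;
  moderate → 5; severe or any severe descriptor such as *throbbing*,
  *pulsating*, *stabbing* → 7; the highest severity represented wins) and
  associated ∈ {0..3} (one point each for nausea, vomiting, and
  photophobia-or-phonophobia).
* **Rule-based concept extraction** (NegEx/ConText style): lexicon surface
  forms per concept, sentence-scoped negation cues with scope terminators,
  token-window severity/descriptor attachment, and context-based
  disambiguation of ambiguous abbreviations ("MA" → *migraine with aura*
  vs *medical assistant*).
* **Structured-data comparison arm:** encounter-level features from
  ICD-10-CM codes via a longest-prefix code map (codes can never carry
  severity or descriptor facts — the arm's characteristic deficit).
* **Cohort filters:** evaluable encounters (headache as chief complaint or
  mentioned ≥ 2×), patients with migraine evidence and two evaluable
  encounters ≥ 14 days apart, patient-level train/validation split.
* **Validation statistics:** encounter-level recall / precision / F1 per
  feature (facts with < 20 reference occurrences excluded,
  occurrence-weighted averages), Cohen's kappa with a 0.7 adequacy gate and
  an adjudication workflow for dual annotation, and exact (Δ=0) / close
  (Δ≤1) outcome-score match rates with a 70% close-match success gate.
* **Synthetic EHR generator** that emits notes, diagnosis codes and exact
  ground truth (spans, encounter feature sets, scores) from a template
  grammar, with configurable prevalences, negation/abbreviation/distractor
  rates and structured-coding sensitivities.

## Worked example

Run the full study pipeline on a synthetic corpus (simulate → cohort →
extract → score → evaluate):

```bash
migrascore run-study --out demo --seed 42
```

prints

```
evaluated 896 encounters: exact 100.0%, close 100.0%
```

and writes `demo/report.md`, which begins:

```
| Feature          | Occurrence | Structured R | Structured P | Structured F1 | Unstructured R | Unstructured P | Unstructured F1 |
| headache         | 896        | 30.5%        | 100.0%       | 46.7%         | 100.0%         | 100.0%         | 100.0%          |
| migraine         | 652        | 57.8%        | 99.5%       | 73.1%         | 100.0%         | 100.0%         | 100.0%          |
| headache (mild)  | 49         | 0.0%         | NA           | NA            | 100.0%         | 100.0%         | 100.0%          |
| headache (severe)| 92         | 0.0%         | NA           | NA            | 100.0%         | 100.0%         | 100.0%          |
```

Reading the numbers: the text arm recovers every feature perfectly here
because the synthetic narratives are built from the same grammar the rules
cover (see `docs/methods.md` for what that does and does not demonstrate),
while the structured arm — driven by coding sensitivities that mimic
real-world symptom-coding behaviour — misses most symptoms outright and can
never produce a severity row ("0.0% / NA"), reproducing the mechanism that
makes billing codes unusable for soft outcomes.

Every stage is also a standalone subcommand (`simulate`, `cohort`,
`extract-text`, `extract-structured`, `score`, `evaluate`, `kappa`,
`report`), and the same functionality is importable:

```python
from migrascore import EncounterNote, extract_note, aggregate_encounter, total_score

note = EncounterNote(
    patient_id="p1", encounter_id="e1", date="2024-05-02",
    specialty="neurology", chief_complaint="headache",
    narrative="Severe throbbing headache. Reports nausea. Denies vomiting.",
)
mentions = extract_note(note)
features = aggregate_encounter("e1", mentions)
print(total_score(features))   # severity_points=7 associated_points=1 total=8
```

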