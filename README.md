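# crystalbone

Short-term (1–2 year) fracture-risk prediction from longitudinal
electronic-health-record diagnosis histories.

Fragility fractures are common after age 50, and high fracture risk is
widely undertreated; the established calculators (FRAX, Garvan) estimate
5–10-year risk from cross-sectional risk factors and say little about the
next 1–2 years. `crystalbone` implements a sequence-based alternative:
treat each ICD diagnosis code as a word and a patient's chronological code
history as a document, and learn whether the trajectory looks like that of
a patient about to fracture.

The package contains the full pipeline:

* **EHR data model** — long-format CSV ingest (diagnoses, medications,
  demographics), namespaced code tokens, deterministic per-patient records;
* **synthetic cohort generator** — pan-therapeutic (8.5% fracture
  incidence over age 50) and bone-health (39%) cohorts with Zipf code
  streams, age/sex/frailty-driven fracture hazards, pre-fracture
  risk-code signatures, and injected physician interventions, so the whole
  pipeline runs and is tested without any external data;
* **fracture qualification** — claims-style case definition: site-prefix
  code catalog, chronological scan, 90-day same-site washout,
  aftercare/sequela exclusion;
* **sliding windows** — up to 5 labeled 730-day code sequences per anchor
  event, patient-level 70:30 split, 50:50 oversampling from the
  bone-health pool, min-count-5 vocabulary;
* **embeddings** — 100-d skip-gram code vectors and 128-d
  distributed-bag-of-words window vectors (vectorized numpy SGD,
  bit-reproducible);
* **risk models** — framework 1 (code vectors → LSTM + statics),
  framework 2 (window vector + statics → gradient boosted trees), two
  demographic baselines, and a logistic-regression ensemble;
* **evaluation** — AUROC (Mann–Whitney), AUPRC (average precision),
  thresholded metrics, primary/subsequent fracture stratification;
* **human-level comparison** — retrospective physician-intervention
  detection (densitometry, osteoporosis diagnoses, treatments), the
  intervention×outcome×flag cohort analysis, and the first-treatment
  overlap analysis.

## Worked example

Run the full experiment on a simulated cohort (3,000 pan-therapeutic +
1,200 bone-health patients; about 6 minutes on one CPU):

```bash
crystalbone run --out runs/demo --simulate
```

which prints (numbers from this configuration's fixed seeds):

```
holdout AUROC: {"lstm_seq": 0.7247, "gbdt_vec": 0.6984, "baseline_age_sex": 0.676,
"baseline_age_sex_count": 0.6863, "ensemble": 0.7401}
artifacts in runs/demo (retrained=True)
```

Reading the numbers: 13,727 pan-therapeutic windows were built, split by
patient into 18,232 balanced training windows (after bone-health
oversampling) and 4,114 untouched holdout windows (212 fracture windows,
5.2% — far below 50%, which is what motivates the oversampling). Both
sequence frameworks and their ensemble rank fracture windows above
non-fracture windows better than the demographic baselines
(0.698–0.740 vs 0.676–0.686): the code sequence carries risk signal beyond
age, sex, and utilization, which is the package's central claim. The
absolute values are specific to the synthetic cohort and are *not*
comparable to performance on real EHR data.

The same run writes the human-level-performance reports.
`runs/demo/hlp_cohort.json` cross-tabulates the framework-1 flags: of 134
holdout fracture windows with no physician intervention in their span, 84
(62.7%) were flagged — at the window level, most imminent fractures that
physicians had not acted on were visible to the model — while 74.5% of the
unique untreated fracture events had at least one flagged window.
`runs/demo/hlp_overlap.json` scores each treated patient's history up to
their first pharmacologic intervention: 47 of 57 treated patients had the
required 2 years of prior history, 63.8% of those were flagged, and of the
12 who went on to fracture within 2 years the model had flagged 10.

The library surface mirrors the pipeline stages, e.g.:

```python
from crystalbone import (GeneratorConfig, generate_cohort, assemble_records,
                         qualify_fracture_events, anchor_events)

cohort = generate_cohort(GeneratorConfig(n_patients=1000, seed=7))
records, _ = assemble_records(cohort.diagnoses, cohort.medications,
                              cohort.demographics)
events = qualify_fracture_events(records["PT0000042"])
```

`docs/methods.md` describes the model, the generator's statistical
construction, and every numerical choice.

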