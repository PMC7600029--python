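# Methods

## Problem and model

`crystalbone` predicts whether a patient will sustain a qualifying
fragility fracture within a short (default 2-year) horizon, using nothing
but the chronological sequence of diagnosis codes in the preceding 2 years
plus three static features (age, sex, diagnosis count). The approach
treats diagnosis codes as words and patient histories as documents:

* **Framework 1** learns a 100-d skip-gram (word2vec-style) vector per
  code from code co-occurrence, then classifies the embedded sequence
  with a recurrent (LSTM) network whose final state and temporal mean
  hidden state are merged with a dense transform of the statics.
* **Framework 2** learns a 128-d distributed-bag-of-words (doc2vec-style)
  vector per *window* and classifies the 131-column table
  (128 vector dims + age, sex, diagnosis count) with gradient boosted
  trees.
* An **ensemble** combines the two framework probabilities with a
  logistic-regression metaclassifier fitted on a patient-level
  calibration fold the base models never saw.
* Two **baselines** (age+sex; age+sex+diagnosis count) use the same
  boosted-tree classifier and isolate the added value of sequence data.

## Cohort construction

An *anchor event* is a qualifying fracture, or — for patients with no
qualifying fracture — the last recorded diagnosis. Patients must be at
least 50 years old at the anchor and carry at least 730 days of history
before it. Each anchor proposes up to 5 windows whose ends step back from
the day before the anchor in 183-day strides; a window is the code
sequence in the half-open 730-day span ending at its end date, labeled
positive iff a qualifying fracture falls within the following 730 days.
Candidates are dropped when history does not cover the span, or when a
*different* fracture of the same patient falls in the span or horizon
(ambiguous attribution). With a 183-day stride, exactly one of the five
candidates of a fracture anchor falls outside the horizon and carries a
negative label — fracture patients therefore contribute negative windows
too, which is deliberate.

Qualifying fractures follow a claims-style case definition: a catalog of
site-specific code prefixes (editable CSV), a chronological scan, a
same-site washout (default 90 days) that absorbs follow-up coding, and
exclusion of ICD-10-CM aftercare/sequela forms (7th character D/S).
Cross-site codes always open distinct events. The exact published rule
set this emulates is not fully public; the catalog + washout design keeps
every choice swappable.

## Sampling

Pan-therapeutic windows are split 70:30 **by patient** into train and
holdout. The training side is balanced to 50:50 by oversampling fracture
windows from the bone-health cohort (with replacement if the pool is
small); the holdout keeps its natural class distribution and is never
oversampled. Both embedding models train only on *natural*
pan-therapeutic training windows — never oversampled or bone-health
windows — to avoid biasing the learned geometry toward bone-health
coding; this is asserted at run time from window provenance tags.

The vocabulary is built from that same embedding reference corpus with a
minimum token count of 5; rarer codes map to an unknown token whose
vector is zero, so rare-code removal reaches the classifiers only through
the diagnosis-count feature. (Whether the original min-count filter was
computed on the training corpus or all data is ambiguous in the source
description; we use the embedding reference corpus.)

## Numerical implementation of the embeddings and the LSTM

This environment provides no word2vec/doc2vec or deep-learning library,
so the three learned components are implemented as vectorized numpy SGD:

* Skip-gram with negative sampling (context window 10, 5 negatives,
  unigram^0.75 noise, frequent-token subsampling at 1e-3, linear
  learning-rate decay from 0.05, batch size 512).
* DBOW with the same negative-sampling machinery; training uses small
  batches (32 pairs, learning rate 0.05, 15 epochs) because document
  vectors learn markedly better the closer the batched updates are to
  sequential SGD; inference fits a new document vector against the
  frozen token output matrix (40 inference epochs).
* A single-layer LSTM (64 units by default) with forget-gate bias 1;
  the classifier head concatenates the final hidden state, the temporal
  mean of the hidden states (a direct evidence-accumulation path that a
  final state alone reaches only through a much harder optimization),
  and a 32-unit ReLU transform of the statics, followed by a 32-unit
  merge layer and a sigmoid. Trained with minibatch Adam and manual
  backpropagation through time (verified against finite differences in
  the test suite), inputs divided by the embedding matrix's global
  standard deviation (scale-only, so zero padding rows survive), early
  stopping on validation AUROC.

Three numerical choices matter for stability of the batched SGD and are
non-standard relative to streaming reference implementations: negative
samples that coincide with the positive target are masked (essential for
tiny vocabularies), per-row updates are averaged over in-batch duplicates
so that very frequent tokens cannot take runaway summed steps, and
weights are clipped to a generous bound after every epoch.  All training
is single-threaded and bit-reproducible given config + seed.

Model selection never scores the oversampled training mixture: the
validation folds used for LSTM early stopping, boosted-tree early
stopping, and the ensemble's calibration fold all keep only *natural*
windows of held-out patients, so stopping points and meta-weights are
chosen on the distribution the models are evaluated on.  Boosted-tree
models (framework 2 and both baselines) share one conservative
configuration: depth 3, learning rate 0.05, subsampling 0.8, up to 400
trees with AUROC early stopping — without that early stopping, boosting
memorizes the exact feature values of oversampled duplicate windows.

Sequences are truncated to the most recent 200 tokens (recency is the
clinically salient end of a window) and front-padded with zeros; the
pre-truncation diagnosis count is kept as a static feature. Code vectors
are frozen during LSTM training by construction; the LSTM consumes the
embedded matrix, not trainable token ids.

## Synthetic cohort generator

The generator emulates the statistical structure the pipeline assumes,
not real ICD semantics:

* Per-patient observation spans of 3–10 years inside a 2007–2018 study
  period; background codes as a Poisson stream (default 12 events per
  patient-year) over a Zipf-distributed synthetic vocabulary (default
  2,000 tokens — far below a real pan-therapeutic vocabulary, but large
  enough to preserve the long tail that motivates the min-count filter).
* Ages mostly 52–92 at entry (5% younger, to exercise the age filter);
  sex skewed female, more so in the bone-health cohort.
* Fracture probability per patient is
  `exp(0.06 * (age - 70) + 0.6 * female + frailty)` (frailty sd 0.3)
  scaled by a constant found by bisection so that the expected fracture
  share of anchor events among over-50 patients equals the configured
  incidence target — 8.5% (pan-therapeutic) or 39% (bone-health) by
  default. Age and sex must be genuine risk factors (so the demographic
  baselines have something real to recover) and must stay *consistent*
  between the bone-health training positives and the pan-therapeutic
  holdout — without a real sex effect, the female-skewed bone-health
  oversampling pool would teach models a spurious sex signal that is
  pure noise at evaluation time. The coefficients are calibrated against
  two published anchors: hip-fracture incidence roughly doubles per
  decade but the any-site outcome modeled here has a much flatter
  gradient (wrist/forearm risk plateaus after the 50s), and an age+sex
  boosted-tree baseline on these cohorts scores close to the ~0.67
  AUROC reported for that baseline on real EHR data. 10% of fracture
  patients receive a second fracture at least 200 days later.
* Fracture events are coded with initial-encounter tokens plus absorbed
  aftercare ("D") coding; 12 mid-frequency *signal codes* have their
  rate tripled in the 540 days before each fracture (configurable
  token→relative-risk map), which is the signal the sequence models are
  expected to recover.
* Interventions from the physician-intervention catalog (densitometry
  procedure tokens, osteoporosis diagnoses, pharmacologic drugs) are
  injected before 35% of fractures and for ~12% of non-fracture
  patients, enabling the human-level-performance analyses.

What the generator does **not** model: comorbidity networks, care-seeking
dynamics, coding drift, visit structure, inter-event time information, or
real code semantics. Passing tests on this generator demonstrates that
the pipeline recovers planted longitudinal signal under its own
assumptions — not that it attains any particular accuracy on real EHR
data.

A null configuration (`null_config()`) removes signal codes, the age and
sex effects, frailty, and interventions, making codes exchangeable
between classes; all models must then score at chance, which is the
pipeline's leakage check.

## Evaluation

AUROC is the Mann-Whitney concordance with midrank tie handling (equal to
brute-force pairwise concordance, which the test suite verifies
exhaustively on small inputs). AUPRC is average precision (step-wise
integration), not trapezoidal interpolation — the two differ at small n.
Thresholded metrics (recall, specificity, precision) default to a 0.5
threshold on the balanced-training probability scale; the operating point
behind the original published table is not stated, so the threshold is a
config knob and never part of a ranking claim. Stratified reports score
primary and subsequent fracture windows separately; negative windows have
no fracture type and join both strata's negatives (switchable).

The human-level-performance module flags a window as
"physician-identified" if its span contains any catalog intervention
(prefix match on diagnosis/procedure tokens, case-insensitive prefix
match on drug names). The cohort analysis cross-tabulates these flags
against model flags and outcomes; the overlap analysis scores one window
per treated patient ending the day before their first pharmacologic
intervention, under the same 730-day coverage rule. Intervention effects
confound the intervention-cohort cells; reports carry that caveat as a
footnote rather than any adjustment.

## Problem sizes

Desk-scale defaults were chosen so a full experiment runs on a laptop
CPU: pipeline simulations use a few thousand patients (the signal-recovery
check in the acceptance suite uses a 3,000-patient pan-therapeutic cohort
plus a 1,200-patient bone-health pool, roughly 18,000 balanced training
windows),
and generator calibration is verified on 50,000-patient cohorts. The
acceptance script regenerates both 50,000-patient cohorts from scratch
and reports their measured incidence rates.

## Known limitations

* Constant time between codes and uniform sequence length are assumed,
  as in the modeling approach this package implements; no visit grouping
  or time-gap encoding.
* The fracture case definition is a skeleton of the published
  claims-based rules; trauma-code exclusions and exact site subsets are
  configuration, not fixed truth.
* The numpy LSTM and embedding trainers favor determinism and clarity
  over speed; they are adequate at desk scale but not for millions of
  patients.
* Holdout AUROCs on synthetic cohorts are not comparable to published
  values on proprietary EHR data; only the qualitative ordering
  (frameworks > baselines, ensemble ≥ frameworks) is expected to
  transfer.
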