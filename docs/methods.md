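# Methods

`serialcox` predicts a cancer patient's survival risk from their serial
free-text radiology reports and provides the surrounding analysis: a
censoring-aware evaluation suite, differential N-gram risk-term
extraction, and individualized survival graphs. This note records the
model, the synthetic data-generating process, the numerical choices and
their rationale, and the known limitations.

## Model

A patient is an ordered sequence of dated reports plus a right-censored
outcome (follow-up time in months, death indicator). The risk score is a
log relative hazard produced in four stages:

1. **Token embedding.** Reports are lowercased and split on whitespace
   and punctuation, preserving hyphenated codes ("t3", "m-rectum").
   The default backbone is a trainable lookup table E ∈ R^{V×d};
   out-of-vocabulary tokens share one UNK row. Any context-sensitive
   encoder (e.g. a clinical transformer loaded from a local checkpoint)
   can be plugged in through the same `encode(tokens) -> (n, d)`
   interface; the lookup table is the default because the pipeline, not
   the pretrained backbone, is the object of study here.
2. **Attention pooling.** Additive single-head attention,
   s_i = v·tanh(W h_i), a = softmax(s), report vector r = Σ a_i h_i.
   The weights form a probability vector and are returned for
   inspection, so the pooled vector always lies in the convex hull of
   the token embeddings.
3. **Recurrent aggregation.** A GRU consumes the report vectors in
   chronological order from a zero initial state:
   z = σ(W_z x + U_z h + b_z), r = σ(W_r x + U_r h + b_r),
   h̃ = tanh(W_h x + r ∘ (U_h h) + b_h), h' = (1−z) ∘ h + z ∘ h̃.
   The final hidden state is the patient embedding vector. Intervals
   between reports are not model inputs; only order matters.
4. **Cox head.** risk = β·h, with no intercept (the partial likelihood
   is shift-invariant).

Training minimizes the negative log Cox partial likelihood with Breslow
tie handling, summed (not averaged) over events and optimized full-batch
so every event's risk set is exact. All forward and backward passes are
vectorized numpy with hand-derived gradients; the test-suite verifies
them against central finite differences end-to-end (loss through GRU,
attention and embeddings).

### Optimization defaults and why

* embed/attention/hidden dimensions 32 — at the desk scale studied here
  (cohorts of 1,000–4,000 patients, vocabularies of a few hundred
  types) 32 dimensions saturate held-out concordance, and full-batch
  numpy training at dimension 64 costs ~4× more for no measurable gain.
* Adam, learning rate 5e-3, 60 epochs, full batch. This setting was
  chosen on training diagnostics: survival corpora with ~15% events
  carry very little likelihood signal (on a planted-single-term corpus
  the true model improves the training loss by only ~3% over the null),
  so prolonged or aggressive optimization drives the loss far below the
  oracle level by memorizing event patients (training C-index → 0.98
  while held-out C-index falls). Moderate-length Adam training stops
  near the generalizing solution; weight decay, token dropout and
  smaller networks were all tried and were strictly worse on held-out
  concordance. A decoupled (AdamW-style) `weight_decay` knob is exposed
  but defaults to 0.
* The Cox head starts at zero (risk ≡ 0 at initialization), embeddings
  are N(0, 0.1), attention and GRU weights are uniform Xavier. Fits are
  bit-reproducible for a fixed seed.

### Degenerate inputs and numerics

* Partial likelihood with zero events returns 0 with a
  `NoEventsWarning`; training requires ≥2 events.
* Log-sum-exp is max-shifted; tied event times share the full Breslow
  risk set (groups located by a single sorted pass).
* Attention over padded positions uses a −1e30 score mask, so padded
  batch computation equals the per-patient loop to machine precision
  (asserted in tests).

## Synthetic data-generating process

The generator emulates a rectal-cancer MRI report cohort so every stage
is testable without protected records:

* 1–4 serial reports per patient with probabilities
  {1: 0.58, 2: 0.33, 3: 0.06, 4: 0.03}, matching the report-count mix of
  the emulated cohort (58% single-report patients).
* Report text: 15–40 tokens of neutral radiology boilerplate (with
  punctuation and hyphenated sequence names to stress the tokenizer)
  plus the patient's prognostic phrases spliced at random positions.
  The default phrase table mirrors rectal-MRI findings: "crm
  threatening" (log-hazard 1.2, prevalence 0.15), "mesorectal fat
  infiltration" (0.9, 0.25), "t3" (0.7, 0.35), "enlarged lymph node"
  (0.8, 0.20), "suspicious regional lymph node metastases" (1.0, 0.10)
  and a protective "no significant lymph node enlargements" (−0.8,
  0.30).
* Survival: T ~ Exponential(λ0·e^η) with λ0 = 0.0016/month and
  η = Σ β_k x_k over the phrases in the patient's **last** report
  (current disease status). Censoring is administrative at a 90-month
  horizon with staggered study entry (follow-up cap uniform on
  (0, horizon), giving a median follow-up near 45 months); an optional
  independent exponential censor can be added. λ0 and the horizon were
  calibrated once so the death fraction lands near 16%, the regime the
  package is meant for.
* **Response mechanism** (`response_prob`, default 0 and set to 0.5 in
  the serial-information studies): a multi-report patient whose reports
  carry a positive-hazard phrase drops the worst phrase from all
  reports after the first with this probability, and the hazard follows
  the last report — so the first report overstates a responder's risk
  and only the serial model can see the correction. 0.5 mirrors typical
  neoadjuvant response rates. A symmetric `progression_prob` can add a
  phrase instead.

What the generator does **not** emulate: clinically realistic prose,
report-length/severity correlation, inter-radiologist style, covariate
drift over calendar time, or informative censoring. Passing tests
demonstrate that the pipeline recovers planted multiplicative text
hazards under right censoring — not that it reaches any particular
performance on real reports.

## Evaluation suite

* **C-index** (Harrell): pairs comparable iff the earlier observed time
  is an event; risk ties score 1/2. Continuous-time data makes this
  coincide with the standard reference implementations, which the tests
  exploit.
* **Tertiles**: patients ranked by risk with stable order; outer-group
  sizes differ by ≤1 even under ties; cut points reported at the
  33.33/66.67 empirical percentiles.
* **Kaplan–Meier** product-limit curve and the **two-group log-rank**
  test (1 df, chi-squared) are computed from first principles and
  cross-checked against an established survival library on random data.
* **Spearman** rank correlation with average ranks for ties.
* **N-year AUROC**: positives survived ≥ N years (event or not),
  negatives died before N years, patients censored before N years are
  excluded (the simplest defensible policy; exclusions are visible
  through the per-threshold `missing` flags when a class empties). The
  positive-class score is the negated risk, so a useful model scores
  above 0.5. Thresholds default to 1, 2, 4 and 5 years.

## Risk-term extraction

N-grams (n = 1..5, covering phrase lengths up to "with mesorectal fat
infiltration") are collected with patient-level presence — one count per
patient regardless of how many reports repeat a phrase — which is robust
to verbose reports. Each N-gram present in ≥5 patients of the combined
high/low tertile groups is tested with Fisher's exact test on the 2×2
presence table; Benjamini–Hochberg controls the FDR at α = 0.05.
Significant N-grams are clustered by single-linkage on normalized
Levenshtein distance d/max(|a|,|b|) with threshold 0.3; each cluster is
reported through one representative: highest presence count, then lowest
p-value, then the **longest** phrase, then lexicographic. The length
preference matters: with patient-level presence every sub-gram of a
phrase has an identical patient set, and preferring the most specific
member (as with maximal frequent patterns) keeps "enlarged lymph node"
from being reported as "enlarged lymph".

Patient embedding vectors for visualization come from the final GRU
hidden state, by default fed with the first report only; 2-D projection
delegates to an established t-SNE (or a deterministic PCA fallback for
small cohorts and tests).

## Individualized survival graphs

For a new patient the model predicts a (serial-mode) risk; the training
patients with the smallest |risk_train − risk_new| — k = max(1,
round(0.05·n)), ties by stable order — contribute their observed
outcomes to a Kaplan–Meier curve. The 5% neighborhood is symmetric in
risk; similarity is deliberately one-dimensional (the scalar risk), not
embedding-space distance. Increasing the fraction yields nested
neighborhoods, and fraction 1.0 reproduces the whole-cohort curve
exactly.

## Design choices on genuinely open points

* Splits are random and stratified on event status (seeded); nothing in
  the data model supports temporal splitting of a synthetic cohort.
* Whole reports are encoded; findings and impression sections are not
  separated.
* Truncation (default 512 tokens) keeps the head of a report, since
  findings precede the impression.
* The serial/single C-index comparison is reported descriptively; no
  paired significance test is attached because no standard test matches
  the nested-prediction setting cleanly.

## Problem sizes used in the checked experiments

Tests and the acceptance script run at cohort sizes 1,000 (recovery,
interpretability, null calibration) and 2,000 (serial-vs-first
comparisons, where the responder subgroup is small and the C-index
difference needs a larger test set to be resolvable), with 800/200 and
1,600/400 splits. The signal-recovery studies show that at ~150 events
per fit the held-out concordance of the fitted model sits within ~0.04
of the oracle (the true linear predictor) — close to the information
ceiling of the generating process, which for a single binary term with
log-hazard 1.5 and prevalence 0.5 is ≈ 0.66.

## Limitations

* The default backbone is a bag-of-embeddings: it cannot resolve
  negation or word order within a report ("no t3 lesion" contains the
  token "t3"). The protective phrases in the generator are token-
  disjoint from the harmful ones for this reason; real reports are not.
* Exponential baseline hazard only (Weibull shape is a config
  extension point, not implemented).
* No confidence intervals on the C-index or bands on neighbor KM
  curves.
* Mini-batch training (``fit(batch_size=...)``) approximates each
  event's risk set within its batch; it exists for corpora too large
  for full-batch passes, and all defaults and reported results use the
  exact full-batch path.
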