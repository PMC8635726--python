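# serialcox

Survival risk from serial free-text radiology reports.

Oncology EMRs accumulate unstructured radiology reports — ordered,
dated free text that tracks a patient's disease over time — but almost
all survival modelling ignores them. `serialcox` implements a neural
Cox proportional-hazards pipeline that maps a patient's serial reports
directly to a survival risk score, together with the analyses a
clinical study of such a model needs: censoring-aware evaluation,
interpretable risk-term extraction, and individualized survival graphs
for new patients. It is aimed at biostatisticians and clinical-NLP
researchers who want a fully testable, dependency-light reference
implementation of this kind of pipeline.

## The model

For a patient with reports x₁, …, x_k (chronological order):

1. each report's tokens are embedded (trainable lookup table by
   default; any external encoder with an `encode(tokens) -> (n, d)`
   method can be plugged in),
2. additive attention pools token embeddings into one report vector:
   a = softmax(v·tanh(W hᵢ)), r = Σ aᵢ hᵢ,
3. a GRU folds the report vectors into a patient embedding h, and
4. a linear Cox head scores the log relative hazard: risk = β·h.

All parameters are trained end-to-end by full-batch Adam on the
negative log Cox partial likelihood with Breslow tie handling,

L(β, …) = −Σ_{i: δᵢ=1} [ rᵢ − log Σ_{j: tⱼ ≥ tᵢ} exp(rⱼ) ],

implemented in vectorized numpy with hand-derived, finite-difference-
verified gradients. Around the model:

* `synthetic` — a report-corpus generator with planted multiplicative
  text hazards (exponential survival, right censoring, serial-report
  "response" dynamics) so every stage is testable end to end;
* `evaluation` — Harrell's C-index, risk tertiles, Kaplan–Meier,
  log-rank, Spearman R_s, and N-year survival AUROC under censoring;
* `terms` — differential N-gram extraction between predicted high- and
  low-risk groups (Fisher's exact + Benjamini–Hochberg), edit-distance
  clustering to representative phrases, per-term log-rank tests, and
  2-D projection of patient embeddings;
* `survival_graph` — an individualized Kaplan–Meier curve for a new
  patient from the 5% of training patients with the most similar
  predicted risk.

## Worked example

```python
import serialcox as sc

cohort = sc.generate_cohort(sc.SynthConfig(n_patients=1000, seed=1))
train, test = sc.split_cohort(cohort, 0.2, seed=1)

results = sc.SerialCoxModel(train).fit(seed=1)
print(results.summary())

report = results.evaluate(test)
print(f"held-out C-index (serial): {report.c_index:.3f}")
print(f"2-year survival AUROC: {report.auroc[2]:.3f}")
print(f"log-rank high vs low tertile: chi2 = {report.logrank_chi2:.1f}, "
      f"p = {report.logrank_p:.1e}")

graph = results.survival_graph(test[0], fraction=0.05)
print(f"new patient risk {graph.risk:.3f} (percentile {graph.percentile:.1f}), "
      f"{len(graph.neighbor_ids)} neighbors, S(24 mo) = "
      f"{graph.km.survival_at(24.0):.3f}")
```

prints

```
Serial neural Cox survival model
========================================
patients:            800
events (deaths):     121
reports:             1225
vocabulary size:     121
embed/attn/hidden:   32/32/32
epochs:              60
seed:                1
initial loss:        736.3454
final loss:          659.1038
|beta|_2:            1.1265
held-out C-index (serial): 0.741
2-year survival AUROC: 0.807
log-rank high vs low tertile: chi2 = 15.3, p = 9.1e-05
new patient risk -0.027 (percentile 39.8), 40 neighbors, S(24 mo) = 0.971
```

The C-index of 0.741 says that in 74% of comparable patient pairs the
model assigns the higher risk to the patient who died earlier; the
log-rank p-value confirms the predicted high- and low-risk tertiles
have genuinely different survival; and the survival graph places the
new patient at the 40th risk percentile with the Kaplan–Meier curve of
their 40 risk-nearest training patients (97% estimated 2-year
survival).

The same pipeline is scriptable from the shell:

```bash
serialcox simulate --out corpus.jsonl --n 1000 --seed 1
serialcox train --corpus corpus.jsonl --out model/ --seed 1
serialcox evaluate --model model/ --train-corpus corpus.jsonl --corpus corpus.jsonl
serialcox terms --model model/ --train-corpus corpus.jsonl --corpus corpus.jsonl
serialcox survival-graph --model model/ --train-corpus corpus.jsonl \
    --new-reports new_patient.jsonl
```

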