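# ttdml — time-to-death prediction after terminal extubation

Organ donation after circulatory death (DCD) hinges on an unanswerable
bedside question: after life support is withdrawn, will this patient die
within the warm-ischemia window that keeps their organs transplantable?
`ttdml` is a research library for that prediction problem. It models a
patient's irregularly-sampled pre-extubation ICU history — 25
longitudinal channels (vitals, ventilation, neuro assessments, labs,
medication doses) plus 5 static variables — and predicts the probability
that time-to-death (TTD) falls in each of four ordinal bins:
<30, 30–60, 60–120, and >120 minutes.

The core model is an **ODE-RNN**: between observations the hidden state
`h` evolves continuously by integrating a learned vector field
`dh/dτ = f_ODE(h)`; at each observation a GRU cell updates `h` from the
observed values `x_i`, the observation mask `m_i` (informative
missingness), and the gap `Δt_i`. The final state is fused with the
static variables into a **latent phenotype** `z`, and an MLP head maps
`z` to softmax probabilities `(p_0, p_1, p_2, p_3)`, which sum to 1 by
construction. Alongside the model the package ships:

* a synthetic DCD-cohort simulator with known ground truth (real
  cohorts are protected health information), whose TTD follows a
  log-normal accelerated-failure-time model driven by trajectory-shape
  features: heart-rate range, minimum SpO2, mean GCS, maximum MAP, BMI;
* preprocessing (forward/backward/mean-fill imputation, masks,
  train-only normalization, 2021 temporal split, history truncation);
* baselines (RNN/LSTM/GRU, XGBoost on last observations, a configurable
  clinical-criteria checklist, the marginal predictor);
* the metric suite (4-way accuracy, grouped binary ROC-AUC / PR-AUC /
  F1 / PPV / NPV, expected calibration error, calibration curves,
  multi-seed mean ± sd);
* interpretation (trajectory-level permutation importance, and the
  "phenoscape": UMAP embedding + clustering of the latent phenotypes).

Everything is deterministic under a seed, in float64 numpy, with an
in-package reverse-mode autodiff — no deep-learning framework required.

## Worked example

```python
from ttdml import (ModelConfig, NormalizationStats, SimulationConfig,
                   evaluate_model, prepare_cohort, simulate_cohort,
                   temporal_split, train_model)

cohort, _ = simulate_cohort(SimulationConfig(n_patients=600, seed=0))
train_c, test_c = temporal_split(cohort)      # train < 2021 <= test
stats = NormalizationStats.fit(train_c)       # train-side stats only
train, test = prepare_cohort(train_c, stats), prepare_cohort(test_c, stats)

model = train_model(train, ModelConfig(seed=0, epochs=30), kind="ode_rnn")
report = evaluate_model(model, test, model_name="ode_rnn")
```

Running this (`python examples/02_train_and_evaluate.py`) prints:

```
n_train=400  n_test=200
accuracy4        0.710
accuracy_lt30    0.745
roc_auc_lt30     0.726
pr_auc_lt30      0.872
f1_lt30          0.835
ppv_lt30         0.791
npv_lt30         0.541
ece_lt30         0.130
```

`accuracy4` is 4-way argmax accuracy (chance = 0.25, the marginal
predictor scores ≈ 0.66 on this imbalanced cohort); the `lt30` metrics
score the grouped binary task "dies within 30 minutes", whose positive
probability is `p_0`; `ece_lt30` is the expected calibration error of
those probabilities over 10 equal-width bins. At the default study scale
(2000 patients, five seeds) the ODE-RNN reaches ≈ 0.71 4-way accuracy
vs ≈ 0.70 for the last-observation XGBoost and 0.66 for the marginal
predictor, with ECE ≈ 0.06 — the trajectory-shape drivers are exactly
what a static model cannot see.

The other scripts in `examples/` are one capability each: simulating and
summarizing a cohort, permutation importance, the phenoscape clustering,
and early prediction using only data up to 12 h before extubation.

A thin CLI mirrors the library for shell use:

```bash
ttd simulate --n 1000 --seed 0 --out cohort/
ttd train --cohort cohort/ --kind ode_rnn --out model.npz
ttd evaluate --model model.npz --cohort cohort/ --out report.json
ttd run --config run.yaml --out runs/exp1   # full pipeline
```

## Layout

```
src/ttdml/        vocabulary, cohort I/O, simulate, preprocessing,
                  nn (autodiff), model (ODE-RNN + sequence baselines),
                  baselines, evaluation, interpretation, pipeline, cli
examples/         narrative scripts, one per capability
tests/            pytest suite (unit, property, end-to-end)
docs/methods.md   the model, generator and conventions in detail
```
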