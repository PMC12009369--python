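"""Early prediction: train and evaluate with data up to 12 h pre-extubation.

Dropping the final 12 hours of history emulates making the call half a day
before withdrawal of life support, when procurement logistics still have
time to react. Expect lower accuracy than the full-history model: the most
recent (and most informative) observations are withheld.
"""

from ttdml import (ModelConfig, NormalizationStats, PreprocessConfig,
                   SimulationConfig, evaluate_model, prepare_cohort,
                   simulate_cohort, temporal_split, train_model)

# longer histories so most patients still have data beyond the horizon
cohort, _ = simulate_cohort(SimulationConfig(n_patients=600, seed=0,
                                             history_median_min=1500.0))
train_c, test_c = temporal_split(cohort)
stats = NormalizationStats.fit(train_c)

for label, pre in [("full history", PreprocessConfig()),
                   ("up to 12 h before extubation",
                    PreprocessConfig(horizon_min=720.0))]:
    train = prepare_cohort(train_c, stats, pre)
    test = prepare_cohort(test_c, stats, pre)
    model = train_model(train, ModelConfig(seed=0, epochs=25), kind="ode_rnn")
    report = evaluate_model(model, test)
    print(f"{label:32s} n_test={len(test):4d} "
          f"accuracy4={report.mean['accuracy4']:.3f} "
          f"roc_auc_lt30={report.mean['roc_auc_lt30']:.3f}")
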