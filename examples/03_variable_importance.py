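"""Permutation variable importance for a trained model.

Each longitudinal channel's whole per-patient trajectory (values and mask
together) is swapped across patients; each static variable's value is
swapped across patients. The importance of a variable is the drop in
ROC-AUC of the <30-minute task it causes, averaged over repeats: large
positive deltas mean the model relies on that variable, deltas near zero
mean it is ignored.
"""

from ttdml import (BinaryTask, ModelConfig, NormalizationStats,
                   SimulationConfig, importance_table, prepare_cohort,
                   simulate_cohort, temporal_split, train_model)

cohort, _ = simulate_cohort(SimulationConfig(n_patients=500, seed=0))
train_c, test_c = temporal_split(cohort)
stats = NormalizationStats.fit(train_c)
train = prepare_cohort(train_c, stats)

model = train_model(train, ModelConfig(seed=0, epochs=25), kind="ode_rnn")
table = importance_table(
    model, test_c, stats, [BinaryTask(30.0)],
    variables=["pulse", "spo2", "gcs", "map", "bnp", "lidocaine",
               "age", "bmi", "sex"],
    n_repeats=3, seed=0)

print(table.sort_values("rank")[
    ["variable", "kind", "delta_mean", "delta_sd", "rank"]
].to_string(index=False))
print("\ndelta_mean = baseline ROC-AUC minus permuted ROC-AUC; the default "
      "cohort carries its signal in the vitals and neuro channels, so those "
      "should out-rank the static variables and the unused labs/medications.")
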