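"""Train the cost model M2 and predict annual visit costs.

M2 reads a long-follow-up patient's visit history up to the final-year
cutoff and decodes the cost types of the final-year visits.  The training
loss combines a squared error on the annual expected cost (through the
per-type cost schedule e_c) with a per-visit cross-entropy:
L = log10(L1) + L2.  Runs in about a minute on one CPU.
"""

import numpy as np

from osacost import (
    CovariateVocab,
    ModelConfig,
    SyntheticConfig,
    TrainSettings,
    assign_cohorts,
    build_vocab_and_schedule,
    encode_for_prediction,
    evaluate_m2,
    generate_cohort,
    predict_annual_cost,
    split_cohort,
    train_m2,
)

patients, _ = generate_cohort(
    SyntheticConfig(n_patients=600, short_followup_fraction=0.3,
                    n_cost_types=8, seed=8)
)
_, d2 = assign_cohorts(patients)
vocab, schedule = build_vocab_and_schedule([d2])
covariates = CovariateVocab.from_cohorts([d2])

config = ModelConfig(
    d_model=32, n_heads=4, n_encoder_layers=1, n_decoder_layers=1,
    feedforward_width=64, dropout=0.0, max_input_len=64, max_target_len=24,
    vocab_sizes={
        "cost_type": vocab.size, "age": 121,
        "gender": covariates.n_gender,
        "specialist": covariates.n_specialist, "diff_bucket": 17,
    },
    seed=8,
)
train_c, val_c, test_c = split_cohort(d2, (0.8, 0.1, 0.1), seed=8)
enc = lambda c: encode_for_prediction(c, vocab, covariates,
                                      config.max_input_len,
                                      config.max_target_len)
train, val, test = enc(train_c), enc(val_c), enc(test_c)

m2, trace = train_m2(
    train, val, config, schedule, vocab,
    TrainSettings(epochs=20, batch_size=32, learning_rate=1e-3, seed=8),
)
print(f"trained {len(trace['train'])} epochs; "
      f"best validation loss {trace['best_val']:.3f} "
      f"at epoch {trace['best_epoch']}")

report = evaluate_m2(m2, test, schedule, vocab)
print("\nheld-out evaluation:")
for k, acc in sorted(report.top_k.items()):
    print(f"  top-{k} cost-type accuracy: {acc:.3f}")
print(f"  annual-cost RMSE: {report.rmse:.1f} EUR")
print(f"  annual-cost R^2:  {report.r_squared:.3f}")

out = predict_annual_cost(m2, test, schedule, vocab)
truth = test.true_annual_costs
print("\nfirst five test patients (predicted vs true annual cost, EUR):")
for pid, pred, true in list(zip(test.patient_ids, out["annual_cost"], truth))[:5]:
    print(f"  {pid}: {pred:8.1f} vs {true:8.1f}")
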