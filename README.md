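# osacost

Two-model Transformer pipeline for predicting next-year healthcare visit
costs from chronic-disease EHR visit sequences, with model-based data
augmentation for scarce long-follow-up cohorts.

Patients with obstructive sleep apnea (or any chronic condition coded at a
first diagnosis date) accumulate visit records: days since diagnosis
(`diff_dgn`), demographics, specialist type, a categorical *cost type*, and
a euro cost. Predicting a patient's final follow-up year requires at least
a year of history — but most patients in a registry snapshot have less.
This package turns that problem around:

- **M1 (augmenter)** — an encoder–decoder Transformer trained on the
  short-follow-up cohort **D¹** (< 365 days) to predict a patient's next
  one or two visit cost types from the history so far.
- **Augmentation algorithm** — samples copies of long-follow-up training
  patients, anchors a first-year visit in each copy, and edits it based on
  M1's prediction: *delete* when the prediction is unsupported in D²,
  *inject* the second predicted visit when the first is correct, *replace*
  otherwise. Every written cost type stays inside V², the cost-type
  support of D², so the cohort's sequence-pattern distribution is
  preserved.
- **M2 (cost model)** — a second Transformer trained on the enlarged
  long-follow-up cohort **D²** (≥ 365 days) to decode the cost types of
  the final-year visits and, through a per-type cost schedule e_c, the
  annual total cost. Its loss combines regression and classification:
  `L = log10(L1) + L2`, where L1 is the squared annual expected-cost error
  and L2 the per-visit cross-entropy.

Everything — including reverse-mode automatic differentiation, multi-head
attention, and Adam — is implemented on NumPy alone; no deep-learning
framework is required.

## Quick example

```python
from osacost import (
    SyntheticConfig, generate_cohort, assign_cohorts,
    build_vocab_and_schedule, CovariateVocab, ModelConfig, TrainSettings,
    split_cohort, encode_for_prediction, train_m2, evaluate_m2,
)

patients, _ = generate_cohort(SyntheticConfig(
    n_patients=600, short_followup_fraction=0.3, n_cost_types=8, seed=8))
_, d2 = assign_cohorts(patients)
vocab, schedule = build_vocab_and_schedule([d2])
covariates = CovariateVocab.from_cohorts([d2])
config = ModelConfig(
    d_model=32, n_heads=4, n_encoder_layers=1, n_decoder_layers=1,
    feedforward_width=64, dropout=0.0, max_input_len=64, max_target_len=24,
    vocab_sizes={"cost_type": vocab.size, "age": 121,
                 "gender": covariates.n_gender,
                 "specialist": covariates.n_specialist, "diff_bucket": 17},
    seed=8)
train_c, val_c, test_c = split_cohort(d2, (0.8, 0.1, 0.1), seed=8)
enc = lambda c: encode_for_prediction(c, vocab, covariates, 64, 24)
m2, _ = train_m2(enc(train_c), enc(val_c), config, schedule, vocab,
                 TrainSettings(epochs=20, batch_size=32,
                               learning_rate=1e-3, seed=8))
print(evaluate_m2(m2, enc(test_c), schedule, vocab).to_dict())
```

On this seeded synthetic cohort the run above reaches, held out: top-3
cost-type accuracy 0.808, top-5 0.912, annual-cost RMSE 160.4 EUR, and
R² 0.889 against a mean-annual-cost baseline (about a minute on one CPU).

The `examples/` directory walks through the whole method:

| script | shows |
|---|---|
| `examples/01_generate_cohort.py` | synthetic cohort generation, D¹/D² partition |
| `examples/02_windowing.py` | the two input/target windowings (t′ / t″) |
| `examples/03_augment.py` | training M1 and running the augmentation algorithm |
| `examples/04_cost_model.py` | training M2 and predicting annual costs |
| `examples/05_full_pipeline.py` | the raw/random/model-augmentation comparison |

## Command line

A thin CLI wraps the library for file-based use:

```bash
osacost synth generator.yaml visits.csv       # write a synthetic visit CSV
osacost run pipeline.yaml                     # run a full comparison
osacost evaluate predictions.csv              # RMSE / R² of a predictions file
```

`pipeline.yaml` mirrors `PipelineConfig` (see
`examples/05_full_pipeline.py` for the equivalent in-Python configuration).

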