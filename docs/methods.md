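# Methods

This document describes the data model, the two Transformers, the
augmentation algorithm, the losses and metrics, the synthetic cohort
generator, and the numerical choices the implementation makes.

## Data model

A **visit record** holds `patient_id`, `diff_dgn` (days elapsed since the
patient's first diagnosis — the sequence's time axis), `age`, `gender`,
`specialist_type`, a categorical `cost_type`, and `cost_eur`. A
**patient history** is a patient's visits sorted by `diff_dgn`; `s_i`
denotes the number of visits and `t_i` the last visit day (follow-up
duration).

Patients are partitioned by follow-up duration:

- **D¹**: `t_i < 365` days — too short for next-year prediction; used to
  train the augmentation model M1.
- **D²**: `t_i ≥ 365` days — used to train and evaluate the cost model
  M2. A patient with exactly 365 days of follow-up belongs to D².

### Windowings

Two input/target splits are used:

- **Augmentation split** (M1 training): inputs are visits `1..s_i-2`,
  targets the last two visits. A patient needs at least three visits to
  contribute.
- **Prediction split** (M2): the boundary is the final-year cutoff
  `t_i - 364`. The last input day is
  `t′ = max{x ∈ T_i : 0 ≤ x < t_i - 364}` and the first target day
  `t″ = min{x ∈ T_i : t_i - 364 ≤ x ≤ t_i}`. For a patient with visits at
  days {0, 30, 70, 248, 690, 810, 1100, 1140}: cutoff 776, t′ = 690,
  t″ = 810. A D² patient whose every visit falls inside the final year
  has no input window and is excluded (logged).

### Tokenization

Model inputs sum five embedded variables per visit: cost type, age
(integer years, 0–120), gender, specialist type, and a log-spaced
`diff_dgn` bucket (16 buckets plus a zero bucket). Input sequences are
`[CLS] v₁ … vₛ [SEP] [PAD]…`; when a history exceeds the input-length
budget the *oldest* visits are dropped. Decoder targets are the target
visits' cost-type ids followed by `[SEP]`. The three special tokens are
appended after the real cost types in the vocabulary and are priced 0 in
the cost schedule.

The per-type cost value `e_c` is the mean observed euro cost of type `c`
over the cohorts used to build the schedule.

## Models

Both M1 and M2 are post-norm encoder–decoder Transformers with sinusoidal
positional encodings, multi-head scaled dot-product attention, ReLU
feed-forward blocks, residual connections and layer normalization. The
decoder input is the target sequence shifted right with `[CLS]` as the
start token (teacher forcing); causal and padding masks use a −10⁹
additive constant. Free-running generation is batched greedy decoding
that excludes `[CLS]` and `[PAD]` from the argmax and stops at `[SEP]`.

All tensor operations run on a small reverse-mode automatic
differentiation core over float64 NumPy arrays (softmax and log-softmax
with analytic backwards, embedding scatter via `np.add.at`, broadcasting
un-reduction, Adam). Gradients are verified against central finite
differences in the test suite.

- **M1** decodes a fixed two-visit horizon (`max_target_len = 4`). Its
  cross-entropy supervises only the two visit positions, not the terminal
  `[SEP]`: with a two-token horizon the stop symbol would otherwise make
  up a third of the supervision and bias greedy decoding toward stopping
  immediately.
- **M2** decodes the full final-year visit sequence and is trained with
  the combined loss below.

## Losses

For patient *i* with final-year visits *k* and predicted type
probabilities `p̂_ikc`:

- **L1** (regression): the squared error between the annual *expected*
  cost `Σ_k Σ_c p̂_ikc e_c` and the annual true cost `Σ_k c_ik`, averaged
  over the batch. Only real visit positions enter; `[SEP]` and padding
  are masked out.
- **L2** (classification): per-visit cross-entropy averaged per patient
  (over the supervised positions, including the terminal `[SEP]` for M2)
  and then over the batch.
- **Combined**: `L = log10(L1) + L2`. The logarithm keeps the
  euro-scaled regression term from swamping the cross-entropy. L1 is
  clamped below at 1e-12 before the logarithm so an exact regression fit
  cannot produce −∞.

Training uses Adam, minibatch shuffling from a seeded generator, early
stopping on the validation combined loss, and restores the best-epoch
checkpoint.

## Augmentation algorithm

Given a trained M1, the D² training cohort, a sample ratio ρ and an
iteration count R (defaults ρ = 0.55, R = 3):

1. Each iteration samples ⌊ρN⌋ training patients uniformly without
   replacement and deep-copies them (the source cohort is never mutated).
2. In each copy one anchor visit k is chosen uniformly among candidates:
   k ≥ 2 (non-empty history) with `diff_dgn < 365` (inside the first
   year). Copies without candidates are kept unedited.
3. M1 greedily decodes two visits from the history before k, giving
   predictions v̂_k, v̂_{k+1} and the first-step probability row.
4. Case analysis, with V² = the set of cost types observed in D²:
   - v̂_k missing or ∉ V² → **delete** visit k;
   - v̂_k equals the true type → **inject** a new visit after k carrying
     v̂_{k+1} (one day later, priced by the schedule) — only if v̂_{k+1}
     is itself in V², otherwise the copy is left unchanged, so the V²
     invariant can never be violated through injection;
   - otherwise → **replace** visit k's type with the
     highest-probability type in V² (ties to the lowest vocabulary
     index), repriced by the schedule.

The final M2 training cohort is the originals plus every surviving copy:
with no deletions of whole copies, N + R⌊ρN⌋ patients (e.g. 3,910 + 3 ×
2,150 = 10,360 at ρ = 0.55).

A **random comparator** with identical sampling mechanics applies a
uniformly random delete/replace/insert at each anchor, drawing types from
the empirical D² distribution.

### Quality gate

The pipeline accepts M1's augmentations only if its held-out top-3
accuracy reaches `gate_threshold` (default 0.91). On stochastic synthetic
cohorts the Bayes-optimal accuracy is far below that — the generator's
Markov rows are genuinely entropic — so runs on synthetic data must relax
the gate explicitly (the examples use 0.0–0.5). Failing the gate skips
the transformer mode and records the failure in the report rather than
silently training on untrusted augmentations.

## Metrics

- **Top-k accuracy**: fraction of all target visits whose true cost type
  is among the k highest-probability types. Ranking uses a stable sort on
  negated scores, so ties resolve to the lowest vocabulary index —
  deterministic across platforms.
- **RMSE** and **R²** are computed over per-patient annual totals; R² is
  relative to the mean-annual-cost baseline and is reported as NaN when
  the true totals have zero variance (no baseline to beat).

## Synthetic cohort generator

Per patient: a first visit at day 0, geometric gaps calibrated to
`visit_rate` visits per year, cost types following a first-order Markov
chain whose rows are Dirichlet draws (`transition_concentration`
controls entropy; 0.0 degenerates to a deterministic permutation kernel),
and lognormal visit costs around per-type nominal values
(`cost_lognormal_sigma = 0` gives exactly the nominal cost). Short- and
long-follow-up patients share one kernel; long patients get a guard visit
so they genuinely cross the 365-day boundary. The generator returns the
ground-truth kernel for diagnostics only — models never see it.

Defaults: 1,000 patients, 70 % short follow-up, 12 cost types, 12 visits
per year, concentration 0.25, σ = 0.25, up to 3 years of follow-up.

## Problem sizes

The package's standard desk-scale benchmark (used by the slow tests) is
~2,000 patients with 12 cost types: large enough that M1 reliably beats a
marginal-frequency baseline and augmentation effects are measurable,
small enough to train in minutes on one CPU with this NumPy stack.
Real registry cohorts (tens of thousands of visits, 50–100 cost types)
are well within the data structures' limits but need proportionally more
compute.

## Numerical choices

- float64 throughout; no nondeterministic reductions.
- Softmax/log-softmax subtract the row max before exponentiation.
- Additive mask constant −10⁹ (not −∞, which would generate NaNs under
  `exp`).
- L1 clamp at 1e-12 before `log10`.
- All sampling flows through `numpy.random.Generator(PCG64(seed))`;
  pipeline sub-seeds are fixed offsets of the base seed, so a
  configuration plus seed determines every byte of the report JSON.

## Limitations

- Greedy decoding only; no beam search.
- Injected visits are placed one day after their anchor rather than
  sampling a realistic gap.
- The cost schedule prices a type by its mean observed cost, so
  within-type cost variance is irreducible error for the regression head
  (visible as an R² ceiling on cohorts with large σ).
- The NumPy training loop is single-threaded BLAS-bound; it is meant for
  desk-scale experiments, not production training.
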