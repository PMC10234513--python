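"""Sampling, Algorithm case logic, and M1 training contracts."""

import numpy as np
import pytest

from osacost.augment import (
    AugmentationResult,
    M1Predictor,
    aggregate_with_originals,
    augment,
    marginal_topk_accuracy,
    random_augment,
    sample_patients,
    train_m1,
)
from osacost.costmodel import TrainSettings
from osacost.records import (
    Cohort,
    CostSchedule,
    CostTypeVocabulary,
    CovariateVocab,
    PatientHistory,
    VisitRecord,
    assign_cohorts,
    build_vocab_and_schedule,
)
from osacost.synthetic import SyntheticConfig, generate_cohort
from osacost.transformer import ModelConfig

from conftest import make_patient


# -- sampling -------------------------------------------------------------------


def cohort_of(n, label="D2"):
    return Cohort(
        [make_patient(f"p{i}", [0, 50, 400]) for i in range(n)], label
    )


def test_sample_size_is_floor_of_ratio_times_n():
    rng = np.random.Generator(np.random.PCG64(0))
    out = sample_patients(cohort_of(3910), 0.55, rng)
    assert len(out) == 2150  # floor(0.55 * 3910)


def test_sample_ratio_one_returns_all_without_replacement():
    rng = np.random.Generator(np.random.PCG64(1))
    out = sample_patients(cohort_of(20), 1.0, rng)
    assert sorted(p.patient_id for p in out) == sorted(
        f"p{i}" for i in range(20)
    )


def test_sampling_is_seed_deterministic():
    a = sample_patients(cohort_of(50), 0.5, np.random.Generator(np.random.PCG64(7)))
    b = sample_patients(cohort_of(50), 0.5, np.random.Generator(np.random.PCG64(7)))
    assert [p.patient_id for p in a] == [p.patient_id for p in b]


@pytest.mark.parametrize("ratio", [0.0, -0.1, 1.5])
def test_invalid_sample_ratio_rejected(ratio):
    rng = np.random.Generator(np.random.PCG64(2))
    with pytest.raises(ValueError, match="ratio"):
        sample_patients(cohort_of(5), ratio, rng)


def test_sampled_copies_are_independent_of_source():
    src = cohort_of(10)
    rng = np.random.Generator(np.random.PCG64(3))
    out = sample_patients(src, 1.0, rng)
    out[0].visits[0] = VisitRecord("p0", 0, 50, "F", "S0", "A", 999.0)
    assert src.patients[0].visits[0].cost_eur == 10.0


# -- Algorithm case logic via a scripted predictor -------------------------------


class ScriptedPredictor:
    """Stands in for M1: answers every history with a fixed (t1, t2, probs)."""

    def __init__(self, vocab, t1, t2, probs=None):
        self.vocab = vocab
        self._answer = (t1, t2, probs if probs is not None
                        else np.full(vocab.size, 1.0 / vocab.size))

    def predict_batch(self, histories):
        return [self._answer for _ in histories]


@pytest.fixture
def case_world():
    vocab = CostTypeVocabulary(["A", "B", "X"])
    schedule = CostSchedule({"A": 10.0, "B": 20.0, "X": 30.0})
    # D2 supports only A and B, so V2 = {A, B}; X is M1-only vocabulary.
    d2 = Cohort(
        [
            make_patient("p0", [0, 100, 400], ["A", "B", "A"]),
            make_patient("p1", [0, 200, 500], ["B", "A", "B"]),
        ],
        "D2",
    )
    return vocab, schedule, d2


def run_case(case_world, t1, t2, probs=None):
    vocab, schedule, d2 = case_world
    pred = ScriptedPredictor(vocab, t1, t2, probs)
    return augment(pred, d2, schedule, ratio=1.0, iterations=1, seed=0)


def test_unsupported_prediction_deletes_anchor(case_world):
    res = run_case(case_world, t1="X", t2=None)
    assert res.n_deleted == 2 and res.n_processed_anchors == 2
    for c in res.augmented_patients:
        assert len(c.visits) == 2  # one visit removed


def test_no_prediction_deletes_anchor(case_world):
    res = run_case(case_world, t1=None, t2=None)
    assert res.n_deleted == 2


def test_correct_prediction_injects_supported_second_type(case_world):
    vocab, schedule, d2 = case_world
    # anchor is always visit 2 (the only k with history and diff_dgn < 365):
    # p0's visit 2 is type B, p1's is type A.  Predicting "B" matches p0 only.
    res = run_case(case_world, t1="B", t2="A")
    assert res.n_injected == 1 and res.n_replaced == 1
    p0 = next(c for c in res.augmented_patients if c.patient_id.startswith("p0"))
    assert len(p0.visits) == 4
    inj = p0.visits[2]
    assert inj.cost_type == "A"
    assert inj.cost_eur == schedule.cost_of("A")
    assert inj.diff_dgn == p0.visits[1].diff_dgn + 1
    assert [v.diff_dgn for v in p0.visits] == sorted(v.diff_dgn for v in p0.visits)


def test_correct_prediction_with_unsupported_followup_leaves_unchanged(case_world):
    res = run_case(case_world, t1="B", t2="X")
    assert res.n_injected == 0
    assert res.n_unchanged == 1 and res.n_replaced == 1


def test_wrong_prediction_replaces_with_best_supported_type(case_world):
    vocab, schedule, d2 = case_world
    probs = np.array([0.1, 0.2, 0.7])  # argmax X, but X is outside V2
    res = run_case(case_world, t1="A", t2=None, probs=probs)
    # "A" matches p1's anchor (inject path blocked: t2 None -> unchanged);
    # p0's anchor is B != A -> replace with best of {A, B} = B
    assert res.n_replaced == 1 and res.n_unchanged == 1
    p0 = next(c for c in res.augmented_patients if c.patient_id.startswith("p0"))
    assert p0.visits[1].cost_type == "B"
    assert p0.visits[1].cost_eur == schedule.cost_of("B")


def test_replacement_ties_break_to_lowest_index(case_world):
    vocab, schedule, _ = case_world
    probs = np.array([0.4, 0.4, 0.2])
    res = run_case(case_world, t1="A", t2=None, probs=probs)
    p0 = next(c for c in res.augmented_patients if c.patient_id.startswith("p0"))
    assert p0.visits[1].cost_type == "A"  # index of A < index of B


def test_all_augmented_types_stay_inside_v2(case_world):
    vocab, schedule, d2 = case_world
    v2 = d2.cost_type_support()
    for t1, t2 in [("X", "X"), ("A", "B"), ("B", "A"), (None, None)]:
        res = run_case(case_world, t1, t2)
        for c in res.augmented_patients:
            assert {v.cost_type for v in c.visits} <= v2


def test_source_cohort_is_never_mutated(case_world):
    vocab, schedule, d2 = case_world
    before = [
        [(v.diff_dgn, v.cost_type, v.cost_eur) for v in p.visits]
        for p in d2
    ]
    run_case(case_world, t1="X", t2=None)
    after = [
        [(v.diff_dgn, v.cost_type, v.cost_eur) for v in p.visits]
        for p in d2
    ]
    assert before == after


def test_counter_conservation_over_iterations(case_world):
    vocab, schedule, d2 = case_world
    pred = ScriptedPredictor(vocab, "B", "A")
    res = augment(pred, d2, schedule, ratio=1.0, iterations=3, seed=5)
    # every copy has exactly one usable anchor, so anchors == copies
    assert res.n_processed_anchors + res.n_skipped_unusable == 3 * 2
    assert len(res.provenance) == 6
    assert all(src in {"p0", "p1"} for src in res.provenance.values())


def test_patient_without_usable_anchor_is_kept_unedited():
    vocab = CostTypeVocabulary(["A"])
    schedule = CostSchedule({"A": 10.0})
    d2 = Cohort([make_patient("solo", [0, 400, 500])], "D2")  # k=2,3 are >= 365
    pred = ScriptedPredictor(vocab, "A", "A")
    res = augment(pred, d2, schedule, ratio=1.0, iterations=1, seed=0)
    assert res.n_skipped_unusable == 1 and res.n_processed_anchors == 0
    assert len(res.augmented_patients) == 1
    assert len(res.augmented_patients[0].visits) == 3


def test_vocabulary_must_cover_d2_support(case_world):
    _, schedule, d2 = case_world
    narrow = CostTypeVocabulary(["A"])
    pred = ScriptedPredictor(narrow, "A", None)
    with pytest.raises(ValueError, match="does not cover"):
        augment(pred, d2, schedule)


def test_aggregate_with_originals_counts(case_world):
    vocab, schedule, d2 = case_world
    res = run_case(case_world, t1="X", t2=None)
    merged = aggregate_with_originals(d2, res)
    assert len(merged) == len(d2) + len(res.augmented_patients)
    assert merged.label == "augmented"


# -- random comparator ------------------------------------------------------------


def test_random_augment_is_deterministic(case_world):
    _, schedule, d2 = case_world
    a = random_augment(d2, schedule, ratio=1.0, iterations=2, seed=9)
    b = random_augment(d2, schedule, ratio=1.0, iterations=2, seed=9)
    assert [p.patient_id for p in a.augmented_patients] == [
        p.patient_id for p in b.augmented_patients
    ]
    assert (a.n_injected, a.n_replaced, a.n_deleted) == (
        b.n_injected, b.n_replaced, b.n_deleted
    )


def test_random_augment_actions_are_roughly_uniform():
    patients = [make_patient(f"p{i}", [0, 50, 400]) for i in range(600)]
    d2 = Cohort(patients, "D2")
    _, schedule = build_vocab_and_schedule([d2])
    res = random_augment(d2, schedule, ratio=1.0, iterations=1, seed=4)
    n = res.n_processed_anchors
    assert n == 600
    # each action ~ Binomial(600, 1/3): 4 sigma ~ 46
    for count in (res.n_injected, res.n_replaced, res.n_deleted):
        assert abs(count - 200) < 46


def test_random_augment_types_come_from_d2(case_world):
    _, schedule, d2 = case_world
    res = random_augment(d2, schedule, ratio=1.0, iterations=4, seed=2)
    v2 = d2.cost_type_support()
    for c in res.augmented_patients:
        assert {v.cost_type for v in c.visits} <= v2


# -- M1 training ------------------------------------------------------------------


def test_train_m1_learns_a_single_type_world():
    """A one-type cohort is perfectly predictable: top-k must reach 1.0."""
    rng = np.random.Generator(np.random.PCG64(0))
    patients = []
    for i in range(40):
        days = np.cumsum(rng.integers(5, 40, size=5))
        days[0] = 0
        patients.append(make_patient(f"p{i}", days.tolist()))
    d1 = Cohort(patients, "D1")
    vocab, _ = build_vocab_and_schedule([d1])
    covariates = CovariateVocab.from_cohorts([d1])
    config = ModelConfig(
        d_model=16, n_heads=2, n_encoder_layers=1, n_decoder_layers=1,
        feedforward_width=32, dropout=0.0, max_input_len=16, max_target_len=4,
        vocab_sizes={
            "cost_type": vocab.size, "age": 121,
            "gender": covariates.n_gender,
            "specialist": covariates.n_specialist, "diff_bucket": 17,
        }, seed=3,
    )
    _, report = train_m1(d1, vocab, covariates, config,
                         TrainSettings(epochs=8, batch_size=8,
                                       learning_rate=3e-3, seed=3),
                         k_values=(1, 3))
    assert report["top_k"][1] == 1.0
    assert report["trace"]["train"][-1] < report["trace"]["train"][0]


def test_train_m1_rejects_empty_cohort(small_context):
    ctx = small_context
    with pytest.raises(ValueError, match="empty"):
        train_m1(Cohort([], "D1"), ctx["vocab"], ctx["covariates"],
                 ctx["config"])


def test_marginal_baseline_hand_case():
    d = Cohort(
        [make_patient("p", [0, 10, 20], ["A", "A", "B"])], "D1"
    )
    vocab = CostTypeVocabulary(["A", "B"])
    truths = [np.array([vocab.index("A"), vocab.index("B")])]
    acc = marginal_topk_accuracy(d, truths, vocab, (1,))
    assert acc[1] == pytest.approx(0.5)  # marginal mode is A
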