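"""Cohort construction, windowing and tokenization contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from osacost.records import (
    Cohort,
    CostTypeVocabulary,
    CovariateVocab,
    InputTargetSplit,
    PatientHistory,
    VisitRecord,
    assign_cohorts,
    build_vocab_and_schedule,
    cohort_to_frame,
    compute_diff_dgn,
    group_patients,
    read_cohort_csv,
    split_for_augmentation,
    split_for_prediction,
    tokenize,
    write_cohort_csv,
)

from conftest import make_patient


# -- diff_dgn ----------------------------------------------------------------


def test_compute_diff_dgn_calendar_day_offsets():
    rows = pd.DataFrame({
        "patient_id": ["p1"] * 3,
        "date": ["2010-01-01", "2010-03-12", "2013-02-14"],
        "age": [50, 50, 53],
        "gender": ["F"] * 3,
        "specialist_type": ["S0"] * 3,
        "cost_type": ["A"] * 3,
        "cost_eur": [10.0] * 3,
    })
    recs = compute_diff_dgn(rows, {"p1": "2010-01-01"})
    assert [r.diff_dgn for r in recs] == [0, 70, 1140]


def test_compute_diff_dgn_simple_offsets():
    rows = pd.DataFrame({
        "patient_id": ["p1", "p1"],
        "date": ["2010-01-01", "2010-01-31"],
        "age": [50, 50], "gender": ["F", "F"],
        "specialist_type": ["S0", "S0"], "cost_type": ["A", "A"],
        "cost_eur": [1.0, 1.0],
    })
    recs = compute_diff_dgn(rows, {"p1": "2010-01-01"})
    assert [r.diff_dgn for r in recs] == [0, 30]


def test_compute_diff_dgn_rejects_visit_before_diagnosis(caplog):
    rows = pd.DataFrame({
        "patient_id": ["p1", "p1"],
        "date": ["2009-12-31", "2010-01-05"],
        "age": [50, 50], "gender": ["F", "F"],
        "specialist_type": ["S0", "S0"], "cost_type": ["A", "A"],
        "cost_eur": [1.0, 1.0],
    })
    with caplog.at_level("WARNING"):
        recs = compute_diff_dgn(rows, {"p1": "2010-01-01"})
    assert len(recs) == 1 and recs[0].diff_dgn == 4
    assert "before diagnosis" in caplog.text


def test_compute_diff_dgn_unknown_patient_errors():
    rows = pd.DataFrame({
        "patient_id": ["ghost"], "date": ["2010-01-01"], "age": [1],
        "gender": ["F"], "specialist_type": ["S0"], "cost_type": ["A"],
        "cost_eur": [0.0],
    })
    with pytest.raises(KeyError, match="ghost"):
        compute_diff_dgn(rows, {})


# -- cohort assignment --------------------------------------------------------


@pytest.mark.parametrize("last_day,expected", [(364, "D1"), (365, "D2")])
def test_year_boundary_assignment(last_day, expected):
    p = make_patient("p", [0, last_day])
    d1, d2 = assign_cohorts([p])
    target = d1 if expected == "D1" else d2
    assert len(target) == 1 and len(d1) + len(d2) == 1


def test_worked_example_patient_goes_to_prediction_cohort():
    p = make_patient("p", [0, 30, 70, 248, 690, 810, 1100, 1140])
    d1, d2 = assign_cohorts([p])
    assert len(d2) == 1


@given(st.lists(st.lists(st.integers(0, 2000), min_size=1, max_size=12),
                min_size=1, max_size=25))
@settings(max_examples=50, deadline=None)
def test_cohort_partition_is_exhaustive_and_disjoint(day_lists):
    patients = [
        make_patient(f"p{i}", sorted({0, *days}))
        for i, days in enumerate(day_lists)
    ]
    d1, d2 = assign_cohorts(patients)
    assert len(d1) + len(d2) == len(patients)
    ids1 = {p.patient_id for p in d1}
    ids2 = {p.patient_id for p in d2}
    assert not ids1 & ids2


# -- augmentation split -------------------------------------------------------


@pytest.mark.parametrize("n_visits,n_inputs", [(5, 3), (3, 1)])
def test_augmentation_split_takes_last_two_as_targets(n_visits, n_inputs):
    p = make_patient("p", list(range(0, n_visits * 10, 10)))
    split = split_for_augmentation(p)
    assert len(split.input_visits) == n_inputs
    assert len(split.target_visits) == 2
    assert split.target_visits == p.visits[-2:]


def test_augmentation_split_requires_three_visits():
    with pytest.raises(ValueError, match="needs >= 3"):
        split_for_augmentation(make_patient("p", [0, 5]))


# -- prediction split ---------------------------------------------------------


def test_prediction_split_worked_example():
    p = make_patient("p", [0, 30, 70, 248, 690, 810, 1100, 1140])
    split = split_for_prediction(p)
    assert split.t_prime == 690
    assert split.t_double_prime == 810
    assert [v.diff_dgn for v in split.input_visits] == [0, 30, 70, 248, 690]
    assert [v.diff_dgn for v in split.target_visits] == [810, 1100, 1140]


@pytest.mark.parametrize("days,tp,tpp", [
    ([0, 365], 0, 365),
    ([0, 100, 400, 500], 100, 400),
])
def test_prediction_split_boundaries(days, tp, tpp):
    split = split_for_prediction(make_patient("p", days))
    assert (split.t_prime, split.t_double_prime) == (tp, tpp)


def test_prediction_split_unusable_patient_is_rejected():
    # every visit inside the final year: nothing left as input
    with pytest.raises(ValueError, match="unusable"):
        split_for_prediction(make_patient("p", [200, 300, 465]))


def test_prediction_split_matches_brute_force_scan():
    rng = np.random.Generator(np.random.PCG64(7))
    for _ in range(1000):
        n = int(rng.integers(2, 15))
        days = sorted({0, *rng.integers(1, 2500, size=n).tolist()})
        t_i = max(days)
        if t_i < 365:
            continue
        cutoff = t_i - 364
        expected_tp = max((x for x in days if x < cutoff), default=None)
        if expected_tp is None:
            with pytest.raises(ValueError):
                split_for_prediction(make_patient("p", days))
            continue
        expected_tpp = min(x for x in days if cutoff <= x <= t_i)
        split = split_for_prediction(make_patient("p", days))
        assert split.t_prime == expected_tp
        assert split.t_double_prime == expected_tpp
        # window partition: each visit in exactly one of input/target/gap
        assert split.t_prime < cutoff <= split.t_double_prime
        n_gap = sum(1 for x in days if split.t_prime < x < split.t_double_prime)
        assert len(split.input_visits) + len(split.target_visits) + n_gap == len(days)


# -- vocabulary and schedule --------------------------------------------------


def test_schedule_value_is_mean_observed_cost():
    p = make_patient("p", [0, 400], cost_types=["A", "A"], costs=[10.0, 20.0])
    _, d2 = assign_cohorts([p])
    vocab, schedule = build_vocab_and_schedule([d2])
    assert schedule.cost_of("A") == pytest.approx(15.0)


def test_vocabulary_is_union_over_cohorts():
    p1 = make_patient("p1", [0, 10, 20], cost_types=["A", "B", "A"])
    p2 = make_patient("p2", [0, 400], cost_types=["B", "C"])
    d1, d2 = assign_cohorts([p1, p2])
    vocab, _ = build_vocab_and_schedule([d1, d2])
    assert set(vocab.types) == {"A", "B", "C"}
    assert vocab.n_types == 3
    assert vocab.covers(d1) and vocab.covers(d2)


def test_vocabulary_size_follows_short_followup_cohort_when_superset():
    # 91 types in the short-follow-up cohort, 50 of them in the other
    types_d1 = [f"T{i:02d}" for i in range(91)]
    types_d2 = types_d1[:50]
    p1 = make_patient("a", list(range(0, 91 * 2, 2)), cost_types=types_d1)
    p2 = make_patient("b", list(range(0, 50 * 10, 10)), cost_types=types_d2)
    d1, d2 = assign_cohorts([p1, p2])
    vocab, _ = build_vocab_and_schedule([d1, d2])
    assert vocab.n_types == 91


def test_specials_are_distinct_and_priced_at_zero():
    vocab = CostTypeVocabulary(["A", "B"])
    assert len({vocab.cls_id, vocab.sep_id, vocab.pad_id}) == 3
    assert min(vocab.cls_id, vocab.sep_id, vocab.pad_id) >= vocab.n_types
    from osacost.records import CostSchedule
    sched = CostSchedule({"A": 5.0, "B": 7.0})
    e = sched.as_vector(vocab)
    assert e[vocab.cls_id] == e[vocab.sep_id] == e[vocab.pad_id] == 0.0


# -- tokenization -------------------------------------------------------------


@pytest.fixture
def tok_context():
    vocab = CostTypeVocabulary(["A", "B", "C"])
    cov = CovariateVocab(["F", "M"], ["S0", "S1"])
    return vocab, cov


def test_tokenize_empty_target_is_sep_then_pad(tok_context):
    vocab, cov = tok_context
    p = make_patient("p", [0, 10, 20])
    split = InputTargetSplit("p", p.visits, [], 20, -1, 3, -1)
    tok = tokenize(split, vocab, cov, max_input_len=8, max_target_len=4)
    assert tok.target_tokens[0] == vocab.sep_id
    assert (tok.target_tokens[1:] == vocab.pad_id).all()
    assert tok.target_mask.tolist() == [True, False, False, False]


def test_tokenize_padding_arithmetic(tok_context):
    vocab, cov = tok_context
    p = make_patient("p", [0, 10, 20, 30, 40], cost_types=list("ABCAB"))
    split = split_for_augmentation(p)  # 3 inputs, 2 targets
    tok = tokenize(split, vocab, cov, max_input_len=8, max_target_len=6)
    # input: CLS + 3 visits + SEP + 3 PAD
    assert tok.input_tokens["cost_type"][0] == vocab.cls_id
    assert tok.input_tokens["cost_type"][4] == vocab.sep_id
    assert (tok.input_tokens["cost_type"][5:] == vocab.pad_id).all()
    # target: 2 types + SEP + 3 PAD
    assert tok.target_tokens[2] == vocab.sep_id
    assert (tok.target_tokens[3:] == vocab.pad_id).all()
    # neutral slots for the non-cost variables at special positions
    assert tok.input_tokens["age"][0] == 0 and tok.input_tokens["age"][4] == 0


def test_tokenize_mask_counts_real_tokens(tok_context):
    vocab, cov = tok_context
    rng = np.random.Generator(np.random.PCG64(3))
    for _ in range(100):
        n_in = int(rng.integers(1, 6))
        n_tgt = int(rng.integers(0, 4))
        days = list(range(0, (n_in + n_tgt) * 10, 10))
        types = [str(rng.choice(list("ABC"))) for _ in days]
        p = make_patient("p", days, cost_types=types)
        split = InputTargetSplit("p", p.visits[:n_in], p.visits[n_in:],
                                 0, 0, n_in, n_in + 1)
        tok = tokenize(split, vocab, cov, 10, 6)
        assert tok.input_mask.sum() == n_in + 2     # CLS + visits + SEP
        assert tok.target_mask.sum() == n_tgt + 1   # types + SEP


def test_tokenize_truncates_oldest_input_visits_only(tok_context):
    vocab, cov = tok_context
    p = make_patient("p", list(range(0, 60, 10)), cost_types=list("ABCABC"))
    split = InputTargetSplit("p", p.visits[:5], p.visits[5:], 40, 50, 5, 6)
    tok = tokenize(split, vocab, cov, max_input_len=5, max_target_len=3)
    assert tok.n_truncated == 2
    # kept the three newest input visits: C, A, B
    kept = [vocab.type_of(int(i)) for i in tok.input_tokens["cost_type"][1:4]]
    assert kept == ["C", "A", "B"]
    assert tok.target_mask.sum() == 2  # target visit + SEP, untouched


# -- CSV round trip -----------------------------------------------------------


def test_cohort_csv_round_trip(tmp_path, small_cohort):
    patients, _ = small_cohort
    path = tmp_path / "visits.csv"
    write_cohort_csv(patients, path)
    back = read_cohort_csv(path)
    assert len(back.patients) == len(patients)
    for orig, re in zip(patients, back.patients):
        assert orig.patient_id == re.patient_id
        assert orig.visit_days == re.visit_days
        assert orig.cost_types == re.cost_types
        for a, b in zip(orig.visits, re.visits):
            assert a.cost_eur == pytest.approx(b.cost_eur)
            assert (a.age, a.gender, a.specialist_type) == (b.age, b.gender, b.specialist_type)
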