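import numpy as np
import pytest

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


def make_patient(pid: str, days, cost_types=None, costs=None, age=50,
                 gender="F", specialist="S0") -> PatientHistory:
    """Convenience constructor for hand-built patients."""
    days = list(days)
    cost_types = cost_types or ["A"] * len(days)
    costs = costs or [10.0] * len(days)
    visits = [
        VisitRecord(pid, d, age, gender, specialist, ct, c)
        for d, ct, c in zip(days, cost_types, costs)
    ]
    return PatientHistory(pid, visits)


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort shared by fast tests."""
    patients, truth = generate_cohort(
        SyntheticConfig(n_patients=120, short_followup_fraction=0.5,
                        n_cost_types=6, seed=11)
    )
    return patients, truth


@pytest.fixture(scope="session")
def small_context(small_cohort):
    """Cohorts, vocabularies and a tiny model config for the small cohort."""
    patients, _ = small_cohort
    d1, d2 = assign_cohorts(patients)
    vocab, schedule = build_vocab_and_schedule([d1, d2])
    covariates = CovariateVocab.from_cohorts([d1, d2])
    vocab_sizes = {
        "cost_type": vocab.size,
        "age": 121,
        "gender": covariates.n_gender,
        "specialist": covariates.n_specialist,
        "diff_bucket": 17,
    }
    config = ModelConfig(
        d_model=16, n_heads=2, n_encoder_layers=1, n_decoder_layers=1,
        feedforward_width=32, dropout=0.0, max_input_len=40,
        max_target_len=26, vocab_sizes=vocab_sizes, seed=5,
    )
    return {
        "d1": d1, "d2": d2, "vocab": vocab, "schedule": schedule,
        "covariates": covariates, "config": config,
    }
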