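"""Seeded generator of EHR-like visit cohorts.

Emulates the statistical shape the two-model pipeline assumes: per-patient
irregular visit-day sequences starting at day 0, categorical covariates, a
cost-type sequence with first-order Markov (history-dependent) structure, a
mix of short (< 365-day) and long follow-ups, and per-visit euro costs drawn
from type-specific lognormals.

Short- and long-follow-up patients share one transition kernel — the premise
that makes information learned on the short-follow-up cohort transferable to
the long-follow-up one.  First-order Markov dynamics are the minimal
structure under which a sequence model can beat a marginal-frequency
predictor, making the benefit of model-based augmentation measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import Cohort, PatientHistory, VisitRecord, YEAR_DAYS

__all__ = ["SyntheticConfig", "generate_cohort", "generate_visits_frame"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    visit_rate is the mean number of visits per 365-day year; inter-visit
    gaps are geometric with that mean.  transition_concentration is the
    Dirichlet concentration of each Markov-kernel row: small values give
    strongly history-dependent (peaked) cost-type dynamics, large values
    approach i.i.d. draws.  cost_lognormal_sigma = 0 makes every visit of a
    type cost exactly that type's nominal value.
    """

    n_patients: int = 1000
    short_followup_fraction: float = 0.7
    n_cost_types: int = 12
    n_specialists: int = 5
    visit_rate: float = 12.0
    transition_concentration: float = 0.25
    cost_mu_range: tuple[float, float] = (3.5, 5.5)
    cost_lognormal_sigma: float = 0.25
    max_followup_years: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if not 0.0 <= self.short_followup_fraction <= 1.0:
            raise ValueError("short_followup_fraction must lie in [0, 1]")
        if self.n_cost_types < 1 or self.n_specialists < 1:
            raise ValueError("counts must be positive")
        if self.visit_rate <= 0:
            raise ValueError("visit_rate must be positive")


@dataclass
class GeneratorTruth:
    """The generating parameters, kept for convergence checks in tests."""

    transition_matrix: np.ndarray
    initial_distribution: np.ndarray
    cost_type_names: list[str]
    nominal_costs: np.ndarray


def _sample_kernel(rng: np.random.Generator, cfg: SyntheticConfig) -> GeneratorTruth:
    C = cfg.n_cost_types
    if cfg.transition_concentration == 0.0:
        # fully deterministic dynamics: each type maps to exactly one
        # successor (a random permutation, so every type stays reachable)
        trans = np.zeros((C, C))
        trans[np.arange(C), rng.permutation(C)] = 1.0
    else:
        alpha = np.full(C, cfg.transition_concentration)
        trans = rng.dirichlet(alpha, size=C)
    init = rng.dirichlet(np.full(C, 1.0))
    names = [f"K{j:02d}" for j in range(C)]
    mu = rng.uniform(*cfg.cost_mu_range, size=C)
    nominal = np.exp(mu)
    return GeneratorTruth(trans, init, names, nominal)


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[list[PatientHistory], GeneratorTruth]:
    """Generate a seeded synthetic cohort of patient histories.

    Each patient: first visit at day 0; subsequent inter-visit gaps are
    geometric with mean 365/visit_rate days; follow-up duration uniform on
    [30, 364] for the short fraction and [365, 365*max_followup_years] for
    the rest; cost types follow the patient-shared Markov kernel; age,
    gender and specialist are sampled per patient, with the specialist
    loosely tied to the patient's initial cost type.
    """
    rng = np.random.Generator(np.random.PCG64(config.seed))
    truth = _sample_kernel(rng, config)
    C = config.n_cost_types
    mean_gap = YEAR_DAYS / config.visit_rate
    p_gap = min(1.0, 1.0 / mean_gap)

    patients: list[PatientHistory] = []
    for i in range(config.n_patients):
        short = rng.random() < config.short_followup_fraction
        if short:
            horizon = int(rng.integers(30, YEAR_DAYS))  # < 365
        else:
            hi = int(YEAR_DAYS * config.max_followup_years)
            horizon = int(rng.integers(YEAR_DAYS, hi + 1))

        age0 = int(rng.integers(25, 80))
        gender = "F" if rng.random() < 0.4 else "M"

        day = 0
        state = int(rng.choice(C, p=truth.initial_distribution))
        specialist = f"S{(state + int(rng.integers(0, 2))) % config.n_specialists}"
        visits: list[VisitRecord] = []
        while day <= horizon:
            sigma = config.cost_lognormal_sigma
            nominal = truth.nominal_costs[state]
            cost = float(nominal * np.exp(sigma * rng.standard_normal())) if sigma > 0 else float(nominal)
            visits.append(
                VisitRecord(
                    patient_id=f"P{i:06d}",
                    diff_dgn=day,
                    age=age0 + day // YEAR_DAYS,
                    gender=gender,
                    specialist_type=specialist,
                    cost_type=truth.cost_type_names[state],
                    cost_eur=cost,
                )
            )
            day += 1 + int(rng.geometric(p_gap))
            state = int(rng.choice(C, p=truth.transition_matrix[state]))
        # guarantee the long-follow-up patients really cross the year mark
        if not short and visits[-1].diff_dgn < YEAR_DAYS:
            visits.append(
                VisitRecord(
                    patient_id=f"P{i:06d}",
                    diff_dgn=horizon,
                    age=age0 + horizon // YEAR_DAYS,
                    gender=gender,
                    specialist_type=specialist,
                    cost_type=truth.cost_type_names[state],
                    cost_eur=float(truth.nominal_costs[state]),
                )
            )
        patients.append(PatientHistory(f"P{i:06d}", visits))
    return patients, truth


def generate_visits_frame(config: SyntheticConfig):
    """Generate a cohort and return it as the canonical visits DataFrame."""
    from .records import cohort_to_frame

    patients, _ = generate_cohort(config)
    return cohort_to_frame(patients)
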