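"""Patient visit-sequence data model, cohort construction and tokenization.

The time axis of every patient's record is ``diff_dgn`` — whole days elapsed
since the patient's first diagnosis of the index disease (obstructive sleep
apnea, trigger code G47.3 by default).  Patients whose total follow-up is
shorter than one year form the auxiliary cohort ``D1`` used to train the
augmentation model; patients with at least a year of follow-up form ``D2``,
the cohort on which next-year visit costs are predicted.

A 365-day year is used for the follow-up windows throughout; ``diff_dgn``
itself is plain calendar-day subtraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from datetime import date, datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

YEAR_DAYS = 365

CLS_TOKEN = "[CLS]"
SEP_TOKEN = "[SEP]"
PAD_TOKEN = "[PAD]"

CSV_COLUMNS = [
    "patient_id",
    "diff_dgn",
    "age",
    "gender",
    "specialist_type",
    "cost_type",
    "cost_eur",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VisitRecord:
    """One visit of one patient.

    ``diff_dgn`` is days since the first diagnosis (>= 0; the first visit of
    every patient is at day 0).  ``cost_eur`` is the euro amount billed for
    this particular visit; the per-type schedule value is derived from these.
    """

    patient_id: str
    diff_dgn: int
    age: int
    gender: str
    specialist_type: str
    cost_type: str
    cost_eur: float = 0.0

    def __post_init__(self):
        if self.diff_dgn < 0:
            raise ValueError(
                f"diff_dgn must be >= 0, got {self.diff_dgn} "
                f"for patient {self.patient_id}"
            )


@dataclass
class PatientHistory:
    """A patient's visits in ascending ``diff_dgn`` order.

    Ties in diff_dgn keep stable input order; the visit index k (1-based)
    stays unique regardless.
    """

    patient_id: str
    visits: list[VisitRecord]

    def __post_init__(self):
        if not self.visits:
            raise ValueError(f"patient {self.patient_id} has no visits")
        self.visits = sorted(
            self.visits, key=lambda v: v.diff_dgn
        )  # stable: ties keep input order

    @property
    def s_i(self) -> int:
        """Number of visits."""
        return len(self.visits)

    @property
    def t_i(self) -> int:
        """Follow-up duration: diff_dgn of the last visit."""
        return self.visits[-1].diff_dgn

    @property
    def visit_days(self) -> list[int]:
        """The set T_i of diff_dgn values, in order (duplicates preserved)."""
        return [v.diff_dgn for v in self.visits]

    @property
    def cost_types(self) -> list[str]:
        return [v.cost_type for v in self.visits]


@dataclass
class Cohort:
    """A labelled collection of patient histories.

    label ``D1``: every patient has follow-up < 365 days;
    label ``D2``: every patient has follow-up >= 365 days;
    label ``augmented``: mixed provenance (originals plus modified copies).
    """

    patients: list[PatientHistory]
    label: str = "unlabelled"

    def __post_init__(self):
        if self.label == "D1" and any(p.t_i >= YEAR_DAYS for p in self.patients):
            raise ValueError("D1 cohort contains a patient with >= 365 days follow-up")
        if self.label == "D2" and any(p.t_i < YEAR_DAYS for p in self.patients):
            raise ValueError("D2 cohort contains a patient with < 365 days follow-up")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def cost_type_support(self) -> set[str]:
        """The set of cost types occurring anywhere in the cohort (V² for D2)."""
        return {v.cost_type for p in self.patients for v in p.visits}


@dataclass
class InputTargetSplit:
    """A patient's visits partitioned into a model-input window and targets.

    For the prediction task the boundary is the final-year cutoff
    t_i - 364: ``t_prime`` is the last visit day strictly before the cutoff
    and ``t_double_prime`` the first visit day at or after it.  Visits with
    diff_dgn strictly between the two belong to neither window (cannot occur
    for the prediction split, by construction).
    """

    patient_id: str
    input_visits: list[VisitRecord]
    target_visits: list[VisitRecord]
    t_prime: int
    t_double_prime: int
    s_prime: int
    s_double_prime: int


class CostTypeVocabulary:
    """Cost-type <-> integer index mapping with CLS/SEP/PAD specials.

    Indices 0..C-1 are the C cost types (sorted for reproducibility);
    the three specials follow at C, C+1, C+2.
    """

    def __init__(self, types: Sequence[str]):
        self.types = list(dict.fromkeys(types))
        self._index = {t: i for i, t in enumerate(self.types)}
        c = len(self.types)
        self.cls_id = c
        self.sep_id = c + 1
        self.pad_id = c + 2

    @property
    def n_types(self) -> int:
        """C — the number of real cost types."""
        return len(self.types)

    @property
    def size(self) -> int:
        """Total vocabulary size including specials."""
        return len(self.types) + 3

    def index(self, cost_type: str) -> int:
        try:
            return self._index[cost_type]
        except KeyError:
            raise KeyError(f"cost type {cost_type!r} not in vocabulary") from None

    def type_of(self, idx: int) -> str:
        if 0 <= idx < len(self.types):
            return self.types[idx]
        return {self.cls_id: CLS_TOKEN, self.sep_id: SEP_TOKEN, self.pad_id: PAD_TOKEN}[idx]

    def __contains__(self, cost_type: str) -> bool:
        return cost_type in self._index

    def covers(self, cohort: Cohort) -> bool:
        return cohort.cost_type_support() <= set(self.types)

    def to_json(self) -> str:
        return json.dumps({"types": self.types}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CostTypeVocabulary":
        return cls(json.loads(text)["types"])


class CostSchedule:
    """Per-cost-type euro value e_c.  Specials map to 0."""

    def __init__(self, values: Mapping[str, float]):
        for t, v in values.items():
            if v < 0:
                raise ValueError(f"negative cost for type {t!r}")
        self.values = dict(values)

    def cost_of(self, cost_type: str) -> float:
        if cost_type in (CLS_TOKEN, SEP_TOKEN, PAD_TOKEN):
            return 0.0
        return self.values[cost_type]

    def as_vector(self, vocab: CostTypeVocabulary) -> np.ndarray:
        """e as a vector over the full vocabulary (specials -> 0)."""
        e = np.zeros(vocab.size)
        for i, t in enumerate(vocab.types):
            e[i] = self.values.get(t, 0.0)
        return e

    def to_json(self) -> str:
        return json.dumps({"values": self.values}, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CostSchedule":
        return cls(json.loads(text)["values"])


@dataclass
class TokenizedSequences:
    """Padded index sequences for one split, plus validity masks.

    Input streams carry one index array per variable.  The non-cost variables
    use index 0 as a neutral slot at CLS/SEP/PAD positions (their real values
    are shifted up by one).  The target stream is cost-type indices followed
    by SEP then PAD.
    """

    input_tokens: dict[str, np.ndarray]
    input_mask: np.ndarray
    target_tokens: np.ndarray
    target_mask: np.ndarray
    n_truncated: int = 0


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _parse_date(value) -> date:
    if isinstance(value, date):
        return value
    return datetime.strptime(str(value), "%Y-%m-%d").date()


def compute_diff_dgn(
    raw_records: pd.DataFrame,
    diagnosis_dates: Mapping[str, date | str],
) -> list[VisitRecord]:
    """Convert dated visit rows into day-offset visit records.

    ``raw_records`` needs columns patient_id, date, age, gender,
    specialist_type, cost_type and optionally cost_eur.  Visits dated before
    the patient's diagnosis are rejected with a logged diagnostic; a patient
    with no diagnosis date is an error.
    """
    records: list[VisitRecord] = []
    for row in raw_records.itertuples(index=False):
        pid = str(row.patient_id)
        if pid not in diagnosis_dates:
            raise KeyError(f"no diagnosis date for patient {pid}")
        dgn = _parse_date(diagnosis_dates[pid])
        visit_day = _parse_date(row.date)
        offset = (visit_day - dgn).days
        if offset < 0:
            logger.warning(
                "rejected visit on %s before diagnosis %s for patient %s",
                visit_day, dgn, pid,
            )
            continue
        records.append(
            VisitRecord(
                patient_id=pid,
                diff_dgn=offset,
                age=int(row.age),
                gender=str(row.gender),
                specialist_type=str(row.specialist_type),
                cost_type=str(row.cost_type),
                cost_eur=float(getattr(row, "cost_eur", 0.0)),
            )
        )
    records.sort(key=lambda r: (r.patient_id, r.diff_dgn))
    return records


def group_patients(records: Iterable[VisitRecord]) -> list[PatientHistory]:
    """Group visit records into per-patient histories (sorted by id)."""
    by_patient: dict[str, list[VisitRecord]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, []).append(r)
    return [PatientHistory(pid, visits) for pid, visits in sorted(by_patient.items())]


def assign_cohorts(patients: Sequence[PatientHistory]) -> tuple[Cohort, Cohort]:
    """Partition patients into D1 (t_i < 365) and D2 (t_i >= 365).

    A follow-up of exactly 365 days goes to D2, keeping its one-year target
    window non-degenerate.
    """
    if not patients:
        raise ValueError("assign_cohorts requires at least one patient")
    d1 = [p for p in patients if p.t_i < YEAR_DAYS]
    d2 = [p for p in patients if p.t_i >= YEAR_DAYS]
    return Cohort(d1, "D1"), Cohort(d2, "D2")


def split_for_augmentation(patient: PatientHistory) -> InputTargetSplit:
    """Split a short-follow-up patient into history input and last-two-visit
    targets for training the augmentation model.

    Requires s_i >= 3 so that the input window is non-empty.
    """
    if patient.s_i < 3:
        raise ValueError(
            f"patient {patient.patient_id} has {patient.s_i} visits; "
            "needs >= 3 for the augmentation split"
        )
    inputs = patient.visits[:-2]
    targets = patient.visits[-2:]
    return InputTargetSplit(
        patient_id=patient.patient_id,
        input_visits=inputs,
        target_visits=targets,
        t_prime=inputs[-1].diff_dgn,
        t_double_prime=targets[0].diff_dgn,
        s_prime=len(inputs),
        s_double_prime=len(inputs) + 1,
    )


def split_for_prediction(patient: PatientHistory) -> InputTargetSplit:
    """Split a long-follow-up patient around the final-year boundary.

    t' = max{x in T_i : 0 <= x < t_i - 364} is the last input day and
    t'' = min{x in T_i : t_i - 364 <= x <= t_i} the first target day.
    Patients with no visit before the cutoff are unusable for prediction.
    """
    t_i = patient.t_i
    cutoff = t_i - (YEAR_DAYS - 1)
    days = patient.visit_days
    input_days = [x for x in days if 0 <= x < cutoff]
    if not input_days:
        raise ValueError(
            f"patient {patient.patient_id} has no visit before day {cutoff}; "
            "unusable for next-year prediction"
        )
    t_prime = max(input_days)
    t_double_prime = min(x for x in days if cutoff <= x <= t_i)
    input_visits = [v for v in patient.visits if v.diff_dgn <= t_prime]
    target_visits = [v for v in patient.visits if v.diff_dgn >= t_double_prime]
    return InputTargetSplit(
        patient_id=patient.patient_id,
        input_visits=input_visits,
        target_visits=target_visits,
        t_prime=t_prime,
        t_double_prime=t_double_prime,
        s_prime=len(input_visits),
        s_double_prime=patient.s_i - len(target_visits) + 1,
    )


def build_vocab_and_schedule(
    cohorts: Sequence[Cohort],
) -> tuple[CostTypeVocabulary, CostSchedule]:
    """Build the cost-type vocabulary (union over cohorts) and the schedule.

    The schedule value e_c is the mean observed euro cost of type c across
    all visits in the given cohorts.  A type with no observed cost raises.
    """
    sums: dict[str, float] = {}
    counts: dict[str, int] = {}
    for cohort in cohorts:
        for p in cohort:
            for v in p.visits:
                sums[v.cost_type] = sums.get(v.cost_type, 0.0) + v.cost_eur
                counts[v.cost_type] = counts.get(v.cost_type, 0) + 1
    if not counts:
        raise ValueError("no visits found in the given cohorts")
    vocab = CostTypeVocabulary(sorted(counts))
    schedule = CostSchedule({t: sums[t] / counts[t] for t in counts})
    return vocab, schedule


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

N_AGE_TOKENS = 121          # integer years 0..119, +1 neutral slot
N_DIFF_BUCKETS = 16         # log-spaced day buckets, +1 neutral slot at 0

_DIFF_EDGES = np.unique(
    np.round(np.logspace(0, np.log10(4000), N_DIFF_BUCKETS - 2)).astype(int)
)


def diff_dgn_bucket(diff_dgn: int) -> int:
    """Log-spaced day bucket for diff_dgn; 0 is reserved as neutral."""
    return 1 + int(np.searchsorted(_DIFF_EDGES, diff_dgn, side="right"))


class CovariateVocab:
    """Index maps for gender and specialist type (0 = neutral slot)."""

    def __init__(self, genders: Sequence[str], specialists: Sequence[str]):
        self.genders = sorted(dict.fromkeys(genders))
        self.specialists = sorted(dict.fromkeys(specialists))
        self._g = {g: i + 1 for i, g in enumerate(self.genders)}
        self._s = {s: i + 1 for i, s in enumerate(self.specialists)}

    @property
    def n_gender(self) -> int:
        return len(self.genders) + 1

    @property
    def n_specialist(self) -> int:
        return len(self.specialists) + 1

    def gender_index(self, g: str) -> int:
        return self._g[g]

    def specialist_index(self, s: str) -> int:
        return self._s[s]

    @classmethod
    def from_cohorts(cls, cohorts: Sequence[Cohort]) -> "CovariateVocab":
        genders, specialists = [], []
        for cohort in cohorts:
            for p in cohort:
                for v in p.visits:
                    genders.append(v.gender)
                    specialists.append(v.specialist_type)
        return cls(genders, specialists)


def tokenize(
    split: InputTargetSplit,
    vocab: CostTypeVocabulary,
    covariates: CovariateVocab,
    max_input_len: int,
    max_target_len: int,
) -> TokenizedSequences:
    """Tokenize one input/target split into padded index sequences.

    Input layout: [CLS] visit_1 .. visit_n [SEP] [PAD]...; each visit is a
    column of per-variable indices.  If the input overflows, the *oldest*
    input visits are truncated (targets never are).  Target layout:
    cost-type indices then [SEP] then [PAD]...
    """
    n_truncated = 0
    visits = split.input_visits
    budget = max_input_len - 2  # room for CLS and SEP
    if budget < 0:
        raise ValueError("max_input_len must be >= 2")
    if len(visits) > budget:
        n_truncated = len(visits) - budget
        logger.info(
            "truncating %d oldest input visits for patient %s",
            n_truncated, split.patient_id,
        )
        visits = visits[n_truncated:]

    L = max_input_len
    cost_ids = np.full(L, vocab.pad_id, dtype=np.int64)
    age_ids = np.zeros(L, dtype=np.int64)
    gender_ids = np.zeros(L, dtype=np.int64)
    spec_ids = np.zeros(L, dtype=np.int64)
    diff_ids = np.zeros(L, dtype=np.int64)
    mask = np.zeros(L, dtype=bool)

    cost_ids[0] = vocab.cls_id
    mask[0] = True
    for j, v in enumerate(visits, start=1):
        cost_ids[j] = vocab.index(v.cost_type)
        age_ids[j] = min(v.age, N_AGE_TOKENS - 2) + 1
        gender_ids[j] = covariates.gender_index(v.gender)
        spec_ids[j] = covariates.specialist_index(v.specialist_type)
        diff_ids[j] = diff_dgn_bucket(v.diff_dgn)
        mask[j] = True
    cost_ids[len(visits) + 1] = vocab.sep_id
    mask[len(visits) + 1] = True

    if len(split.target_visits) + 1 > max_target_len:
        raise ValueError(
            f"target sequence of patient {split.patient_id} "
            f"({len(split.target_visits)} visits) exceeds max_target_len "
            f"{max_target_len}; targets are never truncated"
        )
    T = max_target_len
    tgt = np.full(T, vocab.pad_id, dtype=np.int64)
    tmask = np.zeros(T, dtype=bool)
    for j, v in enumerate(split.target_visits):
        tgt[j] = vocab.index(v.cost_type)
        tmask[j] = True
    tgt[len(split.target_visits)] = vocab.sep_id
    tmask[len(split.target_visits)] = True

    return TokenizedSequences(
        input_tokens={
            "cost_type": cost_ids,
            "age": age_ids,
            "gender": gender_ids,
            "specialist": spec_ids,
            "diff_bucket": diff_ids,
        },
        input_mask=mask,
        target_tokens=tgt,
        target_mask=tmask,
        n_truncated=n_truncated,
    )


# ---------------------------------------------------------------------------
# CSV / JSON I/O
# ---------------------------------------------------------------------------


def cohort_to_frame(patients: Iterable[PatientHistory]) -> pd.DataFrame:
    rows = [
        (v.patient_id, v.diff_dgn, v.age, v.gender, v.specialist_type,
         v.cost_type, v.cost_eur)
        for p in patients
        for v in p.visits
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def write_cohort_csv(patients: Iterable[PatientHistory], path: str | Path) -> None:
    cohort_to_frame(patients).to_csv(path, index=False, encoding="utf-8")


def read_cohort_csv(path: str | Path, label: str = "unlabelled") -> Cohort:
    df = pd.read_csv(path, encoding="utf-8", dtype={"patient_id": str})
    records = [
        VisitRecord(
            patient_id=str(r.patient_id),
            diff_dgn=int(r.diff_dgn),
            age=int(r.age),
            gender=str(r.gender),
            specialist_type=str(r.specialist_type),
            cost_type=str(r.cost_type),
            cost_eur=float(r.cost_eur),
        )
        for r in df.itertuples(index=False)
    ]
    return Cohort(group_patients(records), label)
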