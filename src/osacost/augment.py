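"""Augmentation model M1 and the sequence-augmentation algorithm.

M1 is an encoder–decoder Transformer trained on the short-follow-up cohort
D¹ to predict a patient's next one or two visit cost types from the history
so far (fixed two-visit decoding horizon, per-position cross-entropy loss).

The augmentation algorithm builds extra training material for the cost
model: it samples patients from the D² training set, anchors a visit k
inside each sampled copy's first year, asks M1 for the cost types of visits
k and k+1 given the history before k, and then perturbs the copy —

* the predicted type is unsupported in D² (outside V²)  -> delete visit k;
* the prediction matches the true type and a second prediction exists
  -> inject a new visit after k carrying the second predicted type;
* otherwise -> replace visit k's type with the highest-probability type
  that D² supports (ties to the lowest index).

Each perturbed copy differs from its source in at most a couple of visits,
so the cohort's sequence-pattern distribution is preserved while the
training set grows.  A uniformly random delete/replace/insert comparator is
provided for ablation.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .autodiff import Adam
from .encoding import EncodedDataset, encode_splits
from .metrics import top_k_accuracy
from .records import (
    Cohort,
    CostSchedule,
    CostTypeVocabulary,
    CovariateVocab,
    InputTargetSplit,
    PatientHistory,
    VisitRecord,
    YEAR_DAYS,
    split_for_augmentation,
    tokenize,
)
from .costmodel import TrainSettings, loss_l2
from .transformer import ModelConfig, SeqTransformer, iterate_minibatches

logger = logging.getLogger(__name__)


@dataclass
class AugmentationResult:
    """Modified patient copies plus bookkeeping counters."""

    augmented_patients: list[PatientHistory]
    n_injected: int = 0
    n_replaced: int = 0
    n_deleted: int = 0
    n_unchanged: int = 0
    n_skipped_unusable: int = 0
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def n_processed_anchors(self) -> int:
        return self.n_injected + self.n_replaced + self.n_deleted + self.n_unchanged


# ---------------------------------------------------------------------------
# M1 training
# ---------------------------------------------------------------------------


def encode_for_augmentation(
    cohort: Cohort,
    vocab: CostTypeVocabulary,
    covariates: CovariateVocab,
    max_input_len: int,
    max_target_len: int = 4,
) -> EncodedDataset:
    """History-input / last-two-visit-target encoding of a D1-style cohort.

    Patients with fewer than three visits cannot contribute a non-empty
    input window and are excluded (logged).
    """
    splits = []
    for p in cohort:
        try:
            splits.append(split_for_augmentation(p))
        except ValueError as exc:
            logger.info("excluded from M1 training: %s", exc)
    return encode_splits(splits, vocab, covariates, max_input_len, max_target_len)


def train_m1(
    d1: Cohort,
    vocab: CostTypeVocabulary,
    covariates: CovariateVocab,
    config: ModelConfig,
    settings: TrainSettings | None = None,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    k_values: tuple[int, ...] = (3, 5, 10),
) -> tuple[SeqTransformer, dict]:
    """Train M1 on the short-follow-up cohort with cross-entropy over the
    two target visits (plus terminal SEP) and report held-out top-k accuracy.
    """
    if len(d1) == 0:
        raise ValueError("empty D1 cohort")
    settings = settings or TrainSettings()
    data = encode_for_augmentation(d1, vocab, covariates, config.max_input_len,
                                   config.max_target_len)
    rng = np.random.Generator(np.random.PCG64(settings.seed))
    n = len(data)
    order = rng.permutation(n)
    n_train = int(round(split_fractions[0] * n))
    n_val = int(round(split_fractions[1] * n))
    train = data.subset(order[:n_train])
    val = data.subset(order[n_train:n_train + n_val])
    test = data.subset(order[n_train + n_val:])
    if len(train) == 0 or len(val) == 0 or len(test) == 0:
        raise ValueError("D1 too small for a train/val/test split")

    model = SeqTransformer(config)
    model.reseed_dropout(settings.seed + 201)
    opt = Adam(model.parameters(), lr=settings.learning_rate)
    best_val = np.inf
    best_state = {k: v.data.copy() for k, v in model.params.items()}
    since_best = 0
    trace = {"train": [], "val": []}

    def ce_on(subset: EncodedDataset, idx: np.ndarray):
        tokens = {k: v[idx] for k, v in subset.input_tokens.items()}
        logits = model.forward(tokens, subset.input_mask[idx],
                               subset.target_ids[idx], subset.target_mask[idx],
                               vocab.cls_id)
        # fixed two-visit horizon: only the visit positions are supervised
        return logits, loss_l2(logits, subset.target_ids[idx],
                               subset.visit_mask[idx])

    for epoch in range(settings.epochs):
        model.train()
        losses = []
        for idx in iterate_minibatches(len(train), settings.batch_size, rng):
            opt.zero_grad()
            _, loss = ce_on(train, idx)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        model.eval()
        _, vloss = ce_on(val, np.arange(len(val)))
        trace["train"].append(float(np.mean(losses)))
        trace["val"].append(float(vloss.data))
        if float(vloss.data) < best_val:
            best_val = float(vloss.data)
            best_state = {k: v.data.copy() for k, v in model.params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= settings.patience:
                break
    for k, v in model.params.items():
        v.data = best_state[k]
    model.eval()

    # held-out top-k over the true target slots
    logits, _ = ce_on(test, np.arange(len(test)))
    probs = logits.softmax(axis=-1).data
    rows = [probs[i][test.visit_mask[i]] for i in range(len(test))]
    true_types = [test.target_ids[i][test.visit_mask[i]] for i in range(len(test))]
    report = {
        "top_k": top_k_accuracy(rows, true_types, k_values),
        "n_test_patients": len(test),
        "trace": trace,
    }
    return model, report


def marginal_topk_accuracy(
    train_cohort: Cohort,
    true_types: list[np.ndarray],
    vocab: CostTypeVocabulary,
    k_values: tuple[int, ...] = (1,),
) -> dict[int, float]:
    """Baseline that ranks cost types by their marginal training frequency,
    ignoring each patient's history."""
    freq = np.zeros(vocab.size)
    for p in train_cohort:
        for v in p.visits:
            freq[vocab.index(v.cost_type)] += 1
    rows = [np.tile(freq, (len(t), 1)) for t in true_types]
    return top_k_accuracy(rows, true_types, k_values)


# ---------------------------------------------------------------------------
# M1 as a next-visit predictor
# ---------------------------------------------------------------------------


class M1Predictor:
    """Batched next-one-or-two-visit prediction from partial histories."""

    def __init__(self, model: SeqTransformer, vocab: CostTypeVocabulary,
                 covariates: CovariateVocab):
        self.model = model
        self.vocab = vocab
        self.covariates = covariates

    def predict_batch(
        self, histories: list[list[VisitRecord]]
    ) -> list[tuple[str | None, str | None, np.ndarray]]:
        """For each history (visits strictly before the anchored visit),
        return (predicted type of the next visit or None, predicted type of
        the visit after or None, first-step probability row over the
        vocabulary)."""
        vocab = self.vocab
        splits = [
            InputTargetSplit(
                patient_id=h[0].patient_id, input_visits=list(h),
                target_visits=[], t_prime=h[-1].diff_dgn, t_double_prime=-1,
                s_prime=len(h), s_double_prime=-1,
            )
            for h in histories
        ]
        toks = [
            tokenize(s, vocab, self.covariates,
                     self.model.config.max_input_len, 2)
            for s in splits
        ]
        input_tokens = {
            k: np.stack([t.input_tokens[k] for t in toks])
            for k in toks[0].input_tokens
        }
        input_mask = np.stack([t.input_mask for t in toks])
        emitted, prob_rows = self.model.greedy_decode(
            input_tokens, input_mask, vocab.cls_id, vocab.sep_id,
            vocab.pad_id, max_steps=2,
        )
        out = []
        for e, rows in zip(emitted, prob_rows):
            t1 = vocab.type_of(e[0]) if len(e) >= 1 else None
            t2 = vocab.type_of(e[1]) if len(e) >= 2 else None
            out.append((t1, t2, rows[0]))
        return out


# ---------------------------------------------------------------------------
# Sampling and Algorithm mechanics
# ---------------------------------------------------------------------------


def sample_patients(
    d2_train: Cohort, ratio: float, rng: np.random.Generator
) -> list[PatientHistory]:
    """Uniform sample without replacement of floor(ratio × N) deep copies."""
    if not 0.0 < ratio <= 1.0:
        raise ValueError("sample ratio must lie in (0, 1]")
    n = int(np.floor(ratio * len(d2_train)))
    idx = rng.choice(len(d2_train), size=n, replace=False)
    idx.sort()
    return [copy.deepcopy(d2_train.patients[i]) for i in idx]


def _anchor_candidates(patient: PatientHistory) -> list[int]:
    """1-based visit indices k usable as anchors: a non-empty history before
    k and an anchored visit inside the first follow-up year."""
    return [
        k for k in range(2, patient.s_i + 1)
        if patient.visits[k - 1].diff_dgn < YEAR_DAYS
    ]


def _renamed(patient: PatientHistory, new_id: str) -> PatientHistory:
    return PatientHistory(
        new_id, [dc_replace(v, patient_id=new_id) for v in patient.visits]
    )


def augment(
    predictor: M1Predictor,
    d2_train: Cohort,
    schedule: CostSchedule,
    ratio: float = 0.55,
    iterations: int = 3,
    seed: int = 0,
    anchors_per_patient: int = 1,
) -> AugmentationResult:
    """Run the model-based augmentation over ``iterations`` independent
    samples of the D² training cohort and return the modified copies.

    The source cohort is never mutated.  Every cost type written into a copy
    is restricted to V², the cost-type support of ``d2_train``.
    """
    v2 = d2_train.cost_type_support()
    if not v2 <= set(predictor.vocab.types):
        missing = sorted(v2 - set(predictor.vocab.types))
        raise ValueError(f"M1 vocabulary does not cover D² cost types: {missing}")
    v2_indices = sorted(predictor.vocab.index(t) for t in v2)

    rng = np.random.Generator(np.random.PCG64(seed))
    result = AugmentationResult(augmented_patients=[])
    for it in range(iterations):
        sampled = sample_patients(d2_train, ratio, rng)
        copies: list[PatientHistory] = []
        anchor_jobs: list[tuple[int, int]] = []  # (copy index, anchor k)
        for p in sampled:
            new_id = f"{p.patient_id}-aug{it}"
            c = _renamed(p, new_id)
            result.provenance[new_id] = p.patient_id
            copies.append(c)
            cands = _anchor_candidates(c)
            if not cands:
                result.n_skipped_unusable += 1
                continue
            n_pick = min(anchors_per_patient, len(cands))
            picks = rng.choice(len(cands), size=n_pick, replace=False)
            # apply anchors in descending k so indices stay valid after edits
            for j in sorted(picks, reverse=True):
                anchor_jobs.append((len(copies) - 1, cands[j]))

        if anchor_jobs:
            histories = [copies[ci].visits[:k - 1] for ci, k in anchor_jobs]
            predictions = predictor.predict_batch(histories)
            for (ci, k), (t1, t2, probs) in zip(anchor_jobs, predictions):
                _apply_case(copies[ci], k, t1, t2, probs, v2, v2_indices,
                            predictor.vocab, schedule, result)

        result.augmented_patients.extend(c for c in copies if c.visits)
    return result


def _apply_case(patient, k, t1, t2, probs, v2, v2_indices, vocab,
                schedule, result) -> None:
    """Apply the delete / inject / replace decision at anchor k (1-based)."""
    true_type = patient.visits[k - 1].cost_type
    if t1 is None or t1 not in v2:
        del patient.visits[k - 1]
        result.n_deleted += 1
        return
    if t1 == true_type:
        # inject only a D²-supported second prediction, so every cost type
        # in the augmented cohort stays inside V²
        if t2 is not None and t2 in v2:
            anchor = patient.visits[k - 1]
            injected = dc_replace(
                anchor,
                diff_dgn=anchor.diff_dgn + 1,
                cost_type=t2,
                cost_eur=schedule.cost_of(t2),
            )
            patient.visits.insert(k, injected)
            result.n_injected += 1
        else:
            result.n_unchanged += 1
        return
    # replacement: highest-probability type supported in D² (ties -> lowest index)
    sub = probs[v2_indices]
    best = v2_indices[int(np.argmax(sub))]
    new_type = vocab.type_of(best)
    patient.visits[k - 1] = dc_replace(
        patient.visits[k - 1], cost_type=new_type,
        cost_eur=schedule.cost_of(new_type),
    )
    result.n_replaced += 1


def random_augment(
    d2_train: Cohort,
    schedule: CostSchedule,
    ratio: float = 0.55,
    iterations: int = 3,
    seed: int = 0,
    anchors_per_patient: int = 1,
) -> AugmentationResult:
    """Comparator: same sampling and copy mechanics, but each anchored visit
    undergoes an action chosen uniformly from {delete, replace, insert}, with
    replacement/insertion types drawn from the empirical D² cost-type
    distribution."""
    types, counts = np.unique(
        [v.cost_type for p in d2_train for v in p.visits], return_counts=True
    )
    p_types = counts / counts.sum()
    rng = np.random.Generator(np.random.PCG64(seed))
    result = AugmentationResult(augmented_patients=[])
    for it in range(iterations):
        sampled = sample_patients(d2_train, ratio, rng)
        for p in sampled:
            new_id = f"{p.patient_id}-rnd{it}"
            c = _renamed(p, new_id)
            result.provenance[new_id] = p.patient_id
            cands = _anchor_candidates(c)
            if not cands:
                result.n_skipped_unusable += 1
                result.augmented_patients.append(c)
                continue
            n_pick = min(anchors_per_patient, len(cands))
            picks = rng.choice(len(cands), size=n_pick, replace=False)
            for j in sorted(picks, reverse=True):
                k = cands[j]
                action = rng.integers(0, 3)
                if action == 0:
                    del c.visits[k - 1]
                    result.n_deleted += 1
                elif action == 1:
                    t = str(rng.choice(types, p=p_types))
                    c.visits[k - 1] = dc_replace(
                        c.visits[k - 1], cost_type=t, cost_eur=schedule.cost_of(t)
                    )
                    result.n_replaced += 1
                else:
                    t = str(rng.choice(types, p=p_types))
                    anchor = c.visits[k - 1]
                    c.visits.insert(k, dc_replace(
                        anchor, diff_dgn=anchor.diff_dgn + 1,
                        cost_type=t, cost_eur=schedule.cost_of(t),
                    ))
                    result.n_injected += 1
            if c.visits:
                result.augmented_patients.append(c)
    return result


def aggregate_with_originals(
    d2_train: Cohort, result: AugmentationResult
) -> Cohort:
    """Final M2 training cohort: the original training patients plus every
    surviving modified copy."""
    return Cohort(
        list(d2_train.patients) + list(result.augmented_patients), "augmented"
    )
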