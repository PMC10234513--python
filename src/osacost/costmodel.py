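"""Cost-prediction model M2: multi-task loss, training and annual-cost output.

M2 is an encoder–decoder Transformer over a long-follow-up patient's history
window (everything up to t', one year before the end of follow-up).  Its
decoder emits a cost-type distribution for every visit of the final year.
Training minimises

    L = log10(L1) + L2

where L1 is the batch-mean squared error between each patient's annual true
cost and the annual expected cost  Σ_k Σ_c p̂_ikc · e_c  implied by the
predicted distributions and the per-type cost schedule, and L2 is the mean
per-visit cross-entropy of the predicted cost types.  The common logarithm
scales L1 (squared euros, typically orders of magnitude above L2) onto a
comparable footing.  Because L1 in euros² can legitimately fall below 1 on
small synthetic cohorts, it is clamped at 1e-12 inside the log.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .encoding import EncodedDataset, encode_splits
from .metrics import EvalReport, r_squared, rmse, top_k_accuracy
from .records import (
    Cohort,
    CostSchedule,
    CostTypeVocabulary,
    CovariateVocab,
    split_for_prediction,
)
from .transformer import ModelConfig, SeqTransformer, iterate_minibatches

logger = logging.getLogger(__name__)

LOG10_CLAMP = 1e-12
_LN10 = float(np.log(10.0))


@dataclass
class LossBreakdown:
    """The three components of one minibatch loss evaluation."""

    l1: float
    l2: float
    combined: float

    def __post_init__(self):
        if self.l1 < 0 or self.l2 < 0:
            raise ValueError("loss components must be non-negative")


@dataclass
class TrainSettings:
    """Optimisation settings; batch size 64 and learning rate 1e-4 are the
    study defaults."""

    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 1e-4
    patience: int = 10
    seed: int = 0


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------


def loss_l1(
    probs: Tensor,
    visit_costs: np.ndarray,
    visit_mask: np.ndarray,
    cost_vector: np.ndarray,
) -> Tensor:
    """Annual-cost regression loss.

    ``probs``: (N, T, V) predicted cost-type probabilities at the
    teacher-forced target slots.  ``visit_costs``: (N, T) actual euro cost of
    each true visit (0 at non-visit slots).  ``visit_mask``: (N, T) True at
    the K_i true visit slots.  ``cost_vector``: e over the vocabulary.

    Per patient the inner sum  Σ_k Σ_c (p̂_ikc e_c − c_ikc)  telescopes to
    (annual expected cost − annual true cost); the loss is the batch mean of
    its square.
    """
    if probs.shape[:2] != np.asarray(visit_costs).shape:
        raise ValueError("probability rows and cost rows are misaligned")
    mask = np.asarray(visit_mask, dtype=float)
    e = Tensor(np.asarray(cost_vector, dtype=float))
    expected = (probs * e).sum(axis=-1)                               # (N, T)
    per_visit_err = (expected - Tensor(visit_costs)) * Tensor(mask)
    annual_err = per_visit_err.sum(axis=1)                            # (N,)
    return (annual_err * annual_err).mean()


def loss_l2(logits: Tensor, true_types: np.ndarray, mask: np.ndarray) -> Tensor:
    """Per-visit classification loss.

    Mean (over patients) of the per-patient mean (over its masked target
    positions) softmax cross-entropy between logits and the true type.
    """
    true_types = np.asarray(true_types)
    if logits.shape[:2] != true_types.shape:
        raise ValueError("logits and targets are misaligned")
    mask = np.asarray(mask, dtype=float)
    counts = mask.sum(axis=1)
    if (counts == 0).any():
        raise ValueError("every patient needs at least one unmasked target")
    logp = logits.log_softmax(axis=-1)
    picked = logp.take_along_last(true_types)          # (N, T)
    per_patient = (picked * Tensor(mask)).sum(axis=1) * Tensor(1.0 / counts)
    return -per_patient.mean()


def combine_loss(l1: Tensor | float, l2: Tensor | float) -> Tensor:
    """Total loss log10(L1) + L2 with L1 clamped at 1e-12."""
    l1 = l1 if isinstance(l1, Tensor) else Tensor(float(l1))
    l2 = l2 if isinstance(l2, Tensor) else Tensor(float(l2))
    clamped = l1.masked_fill(l1.data < LOG10_CLAMP, LOG10_CLAMP)
    return clamped.log() * (1.0 / _LN10) + l2


# ---------------------------------------------------------------------------
# Dataset preparation
# ---------------------------------------------------------------------------


def encode_for_prediction(
    cohort: Cohort,
    vocab: CostTypeVocabulary,
    covariates: CovariateVocab,
    max_input_len: int,
    max_target_len: int,
) -> EncodedDataset:
    """Window every usable patient around the final-year boundary and encode.

    Patients without a visit before t_i − 364 are dropped with a log line.
    """
    splits = []
    for p in cohort:
        try:
            splits.append(split_for_prediction(p))
        except ValueError as exc:
            logger.info("dropping patient: %s", exc)
    return encode_splits(splits, vocab, covariates, max_input_len, max_target_len)


def _batch_loss(
    model: SeqTransformer,
    data: EncodedDataset,
    idx: np.ndarray,
    cost_vector: np.ndarray,
    cls_id: int,
) -> tuple[Tensor, LossBreakdown]:
    tokens = {k: v[idx] for k, v in data.input_tokens.items()}
    logits = model.forward(tokens, data.input_mask[idx],
                           data.target_ids[idx], data.target_mask[idx], cls_id)
    probs = logits.softmax(axis=-1)
    l1 = loss_l1(probs, data.visit_costs[idx], data.visit_mask[idx], cost_vector)
    # the cross-entropy part supervises the visit types and the terminal SEP
    l2 = loss_l2(logits, data.target_ids[idx], data.target_mask[idx])
    total = combine_loss(l1, l2)
    return total, LossBreakdown(float(l1.data), float(l2.data), float(total.data))


# ---------------------------------------------------------------------------
# Training / prediction
# ---------------------------------------------------------------------------


def train_m2(
    train_data: EncodedDataset,
    val_data: EncodedDataset,
    config: ModelConfig,
    schedule: CostSchedule,
    vocab: CostTypeVocabulary,
    settings: TrainSettings | None = None,
) -> tuple[SeqTransformer, dict]:
    """Teacher-forced training of M2 with early stopping on the validation
    combined loss; the checkpoint with minimal validation loss is returned.
    Fully seeded: two runs with the same inputs produce identical models."""
    settings = settings or TrainSettings()
    if len(train_data) == 0:
        raise ValueError("empty training set")
    model = SeqTransformer(config)
    model.reseed_dropout(settings.seed + 101)
    opt = Adam(model.parameters(), lr=settings.learning_rate)
    rng = np.random.Generator(np.random.PCG64(settings.seed))
    e = schedule.as_vector(vocab)

    best_val = np.inf
    best_state = {k: v.data.copy() for k, v in model.params.items()}
    best_epoch = -1
    trace = {"train": [], "val": []}
    since_best = 0
    for epoch in range(settings.epochs):
        model.train()
        epoch_losses = []
        for idx in iterate_minibatches(len(train_data), settings.batch_size, rng):
            opt.zero_grad()
            total, parts = _batch_loss(model, train_data, idx, e, vocab.cls_id)
            total.backward()
            opt.step()
            epoch_losses.append(parts.combined)
        model.eval()
        _, val_parts = _batch_loss(
            model, val_data, np.arange(len(val_data)), e, vocab.cls_id
        )
        trace["train"].append(float(np.mean(epoch_losses)))
        trace["val"].append(val_parts.combined)
        if val_parts.combined < best_val:
            best_val = val_parts.combined
            best_state = {k: v.data.copy() for k, v in model.params.items()}
            best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= settings.patience:
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break
    for k, v in model.params.items():
        v.data = best_state[k]
    model.eval()
    trace["best_epoch"] = best_epoch
    trace["best_val"] = best_val
    return model, trace


def predict_annual_cost(
    model: SeqTransformer,
    data: EncodedDataset,
    schedule: CostSchedule,
    vocab: CostTypeVocabulary,
    teacher_forced: bool = True,
    max_steps: int | None = None,
) -> dict:
    """Predict per-visit cost-type distributions and annual expected costs.

    Teacher-forced mode aligns one probability row to each true target visit
    (the evaluation regime of the annual-cost loss); free-running mode
    greedy-decodes to SEP or ``max_steps`` and prices the decoded visits.
    Returns per-patient prob rows, argmax types, and annual cost in euros.
    """
    model.eval()
    e = schedule.as_vector(vocab)
    if teacher_forced:
        logits = model.forward(data.input_tokens, data.input_mask,
                               data.target_ids, data.target_mask, vocab.cls_id)
        probs = logits.softmax(axis=-1).data                   # (N, T, V)
        rows = [probs[i][data.visit_mask[i]] for i in range(len(data))]
    else:
        _, prob_rows = model.greedy_decode(
            data.input_tokens, data.input_mask, vocab.cls_id, vocab.sep_id,
            vocab.pad_id, max_steps or data.target_ids.shape[1],
        )
        # drop the stopping SEP row if the decode terminated on SEP
        rows = []
        for r in prob_rows:
            if len(r) and np.argmax(r[-1]) == vocab.sep_id:
                r = r[:-1]
            rows.append(np.asarray(r))
    annual = np.array([
        float(np.asarray(r).sum(axis=0) @ e) if len(r) else 0.0
        for r in rows
    ])
    argmax_types = [
        [vocab.type_of(int(j)) for j in np.argmax(r[:, :vocab.n_types], axis=1)]
        if len(r) else []
        for r in rows
    ]
    return {
        "prob_rows": rows,
        "annual_cost": annual,
        "argmax_types": argmax_types,
        "patient_ids": data.patient_ids,
    }


def evaluate_m2(
    model: SeqTransformer,
    data: EncodedDataset,
    schedule: CostSchedule,
    vocab: CostTypeVocabulary,
    k_values: tuple[int, ...] = (3, 5, 10),
) -> EvalReport:
    """Teacher-forced evaluation: top-k over true target slots plus RMSE and
    R² over per-patient annual costs."""
    pred = predict_annual_cost(model, data, schedule, vocab, teacher_forced=True)
    true_types = [
        data.target_ids[i][data.visit_mask[i]] for i in range(len(data))
    ]
    top_k = top_k_accuracy(pred["prob_rows"], true_types, k_values)
    true_annual = data.true_annual_costs
    return EvalReport(
        top_k=top_k,
        rmse=rmse(pred["annual_cost"], true_annual),
        r_squared=r_squared(pred["annual_cost"], true_annual),
        n_patients=len(data),
        n_target_visits=int(data.visit_mask.sum()),
    )
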