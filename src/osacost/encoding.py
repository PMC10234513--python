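"""Batch encoding: stack per-patient tokenized splits into model arrays."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .records import (
    Cohort,
    CostTypeVocabulary,
    CovariateVocab,
    InputTargetSplit,
    TokenizedSequences,
    tokenize,
)

logger = logging.getLogger(__name__)


@dataclass
class EncodedDataset:
    """Stacked padded sequences for a set of patients.

    ``target_mask`` is True over real target tokens including the terminal
    SEP; ``visit_mask`` is True over the true visit slots only, which is the
    region the regression loss and the metrics operate on.
    """

    patient_ids: list[str]
    input_tokens: dict[str, np.ndarray]   # each (N, L)
    input_mask: np.ndarray                # (N, L) bool
    target_ids: np.ndarray                # (N, T) int
    target_mask: np.ndarray               # (N, T) bool
    visit_mask: np.ndarray                # (N, T) bool
    visit_costs: np.ndarray               # (N, T) actual € per visit, 0 elsewhere

    def __len__(self) -> int:
        return len(self.patient_ids)

    def subset(self, idx: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            patient_ids=[self.patient_ids[i] for i in idx],
            input_tokens={k: v[idx] for k, v in self.input_tokens.items()},
            input_mask=self.input_mask[idx],
            target_ids=self.target_ids[idx],
            target_mask=self.target_mask[idx],
            visit_mask=self.visit_mask[idx],
            visit_costs=self.visit_costs[idx],
        )

    @property
    def true_annual_costs(self) -> np.ndarray:
        """Per-patient annual true cost: sum of target-window visit costs."""
        return (self.visit_costs * self.visit_mask).sum(axis=1)


def encode_splits(
    splits: list[InputTargetSplit],
    vocab: CostTypeVocabulary,
    covariates: CovariateVocab,
    max_input_len: int,
    max_target_len: int,
) -> EncodedDataset:
    """Tokenize and stack splits; patients whose target window overflows
    ``max_target_len`` are excluded (targets are never truncated)."""
    kept: list[tuple[InputTargetSplit, TokenizedSequences]] = []
    for split in splits:
        if len(split.target_visits) + 1 > max_target_len:
            logger.info(
                "excluding patient %s: %d target visits exceed max_target_len %d",
                split.patient_id, len(split.target_visits), max_target_len,
            )
            continue
        kept.append((split, tokenize(split, vocab, covariates,
                                     max_input_len, max_target_len)))
    if not kept:
        raise ValueError("no encodable patients")

    n = len(kept)
    first = kept[0][1]
    input_tokens = {
        k: np.stack([tok.input_tokens[k] for _, tok in kept])
        for k in first.input_tokens
    }
    visit_costs = np.zeros((n, max_target_len))
    visit_mask = np.zeros((n, max_target_len), dtype=bool)
    for i, (split, _) in enumerate(kept):
        for j, v in enumerate(split.target_visits):
            visit_costs[i, j] = v.cost_eur
            visit_mask[i, j] = True
    return EncodedDataset(
        patient_ids=[s.patient_id for s, _ in kept],
        input_tokens=input_tokens,
        input_mask=np.stack([tok.input_mask for _, tok in kept]),
        target_ids=np.stack([tok.target_tokens for _, tok in kept]),
        target_mask=np.stack([tok.target_mask for _, tok in kept]),
        visit_mask=visit_mask,
        visit_costs=visit_costs,
    )
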