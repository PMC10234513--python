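"""Evaluation statistics: top-k accuracy, RMSE and R² over annual costs.

Top-k accuracy counts a target visit as correct when its true cost type is
among the k types with the highest predicted likelihood (ties in likelihood
broken toward the lowest type index before ranking).  RMSE and R² operate on
per-patient annual totals: the prediction for a patient-year is the summed
expected cost Σ_k Σ_c p̂_ikc · e_c over the teacher-forced target slots, and
the R² baseline predicts every patient's annual cost as the mean annual
true cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalReport", "top_k_accuracy", "rmse", "r_squared"]

R2_UNDEFINED = float("nan")


@dataclass
class EvalReport:
    """Summary of one model's evaluation on one test cohort."""

    top_k: dict[int, float] = field(default_factory=dict)
    rmse: float = 0.0
    r_squared: float = 0.0
    n_patients: int = 0
    n_target_visits: int = 0

    def __post_init__(self):
        ks = sorted(self.top_k)
        for a, b in zip(ks, ks[1:]):
            if self.top_k[a] > self.top_k[b] + 1e-12:
                raise ValueError("top-k accuracy must be non-decreasing in k")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")

    def to_dict(self) -> dict:
        return {
            "top_k": {str(k): v for k, v in sorted(self.top_k.items())},
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "n_patients": self.n_patients,
            "n_target_visits": self.n_target_visits,
        }


def top_k_accuracy(
    scores: list[np.ndarray],
    true_types: list[np.ndarray],
    k_values: tuple[int, ...] = (3, 5, 10),
) -> dict[int, float]:
    """Fraction of target visits whose true type is in the top-k prediction.

    ``scores``: per patient, an array (n_target_visits, C) of predicted
    likelihoods; ``true_types``: per patient, the int array of true type
    indices.  Accuracy = hits / total target visits across all patients.
    """
    total = sum(len(t) for t in true_types)
    if total == 0:
        raise ValueError("no target visits to score")
    out: dict[int, float] = {}
    for k in k_values:
        hits = 0
        for s, t in zip(scores, true_types):
            s = np.asarray(s, dtype=float)
            t = np.asarray(t)
            if s.shape[0] != t.shape[0]:
                raise ValueError("scores and true_types row counts differ")
            # stable sort on -score: likelihood ties go to the lowest index
            order = np.argsort(-s, axis=1, kind="stable")
            topk = order[:, :k]
            hits += int((topk == t[:, None]).any(axis=1).sum())
        out[k] = hits / total
    return out


def rmse(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Root mean squared error of paired annual costs (euros)."""
    predicted = np.asarray(predicted, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predicted.size == 0:
        raise ValueError("empty input")
    if predicted.shape != truth.shape:
        raise ValueError("paired lists must have equal length")
    return float(np.sqrt(np.mean((predicted - truth) ** 2)))


def r_squared(predicted_annual: np.ndarray, true_annual: np.ndarray) -> float:
    """Proportion of annual-cost variance explained.

    R² = 1 − Σ_i (ĉ_i − c_i)² / Σ_i (c̄ − c_i)² over per-patient annual
    totals, where c̄ is the mean true annual cost.  Returns NaN when every
    true annual cost is identical (zero-variance baseline).
    """
    predicted_annual = np.asarray(predicted_annual, dtype=float)
    true_annual = np.asarray(true_annual, dtype=float)
    if predicted_annual.size == 0:
        raise ValueError("empty input")
    baseline = true_annual.mean()
    denom = np.sum((baseline - true_annual) ** 2)
    if denom == 0.0:
        return R2_UNDEFINED
    return float(1.0 - np.sum((predicted_annual - true_annual) ** 2) / denom)
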