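"""End-to-end experiment: cohorts → M1 + gate → augmentation → M2 → report.

The pipeline fixes the D² train/validation/test split before any
augmentation, trains the augmentation model M1 on D¹, checks it against a
top-3 accuracy quality gate, builds the requested training cohorts (raw,
randomly augmented, model augmented — augmentation samples only from the
training patients, never validation or test), trains one cost model M2 per
mode, and evaluates every mode on the same held-out test patients.

Everything is derived from one base seed, so two runs with an identical
configuration produce byte-identical report JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .augment import (
    M1Predictor,
    aggregate_with_originals,
    augment,
    random_augment,
    train_m1,
)
from .costmodel import (
    TrainSettings,
    encode_for_prediction,
    evaluate_m2,
    train_m2,
)
from .records import (
    Cohort,
    CovariateVocab,
    assign_cohorts,
    build_vocab_and_schedule,
    read_cohort_csv,
    write_cohort_csv,
)
from .synthetic import SyntheticConfig, generate_cohort
from .transformer import ModelConfig

logger = logging.getLogger(__name__)

VALID_MODES = ("none", "random", "transformer")


@dataclass
class PipelineConfig:
    """Configuration of one full comparison run."""

    visits_csv: str | None = None
    synthetic: SyntheticConfig | None = None
    modes: tuple[str, ...] = VALID_MODES
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    sample_ratio: float = 0.55
    iterations: int = 3
    gate_threshold: float = 0.91
    seed: int = 0
    m1_model: dict = field(default_factory=dict)
    m2_model: dict = field(default_factory=dict)
    m1_train: dict = field(default_factory=dict)
    m2_train: dict = field(default_factory=dict)
    out_dir: str | None = None

    def __post_init__(self):
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        for m in self.modes:
            if m not in VALID_MODES:
                raise ValueError(f"unknown augmentation mode {m!r}")
        if self.visits_csv is None and self.synthetic is None:
            raise ValueError("either visits_csv or a synthetic config is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "modes" in raw:
            raw["modes"] = tuple(raw["modes"])
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        return cls(**raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def split_cohort(
    cohort: Cohort, fractions: tuple[float, float, float], seed: int
) -> tuple[Cohort, Cohort, Cohort]:
    """Patient-level train/validation/test split, fixed before augmentation."""
    rng = np.random.Generator(np.random.PCG64(seed))
    order = rng.permutation(len(cohort))
    n_train = int(round(fractions[0] * len(cohort)))
    n_val = int(round(fractions[1] * len(cohort)))
    pick = lambda idx: Cohort([cohort.patients[i] for i in idx], cohort.label)
    return (
        pick(order[:n_train]),
        pick(order[n_train:n_train + n_val]),
        pick(order[n_train + n_val:]),
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested comparison and return (and optionally write) the
    report: one evaluation row per augmentation mode, shared test split."""
    if config.visits_csv is not None:
        all_patients = read_cohort_csv(config.visits_csv).patients
    else:
        all_patients, _ = generate_cohort(config.synthetic)
    d1, d2 = assign_cohorts(all_patients)
    logger.info("cohorts: |D1|=%d |D2|=%d", len(d1), len(d2))

    vocab, schedule = build_vocab_and_schedule([d1, d2])
    covariates = CovariateVocab.from_cohorts([d1, d2])
    d2_train, d2_val, d2_test = split_cohort(
        d2, config.split_fractions, config.seed + 11
    )

    common_vocab = {
        "cost_type": vocab.size,
        "age": 121,
        "gender": covariates.n_gender,
        "specialist": covariates.n_specialist,
        "diff_bucket": 17,
    }
    m1_kwargs = {"max_target_len": 4, **config.m1_model}
    m1_config = ModelConfig(vocab_sizes=common_vocab,
                            seed=config.seed + 21, **m1_kwargs)
    m2_config = ModelConfig(vocab_sizes=common_vocab,
                            seed=config.seed + 22, **config.m2_model)

    report: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_d1": len(d1),
        "n_d2": len(d2),
        "modes": {},
    }

    needs_m1 = "transformer" in config.modes
    m1 = None
    if needs_m1:
        m1, m1_report = train_m1(
            d1, vocab, covariates, m1_config,
            TrainSettings(seed=config.seed + 31, **config.m1_train),
        )
        report["m1_top_k"] = {str(k): v for k, v in sorted(m1_report["top_k"].items())}

    val_data = encode_for_prediction(d2_val, vocab, covariates,
                                     m2_config.max_input_len,
                                     m2_config.max_target_len)
    test_data = encode_for_prediction(d2_test, vocab, covariates,
                                      m2_config.max_input_len,
                                      m2_config.max_target_len)

    report["n_test_patients"] = len(test_data)

    for mode in config.modes:
        if mode == "none":
            train_cohort = d2_train
        elif mode == "random":
            result = random_augment(
                d2_train, schedule, config.sample_ratio, config.iterations,
                seed=config.seed + 41,
            )
            train_cohort = aggregate_with_originals(d2_train, result)
            report["modes"][mode] = {"counters": _counters(result)}
        else:  # transformer
            top3 = report["m1_top_k"].get("3", 0.0)
            if top3 < config.gate_threshold:
                logger.error(
                    "M1 quality gate failed: held-out top-3 accuracy %.3f "
                    "is below the threshold %.3f; skipping transformer-mode "
                    "augmentation", top3, config.gate_threshold,
                )
                report["modes"][mode] = {
                    "gate_failed": True, "m1_top3": top3,
                    "threshold": config.gate_threshold,
                }
                continue
            predictor = M1Predictor(m1, vocab, covariates)
            result = augment(
                predictor, d2_train, schedule, config.sample_ratio,
                config.iterations, seed=config.seed + 42,
            )
            train_cohort = aggregate_with_originals(d2_train, result)
            report["modes"][mode] = {"counters": _counters(result)}

        train_data = encode_for_prediction(
            train_cohort, vocab, covariates,
            m2_config.max_input_len, m2_config.max_target_len,
        )
        m2, trace = train_m2(
            train_data, val_data, m2_config, schedule, vocab,
            TrainSettings(seed=config.seed + 51, **config.m2_train),
        )
        eval_report = evaluate_m2(m2, test_data, schedule, vocab)
        entry = report["modes"].setdefault(mode, {})
        entry["n_train_patients"] = len(train_cohort)
        entry["best_epoch"] = trace["best_epoch"]
        entry["evaluation"] = eval_report.to_dict()

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(render_report_json(report))
        (out / "report.md").write_text(render_report_markdown(report))
        (out / "manifest.json").write_text(json.dumps(
            {"config": asdict(config), "config_hash": report["config_hash"]},
            indent=1, sort_keys=True, default=str,
        ))
        write_cohort_csv(d2_train.patients, out / "d2_train.csv")
        write_cohort_csv(d2_test.patients, out / "d2_test.csv")
    return report


def _counters(result) -> dict:
    return {
        "n_injected": result.n_injected,
        "n_replaced": result.n_replaced,
        "n_deleted": result.n_deleted,
        "n_unchanged": result.n_unchanged,
        "n_skipped_unusable": result.n_skipped_unusable,
        "n_copies": len(result.augmented_patients),
    }


def render_report_json(report: dict) -> str:
    return json.dumps(report, indent=1, sort_keys=True)


def render_report_markdown(report: dict) -> str:
    """Comparison table: one row per augmentation mode."""
    lines = [
        "| mode | top-3 | top-5 | top-10 | RMSE (EUR) | R2 | n train |",
        "|------|-------|-------|--------|------------|----|---------|",
    ]
    for mode, entry in sorted(report["modes"].items()):
        ev = entry.get("evaluation")
        if ev is None:
            lines.append(f"| {mode} | (gate failed) | | | | | |")
            continue
        tk = ev["top_k"]
        lines.append(
            f"| {mode} | {tk.get('3', float('nan')):.3f} "
            f"| {tk.get('5', float('nan')):.3f} "
            f"| {tk.get('10', float('nan')):.3f} "
            f"| {ev['rmse']:.1f} | {ev['r_squared']:.3f} "
            f"| {entry['n_train_patients']} |"
        )
    return "\n".join(lines) + "\n"
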