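"""Optimization loop, LR schedule, checkpointing and the multi-seed protocol.

Training uses AdamW with a per-step schedule: linear warmup from 0 to
the base learning rate over the first ``warmup_epochs`` worth of steps,
then cosine annealing down to ``min_lr`` at the final step.  Supervision
is per-label binary cross-entropy on the three exam outputs.  After each
epoch the model is scored on the validation split by macro AUROC; the
checkpoint with the best validation macro AUROC is retained (earliest
epoch on ties) and evaluated exactly once on the test split.  There is
no early stopping.

The protocol runner trains every method over the same seed set on
identical splits, reports each metric as mean ± sample sd across seeds,
and compares methods to a designated reference with seed-paired
two-sided t-tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import (MetricReport, METRICS, compute_metric_report,
                         mean_sd, paired_t_test, perturb_batch)
from .exceptions import ConfigurationError, ContractError, LeakageError, \
    ProtocolError
from .model import ExamClassifier, ModelConfig, bce_with_logits
from .nn import AdamW, Module
from .preprocess import ExamTensor
from .synthetic import LABELS

REFERENCE_SEEDS = (42, 123, 2024, 3407, 9999)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 50
    batch_size: int = 16
    base_lr: float = 1e-4
    weight_decay: float = 1e-2
    warmup_epochs: int = 5
    min_lr: float = 1e-6
    seeds: tuple[int, ...] = REFERENCE_SEEDS
    deterministic: bool = True
    eval_batch_size: int = 64
    max_grad_norm: float | None = None   # global-norm gradient clipping

    def __post_init__(self):
        if not 0 <= self.warmup_epochs < self.epochs:
            raise ConfigurationError("warmup_epochs must be < epochs")
        if not 0 <= self.min_lr < self.base_lr:
            raise ConfigurationError("min_lr must be < base_lr")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")

    @staticmethod
    def tiny(**overrides) -> "TrainConfig":
        """Desk-scale schedule for the synthetic-data suite."""
        base = dict(epochs=5, batch_size=8, base_lr=5e-3, weight_decay=1e-2,
                    warmup_epochs=1, min_lr=1e-6, seeds=(42, 123, 2024),
                    max_grad_norm=1.0)
        base.update(overrides)
        return TrainConfig(**base)


def lr_at(step: int, total_steps: int, config: TrainConfig) -> float:
    """Learning rate at a global step: linear warmup then cosine decay."""
    if not 0 <= step < total_steps:
        raise ContractError(f"step {step} outside [0, {total_steps})")
    warmup_steps = int(round(config.warmup_epochs / config.epochs
                             * total_steps))
    if step < warmup_steps:
        return config.base_lr * step / warmup_steps
    span = max(1, total_steps - 1 - warmup_steps)
    progress = (step - warmup_steps) / span
    return config.min_lr + 0.5 * (config.base_lr - config.min_lr) \
        * (1.0 + np.cos(np.pi * progress))


# -- data containers ---------------------------------------------------------

@dataclass
class ExamArrays:
    """Stacked exams: X (N, 3, S, R, R) float32, y (N, 3) int, ids."""
    X: np.ndarray
    y: np.ndarray
    ids: tuple[str, ...]

    @staticmethod
    def from_exams(exams: list[ExamTensor]) -> "ExamArrays":
        X = np.stack([e.views for e in exams]).astype(np.float32)
        y = np.stack([e.label_vector for e in exams])
        return ExamArrays(X=X, y=y, ids=tuple(e.exam_id for e in exams))

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class Splits:
    train: ExamArrays
    validation: ExamArrays
    test: ExamArrays

    def __post_init__(self):
        pools = {"train": set(self.train.ids),
                 "validation": set(self.validation.ids),
                 "test": set(self.test.ids)}
        names = list(pools)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = pools[a] & pools[b]
                if overlap:
                    raise LeakageError(
                        f"exam ids shared between {a} and {b}: "
                        f"{sorted(overlap)[:5]}")


@dataclass
class RunResult:
    seed: int
    train_losses: list[float]
    val_macro_auroc: list[float]
    selected_epoch: int
    test_report: MetricReport
    model: ExamClassifier | None = field(default=None, repr=False)


# -- single run --------------------------------------------------------------

def train_one(splits: Splits, model_config: ModelConfig,
              train_config: TrainConfig, seed: int,
              encoder: Module | None = None) -> RunResult:
    """Train one model; select the best-validation checkpoint; evaluate it
    exactly once on the test split."""
    rng = np.random.default_rng(seed)
    S = splits.train.X.shape[2]
    model = ExamClassifier(model_config, S, seed=seed, encoder=encoder)
    opt = AdamW(model.parameters(), lr=train_config.base_lr,
                weight_decay=train_config.weight_decay)
    n = splits.train.n
    steps_per_epoch = int(np.ceil(n / train_config.batch_size))
    total_steps = steps_per_epoch * train_config.epochs

    train_losses: list[float] = []
    val_history: list[float] = []
    best_auroc, best_epoch, best_state = -np.inf, -1, None
    step = 0
    for epoch in range(train_config.epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            out = model.forward(splits.train.X[idx])
            loss = bce_with_logits(out["logits"], splits.train.y[idx])
            model.zero_grad()
            loss.backward()
            if train_config.max_grad_norm is not None:
                norm = np.sqrt(sum(float((p.grad ** 2).sum())
                                   for p in opt.params if p.grad is not None))
                if norm > train_config.max_grad_norm:
                    scale = train_config.max_grad_norm / norm
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.lr = lr_at(step, total_steps, train_config)
            opt.step()
            epoch_losses.append(loss.item())
            step += 1
        train_losses.append(float(np.mean(epoch_losses)))

        probs = model.predict_proba(splits.validation.X,
                                    train_config.eval_batch_size)
        report = compute_metric_report(probs, splits.validation.y)
        val_history.append(report.macro["auroc"])
        if report.macro["auroc"] > best_auroc:  # strict: earliest best wins
            best_auroc = report.macro["auroc"]
            best_epoch = epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    test_probs = model.predict_proba(splits.test.X,
                                     train_config.eval_batch_size)
    test_report = compute_metric_report(test_probs, splits.test.y)
    return RunResult(seed=seed, train_losses=train_losses,
                     val_macro_auroc=val_history, selected_epoch=best_epoch,
                     test_report=test_report, model=model)


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(path: str, model: ExamClassifier,
                    extra: dict | None = None) -> None:
    meta = {"config": vars(model.config) | {
        "pool_kernels": list(model.config.pool_kernels),
        "encoder_channels": list(model.config.encoder_channels)},
        "S": model.S, **(extra or {})}
    np.savez(path, __meta__=json.dumps(meta),
             **{k: v for k, v in model.state_dict().items()})


def load_checkpoint(path: str) -> ExamClassifier:
    try:
        archive = np.load(path, allow_pickle=False)
        meta = json.loads(str(archive["__meta__"]))
        cfg = dict(meta["config"])
        cfg["pool_kernels"] = tuple(cfg["pool_kernels"])
        cfg["encoder_channels"] = tuple(cfg["encoder_channels"])
        model = ExamClassifier(ModelConfig(**cfg), meta["S"])
        model.load_state_dict({k: archive[k] for k in archive.files
                               if k != "__meta__"})
    except (KeyError, ValueError, json.JSONDecodeError, OSError) as exc:
        raise ContractError(f"corrupt or incompatible checkpoint {path}: "
                            f"{exc}") from exc
    return model


# -- multi-seed protocol -----------------------------------------------------

@dataclass
class ProtocolReport:
    runs: dict[str, list[RunResult]]
    summary: pd.DataFrame
    paired_tests: pd.DataFrame
    reference: str


def summarize_protocol(metric_values: dict[str, dict[int, dict[str, float]]],
                       reference: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the mean ± sd table and seed-paired t-tests vs the reference.

    ``metric_values[method][seed][metric]`` holds one run's test metric.
    """
    seed_sets = {m: tuple(sorted(v)) for m, v in metric_values.items()}
    if len(set(seed_sets.values())) != 1:
        raise ProtocolError(f"mismatched seed sets across methods: {seed_sets}")
    if reference not in metric_values:
        raise ProtocolError(f"reference method {reference!r} not among "
                            f"{sorted(metric_values)}")
    seeds = sorted(next(iter(seed_sets.values())))
    summary_rows, test_rows = [], []
    for method, by_seed in metric_values.items():
        row: dict[str, object] = {"method": method}
        for metric in METRICS:
            values = [by_seed[s][metric] for s in seeds]
            mean, sd = mean_sd(values)
            row[f"{metric}_mean"] = mean
            row[f"{metric}_sd"] = sd
            row[metric] = f"{mean:.4f} ± {sd:.4f}"
            if method != reference:
                ref_values = [metric_values[reference][s][metric]
                              for s in seeds]
                result = paired_t_test(values, ref_values)
                test_rows.append({"method": method, "metric": metric,
                                  "mean_difference": result.mean_difference,
                                  "t": result.t_statistic, "df": result.df,
                                  "p_value": result.p_value,
                                  "degenerate": result.degenerate})
        summary_rows.append(row)
    return pd.DataFrame(summary_rows), pd.DataFrame(test_rows)


def run_protocol(splits: Splits, methods: dict[str, ModelConfig],
                 train_config: TrainConfig, reference: str,
                 encoder_factory=None) -> ProtocolReport:
    """Train every method over the configured seed set on identical splits
    and summarize with paired statistics against the reference method."""
    if len(train_config.seeds) < 2:
        raise ProtocolError("protocol requires at least 2 seeds")
    if reference not in methods:
        raise ProtocolError(f"reference {reference!r} not in methods "
                            f"{sorted(methods)}")
    runs: dict[str, list[RunResult]] = {}
    values: dict[str, dict[int, dict[str, float]]] = {}
    for name, config in methods.items():
        runs[name] = []
        values[name] = {}
        for seed in train_config.seeds:
            encoder = encoder_factory(seed) if encoder_factory else None
            result = train_one(splits, config, train_config, seed,
                               encoder=encoder)
            runs[name].append(result)
            values[name][seed] = dict(result.test_report.macro)
    summary, tests = summarize_protocol(values, reference)
    return ProtocolReport(runs=runs, summary=summary, paired_tests=tests,
                          reference=reference)


# -- ablation presets (full / w/o multiscale / w/o learned fusion / w/o both)

def ablation_presets(base: ModelConfig) -> dict[str, ModelConfig]:
    from dataclasses import replace
    return {
        "full": base,
        "no_multiscale": replace(base, aggregator="mean"),
        "no_learned_fusion": replace(base, fusion="average"),
        "neither": replace(base, aggregator="mean", fusion="average"),
    }


def robustness_rows(model: ExamClassifier, test: ExamArrays, seed: int,
                    shift: float = 0.5,
                    eval_batch_size: int = 64) -> pd.DataFrame:
    """Evaluate one trained model under each perturbation; one row per
    setting, tagged by perturbation name."""
    rows = []
    for name in ("none", "intensity_shift", "view_dropout"):
        rng = np.random.default_rng(seed)
        X = perturb_batch(test.X, name, rng=rng, shift=shift)
        report = compute_metric_report(
            model.predict_proba(X, eval_batch_size), test.y)
        rows.append({"perturbation": name, **{f"macro_{m}": report.macro[m]
                                              for m in METRICS}})
    return pd.DataFrame(rows)
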