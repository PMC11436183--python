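"""Training loop, evaluation, cross-validation, ablation grid and sweeps.

The default protocol is Adam at learning rate 0.02, batch size 20,
120 epochs, margin loss. Scaled-down presets (smaller geometry, fewer
epochs) are provided for CPU-bound runs; see :data:`PRESETS`.
Every random choice — parameter init, batch order — derives from the
supplied seeds, so a (seed, config, data) triple reproduces every number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Adam
from .complexity import count_complexity
from .data_io import FoldPlan, holdout_split, make_cv_folds
from .errors import ConfigurationError, ShapeError
from .model import STCapsNet
from .objectives import MarginLossParams, accuracy, confusion_counts, margin_loss, one_hot
from .routing import class_scores, predict_classes
from .stcg import ModelConfig
from .synthetic import EEGEpochSet, GenConfig


@dataclass
class TrainConfig:
    learning_rate: float = 0.02
    batch_size: int = 20
    epochs: int = 120
    seed: int = 0
    margin: MarginLossParams = field(default_factory=MarginLossParams)

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigurationError(f"learning_rate must be positive, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ConfigurationError(f"batch_size must be >= 1, got {self.batch_size}")
        if self.epochs < 0:
            raise ConfigurationError(f"epochs must be >= 0, got {self.epochs}")


@dataclass
class RunReport:
    train_loss: list[float]
    train_accuracy: list[float]
    test_accuracy: float | None
    config: dict
    seed: int


# Scaled-down profiles for CPU runs: smaller geometry and budget, same
# optimizer family and loss. "full" is the complete visual-modality protocol.
PRESETS: dict[str, dict] = {
    "full": {
        "model": dict(n_channels=124, n_samples=3073),
        "train": dict(learning_rate=0.02, batch_size=20, epochs=120),
        "gen": dict(n_channels=124, sfreq=1024.0, duration=3.0),
    },
    "reduced": {
        "model": dict(n_channels=16, n_samples=129, F1=8, TI=9, D=2,
                      F2=64, pool1=4, pool2=8, n_caps=8, d_caps=8),
        "train": dict(learning_rate=0.02, batch_size=20, epochs=30),
        "gen": dict(n_channels=16, sfreq=128.0, duration=1.0, n_sources=3),
    },
}


def preset_model_config(name: str = "reduced", **overrides) -> ModelConfig:
    return ModelConfig(**{**PRESETS[name]["model"], **overrides})


def preset_train_config(name: str = "reduced", **overrides) -> TrainConfig:
    return TrainConfig(**{**PRESETS[name]["train"], **overrides})


def preset_gen_config(name: str = "reduced", **overrides) -> GenConfig:
    return GenConfig(**{**PRESETS[name]["gen"], **overrides})


def train_model(
    train: EEGEpochSet,
    cfg: ModelConfig,
    tcfg: TrainConfig,
    routing: str = "selfcorr",
    frontend: str = "st",
    iterations: int = 3,
) -> tuple[STCapsNet, RunReport]:
    """Optimize front-end + routing end-to-end against the margin loss.

    ``epochs = 0`` returns the freshly initialized, untrained model.
    """
    if train.n_trials == 0:
        raise ConfigurationError("training set is empty")
    if train.n_channels != cfg.n_channels or train.n_samples != cfg.n_samples:
        raise ShapeError(
            f"data geometry ({train.n_channels} ch, {train.n_samples} samples) does not "
            f"match config ({cfg.n_channels} ch, {cfg.n_samples} samples)"
        )
    model = STCapsNet(cfg, routing=routing, frontend=frontend,
                      iterations=iterations, seed=tcfg.seed)
    optimizer = Adam(model.parameters(), lr=tcfg.learning_rate)
    shuffle_rng = np.random.default_rng(np.random.SeedSequence([tcfg.seed, 7]))

    losses: list[float] = []
    accuracies: list[float] = []
    targets_all = one_hot(train.labels, cfg.n_out)
    for _ in range(tcfg.epochs):
        order = shuffle_rng.permutation(train.n_trials)
        epoch_loss = 0.0
        n_correct = 0
        for start in range(0, train.n_trials, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            out = model.forward(train.data[idx], train=True)
            norms = class_scores(out)
            loss = margin_loss(norms, targets_all[idx], tcfg.margin)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            epoch_loss += float(loss.data) * len(idx)
            n_correct += int(np.sum(predict_classes(norms) == train.labels[idx]))
        losses.append(epoch_loss / train.n_trials)
        accuracies.append(100.0 * n_correct / train.n_trials)

    report = RunReport(
        train_loss=losses, train_accuracy=accuracies, test_accuracy=None,
        config={"model": cfg.to_dict(), "routing": routing, "frontend": frontend,
                "learning_rate": tcfg.learning_rate, "batch_size": tcfg.batch_size,
                "epochs": tcfg.epochs},
        seed=tcfg.seed,
    )
    return model, report


def evaluate(model: STCapsNet, test: EEGEpochSet, batch_size: int = 50):
    """Eval-mode forward pass over a test set -> (ConfusionCounts, accuracy %)."""
    if test.n_channels != model.cfg.n_channels or test.n_samples != model.cfg.n_samples:
        raise ShapeError(
            f"test geometry ({test.n_channels} ch, {test.n_samples} samples) does not "
            f"match model ({model.cfg.n_channels} ch, {model.cfg.n_samples} samples)"
        )
    preds = np.concatenate([
        model.predict(test.data[i : i + batch_size])
        for i in range(0, test.n_trials, batch_size)
    ])
    counts = confusion_counts(preds, test.labels)
    return counts, accuracy(counts)


def cross_validate(
    eset: EEGEpochSet,
    k: int,
    cfg: ModelConfig,
    tcfg: TrainConfig,
    routing: str = "selfcorr",
    frontend: str = "st",
) -> dict:
    """Stratified k-fold CV; one model per fold, seeded per fold."""
    plan: FoldPlan = make_cv_folds(eset.labels, k, seed=tcfg.seed)
    reports: list[RunReport] = []
    fold_accuracies: list[float] = []
    for fold in range(k):
        train_idx, test_idx = plan.split(fold)
        fold_tcfg = TrainConfig(
            learning_rate=tcfg.learning_rate, batch_size=tcfg.batch_size,
            epochs=tcfg.epochs, seed=tcfg.seed + fold, margin=tcfg.margin,
        )
        model, report = train_model(
            eset.subset(train_idx), cfg, fold_tcfg, routing=routing, frontend=frontend
        )
        _, acc = evaluate(model, eset.subset(test_idx))
        report.test_accuracy = acc
        reports.append(report)
        fold_accuracies.append(acc)
    return {
        "fold_plan": plan,
        "reports": reports,
        "fold_accuracies": fold_accuracies,
        "mean_accuracy": float(np.mean(fold_accuracies)),
        "sd_accuracy": float(np.std(fold_accuracies, ddof=1)) if k > 1 else 0.0,
    }


ABLATION_VARIANTS = {
    "traditional+dynamic": ("traditional", "dynamic"),
    "traditional+selfcorr": ("traditional", "selfcorr"),
    "st+dynamic": ("st", "dynamic"),
    "st+selfcorr": ("st", "selfcorr"),
}


def ablation_run(
    eset: EEGEpochSet,
    cfg: ModelConfig,
    tcfg: TrainConfig,
    variants=tuple(ABLATION_VARIANTS),
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Front-end x routing grid on one shared seeded hold-out split."""
    for v in variants:
        if v not in ABLATION_VARIANTS:
            raise ConfigurationError(
                f"unknown variant {v!r}; valid: {sorted(ABLATION_VARIANTS)}"
            )
    train_set, test_set = holdout_split(eset, test_fraction=test_fraction, seed=tcfg.seed)
    rows = []
    for v in variants:
        frontend, routing = ABLATION_VARIANTS[v]
        model, report = train_model(train_set, cfg, tcfg, routing=routing, frontend=frontend)
        _, acc = evaluate(model, test_set)
        rows.append({
            "variant": v, "frontend": frontend, "routing": routing,
            "test_accuracy": acc, "final_train_accuracy":
                report.train_accuracy[-1] if report.train_accuracy else float("nan"),
        })
    return pd.DataFrame(rows)


def sensitivity_sweep(
    eset: EEGEpochSet,
    axis: str,
    cfg: ModelConfig,
    tcfg: TrainConfig,
    values=None,
    test_fraction: float = 0.2,
) -> pd.DataFrame:
    """Accuracy and parameter count along the capsule-count or -dimension axis.

    ``F2`` is re-derived as ``n_caps * d_caps`` at every sweep point so the
    capsule reshape stays exact; infeasible points are recorded as skipped.
    """
    if axis not in ("n_caps", "d_caps"):
        raise ConfigurationError(f"axis must be 'n_caps' or 'd_caps', got {axis!r}")
    if values is None:
        values = range(2, 13) if axis == "n_caps" else range(1, 9)
    train_set, test_set = holdout_split(eset, test_fraction=test_fraction, seed=tcfg.seed)
    rows = []
    for value in values:
        fields = cfg.to_dict()
        fields[axis] = int(value)
        fields["F2"] = fields["n_caps"] * fields["d_caps"]
        try:
            swept = ModelConfig(**fields)
        except ConfigurationError as exc:
            rows.append({axis: int(value), "test_accuracy": float("nan"),
                         "n_params": -1, "skipped": str(exc)})
            continue
        model, _ = train_model(train_set, swept, tcfg)
        _, acc = evaluate(model, test_set)
        rows.append({
            axis: int(value), "test_accuracy": acc,
            "n_params": count_complexity(swept).total_params, "skipped": "",
        })
    return pd.DataFrame(rows)
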