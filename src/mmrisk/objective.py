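"""Class-balanced dual focal loss and the cross-validated training protocol.

The loss extends focal loss by modulating each sample's cross-entropy
with the gap between the true-class probability ``p_true`` and the
probability assigned elsewhere ``p_other``:

``L = -alpha_t * (1 - p_true + p_other)^gamma * log(p_true)``

With a single sigmoid output the non-target probability collapses to
``p_other = 1 - p_true``, so the modulator is ``(2 * (1 - p_true))^gamma``:
confident correct predictions are strongly down-weighted while hard and
ambiguous samples keep (or gain) weight.  The balance factor is applied
focal-loss style per class: ``alpha`` for positives, ``1 - alpha`` for
negatives.  Defaults: ``alpha = 0.25``, ``gamma = 3``.

Training uses Adam (``beta1 = 0.9``, ``beta2 = 0.999``), an initial
learning rate of 1e-4, L2 weight decay, 20 epochs, and stratified 5-fold
cross-validation (seed 2025) producing the out-of-fold prediction table
that all evaluation metrics are computed on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .autodiff import Tensor
from .fusion import LatentFusionClassifier, ModelConfig, collate
from .nn import Adam
from .types import MultimodalRecord

__all__ = [
    "LossConfig",
    "TrainConfig",
    "dual_focal_loss",
    "batch_dual_focal_loss",
    "train_fold",
    "cross_validate",
]

PROB_FLOOR = 1e-7


@dataclass
class LossConfig:
    alpha: float = 0.25
    gamma: float = 3.0

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must lie in (0, 1]")
        if self.gamma < 0.0:
            raise ValueError("gamma must be >= 0")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    epochs: int = 20
    l2: float = 1e-5
    folds: int = 5
    seed: int = 2025
    bootstrap_n: int = 1000
    batch_size: int = 32

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def dual_focal_loss(p_true, p_other, cfg: LossConfig | None = None):
    """Per-sample dual focal loss value(s); inputs are plain probabilities.

    ``p_true`` below the numeric floor is clamped (a zero true-class
    probability would make the log diverge).
    """
    cfg = cfg or LossConfig()
    p_true = np.asarray(p_true, dtype=float)
    p_other = np.asarray(p_other, dtype=float)
    if np.any(p_true < PROB_FLOOR):
        warnings.warn("p_true clamped to the numeric floor inside log", RuntimeWarning)
    clamped = np.maximum(p_true, PROB_FLOOR)
    return -cfg.alpha * (1.0 - p_true + p_other) ** cfg.gamma * np.log(clamped)


def batch_dual_focal_loss(probs: Tensor, labels: np.ndarray, cfg: LossConfig) -> Tensor:
    """Mean dual focal loss over a batch, differentiable through ``probs``.

    ``probs`` are sigmoid outputs for the positive class; the true-class
    probability is ``p`` for positives and ``1 - p`` for negatives, and
    the balance factor is ``alpha`` / ``1 - alpha`` respectively.
    """
    y = np.asarray(labels, dtype=float)
    p_true = probs * y + (1.0 - probs) * (1.0 - y)
    alpha_t = cfg.alpha * y + (1.0 - cfg.alpha) * (1.0 - y)
    modulator = ((1.0 - p_true) * 2.0) ** cfg.gamma  # 1 - p_true + p_other, p_other = 1 - p_true
    return (modulator * (-p_true.log(floor=PROB_FLOOR)) * alpha_t).mean()


def train_fold(
    model: LatentFusionClassifier,
    train_records: list[MultimodalRecord],
    val_records: list[MultimodalRecord],
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> np.ndarray:
    """Train ``model`` on one fold; return probabilities on the held-out set.

    Deterministic given the config seed (shuffling and dropout draw from a
    generator seeded by it).  A single-class training fold is allowed with
    a warning; empty splits are errors.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    if not train_records or not val_records:
        raise ValueError("empty train or validation split")
    labels = np.array([r.label for r in train_records])
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class training fold; proceeding", RuntimeWarning)

    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.parameters(), lr=cfg.lr, betas=cfg.betas, weight_decay=cfg.l2)
    n = len(train_records)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = collate([train_records[i] for i in idx])
            probs = model.forward(batch, rng=rng)
            loss = batch_dual_focal_loss(probs, batch["labels"], loss_cfg)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
    return model.predict_proba(val_records)


def cross_validate(
    records: list[MultimodalRecord],
    model_config: ModelConfig,
    cfg: TrainConfig | None = None,
    loss_cfg: LossConfig | None = None,
) -> tuple[pd.DataFrame, list[LatentFusionClassifier]]:
    """Stratified k-fold CV producing the out-of-fold prediction table.

    Returns ``(table, fold_models)`` where the table has one row per
    patient: ``patient_id, fold, probability, label``.  Stratification
    guarantees positives in every fold despite the rare outcome.
    """
    cfg = cfg or TrainConfig()
    loss_cfg = loss_cfg or LossConfig()
    y = np.array([r.label for r in records])
    splitter = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    rows = []
    models = []
    for fold, (train_idx, val_idx) in enumerate(splitter.split(np.zeros(len(y)), y)):
        model = LatentFusionClassifier(
            _with_seed(model_config, model_config.seed + fold)
        )
        fold_cfg = TrainConfig(**{**vars(cfg), "seed": cfg.seed + fold})
        val_probs = train_fold(
            model,
            [records[i] for i in train_idx],
            [records[i] for i in val_idx],
            fold_cfg,
            loss_cfg,
        )
        for i, p in zip(val_idx, val_probs):
            rows.append((records[i].patient_id, fold, float(p), int(y[i])))
        models.append(model)
    table = pd.DataFrame(rows, columns=["patient_id", "fold", "probability", "label"])
    return table.sort_values("patient_id", ignore_index=True), models


def _with_seed(config: ModelConfig, seed: int) -> ModelConfig:
    params = vars(config).copy()
    params["seed"] = seed
    return ModelConfig(**params)
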