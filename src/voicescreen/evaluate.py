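"""Training and evaluation protocols: 8:1:1 hold-out and five-fold CV.

Splitting defaults to the participant as the unit, assigned before any
augmentation, so no augmented derivative of one speaker's composite can
straddle partitions (augmentation leakage). ``paper_mode`` reproduces the
original protocol instead: augment the full image set first, then split at
the image level 8:1:1 — which is how 800 augmented images yield 640
training images.

Training follows the published configuration: AdaMax, batch size 4, at
most 60 epochs, early stopping after three epochs without validation-loss
improvement (best-validation weights restored).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .metrics import MetricsReport, PANEL_FIELDS, confusion_and_metrics
from .models import Adamax, ModelSpec, build_model

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "make_splits",
    "train",
    "early_stop_epoch",
    "predict_scores",
    "crossvalidate",
    "holdout_evaluate",
    "aggregate_reports",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and schedule settings (published defaults)."""

    optimizer: str = "adamax"
    learning_rate: float = 1e-6
    batch_size: int = 4
    max_epochs: int = 60
    early_stop_patience: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs,
               self.early_stop_patience) <= 0:
            raise ValueError("all training settings must be positive")
        # patience >= max_epochs simply means early stopping never fires
        # (the degenerate max_epochs=1 schedule stays expressible)


@dataclass
class SplitPlan:
    """Partitioning protocol and (after :func:`make_splits`) assignments.

    ``unit='participant'`` partitions speakers; ``unit='image'`` partitions
    individual images. Hold-out uses ``ratios`` (train, val, test); k-fold
    carves ``val_fraction`` out of each fold's training portion.
    """

    mode: str = "holdout"  # or "kfold"
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1)
    k: int = 5
    val_fraction: float = 0.1
    unit: str = "participant"
    seed: int = 0
    assignments: dict = field(default_factory=dict)
    fold_assignments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("holdout", "kfold"):
            raise ValueError("mode must be 'holdout' or 'kfold'")
        if self.unit not in ("participant", "image"):
            raise ValueError("unit must be 'participant' or 'image'")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("holdout ratios must sum to 1")


def _units(index: pd.DataFrame, unit: str) -> tuple[np.ndarray, np.ndarray]:
    """Unit identifiers and their class labels (1 = AD)."""
    if unit == "participant":
        df = index[["participant_id", "group"]].drop_duplicates("participant_id")
        ids = df["participant_id"].to_numpy()
        y = (df["group"].to_numpy() == "AD").astype(int)
    else:
        ids = index.index.to_numpy()
        y = (index["group"].to_numpy() == "AD").astype(int)
    return ids, y


def make_splits(index: pd.DataFrame, plan: SplitPlan) -> SplitPlan:
    """Assign units to partitions, stratified by class and seeded.

    Returns a copy of ``plan``: hold-out fills ``assignments`` (unit ->
    train/val/test), k-fold fills ``fold_assignments`` (one dict per fold).
    """
    ids, y = _units(index, plan.unit)
    out = replace(plan)
    if plan.mode == "holdout":
        tr_frac, va_frac, te_frac = plan.ratios
        rest_ids, test_ids, rest_y, _ = train_test_split(
            ids, y, test_size=te_frac, stratify=y, random_state=plan.seed
        )
        train_ids, val_ids = train_test_split(
            rest_ids, test_size=va_frac / (tr_frac + va_frac),
            stratify=rest_y, random_state=plan.seed,
        )
        out.assignments = {**{u: "train" for u in train_ids},
                           **{u: "val" for u in val_ids},
                           **{u: "test" for u in test_ids}}
        return out
    # k-fold
    per_class = np.bincount(y, minlength=2)
    if per_class.min() < plan.k:
        raise ValueError(f"need at least k={plan.k} units per class")
    skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    folds = []
    for fold_i, (rest_idx, test_idx) in enumerate(skf.split(ids, y)):
        tr_ids, val_ids = train_test_split(
            ids[rest_idx], test_size=plan.val_fraction,
            stratify=y[rest_idx], random_state=plan.seed + fold_i,
        )
        folds.append({**{u: "train" for u in tr_ids},
                      **{u: "val" for u in val_ids},
                      **{u: "test" for u in ids[test_idx]}})
    out.fold_assignments = folds
    return out


def early_stop_epoch(val_losses: list[float], patience: int) -> int:
    """Number of epochs a patience-based early stop would run.

    Training halts once the validation loss has failed to improve on its
    best value for ``patience`` consecutive epochs.
    """
    best = np.inf
    stale = 0
    for epoch, loss in enumerate(val_losses, start=1):
        if loss < best:
            best = loss
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                return epoch
    return len(val_losses)


def train(
    model,
    cfg: TrainConfig,
    train_images: list[np.ndarray],
    train_labels: np.ndarray,
    val_images: list[np.ndarray],
    val_labels: np.ndarray,
) -> tuple[object, dict]:
    """Fit a model, returning it with a per-epoch loss history.

    Stops at ``max_epochs`` or when validation loss has not improved for
    ``early_stop_patience`` epochs; the best-validation weights are kept.
    """
    if len(train_images) == 0 or len(val_images) == 0:
        raise ValueError("train and validation sets must be non-empty")
    x_train = model.preprocess(train_images)
    y_train = np.asarray(train_labels, dtype=float)
    x_val = model.preprocess(val_images)
    y_val = np.asarray(val_labels, dtype=float)
    opt = Adamax(lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_loss, best_state, stale = np.inf, model.get_state(), 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_train))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            loss, grads = model.loss_and_grads(x_train[batch], y_train[batch])
            opt.step(model.params, grads)
            epoch_losses.append(loss)
        val_loss = model.loss(x_val, y_val)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        if val_loss < best_loss:
            best_loss, best_state, stale = val_loss, model.get_state(), 0
        else:
            stale += 1
            if stale >= cfg.early_stop_patience:
                break
    model.set_state(best_state)
    model.fitted = True
    return model, history


def predict_scores(model, images) -> np.ndarray:
    """Per-image AD probability scores from a fitted model."""
    return np.asarray(model.predict_proba(images), dtype=float)


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, float]:
    """Unweighted mean of the seven-metric panel across folds."""
    return {
        k: float(np.mean([getattr(r, k) for r in reports])) for k in PANEL_FIELDS
    }


def _evaluate_split(
    images: list[np.ndarray],
    labels: np.ndarray,
    membership: np.ndarray,
    model_spec: ModelSpec,
    cfg: TrainConfig,
    augment_cfg=None,
) -> tuple[MetricsReport, dict]:
    """Train on one train/val/test membership vector and score the test set."""
    from .augment import augment_set

    tr = membership == "train"
    va = membership == "val"
    te = membership == "test"
    tr_imgs = [images[i] for i in np.where(tr)[0]]
    tr_labs = labels[tr]
    if augment_cfg is not None:
        tr_imgs, tr_labs, _ = augment_set(tr_imgs, tr_labs, augment_cfg)
    model = build_model(model_spec, seed=cfg.seed)
    model, history = train(
        model, cfg, tr_imgs, tr_labs,
        [images[i] for i in np.where(va)[0]], labels[va],
    )
    scores = predict_scores(model, [images[i] for i in np.where(te)[0]])
    return confusion_and_metrics(scores, labels[te]), history


def _membership(index: pd.DataFrame, assignment: dict, unit: str) -> np.ndarray:
    key = index["participant_id"] if unit == "participant" else index.index
    return np.asarray([assignment[k] for k in key])


def holdout_evaluate(
    images: list[np.ndarray],
    index: pd.DataFrame,
    plan: SplitPlan,
    model_spec: ModelSpec,
    cfg: TrainConfig,
    augment_cfg=None,
) -> tuple[MetricsReport, dict]:
    """Single 8:1:1 evaluation; augmentation (if given) on the train split only."""
    plan = make_splits(index, plan) if not plan.assignments else plan
    labels = (index["group"].to_numpy() == "AD").astype(int)
    member = _membership(index, plan.assignments, plan.unit)
    return _evaluate_split(images, labels, member, model_spec, cfg, augment_cfg)


def crossvalidate(
    images: list[np.ndarray],
    index: pd.DataFrame,
    plan: SplitPlan,
    model_spec: ModelSpec,
    cfg: TrainConfig,
    augment_cfg=None,
) -> tuple[list[MetricsReport], dict[str, float]]:
    """k-fold evaluation: per-fold reports plus their unweighted mean panel."""
    plan = make_splits(index, plan) if not plan.fold_assignments else plan
    labels = (index["group"].to_numpy() == "AD").astype(int)
    reports = []
    for fold in plan.fold_assignments:
        member = _membership(index, fold, plan.unit)
        report, _ = _evaluate_split(images, labels, member, model_spec, cfg, augment_cfg)
        reports.append(report)
    return reports, aggregate_reports(reports)
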