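"""Cross-validation, confusion counting, and SE/SP/ACC evaluation.

The classification unit is the contraction event (one TOCO-peak-anchored
segment), not the single-channel image: the 16 per-channel probability
vectors of an event are aggregated into one decision before counting. With
UC as the positive class,

    SE  = TP / (TP + FN)        sensitivity
    SP  = TN / (FP + TN)        specificity
    ACC = (TP + TN) / (TP + TN + FP + FN)

Metrics are computed in full precision and *reported* rounded to two
decimals with round-half-away-from-zero, matching clinical-table
presentation. Fivefold cross-validation stratifies events by class; the
averaged metrics are reported both from the summed counts across folds (the
headline convention) and as the mean of per-fold metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cnn import (
    TrainConfig,
    TrainedModel,
    aggregate_segment_prediction,
    build_architecture,
    default_train_config,
    predict,
    train,
)
from .imaging import SegmentImage

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "FoldAssignment",
    "PositionalResult",
    "CVResult",
    "compute_metrics",
    "confusion",
    "make_folds",
    "cross_validate",
    "positional_evaluate",
    "round_half_away",
]


class UndefinedMetricError(ValueError):
    """A metric's denominator class has no members."""


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (0.875 -> 0.88), as printed tables do."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class Metrics:
    se: float
    sp: float
    acc: float

    def rounded(self, ndigits: int = 2) -> "Metrics":
        return Metrics(
            round_half_away(self.se, ndigits),
            round_half_away(self.sp, ndigits),
            round_half_away(self.acc, ndigits),
        )


def compute_metrics(c: ConfusionCounts) -> Metrics:
    """SE, SP, ACC from confusion counts, full precision."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("no positive (UC) units: SE undefined")
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("no negative (nonUC) units: SP undefined")
    return Metrics(
        se=c.tp / (c.tp + c.fn),
        sp=c.tn / (c.fp + c.tn),
        acc=(c.tp + c.tn) / c.total,
    )


def confusion(predicted, truth) -> ConfusionCounts:
    """Count TP/FP/TN/FN with UC as the positive class."""
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    c = ConfusionCounts()
    for p, t in zip(predicted, truth):
        if t == "UC":
            if p == "UC":
                c.tp += 1
            else:
                c.fn += 1
        else:
            if p == "UC":
                c.fp += 1
            else:
                c.tn += 1
    return c


@dataclass
class FoldAssignment:
    """Stratified k-fold partition plus the inner 80/20 train/validation split."""

    units: list
    labels: list[str]
    fold_of: np.ndarray  # fold index 1..k per unit
    k: int
    val_units: dict[int, set] = field(default_factory=dict)  # fold -> validation units

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)

    def inner_split(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) index arrays within the fold's training set."""
        tr = self.train_indices(fold)
        val = np.array([i for i in tr if self.units[i] in self.val_units[fold]], dtype=int)
        sub = np.array([i for i in tr if self.units[i] not in self.val_units[fold]], dtype=int)
        return sub, val


def make_folds(units: list, k: int = 5, seed: int = 0, class_labels=None) -> FoldAssignment:
    """Stratified k-fold split of units with a seeded inner 80/20 split.

    Per-class fold sizes differ by at most one.
    """
    if class_labels is None:
        raise ValueError("class_labels are required for stratification")
    labels = list(class_labels)
    if len(labels) != len(units):
        raise ValueError("units and class_labels must align")
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        raise ValueError(f"need at least {k} units per class, got {counts.to_dict()}")
    y = np.asarray(labels)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(units), dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(units)), y), start=1):
        fold_of[test_idx] = fold
    rng = np.random.default_rng(seed)
    val_units: dict[int, set] = {}
    for fold in range(1, k + 1):
        tr = np.flatnonzero(fold_of != fold)
        chosen: list = []
        for cls in counts.index:  # stratified 20% per class
            cls_idx = tr[y[tr] == cls]
            n_val = max(1, int(round(0.2 * cls_idx.size)))
            chosen.extend(rng.permutation(cls_idx)[:n_val])
        val_units[fold] = {units[i] for i in chosen}
    return FoldAssignment(units=list(units), labels=labels, fold_of=fold_of, k=k,
                          val_units=val_units)


def _group_images(images: list[SegmentImage]):
    """Group per-channel images by their parent event; check label consistency."""
    groups: dict = {}
    for im in images:
        groups.setdefault(im.group_key, []).append(im)
    keys = sorted(groups.keys())
    labels = []
    for key in keys:
        labs = {im.label for im in groups[key]}
        if len(labs) != 1:
            raise ValueError(f"inconsistent class labels within event {key}: {labs}")
        labels.append(labs.pop())
    return groups, keys, labels


@dataclass
class CVResult:
    fold_counts: list[ConfusionCounts]
    fold_metrics: list[Metrics]
    summed_counts: ConfusionCounts
    summed_metrics: Metrics  # headline: metrics of the summed counts
    mean_metrics: Metrics  # mean of per-fold metrics
    logs: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (c, m) in enumerate(zip(self.fold_counts, self.fold_metrics), start=1):
            r = m.rounded()
            rows.append(
                dict(fold=f"Fold{i}", FP=c.fp, FN=c.fn, TP=c.tp, TN=c.tn,
                     SE=r.se, SP=r.sp, ACC=r.acc)
            )
        c, r = self.summed_counts, self.summed_metrics.rounded()
        rows.append(dict(fold="Average", FP=c.fp, FN=c.fn, TP=c.tp, TN=c.tn,
                         SE=r.se, SP=r.sp, ACC=r.acc))
        return pd.DataFrame(rows)


def cross_validate(
    images: list[SegmentImage],
    variant: str = "scaled",
    train_config: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
    aggregation: str = "mean",
) -> CVResult:
    """k-fold cross-validation of the CNN on event-grouped images."""
    groups, keys, labels = _group_images(images)
    folds = make_folds(keys, k=k, seed=seed, class_labels=labels)
    arch = build_architecture(variant)
    fold_counts: list[ConfusionCounts] = []
    fold_metrics: list[Metrics] = []
    logs = []
    for fold in range(1, k + 1):
        cfg = train_config or default_train_config(variant, epochs=10)
        sub_idx, val_idx = folds.inner_split(fold)
        train_keys = [keys[i] for i in np.concatenate([sub_idx, val_idx])]
        fit_images = [im for kkey in train_keys for im in groups[kkey]]
        fit_labels = [im.label for kkey in train_keys for im in groups[kkey]]
        val_set = folds.val_units[fold]
        split = np.array([im.group_key not in val_set for im in fit_images])
        model = train(fit_images, fit_labels, cfg, arch, split=split)
        logs.append(model.log)
        preds, truths = [], []
        for i in folds.test_indices(fold):
            ims = groups[keys[i]]
            probs = predict(model, ims)
            preds.append(aggregate_segment_prediction(probs, rule=aggregation))
            truths.append(labels[i])
        c = confusion(preds, truths)
        fold_counts.append(c)
        fold_metrics.append(compute_metrics(c))
        logger.info("fold %d: %s -> %s", fold, c, fold_metrics[-1].rounded())
    summed = sum(fold_counts, ConfusionCounts())
    mean = Metrics(
        se=float(np.mean([m.se for m in fold_metrics])),
        sp=float(np.mean([m.sp for m in fold_metrics])),
        acc=float(np.mean([m.acc for m in fold_metrics])),
    )
    return CVResult(
        fold_counts=fold_counts,
        fold_metrics=fold_metrics,
        summed_counts=summed,
        summed_metrics=compute_metrics(summed),
        mean_metrics=mean,
        logs=logs,
    )


@dataclass
class PositionalResult:
    """Per-window-label confusion counts and metrics."""

    per_label: dict[str, tuple[ConfusionCounts, Metrics]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, (c, m) in self.per_label.items():
            r = m.rounded()
            rows.append(dict(window=label, FP=c.fp, FN=c.fn, TP=c.tp, TN=c.tn,
                             SE=r.se, SP=r.sp, ACC=r.acc))
        return pd.DataFrame(rows)


def positional_evaluate(
    model: TrainedModel,
    positional_images: list[SegmentImage],
    aggregation: str = "mean",
) -> PositionalResult:
    """Classify positionally windowed images with a trained model, per label.

    Images are grouped by (event, window label); each event-window gets one
    aggregated decision. Labels with no test units are omitted with a
    warning.
    """
    by_label: dict[str, dict] = {}
    for im in positional_images:
        by_label.setdefault(im.window_label, {}).setdefault(im.group_key, []).append(im)
    per_label: dict[str, tuple[ConfusionCounts, Metrics]] = {}
    for label in sorted(by_label):
        preds, truths = [], []
        for _, ims in sorted(by_label[label].items()):
            probs = predict(model, ims)
            preds.append(aggregate_segment_prediction(probs, rule=aggregation))
            truths.append(ims[0].label)
        c = confusion(preds, truths)
        try:
            per_label[label] = (c, compute_metrics(c))
        except UndefinedMetricError as exc:
            logger.warning("window %s omitted: %s", label, exc)
    return PositionalResult(per_label=per_label)
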