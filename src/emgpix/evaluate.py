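"""Evaluation: confusion matrices, accuracies and the condition grid.

The study's headline result is a 10-gesture x 6-condition accuracy table:
three image encoders ({time_domain, spectrogram, enhanced_spectrogram})
crossed with two channel counts ({8, 16}), each scored by a confusion
matrix, per-class accuracies and their unweighted mean.  The 8-channel
condition uses the even-indexed half of the 16 electrodes, i.e. every other
contact around the armband ring.

Conventions: confusion rows are the true gesture, columns the predicted
one; the "average accuracy" of a condition is the unweighted arithmetic
mean of the per-class accuracies (not the pooled sample accuracy), and
display rounding is half-up to one decimal.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn import metrics
from sklearn.model_selection import GroupShuffleSplit

from .exceptions import DataError, DomainError, ParameterError
from .models import CnnGestureClassifier, TrainConfig
from .preprocess import FilterSpec, preprocess_chain
from .encode import (
    EIGHT_CHANNEL_SUBSET,
    SpectrogramEncoder,
    StftSpec,
    TimeDomainEncoder,
    WindowSpec,
    segment_dataset,
)
from .simulate import GESTURE_NAMES, Recording

__all__ = [
    "EvaluationReport",
    "confusion_matrix",
    "per_class_accuracy",
    "average_accuracy",
    "round_half_up",
    "encode_condition",
    "evaluate_condition",
    "compare_conditions",
    "grid_to_frame",
    "DEFAULT_CONDITIONS",
]

#: The six study conditions: encoder x channel count.
DEFAULT_CONDITIONS: tuple[tuple[str, int], ...] = (
    ("time_domain", 8),
    ("time_domain", 16),
    ("spectrogram", 8),
    ("spectrogram", 16),
    ("enhanced_spectrogram", 8),
    ("enhanced_spectrogram", 16),
)

_ENCODERS = ("time_domain", "spectrogram", "enhanced_spectrogram")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (97.25 -> 97.3), as used for display."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    """Scores of one (encoder, n_channels) condition."""

    confusion: np.ndarray  # (n_classes, n_classes), rows = true class
    per_class_accuracy: np.ndarray  # percentages
    average_accuracy: float  # percentage, unweighted mean
    condition: tuple[str, int]

    @property
    def n_samples(self) -> int:
        return int(self.confusion.sum())

    def confusion_transposed(self) -> np.ndarray:
        """Predicted-on-rows orientation, for plotting parity."""
        return self.confusion.T


def confusion_matrix(true_labels, predicted_labels, n_classes: int = 10) -> np.ndarray:
    """Integer contingency table; entry (i, j) counts true i predicted j."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.size == 0:
        raise DataError("cannot build a confusion matrix from empty label lists")
    if t.shape != p.shape:
        raise DataError("true and predicted label lists differ in length")
    for name, arr in (("true", t), ("predicted", p)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise DomainError(f"{name} labels must lie in 0..{n_classes - 1}")
    return metrics.confusion_matrix(t, p, labels=np.arange(n_classes))


def per_class_accuracy(confusion: np.ndarray) -> np.ndarray:
    """Diagonal over row sums, as percentages."""
    c = np.asarray(confusion, dtype=float)
    rowsum = c.sum(axis=1)
    empty = np.flatnonzero(rowsum == 0)
    if empty.size:
        raise DataError(f"no evaluated samples for class(es) {empty.tolist()}")
    return 100.0 * np.diag(c) / rowsum


def average_accuracy(per_class: Sequence[float], decimals: int | None = 1) -> float:
    """Unweighted mean of per-class accuracies, in percent.

    Reported half-up rounded to ``decimals`` places (the table convention);
    pass ``decimals=None`` for the exact mean.
    """
    v = np.asarray(per_class, dtype=float)
    if v.size == 0:
        raise DataError("per-class accuracy vector is empty")
    mean = float(v.mean())
    return mean if decimals is None else round_half_up(mean, decimals)


def _select_channels(rec: Recording, n_channels: int) -> Recording:
    if n_channels == rec.n_channels:
        return rec
    if n_channels == 8 and rec.n_channels == 16:
        return rec.with_samples(rec.samples[list(EIGHT_CHANNEL_SUBSET)])
    raise DomainError(
        f"cannot derive {n_channels} channels from a {rec.n_channels}-channel recording"
    )


def encode_condition(
    recordings: Sequence[Recording],
    encoder: str,
    n_channels: int,
    window: WindowSpec | None = None,
    stft: StftSpec | None = None,
    filters: Sequence[FilterSpec] | None = None,
    preprocessed: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Preprocess, segment and encode a dataset for one condition.

    Returns ``(images, labels, groups)`` where ``groups`` identifies the
    (subject, repetition) provenance of each image, used to split without
    leakage between segments of one hold.
    """
    if encoder not in _ENCODERS:
        raise ParameterError(f"encoder must be one of {_ENCODERS}, got {encoder!r}")
    fs = recordings[0].fs
    recs = [_select_channels(r, n_channels) for r in recordings]
    if not preprocessed:
        recs = [preprocess_chain(r, list(filters) if filters else None) for r in recs]
    segments, labels, prov = segment_dataset(recs, window)
    if encoder == "time_domain":
        enc = TimeDomainEncoder(fs=fs)
    else:
        enc = SpectrogramEncoder(fs=fs, window=window, stft=stft,
                                 enhanced=(encoder == "enhanced_spectrogram"))
    images = enc.fit_transform(segments)
    groups = np.asarray([(s, r) for s, r, _ in prov])
    group_ids = groups[:, 0] * (groups[:, 1].max() + 1) + groups[:, 1]
    return images, labels, group_ids


def evaluate_condition(
    images: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    condition: tuple[str, int],
    cfg: TrainConfig | None = None,
) -> EvaluationReport:
    """Group-held-out train/test evaluation of one condition.

    Whole (subject, repetition) groups are held out (default 20%), so
    segments of one hold never straddle the split.
    """
    cfg = cfg or TrainConfig()
    splitter = GroupShuffleSplit(n_splits=1, test_size=cfg.test_size,
                                 random_state=cfg.seed % (2**32))
    train_idx, test_idx = next(splitter.split(images, labels, groups))
    clf = CnnGestureClassifier(
        arch="auto",
        learning_rate=cfg.learning_rate,
        batch_size=cfg.batch_size,
        epochs=cfg.epochs,
        seed=cfg.seed,
    )
    clf.fit(images[train_idx], labels[train_idx])
    pred = clf.predict(images[test_idx])
    n_classes = len(np.unique(labels))
    conf = confusion_matrix(labels[test_idx], pred, n_classes=n_classes)
    per_class = per_class_accuracy(conf)
    return EvaluationReport(
        confusion=conf,
        per_class_accuracy=per_class,
        average_accuracy=average_accuracy(per_class, decimals=None),
        condition=tuple(condition),
    )


def compare_conditions(
    recordings: Sequence[Recording],
    conditions: Sequence[tuple[str, int]] = DEFAULT_CONDITIONS,
    cfg: TrainConfig | None = None,
    window: WindowSpec | None = None,
    stft: StftSpec | None = None,
    filters: Sequence[FilterSpec] | None = None,
) -> dict[tuple[str, int], EvaluationReport]:
    """Run encode -> split -> train -> evaluate for each condition.

    The input dataset must supply 16 channels; the 8-channel conditions use
    the even-indexed electrode subset.  All conditions share the seed in
    ``cfg``, so the whole grid is reproducible.
    """
    if not conditions:
        raise ParameterError("conditions must be nonempty")
    cfg = cfg or TrainConfig()
    if recordings[0].n_channels != 16:
        raise DomainError("compare_conditions expects 16-channel recordings")
    # Preprocess once per channel count, reused across the three encoders.
    pre: dict[int, list[Recording]] = {}
    for n_ch in {c for _, c in conditions}:
        pre[n_ch] = [
            preprocess_chain(_select_channels(r, n_ch),
                             list(filters) if filters else None)
            for r in recordings
        ]
    reports: dict[tuple[str, int], EvaluationReport] = {}
    for encoder, n_ch in conditions:
        images, labels, groups = encode_condition(
            pre[n_ch], encoder, n_ch, window=window, stft=stft, preprocessed=True
        )
        reports[(encoder, n_ch)] = evaluate_condition(
            images, labels, groups, (encoder, n_ch), cfg
        )
    return reports


_COLUMN_TITLES = {
    "time_domain": "Time-Domain",
    "spectrogram": "Spectrogram",
    "enhanced_spectrogram": "Feature-Enhanced",
}


def grid_to_frame(reports: dict[tuple[str, int], EvaluationReport],
                  class_names: Sequence[str] = GESTURE_NAMES) -> pd.DataFrame:
    """Render reports as the 11-row accuracy grid (10 gestures + Average).

    Cells are percentages rounded half-up to one decimal; one column per
    condition.
    """
    columns = {}
    for (encoder, n_ch), rep in reports.items():
        name = f"{_COLUMN_TITLES.get(encoder, encoder)} {n_ch}CH"
        cells = [round_half_up(a) for a in rep.per_class_accuracy]
        cells.append(round_half_up(rep.average_accuracy))
        columns[name] = cells
    index = list(class_names[: len(next(iter(reports.values())).per_class_accuracy)])
    index.append("Average")
    return pd.DataFrame(columns, index=index)
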