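"""Confusion matrices, fall metrics, grouped cross-validation and sweeps.

Fall detection is scored one-vs-rest with falling as the positive class:
the seven other motions are all negatives.  From a confusion matrix ``C``
(rows = true class, columns = predicted, canonical order):

    TP = C[fall, fall]            FN = row_sum(fall) - TP
    FP = col_sum(fall) - TP       TN = total - TP - FP - FN

    accuracy    = (TP + TN) / (TP + FP + TN + FN)
    recall      = TP / (TP + FN)
    specificity = TN / (FP + TN)
    precision   = TP / (TP + FP)
    F1          = 2 * recall * precision / (recall + precision)

Per-class correct answer rates are the diagonal over row sums; the overall
rate is the trace over the total.  Reported percentages round half-up to
0.1 points.  Cross-validation is subject-grouped: folds partition the
subjects (by default 16 subjects into 8 test pairs) so nobody appears in
both the training and the test side of a fold.

Two reference confusion matrices from the original 16-participant study
(one per classifier, 800 samples per class) ship as plain-text fixtures;
all five fall metrics and the per-class rates are recomputed from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import LABEL_TO_INDEX, MOTION_LABELS, MotionLabel

N = len(MOTION_LABELS)


def round_percent(fraction: float, ndigits: int = 1) -> float:
    """A proportion as a percentage, rounded half-up to ``ndigits``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(fraction * 100.0)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """8x8 integer counts; rows = true class, cols = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (N, N):
            raise ValueError(f"confusion matrix must be {N}x{N}")
        if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
            counts = counts.astype(np.int64)
            if np.any(counts < 0):
                raise ValueError("confusion matrix entries must be non-negative integers")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=MOTION_LABELS, columns=MOTION_LABELS)


@dataclass(frozen=True)
class FallMetrics:
    """One-vs-rest counts and the five derived metrics.

    A metric whose denominator is zero is ``None`` (undefined), never 0.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    accuracy: float | None
    recall: float | None
    specificity: float | None
    precision: float | None
    f1: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            k: (round_percent(v) if v is not None else None)
            for k, v in {
                "accuracy": self.accuracy,
                "recall": self.recall,
                "specificity": self.specificity,
                "precision": self.precision,
                "f1": self.f1,
            }.items()
        }


def confusion_matrix(
    truths: Sequence[str], preds: Sequence[str]
) -> ConfusionMatrix:
    """Tally (true, predicted) label pairs in canonical class order."""
    if len(truths) != len(preds):
        raise ValueError(f"length mismatch: {len(truths)} truths vs {len(preds)} predictions")
    counts = np.zeros((N, N), dtype=np.int64)
    for t, p in zip(truths, preds):
        counts[LABEL_TO_INDEX[str(t)], LABEL_TO_INDEX[str(p)]] += 1
    return ConfusionMatrix(counts)


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def fall_metrics(cm: ConfusionMatrix, positive: str = "falling") -> FallMetrics:
    """One-vs-rest metrics with the given class as positive."""
    i = LABEL_TO_INDEX[str(MotionLabel(positive))]
    c = cm.counts
    TP = int(c[i, i])
    FN = int(c[i].sum() - TP)
    FP = int(c[:, i].sum() - TP)
    TN = int(c.sum() - TP - FN - FP)
    recall = _ratio(TP, TP + FN)
    precision = _ratio(TP, TP + FP)
    f1 = None
    if recall is not None and precision is not None and (recall + precision) > 0:
        f1 = 2 * recall * precision / (recall + precision)
    return FallMetrics(
        TP=TP, FP=FP, TN=TN, FN=FN,
        accuracy=_ratio(TP + TN, TP + FP + TN + FN),
        recall=recall,
        specificity=_ratio(TN, FP + TN),
        precision=precision,
        f1=f1,
    )


def per_class_rates(cm: ConfusionMatrix) -> tuple[dict[str, float | None], float | None]:
    """Per-class correct answer rates (diagonal / row sum) and the overall
    rate (trace / total); a zero row yields ``None`` for that class."""
    c = cm.counts
    rates = {
        lab: _ratio(int(c[i, i]), int(c[i].sum()))
        for i, lab in enumerate(MOTION_LABELS)
    }
    overall = _ratio(int(np.trace(c)), int(c.sum()))
    return rates, overall


# ---------------------------------------------------------------------------
# Reference matrix fixtures


def parse_matrix_text(text: str) -> ConfusionMatrix:
    """Parse the documented 8x8 text format: '#' comments, a header row of
    the eight class names, then one row per true class: label + 8 counts."""
    rows = {}
    header: list[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if header is None:
            header = parts
            if tuple(header) != MOTION_LABELS:
                raise ValueError(
                    f"header must list the canonical classes {MOTION_LABELS}, got {header}"
                )
            continue
        lab, vals = parts[0], parts[1:]
        if len(vals) != N:
            raise ValueError(f"row {lab!r} has {len(vals)} counts, expected {N}")
        rows[MotionLabel(lab)] = [int(v) for v in vals]
    if header is None or set(rows) != set(MOTION_LABELS):
        raise ValueError("matrix text must contain a header and all eight class rows")
    counts = np.array([rows[lab] for lab in MOTION_LABELS], dtype=np.int64)
    return ConfusionMatrix(counts)


def load_matrix(path: str | Path) -> ConfusionMatrix:
    return parse_matrix_text(Path(path).read_text())


def load_reference_matrix(classifier: str) -> ConfusionMatrix:
    """The shipped reference confusion matrix for ``'lstm'`` or ``'cnn3d'``."""
    names = {"lstm": "reference_confusion_lstm.txt", "cnn3d": "reference_confusion_cnn3d.txt"}
    if classifier not in names:
        raise ValueError("classifier must be 'lstm' or 'cnn3d'")
    text = resources.files("thermofall.data").joinpath(names[classifier]).read_text()
    return parse_matrix_text(text)


# ---------------------------------------------------------------------------
# Subject-grouped cross-validation


def make_folds(
    subjects: Sequence[str], seed: int = 0, test_size: int = 2
) -> list[tuple[list[str], list[str]]]:
    """Partition subjects into disjoint test groups of ``test_size``.

    With the canonical 16 subjects this yields the 8-fold plan: each fold
    trains on 14 subjects and tests on a distinct pair, and every subject
    is tested exactly once.  Pairing is a seeded shuffle.
    """
    subjects = list(dict.fromkeys(subjects))  # stable unique
    if len(subjects) % test_size != 0:
        raise ValueError(
            f"{len(subjects)} subjects do not divide into test groups of {test_size}"
        )
    rng = np.random.default_rng(seed)
    order = [subjects[i] for i in rng.permutation(len(subjects))]
    folds = []
    for start in range(0, len(order), test_size):
        test = sorted(order[start : start + test_size])
        train = sorted(s for s in subjects if s not in test)
        folds.append((train, test))
    return folds


def grouped_cv_rate(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    seed: int = 0,
    test_size: int = 2,
) -> tuple[float, ConfusionMatrix]:
    """Overall correct answer rate under subject-grouped CV.

    Clones the estimator per fold (fresh weights), accumulates one pooled
    confusion matrix over all folds, and returns (trace/total, matrix).
    """
    from sklearn.base import clone

    folds = make_folds(list(groups), seed=seed, test_size=test_size)
    pooled = np.zeros((N, N), dtype=np.int64)
    for train_subj, test_subj in folds:
        tr = np.isin(groups, train_subj)
        te = np.isin(groups, test_subj)
        est = clone(estimator)
        est.fit(X[tr], y[tr])
        cm = confusion_matrix(list(y[te]), list(est.predict(X[te])))
        pooled += cm.counts
    cm_all = ConfusionMatrix(pooled)
    _, overall = per_class_rates(cm_all)
    return float(overall), cm_all


def frame_sweep(
    dataset,
    model,
    T_values: Sequence[int],
    estimator_factory,
    to_inputs,
    seed: int = 0,
    test_size: int = 2,
) -> pd.DataFrame:
    """Cross-validated overall rate for each candidate window length.

    ``estimator_factory(T)`` builds a fresh classifier; ``to_inputs`` is
    :func:`thermofall.pipeline.dataset_to_windows` or
    :func:`~thermofall.pipeline.dataset_to_features`.  Window lengths must
    lie in [10, 20] (about 0.7-1.3 s at 15 Hz, bracketing the duration of
    the one-shot motions).
    """
    T_values = list(T_values)
    if not T_values:
        raise ValueError("empty list of window lengths")
    for T in T_values:
        if not 10 <= T <= 20:
            raise ValueError(f"window length {T} outside [10, 20]")
    rows = []
    for T in T_values:
        X, y, groups = to_inputs(dataset, model, T=T)
        rate, _ = grouped_cv_rate(
            estimator_factory(T), X, y, groups, seed=seed, test_size=test_size
        )
        rows.append({"T": T, "overall_rate": rate, "seed": seed})
    return pd.DataFrame(rows)
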