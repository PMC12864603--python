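"""Classification metrics, cross-validation, paired tests, length ablation.

The metric suite is the standard confusion-matrix family: Matthews
correlation coefficient, accuracy, precision, sensitivity and specificity.
Degenerate denominators (an empty predicted-positive set, a one-class
fold) are reported as 0 with an explicit flag rather than NaN, so
aggregation over folds stays well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import clone

from .data import ConfigurationError, DatasetManifest, make_folds, split_by_length


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    mcc: float
    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    counts: ConfusionCounts
    degenerate: tuple[str, ...] = ()

    def as_dict(self) -> dict:
        return {"mcc": self.mcc, "accuracy": self.accuracy,
                "precision": self.precision, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "n": self.counts.n}


METRIC_NAMES = ("mcc", "accuracy", "precision", "sensitivity", "specificity")


def confusion(predictions, truth) -> ConfusionCounts:
    """Tally the 2x2 table from Prediction objects (or 0/1 labels) vs truth.

    ``truth`` may be a mapping id -> label (ids are then aligned and must
    match) or an array positionally aligned with ``predictions``.
    """
    if hasattr(truth, "get"):
        labels = []
        for p in predictions:
            if p.id not in truth:
                raise ConfigurationError(f"no truth label for id {p.id!r}")
            labels.append(truth[p.id])
        truth_arr = np.asarray(labels)
    else:
        truth_arr = np.asarray(truth)
        if len(truth_arr) != len(predictions):
            raise ConfigurationError("predictions and truth differ in length")
    pred_arr = np.array([p.label if hasattr(p, "label") else int(p)
                         for p in predictions])
    tp = int(np.sum((pred_arr == 1) & (truth_arr == 1)))
    tn = int(np.sum((pred_arr == 0) & (truth_arr == 0)))
    fp = int(np.sum((pred_arr == 1) & (truth_arr == 0)))
    fn = int(np.sum((pred_arr == 0) & (truth_arr == 1)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Exact evaluation of the five confusion-matrix metrics."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.n == 0:
        raise ConfigurationError("empty confusion table")
    degenerate: list[str] = []
    denom = math.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0.0:
        mcc = 0.0
        degenerate.append("mcc_zero_denominator")
    else:
        mcc = (tp * tn - fp * fn) / denom
    accuracy = (tp + tn) / counts.n
    if tp + fp == 0:
        precision = 0.0
        degenerate.append("precision_no_predicted_positives")
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        sensitivity = 0.0
        degenerate.append("sensitivity_no_positives")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        specificity = 0.0
        degenerate.append("specificity_no_negatives")
    else:
        specificity = tn / (tn + fp)
    return MetricReport(mcc=mcc, accuracy=accuracy, precision=precision,
                        sensitivity=sensitivity, specificity=specificity,
                        counts=counts, degenerate=tuple(degenerate))


def evaluate_predictions(predictions, truth) -> MetricReport:
    return compute_metrics(confusion(predictions, truth))


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    reports: list[MetricReport]
    mean: dict[str, float] = field(init=False)
    std: dict[str, float] = field(init=False)

    def __post_init__(self):
        values = {m: [getattr(r, m) for r in self.reports] for m in METRIC_NAMES}
        self.mean = {m: float(np.mean(v)) for m, v in values.items()}
        self.std = {m: float(np.std(v, ddof=1)) if len(self.reports) > 1 else 0.0
                    for m, v in values.items()}

    def per_fold(self, metric: str) -> np.ndarray:
        return np.array([getattr(r, metric) for r in self.reports])


def cross_validate(estimator, manifest: DatasetManifest, k: int = 5,
                   seed: int = 0) -> CVResult:
    """Stratified k-fold CV: train on k-1 folds, test on the held-out fold.

    The estimator is cloned per fold; estimators that hold out an internal
    validation slice for early stopping do so from the training folds only,
    leaving the test fold untouched.
    """
    folds = make_folds(manifest, k=k, seed=seed)
    reports = []
    for fold in range(k):
        train_man = manifest.subset(folds.train_indices(fold))
        test_man = manifest.subset(folds.test_indices(fold))
        est = clone(estimator)
        est.fit(train_man.sequences(), train_man.labels())
        pred = est.predict(test_man.sequences())
        reports.append(compute_metrics(confusion(pred, test_man.labels())))
    return CVResult(reports=reports)


def paired_t_test(metric_a: Sequence[float],
                  metric_b: Sequence[float]) -> tuple[float, float]:
    """Classical paired t-test on fold-wise differences (df = k - 1).

    Zero-variance differences: p = 1.0 when the mean difference is also 0,
    otherwise (t, p) = (inf with the sign of the mean difference, 0.0),
    flagging a fully systematic offset.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ConfigurationError("need two equal-length vectors of >= 2 folds")
    d = a - b
    k = len(d)
    sd = d.std(ddof=1)
    if sd <= 1e-12 * max(1.0, float(np.abs(d).max(initial=0.0))):
        if abs(d.mean()) <= 1e-12:
            return 0.0, 1.0
        return math.copysign(math.inf, d.mean()), 0.0
    t = d.mean() / (sd / math.sqrt(k))
    from scipy.stats import t as t_dist
    p = 2.0 * t_dist.sf(abs(t), df=k - 1)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# length-stratified ablation
# ---------------------------------------------------------------------------

def length_stratified_eval(estimator, manifest: DatasetManifest,
                           threshold: int = 15) -> dict[str, MetricReport | None]:
    """Evaluate a fitted estimator separately on short (< threshold) and long
    (>= threshold) peptides; an empty stratum is reported as None."""
    short, long_ = split_by_length(manifest, threshold=threshold)
    out: dict[str, MetricReport | None] = {}
    for name, stratum in (("short", short), ("long", long_)):
        if not len(stratum):
            out[name] = None
            continue
        pred = estimator.predict(stratum.sequences())
        out[name] = compute_metrics(confusion(pred, stratum.labels()))
    return out


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def grid_search(estimator, param_grid: Sequence[dict],
                manifest: DatasetManifest, k: int = 5,
                seed: int = 0) -> list[tuple[dict, CVResult]]:
    """Exhaustive CV over a finite config grid, ranked by mean accuracy.

    Ties break by mean MCC, then by grid order.  Deterministic for a seed.
    """
    if not param_grid:
        raise ConfigurationError("empty parameter grid")
    results = []
    for order, cfg in enumerate(param_grid):
        est = clone(estimator).set_params(**cfg)
        cv = cross_validate(est, manifest, k=k, seed=seed)
        results.append((order, cfg, cv))
    results.sort(key=lambda item: (-item[2].mean["accuracy"],
                                   -item[2].mean["mcc"], item[0]))
    return [(cfg, cv) for _, cfg, cv in results]
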