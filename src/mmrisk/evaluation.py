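"""Discrimination, calibration, and clinical-utility metrics.

All metrics operate on an out-of-fold prediction table with one row per
patient: ``patient_id, label, probability, fold``.  Discrimination is
summarized by AUC (equivalently the Mann-Whitney pairwise statistic,
ties counted 1/2) and AUPR (step-interpolated area under the
precision-recall curve); the operating threshold maximizes the Youden
index TPR - FPR; probability accuracy uses the Brier score
``mean((y - p)^2)``; clinical utility uses decision-curve net benefit

``NB(p_t) = TP(p_t)/N - FP(p_t)/N * p_t / (1 - p_t)``

against the treat-all line ``pi - (1 - pi) * p_t / (1 - p_t)`` and the
treat-none line at 0.  Confidence intervals are percentile bootstrap over
patient-level resamples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricsReport",
    "DecisionCurve",
    "auc",
    "aupr",
    "youden_threshold",
    "recall_at",
    "brier",
    "calibration_curve",
    "decision_curve",
    "bootstrap_ci",
    "compute_report",
]


def _validate(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    y = table["label"].to_numpy(dtype=int)
    p = table["probability"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return y, p


@dataclass
class MetricsReport:
    auc: tuple[float, float, float]
    aupr: tuple[float, float, float]
    recall_at_youden: tuple[float, float, float]
    brier: tuple[float, float, float]
    youden_threshold: float

    def as_dict(self) -> dict:
        out = {}
        for name in ("auc", "aupr", "recall_at_youden", "brier"):
            point, lo, hi = getattr(self, name)
            out[name] = {"point": point, "ci_low": lo, "ci_high": hi}
        out["youden_threshold"] = self.youden_threshold
        return out


@dataclass
class DecisionCurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray


def auc(table: pd.DataFrame) -> float:
    """Area under the ROC curve (pairwise concordance, ties counted 1/2)."""
    y, p = _validate(table)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(roc_auc_score(y, p))


def aupr(table: pd.DataFrame) -> float:
    """Step-interpolated area under the precision-recall curve."""
    y, p = _validate(table)
    if y.sum() == 0:
        raise ValueError("AUPR undefined: no positives")
    return float(average_precision_score(y, p))


def youden_threshold(table: pd.DataFrame) -> float:
    """Observed score maximizing TPR - FPR; ties go to the higher threshold."""
    y, p = _validate(table)
    if len(np.unique(y)) < 2:
        raise ValueError("Youden threshold undefined: only one class present")
    candidates = np.unique(p)
    best_thr, best_j = candidates[0], -np.inf
    for thr in candidates:
        pred = p >= thr
        tpr = (pred & (y == 1)).sum() / (y == 1).sum()
        fpr = (pred & (y == 0)).sum() / (y == 0).sum()
        j = tpr - fpr
        if j >= best_j:  # >= : ties broken toward the higher threshold
            best_j, best_thr = j, thr
    return float(best_thr)


def recall_at(table: pd.DataFrame, threshold: float) -> float:
    """Sensitivity TP / (TP + FN) when p >= threshold calls a positive."""
    y, p = _validate(table)
    n_pos = (y == 1).sum()
    if n_pos == 0:
        raise ValueError("recall undefined: no positives")
    return float(((p >= threshold) & (y == 1)).sum() / n_pos)


def brier(table: pd.DataFrame) -> float:
    y, p = _validate(table)
    return float(np.mean((y - p) ** 2))


def calibration_curve(table: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width reliability bins; empty bins are omitted.

    Returns columns ``mean_predicted``, ``observed_rate``, ``count``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y, p = _validate(table)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1]), 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            rows.append((float(p[mask].mean()), float(y[mask].mean()), int(mask.sum())))
    return pd.DataFrame(rows, columns=["mean_predicted", "observed_rate", "count"])


def decision_curve(table: pd.DataFrame, thresholds: np.ndarray | None = None) -> DecisionCurve:
    """Net benefit of the model vs treat-all and treat-none strategies."""
    if thresholds is None:
        thresholds = np.arange(0.01, 0.501, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    y, p = _validate(table)
    n = len(y)
    prevalence = y.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, (t, w) in enumerate(zip(thresholds, odds)):
        pred = p >= t
        tp = (pred & (y == 1)).sum()
        fp = (pred & (y == 0)).sum()
        nb_model[i] = tp / n - fp / n * w
    nb_all = prevalence - (1.0 - prevalence) * odds
    return DecisionCurve(thresholds, nb_model, nb_all, np.zeros_like(thresholds))


def bootstrap_ci(
    table: pd.DataFrame,
    metric,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval over patient-level resamples.

    Resamples on which the metric is undefined (e.g. single-class) are
    redrawn; if more than half of the attempts fail the metric is deemed
    unstable and an error is raised.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(table)
    values = []
    failures = 0
    attempts = 0
    while len(values) < n_boot:
        attempts += 1
        if failures > max(n_boot, attempts) * 0.5 and attempts > 2 * n_boot:
            raise ValueError("metric undefined on more than half of bootstrap resamples")
        sample = table.iloc[rng.integers(0, n, size=n)]
        try:
            values.append(metric(sample))
        except ValueError:
            failures += 1
            continue
    if failures:
        warnings.warn(f"{failures} degenerate bootstrap resamples redrawn", RuntimeWarning)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compute_report(table: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MetricsReport:
    """Point estimates with bootstrap CIs for the four headline metrics.

    The recall CI keeps the Youden threshold fixed at its full-table value
    across resamples.
    """
    thr = youden_threshold(table)
    metrics = {
        "auc": auc,
        "aupr": aupr,
        "recall_at_youden": lambda t: recall_at(t, thr),
        "brier": brier,
    }
    results = {}
    for i, (name, fn) in enumerate(metrics.items()):
        point = fn(table)
        lo, hi = bootstrap_ci(table, fn, n_boot=n_boot, seed=seed + i)
        lo, hi = min(lo, point), max(hi, point)
        results[name] = (float(point), float(lo), float(hi))
    return MetricsReport(youden_threshold=thr, **results)
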