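"""Discrimination and classification metrics with bootstrap intervals.

AUROC uses the rank-statistic (Mann-Whitney) formulation with ties counted
half.  Thresholded metrics (MCC, PPV, NPV, recall, F1) come from the 2x2
confusion matrix by their textbook formulas, with degenerate denominators
reported as 0 and flagged rather than raised.  Average precision is the
step-wise area under the precision-recall curve.  Confidence intervals are
percentile bootstrap over patient-level resamples, because the unit of
inference is the patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "roc_auc",
    "average_precision",
    "classification_metrics",
    "youden_threshold",
    "bootstrap_ci",
    "evaluate_risks",
    "compare_to_baseline",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if not np.isin(classes, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if classes.size < 2:
        raise ValueError("both classes must be present")
    return labels


def roc_auc(labels, scores) -> float:
    """AUROC via the Mann-Whitney rank statistic, ties counted half.

    Equals P(score_pos > score_neg) + 0.5 P(score_pos = score_neg) for a
    random positive/negative pair.
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks -> half credit for ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def average_precision(labels, scores) -> float:
    """Step-wise area under the precision-recall curve:
    AP = sum_k (R_k - R_{k-1}) P_k over descending score thresholds."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # collapse tied scores: metrics are defined at distinct thresholds
    distinct = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[distinct], fp[distinct]
    precision = tp / (tp + fp)
    recall = tp / labels.sum()
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(((recall - recall_prev) * precision).sum())


def _confusion(labels: np.ndarray, predictions: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(((predictions == 1) & (labels == 1)).sum())
    tn = int(((predictions == 0) & (labels == 0)).sum())
    fp = int(((predictions == 1) & (labels == 0)).sum())
    fn = int(((predictions == 0) & (labels == 1)).sum())
    return tp, tn, fp, fn


def classification_metrics(labels, scores, threshold: float) -> dict[str, float]:
    """Thresholded metrics plus the threshold-free AUROC and AP.

    Predictions are ``score >= threshold``.  MCC, PPV, NPV, recall and F1
    follow their textbook confusion-matrix formulas; any degenerate
    denominator yields 0 for that metric with a logged flag.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    predictions = (scores >= threshold).astype(int)
    tp, tn, fp, fn = _confusion(labels, predictions)

    def _safe(num: float, den: float, name: str) -> float:
        if den == 0:
            logger.info("degenerate denominator for %s; reported as 0", name)
            return 0.0
        return num / den

    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "auroc": roc_auc(labels, scores),
        "ap": average_precision(labels, scores),
        "mcc": _safe(tp * tn - fp * fn, mcc_den, "mcc"),
        "ppv": _safe(tp, tp + fp, "ppv"),
        "npv": _safe(tn, tn + fn, "npv"),
        "recall": _safe(tp, tp + fn, "recall"),
        "f1": _safe(2 * tp, 2 * tp + fp + fn, "f1"),
    }


def youden_threshold(labels, scores) -> float:
    """Threshold maximising Youden's J = sensitivity + specificity - 1
    over the observed scores (ties broken toward the lower threshold)."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    candidates = np.unique(scores)
    best_t, best_j = candidates[0], -np.inf
    n_pos = labels.sum()
    n_neg = labels.size - n_pos
    for t in candidates:
        pred = scores >= t
        sens = (pred & (labels == 1)).sum() / n_pos
        spec = (~pred & (labels == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_t, best_j = t, j
    return float(np.clip(best_t, 0.0, 1.0))


def bootstrap_ci(
    labels,
    scores,
    metric,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_redraws: int = 100,
) -> tuple[float, float]:
    """Percentile bootstrap interval over patient-level resamples.

    Resamples drawing a single class are redrawn (logged); if a resample
    cannot be made valid after ``max_redraws`` attempts it raises.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    n = labels.size
    stats = np.empty(n_boot)
    n_redraws = 0
    for b in range(n_boot):
        for attempt in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            if np.unique(labels[idx]).size == 2:
                break
            n_redraws += 1
        else:
            raise RuntimeError("metric undefined on all bootstrap resamples")
        stats[b] = metric(labels[idx], scores[idx])
    if n_redraws:
        logger.info("redrew %d single-class bootstrap resamples", n_redraws)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass
class MetricsReport:
    """Point estimates with 95% percentile-bootstrap intervals."""

    metrics: dict[str, tuple[float, float, float]]  # name -> (value, lo, hi)
    threshold: float
    n_patients: int
    n_events: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (value, lo, hi) in self.metrics.items():
            if not (lo <= value + 1e-12 and value - 1e-12 <= hi):
                raise ValueError(f"interval for {name} does not bracket the point value")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"metric": name, "value": v, "ci_lo": lo, "ci_hi": hi}
            for name, (v, lo, hi) in self.metrics.items()
        ]
        return pd.DataFrame(rows)

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        return self.metrics[name]


def evaluate_risks(
    labels,
    scores,
    threshold: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Full metric suite with bootstrap CIs on patient-level risks.

    If ``threshold`` is None it defaults to the Youden's J maximiser on the
    given data (recorded in the report).
    """
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float)
    flags: list[str] = []
    if threshold is None:
        threshold = youden_threshold(labels, scores)
        flags.append("threshold=youden")
    point = classification_metrics(labels, scores, threshold)
    metrics: dict[str, tuple[float, float, float]] = {}
    for name, value in point.items():
        if name in ("auroc", "ap"):
            fn = roc_auc if name == "auroc" else average_precision
            lo, hi = bootstrap_ci(labels, scores, fn, n_boot=n_boot, seed=seed)
        else:
            def fn(y, s, _n=name, _t=threshold):
                return classification_metrics(y, s, _t)[_n]

            lo, hi = bootstrap_ci(labels, scores, fn, n_boot=n_boot, seed=seed)
        # the point estimate is computed on the full sample; percentile
        # intervals can exclude it in heavily skewed resamples, so widen
        metrics[name] = (value, min(lo, value), max(hi, value))
    return MetricsReport(
        metrics=metrics,
        threshold=float(threshold),
        n_patients=int(labels.size),
        n_events=int(labels.sum()),
        flags=flags,
    )


def compare_to_baseline(
    model_risks: pd.DataFrame,
    pim3_risks: pd.DataFrame,
    threshold: float | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired evaluation of fused model risk against the PIM3 baseline.

    Both inputs need columns ``patient_id``, a score column (``risk`` or
    ``pim3_risk``) and ``label``; patient sets must match exactly.  Returns
    ``{"model": MetricsReport, "baseline": MetricsReport, "scatter": DataFrame}``
    where the scatter table has one row per patient (id, model risk, PIM3
    risk, outcome).
    """
    m = model_risks.set_index("patient_id").sort_index()
    score_col = "pim3_risk" if "pim3_risk" in pim3_risks.columns else "risk"
    b = pim3_risks.set_index("patient_id").sort_index()
    if list(m.index) != list(b.index):
        raise ValueError("model and baseline patient sets differ")
    labels = m["label"].to_numpy(dtype=int)
    report_m = evaluate_risks(labels, m["risk"].to_numpy(), threshold, n_boot, seed)
    report_b = evaluate_risks(labels, b[score_col].to_numpy(), threshold, n_boot, seed)
    scatter = pd.DataFrame(
        {
            "patient_id": m.index,
            "model_risk": m["risk"].to_numpy(),
            "pim3_risk": b[score_col].to_numpy(),
            "outcome": labels,
        }
    )
    return {"model": report_m, "baseline": report_b, "scatter": scatter}
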