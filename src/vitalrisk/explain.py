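"""Model-agnostic Shapley attribution, per-window risk traces and
survival-to-non-survival transition detection.

Attributions are computed in probability space against a background sample:
the value of a coalition S is the model's mean prediction with features in S
taken from the instance and the rest from background rows.  Exact mode
enumerates all coalitions (feasible for small feature sets); sampled mode
uses seeded permutation sampling, whose telescoping construction satisfies
local accuracy exactly with respect to the sampled background rows.

A risk trace splits one patient's monitored episode into consecutive
intervals, featurises each, predicts the per-window risk, and attributes it.
A transition event marks the window where a feature's contribution flips
from favouring survival (<= 0) to favouring death (> 0).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CHANNELS
from .features import (
    assemble_sample,
    feature_columns,
    window_statistics,
)
from .modeling import TrainedModel
from .preprocessing import PatientZGrid

logger = logging.getLogger(__name__)

__all__ = [
    "AttributionVector",
    "RiskTrace",
    "TransitionEvent",
    "shapley_attributions",
    "risk_trace",
    "detect_transitions",
]


@dataclass
class AttributionVector:
    """Signed per-feature contributions to one prediction.

    ``base_value`` is the expected prediction over the background;
    local accuracy requires base + sum(contributions) = prediction.
    """

    feature_names: list[str]
    contributions: np.ndarray
    base_value: float
    prediction: float
    standard_errors: np.ndarray | None = None

    def local_accuracy_gap(self) -> float:
        return abs(self.base_value + float(self.contributions.sum()) - self.prediction)

    def as_series(self) -> pd.Series:
        return pd.Series(self.contributions, index=self.feature_names)


@dataclass
class TransitionEvent:
    """A feature's contribution flipping from <= 0 to > 0 between windows."""

    window_index: int
    window_start_s: float
    feature: str
    contribution_before: float
    contribution_after: float

    def __post_init__(self) -> None:
        if not (self.contribution_before <= 0.0 < self.contribution_after):
            raise ValueError("transition requires contribution before <= 0 < after")


@dataclass
class RiskTrace:
    """Ordered per-window risks and attributions for one patient."""

    patient_id: str
    window_starts_s: list[float]
    window_ends_s: list[float]
    risks: list[float]
    attributions: list[AttributionVector] = field(repr=False)

    def __len__(self) -> int:
        return len(self.risks)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: one row per (window, feature)."""
        rows = []
        for i, att in enumerate(self.attributions):
            for name, phi in zip(att.feature_names, att.contributions):
                rows.append(
                    {
                        "patient_id": self.patient_id,
                        "window_index": i,
                        "window_start_s": self.window_starts_s[i],
                        "risk": self.risks[i],
                        "feature": name,
                        "contribution": float(phi),
                    }
                )
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        """Dashboard-ready JSON: per-window risk, base value and named
        contributions."""
        payload = {
            "patient_id": self.patient_id,
            "windows": [
                {
                    "start_s": self.window_starts_s[i],
                    "end_s": self.window_ends_s[i],
                    "risk": self.risks[i],
                    "base_value": att.base_value,
                    "contributions": dict(
                        zip(att.feature_names, map(float, att.contributions))
                    ),
                }
                for i, att in enumerate(self.attributions)
            ],
        }
        return json.dumps(payload, indent=2)

    def feature_importance(self) -> pd.DataFrame:
        """Global-over-trace importance: mean |contribution| per feature,
        descending."""
        mean_abs = np.mean([np.abs(a.contributions) for a in self.attributions], axis=0)
        df = pd.DataFrame(
            {"feature": self.attributions[0].feature_names, "mean_abs_contribution": mean_abs}
        )
        return df.sort_values("mean_abs_contribution", ascending=False, ignore_index=True)

    def plot(self, ax=None, top_k: int = 5):
        """Risk trajectory with the top-|contribution| features annotated."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        t = np.asarray(self.window_starts_s) / 60.0
        ax.plot(t, self.risks, "r-^", label="predicted risk")
        mean_abs = np.mean(
            [np.abs(a.contributions) for a in self.attributions], axis=0
        )
        names = self.attributions[0].feature_names
        top = np.argsort(-mean_abs)[:top_k]
        for j in top:
            ax.plot(
                t,
                [a.contributions[j] for a in self.attributions],
                "--",
                alpha=0.6,
                label=names[j],
            )
        ax.set_xlabel("minutes from monitoring start")
        ax.set_ylabel("risk / contribution")
        ax.legend(fontsize=8)
        return ax


def _coalition_values(
    predict_fn, x: np.ndarray, background: np.ndarray, masks: np.ndarray
) -> np.ndarray:
    """v(S) for every mask row: mean prediction with masked features from x,
    the rest from each background row, averaged over the background."""
    n_bg = background.shape[0]
    values = np.empty(masks.shape[0])
    chunk = max(1, 65536 // max(n_bg, 1))
    for start in range(0, masks.shape[0], chunk):
        block = masks[start : start + chunk]
        # masked coordinates from the instance, the rest from each background row
        reps = np.where(block[:, None, :], x[None, None, :], background[None, :, :])
        preds = predict_fn(reps.reshape(-1, x.size))
        values[start : start + chunk] = preds.reshape(block.shape[0], n_bg).mean(axis=1)
    return values


def _exact_shapley(
    predict_fn, x: np.ndarray, background: np.ndarray
) -> tuple[np.ndarray, float, float]:
    d = x.size
    n_masks = 1 << d
    masks = (
        (np.arange(n_masks)[:, None] >> np.arange(d)[None, :]) & 1
    ).astype(bool)
    v = _coalition_values(predict_fn, x, background, masks)
    sizes = masks.sum(axis=1)
    # Shapley kernel weights |S|! (d - |S| - 1)! / d!
    log_fact = np.cumsum(np.log(np.arange(1, d + 1)))
    log_fact = np.r_[0.0, log_fact]  # log k! for k = 0..d

    def weight(s: int) -> float:
        return float(np.exp(log_fact[s] + log_fact[d - s - 1] - log_fact[d]))

    phi = np.zeros(d)
    for j in range(d):
        has_j = masks[:, j]
        without = np.where(~has_j)[0]
        with_j = without | (1 << j)
        w = np.array([weight(s) for s in sizes[without]])
        phi[j] = float((w * (v[with_j] - v[without])).sum())
    base = float(v[0])
    pred = float(v[-1])
    return phi, base, pred


def _sampled_shapley(
    predict_fn,
    x: np.ndarray,
    background: np.ndarray,
    n_perms: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float, np.ndarray]:
    d = x.size
    n_bg = background.shape[0]
    contribs = np.zeros((n_perms, d))
    bg_preds = np.empty(n_perms)
    for k in range(n_perms):
        perm = rng.permutation(d)
        b = background[rng.integers(n_bg)]
        rows = np.empty((d + 1, d))
        rows[0] = b
        current = b.copy()
        for step, j in enumerate(perm, start=1):
            current[j] = x[j]
            rows[step] = current
        preds = predict_fn(rows)
        deltas = np.diff(preds)
        contribs[k, perm] = deltas
        bg_preds[k] = preds[0]
    phi = contribs.mean(axis=0)
    se = contribs.std(axis=0, ddof=1) / np.sqrt(n_perms) if n_perms > 1 else np.zeros(d)
    base = float(bg_preds.mean())
    pred = float(predict_fn(x[None, :])[0])
    return phi, base, pred, se


def shapley_attributions(
    predict_fn,
    instance,
    background,
    mode: str = "sampled",
    n_perms: int = 200,
    seed: int = 0,
    feature_names: list[str] | None = None,
    exact_cap: int = 12,
) -> AttributionVector:
    """Shapley attribution of one prediction against a background set.

    Parameters
    ----------
    predict_fn
        Maps an (n, d) array to n probabilities.
    instance
        Length-d vector (array or Series; a Series supplies feature names).
    background
        (n_bg, d) array of reference rows; must be non-empty.
    mode
        "exact" enumerates all 2^d coalitions (requires d <= ``exact_cap``);
        "sampled" uses seeded permutation sampling with ``n_perms`` >= 100.
    """
    if isinstance(instance, pd.Series):
        feature_names = feature_names or list(instance.index)
        x = instance.to_numpy(dtype=float)
    else:
        x = np.asarray(instance, dtype=float).ravel()
    background = np.asarray(background, dtype=float)
    if background.ndim == 1:
        background = background[None, :]
    if background.shape[0] == 0:
        raise ValueError("background set is empty")
    if background.shape[1] != x.size:
        raise ValueError("background width differs from instance length")
    names = feature_names or [f"x{j}" for j in range(x.size)]

    if mode == "exact":
        if x.size > exact_cap:
            raise ValueError(
                f"exact mode enumerates 2^d coalitions; d={x.size} exceeds cap {exact_cap}"
            )
        phi, base, pred = _exact_shapley(predict_fn, x, background)
        se = None
    elif mode == "sampled":
        if n_perms < 100:
            raise ValueError("sampled mode requires n_perms >= 100")
        rng = np.random.default_rng(seed)
        phi, base, pred, se = _sampled_shapley(predict_fn, x, background, n_perms, rng)
    else:
        raise ValueError(f"unknown mode: {mode}")
    return AttributionVector(
        feature_names=list(names),
        contributions=phi,
        base_value=base,
        prediction=pred,
        standard_errors=se,
    )


def risk_trace(
    model: TrainedModel,
    grid: PatientZGrid,
    record,
    background: np.ndarray,
    interval_minutes: float = 10.0,
    mode: str = "sampled",
    n_perms: int = 200,
    seed: int = 0,
) -> RiskTrace:
    """Dynamic per-interval risk with attributions for one patient.

    The standardised stream is cut into consecutive non-overlapping
    ``interval_minutes`` windows; each is featurised (same 112-feature
    contract as training), predicted and attributed.  Returns an empty trace
    (logged) if no complete interval fits.
    """
    w = int(round(interval_minutes * 60.0 / grid.sampling_interval_s))
    n_windows = grid.times.size // w
    if n_windows == 0:
        logger.warning(
            "patient %s: stream shorter than one %.0f-min interval; empty trace",
            grid.patient_id, interval_minutes,
        )
        return RiskTrace(grid.patient_id, [], [], [], [])
    record = record if isinstance(record, dict) else dict(record)
    cols = feature_columns()
    starts, ends, risks, atts = [], [], [], []
    for k in range(n_windows):
        sl = slice(k * w, (k + 1) * w)
        times = grid.times[sl]
        stats = {
            ch: window_statistics(grid.z[j, sl], times) for j, ch in enumerate(CHANNELS)
        }
        vec = assemble_sample(record, stats)
        x = pd.Series(vec)[cols]
        # common random numbers across windows: every window is attributed
        # with the same permutations and background draws, so contribution
        # differences between windows reflect the data, not Monte Carlo noise
        att = shapley_attributions(
            model.predict_proba_array,
            x,
            background,
            mode=mode,
            n_perms=n_perms,
            seed=seed,
        )
        starts.append(float(times[0]))
        ends.append(float(times[-1] + grid.sampling_interval_s))
        risks.append(att.prediction)
        atts.append(att)
    return RiskTrace(grid.patient_id, starts, ends, risks, atts)


def detect_transitions(trace: RiskTrace, dead_zone: float = 0.0) -> list[TransitionEvent]:
    """Survival-to-non-survival transition moments in a risk trace.

    For each feature, an event is emitted at every window where its
    contribution moves from <= 0 to > 0 (strict sign flip toward the
    non-survival outcome).  ``dead_zone`` > 0 adds a symmetric band that
    both sides must clear, suppressing chatter around zero (off by
    default).  Events are ordered by window index then feature name.
    """
    if len(trace) < 2:
        raise ValueError("transition detection needs a trace with >= 2 windows")
    events: list[TransitionEvent] = []
    names = trace.attributions[0].feature_names
    contrib = np.vstack([a.contributions for a in trace.attributions])
    for i in range(1, len(trace)):
        before, after = contrib[i - 1], contrib[i]
        flip = (before <= -dead_zone) & (after > dead_zone)
        for j in sorted(np.where(flip)[0], key=lambda j: names[j]):
            events.append(
                TransitionEvent(
                    window_index=i,
                    window_start_s=trace.window_starts_s[i],
                    feature=names[j],
                    contribution_before=float(before[j]),
                    contribution_after=float(after[j]),
                )
            )
    return events
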