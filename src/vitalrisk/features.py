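"""Window extraction and featurisation.

Each 10-minute window of a patient's standardised stream is summarised by 13
statistics per channel (central tendency, dispersion, shape, entropy,
spectral power, trend) and joined with 21 encoded static EHR variables into
a fixed-order 112-element feature vector labelled with the patient's
outcome.

Class balancing happens at extraction time: deceased (minority) patients are
windowed with an overlapping stride of ``minority_step_points`` grid points,
survivors with consecutive non-overlapping windows, so that at ~6% mortality
and ~1 Hz sampling the two classes contribute comparable sample counts.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from numba import njit
from scipy.stats import kurtosis as _kurtosis
from scipy.stats import skew as _skew

from .config import CHANNELS, WindowSpec
from .preprocessing import PatientZGrid

logger = logging.getLogger(__name__)

__all__ = [
    "STAT_NAMES",
    "STATIC_FEATURES",
    "feature_columns",
    "window_statistics",
    "sample_entropy",
    "shannon_entropy",
    "extract_windows",
    "encode_static",
    "assemble_sample",
    "build_samples",
]

#: The 13 per-channel window statistics, in feature-vector order.
STAT_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "sd",
    "min",
    "max",
    "range",
    "iqr",
    "skewness",
    "kurtosis",
    "shannon_entropy",
    "sample_entropy",
    "psd_power",
    "slope",
)

#: The 21 encoded static EHR variables, in feature-vector order.  Categorical
#: fields use a fixed codebook: gender -> male indicator; diagnosis group and
#: critical incident -> one-hot; vasoactive infusion -> single/multiple
#: indicators (none = both zero); booleans -> 0/1.
STATIC_FEATURES: tuple[str, ...] = (
    "age_months",
    "age_group_ord",
    "weight_kg",
    "gender_male",
    "dx_respiratory",
    "dx_cardiovascular",
    "dx_neurological",
    "dx_infection",
    "dx_gastrointestinal",
    "dx_trauma",
    "dx_other",
    "invasive_ventilation",
    "vaso_single",
    "vaso_multiple",
    "inhaled_no",
    "ecmo",
    "pim3_risk",
    "ci_none",
    "ci_patient",
    "ci_equipment",
    "transport_minutes",
)

_AGE_GROUP_ORD = {"newborn": 0, "infant": 1, "preschool": 2, "school": 3, "adolescent": 4}

# Binned Shannon entropy: 16 equal-width bins over [-5, 5] Z; out-of-range
# values fall into the edge bins.
_ENTROPY_BINS = np.linspace(-5.0, 5.0, 17)


def feature_columns() -> list[str]:
    """Fixed, documented ordering of all 112 feature columns
    (21 static then, channel-major, 7 x 13 derived)."""
    cols = list(STATIC_FEATURES)
    for ch in CHANNELS:
        cols.extend(f"{ch}_{stat}" for stat in STAT_NAMES)
    return cols


def shannon_entropy(values: np.ndarray) -> float:
    """Shannon entropy (nats) of values binned into 16 equal-width bins over
    [-5, 5] Z; values outside are clipped into the edge bins."""
    clipped = np.clip(values, _ENTROPY_BINS[0], _ENTROPY_BINS[-1])
    counts, _ = np.histogram(clipped, bins=_ENTROPY_BINS)
    p = counts[counts > 0] / values.size
    return float(-(p * np.log(p)).sum())


def sample_entropy(values: np.ndarray, m: int = 2, r: float | None = None) -> float:
    """Sample entropy SampEn(m, r): -ln(A/B) where B counts template pairs of
    length ``m`` within Chebyshev distance ``r`` and A the same for length
    ``m + 1``, excluding self-matches.

    ``r`` defaults to 0.2 x SD of the window.  Degenerate cases (constant
    window, too few points, or zero matches) return 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n <= m + 1:
        return 0.0
    if r is None:
        r = 0.2 * float(values.std())
    if r <= 0:
        return 0.0
    a, b = _sampen_counts(values, m, float(r))
    if b == 0 or a == 0:
        return 0.0
    return float(-np.log(a / b))


@njit(cache=False)
def _sampen_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """Unordered template-pair counts (A at length m+1, B at length m) for
    sample entropy; self-matches excluded by construction."""
    n = x.size
    n_templates = n - m
    a = 0
    b = 0
    for i in range(n_templates):
        for j in range(i + 1, n_templates):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def _psd_total_power(values: np.ndarray) -> float:
    """Total periodogram power of the mean-removed window.

    By Parseval's identity this equals the (population) variance of the
    series; it is computed in the frequency domain from the DFT.
    """
    x = values - values.mean()
    spectrum = np.fft.fft(x)
    return float((np.abs(spectrum) ** 2).sum() / x.size**2)


def _slope(times: np.ndarray, values: np.ndarray) -> float:
    """Least-squares slope of value against time (per second)."""
    t = times - times.mean()
    denom = (t * t).sum()
    if denom == 0:
        return 0.0
    return float((t * (values - values.mean())).sum() / denom)


def window_statistics(
    values: np.ndarray, times: np.ndarray | None = None
) -> dict[str, float]:
    """Compute the 13 named statistics of one window of Z-values.

    ``times`` (seconds) is only needed for the slope; if omitted, unit
    spacing is assumed.  On a constant window, skewness and kurtosis are 0 by
    convention (logged) and SD, range, entropy, power and slope are all 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("window must be non-empty")
    if times is None:
        times = np.arange(values.size, dtype=float)
    # constancy detected exactly (min == max): np.std on a constant array
    # can return ~1e-16 through roundoff, which would break the 0-convention
    constant = values.min() == values.max()
    sd = 0.0 if constant else float(values.std())
    q75, q25 = np.percentile(values, [75, 25])
    if sd == 0:
        logger.debug("constant window: skewness/kurtosis set to 0 by convention")
        skewness, kurt = 0.0, 0.0
    else:
        with warnings.catch_warnings():
            # near-constant windows (e.g. SpO2 pegged at 100%) trigger a
            # harmless precision warning in the moment computation
            warnings.simplefilter("ignore", RuntimeWarning)
            skewness = float(_skew(values))
            kurt = float(_kurtosis(values))  # Fisher (excess)
    return {
        "mean": float(values.mean()),
        "median": float(np.median(values)),
        "sd": sd,
        "min": float(values.min()),
        "max": float(values.max()),
        "range": float(values.max() - values.min()),
        "iqr": float(q75 - q25),
        "skewness": skewness,
        "kurtosis": kurt,
        "shannon_entropy": shannon_entropy(values) if sd > 0 else 0.0,
        "sample_entropy": sample_entropy(values) if sd > 0 else 0.0,
        "psd_power": 0.0 if constant else _psd_total_power(values),
        "slope": 0.0 if constant else _slope(np.asarray(times, dtype=float), values),
    }


def _window_statistics_block(windows: np.ndarray, dt: float) -> np.ndarray:
    """Vectorised 13 statistics for a stack of windows (n_windows, w).

    Equivalent to calling :func:`window_statistics` row by row on windows of
    sampling interval ``dt``; the scalar path is the reference, this is the
    throughput path used by cohort featurisation.
    """
    n_win, w = windows.shape
    out = np.empty((n_win, len(STAT_NAMES)))
    mean = windows.mean(axis=1)
    mn = windows.min(axis=1)
    mx = windows.max(axis=1)
    const = mn == mx
    sd = np.where(const, 0.0, windows.std(axis=1))
    q25, q75 = np.percentile(windows, [25, 75], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        skewness = _skew(windows, axis=1)
        kurt = _kurtosis(windows, axis=1)
    skewness = np.where(const, 0.0, skewness)
    kurt = np.where(const, 0.0, kurt)
    # binned Shannon entropy, vectorised over rows
    clipped = np.clip(windows, _ENTROPY_BINS[0], _ENTROPY_BINS[-1])
    idx = np.minimum(np.searchsorted(_ENTROPY_BINS, clipped, side="right") - 1, 15)
    ent = np.empty(n_win)
    for i in range(n_win):
        counts = np.bincount(idx[i], minlength=16)
        p = counts[counts > 0] / w
        ent[i] = -(p * np.log(p)).sum()
    ent = np.where(const, 0.0, ent)
    # spectral power via Parseval-consistent DFT
    centred = windows - mean[:, None]
    psd = (np.abs(np.fft.fft(centred, axis=1)) ** 2).sum(axis=1) / w**2
    psd = np.where(const, 0.0, psd)
    # least-squares slope against time in seconds
    t = (np.arange(w) - (w - 1) / 2.0) * dt
    slope = np.where(const, 0.0, centred @ t / (t * t).sum())
    samp = np.array(
        [0.0 if const[i] else sample_entropy(windows[i]) for i in range(n_win)]
    )
    cols = [mean, np.median(windows, axis=1), sd, mn, mx, mx - mn, q75 - q25,
            skewness, kurt, ent, samp, psd, slope]
    for j, col in enumerate(cols):
        out[:, j] = col
    return out


def window_count(n_points: int, window_points: int, step: int | None) -> int:
    """Number of extractable windows: overlapping (minority) if ``step`` is
    given, else consecutive non-overlapping."""
    if n_points < window_points:
        return 0
    if step is not None:
        return (n_points - window_points) // step + 1
    return n_points // window_points


def extract_windows(
    grid: PatientZGrid,
    deceased: bool,
    spec: WindowSpec | None = None,
) -> list[tuple[int, np.ndarray]]:
    """Extract window start indices and Z-value blocks for one patient.

    Deceased patients yield overlapping windows starting at grid indices
    0, s, 2s, ... (s = ``minority_step_points``); survivors yield
    consecutive disjoint windows.  Windows with fewer than
    ``min_points_per_window`` observed points (on every channel combined)
    are dropped.  Returns ``[(start_index, z_block (n_channels, w)), ...]``;
    an empty list if the stream is shorter than one window.
    """
    spec = spec or WindowSpec()
    w = spec.window_points(grid.sampling_interval_s)
    n_points = grid.times.size
    step = spec.minority_step_points if deceased else None
    n_win = window_count(n_points, w, step)
    stride = step if deceased else w
    out: list[tuple[int, np.ndarray]] = []
    for k in range(n_win):
        start = k * stride
        obs = int(grid.observed[:, start : start + w].any(axis=0).sum())
        if obs < spec.min_points_per_window:
            logger.debug(
                "patient %s window @%d dropped: %d observed points < %d",
                grid.patient_id, start, obs, spec.min_points_per_window,
            )
            continue
        out.append((start, grid.z[:, start : start + w]))
    return out


def encode_static(record: pd.Series | dict) -> dict[str, float]:
    """Encode one EHR row into the 21 static features (documented codebook)."""
    r = dict(record)
    dx = r["diagnosis_group"]
    ci = r["critical_incident"]
    vaso = r["vaso_type"]
    enc = {
        "age_months": float(r["age_months"]),
        "age_group_ord": float(_AGE_GROUP_ORD[r["age_group"]]),
        "weight_kg": float(r["weight_kg"]),
        "gender_male": float(r["gender"] == "male"),
        "dx_respiratory": float(dx == "respiratory"),
        "dx_cardiovascular": float(dx == "cardiovascular"),
        "dx_neurological": float(dx == "neurological"),
        "dx_infection": float(dx == "infection"),
        "dx_gastrointestinal": float(dx == "gastrointestinal"),
        "dx_trauma": float(dx == "trauma"),
        "dx_other": float(dx == "other"),
        "invasive_ventilation": float(bool(r["invasive_ventilation"])),
        "vaso_single": float(vaso == "single"),
        "vaso_multiple": float(vaso == "multiple"),
        "inhaled_no": float(bool(r["inhaled_no"])),
        "ecmo": float(bool(r.get("ecmo", False))),
        "pim3_risk": float(r["pim3_risk"]),
        "ci_none": float(ci == "none"),
        "ci_patient": float(ci == "patient"),
        "ci_equipment": float(ci == "equipment"),
        "transport_minutes": float(r["transport_minutes"]),
    }
    assert list(enc) == list(STATIC_FEATURES)
    return enc


def assemble_sample(
    record: pd.Series | dict,
    channel_stats: dict[str, dict[str, float]],
) -> dict[str, float]:
    """Concatenate static block and per-channel derived block in fixed order.

    ``channel_stats`` maps every channel name to its 13 statistics; a missing
    channel raises KeyError (the caller drops the sample with a logged
    reason).
    """
    missing = [ch for ch in CHANNELS if ch not in channel_stats]
    if missing:
        raise KeyError(f"window missing channels {missing}; sample dropped")
    vec = encode_static(record)
    for ch in CHANNELS:
        for stat in STAT_NAMES:
            vec[f"{ch}_{stat}"] = float(channel_stats[ch][stat])
    return vec


def build_samples(
    ehr: pd.DataFrame,
    grids: dict[str, PatientZGrid],
    spec: WindowSpec | None = None,
    label_col: str = "died_30d",
) -> pd.DataFrame:
    """Featurise a whole cohort into the window-sample table.

    Returns a DataFrame with ``patient_id``, ``window_start_s``, ``label``
    and the 112 feature columns.  Patients with a dropped channel contribute
    no samples (logged); the minority/majority sample ratio is logged.
    """
    spec = spec or WindowSpec()
    cols = feature_columns()
    n_static = len(STATIC_FEATURES)
    rows: list[np.ndarray] = []
    meta: list[tuple[str, float, int]] = []
    for row in ehr.itertuples(index=False):
        pid = row.patient_id
        grid = grids.get(pid)
        if grid is None:
            continue
        if grid.dropped_channels:
            logger.info(
                "patient %s skipped: channels %s unimputable", pid, grid.dropped_channels
            )
            continue
        windows = extract_windows(grid, bool(getattr(row, label_col)), spec)
        if not windows:
            continue
        static = np.array(list(encode_static(row._asdict()).values()))
        starts = np.array([s for s, _ in windows])
        stack_per_channel = []
        for j in range(len(CHANNELS)):
            blocks = np.stack([blk[j] for _, blk in windows])
            stack_per_channel.append(
                _window_statistics_block(blocks, grid.sampling_interval_s)
            )
        derived = np.concatenate(stack_per_channel, axis=1)
        for i, start in enumerate(starts):
            rows.append(np.concatenate([static, derived[i]]))
            meta.append((pid, float(grid.times[start]), int(getattr(row, label_col))))
    if not rows:
        return pd.DataFrame(columns=["patient_id", "window_start_s", "label", *cols])
    feat = pd.DataFrame(np.vstack(rows), columns=cols)
    head = pd.DataFrame(meta, columns=["patient_id", "window_start_s", "label"])
    samples = pd.concat([head, feat], axis=1)
    assert samples.shape[1] == 3 + n_static + len(CHANNELS) * len(STAT_NAMES)
    n_pos = int((samples["label"] == 1).sum())
    n_neg = int((samples["label"] == 0).sum())
    if n_neg:
        logger.info("sample balance: %d deceased / %d survivor = %.2f", n_pos, n_neg, n_pos / n_neg)
    return samples
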