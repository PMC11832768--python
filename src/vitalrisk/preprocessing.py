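"""Cleaning, imputation and age-adjusted Z-score standardisation.

Pipeline order is fixed: clean -> impute -> standardise.  Cleaning converts
clinically implausible values to missing (never clips: clipping would
fabricate physiology).  Imputation is variable-wise and deterministic:
linear interpolation in the interior, nearest-value fill at the edges.
Standardisation maps each channel onto dimensionless Z-scores using the
patient's age-group reference mean and SD, removing the strong age
dependence of paediatric vital signs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    CHANNELS,
    DEFAULT_PLAUSIBILITY_BOUNDS,
    DEFAULT_REFERENCE_RANGES,
    validate_bounds,
    validate_reference_ranges,
)
from .synthetic import VitalSignSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ZScoreSeries",
    "PatientZGrid",
    "UnimputableSeriesError",
    "clean_series",
    "impute_series",
    "standardize_series",
    "clean_values",
    "impute_values",
    "preprocess_cohort",
]


class UnimputableSeriesError(ValueError):
    """Raised when a series has zero observed values and cannot be imputed."""


@dataclass
class ZScoreSeries:
    """Age-standardised version of a :class:`VitalSignSeries`."""

    patient_id: str
    channel: str
    times: np.ndarray
    zvalues: np.ndarray
    reference: tuple[float, float]  # (mean, sd) used

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.zvalues = np.asarray(self.zvalues, dtype=float)
        if self.times.shape != self.zvalues.shape:
            raise ValueError("times and zvalues must have equal length")


@dataclass
class PatientZGrid:
    """All channels of one patient on a common time grid, Z-standardised.

    ``z`` has shape (n_channels, n_points) with rows ordered as
    :data:`vitalrisk.config.CHANNELS`; ``observed`` marks grid points that
    were actually measured (pre-imputation) per channel.
    """

    patient_id: str
    times: np.ndarray
    z: np.ndarray
    observed: np.ndarray
    sampling_interval_s: float
    dropped_channels: list[str] = field(default_factory=list)


def clean_values(
    values: np.ndarray, lo: float, hi: float
) -> tuple[np.ndarray, int]:
    """Replace values outside the closed interval [lo, hi] with NaN.

    Returns the cleaned array and the number of values removed.
    """
    values = np.asarray(values, dtype=float)
    bad = ~np.isnan(values) & ((values < lo) | (values > hi))
    out = values.copy()
    out[bad] = np.nan
    return out, int(bad.sum())


def clean_series(
    series: VitalSignSeries,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> tuple[VitalSignSeries, int]:
    """Mask clinically implausible values in one series.

    Values outside the channel's closed plausibility interval become missing;
    timestamps are retained, in-range values are untouched.  Returns the
    cleaned series and the count of removed values.
    """
    bounds = DEFAULT_PLAUSIBILITY_BOUNDS if bounds is None else bounds
    validate_bounds(bounds)
    if series.channel not in bounds:
        raise KeyError(f"channel {series.channel} absent from plausibility bounds")
    lo, hi = bounds[series.channel]
    cleaned, n_removed = clean_values(series.values, lo, hi)
    return VitalSignSeries(series.patient_id, series.channel, series.times, cleaned), n_removed


def impute_values(times: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Linear interpolation at interior gaps, nearest-value fill at edges.

    Observed values are returned unchanged.  Raises
    :class:`UnimputableSeriesError` if nothing is observed.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    if not mask.any():
        raise UnimputableSeriesError("series has no observed values")
    if mask.all():
        return values.copy()
    # np.interp holds the first/last observed value constant outside the
    # observed span, which is exactly the nearest-value edge policy.
    return np.interp(times, times[mask], values[mask])


def impute_series(series: VitalSignSeries) -> VitalSignSeries:
    """Fill all missing values of a cleaned series (see :func:`impute_values`)."""
    filled = impute_values(series.times, series.values)
    return VitalSignSeries(series.patient_id, series.channel, series.times, filled)


def standardize_series(
    series: VitalSignSeries,
    age_group: str,
    refs: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> ZScoreSeries:
    """Convert a series to age-adjusted Z-scores: z = (value - mean) / SD."""
    refs = DEFAULT_REFERENCE_RANGES if refs is None else refs
    key = (age_group, series.channel)
    if key not in refs:
        raise KeyError(f"no reference range for {key}")
    mean, sd = refs[key]
    if sd <= 0:
        raise ValueError(f"reference SD must be positive for {key}, got {sd}")
    z = (series.values - mean) / sd
    return ZScoreSeries(series.patient_id, series.channel, series.times, z, (mean, sd))


def _patient_grid(
    pid: str,
    group: pd.DataFrame,
    age_group: str,
    bounds: dict[str, tuple[float, float]],
    refs: dict[tuple[str, str], tuple[float, float]],
) -> PatientZGrid | None:
    """Clean, impute and standardise one patient's channels onto their
    common time grid.  Returns None if no channel is imputable."""
    times = np.unique(group["time_s"].to_numpy(dtype=float))
    if times.size == 0:
        return None
    n = times.size
    z = np.full((len(CHANNELS), n), np.nan)
    observed = np.zeros((len(CHANNELS), n), dtype=bool)
    dropped: list[str] = []
    chan_codes = group["channel"].to_numpy()
    t_all = group["time_s"].to_numpy(dtype=float)
    v_all = group["value"].to_numpy(dtype=float)
    for j, ch in enumerate(CHANNELS):
        sel = chan_codes == ch
        if not sel.any():
            dropped.append(ch)
            continue
        t = t_all[sel]
        v, _ = clean_values(v_all[sel], *bounds[ch])
        idx = np.searchsorted(times, t)
        col = np.full(n, np.nan)
        col[idx] = v
        obs = ~np.isnan(col)
        if not obs.any():
            dropped.append(ch)
            logger.info("patient %s channel %s unimputable (no observed values)", pid, ch)
            continue
        filled = np.interp(times, times[obs], col[obs])
        mean, sd = refs[(age_group, ch)]
        z[j] = (filled - mean) / sd
        observed[j] = obs
    if len(dropped) == len(CHANNELS):
        return None
    dt = float(np.median(np.diff(times))) if n > 1 else 1.0
    return PatientZGrid(pid, times, z, observed, dt, dropped)


def preprocess_cohort(
    vitals: pd.DataFrame,
    ehr: pd.DataFrame,
    bounds: dict[str, tuple[float, float]] | None = None,
    refs: dict[tuple[str, str], tuple[float, float]] | None = None,
) -> dict[str, PatientZGrid]:
    """Run clean -> impute -> standardise for every patient in a cohort.

    Parameters
    ----------
    vitals
        Long-format table ``patient_id, time_s, channel, value``.
    ehr
        EHR table providing each patient's ``age_group``.

    Returns
    -------
    dict mapping patient_id to :class:`PatientZGrid`.  Patients with no
    imputable channel are omitted (logged).
    """
    bounds = DEFAULT_PLAUSIBILITY_BOUNDS if bounds is None else bounds
    refs = DEFAULT_REFERENCE_RANGES if refs is None else refs
    validate_bounds(bounds)
    validate_reference_ranges(refs)
    age_groups = ehr.set_index("patient_id")["age_group"].to_dict()
    grids: dict[str, PatientZGrid] = {}
    for pid, group in vitals.groupby("patient_id", observed=True, sort=True):
        pid = str(pid)
        if pid not in age_groups:
            logger.warning("patient %s has vitals but no EHR row; skipped", pid)
            continue
        grid = _patient_grid(pid, group, age_groups[pid], bounds, refs)
        if grid is None:
            logger.info("patient %s excluded: no imputable channel", pid)
            continue
        grids[pid] = grid
    return grids
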