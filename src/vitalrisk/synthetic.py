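"""Synthetic transport-cohort generator.

Emits (EHR table, long-format vital-sign table) pairs with the statistical
structure the downstream pipeline assumes: a fixed 30-day mortality fraction,
age-band demographics, a log-normal monitoring duration, per-channel
mean-reverting vital-sign trajectories around age-group reference values,
outcome-conditioned deterioration drifts, and channel-specific missingness
plus implausible-value artifacts.

The trajectory model is an Ornstein-Uhlenbeck (AR(1) after discretisation)
process in Z-score space around the age-group reference mean, plus a
patient-level random offset and, for non-survivors, a linear drift from 0 to
the configured deterioration effect over the episode.  Survivor streams are
therefore stationary while non-survivor streams deteriorate progressively.
All raw values are kept inside the clinical plausibility bounds before
artifact injection, so cleaning removes only injected artifacts.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .config import (
    AGE_BAND_UPPER_MONTHS,
    AGE_GROUPS,
    CHANNELS,
    DEFAULT_PLAUSIBILITY_BOUNDS,
    DEFAULT_REFERENCE_RANGES,
    CohortConfig,
    age_group_from_months,
)

__all__ = ["CohortConfig", "VitalSignSeries", "generate_cohort", "inject_artifacts"]

# Study-population structure the generator emulates: age-band and
# diagnosis-group frequencies, intervention rates, and outcome-conditioned
# severity-score (PIM3) distributions of a regional paediatric transport
# cohort.
AGE_GROUP_PROBS = {
    "newborn": 0.379,
    "infant": 0.205,
    "preschool": 0.176,
    "school": 0.145,
    "adolescent": 0.095,
}

DIAGNOSIS_GROUPS = (
    "respiratory",
    "cardiovascular",
    "neurological",
    "infection",
    "gastrointestinal",
    "trauma",
    "other",
)
DIAGNOSIS_PROBS = (0.348, 0.257, 0.184, 0.064, 0.044, 0.013, 0.090)

VENTILATION_RATE = 0.724
VASO_RATE = 0.314  # any vasoactive infusion; 3/4 single agent, 1/4 multiple
INHALED_NO_RATE = 0.025
ECMO_RATE = 0.02

# Transport (road) time: log-normal with median 206 min, IQR ~160-258 min.
TRANSPORT_MEDIAN_MIN = 206.0
TRANSPORT_SIGMA = 0.354

# Outcome-conditioned PIM3 Beta distributions, calibrated so that PIM3 alone
# discriminates moderately (patient-level AUROC ~0.74 on large cohorts):
# survivors centred on ~3% predicted risk, non-survivors heavier-tailed.
PIM3_BETA_SURVIVOR = (2.2, 62.0)
PIM3_BETA_DECEASED = (1.1, 11.0)

# Weight-for-age anchors (months -> kg), linearly interpolated; a log-normal
# multiplicative factor adds between-child spread.
_WEIGHT_ANCHOR_MONTHS = np.array([0.0, 6.0, 12.0, 24.0, 48.0, 96.0, 144.0, 216.0])
_WEIGHT_ANCHOR_KG = np.array([3.5, 7.5, 10.0, 12.0, 16.0, 25.0, 40.0, 60.0])


@dataclass
class VitalSignSeries:
    """One channel of one patient's monitoring stream.

    ``times`` are seconds from monitoring start (strictly increasing);
    ``values`` are in channel units with NaN marking missing points.
    """

    patient_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


def _sample_ages_months(rng: np.random.Generator, n: int) -> np.ndarray:
    groups = rng.choice(AGE_GROUPS, size=n, p=[AGE_GROUP_PROBS[g] for g in AGE_GROUPS])
    lower = {"newborn": 0.0, "infant": 1.0, "preschool": 12.0, "school": 48.0, "adolescent": 132.0}
    lo = np.array([lower[g] for g in groups])
    hi = np.array([AGE_BAND_UPPER_MONTHS[g] for g in groups])
    return lo + rng.uniform(0.0, 1.0, size=n) * (hi - lo)


def _weight_from_age(rng: np.random.Generator, age_months: np.ndarray) -> np.ndarray:
    base = np.interp(age_months, _WEIGHT_ANCHOR_MONTHS, _WEIGHT_ANCHOR_KG)
    return base * rng.lognormal(mean=0.0, sigma=0.15, size=age_months.size)


def _generate_ehr(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_patients
    n_deceased = int(round(n * config.mortality_rate))
    died_30d = np.zeros(n, dtype=bool)
    if n_deceased > 0:
        died_30d[rng.choice(n, size=n_deceased, replace=False)] = True
    died_48h = died_30d & (rng.uniform(size=n) < config.mortality_48h_given_30d)

    age_months = _sample_ages_months(rng, n)
    age_group = np.array([age_group_from_months(a) for a in age_months])
    weight = _weight_from_age(rng, age_months)
    gender = rng.choice(["male", "female"], size=n, p=[0.55, 0.45])
    diagnosis = rng.choice(DIAGNOSIS_GROUPS, size=n, p=DIAGNOSIS_PROBS)
    ventilated = rng.uniform(size=n) < VENTILATION_RATE
    vaso_any = rng.uniform(size=n) < VASO_RATE
    vaso_multi = vaso_any & (rng.uniform(size=n) < 0.25)
    vaso_type = np.where(vaso_multi, "multiple", np.where(vaso_any, "single", "none"))
    inhaled_no = rng.uniform(size=n) < INHALED_NO_RATE
    ecmo = rng.uniform(size=n) < ECMO_RATE

    a_s, b_s = PIM3_BETA_SURVIVOR
    a_d, b_d = PIM3_BETA_DECEASED
    pim3 = np.where(died_30d, rng.beta(a_d, b_d, size=n), rng.beta(a_s, b_s, size=n))

    incident_any = rng.uniform(size=n) < config.incident_rate
    incident_equip = incident_any & (rng.uniform(size=n) < 0.4)
    critical_incident = np.where(
        incident_equip, "equipment", np.where(incident_any, "patient", "none")
    )

    transport_minutes = rng.lognormal(np.log(TRANSPORT_MEDIAN_MIN), TRANSPORT_SIGMA, size=n)
    duration_minutes = rng.lognormal(
        np.log(config.duration_median_minutes), config.duration_sigma, size=n
    )

    return pd.DataFrame(
        {
            "patient_id": [f"P{i:05d}" for i in range(n)],
            "age_months": age_months,
            "age_group": age_group,
            "weight_kg": weight,
            "gender": gender,
            "diagnosis_group": diagnosis,
            "invasive_ventilation": ventilated,
            "vaso_type": vaso_type,
            "inhaled_no": inhaled_no,
            "ecmo": ecmo,
            "pim3_risk": pim3,
            "critical_incident": critical_incident,
            "transport_minutes": transport_minutes,
            "monitored_minutes": duration_minutes,
            "died_30d": died_30d,
            "died_48h": died_48h,
        }
    )


def _patient_trajectories(
    config: CohortConfig,
    rng: np.random.Generator,
    age_group: str,
    duration_minutes: float,
    deceased: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (times, raw value matrix len(CHANNELS) x L) for one patient."""
    dt = config.sampling_interval_s
    n_points = max(2, int(round(duration_minutes * 60.0 / dt)))
    times = np.arange(n_points) * dt

    a = np.exp(-dt / config.ou_tau_s)
    innov_sd = config.ou_sigma * np.sqrt(1.0 - a * a)
    eps = rng.normal(scale=innov_sd, size=(n_points, len(CHANNELS)))
    z0 = rng.normal(scale=config.ou_sigma, size=len(CHANNELS))
    # AR(1): z[t] = a z[t-1] + eps[t], initialised at the stationary draw z0.
    zi = (a * z0)[None, :]
    z, _ = lfilter([1.0], [1.0, -a], eps, axis=0, zi=zi)

    offsets = rng.normal(scale=config.patient_offset_sd, size=len(CHANNELS))
    z = z + offsets[None, :]
    if deceased:
        ramp = np.linspace(0.0, 1.0, n_points)
        for j, ch in enumerate(CHANNELS):
            effect = config.deterioration_effect.get(ch, 0.0)
            if effect:
                z[:, j] = z[:, j] + ramp * effect

    values = np.empty((len(CHANNELS), n_points))
    for j, ch in enumerate(CHANNELS):
        mean, sd = DEFAULT_REFERENCE_RANGES[(age_group, ch)]
        lo, hi = DEFAULT_PLAUSIBILITY_BOUNDS[ch]
        values[j] = np.clip(mean + sd * z[:, j], lo, hi)
    return times, values


def inject_artifacts(series: VitalSignSeries, config: CohortConfig) -> VitalSignSeries:
    """Degrade a clean series with missing points and implausible outliers.

    Each point is independently replaced by NaN with its channel's missing
    rate, and (independently) by an out-of-range spike with probability
    ``outlier_rate``.  Length and timestamps are unchanged.
    """
    if series.channel not in CHANNELS:
        raise ValueError(f"unknown channel: {series.channel}")
    # Seed derived from (config seed, patient id, channel) so artifact noise
    # is reproducible per series regardless of call order.
    pid_key = zlib.crc32(series.patient_id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, pid_key, CHANNELS.index(series.channel)])
    )
    values = series.values.copy()
    n = values.size
    lo, hi = DEFAULT_PLAUSIBILITY_BOUNDS[series.channel]
    out_mask = rng.uniform(size=n) < config.outlier_rate
    if out_mask.any():
        span = hi - lo
        spikes = hi + rng.uniform(0.05 * span, 0.5 * span, size=int(out_mask.sum()))
        if lo > 0:  # channels with a physical floor can also fail low
            low_side = rng.uniform(size=int(out_mask.sum())) < 0.5
            spikes = np.where(low_side, lo - rng.uniform(0.05 * span, 0.5 * span, size=spikes.size), spikes)
        values[out_mask] = spikes
    rate = config.missing_rate_per_channel.get(series.channel, 0.0)
    miss_mask = rng.uniform(size=n) < rate
    values[miss_mask] = np.nan
    return VitalSignSeries(series.patient_id, series.channel, series.times, values)


def generate_cohort(
    config: CohortConfig, inject: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a synthetic transport cohort.

    Parameters
    ----------
    config
        Generator settings; ``config.seed`` makes the output fully
        reproducible.
    inject
        If True (default), apply missingness and outlier artifacts after
        trajectory generation; if False, return the clean streams.

    Returns
    -------
    ehr : pandas.DataFrame
        One row per transport episode (demographics, diagnosis group,
        interventions, PIM3 risk, critical incident, outcomes).  Exactly
        ``round(n_patients * mortality_rate)`` rows have ``died_30d`` True.
    vitals : pandas.DataFrame
        Long format: ``patient_id, time_s, channel, value`` with NaN for
        missing points, sorted by patient, channel, time.
    """
    rng = np.random.default_rng(config.seed)
    ehr = _generate_ehr(config, rng)

    pid_parts: list[np.ndarray] = []
    time_parts: list[np.ndarray] = []
    chan_parts: list[np.ndarray] = []
    value_parts: list[np.ndarray] = []
    for row in ehr.itertuples(index=False):
        times, values = _patient_trajectories(
            config, rng, row.age_group, row.monitored_minutes, row.died_30d
        )
        n_points = times.size
        for j, ch in enumerate(CHANNELS):
            series = VitalSignSeries(row.patient_id, ch, times, values[j])
            if inject:
                series = inject_artifacts(series, config)
            pid_parts.append(np.full(n_points, row.patient_id, dtype=object))
            time_parts.append(times)
            chan_parts.append(np.full(n_points, ch, dtype=object))
            value_parts.append(series.values)

    vitals = pd.DataFrame(
        {
            "patient_id": pd.Categorical(np.concatenate(pid_parts)),
            "time_s": np.concatenate(time_parts).astype(np.float64),
            "channel": pd.Categorical(np.concatenate(chan_parts), categories=list(CHANNELS)),
            "value": np.concatenate(value_parts).astype(np.float32),
        }
    )
    return ehr, vitals
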