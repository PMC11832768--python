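"""Shared vocabulary and configuration objects for the transport-risk pipeline.

Everything downstream agrees on the seven monitored channels, the paediatric
age bands, the clinical plausibility bounds used for cleaning, and the
age-group reference ranges used for Z-score standardisation.  Reference
ranges ship as editable defaults (plausible paediatric norms); sites with
their own normative tables load them from YAML via :func:`load_reference_ranges`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import yaml

#: Monitored vital-sign channels, in canonical order.  This order fixes the
#: derived-feature block layout of every feature vector.
CHANNELS: tuple[str, ...] = ("HR", "SBP", "DBP", "MBP", "RR", "SPO2", "TEMP")

#: Units per channel, for documentation and exports.
CHANNEL_UNITS: dict[str, str] = {
    "HR": "bpm",
    "SBP": "mmHg",
    "DBP": "mmHg",
    "MBP": "mmHg",
    "RR": "breaths/min",
    "SPO2": "%",
    "TEMP": "degC",
}

#: Clinical plausibility bounds (closed intervals, channel units).  Values
#: outside these are physiologically impossible monitor output and are
#: treated as artifacts by the cleaning stage.
DEFAULT_PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "HR": (0.0, 300.0),
    "SBP": (0.0, 270.0),
    "DBP": (0.0, 250.0),
    "MBP": (0.0, 250.0),
    "RR": (0.0, 180.0),
    "SPO2": (0.0, 100.0),
    "TEMP": (20.0, 45.0),
}

#: Per-channel missingness observed in transport-grade monitoring data
#: (fraction of points), used as generator defaults.
DEFAULT_MISSING_RATES: dict[str, float] = {
    "HR": 0.0285,
    "SBP": 0.0925,
    "DBP": 0.0930,
    "MBP": 0.0876,
    "RR": 0.0311,
    "SPO2": 0.0287,
    "TEMP": 0.125,
}

#: Paediatric age bands, half-open in months except newborn, ordered.
AGE_GROUPS: tuple[str, ...] = ("newborn", "infant", "preschool", "school", "adolescent")

#: Upper edge (months, inclusive) of each age band.
AGE_BAND_UPPER_MONTHS: dict[str, float] = {
    "newborn": 1.0,
    "infant": 12.0,
    "preschool": 48.0,
    "school": 132.0,
    "adolescent": 216.0,
}


def age_group_from_months(age_months: float) -> str:
    """Map an age in months to its band (newborn <=1m, infant <=12m,
    pre-school <=4y, school <=11y, adolescent <=18y)."""
    if age_months < 0:
        raise ValueError(f"age_months must be non-negative, got {age_months}")
    for group in AGE_GROUPS:
        if age_months <= AGE_BAND_UPPER_MONTHS[group]:
            return group
    raise ValueError(f"age {age_months} months is outside the paediatric range")


#: Editable default reference ranges, (mean, SD) in channel units per
#: (age_group, channel).  These are plausible paediatric norms, not a
#: published normative table; replace with site-specific values for real use.
DEFAULT_REFERENCE_RANGES: dict[tuple[str, str], tuple[float, float]] = {
    ("newborn", "HR"): (140.0, 20.0),
    ("newborn", "SBP"): (70.0, 10.0),
    ("newborn", "DBP"): (45.0, 8.0),
    ("newborn", "MBP"): (55.0, 8.0),
    ("newborn", "RR"): (45.0, 10.0),
    ("newborn", "SPO2"): (97.0, 2.0),
    ("newborn", "TEMP"): (36.8, 0.5),
    ("infant", "HR"): (125.0, 20.0),
    ("infant", "SBP"): (85.0, 12.0),
    ("infant", "DBP"): (50.0, 9.0),
    ("infant", "MBP"): (62.0, 9.0),
    ("infant", "RR"): (35.0, 8.0),
    ("infant", "SPO2"): (97.0, 2.0),
    ("infant", "TEMP"): (36.9, 0.5),
    ("preschool", "HR"): (110.0, 18.0),
    ("preschool", "SBP"): (95.0, 12.0),
    ("preschool", "DBP"): (55.0, 9.0),
    ("preschool", "MBP"): (68.0, 9.0),
    ("preschool", "RR"): (26.0, 6.0),
    ("preschool", "SPO2"): (97.5, 1.8),
    ("preschool", "TEMP"): (36.9, 0.5),
    ("school", "HR"): (95.0, 15.0),
    ("school", "SBP"): (105.0, 12.0),
    ("school", "DBP"): (62.0, 9.0),
    ("school", "MBP"): (76.0, 9.0),
    ("school", "RR"): (20.0, 5.0),
    ("school", "SPO2"): (97.5, 1.8),
    ("school", "TEMP"): (36.8, 0.5),
    ("adolescent", "HR"): (80.0, 14.0),
    ("adolescent", "SBP"): (115.0, 12.0),
    ("adolescent", "DBP"): (68.0, 9.0),
    ("adolescent", "MBP"): (83.0, 9.0),
    ("adolescent", "RR"): (16.0, 4.0),
    ("adolescent", "SPO2"): (97.5, 1.8),
    ("adolescent", "TEMP"): (36.8, 0.5),
}


def validate_bounds(bounds: Mapping[str, tuple[float, float]]) -> None:
    for ch, (lo, hi) in bounds.items():
        if not lo < hi:
            raise ValueError(f"plausibility bounds for {ch} need lo < hi, got [{lo}, {hi}]")


def validate_reference_ranges(refs: Mapping[tuple[str, str], tuple[float, float]]) -> None:
    for (group, ch), (mean, sd) in refs.items():
        if sd <= 0:
            raise ValueError(f"reference SD must be positive for ({group}, {ch}), got {sd}")


def save_reference_ranges(refs: Mapping[tuple[str, str], tuple[float, float]], path) -> None:
    """Write reference ranges as YAML: ``group: {channel: {mean: .., sd: ..}}``."""
    nested: dict[str, dict[str, dict[str, float]]] = {}
    for (group, ch), (mean, sd) in refs.items():
        nested.setdefault(group, {})[ch] = {"mean": float(mean), "sd": float(sd)}
    with open(path, "w") as fh:
        yaml.safe_dump(nested, fh, sort_keys=True)


def load_reference_ranges(path) -> dict[tuple[str, str], tuple[float, float]]:
    with open(path) as fh:
        nested = yaml.safe_load(fh)
    refs = {
        (group, ch): (float(entry["mean"]), float(entry["sd"]))
        for group, channels in nested.items()
        for ch, entry in channels.items()
    }
    validate_reference_ranges(refs)
    return refs


def save_bounds(bounds: Mapping[str, tuple[float, float]], path) -> None:
    nested = {ch: {"lo": float(lo), "hi": float(hi)} for ch, (lo, hi) in bounds.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(nested, fh, sort_keys=True)


def load_bounds(path) -> dict[str, tuple[float, float]]:
    with open(path) as fh:
        nested = yaml.safe_load(fh)
    bounds = {ch: (float(v["lo"]), float(v["hi"])) for ch, v in nested.items()}
    validate_bounds(bounds)
    return bounds


@dataclass
class WindowSpec:
    """Sliding-window extraction parameters.

    ``window_minutes`` is the wall-clock window length; the number of grid
    points it spans depends on the stream's sampling interval.  Deceased
    (minority-class) patients are windowed with an overlapping stride of
    ``minority_step_points`` grid points; survivors with consecutive
    non-overlapping windows.
    """

    window_minutes: float = 10.0
    minority_step_points: int = 50
    min_points_per_window: int = 1

    def __post_init__(self) -> None:
        if self.window_minutes <= 0:
            raise ValueError("window_minutes must be positive")
        if self.minority_step_points < 1:
            raise ValueError("minority_step_points must be >= 1")
        if self.min_points_per_window < 0:
            raise ValueError("min_points_per_window must be >= 0")

    def window_points(self, sampling_interval_s: float) -> int:
        """Window length in grid points at the given sampling interval."""
        return int(round(self.window_minutes * 60.0 / sampling_interval_s))


@dataclass
class CohortConfig:
    """Parameters of the synthetic transport cohort generator.

    Defaults emulate the statistical structure of a regional paediatric
    critical-care transport population: ~6% 30-day mortality, a log-normal
    monitoring duration with median ~67 minutes, channel-specific
    missingness, and outcome-conditioned physiological deterioration
    expressed as Z-score drifts.
    """

    n_patients: int
    mortality_rate: float = 0.06
    mortality_48h_given_30d: float = 0.27
    sampling_interval_s: float = 1.0
    duration_median_minutes: float = 67.0
    duration_sigma: float = 0.68
    missing_rate_per_channel: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MISSING_RATES)
    )
    outlier_rate: float = 0.005
    deterioration_effect: dict[str, float] = field(
        default_factory=lambda: {"SPO2": -1.5, "SBP": -1.0}
    )
    incident_rate: float = 0.149
    # Mean-reverting (Ornstein-Uhlenbeck) noise around the age-group
    # reference: relaxation time, stationary SD, and between-patient offset SD,
    # all in Z-score units / seconds.
    ou_tau_s: float = 300.0
    ou_sigma: float = 0.6
    patient_offset_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0.0 <= self.mortality_rate <= 1.0:
            raise ValueError("mortality_rate must be in [0, 1]")
        if not 0.0 <= self.mortality_48h_given_30d <= 1.0:
            raise ValueError("mortality_48h_given_30d must be in [0, 1]")
        if self.sampling_interval_s <= 0:
            raise ValueError("sampling_interval_s must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be in [0, 1]")
        if not 0.0 <= self.incident_rate <= 1.0:
            raise ValueError("incident_rate must be in [0, 1]")
        for ch, rate in self.missing_rate_per_channel.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel in missing rates: {ch}")
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {ch} must be in [0, 1], got {rate}")
        for ch in self.deterioration_effect:
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel in deterioration_effect: {ch}")

    def with_seed(self, seed: int) -> "CohortConfig":
        return replace(self, seed=seed)


@dataclass
class ModelSpec:
    """Backend choice plus hyperparameter-search settings for training."""

    backend: str = "random_forest"
    cv_folds: int = 5
    n_search: int = 10
    seed: int = 0
    search_space: dict | None = None  # None -> backend default space

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_search < 1:
            raise ValueError("n_search must be >= 1")
        if self.search_space is not None and len(self.search_space) == 0:
            raise ValueError("search_space must be non-empty")
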