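"""Reading and writing the pipeline's on-disk formats.

EHR: one CSV row per transport episode with a fixed, documented header.
Vitals: long-format CSV ``patient_id,time_s,channel,value`` with an empty
value field for missing points.  Both round-trip exactly through pandas.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .config import CHANNELS

EHR_COLUMNS = [
    "patient_id",
    "age_months",
    "age_group",
    "weight_kg",
    "gender",
    "diagnosis_group",
    "invasive_ventilation",
    "vaso_type",
    "inhaled_no",
    "ecmo",
    "pim3_risk",
    "critical_incident",
    "transport_minutes",
    "monitored_minutes",
    "died_30d",
    "died_48h",
]

_EHR_BOOL = ["invasive_ventilation", "inhaled_no", "ecmo", "died_30d", "died_48h"]


def write_ehr(ehr: pd.DataFrame, path) -> None:
    missing = [c for c in EHR_COLUMNS if c not in ehr.columns]
    if missing:
        raise ValueError(f"EHR table missing columns {missing}")
    ehr[EHR_COLUMNS].to_csv(path, index=False)


def read_ehr(path) -> pd.DataFrame:
    ehr = pd.read_csv(path)
    for col in _EHR_BOOL:
        ehr[col] = ehr[col].astype(bool)
    return ehr


def write_vitals(vitals: pd.DataFrame, path) -> None:
    vitals.to_csv(path, index=False, na_rep="")


def read_vitals(path) -> pd.DataFrame:
    vitals = pd.read_csv(
        path,
        dtype={"patient_id": "category", "time_s": np.float64, "value": np.float32},
    )
    vitals["channel"] = pd.Categorical(vitals["channel"], categories=list(CHANNELS))
    return vitals


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path)


def ensure_dir(path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    return path
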