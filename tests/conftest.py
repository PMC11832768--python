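import numpy as np
import pandas as pd
import pytest

from vitalrisk import CohortConfig, ModelSpec, TransportMortalityModel, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small but fully featurisable cohort (coarse sampling keeps it fast)."""
    cfg = CohortConfig(n_patients=60, seed=42, sampling_interval_s=2.0)
    ehr, vitals = generate_cohort(cfg)
    return cfg, ehr, vitals


@pytest.fixture(scope="session")
def small_model(small_cohort):
    _, ehr, vitals = small_cohort
    return TransportMortalityModel.from_cohort(
        ehr, vitals, spec=ModelSpec(backend="random_forest", n_search=1, cv_folds=3)
    )


@pytest.fixture(scope="session")
def small_results(small_model):
    return small_model.fit(seed=0)


def toy_samples(n_patients=40, per_patient=4, n_features=5, seed=0, separation=2.0):
    """Window-sample table with a planted linear signal, patient-grouped."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        label = int(i < n_patients // 2)
        shift = separation * label
        for k in range(per_patient):
            x = rng.normal(size=n_features)
            x[0] += shift
            rows.append([f"T{i:03d}", float(k * 600), label, *x])
    cols = ["patient_id", "window_start_s", "label"] + [f"f{j}" for j in range(n_features)]
    return pd.DataFrame(rows, columns=cols)
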