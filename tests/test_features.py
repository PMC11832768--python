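"""Window extraction counts, the 13 statistics, and feature assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vitalrisk import (
    CHANNELS,
    STAT_NAMES,
    STATIC_FEATURES,
    WindowSpec,
    assemble_sample,
    feature_columns,
    window_statistics,
)
from vitalrisk.features import (
    _window_statistics_block,
    build_samples,
    extract_windows,
    sample_entropy,
)
from vitalrisk.preprocessing import PatientZGrid


def brute_force_sample_entropy(x, m=2, r=None):
    """Direct template-matching SampEn: O(n^2) pair enumeration."""
    x = np.asarray(x, float)
    n = len(x)
    if r is None:
        r = 0.2 * x.std()
    if r <= 0 or n <= m + 1:
        return 0.0

    def count(length):
        templates = [x[i : i + length] for i in range(n - m)]
        c = 0
        for i in range(len(templates)):
            for j in range(i + 1, len(templates)):
                if np.max(np.abs(templates[i] - templates[j])) <= r:
                    c += 1
        return 2 * c  # ordered pairs

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return 0.0
    return -np.log(a / b)


def make_grid(n_points, dt=5.0, seed=0, n_channels=len(CHANNELS)):
    rng = np.random.default_rng(seed)
    z = rng.normal(size=(n_channels, n_points))
    return PatientZGrid(
        "PX", np.arange(n_points) * dt, z, np.ones_like(z, dtype=bool), dt, []
    )


class TestWindowCounts:
    def test_deceased_overlapping_example(self):
        grid = make_grid(220)
        spec = WindowSpec(window_minutes=10, minority_step_points=50)  # w=120 @ dt=5
        wins = extract_windows(grid, deceased=True, spec=spec)
        assert [s for s, _ in wins] == [0, 50, 100]

    def test_survivor_disjoint_example(self):
        grid = make_grid(240)
        wins = extract_windows(grid, deceased=False, spec=WindowSpec())
        assert [s for s, _ in wins] == [0, 120]

    def test_stream_shorter_than_window(self):
        assert extract_windows(make_grid(100), deceased=True, spec=WindowSpec()) == []

    @given(
        st.integers(10, 500),
        st.integers(5, 200),
        st.integers(1, 80),
        st.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_count_formula_randomised(self, n_points, w_points, step, deceased):
        grid = make_grid(n_points, dt=1.0, n_channels=1)
        spec = WindowSpec(
            window_minutes=w_points / 60.0, minority_step_points=step,
            min_points_per_window=0,
        )
        wins = extract_windows(grid, deceased, spec)
        if deceased:
            expected = (n_points - w_points) // step + 1 if n_points >= w_points else 0
        else:
            expected = n_points // w_points
        assert len(wins) == expected
        for start, block in wins:
            assert block.shape == (1, w_points)

    def test_sparse_windows_dropped(self):
        grid = make_grid(240)
        grid.observed[:] = False
        grid.observed[:, :130] = True  # only the first window has data
        spec = WindowSpec(min_points_per_window=30)
        wins = extract_windows(grid, deceased=False, spec=spec)
        assert [s for s, _ in wins] == [0]


class TestWindowStatistics:
    def test_constant_window_forced_values(self):
        stats = window_statistics(np.full(120, 1.7))
        for name in ("sd", "range", "iqr", "slope", "shannon_entropy",
                     "sample_entropy", "psd_power", "skewness", "kurtosis"):
            assert stats[name] == 0.0, name
        assert stats["mean"] == pytest.approx(1.7, abs=1e-12)
        assert stats["median"] == stats["min"] == stats["max"] == 1.7

    def test_alternating_window_against_brute_force(self):
        x = np.tile([0.0, 1.0], 60)
        stats = window_statistics(x)
        assert stats["mean"] == pytest.approx(0.5)
        assert stats["sd"] == pytest.approx(0.5)
        assert stats["sample_entropy"] == pytest.approx(
            brute_force_sample_entropy(x), abs=1e-12
        )

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_sample_entropy_matches_brute_force_on_noise(self, seed):
        x = np.random.default_rng(seed).normal(size=80)
        assert sample_entropy(x) == pytest.approx(
            brute_force_sample_entropy(x), abs=1e-12
        )

    def test_ramp_slope_and_parseval(self):
        dt = 5.0
        times = np.arange(120) * dt
        x = np.linspace(0.0, 1.0, 120)
        stats = window_statistics(x, times)
        assert stats["slope"] == pytest.approx(1.0 / (times[-1] - times[0]))
        assert stats["psd_power"] == pytest.approx(x.var(), abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_psd_power_equals_variance_random(self, seed):
        x = np.random.default_rng(seed).normal(size=301)
        assert window_statistics(x)["psd_power"] == pytest.approx(x.var(), abs=1e-9)

    def test_vectorised_block_matches_scalar_path(self):
        rng = np.random.default_rng(11)
        windows = rng.normal(size=(6, 90))
        dt = 2.0
        block = _window_statistics_block(windows, dt)
        for i in range(6):
            ref = window_statistics(windows[i], np.arange(90) * dt)
            np.testing.assert_allclose(
                block[i], [ref[name] for name in STAT_NAMES], rtol=1e-9, atol=1e-9
            )

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            window_statistics(np.array([]))


EHR_ROW = {
    "patient_id": "PX",
    "age_months": 2.0,
    "age_group": "infant",
    "weight_kg": 4.5,
    "gender": "male",
    "diagnosis_group": "cardiovascular",
    "invasive_ventilation": True,
    "vaso_type": "single",
    "inhaled_no": False,
    "ecmo": False,
    "pim3_risk": 0.033,
    "critical_incident": "none",
    "transport_minutes": 200.0,
}


class TestAssembly:
    def _stats(self):
        rng = np.random.default_rng(0)
        return {ch: window_statistics(rng.normal(size=60)) for ch in CHANNELS}

    def test_vector_has_documented_length_and_order(self):
        vec = assemble_sample(EHR_ROW, self._stats())
        assert list(vec) == feature_columns()
        assert len(vec) == 21 + 7 * 13 == 112

    def test_pim3_passthrough(self):
        vec = assemble_sample(EHR_ROW, self._stats())
        assert vec["pim3_risk"] == 0.033

    def test_vaso_codebook_distinguishes_levels(self):
        encodings = set()
        for vaso in ("none", "single", "multiple"):
            row = dict(EHR_ROW, vaso_type=vaso)
            vec = assemble_sample(row, self._stats())
            encodings.add((vec["vaso_single"], vec["vaso_multiple"]))
        assert len(encodings) == 3

    def test_missing_channel_rejected(self):
        stats = self._stats()
        del stats["TEMP"]
        with pytest.raises(KeyError, match="TEMP"):
            assemble_sample(EHR_ROW, stats)

    def test_static_block_names_fixed(self):
        assert len(STATIC_FEATURES) == 21
        assert feature_columns()[:21] == list(STATIC_FEATURES)
        assert feature_columns()[21:34] == [f"HR_{s}" for s in STAT_NAMES]


class TestCohortSamples:
    def test_samples_labelled_by_patient_outcome(self, small_cohort, small_model):
        _, ehr, _ = small_cohort
        samples = small_model.samples
        died = ehr.set_index("patient_id")["died_30d"].astype(int)
        assert (samples["label"].to_numpy()
                == died.loc[samples["patient_id"]].to_numpy()).all()
        assert not samples[feature_columns()].isna().any().any()

    def test_windows_stay_inside_monitored_interval(self, small_cohort, small_model):
        cfg, ehr, vitals = small_cohort
        w_s = small_model.window_spec.window_minutes * 60.0
        last = vitals.groupby("patient_id", observed=True)["time_s"].max()
        for pid, group in small_model.samples.groupby("patient_id"):
            assert group["window_start_s"].max() + w_s <= last[pid] + cfg.sampling_interval_s

    def test_featurisation_is_deterministic(self, small_cohort):
        from vitalrisk import preprocess_cohort

        _, ehr, vitals = small_cohort
        grids = preprocess_cohort(vitals, ehr)
        s1 = build_samples(ehr, grids)
        s2 = build_samples(ehr, grids)
        pd.testing.assert_frame_equal(s1, s2)
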