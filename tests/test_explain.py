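"""Shapley attribution axioms, risk traces, and transition detection."""

import itertools
import math

import numpy as np
import pytest

from vitalrisk import (
    AttributionVector,
    RiskTrace,
    detect_transitions,
    risk_trace,
    shapley_attributions,
)
from vitalrisk.preprocessing import PatientZGrid


def brute_force_shapley(predict_fn, x, background, j):
    """phi_j by direct permutation-definition average."""
    d = len(x)
    total = 0.0
    for perm in itertools.permutations(range(d)):
        pos = perm.index(j)
        before = list(perm[:pos])
        vals_without = np.mean(
            [predict_fn(_mix(x, b, before)[None, :])[0] for b in background]
        )
        vals_with = np.mean(
            [predict_fn(_mix(x, b, before + [j])[None, :])[0] for b in background]
        )
        total += vals_with - vals_without
    return total / math.factorial(d)


def _mix(x, b, idx):
    out = b.copy()
    out[idx] = x[idx]
    return out


def linear_predict(coef, intercept=0.0):
    def f(X):
        return X @ coef + intercept

    return f


class TestExactShapley:
    def test_single_feature_gets_full_gap(self):
        f = linear_predict(np.array([2.0]), 1.0)
        att = shapley_attributions(f, np.array([3.0]), np.array([[1.0]]), mode="exact")
        assert att.contributions[0] == pytest.approx(att.prediction - att.base_value)

    def test_linear_model_closed_form(self):
        rng = np.random.default_rng(0)
        coef = np.array([1.5, -2.0, 0.7, 0.0, 3.1])
        f = linear_predict(coef, 0.2)
        x = rng.normal(size=5)
        background = rng.normal(size=(30, 5))
        att = shapley_attributions(f, x, background, mode="exact")
        expected = coef * (x - background.mean(axis=0))
        np.testing.assert_allclose(att.contributions, expected, atol=1e-9)
        assert att.local_accuracy_gap() <= 1e-9

    def test_matches_brute_force_on_nonlinear_model(self):
        rng = np.random.default_rng(1)

        def f(X):
            return np.tanh(X[:, 0] * X[:, 1]) + X[:, 2] ** 2

        x = rng.normal(size=3)
        background = rng.normal(size=(8, 3))
        att = shapley_attributions(f, x, background, mode="exact")
        for j in range(3):
            assert att.contributions[j] == pytest.approx(
                brute_force_shapley(f, x, background, j), abs=1e-9
            )

    def test_symmetric_duplicate_features_share_credit(self):
        def f(X):
            return X[:, 0] + X[:, 1]

        x = np.array([2.0, 2.0])
        background = np.zeros((5, 2))
        att = shapley_attributions(f, x, background, mode="exact")
        assert att.contributions[0] == pytest.approx(att.contributions[1], abs=1e-12)

    def test_dummy_feature_gets_zero(self):
        def f(X):
            return X[:, 0] * 2.0  # ignores feature 1

        rng = np.random.default_rng(2)
        att = shapley_attributions(
            f, rng.normal(size=2), rng.normal(size=(20, 2)), mode="exact"
        )
        assert att.contributions[1] == pytest.approx(0.0, abs=1e-12)

    def test_cap_and_empty_background_rejected(self):
        f = linear_predict(np.ones(20))
        with pytest.raises(ValueError, match="cap"):
            shapley_attributions(f, np.zeros(20), np.zeros((2, 20)), mode="exact")
        with pytest.raises(ValueError, match="empty"):
            shapley_attributions(
                linear_predict(np.ones(2)), np.zeros(2), np.zeros((0, 2)), mode="exact"
            )


class TestSampledShapley:
    def test_local_accuracy_holds_exactly(self):
        rng = np.random.default_rng(3)
        coef = rng.normal(size=6)
        f = linear_predict(coef)
        att = shapley_attributions(
            f, rng.normal(size=6), rng.normal(size=(15, 6)),
            mode="sampled", n_perms=150, seed=0,
        )
        assert att.local_accuracy_gap() <= 1e-9
        assert att.standard_errors is not None

    def test_converges_to_exact_with_more_permutations(self):
        rng = np.random.default_rng(4)

        def f(X):
            return np.sin(X[:, 0]) + X[:, 1] * X[:, 2] - 0.5 * X[:, 3]

        x = rng.normal(size=4)
        background = rng.normal(size=(10, 4))
        exact = shapley_attributions(f, x, background, mode="exact").contributions

        def err(n_perms, seed):
            att = shapley_attributions(
                f, x, background, mode="sampled", n_perms=n_perms, seed=seed
            )
            return np.abs(att.contributions - exact).max()

        coarse = np.median([err(200, s) for s in range(5)])
        fine = np.median([err(3200, s) for s in range(5)])
        assert fine < coarse  # error shrinks as n_perms grows (x16)

    def test_too_few_permutations_rejected(self):
        f = linear_predict(np.ones(2))
        with pytest.raises(ValueError, match="n_perms"):
            shapley_attributions(f, np.zeros(2), np.zeros((2, 2)),
                                 mode="sampled", n_perms=10)

    def test_seeded_sampling_reproducible(self):
        rng = np.random.default_rng(5)
        f = linear_predict(rng.normal(size=4))
        x = rng.normal(size=4)
        bg = rng.normal(size=(12, 4))
        a = shapley_attributions(f, x, bg, mode="sampled", n_perms=120, seed=9)
        b = shapley_attributions(f, x, bg, mode="sampled", n_perms=120, seed=9)
        np.testing.assert_array_equal(a.contributions, b.contributions)


def _trace_from_contributions(contribs, names=None):
    n_windows, d = contribs.shape
    names = names or [f"x{j}" for j in range(d)]
    atts = [
        AttributionVector(names, contribs[i], 0.1, 0.1 + contribs[i].sum())
        for i in range(n_windows)
    ]
    return RiskTrace(
        "PX",
        [600.0 * i for i in range(n_windows)],
        [600.0 * (i + 1) for i in range(n_windows)],
        [a.prediction for a in atts],
        atts,
    )


class TestTransitions:
    def test_all_negative_yields_no_events(self):
        trace = _trace_from_contributions(-np.ones((4, 3)))
        assert detect_transitions(trace) == []

    def test_single_flip_detected_at_right_window(self):
        contribs = np.full((4, 2), -0.1)
        contribs[2:, 0] = 0.2  # feature 0 flips between windows 1 and 2
        events = detect_transitions(_trace_from_contributions(contribs, ["A", "B"]))
        assert len(events) == 1
        assert events[0].feature == "A" and events[0].window_index == 2
        assert events[0].contribution_before == pytest.approx(-0.1)
        assert events[0].contribution_after == pytest.approx(0.2)

    def test_simultaneous_flips_ordered_by_name(self):
        contribs = np.array([[-0.1, -0.2], [0.3, 0.1]])
        events = detect_transitions(_trace_from_contributions(contribs, ["B", "A"]))
        assert [e.feature for e in events] == ["A", "B"]
        assert all(e.window_index == 1 for e in events)

    def test_dead_zone_suppresses_chatter(self):
        contribs = np.array([[-0.01, -0.5], [0.01, 0.5]])
        events = detect_transitions(_trace_from_contributions(contribs, ["A", "B"]),
                                    dead_zone=0.05)
        assert [e.feature for e in events] == ["B"]

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_transitions(_trace_from_contributions(np.zeros((1, 2))))


@pytest.fixture(scope="module")
def trace_inputs(small_results):
    pid = small_results.holdout_risks["patient_id"].iloc[0]
    return small_results, pid


class TestRiskTrace:

    def test_window_count_matches_duration(self, trace_inputs):
        res, pid = trace_inputs
        grid = res.model.grids[pid]
        trace = res.risk_trace(pid, n_perms=100, background_size=20, seed=0)
        w = int(round(600.0 / grid.sampling_interval_s))
        assert len(trace) == grid.times.size // w
        assert trace.window_starts_s == sorted(trace.window_starts_s)

    def test_trace_rows_satisfy_local_accuracy(self, trace_inputs):
        res, pid = trace_inputs
        trace = res.risk_trace(pid, n_perms=100, background_size=20, seed=0)
        for att in trace.attributions:
            assert att.local_accuracy_gap() <= 1e-9

    def test_empty_trace_for_too_short_stream(self, small_results):
        res = small_results
        pid = next(iter(res.model.grids))
        grid = res.model.grids[pid]
        short = PatientZGrid(
            pid, grid.times[:10], grid.z[:, :10], grid.observed[:, :10],
            grid.sampling_interval_s, [],
        )
        record = res.model.ehr.set_index("patient_id").loc[pid].to_dict() | {
            "patient_id": pid
        }
        trace = risk_trace(res.trained, short, record, res.background(10), n_perms=100)
        assert len(trace) == 0
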