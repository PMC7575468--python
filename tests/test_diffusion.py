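"""Simulator validity: closed-form oracles, determinism, discretization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from driftpower import (
    DiffusionParams,
    SimulationError,
    analytic_choice_probability,
    analytic_mean_decision_time,
    sample_trials_exact,
    sato_boundary_sweep,
    simulate_trial,
    simulate_trial_set,
)
from driftpower.diffusion import _euler_batch


def binomial_se(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestParams:
    def test_defaults_are_unbiased(self):
        p = DiffusionParams(drift=2.0, boundary=2.0)
        assert p.start == 1.0
        assert p.unbiased

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"drift": 1.0, "boundary": 0.0},
            {"drift": 1.0, "boundary": 2.0, "start": 0.0},
            {"drift": 1.0, "boundary": 2.0, "start": 2.5},
            {"drift": 1.0, "boundary": 2.0, "non_decision_time": -0.1},
            {"drift": 1.0, "boundary": 2.0, "noise": 0.0},
            {"drift": 1.0, "boundary": 2.0, "dt": 0.0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DiffusionParams(**kwargs)


class TestAnalyticOracles:
    def test_zero_drift_symmetric_start_is_fair_coin(self):
        p = DiffusionParams(drift=0.0, boundary=2.0)
        assert analytic_choice_probability(p) == pytest.approx(0.5)

    def test_choice_probability_closed_form(self):
        p = DiffusionParams(drift=2.0, boundary=2.0)
        # logistic(v*a/s^2) at the unbiased start
        assert analytic_choice_probability(p) == pytest.approx(
            1.0 / (1.0 + np.exp(-4.0)), rel=1e-12
        )

    def test_choice_probability_biased_start_general_formula(self):
        p = DiffusionParams(drift=2.0, boundary=2.0, start=1.0, noise=0.5)
        expected = np.expm1(-2 * 2 * 1.0 / 0.25) / np.expm1(-2 * 2 * 2.0 / 0.25)
        assert analytic_choice_probability(p) == pytest.approx(expected, rel=1e-12)

    def test_mean_decision_time_closed_form(self):
        p = DiffusionParams(drift=2.0, boundary=2.0)
        assert analytic_mean_decision_time(p) == pytest.approx(
            0.5 * np.tanh(2.0), rel=1e-12
        )

    def test_mean_decision_time_zero_drift_limit(self):
        p = DiffusionParams(drift=0.0, boundary=2.0)
        assert analytic_mean_decision_time(p) == pytest.approx(1.0)

    def test_mean_decision_time_requires_unbiased_start(self):
        p = DiffusionParams(drift=2.0, boundary=2.0, start=0.5)
        with pytest.raises(ValueError):
            analytic_mean_decision_time(p)

    def test_mean_decision_time_monotone_in_boundary(self):
        times = [
            analytic_mean_decision_time(DiffusionParams(drift=2.0, boundary=a))
            for a in np.linspace(0.5, 4.0, 10)
        ]
        assert np.all(np.diff(times) > 0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        v=st.floats(-5, 5),
        a=st.floats(0.2, 5),
        w=st.floats(0.05, 0.95),
    )
    def test_choice_probability_bounds_and_drift_monotonicity(self, v, a, w):
        p = DiffusionParams(drift=v, boundary=a, start=w * a)
        prob = analytic_choice_probability(p)
        assert 0.0 <= prob <= 1.0
        bigger = analytic_choice_probability(
            DiffusionParams(drift=v + 0.5, boundary=a, start=w * a)
        )
        assert bigger >= prob - 1e-12


class TestTrialSets:
    def test_requested_length_and_rt_floor(self, rng):
        p = DiffusionParams(drift=2.0, boundary=2.0, non_decision_time=0.3)
        ts = simulate_trial_set(p, 40, rng)
        assert len(ts) == 40
        assert (ts.rt >= 0.3).all()
        assert 0.0 <= ts.correct.mean() <= 1.0

    def test_zero_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_trial_set(DiffusionParams(drift=2.0, boundary=2.0), 0, rng)

    @pytest.mark.parametrize("method", ["exact", "euler"])
    def test_same_seed_reproduces(self, method, rng_factory):
        p = DiffusionParams(drift=2.0, boundary=2.0)
        a = simulate_trial_set(p, 25, rng_factory(7), method=method)
        b = simulate_trial_set(p, 25, rng_factory(7), method=method)
        assert a == b

    def test_single_trial_outcome(self, rng):
        out = simulate_trial(DiffusionParams(drift=2.0, boundary=2.0), rng)
        assert out.rt >= 0.3
        assert isinstance(out.correct, bool)

    def test_max_step_guard_raises(self, rng):
        slow = DiffusionParams(drift=0.0, boundary=5.0, noise=0.2)
        with pytest.raises(SimulationError):
            _euler_batch(slow, 4, rng, max_steps=50)

    def test_trial_frame_schema(self, rng):
        ts = simulate_trial_set(DiffusionParams(drift=2.0, boundary=2.0), 5, rng)
        frame = ts.to_frame(participant_id=3)
        assert list(frame.columns) == ["participant_id", "trial", "correct", "rt_s"]
        assert set(frame["correct"]) <= {0, 1}


class TestSamplersAgainstOracles:
    """Monte-Carlo agreement with the first-passage closed forms."""

    N = 40_000

    @pytest.mark.parametrize("method", ["exact", "euler"])
    @pytest.mark.parametrize("v,a", [(1.0, 1.0), (2.0, 2.0), (3.0, 1.0)])
    def test_accuracy_and_mean_rt_match_closed_forms(self, method, v, a, rng):
        p = DiffusionParams(drift=v, boundary=a, non_decision_time=0.3, dt=0.0005)
        ts = simulate_trial_set(p, self.N, rng, method=method)
        p_true = analytic_choice_probability(p)
        mrt_true = analytic_mean_decision_time(p) + 0.3
        assert abs(ts.correct.mean() - p_true) <= 3 * binomial_se(p_true, self.N)
        se_rt = ts.rt.std(ddof=1) / np.sqrt(self.N)
        assert abs(ts.rt.mean() - mrt_true) <= 3 * se_rt

    def test_zero_drift_hits_either_boundary_equally(self, rng):
        p = DiffusionParams(drift=0.0, boundary=2.0)
        ts = simulate_trial_set(p, 20_000, rng)
        assert abs(ts.correct.mean() - 0.5) <= 3 * binomial_se(0.5, 20_000)

    def test_exact_and_euler_share_rt_distribution(self, rng):
        p = DiffusionParams(drift=2.0, boundary=2.0, dt=0.0005)
        exact = simulate_trial_set(p, 30_000, rng, method="exact").rt
        euler = simulate_trial_set(p, 30_000, rng, method="euler").rt
        qs = np.linspace(0.05, 0.95, 10)
        np.testing.assert_allclose(
            np.quantile(exact, qs), np.quantile(euler, qs), rtol=0.05
        )

    def test_halving_dt_leaves_accuracy_within_noise(self, rng):
        accs = []
        for dt in (0.002, 0.001):
            p = DiffusionParams(drift=2.0, boundary=2.0, dt=dt)
            accs.append(
                simulate_trial_set(p, 30_000, rng, method="euler").correct.mean()
            )
        assert abs(accs[0] - accs[1]) <= 4 * binomial_se(0.982, 30_000)

    def test_exact_sampler_vectorizes_over_parameters(self, rng):
        v = np.array([1.0, 2.0, 3.0])
        a = np.array([2.0, 2.0, 2.0])
        correct, t = sample_trials_exact(
            np.repeat(v, 5000), np.repeat(a, 5000), 1.0, rng
        )
        assert correct.shape == t.shape == (15_000,)
        assert (t > 0).all()


class TestSatoSweep:
    def test_row_count_and_positive_boundaries(self, rng):
        base = DiffusionParams(drift=2.0, boundary=2.0)
        table = sato_boundary_sweep(base, 2.0, 1.0, 200, 40, rng)
        assert len(table) == 200
        assert (table["boundary"] > 0).all()

    def test_speed_accuracy_tradeoff_shape(self, rng):
        """Binned accuracy and mean RT both rise with the boundary."""
        base = DiffusionParams(drift=2.0, boundary=2.0)
        table = sato_boundary_sweep(base, 2.0, 1.0, 600, 40, rng)
        table = table.sort_values("boundary").reset_index(drop=True)
        bins = np.array_split(table.index.to_numpy(), 6)
        acc = [table.loc[idx, "accuracy"].mean() for idx in bins]
        mrt = [table.loc[idx, "mean_rt"].mean() for idx in bins]
        assert np.all(np.diff(acc) > -0.01)
        assert np.all(np.diff(mrt) > -0.01)
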