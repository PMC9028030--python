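"""Closed-form, property and oscillation tests for the shunting core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songmem.shunting import (InputSchedule, NetworkState, ShuntingParams,
                              SignalFunction, ZERO_SIGNAL,
                              feedforward_equilibrium, gwave_peak_path,
                              gwave_sweep_speed, load_params, save_params,
                              simulate, step_network, total_activity)


def _quiet_params(**kw):
    """No recurrent feedback: f and g numerically zero."""
    kw.setdefault("f", ZERO_SIGNAL)
    kw.setdefault("g", ZERO_SIGNAL)
    return ShuntingParams(**kw)


class TestSingleCellEquilibria:
    @pytest.mark.parametrize("I, expected", [
        (0.5, 0.5 / 1.5),        # x* = B I / (A + I)
        (1000.0, 1000.0 / 1001.0),  # saturates strictly below B
    ])
    def test_steady_state_matches_closed_form(self, I, expected):
        params = _quiet_params(A=1.0, B=1.0, C=0.0)
        state = NetworkState.zeros(1)
        sched = InputSchedule.constant([I])
        traj = simulate(state, sched, params, t_end=20.0, dt=0.001)
        assert traj[-1].x[0] == pytest.approx(expected, abs=1e-6)
        assert traj[-1].x[0] < params.B

    def test_zero_input_zero_state_is_fixed_point(self):
        params = _quiet_params()
        state = NetworkState.zeros(3)
        sched = InputSchedule.constant(0.0, n=3)
        traj = simulate(state, sched, params, t_end=1.0)
        assert np.all(traj[-1].x == 0.0)

    def test_zero_horizon_returns_initial_state(self):
        params = _quiet_params()
        state = NetworkState.zeros(2)
        traj = simulate(state, InputSchedule.constant(0.0, n=2), params, 0.0)
        assert len(traj) == 1 and traj[0] is state


class TestNormalization:
    @pytest.mark.parametrize("n, expected_total", [(2, 2 / 3), (4, 4 / 5)])
    def test_total_activity_follows_closed_form(self, n, expected_total):
        params = ShuntingParams(A=1.0, B=1.0)
        x = feedforward_equilibrium(np.ones(n), params)
        assert x.sum() == pytest.approx(expected_total, abs=1e-6)
        assert x.sum() < params.B

    def test_total_activity_of_empty_state_is_zero(self):
        assert total_activity(NetworkState.zeros(4)) == 0.0

    def test_ratio_preservation(self):
        params = ShuntingParams(A=2.0, B=1.5)
        I = np.array([0.2, 0.5, 1.1, 3.0])
        x = feedforward_equilibrium(I, params)
        for i in range(4):
            for j in range(4):
                assert x[i] / x[j] == pytest.approx(I[i] / I[j], rel=1e-6)

    def test_total_monotone_in_input_and_bounded(self):
        params = ShuntingParams(A=1.0, B=1.0)
        totals = [feedforward_equilibrium(np.full(n, 1.0), params).sum()
                  for n in range(1, 9)]
        assert np.all(np.diff(totals) > 0)
        assert max(totals) < params.B


class TestBoundedness:
    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 50), min_size=2, max_size=5),
           st.lists(st.floats(0, 50), min_size=2, max_size=5))
    def test_activities_stay_in_range_for_random_inputs(self, I, J):
        n = min(len(I), len(J))
        params = ShuntingParams(A=1.0, B=1.0, C=0.5,
                                f=SignalFunction("sigmoid", gain=2.0),
                                g=SignalFunction("linear", gain=1.0))
        state = NetworkState.zeros(n)
        sched = InputSchedule.constant(I[:n], J[:n])
        traj = simulate(state, sched, params, t_end=2.0, dt=0.002)
        for s in traj:
            assert np.all(s.x <= params.B + 1e-12)
            assert np.all(s.x >= -params.C - 1e-12)


class TestOscillationGating:
    def _slow_params(self):
        # strong recurrent on-center, slow self-inhibitory interneurons
        return ShuntingParams(
            A=1.0, B=1.0, C=0.5, epsilon=0.1, slow_inhibition=True,
            f=SignalFunction("sigmoid", gain=8.0, power=2.0, half_point=0.4),
            g=SignalFunction("linear", gain=1.0),
            on_center=np.eye(2), off_surround=np.eye(2) * 20.0,
            dt=0.002,
        )

    def _amplitude(self, arousal):
        params = self._slow_params()
        state = NetworkState.zeros(2, slow=True)
        sched = InputSchedule.constant(arousal, n=2)
        traj = simulate(state, sched, params, t_end=120.0, dt=0.002,
                        record_every=5)
        tail = np.array([s.x for s in traj[len(traj) // 2:]])
        return float(tail[:, 0].max() - tail[:, 0].min())

    def test_arousal_gates_oscillation(self):
        """Tonic arousal converts the phasic network into an oscillator."""
        assert self._amplitude(0.01) < 0.05
        assert self._amplitude(1.0) > 0.3

    def test_oscillation_threshold_is_finite(self):
        lo, hi = 0.01, 1.0
        for _ in range(8):
            mid = 0.5 * (lo + hi)
            if self._amplitude(mid) > 0.2:
                hi = mid
            else:
                lo = mid
        assert 0.01 < hi < 1.0


class TestGWave:
    def test_equal_envelopes_peak_at_midpoint(self):
        path = gwave_peak_path(0.0, 1.0, onset2_delay=0.1, sigma=0.7,
                               rise=20.0, decay=8.0, dt=0.001)
        ts = np.array([p[0] for p in path])
        ps = np.array([p[1] for p in path])
        # find the instant where envelopes are closest to equal: peak ~ midpoint
        mid_idx = np.argmin(np.abs(ps - 0.5))
        assert abs(ps[mid_idx] - 0.5) < 0.02

    def test_shorter_isi_sweeps_faster(self):
        speeds = []
        for isi in (0.2, 0.1, 0.05):
            path = gwave_peak_path(0.0, 1.0, onset2_delay=isi, sigma=0.5)
            speeds.append(gwave_sweep_speed(path, 0.0, 1.0))
        assert speeds[0] < speeds[1] < speeds[2]

    def test_larger_separation_sweeps_faster(self):
        speeds = []
        for sep in (0.5, 1.0, 1.5):
            path = gwave_peak_path(0.0, sep, onset2_delay=0.1, sigma=1.0)
            speeds.append(gwave_sweep_speed(path, 0.0, sep))
        assert speeds[0] < speeds[1] < speeds[2]

    def test_disjoint_fields_jump_discontinuously(self):
        path = gwave_peak_path(0.0, 1.0, onset2_delay=0.1, sigma=0.005)
        ps = np.array([p[1] for p in path])
        travelled = ps[(ps > 0.1) & (ps < 0.9)]
        assert travelled.size == 0  # no intermediate positions visited


class TestConfigRoundTrip:
    def test_params_survive_json_round_trip(self, tmp_path):
        params = ShuntingParams(A=2.0, B=1.2, C=0.3, epsilon=0.25,
                                slow_inhibition=True,
                                off_surround=np.array([[0.0, 1.0], [1.0, 0.0]]))
        path = tmp_path / "params.json"
        save_params(params, path)
        loaded = load_params(path)
        assert loaded.A == params.A and loaded.C == params.C
        assert loaded.slow_inhibition
        assert np.allclose(loaded.off_surround, params.off_surround)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ShuntingParams(A=-1.0)
        with pytest.raises(ValueError):
            ShuntingParams(off_surround=np.array([[-1.0]]))
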