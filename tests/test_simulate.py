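"""Integration, equilibration and oscillation metrics."""

import numpy as np
import pytest

from qssareduce import (
    equilibrate,
    integrate,
    oscillation_metrics,
    parse_model,
    shape_mse,
)
from qssareduce.fixtures import SM_EQUILIBRATION_OVERRIDES, pulsed_protocol
from qssareduce.simulate import Trajectory


def test_equilibrate_simple_relaxation():
    toy = parse_model("[variables]\nx\n\n[equations]\nx' = 1 - x\n")
    state = equilibrate(toy)
    assert state[0] == pytest.approx(1.0, abs=1e-8)


def test_equilibrate_sm_rest_state(sm):
    """Without stimulus the simplified model drains: active IKK and the
    nuclear complex vanish exactly, neutral IKK recovers to the total, and
    the free NF-kB / IkBa pools empty through the irreversible association
    flux (the complex-dissociation pathway is not part of this model)."""
    state = dict(zip(sm.variables, equilibrate(sm, SM_EQUILIBRATION_OVERRIDES)))
    assert state["w"] == pytest.approx(0.0, abs=1e-12)
    assert state["z"] == pytest.approx(0.0, abs=1e-12)
    assert state["v"] == pytest.approx(sm.param_value("k2"), rel=1e-6)
    for drained in "pqrsu":
        assert abs(state[drained]) < 1e-8


def test_integrate_constant_field():
    toy = parse_model("[variables]\nx = 5.0\n\n[equations]\nx' = 0\n")
    traj = integrate(toy, toy.initial_conditions, None, 100.0, step=10.0)
    assert np.allclose(traj.series("x"), 5.0)


def test_ikk_pool_is_forward_invariant(sm_traj):
    """v + w <= k2 along the stimulated solution: at the boundary the pool's
    net flux is -k23*w <= 0."""
    k2 = sm_traj.system.param_value("k2")
    pool = sm_traj.series("v") + sm_traj.series("w")
    assert pool.max() <= k2 * (1 + 1e-9)


def test_sinusoid_period_recovered_to_grid_accuracy():
    t = np.arange(0.0, 200.0 + 0.5, 0.5)
    x = np.sin(2 * np.pi * t / 7.0)
    traj = Trajectory(t, x[:, None], ["x"])
    met = oscillation_metrics(traj, "x", transient=0.0)
    assert met.oscillatory
    assert met.period_min == pytest.approx(7.0 / 60.0, abs=0.5 / 60.0)


def test_constant_readout_not_oscillatory():
    t = np.arange(0.0, 100.0, 1.0)
    traj = Trajectory(t, np.full((len(t), 1), 2.0), ["x"])
    met = oscillation_metrics(traj, "x", transient=0.0)
    assert not met.oscillatory


def test_ringdown_flagged_not_sustained():
    t = np.arange(0.0, 600.0, 0.5)
    x = np.exp(-t / 80.0) * np.sin(2 * np.pi * t / 7.0)
    traj = Trajectory(t, x[:, None], ["x"])
    met = oscillation_metrics(traj, "x", transient=0.0)
    assert not met.oscillatory
    assert not met.sustained


def test_shape_mse_zero_for_identical_and_rescaled_waveforms():
    t = np.arange(0.0, 400.0, 0.1)

    def wave(period):
        return np.sin(2 * np.pi * t / period) + 0.3 * np.sin(4 * np.pi * t / period)

    a = Trajectory(t, wave(11.0)[:, None], ["x"])
    b = Trajectory(t, wave(23.0)[:, None], ["x"])
    assert shape_mse(a, a, "x", transient=0.0) == 0.0
    assert shape_mse(a, b, "x", transient=0.0) < 1e-4


def test_pulsed_integration_matches_segmentwise_runs(sm):
    """One call over a pulse train equals manual per-segment integration."""
    proto = pulsed_protocol(n_pulses=2)
    t_end = 150 * 60.0
    traj = integrate(sm, sm.initial_conditions, proto, t_end, step=30.0)
    # split the run at an arbitrary interior time and glue the halves
    mid = 75 * 60.0
    first = integrate(sm, sm.initial_conditions, proto, mid, step=30.0)
    shifted = StimulusShift(proto, mid)
    second = integrate(sm, first.final_state(), shifted, t_end - mid, step=30.0)
    glued = np.vstack([first.states, second.states[1:]])
    assert glued.shape == traj.states.shape
    assert np.max(np.abs(glued - traj.states)) < 1e-8


class StimulusShift:
    """A protocol translated to start at a later reference time."""

    def __init__(self, proto, offset):
        self.input = proto.input
        self.default = proto.default
        self.segments = tuple((a - offset, b - offset, v)
                              for a, b, v in proto.segments if b > offset)
        self._proto, self._offset = proto, offset

    def value(self, t):
        return self._proto.value(t + self._offset)

    def edges(self, t_end):
        return [e - self._offset for e in self._proto.edges(self._offset + t_end)
                if e > self._offset]

    def period_hint(self):
        return self._proto.period_hint()


def test_halved_tolerances_leave_period_unchanged(sm, continuous):
    """Integration-tolerance refinement moves the period by < 0.1%."""
    t_end, trans = 2000 * 60.0, 800 * 60.0
    p = []
    for rtol, atol in [(1e-8, 1e-12), (5e-9, 5e-13)]:
        traj = integrate(sm, sm.initial_conditions, continuous, t_end,
                         rtol=rtol, atol=atol)
        p.append(oscillation_metrics(traj, "r", trans).period_min)
    assert abs(p[1] - p[0]) / p[0] < 1e-3
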