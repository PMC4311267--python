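"""Stiff integration under stimulus protocols and oscillation metrics.

The representative solutions of the NF-kB models are limit cycles (or
entrained pulse responses) of stiff rational ODE systems; everything here is
built on :func:`scipy.integrate.solve_ivp` with LSODA and on
:func:`scipy.signal.find_peaks` for period/amplitude readouts.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp
from scipy.signal import find_peaks

from .model_core import (
    ModelError,
    ODESystemSpec,
    StimulusProtocol,
    make_symbol,
    xreplace_shared,
)

logger = logging.getLogger("qssareduce")

__all__ = [
    "Trajectory",
    "OscillationMetrics",
    "IntegrationError",
    "compile_outputs",
    "equilibrate",
    "integrate",
    "oscillation_metrics",
    "shape_mse",
    "pulse_response",
]

#: default reporting-grid step (s)
DEFAULT_STEP = 10.0
#: default relative / absolute integration tolerances
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-12
#: horizon and transient for continuous-input representative solutions (s)
CONTINUOUS_HORIZON = 3000 * 60.0
CONTINUOUS_TRANSIENT = 1000 * 60.0
#: pulsed-input representative solutions: input periods simulated / discarded
PULSED_PERIODS = 10
PULSED_DISCARD = 2
#: convergence criterion for equilibration: max_i |f_i| / max(|x_i|, floor)
EQUILIBRIUM_RTOL = 1e-9
EQUILIBRIUM_FLOOR = 1e-6
EQUILIBRATE_CAP = 1e7
#: concentrations below -NEGATIVE_TOL trigger a warning flag
NEGATIVE_TOL = 1e-9


class IntegrationError(RuntimeError):
    """Solver failure or non-convergence."""


# ---------------------------------------------------------------------------
# Compilation of def-graph expressions to fast callables
# ---------------------------------------------------------------------------

def compile_outputs(system, outputs, free_params=(), extra_defs=None):
    """Compile expressions over a system into one numeric function.

    Returns ``f(y, inputs, params) -> list of values`` where ``y`` is the
    dynamic state (in ``system.variables`` order), ``inputs`` the current
    input-signal values (in ``system.inputs`` order) and ``params`` the
    values of ``free_params`` (all other parameters are baked in numerically).
    Definitions are evaluated once per call, in dependency order, so deeply
    reduced models stay cheap to evaluate.  Accepts vectorised ``y``/``inputs``
    (trailing sample axis) for trajectory-wide evaluation.
    """
    outputs = [sp.sympify(o) for o in outputs]
    defs = dict(system.defs)
    for s, e in (extra_defs or {}).items():
        defs[s] = sp.sympify(e)
    topo = _topo(defs)

    rule = {psym: sp.Float(v) for psym, v in system.numeric_parameters().items()
            if str(psym) not in free_params}
    vsyms = [make_symbol(v) for v in system.variables]
    isyms = [make_symbol(i) for i in system.inputs]
    psyms = [make_symbol(p) for p in free_params]
    args = (vsyms, isyms, psyms)

    def_funs = []
    for i, s in enumerate(topo):
        fn = sp.lambdify(args + (topo[:i],), xreplace_shared(defs[s], rule),
                         modules="numpy", cse=True)
        def_funs.append(fn)
    out_fun = sp.lambdify(args + (topo,), [xreplace_shared(o, rule)
                                           for o in outputs],
                          modules="numpy", cse=True)

    def f(y, inputs=(), params=()):
        dvals = []
        for fn in def_funs:
            dvals.append(fn(y, inputs, params, dvals))
        return out_fun(y, inputs, params, dvals)

    return f


def _topo(defs):
    order, state = [], {}

    def visit(s):
        st = state.get(s)
        if st == 2:
            return
        if st == 1:
            raise ModelError(f"cyclic definitions at {s}")
        state[s] = 1
        for fs in defs[s].free_symbols:
            if fs in defs:
                visit(fs)
        state[s] = 2
        order.append(s)

    for s in defs:
        visit(s)
    return order


def rhs_function(system, free_params=()):
    """Compiled right-hand side ``f(y, inputs, params) -> ndarray``."""
    fun = compile_outputs(system, [system.rhs[v] for v in system.variables],
                          free_params=free_params)

    def f(y, inputs=(), params=()):
        return np.asarray(fun(y, inputs, params), dtype=float)

    return f


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """A sampled solution: uniform time grid (s) and state matrix (time x var)."""

    times: np.ndarray
    states: np.ndarray
    variables: list
    system: ODESystemSpec = None
    protocol: StimulusProtocol = None
    negative_excursion: bool = False

    def series(self, name: str) -> np.ndarray:
        if name in self.variables:
            return self.states[:, self.variables.index(name)]
        raise ModelError(f"{name!r} is not a dynamic variable of this trajectory")

    def input_series(self, name: str = None) -> np.ndarray:
        proto = self.protocol
        if proto is None or (name is not None and proto.input != name):
            return np.zeros_like(self.times)
        return np.array([proto.value(t) for t in self.times])

    def final_state(self) -> dict:
        return dict(zip(self.variables, self.states[-1]))

    def window(self, t_start: float) -> "Trajectory":
        m = self.times >= t_start
        return Trajectory(self.times[m], self.states[m], self.variables,
                          self.system, self.protocol, self.negative_excursion)

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("time_s," + ",".join(self.variables) + "\n")
        for t, row in zip(self.times, self.states):
            buf.write(f"{t:.6g}," + ",".join(f"{x:.10g}" for x in row) + "\n")
        return buf.getvalue()

    @classmethod
    def from_csv(cls, text: str) -> "Trajectory":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split(",")
        if header[0] != "time_s":
            raise ModelError("trajectory CSV must start with a time_s column")
        data = np.array([[float(x) for x in ln.split(",")] for ln in lines[1:]])
        return cls(data[:, 0], data[:, 1:], header[1:])


def _state_vector(system, state0):
    if isinstance(state0, dict):
        missing = [v for v in system.variables if v not in state0]
        if missing:
            raise ModelError(f"initial state missing variables {missing}")
        return np.array([float(state0[v]) for v in system.variables])
    arr = np.asarray(state0, dtype=float)
    if arr.shape != (system.dim,):
        raise ModelError(
            f"initial state has shape {arr.shape}, expected ({system.dim},)"
        )
    return arr


def integrate(system, state0, protocol=None, t_end=CONTINUOUS_HORIZON,
              step=DEFAULT_STEP, rtol=DEFAULT_RTOL, atol=DEFAULT_ATOL,
              method="LSODA"):
    """Integrate under a piecewise-constant stimulus protocol.

    The solver is stopped and restarted at every protocol discontinuity so
    each segment sees a smooth vector field; the solution is sampled on a
    uniform reporting grid.  Concentration excursions below ``-NEGATIVE_TOL``
    are flagged on the returned :class:`Trajectory` (the solver itself runs
    unconstrained).
    """
    y0 = _state_vector(system, state0)
    if not np.all(np.isfinite(y0)):
        raise ModelError("initial state contains non-finite values")
    if protocol is not None and protocol.input not in system.inputs and \
            protocol.input not in system.parameters:
        raise ModelError(
            f"protocol drives {protocol.input!r}, not an input or parameter "
            f"of {system.label!r}"
        )

    fun = rhs_function(system)
    times = np.arange(0.0, t_end + 0.5 * step, step)
    states = np.empty((len(times), system.dim))
    states[0] = y0

    edges = [0.0] + (protocol.edges(t_end) if protocol is not None else []) + [t_end]
    filled = 1
    for a, b in zip(edges, edges[1:]):
        ivals = _input_values(system, protocol, 0.5 * (a + b))
        seg_mask = (times > a) & (times <= b)
        t_eval = times[seg_mask]
        sol = solve_ivp(lambda t, y: fun(y, ivals), (a, b), y0, method=method,
                        rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{a:g}, {b:g}] for {system.label!r}: {sol.message}"
            )
        if len(t_eval):
            states[filled:filled + len(t_eval)] = sol.y.T
            filled += len(t_eval)
        # continue from the exact segment end, not the last reporting sample
        if sol.t[-1] < b:
            tail = solve_ivp(lambda t, y: fun(y, ivals),
                             (sol.t[-1] if len(sol.t) else a, b),
                             sol.y[:, -1] if len(sol.t) else y0,
                             method=method, rtol=rtol, atol=atol)
            if not tail.success:
                raise IntegrationError(
                    f"solver failed closing segment [{a:g}, {b:g}]: {tail.message}"
                )
            y0 = tail.y[:, -1]
        else:
            y0 = sol.y[:, -1]
    states = states[:filled]
    times = times[:filled]
    if not np.all(np.isfinite(states)):
        raise IntegrationError(f"non-finite state in trajectory of {system.label!r}")
    negative = bool((states < -NEGATIVE_TOL).any())
    if negative:
        logger.warning("trajectory of %s dips below -%g", system.label, NEGATIVE_TOL)
    return Trajectory(times, states, list(system.variables), system, protocol,
                      negative_excursion=negative)


def _input_values(system, protocol, t):
    vals = []
    for name in system.inputs:
        if protocol is not None and protocol.input == name:
            vals.append(protocol.value(t))
        else:
            vals.append(0.0)
    return vals


def equilibrate(system, overrides=None, rtol=1e-10, atol=1e-14,
                cap=EQUILIBRATE_CAP):
    """Relax the system to steady state with all stimulus inputs off.

    Starts from zeros, with ``overrides`` (name -> value) applied; override
    entries for variables the system no longer carries are ignored, so the
    same rest-state specification serves a whole reduction lineage.
    Integration proceeds in growing chunks until
    ``max_i |f_i| / max(|x_i|, 1e-6) < 1e-9`` or the time cap is reached.

    Returns the state vector (``system.variables`` order).
    """
    y = np.zeros(system.dim)
    for name, val in (overrides or {}).items():
        if name in system.variables:
            y[system.variables.index(name)] = float(val)
    fun = rhs_function(system)
    ivals = [0.0] * len(system.inputs)

    def residual(state):
        f = np.abs(fun(state, ivals))
        scale = np.maximum(np.abs(state), EQUILIBRIUM_FLOOR)
        return float(np.max(f / scale))

    elapsed, chunk = 0.0, 1e5
    while True:
        sol = solve_ivp(lambda t, yy: fun(yy, ivals), (0.0, chunk), y,
                        method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"equilibration failed for {system.label!r}: {sol.message}"
            )
        y = sol.y[:, -1]
        if not np.all(np.isfinite(y)):
            raise IntegrationError(f"divergent equilibration for {system.label!r}")
        elapsed += chunk
        if residual(y) < EQUILIBRIUM_RTOL:
            return y
        if elapsed >= cap:
            raise IntegrationError(
                f"no equilibrium within {cap:g} s for {system.label!r} "
                f"(residual {residual(y):.3g})"
            )
        chunk = min(3 * chunk, cap - elapsed)


# ---------------------------------------------------------------------------
# Oscillation metrics
# ---------------------------------------------------------------------------

#: peak prominence threshold, as a fraction of the post-transient range
PEAK_PROMINENCE = 0.05
#: maximum coefficient of variation of peak intervals for "oscillatory"
MAX_INTERVAL_CV = 0.10
#: a ring-down is flagged when late peak heights fall below this fraction of
#: early ones (a stable limit cycle keeps the ratio near 1)
SUSTAINED_RATIO = 0.5


@dataclass
class OscillationMetrics:
    """Limit-cycle summary of one readout over a post-transient window."""

    oscillatory: bool
    period_min: float | None = None
    amplitude: float = 0.0
    peak_times_min: np.ndarray = field(default_factory=lambda: np.array([]))
    n_cycles: int = 0
    interval_cv: float | None = None
    sustained: bool = True
    reason: str = ""

    def __bool__(self):
        return self.oscillatory


def oscillation_metrics(traj, readout="r", transient=CONTINUOUS_TRANSIENT):
    """Period / amplitude of a readout after discarding ``[0, transient)``.

    Local maxima with prominence >= 5% of the window range are counted as
    cycle peaks; the period is the mean peak-to-peak interval (reported in
    minutes), the amplitude is max - min over the window (uM).  The readout
    is "not oscillatory" when fewer than 3 peaks are found, when the
    intervals vary by more than 10% (CV), or when peak heights decay (a
    ring-down toward a stable equilibrium rather than a limit cycle).
    """
    w = traj.window(transient)
    if len(w.times) < 8:
        raise ModelError("trajectory shorter than the requested transient")
    x = w.series(readout)
    rng = float(x.max() - x.min())
    if rng <= 0:
        return OscillationMetrics(False, amplitude=0.0, reason="constant readout")
    peaks, props = find_peaks(x, prominence=PEAK_PROMINENCE * rng)
    if len(peaks) < 3:
        return OscillationMetrics(False, amplitude=rng, n_cycles=len(peaks),
                                  reason=f"only {len(peaks)} peaks")
    tpk = w.times[peaks] / 60.0
    intervals = np.diff(tpk)
    cv = float(intervals.std() / intervals.mean())
    prom = props["prominences"]
    half = max(1, len(prom) // 3)
    ratio = float(np.mean(prom[-half:]) / np.mean(prom[:half]))
    sustained = ratio >= SUSTAINED_RATIO
    if cv > MAX_INTERVAL_CV:
        return OscillationMetrics(False, amplitude=rng, peak_times_min=tpk,
                                  n_cycles=len(peaks), interval_cv=cv,
                                  sustained=sustained,
                                  reason=f"interval CV {cv:.2f} > {MAX_INTERVAL_CV}")
    if not sustained:
        return OscillationMetrics(False, amplitude=rng, peak_times_min=tpk,
                                  n_cycles=len(peaks), interval_cv=cv,
                                  sustained=False,
                                  reason=f"peaks decaying (late/early {ratio:.2f})")
    return OscillationMetrics(True, period_min=float(intervals.mean()),
                              amplitude=rng, peak_times_min=tpk,
                              n_cycles=len(peaks), interval_cv=cv)


def _one_cycle(traj, readout, transient):
    """Extract one full peak-to-peak cycle, rescaled to a unit-period grid."""
    met = oscillation_metrics(traj, readout, transient)
    if not met:
        raise ModelError(
            f"{traj.system.label if traj.system else 'trajectory'} is not "
            f"oscillatory in {readout!r}: {met.reason}"
        )
    w = traj.window(transient)
    x = w.series(readout)
    rng = x.max() - x.min()
    peaks, _ = find_peaks(x, prominence=PEAK_PROMINENCE * rng)
    a, b = peaks[-2], peaks[-1]
    phase = (w.times[a:b + 1] - w.times[a]) / (w.times[b] - w.times[a])
    grid = np.linspace(0.0, 1.0, 1000)
    return np.interp(grid, phase, x[a:b + 1])


def shape_mse(traj_a, traj_b, readout="r", transient=CONTINUOUS_TRANSIENT):
    """Waveform discrepancy of one oscillation cycle, period removed.

    One peak-to-peak cycle of each trajectory is rescaled to unit period,
    resampled on a common 1000-point grid aligned at the peak, and the mean
    squared difference of the readout returned (uM^2).  Identical waveforms
    at different periods give zero by construction.
    """
    ca = _one_cycle(traj_a, readout, transient)
    cb = _one_cycle(traj_b, readout, transient)
    return float(np.mean((ca - cb) ** 2))


# ---------------------------------------------------------------------------
# Pulse-train responses
# ---------------------------------------------------------------------------

#: a "full-size" translocation peak: prominence >= this fraction of the range
MAJOR_PROMINENCE = 0.2


@dataclass
class PulseResponse:
    """Entrainment summary of a readout under a periodic pulse protocol."""

    n_pulses: int
    n_major_peaks: int
    response_period_min: float | None
    entrainment_ratio: float

    @property
    def entrained(self) -> bool:
        return abs(self.entrainment_ratio - 1.0) <= 0.15

    @property
    def period_doubled(self) -> bool:
        return abs(self.entrainment_ratio - 0.5) <= 0.15


def pulse_response(traj, readout="r", transient=None):
    """Count full-size response peaks per stimulus pulse.

    A driven oscillator that answers every pulse has one major peak (20%
    prominence) per pulse; a period-doubled response answers every second
    pulse only.  ``transient`` defaults to two input periods.
    """
    proto = traj.protocol
    if proto is None or proto.period_hint() is None:
        raise ModelError("pulse_response needs a periodic pulse protocol")
    period = proto.period_hint()
    if transient is None:
        transient = PULSED_DISCARD * period
    w = traj.window(transient)
    x = w.series(readout)
    rng = x.max() - x.min()
    if rng <= 0:
        return PulseResponse(0, 0, None, 0.0)
    peaks, _ = find_peaks(x, prominence=MAJOR_PROMINENCE * rng)
    starts = [a for a, _, _ in proto.segments if transient <= a < w.times[-1]]
    n_pulses = len(starts)
    tpk = w.times[peaks] / 60.0
    resp = float(np.diff(tpk).mean()) if len(tpk) >= 2 else None
    ratio = len(peaks) / n_pulses if n_pulses else 0.0
    return PulseResponse(n_pulses, len(peaks), resp, ratio)
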