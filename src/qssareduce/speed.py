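"""Speed coefficients: ranking variables by relaxation rate along a solution.

The speed coefficient of variable i is lambda_i(t) = |d f_i / d x_i|, the
absolute diagonal Jacobian entry evaluated along a representative solution.
A large lambda_i means x_i relaxes quickly toward its momentary steady state
and is a candidate for quasi-steady-state elimination.  Ties between
variables whose instantaneous speeds cross are broken by the
"fastest at its slowest" rule: rank by the minimum of lambda_i over the
analysed window and pick the variable whose minimum is largest.

For reduced systems the diagonal entry chains through the substitution
definitions, which is exactly the derivative of the fully substituted
right-hand side.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass

import numpy as np
import sympy as sp

from .model_core import ModelError, make_symbol
from .simulate import compile_outputs

logger = logging.getLogger("qssareduce")

__all__ = ["SpeedProfile", "speed_coefficients", "rank_fastest"]


@dataclass
class SpeedProfile:
    """Per-variable lambda_i(t) series on a trajectory's reporting grid."""

    variables: list
    times: np.ndarray
    values: np.ndarray          # (time, variable), already absolute
    window_start: float = 0.0   # default ranking window (s)

    def series(self, name: str) -> np.ndarray:
        return self.values[:, self.variables.index(name)]

    def minima(self, window_start: float | None = None) -> dict:
        """min over time of each lambda_i, restricted to ``t >= window_start``."""
        t0 = self.window_start if window_start is None else window_start
        m = self.times >= t0
        if not m.any():
            raise ModelError("ranking window is empty")
        return {v: float(self.values[m, i].min())
                for i, v in enumerate(self.variables)}

    def argmin_times(self, window_start: float | None = None) -> dict:
        t0 = self.window_start if window_start is None else window_start
        m = np.where(self.times >= t0)[0]
        return {v: float(self.times[m[np.argmin(self.values[m, i])]])
                for i, v in enumerate(self.variables)}

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("time_s," + ",".join(self.variables) + "\n")
        for t, row in zip(self.times, self.values):
            buf.write(f"{t:.6g}," + ",".join(f"{x:.10g}" for x in row) + "\n")
        return buf.getvalue()

    def summary_csv(self, window_start: float | None = None) -> str:
        mins = self.minima(window_start)
        arg = self.argmin_times(window_start)
        lines = ["variable,min_lambda_per_s,argmin_time_s"]
        for v, m in sorted(mins.items(), key=lambda kv: (-kv[1], kv[0])):
            lines.append(f"{v},{m:.10g},{arg[v]:.6g}")
        return "\n".join(lines) + "\n"


def speed_coefficients(system, traj, window_start=0.0, thin=1):
    """Evaluate lambda_i(t) = |d f_i / d x_i| along a trajectory.

    The diagonal derivative is formed symbolically once per variable
    (chaining through the substitution definitions of reduced models) and
    then evaluated pointwise on the reporting grid; ``thin`` keeps every
    n-th sample.  ``window_start`` sets the profile's default ranking
    window (seconds); the series itself always covers the whole trajectory.
    """
    if list(traj.variables) != list(system.variables):
        raise ModelError("trajectory does not match the system's variables")
    aux = {}
    try:
        diag = [system.total_gradient(system.rhs[v], v, aux=aux)
                for v in system.variables]
    except Exception as exc:  # malformed expression surfaced by sympy
        raise ModelError(f"symbolic differentiation failed: {exc}") from exc
    fun = compile_outputs(system, [sp.Abs(d) for d in diag], extra_defs=aux)

    idx = np.arange(0, len(traj.times), max(1, int(thin)))
    tvals = traj.times[idx]
    inputs_t = np.array([[traj.protocol.value(t) if traj.protocol is not None
                          and traj.protocol.input == name else 0.0
                          for name in system.inputs] for t in tvals])
    vals = fun(traj.states[idx].T, inputs_t.T)
    out = np.column_stack([np.broadcast_to(np.asarray(v, dtype=float),
                                           tvals.shape) for v in vals])
    return SpeedProfile(list(system.variables), tvals, out,
                        window_start=window_start)


def rank_fastest(profile, exclude=(), window_start=None):
    """Order variables for elimination, fastest-at-its-slowest first.

    Returns a list of ``(variable, min_lambda)`` sorted by descending
    minimum speed; ties broken lexicographically by name.  ``exclude``
    removes variables from consideration (e.g. readouts that must stay
    dynamic).
    """
    mins = profile.minima(window_start)
    for v in exclude:
        mins.pop(v, None)
    if not mins:
        raise ModelError("all variables excluded from ranking")
    ranked = sorted(mins.items(), key=lambda kv: (-kv[1], kv[0]))
    logger.info("speed ranking: %s",
                ", ".join(f"{v}={m:.3g}" for v, m in ranked))
    return ranked
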