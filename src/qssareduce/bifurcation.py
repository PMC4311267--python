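"""Equilibrium continuation, Hopf localisation and limit-cycle envelopes.

The NF-kB models lose stability of their resting state through a Hopf
bifurcation as the stimulus dose parameter increases; locating that point
(and how it drifts under model reduction) is the package's standard check of
how well a reduced model preserves dynamics away from the representative
solution.  Continuation is a plain parameter grid with Newton-seeded
equilibria plus bisection of eigenvalue sign changes -- adequate here
because the documented ranges contain fold-free equilibrium branches.
Limit cycles are characterised by direct long integration, not collocation.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .model_core import ModelError, make_symbol
from .simulate import (
    CONTINUOUS_HORIZON,
    CONTINUOUS_TRANSIENT,
    IntegrationError,
    compile_outputs,
)

logger = logging.getLogger("qssareduce")

__all__ = [
    "HopfResult",
    "EnvelopePoint",
    "find_equilibrium",
    "hopf_scan",
    "cycle_envelope",
]

#: Newton convergence: max |f_i| below this is an equilibrium
NEWTON_TOL = 1e-12
NEWTON_MAX_ITER = 200
#: bisection stops when the parameter bracket is narrower than this
HOPF_PARAM_TOL = 1e-4
#: a crossing eigenvalue pair must carry at least this imaginary part (1/s)
HOPF_MIN_IMAG = 1e-6
#: |Re| of the critical pair at the reported Hopf point stays below this
HOPF_RESID_TOL = 1e-6


def _system_functions(system, free_params=()):
    """Compiled rhs and Jacobian with ``free_params`` left adjustable.

    The Jacobian chains through the definition table, so for reduced models
    it equals the Jacobian of the fully substituted system.
    """
    aux = {}
    n = system.dim
    jac_rows = []
    for v in system.variables:
        jac_rows.extend(system.total_gradient(system.rhs[v], x, aux=aux)
                        for x in system.variables)
    outputs = [system.rhs[v] for v in system.variables] + jac_rows
    fun = compile_outputs(system, outputs, free_params=free_params,
                          extra_defs=aux)

    def split(y, inputs, params):
        vals = [float(x) for x in fun(y, inputs, params)]
        return (np.array(vals[:n]),
                np.array(vals[n:]).reshape(n, n))

    return split


def _scan_args(system, parameter):
    """Route a scan parameter to the free-parameter slot or the input vector."""
    if parameter in system.parameters:
        free = (parameter,)

        def pack(value):
            return [0.0] * len(system.inputs), [float(value)]
    elif parameter in system.inputs:
        free = ()
        idx = system.inputs.index(parameter)

        def pack(value):
            ivals = [0.0] * len(system.inputs)
            ivals[idx] = float(value)
            return ivals, []
    else:
        raise ModelError(
            f"{parameter!r} is neither a parameter nor an input of "
            f"{system.label!r}")
    return free, pack


def _newton(split, y0, inputs, params, tol=NEWTON_TOL):
    y = np.asarray(y0, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ModelError("equilibrium guess contains non-finite values")
    f, J = split(y, inputs, params)
    for _ in range(NEWTON_MAX_ITER):
        if np.max(np.abs(f)) < tol:
            return y
        try:
            step = np.linalg.solve(J, -f)
        except np.linalg.LinAlgError as exc:
            raise IntegrationError(f"singular Jacobian in Newton: {exc}") from exc
        lam, norm0 = 1.0, np.linalg.norm(f)
        while lam > 1e-8:
            y_new = y + lam * step
            f_new, J_new = split(y_new, inputs, params)
            if np.linalg.norm(f_new) < norm0 or np.max(np.abs(f_new)) < tol:
                y, f, J = y_new, f_new, J_new
                break
            lam *= 0.5
        else:
            raise IntegrationError("Newton damping failed to reduce the residual")
    raise IntegrationError(
        f"Newton did not reach |f| < {tol:g} (residual {np.max(np.abs(f)):.3g})")


def find_equilibrium(system, overrides=None, guess=None, tol=NEWTON_TOL):
    """Root of f(x) = 0 by damped Newton with the symbolic Jacobian.

    ``overrides`` maps parameter or input names to values (e.g. fixing the
    stimulus switch); ``guess`` is a state vector or name->value map,
    defaulting to the system's stored initial conditions.  Returns the state
    vector with max |f_i| below ``tol``.
    """
    overrides = dict(overrides or {})
    free = tuple(k for k in overrides if k in system.parameters)
    for k in overrides:
        if k not in system.parameters and k not in system.inputs:
            raise ModelError(f"unknown parameter/input {k!r}")
    split = _system_functions(system, free_params=free)
    ivals = [float(overrides.get(name, 0.0)) for name in system.inputs]
    pvals = [float(overrides[k]) for k in free]
    if guess is None:
        guess = [system.initial_conditions.get(v, 0.0) for v in system.variables]
    elif isinstance(guess, dict):
        guess = [guess.get(v, 0.0) for v in system.variables]
    return _newton(split, guess, ivals, pvals, tol=tol)


def _settle(system, split, pack, value, t_max=1e7):
    """Steady state at a parameter value: chunked relaxation, Newton polish.

    After each relaxation chunk a Newton solve is attempted, so the loop
    terminates quickly near an attracting equilibrium and fails cleanly
    (instead of integrating forever) when the flow never settles.
    """
    inputs, params = pack(value)
    y = np.array([system.initial_conditions.get(v, 0.0)
                  for v in system.variables])
    elapsed, chunk = 0.0, 1e4
    last_exc = None
    while elapsed < t_max:
        sol = solve_ivp(lambda t, yy: split(yy, inputs, params)[0],
                        (0.0, chunk), y, method="LSODA", rtol=1e-9, atol=1e-13)
        if not sol.success:
            raise IntegrationError(f"relaxation failed: {sol.message}")
        y = sol.y[:, -1]
        elapsed += chunk
        chunk = min(3 * chunk, t_max - elapsed + 1.0)
        try:
            return _newton(split, y, inputs, params)
        except IntegrationError as exc:
            last_exc = exc
    raise IntegrationError(
        f"no equilibrium found by relaxation within {t_max:g} s: {last_exc}")


def _seed_equilibrium(system, split, pack, value):
    """Newton from the stored initial conditions, falling back to relaxation."""
    inputs, params = pack(value)
    guess = np.array([system.initial_conditions.get(v, 0.0)
                      for v in system.variables])
    try:
        return _newton(split, guess, inputs, params)
    except IntegrationError:
        return _settle(system, split, pack, value)


@dataclass
class HopfResult:
    """A located Hopf point of the equilibrium branch."""

    parameter: str
    bracket: tuple
    value: float
    imag_part: float            # |Im| of the crossing pair (1/s)
    re_below: float             # max Re eigenvalue just below the bracket
    re_above: float             # ... and just above
    is_hopf: bool = True        # False for a real-eigenvalue sign change

    @property
    def destabilising(self) -> bool:
        """True when stability is lost as the parameter increases."""
        return self.re_below < 0 < self.re_above


@dataclass
class ScanPoint:
    value: float
    equilibrium: np.ndarray
    max_re: float
    imag_at_max: float
    stable: bool


@dataclass
class HopfScan:
    parameter: str
    points: list = field(default_factory=list)
    hopf: list = field(default_factory=list)
    other_crossings: list = field(default_factory=list)
    truncated: bool = False     # continuation lost the branch mid-range


def hopf_scan(system, parameter, prange, n_grid=60):
    """Locate Hopf points of the equilibrium branch over a parameter range.

    The equilibrium is continued across ``n_grid`` points of
    ``prange = (lo, hi)`` (each Newton solve seeded by its neighbour; the
    first by relaxation), the leading Jacobian eigenvalue is tracked, and
    every sign change of its real part is refined by bisection to a bracket
    narrower than 1e-4.  Crossings with |Im| below 1e-6 1/s are reported
    separately as non-Hopf.
    """
    lo, hi = map(float, prange)
    if not hi > lo:
        raise ModelError(f"empty parameter range {prange}")
    free, pack = _scan_args(system, parameter)
    split = _system_functions(system, free_params=free)

    def eig(y, value):
        inputs, params = pack(value)
        _, J = split(y, inputs, params)
        ev = np.linalg.eigvals(J)
        lead = ev[np.argmax(ev.real)]
        return float(lead.real), float(abs(lead.imag))

    scan = HopfScan(parameter)
    grid = np.linspace(lo, hi, int(n_grid))
    y = _settle(system, split, pack, grid[0])
    for value in grid:
        inputs, params = pack(value)
        try:
            y = _newton(split, y, inputs, params)
        except IntegrationError as exc:
            scan.truncated = True
            logger.warning("continuation lost at %s = %g: %s",
                           parameter, value, exc)
            break
        re, im = eig(y, value)
        scan.points.append(ScanPoint(value, y.copy(), re, im, re < 0))

    for i, (a, b) in enumerate(zip(scan.points, scan.points[1:])):
        if a.max_re == 0.0:
            # the crossing sits exactly on a grid node
            before = scan.points[i - 1] if i else a
            result = HopfResult(parameter, (a.value, a.value), a.value,
                                a.imag_at_max, re_below=before.max_re,
                                re_above=b.max_re,
                                is_hopf=a.imag_at_max > HOPF_MIN_IMAG)
            (scan.hopf if result.is_hopf else scan.other_crossings).append(result)
            continue
        if b.max_re == 0.0 or a.max_re * b.max_re >= 0:
            continue
        xa, xb, ya = a.value, b.value, a.equilibrium.copy()
        sign_a = np.sign(a.max_re)
        im_mid = a.imag_at_max
        while xb - xa > HOPF_PARAM_TOL:
            xm = 0.5 * (xa + xb)
            inputs, params = pack(xm)
            ym = _newton(split, ya, inputs, params)
            re_m, im_mid = eig(ym, xm)
            if np.sign(re_m) == sign_a:
                xa, ya = xm, ym
            else:
                xb = xm
        result = HopfResult(parameter, (xa, xb), 0.5 * (xa + xb), im_mid,
                            re_below=a.max_re, re_above=b.max_re,
                            is_hopf=im_mid > HOPF_MIN_IMAG)
        (scan.hopf if result.is_hopf else scan.other_crossings).append(result)
        logger.info("%s crossing at %s = %.6g (|Im| = %.3g)",
                    "Hopf" if result.is_hopf else "real-eigenvalue",
                    parameter, result.value, result.imag_part)
    return scan


@dataclass
class EnvelopePoint:
    """Equilibrium and limit-cycle extent of a readout at one parameter value."""

    value: float
    equilibrium_readout: float
    stable: bool
    cycle_min: float
    cycle_max: float
    failed: bool = False

    @property
    def oscillatory(self) -> bool:
        return self.cycle_max > self.cycle_min


def cycle_envelope(system, parameter, values, readout="r",
                   t_end=CONTINUOUS_HORIZON, transient=CONTINUOUS_TRANSIENT):
    """Equilibrium branch plus limit-cycle min/max of a readout.

    For each parameter value (sorted): continue the equilibrium, classify
    stability from the Jacobian eigenvalues; where unstable, integrate from
    a slightly perturbed equilibrium, discard the transient and record the
    readout's min and max.  A failed point is flagged and the scan continues.
    """
    values = sorted(float(v) for v in values)
    free, pack = _scan_args(system, parameter)
    split = _system_functions(system, free_params=free)
    ridx = system.variables.index(readout)
    out = []
    y = None
    for value in values:
        inputs, params = pack(value)
        try:
            y = (_seed_equilibrium(system, split, pack, value) if y is None
                 else _newton(split, y, inputs, params))
            _, J = split(y, inputs, params)
            stable = float(np.max(np.linalg.eigvals(J).real)) < 0
            eq_r = float(y[ridx])
            if stable:
                out.append(EnvelopePoint(value, eq_r, True, eq_r, eq_r))
                continue
            y0 = y * 1.01 + 1e-6
            sol = solve_ivp(lambda t, yy: split(yy, inputs, params)[0],
                            (0.0, t_end), y0, method="LSODA",
                            rtol=1e-8, atol=1e-12,
                            t_eval=np.linspace(transient, t_end, 4000))
            if not sol.success:
                raise IntegrationError(sol.message)
            series = sol.y[ridx]
            out.append(EnvelopePoint(value, eq_r, False,
                                     float(series.min()), float(series.max())))
        except (IntegrationError, ModelError) as exc:
            logger.warning("envelope point %s = %g failed: %s",
                           parameter, value, exc)
            out.append(EnvelopePoint(value, float("nan"), False,
                                     float("nan"), float("nan"), failed=True))
            y = None
    return out


def envelope_csv(points, parameter="param") -> str:
    buf = io.StringIO()
    buf.write(f"{parameter},equilibrium,stable,cycle_min,cycle_max,failed\n")
    for p in points:
        buf.write(f"{p.value:.10g},{p.equilibrium_readout:.10g},"
                  f"{int(p.stable)},{p.cycle_min:.10g},{p.cycle_max:.10g},"
                  f"{int(p.failed)}\n")
    return buf.getvalue()
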