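"""Quasi-steady-state elimination and the iterative reduction algorithm.

A fast variable x_j whose equation is affine,

    dx_j/dt = alpha_j(x) - beta_j(x) * x_j,

is eliminated by replacing it with its quasi-steady-state

    zeroth order:  xbar0 = alpha/beta
    first order:   xbar1 = alpha/beta + (alpha*beta' - beta*alpha') / beta**3,

where the primes are total time derivatives expanded through the reduced
(zeroth-order) system.  The first-order term corrects for the finite lag of
x_j behind its momentary steady state and can rescue oscillations that a
zeroth-order elimination over-damps.

Iterating simulate -> rank by speed coefficients -> eliminate -> re-simulate
produces a lineage of progressively smaller models, each validated against
its predecessor by comparing limit-cycle period, amplitude and waveform.

Nesting of corrections: when a prior first-order substitution references the
variable now being eliminated (e.g. the active-kinase equation after the
neutral kinase was removed with a correction), those nested occurrences are
resolved at the pure zeroth-order *backbone* closed form.  They sit inside
O(eps) correction terms, so the choice only affects O(eps^2) contributions,
beyond the order of the expansion; a substitution that would still reference
its own variable after this resolution is rejected as self-referential.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import sympy as sp

from .model_core import (
    ModelError,
    ODESystemSpec,
    QSSASubstitution,
    fresh_symbol,
    make_symbol,
    xreplace_shared,
)
from .simulate import (
    CONTINUOUS_HORIZON,
    CONTINUOUS_TRANSIENT,
    DEFAULT_STEP,
    PULSED_DISCARD,
    PULSED_PERIODS,
    compile_outputs,
    integrate,
    oscillation_metrics,
    shape_mse,
)
from .speed import rank_fastest, speed_coefficients

logger = logging.getLogger("qssareduce")

__all__ = [
    "AffinePair",
    "affine_decompose",
    "qssa_expression",
    "total_time_derivative",
    "reduce_once",
    "reduce_iteratively",
    "compare_models",
    "qssa_residual",
    "ReductionLineage",
    "LineageStep",
    "ComparisonRecord",
]


# ---------------------------------------------------------------------------
# Affine decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AffinePair:
    """f_j split as alpha - beta*x_j, both free of x_j.

    ``alpha``/``beta`` may reference the system's definition symbols (other
    substitutions left opaque); ``fstar`` is the preprocessed right-hand side
    the decomposition was taken from.
    """

    variable: str
    alpha: sp.Expr
    beta: sp.Expr
    fstar: sp.Expr = None


#: definition-name prefixes marking first-order correction machinery
_CORRECTION_PREFIXES = ("_da_", "_db_", "_g_")


def _is_correction(sym):
    return sym.name.startswith(_CORRECTION_PREFIXES)


def _closure_depends(defs, start_expr, target, skip_corrections=False):
    """Does ``start_expr``, chased through ``defs``, reference ``target``?

    With ``skip_corrections`` the chase does not descend into first-order
    correction definitions, i.e. it detects *leading-order* (structural)
    dependence only.
    """
    seen = set()

    def rec(e):
        for fs in e.free_symbols:
            if fs == target:
                return True
            if fs in defs and fs not in seen:
                seen.add(fs)
                if skip_corrections and _is_correction(fs):
                    continue
                if rec(defs[fs]):
                    return True
        return False

    return rec(sp.sympify(start_expr))


def _prepare_fstar(system, j):
    """Rewrite f_j so that all leading-order x_j dependence is explicit.

    Definitions through which x_j feeds back at leading order (outside
    first-order correction terms) are inlined transitively; definitions that
    depend on x_j only through corrections are referenced unchanged -- the
    elimination later redirects those occurrences to the zeroth-order
    backbone, an O(eps^2) choice.
    """
    xj = make_symbol(j)
    defs = system.defs

    def structural(sym):
        return (not _is_correction(sym)
                and _closure_depends(defs, defs[sym], xj, skip_corrections=True))

    fstar = sp.sympify(system.rhs[j])
    for _ in range(1 + len(defs)):
        rule = {fs: defs[fs] for fs in fstar.free_symbols
                if fs in defs and structural(fs)}
        if not rule:
            return fstar
        fstar = xreplace_shared(fstar, rule)
    raise ModelError(f"definition inlining for {j!r} did not terminate")


def affine_decompose(system, j):
    """Split f_j = alpha - beta*x_j; error if f_j is not affine in x_j.

    beta = -d f_j / d x_j and alpha = f_j at x_j = 0, after substitutions
    with leading-order x_j dependence have been inlined (so e.g. the decay
    rate a variable feels through an earlier zeroth-order elimination is
    captured in beta).
    """
    if j not in system.variables:
        raise ModelError(f"{j!r} is not a dynamic variable of {system.label!r}")
    xj = make_symbol(j)
    fstar = _prepare_fstar(system, j)
    second = sp.simplify(sp.diff(fstar, xj, 2))
    if second != 0:
        raise ModelError(
            f"rhs of {j!r} is not affine in {j!r}: d2f/d{j}2 = {second}"
        )
    beta = sp.together(-sp.diff(fstar, xj))
    alpha = sp.together(xreplace_shared(fstar, {xj: sp.S.Zero}))
    if sp.simplify(beta) == 0:
        raise ModelError(f"decay coefficient beta of {j!r} is identically zero")
    if sp.count_ops(fstar) < 2000:  # identity guard, skipped for huge forms
        if sp.simplify(sp.together(alpha - beta * xj - fstar)) != 0:
            raise ModelError(f"affine decomposition of {j!r} failed the identity check")
    return AffinePair(j, alpha, beta, fstar)


def total_time_derivative(expr, system):
    """d expr / dt along the system's flow: sum_i (d expr/d x_i) f_i.

    ``expr`` must be a function of dynamic variables, parameters and inputs;
    inputs are piecewise-constant (zero derivative within protocol segments).
    """
    expr = sp.sympify(expr)
    allowed = system._allowed_symbols()
    bad = expr.free_symbols - allowed
    if bad:
        raise ModelError(f"unresolved symbol(s) {sorted(map(str, bad))}")
    return system.time_derivative(expr)


# ---------------------------------------------------------------------------
# One elimination step
# ---------------------------------------------------------------------------

def _bb_closure(system):
    """Definition symbols reachable from the backbone pointers."""
    out, stack = set(), [s for s in system.backbones.values()
                         if s in system.defs]
    while stack:
        s = stack.pop()
        if s in out:
            continue
        out.add(s)
        for fs in system.defs[s].free_symbols:
            if fs in system.defs:
                stack.append(fs)
    return out


def _lineage_label(parent, j, order):
    if any(s.kind.startswith("qssa") for s in parent.substitutions):
        return parent.label + f"{j}{order}"
    return f"{j}{order}"


def _graph_gradient(expr, x, defs, cache):
    """Chain-rule d expr / d x through a plain def table (mutates ``defs``)."""
    out = expr.diff(x)
    for fs in expr.free_symbols:
        if fs not in defs:
            continue
        key = (fs, x)
        if key not in cache:
            cache[key] = sp.S.Zero  # placeholder; defs are acyclic
            g = _graph_gradient(defs[fs], x, defs, cache)
            if g == 0:
                cache[key] = sp.S.Zero
            else:
                gsym = fresh_symbol(f"g_{fs.name}_{x.name}")
                defs[gsym] = g
                cache[key] = gsym
        g = cache[key]
        if g != 0:
            out = out + expr.diff(fs) * g
    return out


def reduce_once(system, j, order=0):
    """Eliminate dynamic variable ``j`` by QSSA of the given order.

    Returns a new system of dimension ``dim - 1`` whose remaining equations
    are unchanged expressions: occurrences of ``j`` now resolve through the
    definition table.  The pure zeroth-order closed form (backbone) is also
    registered, and nested occurrences of ``j`` inside earlier correction
    terms are redirected to it (see module docstring).
    """
    if order not in (0, 1):
        raise ModelError(f"QSSA order must be 0 or 1, got {order!r}")
    pair = affine_decompose(system, j)
    xj = make_symbol(j)
    defs = system.defs
    bbsym = sp.Symbol(f"_bb_{j}")

    # ---- backbone decomposition in the all-zeroth-order view
    bbmap = {make_symbol(var): bsym
             for var, bsym in system.backbones.items()
             if bsym != make_symbol(var)}
    fbb = xreplace_shared(system.rhs[j], bbmap)
    for _ in range(1 + len(defs)):
        rule = {fs: defs[fs] for fs in fbb.free_symbols
                if fs in defs and _closure_depends(defs, defs[fs], xj)}
        if not rule:
            break
        fbb = xreplace_shared(fbb, rule)
    if sp.simplify(sp.diff(fbb, xj, 2)) != 0:
        raise ModelError(f"backbone rhs of {j!r} is not affine in {j!r}")
    beta_bb = sp.together(-sp.diff(fbb, xj))
    alpha_bb = sp.together(xreplace_shared(fbb, {xj: sp.S.Zero}))
    if sp.simplify(beta_bb) == 0:
        raise ModelError(f"backbone decay coefficient of {j!r} vanishes")
    bb_expr = alpha_bb / beta_bb

    # ---- keep the backbone subgraph closed: entries still referencing x_j
    # get renamed copies with x_j resolved to the new backbone
    bb_syms = _bb_closure(system)
    bb_affected = [s for s in bb_syms if _closure_depends(defs, defs[s], xj)]
    ren = {s: fresh_symbol(s.name) for s in bb_affected}
    ren_rule = {xj: bbsym, **ren}
    renamed_bb = {ren[s]: xreplace_shared(defs[s], ren_rule)
                  for s in bb_affected}

    # ---- snapshots of definitions that depend on x_j through corrections
    dep_syms = [s for s in defs if _closure_depends(defs, defs[s], xj)]
    prime = {s: fresh_symbol(s.name) for s in dep_syms}
    prime_rule = {xj: bbsym, **prime, **ren}
    primed_defs = {prime[s]: xreplace_shared(defs[s], prime_rule)
                   for s in dep_syms}

    # alpha/beta may reference x_j-dependent definitions; point those at the
    # snapshots so the substitution's own closure never revisits x_j
    alpha = xreplace_shared(pair.alpha, {**prime, **ren})
    beta = xreplace_shared(pair.beta, {**prime, **ren})

    asym, bsym_ = sp.Symbol(f"_a_{j}"), sp.Symbol(f"_b_{j}")
    q0sym = sp.Symbol(f"_{j}0")

    new_defs = dict(defs)
    new_defs.update(renamed_bb)
    new_defs.update(primed_defs)
    new_defs[bbsym] = bb_expr
    new_defs[asym] = alpha
    new_defs[bsym_] = beta
    new_defs[q0sym] = asym / bsym_

    remaining = [v for v in system.variables if v != j]
    if order == 0:
        new_defs[xj] = q0sym
    else:
        # total derivatives of alpha, beta through the zeroth-order reduced
        # system (explicit x_j in the rhs resolves to xbar0, nested x_j in
        # definitions to the backbone snapshots)
        red0_rhs = {v: xreplace_shared(system.rhs[v], {xj: q0sym, **prime, **ren})
                    for v in remaining}
        red0_defs = dict(new_defs)
        cache = {}
        def Dt(e):
            terms = []
            for v in remaining:
                g = _graph_gradient(e, make_symbol(v), red0_defs, cache)
                if g != 0:
                    terms.append(g * red0_rhs[v])
            return sp.Add(*terms)

        da, db = Dt(alpha), Dt(beta)
        for s, e in red0_defs.items():
            if s not in new_defs:
                new_defs[s] = e
        dasym, dbsym = sp.Symbol(f"_da_{j}"), sp.Symbol(f"_db_{j}")
        new_defs[dasym] = da
        new_defs[dbsym] = db
        new_defs[xj] = q0sym + (asym * dbsym - bsym_ * dasym) / bsym_**3

    new = ODESystemSpec.__new__(ODESystemSpec)
    new.variables = remaining
    new.parameters = dict(system.parameters)
    new.inputs = list(system.inputs)
    new.rhs = {v: system.rhs[v] for v in remaining}
    new.defs = new_defs
    new.substitutions = list(system.substitutions) + [
        QSSASubstitution(j, f"qssa{order}", order)
    ]
    new.backbones = {var: ren.get(bsym, bsym)
                     for var, bsym in system.backbones.items()}
    new.backbones[j] = bbsym
    new.initial_conditions = {k: v for k, v in system.initial_conditions.items()
                              if k != j}
    new.conserved = list(system.conserved)
    new.label = _lineage_label(system, j, order)
    if hasattr(system, "input_defaults"):
        new.input_defaults = dict(system.input_defaults)
    try:
        new.validate()
    except ModelError as exc:
        if "cyclic" in str(exc):
            raise ModelError(
                f"substitution for {j!r} is self-referential: {exc}"
            ) from exc
        raise
    new = new.prune_defs()
    logger.info("eliminated %s at order %d -> %s (%d variables)",
                j, order, new.label, new.dim)
    return new


def qssa_expression(pair, order, system):
    """Closed-form QSSA substitution for ``pair.variable``.

    Returns a :class:`QSSASubstitution` whose ``expression`` is flattened to
    dynamic variables, parameters and inputs of the reduced system.
    """
    reduced = reduce_once(system, pair.variable, order)
    expr = reduced.substitution_expression(pair.variable)
    if make_symbol(pair.variable) in expr.free_symbols:
        raise ModelError(f"substitution for {pair.variable!r} is self-referential")
    return QSSASubstitution(pair.variable, f"qssa{order}", order, expression=expr)


# ---------------------------------------------------------------------------
# Model comparison (the numerical embedding check)
# ---------------------------------------------------------------------------

@dataclass
class ComparisonRecord:
    """Reduced-vs-reference limit-cycle comparison under one protocol."""

    reference_label: str
    reduced_label: str
    period_fold: float | None = None
    amplitude_fold: float | None = None
    shape_mse: float | None = None
    max_pointwise_dev: float | None = None
    reference_oscillatory: bool = False
    reduced_oscillatory: bool = False
    note: str = ""


def _cycle_matrix(traj, readout, names, transient):
    """One readout-aligned unit-period cycle of each named variable."""
    from scipy.signal import find_peaks

    from .simulate import PEAK_PROMINENCE

    w = traj.window(transient)
    x = w.series(readout)
    rng = x.max() - x.min()
    peaks, _ = find_peaks(x, prominence=PEAK_PROMINENCE * rng)
    a, b = peaks[-2], peaks[-1]
    phase = (w.times[a:b + 1] - w.times[a]) / (w.times[b] - w.times[a])
    grid = np.linspace(0.0, 1.0, 1000)
    return {n: np.interp(grid, phase, w.series(n)[a:b + 1]) for n in names}


def compare_models(full, reduced, protocol=None, readout="r",
                   t_end=None, transient=None, step=DEFAULT_STEP,
                   start_full=None, start_reduced=None):
    """Simulate both models under one protocol and compare their cycles.

    This realises the numerical embedding check: the reduced model (the
    eps -> 0 limit) is accepted when its solution reproduces the full
    model's (eps = 1).  Returns period and amplitude fold changes
    (reduced/full), the rescaled-waveform MSE of the readout, and the
    maximum pointwise deviation of the shared variables over one
    readout-aligned cycle.  Non-oscillatory cases yield a partial record.
    """
    missing = [v for v in reduced.variables if v not in full.variables]
    if missing:
        raise ModelError(f"reduced model has variables {missing} absent from "
                         f"{full.label!r}")
    t_end, transient = _default_window(protocol, t_end, transient)
    sf = start_full if start_full is not None else full.initial_conditions
    sr = start_reduced if start_reduced is not None else \
        {v: reduced.initial_conditions.get(v, 0.0) for v in reduced.variables}
    tf = integrate(full, sf, protocol, t_end, step=step)
    tr = integrate(reduced, sr, protocol, t_end, step=step)
    return compare_trajectories(tf, tr, readout, transient)


def compare_trajectories(traj_full, traj_reduced, readout="r",
                         transient=CONTINUOUS_TRANSIENT):
    """As :func:`compare_models`, on trajectories already in hand."""
    full = traj_full.system
    reduced = traj_reduced.system
    mf = oscillation_metrics(traj_full, readout, transient)
    mr = oscillation_metrics(traj_reduced, readout, transient)
    rec = ComparisonRecord(
        reference_label=full.label if full else "reference",
        reduced_label=reduced.label if reduced else "reduced",
        reference_oscillatory=bool(mf),
        reduced_oscillatory=bool(mr),
    )
    if mf and mr:
        rec.period_fold = mr.period_min / mf.period_min
        rec.amplitude_fold = mr.amplitude / mf.amplitude if mf.amplitude else None
        rec.shape_mse = shape_mse(traj_full, traj_reduced, readout, transient)
        shared = [v for v in traj_reduced.variables if v in traj_full.variables]
        ca = _cycle_matrix(traj_full, readout, shared, transient)
        cb = _cycle_matrix(traj_reduced, readout, shared, transient)
        rec.max_pointwise_dev = float(max(np.max(np.abs(ca[v] - cb[v]))
                                          for v in shared))
    else:
        bits = []
        if not mf:
            bits.append(f"reference not oscillatory ({mf.reason})")
        if not mr:
            bits.append(f"reduced not oscillatory ({mr.reason})")
        rec.note = "; ".join(bits)
    return rec


def _default_window(protocol, t_end, transient):
    period = protocol.period_hint() if protocol is not None else None
    if period is not None:
        if t_end is None:
            t_end = PULSED_PERIODS * period
        if transient is None:
            transient = PULSED_DISCARD * period
    else:
        if t_end is None:
            t_end = CONTINUOUS_HORIZON
        if transient is None:
            transient = CONTINUOUS_TRANSIENT
    return t_end, transient


# ---------------------------------------------------------------------------
# Iterative reduction
# ---------------------------------------------------------------------------

@dataclass
class LineageStep:
    """One elimination: which variable, at which order, with what effect."""

    variable: str
    order: int
    system: ODESystemSpec
    metrics: object                     # OscillationMetrics of the readout
    vs_parent: ComparisonRecord | None
    vs_root: ComparisonRecord | None
    speed_minima: dict = field(default_factory=dict)
    rescued: bool = False


@dataclass
class ReductionLineage:
    """Root system plus the ordered record of reduction steps."""

    root: ODESystemSpec
    root_metrics: object
    protocol: object
    readout: str
    steps: list = field(default_factory=list)
    stopped_early: bool = False

    @property
    def final(self) -> ODESystemSpec:
        return self.steps[-1].system if self.steps else self.root

    @property
    def elimination_order(self) -> list:
        return [s.variable for s in self.steps]

    def systems(self):
        return [self.root] + [s.system for s in self.steps]

    def metrics_csv(self) -> str:
        """Per-model summary table (periods in minutes, folds vs the root)."""
        buf = io.StringIO()
        buf.write("model,removed,order,n_vars,period_min,period_fold,"
                  "amplitude_fold,shape_mse,oscillatory\n")

        def fmt(x, spec="{:.6g}"):
            return spec.format(x) if x is not None else ""

        m = self.root_metrics
        buf.write(f"{self.root.label},,,{self.root.dim},"
                  f"{fmt(m.period_min)},1,1,0,{bool(m)}\n")
        for s in self.steps:
            c = s.vs_root
            buf.write(
                f"{s.system.label},{s.variable},{s.order},{s.system.dim},"
                f"{fmt(s.metrics.period_min)},"
                f"{fmt(c.period_fold if c else None)},"
                f"{fmt(c.amplitude_fold if c else None)},"
                f"{fmt(c.shape_mse if c else None)},{bool(s.metrics)}\n")
        return buf.getvalue()


def reduce_iteratively(system, protocol=None, n_steps=1, order_policy=None,
                       exclude=(), sequence=None, rescue_order1=True,
                       t_end=None, transient=None, step=DEFAULT_STEP,
                       include_transient_in_ranking=False, readout="r",
                       rank_thin=6):
    """Run the full reduce-and-verify loop for ``n_steps`` eliminations.

    Per step: simulate the representative solution, evaluate speed
    coefficients along it, pick the variable that is fastest at its slowest
    (or follow ``sequence`` when reproducing a documented lineage), eliminate
    it at the order given by ``order_policy`` (default 0), re-simulate and
    record limit-cycle metrics against the parent and the root.

    If a zeroth-order elimination destroys an oscillation the parent had,
    and the policy did not pin the order, the step is retried at first order
    (``rescue_order1``).  A step that still loses the oscillation stops the
    loop (flagged) unless an explicit ``sequence`` asks to push on.

    Representative solutions start from the root's stored initial conditions
    and, for reduced models, from the parent trajectory's final state (or the
    last oscillatory ancestor's), keeping each model near the attractor being
    approximated.
    """
    if n_steps >= system.dim:
        raise ModelError(f"cannot remove {n_steps} of {system.dim} variables")
    order_policy = dict(order_policy or {})
    t_end, transient = _default_window(protocol, t_end, transient)
    window_start = 0.0 if include_transient_in_ranking else transient

    traj = integrate(system, system.initial_conditions, protocol, t_end,
                     step=step)
    root_metrics = oscillation_metrics(traj, readout, transient)
    lineage = ReductionLineage(system, root_metrics, protocol, readout)
    logger.info("lineage root %s: %s", system.label,
                f"period {root_metrics.period_min:.4g} min" if root_metrics
                else f"not oscillatory ({root_metrics.reason})")

    current, current_metrics = system, root_metrics
    root_traj = traj
    osc_state = dict(system.initial_conditions)

    for i in range(n_steps):
        profile = speed_coefficients(current, traj, window_start=window_start,
                                     thin=rank_thin)
        ranked = rank_fastest(profile, exclude)
        j = sequence[i] if sequence is not None else ranked[0][0]
        order = order_policy.get(j, 0)
        if current_metrics:
            osc_state = traj.final_state()

        reduced, traj_red, metrics, rescued = _reduce_and_simulate(
            current, j, order, protocol, t_end, step, transient, readout,
            osc_state)
        if (not metrics and order == 0 and rescue_order1
                and j not in order_policy and current_metrics):
            logger.info("order-0 elimination of %s lost the oscillation; "
                        "retrying at order 1", j)
            reduced, traj_red, metrics, _ = _reduce_and_simulate(
                current, j, 1, protocol, t_end, step, transient, readout,
                osc_state)
            order, rescued = 1, True

        vs_parent = compare_trajectories(traj, traj_red, readout, transient)
        vs_root = (vs_parent if current is system else
                   compare_trajectories(root_traj, traj_red, readout, transient))
        stepinfo = LineageStep(j, order, reduced, metrics, vs_parent, vs_root,
                               speed_minima=dict(ranked), rescued=rescued)
        lineage.steps.append(stepinfo)
        logger.info("step %d: removed %s (order %d) -> %s, %s", i + 1, j,
                    order, reduced.label,
                    f"period {metrics.period_min:.4g} min" if metrics
                    else f"not oscillatory ({metrics.reason})")

        if not metrics and current_metrics and sequence is None:
            lineage.stopped_early = True
            logger.warning("stopping: %s lost the oscillation", reduced.label)
            break
        current, current_metrics, traj = reduced, metrics, traj_red
    return lineage


def _reduce_and_simulate(parent, j, order, protocol, t_end, step, transient,
                         readout, osc_state):
    reduced = reduce_once(parent, j, order)
    start = {v: osc_state.get(v, reduced.initial_conditions.get(v, 0.0))
             for v in reduced.variables}
    traj = integrate(reduced, start, protocol, t_end, step=step)
    metrics = oscillation_metrics(traj, readout, transient)
    return reduced, traj, metrics, False


# ---------------------------------------------------------------------------
# Residual diagnostic
# ---------------------------------------------------------------------------

def qssa_residual(system, j, traj, window_start=0.0):
    """Relative size of the first-order correction along a reduced solution.

    For an order-0 elimination of ``j`` from ``system``, evaluates
    ``|xbar1 - xbar0| / max|xbar0|`` on the reduced model's trajectory
    (whose dynamic variables are those of ``system`` minus ``j``),
    restricted to ``t >= window_start``.  Values well below 1 certify that
    the quasi-steady state tracks faithfully; the conventional acceptance
    bar in this package is 0.1 on the established cycle.
    """
    red1 = reduce_once(system, j, 1)
    if list(traj.variables) != list(red1.variables):
        raise ModelError("trajectory does not match the reduced system")
    traj = traj.window(window_start)
    xj = make_symbol(j)
    q0 = sp.Symbol(f"_{j}0")
    fun = compile_outputs(red1, [sp.Abs(xj - q0), sp.Abs(q0)])
    inputs_t = np.array([[traj.protocol.value(t) if traj.protocol is not None
                          and traj.protocol.input == name else 0.0
                          for name in red1.inputs] for t in traj.times])
    corr, lead = fun(traj.states.T, inputs_t.T)
    corr = np.broadcast_to(np.asarray(corr, dtype=float), traj.times.shape)
    lead = np.broadcast_to(np.asarray(lead, dtype=float), traj.times.shape)
    scale = lead.max()
    if scale == 0:
        return 0.0
    return float(corr.max() / scale)
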