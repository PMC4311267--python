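"""Symbolic representation of reaction ODE systems.

A model is a set of first-order ODEs dx_i/dt = f_i(x, params, inputs) over
named concentration variables, plus an ordered, acyclic table of algebraic
*definitions*.  Definitions serve two purposes:

* substitution chain entries for variables eliminated by conservation or by
  quasi-steady-state approximation (QSSA) -- the eliminated variable's symbol
  stays in the right-hand sides and resolves through the table, the way
  reduced models are conventionally written (q̇ expressed in terms of w̄, s̄,
  p̄, ...);
* internal helper quantities (the affine coefficients alpha/beta of a QSSA,
  their total time derivatives, chain-rule gradients).

Keeping right-hand sides small and factoring repeated algebra through the
definition table is what makes deep reductions with first-order corrections
tractable: fully substituted expressions for such models grow multiplicatively
with each step, while the definition graph grows additively.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

import sympy as sp

logger = logging.getLogger("qssareduce")

import itertools as _itertools

_AUX_COUNTER = _itertools.count(1)


def fresh_symbol(base: str) -> sp.Symbol:
    """A new internal definition symbol with a globally unique name."""
    return sp.Symbol(f"_{base.lstrip('_')}_{next(_AUX_COUNTER)}")


__all__ = [
    "Parameter",
    "QSSASubstitution",
    "StimulusProtocol",
    "ODESystemSpec",
    "ModelError",
    "ModelParseError",
    "parse_model",
    "serialize_model",
    "eliminate_by_conservation",
    "drop_decoupled",
]

#: name pattern accepted for variables, parameters and inputs
_NAME_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_]*$")
#: names starting with an underscore are reserved for internal definitions
_INTERNAL_RE = re.compile(r"^_[A-Za-z0-9_]+$")


class ModelError(ValueError):
    """Invalid model structure or operation."""


class ModelParseError(ModelError):
    """Parse failure; carries the offending line number when known."""

    def __init__(self, message, line=None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def make_symbol(name: str) -> sp.Symbol:
    """Canonical symbol for a model quantity (assumed real and positive).

    Positivity reflects the domain (concentrations and rate constants); it
    lets sympy simplify Hill terms and rational functions without case splits.
    """
    return sp.Symbol(name, positive=True)


@dataclass(frozen=True)
class Parameter:
    """A named rate constant or total with value and unit string."""

    value: float
    unit: str = ""

    def __float__(self):
        return float(self.value)


@dataclass(frozen=True)
class QSSASubstitution:
    """Record of one eliminated variable.

    ``kind`` is ``"qssa0"``, ``"qssa1"`` or ``"conservation"``; ``order`` is
    0/1 for QSSA entries and ``None`` for conservation.  The closed form is
    obtained by flattening the owning system's definition table, see
    :meth:`ODESystemSpec.substitution_expression`.
    """

    variable: str
    kind: str
    order: int | None = None
    expression: object = None  # optional flattened closed form (sympy expr)

    def __post_init__(self):
        if self.kind not in ("qssa0", "qssa1", "conservation"):
            raise ModelError(f"unknown substitution kind {self.kind!r}")


@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant schedule for one time-dependent input signal.

    ``segments`` is a sorted tuple of ``(start_s, end_s, value)``; outside all
    segments the signal takes ``default``.  The classic protocols for the
    NF-kB models are a constant saturating dose (default 1, no segments) and
    trains of short pulses (default 0 with repeated unit-value segments).
    """

    input: str
    default: float = 0.0
    segments: tuple = ()

    def __post_init__(self):
        segs = tuple((float(a), float(b), float(v)) for a, b, v in self.segments)
        for a, b, v in segs:
            if not (b > a):
                raise ModelError(f"empty protocol segment ({a}, {b})")
            if not all(map(_isfinite, (a, b, v))):
                raise ModelError("protocol values must be finite")
        for (a0, b0, _), (a1, _b1, _) in zip(segs, segs[1:]):
            if a1 < b0:
                raise ModelError("protocol segments overlap or are unsorted")
        object.__setattr__(self, "segments", segs)

    def value(self, t: float) -> float:
        """Signal value at time ``t`` (segment starts inclusive, ends exclusive)."""
        for a, b, v in self.segments:
            if a <= t < b:
                return v
        return self.default

    def edges(self, t_end: float):
        """Sorted discontinuity times in (0, t_end)."""
        es = set()
        for a, b, _ in self.segments:
            for e in (a, b):
                if 0.0 < e < t_end:
                    es.add(e)
        return sorted(es)

    def period_hint(self):
        """Spacing between consecutive segment starts, if regular (else None)."""
        starts = [a for a, _, _ in self.segments]
        if len(starts) < 2:
            return None
        gaps = {round(b - a, 9) for a, b in zip(starts, starts[1:])}
        return gaps.pop() if len(gaps) == 1 else None


def _isfinite(x):
    return x == x and abs(x) != float("inf")


@dataclass
class ODESystemSpec:
    """A reaction ODE system with an algebraic definition table.

    Attributes
    ----------
    variables:
        Ordered dynamic variable names (concentrations, uM).
    parameters:
        Name -> :class:`Parameter`.
    inputs:
        Names of declared time-dependent signals (driven by a
        :class:`StimulusProtocol` during integration; treated as plain
        numbers otherwise).
    rhs:
        Variable name -> sympy expression.  Expressions may reference
        dynamic variables, parameters, inputs and definition symbols.
    defs:
        Ordered mapping ``Symbol -> Expr``; acyclic.  Contains eliminated
        variables' substitution entries and internal helpers.
    substitutions:
        Elimination history, oldest first.
    backbones:
        Eliminated variable name -> definition symbol of its pure
        zeroth-order closed form (used to break self-reference when
        first-order corrections nest).
    initial_conditions:
        Default starting state (uM) for representative solutions.
    label:
        Lineage label, e.g. ``"SM"`` or ``"z0p1y0v0s0w1"``.
    """

    variables: list
    parameters: dict
    inputs: list = field(default_factory=list)
    rhs: dict = field(default_factory=dict)
    defs: dict = field(default_factory=dict)
    substitutions: list = field(default_factory=list)
    backbones: dict = field(default_factory=dict)
    initial_conditions: dict = field(default_factory=dict)
    conserved: list = field(default_factory=list)
    label: str = "model"

    # ------------------------------------------------------------------ basic
    def __post_init__(self):
        self.validate()

    def sym(self, name: str) -> sp.Symbol:
        return make_symbol(name)

    @property
    def dim(self) -> int:
        return len(self.variables)

    def copy(self) -> "ODESystemSpec":
        return ODESystemSpec(
            variables=list(self.variables),
            parameters=dict(self.parameters),
            inputs=list(self.inputs),
            rhs=dict(self.rhs),
            defs=dict(self.defs),
            substitutions=list(self.substitutions),
            backbones=dict(self.backbones),
            initial_conditions=dict(self.initial_conditions),
            conserved=list(self.conserved),
            label=self.label,
        )

    def relabel(self, label: str) -> "ODESystemSpec":
        new = self.copy()
        new.label = label
        return new

    def param_value(self, name: str) -> float:
        return float(self.parameters[name].value)

    def numeric_parameters(self, overrides=None) -> dict:
        """Symbol -> float map for all parameters, with optional overrides."""
        vals = {make_symbol(k): float(p.value) for k, p in self.parameters.items()}
        for k, v in (overrides or {}).items():
            vals[make_symbol(k)] = float(v)
        return vals

    # -------------------------------------------------------------- validity
    def validate(self):
        seen = set()
        for v in self.variables:
            if not _NAME_RE.match(v):
                raise ModelError(f"invalid variable name {v!r}")
            if v in seen:
                raise ModelError(f"duplicate variable {v!r}")
            seen.add(v)
        if set(self.rhs) != set(self.variables):
            missing = set(self.variables) - set(self.rhs)
            extra = set(self.rhs) - set(self.variables)
            raise ModelError(
                f"rhs/variables mismatch (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        for s in self.substitutions:
            if s.variable in seen:
                raise ModelError(
                    f"substitution chain contains dynamic variable {s.variable!r}"
                )
        allowed = self._allowed_symbols()
        for v, e in self.rhs.items():
            bad = sp.sympify(e).free_symbols - allowed
            if bad:
                raise ModelError(
                    f"rhs of {v!r} references unknown symbol(s) "
                    f"{sorted(str(b) for b in bad)}"
                )
        for s, e in self.defs.items():
            bad = sp.sympify(e).free_symbols - allowed
            if bad:
                raise ModelError(
                    f"definition {s} references unknown symbol(s) "
                    f"{sorted(str(b) for b in bad)}"
                )
        self.topo_defs()  # raises on cycles

    def _allowed_symbols(self):
        names = (
            list(self.variables)
            + list(self.parameters)
            + list(self.inputs)
        )
        allowed = {make_symbol(n) for n in names}
        allowed |= set(self.defs)
        return allowed

    # ------------------------------------------------------------------ defs
    def topo_defs(self) -> list:
        """Definition symbols in dependency order (referenced-first)."""
        order, state = [], {}

        def visit(s, stack):
            st = state.get(s)
            if st == 2:
                return
            if st == 1:
                cyc = " -> ".join(str(x) for x in stack + [s])
                raise ModelError(f"cyclic definitions: {cyc}")
            state[s] = 1
            for fs in self.defs[s].free_symbols:
                if fs in self.defs:
                    visit(fs, stack + [s])
            state[s] = 2
            order.append(s)

        for s in self.defs:
            visit(s, [])
        return order

    def prune_defs(self) -> "ODESystemSpec":
        """Drop definitions unreachable from the rhs and substitution entries."""
        keep = set()

        def reach(e):
            for fs in e.free_symbols:
                if fs in self.defs and fs not in keep:
                    keep.add(fs)
                    reach(self.defs[fs])

        for e in self.rhs.values():
            reach(e)
        for s in self.substitutions:
            root = make_symbol(s.variable)
            if root in self.defs and root not in keep:
                keep.add(root)
                reach(self.defs[root])
        for sym in self.backbones.values():
            if sym in self.defs and sym not in keep:
                keep.add(sym)
                reach(self.defs[sym])
        new = self.copy()
        new.defs = {s: e for s, e in self.defs.items() if s in keep}
        return new

    def flatten(self, expr) -> sp.Expr:
        """Substitute the whole definition table into ``expr``.

        The result references dynamic variables, parameters and inputs only.
        Uses a sharing-preserving replacement so repeated subexpressions are
        rebuilt once; note the fully substituted *tree* may still be large
        for deeply corrected models.
        """
        expr = sp.sympify(expr)
        table = {}
        for s in self.topo_defs():
            table[s] = xreplace_shared(self.defs[s], table)
        return xreplace_shared(expr, table)

    def flattened_rhs(self, var: str) -> sp.Expr:
        return self.flatten(self.rhs[var])

    def substitution_expression(self, variable: str) -> sp.Expr:
        """Closed form of an eliminated variable over dynamic variables only."""
        for s in self.substitutions:
            if s.variable == variable:
                return self.flatten(make_symbol(variable))
        raise ModelError(f"{variable!r} is not an eliminated variable")

    # -------------------------------------------------------------- calculus
    def total_gradient(self, expr, var: str, aux: dict | None = None) -> sp.Expr:
        """d expr / d var, chaining through the definition table.

        Equals the partial derivative of the flattened expression with
        respect to dynamic variable ``var``.  Intermediate gradients of
        definitions are memoised as new definitions; they are stored in
        ``aux`` if given (an overlay mapping merged with ``defs`` for
        evaluation), else appended to ``self.defs``.
        """
        store = self.defs if aux is None else aux
        cache = getattr(self, "_grad_cache", None)
        if cache is None or cache[0] is not store:
            cache = (store, {})
            self._grad_cache = cache
        return _grad(self, sp.sympify(expr), make_symbol(var), store, cache[1])

    def time_derivative(self, expr) -> sp.Expr:
        """Total time derivative of ``expr`` along the flow.

        Computed on the flattened system, so the result references dynamic
        variables, parameters and inputs only.  Inputs are treated as
        piecewise-constant (zero derivative inside protocol segments).
        Intended for direct use on models of moderate depth; the reduction
        machinery uses the definition-graph equivalent internally.
        """
        flat = self.flatten(expr)
        terms = []
        for v in self.variables:
            g = flat.diff(make_symbol(v))
            if g != 0:
                terms.append(g * self.flattened_rhs(v))
        return sp.Add(*terms)

    # --------------------------------------------------------------- display
    def __repr__(self):
        return (
            f"<ODESystemSpec {self.label!r}: {self.dim} variables "
            f"{tuple(self.variables)}, {len(self.defs)} definitions>"
        )


def _grad(system, expr, x, store, cache):
    """Chain-rule gradient of ``expr`` w.r.t. dynamic ``x`` through defs."""
    out = expr.diff(x)
    for fs in expr.free_symbols:
        entry = system.defs.get(fs)
        if entry is None:
            entry = store.get(fs) if store is not system.defs else None
        if entry is None:
            continue
        key = (fs, x)
        if key not in cache:
            cache[key] = None  # guard; defs are acyclic so this never recurses
            g = _grad(system, entry, x, store, cache)
            if g == 0:
                cache[key] = sp.S.Zero
            else:
                gsym = fresh_symbol(f"g_{fs.name}_{x.name}")
                store[gsym] = g
                cache[key] = gsym
        g = cache[key]
        if g is not None and g != 0:
            out = out + expr.diff(fs) * g
    return out


def xreplace_shared(expr, rule: dict):
    """Structural replacement preserving (and exploiting) subtree sharing."""
    memo = {}

    def rec(e):
        r = memo.get(e)
        if r is not None:
            return r
        if e in rule:
            res = rule[e]
        elif e.args:
            newargs = tuple(rec(a) for a in e.args)
            res = e if all(n is o for n, o in zip(newargs, e.args)) else e.func(*newargs)
        else:
            res = e
        memo[e] = res
        return res

    return rec(sp.sympify(expr))


# ---------------------------------------------------------------------------
# Parsing / serialization
# ---------------------------------------------------------------------------

_SECTIONS = ("variables", "parameters", "inputs", "defs", "equations",
             "conserved", "substitutions")


def parse_model(text: str) -> ODESystemSpec:
    """Parse a structured model description.

    The format is line-oriented with ``[section]`` headers::

        label = SM

        [variables]
        p = 3.81e-3        # name = initial condition (uM)
        q = 1.58e-2

        [parameters]
        k1 = 3.3
        k2 = 0.08 uM

        [inputs]
        k24 = 0            # off-value

        [defs]
        wbar = k24*k22*v/k23

        [equations]
        p' = k19*z - k4*q*p - k15*p + k16*r

        [conserved]
        v + w = k2

    Expressions use standard arithmetic, powers and rational functions; Hill
    terms are written explicitly (``r**h/(r**h + k**h)``).
    """
    label = "model"
    variables, ics = [], {}
    parameters, inputs, input_defaults = {}, [], {}
    raw_defs, raw_eqs, conserved, subs = [], [], [], []
    section = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1].strip().lower()
            if section not in _SECTIONS:
                raise ModelParseError(f"unknown section [{section}]", lineno)
            continue
        if section is None:
            if line.startswith("label"):
                label = line.split("=", 1)[1].strip()
                continue
            raise ModelParseError(f"content outside any section: {line!r}", lineno)
        if section == "variables":
            name, _, val = (x.strip() for x in line.partition("="))
            if not _NAME_RE.match(name):
                raise ModelParseError(f"invalid variable name {name!r}", lineno)
            if name in variables:
                raise ModelParseError(f"duplicate variable {name!r}", lineno)
            variables.append(name)
            if val:
                ics[name] = _parse_float(val, lineno)
        elif section == "parameters":
            name, _, rest = (x.strip() for x in line.partition("="))
            if not _NAME_RE.match(name):
                raise ModelParseError(f"invalid parameter name {name!r}", lineno)
            parts = rest.split(None, 1)
            if not parts:
                raise ModelParseError(f"parameter {name!r} has no value", lineno)
            parameters[name] = Parameter(
                _parse_float(parts[0], lineno), parts[1] if len(parts) > 1 else ""
            )
        elif section == "inputs":
            name, _, val = (x.strip() for x in line.partition("="))
            if not _NAME_RE.match(name):
                raise ModelParseError(f"invalid input name {name!r}", lineno)
            inputs.append(name)
            if val:
                input_defaults[name] = _parse_float(val, lineno)
        elif section == "defs":
            name, _, expr = (x.strip() for x in line.partition("="))
            if not (_NAME_RE.match(name) or _INTERNAL_RE.match(name)):
                raise ModelParseError(f"invalid definition name {name!r}", lineno)
            raw_defs.append((name, expr, lineno))
        elif section == "equations":
            lhs, _, expr = (x.strip() for x in line.partition("="))
            if not lhs.endswith("'"):
                raise ModelParseError(
                    f"equation left side must be <var>' (got {lhs!r})", lineno
                )
            raw_eqs.append((lhs[:-1].strip(), expr, lineno))
        elif section == "conserved":
            total, _, const = (x.strip() for x in line.partition("="))
            conserved.append((total, const))
        elif section == "substitutions":
            name, _, order = (x.strip() for x in line.partition("="))
            order = order.strip()
            if order == "conserved":
                subs.append(QSSASubstitution(name, "conservation"))
            else:
                o = int(order)
                subs.append(QSSASubstitution(name, f"qssa{o}", o))

    if not variables:
        raise ModelParseError("model declares no variables")

    known = {}
    for n in list(variables) + list(parameters) + inputs:
        known[n] = make_symbol(n)
    defs = {}
    for name, expr, lineno in raw_defs:
        e = _parse_expr(expr, known, lineno)
        s = make_symbol(name)
        defs[s] = e
        known[name] = s
    rhs = {}
    for var, expr, lineno in raw_eqs:
        if var not in variables:
            raise ModelParseError(f"equation for undeclared variable {var!r}", lineno)
        if var in rhs:
            raise ModelParseError(f"duplicate equation for {var!r}", lineno)
        rhs[var] = _parse_expr(expr, known, lineno)
    missing = [v for v in variables if v not in rhs]
    if missing:
        raise ModelParseError(f"no equation for variable(s) {missing}")

    system = ODESystemSpec(
        variables=variables,
        parameters=parameters,
        inputs=inputs,
        rhs=rhs,
        defs=defs,
        substitutions=subs,
        initial_conditions=ics,
        conserved=conserved,
        label=label,
    )
    system.input_defaults = input_defaults
    return system


def _parse_float(tok, lineno):
    try:
        return float(tok)
    except ValueError:
        raise ModelParseError(f"not a number: {tok!r}", lineno) from None


def _parse_expr(text, known, lineno):
    try:
        expr = sp.sympify(text, locals=dict(known), rational=False)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ModelParseError(f"cannot parse expression {text!r}: {exc}", lineno) from None
    bad = expr.free_symbols - set(known.values())
    if bad:
        names = sorted(str(b) for b in bad)
        raise ModelParseError(f"unknown symbol(s) {names} in {text!r}", lineno)
    return expr


def serialize_model(system: ODESystemSpec) -> str:
    """Write a system back to the structured text format.

    Substitution-chain entries are emitted in the ``[defs]`` section (the
    closed forms of eliminated variables), so a serialised reduced model
    parses back to a system with symbolically identical right-hand sides.
    """
    out = [f"label = {system.label}", ""]
    out.append("[variables]")
    for v in system.variables:
        ic = system.initial_conditions.get(v)
        out.append(f"{v} = {ic!r}" if ic is not None else v)
    out += ["", "[parameters]"]
    for name, p in system.parameters.items():
        unit = f" {p.unit}" if p.unit else ""
        out.append(f"{name} = {p.value!r}{unit}")
    if system.inputs:
        out += ["", "[inputs]"]
        dflt = getattr(system, "input_defaults", {})
        for name in system.inputs:
            out.append(f"{name} = {dflt.get(name, 0.0)!r}" if name in dflt else name)
    if system.defs:
        out += ["", "[defs]"]
        for s in system.topo_defs():
            out.append(f"{s.name} = {sp.sstr(system.defs[s])}")
    out += ["", "[equations]"]
    for v in system.variables:
        out.append(f"{v}' = {sp.sstr(system.rhs[v])}")
    if system.conserved:
        out += ["", "[conserved]"]
        for total, const in system.conserved:
            out.append(f"{total} = {const}" if const else str(total))
    if system.substitutions:
        out += ["", "[substitutions]"]
        for s in system.substitutions:
            tag = "conserved" if s.kind == "conservation" else str(s.order)
            out.append(f"{s.variable} = {tag}")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Elementary simplifications
# ---------------------------------------------------------------------------

def eliminate_by_conservation(system, total, victim, constant=None):
    """Remove ``victim`` using a conserved linear combination.

    ``total`` is an expression whose total time derivative vanishes under the
    system's flow (e.g. ``v + w + a`` for total IKK).  ``victim`` must appear
    linearly in it.  ``constant`` names the parameter holding the conserved
    value (preferred, keeps it symbolic for bifurcation scans) or gives a
    number; if omitted it is evaluated from the system's initial conditions.
    """
    known = {n: make_symbol(n) for n in
             list(system.variables) + list(system.parameters) + list(system.inputs)}
    total = sp.sympify(total, locals=known) if isinstance(total, str) else sp.sympify(total)
    if victim not in system.variables:
        raise ModelError(f"victim {victim!r} is not a dynamic variable")
    vsym = make_symbol(victim)
    if vsym not in total.free_symbols:
        raise ModelError(f"victim {victim!r} does not appear in the total")

    ddt = sp.simplify(system.time_derivative(total))
    if ddt != 0:
        raise ModelError(f"total {total} is not conserved: d/dt = {ddt}")

    if constant is None:
        ic = system.initial_conditions
        missing = [str(s) for s in total.free_symbols
                   if str(s) in system.variables and str(s) not in ic]
        if missing:
            raise ModelError(
                f"no conservation constant given and no initial conditions for {missing}"
            )
        const_expr = sp.Float(float(total.subs(
            {make_symbol(k): v for k, v in ic.items()})
            .subs(system.numeric_parameters())))
    elif isinstance(constant, str):
        if constant not in system.parameters:
            raise ModelError(f"unknown parameter {constant!r} for conserved total")
        const_expr = make_symbol(constant)
    else:
        const_expr = sp.Float(float(constant))

    sol = sp.solve(sp.Eq(total, const_expr), vsym)
    if len(sol) != 1:
        raise ModelError(f"cannot solve total = const for {victim!r} (solutions: {sol})")
    expr = sp.together(sol[0])

    new = system.copy()
    new.variables = [v for v in new.variables if v != victim]
    del new.rhs[victim]
    new.defs = dict(new.defs)
    new.defs[vsym] = expr
    new.substitutions = list(new.substitutions) + [
        QSSASubstitution(victim, "conservation")
    ]
    new.backbones = dict(new.backbones)
    new.backbones[victim] = vsym
    new.initial_conditions = {k: v for k, v in new.initial_conditions.items()
                              if k != victim}
    new.conserved = list(new.conserved) + [(sp.sstr(total), sp.sstr(const_expr))]
    new.validate()
    logger.info("eliminated %s by conservation: %s = %s", victim, victim, expr)
    return new


def drop_decoupled(system):
    """Remove variables no other retained equation (or definition) depends on.

    Iterates to a fixpoint; returns ``(reduced_system, dropped_names)`` with
    names in removal order.  Dropped variables feed into nothing, so the
    solution of the retained variables is exactly unchanged.
    """
    new = system.copy()
    dropped = []
    while new.dim > 1:
        used = set()
        for v, e in new.rhs.items():
            used |= {str(s) for s in new.flatten(e).free_symbols} - {v}
        candidates = [v for v in new.variables if v not in used]
        # never empty the system: a terminal self-contained variable stays
        if not candidates or len(candidates) == new.dim:
            candidates = candidates[:max(0, new.dim - 1)]
        if not candidates:
            break
        victim = candidates[0]
        new.variables = [v for v in new.variables if v != victim]
        del new.rhs[victim]
        new.initial_conditions = {k: v for k, v in new.initial_conditions.items()
                                  if k != victim}
        dropped.append(victim)
        logger.info("dropped decoupled variable %s", victim)
    new.validate()
    return new, dropped
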