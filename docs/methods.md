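# Methods

## Model class and representation

The package handles autonomous reaction ODE systems
dx_i/dt = f_i(x, k, u(t)) with named concentration variables (µM), rate
constants (s⁻¹ or µM·s⁻¹ scales), and optional piecewise-constant input
signals u(t) (stimulus switches).  Expressions are ordinary arithmetic,
powers and rational functions; saturable transcription is written as an
explicit Hill term r^h/(r^h + k^h).  Time and rate constants are kept in
seconds internally; the metrics layer reports periods in minutes.

A (possibly reduced) system is stored as

* right-hand sides in their original, small form, plus
* an ordered, acyclic **definition table** mapping substitution symbols to
  expressions.

Eliminated variables keep their symbol in the right-hand sides and resolve
through the table — exactly how reduced models are conventionally printed
(q̇ and ṙ written in terms of w̄, s̄, p̄).  This is not cosmetic: fully
substituting a deeply corrected model produces expression trees whose size
grows multiplicatively with each elimination, while the definition graph
grows additively.  Total derivatives and Jacobians are computed by
chain-rule gradients through the graph, which equals differentiating the
flattened system; `flatten()` materialises closed forms on demand for
symbolic checks and serialization.

## Elementary simplifications

Conserved linear combinations (total kinase, total transcription factor)
are verified symbolically (d(total)/dt ≡ 0) and used to eliminate one
member algebraically, preferring a named parameter for the conserved value
so that dose scans can treat it symbolically.  Variables that feed into no
retained equation ("decoupled": present only in their own ODE) are removed
iteratively; their solution is recoverable afterwards by quadrature, so
the retained dynamics are exactly unchanged.  The removal never empties
the system — a terminal self-contained variable stays.

## Speed coefficients and the elimination rule

λ_i(t) = |∂f_i/∂x_i| is evaluated along a representative solution; the
variable with the largest minimum of λ_i over the analysed window is
eliminated next ("fastest at its slowest").  Only the diagonal Jacobian
entries enter the ranking — fast rotational subsystems with zero diagonal
would be mis-classified, which is why every elimination is validated
afterwards by direct comparison of solutions rather than trusted on the
ranking alone.

**Ranking window.**  The minimum is taken over the post-transient part of
the representative solution (the established cycle), not the start-up
transient.  The packaged rest state is a published value equilibrated in a
richer parent model, so switching the stimulus on produces one deep
excursion (nuclear NF-κB dips to 0.0013 µM at ~74 min, an order of
magnitude below the limit-cycle trough); including it would flip the s/w
elimination order at step 5 by dragging down min λ_s = k4·r_min + k8 +
k1·k14.  The established-cycle window reproduces the documented order
z, p, y, v, s, w; an `include_transient_in_ranking` flag exposes the
alternative.

## QSSA derivation

For the selected variable the right-hand side is decomposed as
f_j = α_j − β_j x_j with β_j = −∂f_j/∂x_j, after inlining any earlier
substitutions through which x_j feeds back at leading order (e.g. the
nuclear-complex formula depends on cytoplasmic NF-κB, so its contribution
belongs in β_p).  Non-affine dependence is an error.  The zeroth-order
substitution is α/β; the first-order one adds (α β̇ − β α̇)/β³ with the
dots expanded through the zeroth-order reduced system — dynamic variables
contribute their right-hand sides, inputs are treated as constant within
protocol segments (substitutions are re-evaluated across segment
boundaries by the integrator restarts).

**Nested corrections.**  Later eliminations can encounter the current
variable *inside* an earlier first-order correction term (the active-IKK
equation after the neutral form was removed with a correction: α̇_v
expands through ṙ → p̄ → w).  Such occurrences sit at O(ε) inside O(ε)
terms, so they are resolved at the pure zeroth-order **backbone** closed
form that every eliminated variable also carries — a choice that only
affects O(ε²) contributions, beyond the order of the expansion, and keeps
the definition graph acyclic.  A substitution that would still reference
its own variable at leading order is rejected as self-referential rather
than solved implicitly.

## The iterative algorithm

Per step: simulate the representative solution → evaluate speed
coefficients along it → rank → eliminate the leader at the policy's order
(default 0) → re-simulate → record limit-cycle metrics against the parent
and the root.  If a zeroth-order elimination destroys an oscillation the
parent had and the policy did not pin the order, the step is retried at
first order; with that rescue the default six-step continuous run ends at
the four-variable model with first-order active IKK.  An explicit
elimination sequence can be supplied to reproduce documented lineages.

Representative solutions start from the packaged initial conditions for
the root and from the parent trajectory's final state for reduced models
(falling back to the last oscillatory ancestor when a step loses the
cycle).  Starting on the attractor is what the method compares anyway, and
it matters in practice: some intermediate first-order models are bistable
and their oscillation basin excludes the rest state.

Default horizons: 3000 min with a 1000 min transient for continuous input
(≈20 cycles at the ~100 min period, ≥5 analysed), 10 input periods with 2
discarded for pulsed input.

## Oscillation metrics and comparisons

Cycle peaks are local maxima with prominence ≥ 5% of the post-transient
range (robust to the flat troughs of these models, unlike zero crossings).
Period = mean peak-to-peak interval; amplitude = max − min of the readout
(nuclear NF-κB r unless overridden — the published table does not name its
readout, so this is a documented assumption).  A readout is "not
oscillatory" with < 3 peaks, interval CV > 10%, or decaying peak heights
(late/early prominence < 0.5 — a ring-down toward a stable focus passes
the CV test but is not a limit cycle).  Waveform (shape) MSE: one
peak-to-peak cycle of each model, rescaled to unit period, resampled on a
1000-point peak-aligned grid, mean squared difference in µM².  The
published MSE column's exact definition is not stated; this convention
reproduces its order of magnitude, not its digits.  For pulse trains, a
"full-size" response peak has prominence ≥ 20% of the range; entrainment
ratio = major peaks per stimulus pulse (1 entrained, 0.5 period-doubled).

## Numerics

Stiff integration is LSODA (`scipy.integrate.solve_ivp`), rtol 1e-8,
atol 1e-12, stopped and restarted at every protocol edge, sampled on a
uniform 10 s grid.  Halving the tolerances moves reported periods by
< 0.1%.  The solver runs unconstrained; excursions below −1e-9 µM are
flagged post hoc.  Equilibration integrates with inputs off in growing
chunks until max_i |f_i|/max(|x_i|, 1e-6) < 1e-9 (cap 1e7 s).
Equilibria for continuation are damped-Newton roots of the compiled
symbolic system (residual < 1e-12, backtracking line search); Hopf points
are located by bisecting sign changes of the leading Jacobian eigenvalue's
real part over a parameter grid (bracket < 1e-4, crossing pair must carry
|Im| > 1e-6 s⁻¹, real-axis crossings reported separately).  No
pseudo-arclength continuation is needed: the documented ranges contain
fold-free equilibrium branches, and limit cycles are characterised by
direct long integration rather than collocation.  The pipeline contains no
random numbers; identical configurations reproduce artifacts byte for
byte.

## Packaged models

* `SM` — the ten-variable simplified NF-κB/IκBα/A20 oscillator with the
  published rate constants (the published closed forms of its reductions
  carry two transcription slips, preserved verbatim in `*-printed`
  fixtures: the four-variable model's A/B constants place the
  inactivation rate k23 inconsistently and use the NF-κB total where the
  IKK total is expected — numerically equal, both 0.08 µM — and the
  pulsed model's nuclear-IκBα equation prints p̄ where the parent system
  has q; default builders derive both models algorithmically instead).
* `minimal-continuous` — the four-variable endpoint (q, r, u, x).
* `minimal-pulsed` — the six-variable pulsed-input model (q, r, s, u, v,
  x), which entrains 1:1 to 100-min pulses where the continuous-lineage
  six-variable variant responds only to every second pulse.
* a linear fast–slow toy (ẋ = −z, εż = x − z) with closed-form slow
  manifold, used to verify the convergence orders of the reductions
  (error O(ε) at zeroth, O(ε²) at first order).

## What the fixtures do and do not show

The models are deterministic, well-mixed, two-compartment descriptions
with published constants; passing tests demonstrate that the reduction
machinery reproduces the documented lineage of *these* equations, not that
the underlying biology is four-dimensional.  Cell-to-cell variability,
transcriptional noise and delays are outside the model class.

## Known limitations and open findings

* **Rest state.**  The ten-variable model has no return flux from the
  implicit IκBα·NF-κB complex (that pathway was pruned with the complex
  variables), so its only unstimulated steady state is the drained one
  (free pools empty, kinase fully neutral).  The published rest-state
  column comes from the richer parent model and is *not* an equilibrium
  here; the corresponding acceptance assertions fail by construction and
  are kept as a record of the discrepancy.  Stimulated behaviour is
  unaffected — the limit cycle is attracting.
* **Fully first-order endpoint.**  Deriving the four-variable model with
  first-order corrections for all of p, y, v, s, w destroys the limit
  cycle at the s step under our correction conventions: along the
  z0p1y1v1 cycle the zeroth-order s̄ already errs by ~44% and the
  correction exceeds the leading term, i.e. s is outside the QSSA validity
  regime there, and the resulting model is bistable with only its dead
  equilibrium attracting.  The published period for that variant could not
  be reproduced (its printed equations live in an appendix not available
  to us); the adjacent variant with first-order p and w only matches the
  published value within 2%, which validates the correction machinery
  itself.  The corresponding acceptance assertion is kept failing.
* **Residual heuristic.**  The first-order-correction residual
  (max |x̄¹ − x̄⁰| / max |x̄⁰| on the established cycle) certifies the
  eliminations of z (0.004), p, y and v at well below 0.1, but measures
  0.12 for s — consistent with s being the marginal elimination where the
  lineage's accuracy visibly degrades.
* Higher-order corrections, implicit/nonlinear QSSA root finding,
  eigenvalue-based timescale analysis, fold/period-doubling continuation
  and Floquet analysis are out of scope.
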