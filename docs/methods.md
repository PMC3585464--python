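# Methods

## The model class

A mass-action model couples species `X = {x_1..x_m}` and reactions
`R = {r_1..r_n}`. Reaction `r_j` carries integer reactant and product
stoichiometries and a velocity

    v_j = k_j * prod_i x_i^c_ij,

where the kinetic order `c_ij` defaults to the reactant stoichiometry but
may be overridden (`order(ES)=2` in the reaction format), so autocatalytic
and cooperative steps stay inside the class. Concentrations evolve as
`dx/dt = N v` with `N[i,j] = sP_ij - sR_ij`. A steady state is any state
with `N v = 0`; it is *non-trivial* when fluxes balance without each
velocity vanishing (tonic turnover). The engine is concerned with symbolic,
non-trivial steady states: every concentration and rate constant is left
as an uninterpreted positive symbol.

Units are opaque labels: abundances (molecules) and concentrations are
carried through unchanged, and compartment volumes are ordinary
coefficient symbols. The source/sink token `Ø`/`0` is untyped and never a
species; all sinks are the same formal node.

## The py-substitution change of variables

Every quantity (concentration or rate constant) is assigned by a bijection
`phi` to either the coefficient set `P` or the linear set `Y`, subject to
the requirement that every velocity become homogeneous of degree exactly 1
in the Y-symbols. Then `N v = 0` reads

    C ybar = 0,   C = N * d(v o phi)/dy,

with entries of `C` in the field of fractions of polynomials in the
P-symbols. A basis `B` (special-solution normalized: identity on the free
rows) of the null space of `C` parameterizes all steady states as
`ybar = B u`. The dependency map `psi` sends each free column to its own
basis coefficient and each pivot column to a rational expression; the
reverse relabeling `rho` finally expresses every dependent quantity in the
original names of the independent parameters (all of `P` plus the free
Y-quantities). The composition `sigma = rho o psi o phi` is verified
exactly: substituting `sigma` into the velocity vector must give
`N v = 0` after symbolic simplification, and a nonzero residual is a hard
error, never a warning.

Key counting identities, all enforced by tests: `q = |Y| - rank(C)`
(rank-nullity), and `|independents| = |X| + |R| - rank(N)` regardless of
the partition — the number of dependent quantities only reflects the
network structure.

### Rank is generic

Pivots and ranks treat the P-symbols as algebraically independent: a
specific numeric assignment can drop rank. Realizations are therefore
screened numerically (below) rather than trusted structurally.

### Pivot policy and Y ordering

Row reduction pivots greedily on the lowest-index Y columns, so
low-indexed quantities are favored to become dependent and high-indexed
ones to stay independent; the user steers the split through the Y order or
explicitly via `select_independent`, which inverts the submatrix `G` of
basis rows at the requested quantities and *rejects* (carrying `det G = 0`)
rather than raising when the request is not achievable. The number of
achievable selections — the count of invertible `q`-row submatrices of
`B` — is a row-matroid invariant and hence independent of basis choice;
`count_admissible_partitions` screens each determinant by exact random
rational evaluation and confirms apparent zeros symbolically, so the count
is exact, not probabilistic.

### Pseudospecies for sublinear and superlinear velocities

A velocity of Y-degree 0 (for example a zero-order synthesis whose rate
constant should stay independent) or of degree >= 2 (for example a
catalysis step quadratic in a Y-mapped complex) breaks homogeneity. The
engine repairs it with one auxiliary Y-variable per offending velocity:
the velocity's Y-monomial `mu` is replaced by the new variable, and the
constraint `ybar_new = mu(ybar)` is recorded. After the null-space
solution, constraints are substituted with `ybar = B u`, giving polynomial
equations in the basis coefficients; linear equations pin one `u`
directly, quadratics yield one solution branch per root (the engine
prefers eliminating the highest-index coefficients, which correspond to
the pseudospecies themselves). Manifestly complex roots are dropped with a
diagnostic; cubic-and-higher systems are attempted through the general
solver and returned unsolved to the caller when that fails, rather than
guessed at. Branch feasibility is decided only numerically: a realization
is feasible iff every concentration and rate constant evaluates strictly
positive and the constraints hold to a relative 1e-9.

The spec-level description of the superlinear repair ("a new Y-variable
multiplies the velocity") cannot reduce degree 2 to degree 1; replacing
the whole Y-monomial is the variant that simultaneously reproduces the
sublinear pin (`ybar_new = 1`), the squared-catalysis product constraint
with its two branches, and quadratic closure systems with one negative
(infeasible, discarded) root. That replacement is what this package
implements.

## The King-Altman route for linear models

A model is *linear* (after optionally freezing a set of time-invariant
species) when every reaction converts exactly one time-varying species
into another and every velocity has degree 1 in the remaining
concentrations. Then `dx/dt = K x` with `K`'s off-diagonal entries the
pseudo-first-order transition rate constants (frozen concentrations folded
in) and columns summing to zero. The steady state is proportional to the
principal minors of `-K`; each minor equals the sum over the directed
spanning trees into the root vertex (the King-Altman patterns) of the
edge-rate products. Patterns are enumerated exactly — one outgoing edge
per non-root vertex, acyclicity checked by walking to the root — which is
simple and fully adequate at the <= 10-vertex scale this package targets;
the determinant route is kept as an independent oracle and the two are
asserted equal for every tested graph. Parallel transitions between the
same ordered pair are merged by summing their rates. Concentrations are
reported normalized to a total-concentration symbol; the py-substitution
solution of the same model instead leaves one concentration free, and the
equivalence checker imposes the same total on it and verifies symbolic
equality concentration by concentration.

## Numerical layer

`realize` evaluates `sigma` at positive values of the independent
parameters, so the realized state is a steady state by construction; the
residual `max |N v|` is still computed and must stay below 1e-8 (relative
to the velocity scale). Simulations integrate `dx/dt = N v` with LSODA
(stiff-capable, adaptive; relative tolerance 1e-6, absolute 1e-8 in state
units) over a default 48 h horizon, suited to snap-action switch dynamics.
Perturbations are fold or step changes to one species abundance or rate
constant.

Response metrics:

* `T_d` — first time a designated output crosses 50% of its horizon
  maximum, linearly interpolated between samples; absent when no upward
  crossing occurs.
* `L_min` — minimal input fold-change for which the switch event (output
  exceeding 50% of a reference level anywhere in the horizon) fires;
  found by bisection on the log2 fold-change to 1% relative tolerance
  inside a default 1- to 1e6-fold bracket, with endpoints checked first
  and an optional grid pass that attaches a warning if the predicate is
  non-monotone.
* Sensitivities — backward finite differences (default 1% relative step)
  of either metric with respect to the steady-state value of each
  independent quantity. The dependent quantities are recomputed through
  `sigma` at each perturbed point, so the perturbed system is again at
  steady state ("compensated" perturbation); coefficients are normalized
  by the largest magnitude, making `max |s| = 1` by construction. Note
  that `L_min` is only resolved to the bisection tolerance, so its
  sensitivities to very small steps can quantize to zero; choose
  `rel_step` above the bisection tolerance when that matters.
* Steady-state scans vary one independent abundance over a log-spaced
  grid (default 100-fold, i.e. base/10 to base*10), recompute the
  compensating quantities from `sigma` at each point, and evaluate the
  metric; points whose compensating rates would be negative are flagged
  infeasible and skipped, not fatal.

`L_min` and `T_d` are computed independently and can rank parameters
differently; the package reports both and never conflates them.

## Fixtures and generators

The open Michaelis-Menten system (binding, dissociation, catalysis,
zero-order substrate synthesis, first-order product degradation) is
provided under four partitions: homogeneous (all concentrations to P, all
rate constants to Y), heterogeneous (enzyme kinetic constants forced
independent), sublinear (synthesis constant independent, one
pseudospecies) and superlinear (catalysis quadratic in the complex, one
pseudospecies). The fumarase mechanism (five enzyme forms, four
substrates, six reversible reactions) is provided both frozen-substrate
(linear; the King-Altman comparison case) and fully time-varying with
|Y| = 10 — four substrate concentrations plus the six dissociation-side
rate constants. The degree-1 requirement dictates that the
dissociation-side constants, not the association ones, join the substrates
in Y: association velocities already carry their Y-factor through the
substrate concentration. Under this reconstruction the null space is
five-dimensional and exactly 72 of the 252 five-row basis submatrices are
invertible.

`random_linear_model` draws distinct directed first-order transitions
uniformly without replacement and rejects disconnected draws outright
(rejection, never repair). The property suites run it at six species with
10-14 reactions, the size at which the full solve-and-verify cycle stays
at a few seconds per model while exercising all code paths.

`toy_switch` is a three-species positive-feedback module (inactive pool A,
active form B with an order-2 autocatalytic conversion, input L catalyzing
activation, synthesis and degradation on every species). Its reference
parameterization puts it in an input-dominated low state with a grid-
scanned switching threshold near a 19-fold step in L. It emulates the
*shape* of an apoptosis-style dose threshold — bistability, a hard dose
threshold, compensated steady states — and nothing else: its constants are
internal ground truth for the threshold/sensitivity machinery, not
biology. Passing tests on it demonstrate that the numeric layer finds
thresholds and sensitivities correctly on a system whose ground truth is
independently computable; they say nothing about any real signaling
network's values.

The apoptosis-scale xEARM model (58 species, 115 reactions) is not
bundled: the package ships a loader and a schema validator for a
user-transcribed reaction document, and every xEARM-specific number is
gated on that transcription. SBML import is not provided; the plain-text
reaction format is the sole input format.

## Numerical and symbolic choices

* All symbolic linear algebra runs over exact rationals; no floating
  point enters before the numeric layer.
* Row reduction and null spaces use sympy's domain-matrix representation
  of the fraction field; generic symbolic elimination is avoided because
  its zero tests fall back to expression-level simplification and swell.
* Residual verification tests exact zeroness in the polynomial fraction
  field when the composed map is rational, and falls back to generic
  simplification for radical-bearing branches.
* Dependent expressions are stored raw (as produced by the basis
  combination); `dependents_simplified` computes fully simplified forms
  on demand.
* Degenerate inputs: a full-column-rank coefficient matrix (only the
  trivial steady state) is an error naming the partition as the cause; a
  disconnected transition graph, and an all-minors-zero network, are
  errors in the King-Altman route; an infeasible numeric branch is a
  flag, not an error.

## Known limitations

* Generic rank means specific parameter values can invalidate a
  symbolically valid partition; only `realize` notices.
* Constraint systems beyond quadratics are not guaranteed solvable; the
  unsolved system is returned rather than approximated.
* No stability or uniqueness certification of steady states, no
  bifurcation analysis, no stochastic simulation, and no optimization
  over the admissible-partition space.
* The arborescence enumerator is exponential in vertex count and meant
  for mechanism-scale graphs (<= ~10 vertices), not genome-scale ones.
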