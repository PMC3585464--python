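"""The py-substitution engine: symbolic steady states for mass-action models.

The method splits every model quantity (species concentration or rate
constant) into a coefficient set ``P`` and a linear set ``Y`` such that
every reaction velocity becomes homogeneous of degree exactly 1 in the
Y-symbols. The steady-state condition ``N @ v = 0`` then reads
``C @ ybar = 0`` with the coefficient matrix ``C = N @ d(v)/d(y)`` over
the field of fractions of polynomials in the P-symbols. A null-space
basis ``B`` of ``C`` (special-solution normalized: identity on the free
rows) parameterizes every steady state as ``ybar = B @ u``; composing the
relabeling map ``phi``, the dependency map ``psi`` and the reverse
relabeling ``rho`` yields a map ``sigma`` from independent parameters to
every original quantity.

Zero-order (sublinear) and superlinear velocities are handled by
pseudospecies: an auxiliary Y-variable replaces the offending Y-monomial
of the velocity, and a constraint recording what the pseudospecies must
equal (1 for sublinear, the displaced monomial otherwise) is later
resolved against ``ybar = B @ u``, eliminating one basis coefficient per
pseudospecies; quadratic constraints yield one solution branch per root.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field

import sympy as sp

from .model import MassActionModel, Reaction, Species, concentration_symbol

__all__ = [
    "PartitionMap",
    "PartitionReport",
    "Pseudospecies",
    "CoefficientSystem",
    "DependencyMap",
    "SelectionResult",
    "Branch",
    "SteadyStateSolution",
    "PartitionError",
    "TrivialSteadyStateError",
    "ConstraintResolutionError",
    "VerificationError",
    "validate_partition",
    "introduce_pseudospecies",
    "coefficient_matrix",
    "dependency_map",
    "select_independent",
    "count_admissible_partitions",
    "resolve_constraints",
    "compose_and_verify",
    "solve_steady_state",
]


class PartitionError(ValueError):
    pass


class TrivialSteadyStateError(ValueError):
    """The coefficient matrix has full column rank: only ybar = 0 solves it."""


class ConstraintResolutionError(ValueError):
    pass


class VerificationError(RuntimeError):
    """The composed steady-state map failed the exact N @ v(sigma) = 0 check."""


@dataclass(frozen=True)
class Pseudospecies:
    """Auxiliary Y-variable with the monomial its steady value must equal.

    ``target`` is an expression in original quantity symbols (all of which
    must themselves be in Y); ``1`` for a linearized zero-order velocity.
    """

    name: str
    reaction: str
    target: sp.Expr


@dataclass
class PartitionMap:
    """Ordered assignment of every model quantity to the P or Y set.

    Quantities are named by species name (meaning its concentration) or by
    rate symbol. The Y order is significant: reduced row echelon form
    pivots greedily on the lowest-index Y columns, so quantities assigned
    to *higher* Y indices are favored to remain independent. ``frozen``
    species are held time-invariant: their concentrations live in P and
    their mass-balance rows are dropped.
    """

    model: MassActionModel
    p_order: list[str]
    y_order: list[str]
    frozen: frozenset[str] = frozenset()
    pseudospecies: list[Pseudospecies] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frozen = frozenset(self.frozen)
        quantities = set(self.model.species_names) | {
            r.rate_symbol for r in self.model.reactions}
        assigned = list(self.p_order) + list(self.y_order)
        if len(set(assigned)) != len(assigned):
            dup = sorted({q for q in assigned if assigned.count(q) > 1})
            raise PartitionError(f"quantities assigned twice: {dup}")
        if set(assigned) != quantities:
            missing = quantities - set(assigned)
            extra = set(assigned) - quantities
            msg = []
            if missing:
                msg.append(f"unassigned quantities: {sorted(missing)}")
            if extra:
                msg.append(f"unknown quantities: {sorted(extra)}")
            raise PartitionError("partition is not a bijection; " + "; ".join(msg))
        if not self.frozen <= set(self.model.species_names):
            raise PartitionError("frozen set contains unknown species")
        bad = [f for f in self.frozen if f in self.y_order]
        if bad:
            raise PartitionError(f"frozen species must be in P: {sorted(bad)}")

    # -- symbol plumbing ---------------------------------------------------

    def quantity_symbol(self, name: str) -> sp.Symbol:
        if name in self.model.species_names:
            return concentration_symbol(name)
        return sp.Symbol(name, positive=True)

    @property
    def p_symbols(self) -> list[sp.Symbol]:
        return [self.quantity_symbol(n) for n in self.p_order]

    @property
    def y_symbols(self) -> list[sp.Symbol]:
        return [self.quantity_symbol(n) for n in self.y_order]

    @property
    def p_aliases(self) -> list[sp.Symbol]:
        return [sp.Symbol(f"p{i + 1}", positive=True)
                for i in range(len(self.p_order))]

    @property
    def y_aliases(self) -> list[sp.Symbol]:
        return [sp.Symbol(f"y{i + 1}", positive=True)
                for i in range(len(self.y_order))]

    @property
    def phi(self) -> dict[sp.Symbol, sp.Symbol]:
        """Change of variables: original symbols -> p/y alphabet."""
        fwd = dict(zip(self.p_symbols, self.p_aliases))
        fwd.update(zip(self.y_symbols, self.y_aliases))
        return fwd

    @property
    def phi_inv(self) -> dict[sp.Symbol, sp.Symbol]:
        return {v: k for k, v in self.phi.items()}

    def y_index(self, name: str) -> int:
        return self.y_order.index(name)

    def is_pseudo(self, name: str) -> bool:
        return any(ps.name == name for ps in self.pseudospecies)

    # -- constructors ------------------------------------------------------

    @classmethod
    def homogeneous(cls, model: MassActionModel,
                    frozen: frozenset[str] = frozenset()) -> "PartitionMap":
        """All concentrations to P, all rate constants to Y (declaration order)."""
        return cls(model,
                   p_order=list(model.species_names),
                   y_order=[r.rate_symbol for r in model.reactions],
                   frozen=frozen)

    @classmethod
    def from_sets(cls, model: MassActionModel, Y: list[str],
                  P: list[str] | None = None,
                  frozen: frozenset[str] = frozenset()) -> "PartitionMap":
        """Partition from an ordered Y list; P defaults to the complement."""
        if P is None:
            quantities = list(model.species_names) + [
                r.rate_symbol for r in model.reactions]
            P = [q for q in quantities if q not in set(Y)]
        return cls(model, p_order=list(P), y_order=list(Y), frozen=frozen)


# ---------------------------------------------------------------------------
# validation and pseudospecies


@dataclass
class PartitionReport:
    ok: bool
    degrees: dict[str, int]                 # rate symbol -> Y-degree
    violations: list[tuple[str, int, list[str]]]  # (rate, degree, offenders)

    def __bool__(self) -> bool:
        return self.ok


def _y_degree(reaction: Reaction, pm: PartitionMap) -> tuple[int, list[str]]:
    yset = set(pm.y_order)
    deg, offenders = 0, []
    if reaction.rate_symbol in yset:
        deg += 1
        offenders.append(reaction.rate_symbol)
    for name, order in reaction.kinetic_orders.items():
        if name in yset and order:
            deg += order
            offenders.append(name)
    return deg, offenders


def validate_partition(model: MassActionModel, pm: PartitionMap) -> PartitionReport:
    """Check the degree-1 homogeneity requirement velocity by velocity.

    Velocities of degree 0 or >= 2 in the Y-symbols are flagged together
    with the responsible quantities; a pseudospecies can repair them.
    """
    degrees: dict[str, int] = {}
    violations = []
    for r in model.reactions:
        deg, offenders = _y_degree(r, pm)
        degrees[r.rate_symbol] = deg
        if deg != 1:
            violations.append((r.rate_symbol, deg, offenders))
    return PartitionReport(ok=not violations, degrees=degrees,
                           violations=violations)


def introduce_pseudospecies(model: MassActionModel, pm: PartitionMap,
                            reaction: str, index: int | None = None
                            ) -> tuple[MassActionModel, PartitionMap]:
    """Linearize one flagged velocity with a fresh pseudospecies.

    For a zero-order (in Y) velocity the pseudospecies simply multiplies
    it; for a superlinear velocity it replaces the velocity's concentration
    Y-monomial. Either way the returned partition carries a constraint
    fixing what the pseudospecies' steady value must equal (1, or the
    displaced monomial). *index* positions the pseudospecies in the Y
    order (default: appended, i.e. favored to stay independent).
    """
    j = next((i for i, r in enumerate(model.reactions)
              if r.rate_symbol == reaction), None)
    if j is None:
        raise ValueError(f"no reaction with rate symbol {reaction!r}")
    rj = model.reactions[j]
    deg, offenders = _y_degree(rj, pm)
    if deg == 1:
        raise ValueError(f"velocity of {reaction!r} is already linear in Y")
    if deg >= 2 and rj.rate_symbol in offenders:
        raise PartitionError(
            f"velocity of {reaction!r} is superlinear with its rate constant "
            "in Y; reassign the rate constant to P before linearizing")

    ps_name = f"ps{len(pm.pseudospecies) + 1}"
    while ps_name in model.species_names:
        ps_name += "_"
    target: sp.Expr = sp.Integer(1)
    new_model = model.copy()
    new_rj = new_model.reactions[j]
    if deg >= 2:
        for name in offenders:
            target *= concentration_symbol(name) ** new_rj.kinetic_orders[name]
            del new_rj.kinetic_orders[name]
    new_rj.kinetic_orders[ps_name] = 1
    new_model.species.append(Species(ps_name, role_hint="pseudospecies"))

    y_order = list(pm.y_order)
    y_order.insert(index if index is not None else len(y_order), ps_name)
    new_pm = PartitionMap(new_model, p_order=list(pm.p_order), y_order=y_order,
                          frozen=pm.frozen,
                          pseudospecies=pm.pseudospecies
                          + [Pseudospecies(ps_name, reaction, target)])
    return new_model, new_pm


# ---------------------------------------------------------------------------
# the coefficient system


@dataclass
class CoefficientSystem:
    """The linearized steady-state system ``C @ ybar = 0``.

    ``C`` has one row per non-frozen species (pseudospecies rows are
    identically zero) and one column per Y-quantity, with entries in the
    fraction field of polynomials in the P-symbols (generic rank: the
    P-symbols are treated as algebraically independent). ``B`` is the
    special-solution null-space basis from the RREF: entry 1 at each free
    column's own row, 0 at every other free row.
    """

    model: MassActionModel
    partition: PartitionMap
    C: sp.Matrix
    rref: sp.Matrix
    pivots: tuple[int, ...]
    B: sp.Matrix
    q: int
    row_species: list[str]

    @property
    def rank(self) -> int:
        return len(self.pivots)

    @property
    def free_columns(self) -> list[int]:
        """Zero-based indices of the non-pivot (independent) Y columns."""
        return [j for j in range(self.C.cols) if j not in self.pivots]


def coefficient_matrix(model: MassActionModel, pm: PartitionMap
                       ) -> CoefficientSystem:
    """Form ``C = N @ d(v o phi)/d(y)`` and its RREF/null-space basis.

    Requires a validated partition (degree-1 in Y throughout, after any
    pseudospecies). Raises :class:`TrivialSteadyStateError` when the null
    space is zero-dimensional.
    """
    report = validate_partition(model, pm)
    if not report.ok:
        raise PartitionError(
            f"partition does not linearize velocities: {report.violations}")
    phi = pm.phi
    v_y = model.velocity_vector().subs(phi)
    keep = [i for i, s in enumerate(model.species) if s.name not in pm.frozen]
    N = model.stoichiometric_matrix()[keep, :]
    J = v_y.jacobian(sp.Matrix(pm.y_aliases))
    C = sp.Matrix(N * J)
    C = C.applyfunc(sp.cancel)
    # row-reduce over the fraction field of polynomials in the P-symbols;
    # the domain representation avoids the expression swell of generic
    # symbolic elimination
    from sympy.polys.matrices import DomainMatrix

    dM = DomainMatrix.from_Matrix(C, field=True, extension=True)
    R_dm, pivots = dM.rref()
    R = R_dm.to_Matrix().applyfunc(sp.cancel)
    pivots = tuple(int(j) for j in pivots)
    q = C.cols - len(pivots)
    if q == 0:
        raise TrivialSteadyStateError(
            "coefficient matrix has full column rank: only the trivial "
            "steady state exists for this partition")
    # special-solution null-space basis: identity on the free rows, the
    # negated RREF column on the pivot rows
    free = [j for j in range(C.cols) if j not in pivots]
    cols = []
    for j in free:
        col = sp.zeros(C.cols, 1)
        col[j, 0] = sp.Integer(1)
        for r, pc in enumerate(pivots):
            col[pc, 0] = sp.cancel(-R[r, j])
        cols.append(col)
    B = sp.Matrix.hstack(*cols)
    return CoefficientSystem(model=model, partition=pm, C=C, rref=R,
                             pivots=tuple(pivots), B=B, q=q,
                             row_species=[model.species[i].name for i in keep])


# ---------------------------------------------------------------------------
# dependency map, independent selection, partition counting


@dataclass
class DependencyMap:
    """``psi``: every Y-variable as an expression in ``u`` and P-symbols.

    Free columns map to their own basis coefficient ``u_pi(j)``; pivot
    columns map to rational expressions from ``ybar = B @ u``.
    """

    system: CoefficientSystem
    u_symbols: list[sp.Symbol]
    ybar: sp.Matrix                       # length |Y|, entries in u and p
    free_map: dict[int, sp.Symbol]        # free column index -> u symbol

    @property
    def psi(self) -> dict[sp.Symbol, sp.Expr]:
        return {alias: self.ybar[i]
                for i, alias in enumerate(self.system.partition.y_aliases)}


def dependency_map(system: CoefficientSystem,
                   u_symbols: list[sp.Symbol] | None = None) -> DependencyMap:
    if u_symbols is None:
        u_symbols = [sp.Symbol(f"u{i + 1}", positive=True)
                     for i in range(system.q)]
    if len(u_symbols) != system.q:
        raise ValueError(f"need exactly {system.q} u-symbols")
    u = sp.Matrix(u_symbols)
    ybar = system.B * u
    free_map = dict(zip(system.free_columns, u_symbols))
    return DependencyMap(system=system, u_symbols=list(u_symbols),
                         ybar=ybar, free_map=free_map)


def _det_generically_nonzero(M: sp.Matrix, rng: random.Random,
                             tries: int = 3) -> bool:
    """Generic (symbolic) invertibility of a square matrix of rational
    functions: exact random rational evaluation of the entries first, a
    symbolic determinant only as the fallback for apparent zeros."""
    syms = set().union(*(e.free_symbols for e in M)) if M else set()
    for _ in range(tries):
        subs = {s: sp.Rational(rng.randint(1, 9973), rng.randint(1, 9973))
                for s in syms}
        try:
            val = M.xreplace(subs).det()
            if val != 0:
                return True
        except ZeroDivisionError:
            continue
    return sp.cancel(M.det()) != 0


@dataclass
class SelectionResult:
    accepted: bool
    targets: list[str]
    det: sp.Expr
    u_exprs: list[sp.Expr] | None = None   # u in terms of the targets' symbols
    ybar: sp.Matrix | None = None          # full ybar induced by the selection


def select_independent(system: CoefficientSystem, targets: list[str]
                       ) -> SelectionResult:
    """Try to make exactly the *targets* (a Y-subset of size q) independent.

    Inverts the submatrix ``G`` of basis rows at the target indices
    (``u = G^-1 @ w`` with ``w`` the targets' own symbols); a singular
    ``G`` yields a rejection carrying the determinant, not an exception.
    """
    if len(targets) != system.q:
        raise ValueError(f"need exactly q = {system.q} target quantities")
    pm = system.partition
    rows = [pm.y_index(t) for t in targets]
    G = system.B[rows, :]
    if not _det_generically_nonzero(G, random.Random(0)):
        return SelectionResult(accepted=False, targets=list(targets),
                               det=sp.cancel(G.det()))
    det = sp.cancel(G.det())
    w = sp.Matrix([pm.quantity_symbol(t) for t in targets])
    u = G.LUsolve(w)
    u = u.applyfunc(sp.cancel)
    ybar = (system.B * u).applyfunc(sp.cancel)
    return SelectionResult(accepted=True, targets=list(targets), det=det,
                           u_exprs=list(u), ybar=ybar)


def count_admissible_partitions(system: CoefficientSystem, seed: int = 0) -> int:
    """Number of q-row subsets of B forming an invertible square submatrix.

    This is a property of the row matroid of ``B`` and therefore
    independent of the basis choice. Determinants are screened by exact
    random rational evaluation with symbolic confirmation of zeros.
    """
    rng = random.Random(seed)
    count = 0
    for rows in itertools.combinations(range(system.B.rows), system.q):
        if _det_generically_nonzero(system.B[list(rows), :], rng):
            count += 1
    return count


# ---------------------------------------------------------------------------
# constraint resolution and composition


@dataclass
class Branch:
    branch_id: int
    u_subs: dict[sp.Symbol, sp.Expr]
    diagnostics: str = ""


def resolve_constraints(system: CoefficientSystem, dmap: DependencyMap
                        ) -> list[Branch]:
    """Substitute ``ybar = B @ u`` into every pseudospecies constraint and
    solve for basis coefficients, one branch per real root.

    Linear constraints pin a single ``u``; quadratic ones (superlinear
    pseudospecies) produce up to two branches. Roots that are manifestly
    non-real are dropped; if every root of some constraint is complex the
    result is an empty list and the diagnostic explains why.
    """
    pm = system.partition
    if not pm.pseudospecies:
        return [Branch(0, {})]
    ybar_of = {pm.quantity_symbol(n): dmap.ybar[i]
               for i, n in enumerate(pm.y_order)}
    equations = []
    for ps in pm.pseudospecies:
        lhs = ybar_of[pm.quantity_symbol(ps.name)]
        missing = [s for s in ps.target.free_symbols if s not in ybar_of]
        if missing:
            raise ConstraintResolutionError(
                f"constraint target of {ps.name} references non-Y "
                f"quantities: {missing}")
        rhs = ps.target.xreplace(ybar_of)
        equations.append(sp.expand(sp.together(lhs - rhs)))

    u_present = [u for u in dmap.u_symbols
                 if any(eq.has(u) for eq in equations)]
    n = len(equations)
    if len(u_present) < n:
        raise ConstraintResolutionError(
            "fewer basis coefficients appear in the constraints than "
            "constraints to resolve")
    solutions = None
    chosen: tuple[sp.Symbol, ...] = ()
    # prefer eliminating the highest-index coefficients (they correspond to
    # the highest Y indices, usually the pseudospecies themselves)
    for combo in itertools.combinations(reversed(u_present), n):
        try:
            sols = sp.solve(equations, list(combo), dict=True)
        except Exception:
            continue
        if sols:
            solutions, chosen = sols, combo
            break
    if solutions is None:
        raise ConstraintResolutionError(
            "could not solve the pseudospecies constraint system "
            f"symbolically: {equations}")
    branches: list[Branch] = []
    dropped = 0
    for i, sol in enumerate(solutions):
        if any(v.is_number and not v.is_real for v in sol.values()):
            dropped += 1
            continue
        branches.append(Branch(branch_id=len(branches), u_subs=dict(sol)))
    if not branches and dropped:
        return []
    return branches


def _exact_zero_vector(vec: sp.Matrix) -> sp.Matrix:
    """Exact symbolic zero test per entry, in the rational fraction field
    when possible (fast, no intermediate GCD blow-up), through generic
    simplification otherwise (radical-bearing quadratic branches)."""
    entries = list(vec)
    syms = sorted(set().union(*(e.free_symbols for e in entries), set()),
                  key=lambda s: s.name)
    if not syms:
        return sp.Matrix(len(entries), 1, [sp.nsimplify(e) for e in entries])
    try:
        F = sp.polys.fields.field(syms, sp.QQ)[0]
        out = []
        for e in entries:
            val = F.from_expr(e)
            out.append(sp.Integer(0) if not val else val.as_expr())
        return sp.Matrix(len(out), 1, out)
    except Exception:
        def slow(e: sp.Expr) -> sp.Expr:
            e = sp.cancel(sp.together(e))
            return e if e == 0 else sp.simplify(e)

        return sp.Matrix(len(entries), 1, [slow(e) for e in entries])


@dataclass
class SteadyStateSolution:
    """The composed steady-state map sigma for one constraint branch.

    ``dependents`` maps each dependent original quantity symbol to its
    expression in the independent parameters (original names, via rho);
    ``independents`` holds every P-quantity and each surviving free
    Y-quantity. ``forward_map`` keeps psi on the p/y alphabet for
    reference. ``n_dependent`` counts real (non-pseudo) dependent
    quantities, which equals rank(N) for every admissible partition.
    """

    model: MassActionModel
    partition: PartitionMap
    independents: list[sp.Symbol]
    dependents: dict[sp.Symbol, sp.Expr]
    forward_map: dict[sp.Symbol, sp.Expr]
    backward_map: dict[sp.Symbol, sp.Expr]
    branch_id: int
    residual: sp.Matrix | None = None
    verified: bool = False
    feasible: bool | None = None

    @property
    def dependents_simplified(self) -> dict[sp.Symbol, sp.Expr]:
        """Fully simplified dependent expressions (computed on demand: raw
        cancelled forms are kept as the primary representation)."""
        return {k: sp.simplify(v) for k, v in self.dependents.items()}

    @property
    def n_dependent(self) -> int:
        return len(self.dependents)

    @property
    def n_independent(self) -> int:
        return len(self.independents)

    def sigma(self, symbol: sp.Symbol | str) -> sp.Expr:
        """Steady-state expression for one original quantity."""
        if isinstance(symbol, str):
            symbol = self.partition.quantity_symbol(symbol)
        return self.dependents.get(symbol, symbol)


def compose_and_verify(model: MassActionModel, pm: PartitionMap,
                       dmap: DependencyMap, branch: Branch,
                       original_model: MassActionModel | None = None
                       ) -> SteadyStateSolution:
    """Build sigma = rho o psi o phi for one branch and verify it exactly.

    Verification substitutes the dependent expressions into the *original*
    velocity vector (pre-pseudospecies if *original_model* is given) and
    simplifies ``N @ v`` to the zero vector; a nonzero residual raises
    :class:`VerificationError` since it indicates an internal inconsistency.
    """
    verify_model = original_model if original_model is not None else model
    ybar = dmap.ybar.subs(branch.u_subs)
    # rho: p aliases back to original symbols; surviving u's to the original
    # symbol of their free Y-quantity
    rho = dict(zip(pm.p_aliases, pm.p_symbols))
    for col, u in dmap.free_map.items():
        if u not in branch.u_subs:
            rho[u] = pm.quantity_symbol(pm.y_order[col])
    forward_map = {alias: sp.cancel(ybar[i].subs(
        {u: branch.u_subs.get(u, u) for u in dmap.u_symbols}))
        for i, alias in enumerate(pm.y_aliases)}

    dependents: dict[sp.Symbol, sp.Expr] = {}
    independents: list[sp.Symbol] = list(pm.p_symbols)
    backward_map: dict[sp.Symbol, sp.Expr] = {}
    for i, name in enumerate(pm.y_order):
        orig = pm.quantity_symbol(name)
        expr = ybar[i].xreplace(rho)
        radical = any(not p.exp.is_Integer for p in expr.atoms(sp.Pow))
        if radical:
            expr = sp.simplify(expr)
        backward_map[orig] = expr
        if pm.is_pseudo(name):
            continue
        if expr == orig:
            independents.append(orig)
        else:
            dependents[orig] = expr

    # pseudospecies' constrained values are substituted too, so verification
    # works against either the augmented or the original velocity vector
    subs_map = {k: v for k, v in backward_map.items() if v != k}
    v = verify_model.velocity_vector().xreplace(subs_map)
    keep = [i for i, s in enumerate(verify_model.species)
            if s.name not in pm.frozen and not s.is_pseudo]
    N = verify_model.stoichiometric_matrix()[keep, :]
    residual = _exact_zero_vector(N * v)
    ok = all(e == 0 for e in residual)
    sol = SteadyStateSolution(
        model=verify_model, partition=pm,
        independents=independents, dependents=dependents,
        forward_map=forward_map, backward_map=backward_map,
        branch_id=branch.branch_id, residual=residual, verified=ok)
    if not ok:
        raise VerificationError(
            f"nonzero steady-state residual for branch {branch.branch_id}: "
            f"{list(residual)}")
    return sol


def solve_steady_state(model: MassActionModel, pm: PartitionMap,
                       auto_pseudospecies: bool = True
                       ) -> list[SteadyStateSolution]:
    """End-to-end pipeline: validate, linearize, solve, resolve, verify.

    Returns one verified solution per constraint branch. Velocities that
    fail the degree-1 requirement are repaired with pseudospecies when
    *auto_pseudospecies* is set (appended at the end of the Y order).
    """
    original = model
    report = validate_partition(model, pm)
    if not report.ok:
        if not auto_pseudospecies:
            raise PartitionError(
                f"partition does not linearize velocities: {report.violations}")
        for rate, _deg, _off in report.violations:
            model, pm = introduce_pseudospecies(model, pm, rate)
    system = coefficient_matrix(model, pm)
    dmap = dependency_map(system)
    branches = resolve_constraints(system, dmap)
    return [compose_and_verify(model, pm, dmap, b, original_model=original)
            for b in branches]
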