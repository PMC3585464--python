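"""Mass-action reaction models: parsing, stoichiometry, velocities, linearity.

A mass-action model couples a set of species ``X`` and reactions ``R``.
Each reaction converts an integer combination of reactants into an integer
combination of products at a velocity ``v_j = k_j * prod_i x_i**c_ij``,
where ``k_j`` is the rate constant and ``c_ij`` the kinetic order of
species ``i`` in reaction ``j`` (by default its reactant stoichiometry,
but it may be overridden, e.g. for autocatalytic steps). Species
concentrations evolve as ``dx/dt = N @ v`` with ``N`` the stoichiometric
matrix, ``N[i, j] = sP_ij - sR_ij``.

The plain-text reaction format is one reaction per line::

    # comment
    species: E S ES P        # optional explicit declaration/ordering
    E + S -> ES ; k1
    ES <-> E + S ; kf, kr    # reversible, expands to two reactions
    0 -> S ; k4              # zero-order synthesis ("0" or "Ø" is a sink)
    ES -> E + P ; k3 order(ES)=2   # kinetic-order override
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import networkx as nx
import sympy as sp

__all__ = [
    "Species",
    "Reaction",
    "MassActionModel",
    "TransitionSystem",
    "ModelParseError",
    "parse_model",
    "concentration_symbol",
    "is_linear_model",
    "transition_system",
]

#: tokens accepted for the formal source/sink node; it is never a Species
SINK_TOKENS = {"0", "Ø", "∅"}

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_*']*$")
_ORDER_RE = re.compile(r"order\(\s*([^)\s]+)\s*\)\s*=\s*(\d+)")


class ModelParseError(ValueError):
    """Raised on malformed reaction documents; carries the offending line."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


def concentration_symbol(name: str) -> sp.Symbol:
    """Sympy symbol for the concentration (or abundance) of species *name*."""
    return sp.Symbol(f"x_{name}", positive=True)


@dataclass(frozen=True)
class Species:
    name: str
    time_varying: bool = True
    role_hint: str | None = None

    @property
    def symbol(self) -> sp.Symbol:
        return concentration_symbol(self.name)

    @property
    def is_pseudo(self) -> bool:
        return self.role_hint == "pseudospecies"


@dataclass
class Reaction:
    """One irreversible reaction.

    ``kinetic_orders`` lists every species entering the velocity monomial
    with its exponent; it defaults to the reactant stoichiometry.
    ``reverse_of`` links the reverse half of an expanded reversible pair
    to its forward partner's rate symbol.
    """

    reactant_stoich: dict[str, int]
    product_stoich: dict[str, int]
    rate_symbol: str
    kinetic_orders: dict[str, int] = field(default_factory=dict)
    reverse_of: str | None = None

    def __post_init__(self) -> None:
        if not self.reactant_stoich and not self.product_stoich:
            raise ValueError(
                f"reaction {self.rate_symbol!r}: reactant and product sides both empty"
            )
        if not self.kinetic_orders:
            self.kinetic_orders = dict(self.reactant_stoich)

    @property
    def k(self) -> sp.Symbol:
        return sp.Symbol(self.rate_symbol, positive=True)

    def velocity(self) -> sp.Expr:
        v: sp.Expr = self.k
        for name, order in self.kinetic_orders.items():
            if order:
                v *= concentration_symbol(name) ** order
        return v


@dataclass
class MassActionModel:
    species: list[Species]
    reactions: list[Reaction]
    name: str = "model"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.species:
            if s.name in seen:
                raise ValueError(f"duplicate species {s.name!r}")
            seen.add(s.name)
        rates = [r.rate_symbol for r in self.reactions]
        if len(set(rates)) != len(rates):
            raise ValueError("rate symbols must be unique per reaction")

    # -- structure ---------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def concentration_symbols(self) -> list[sp.Symbol]:
        return [s.symbol for s in self.species]

    @property
    def rate_symbols(self) -> list[sp.Symbol]:
        return [r.k for r in self.reactions]

    def stoichiometric_matrix(self) -> sp.Matrix:
        """Integer matrix ``N`` with ``N[i, j] = sP_ij - sR_ij``."""
        idx = {n: i for i, n in enumerate(self.species_names)}
        N = sp.zeros(self.n_species, self.n_reactions)
        for j, r in enumerate(self.reactions):
            for name, c in r.reactant_stoich.items():
                N[idx[name], j] -= c
            for name, c in r.product_stoich.items():
                N[idx[name], j] += c
        return N

    def velocity_vector(self) -> sp.Matrix:
        """Column vector of symbolic mass-action velocities."""
        return sp.Matrix([r.velocity() for r in self.reactions])

    def time_derivatives(self) -> sp.Matrix:
        """``dx/dt = N @ v``, expanded."""
        return sp.expand(self.stoichiometric_matrix() * self.velocity_vector())

    # -- editing -----------------------------------------------------------

    def copy(self) -> "MassActionModel":
        return MassActionModel(
            species=list(self.species),
            reactions=[replace(r, reactant_stoich=dict(r.reactant_stoich),
                               product_stoich=dict(r.product_stoich),
                               kinetic_orders=dict(r.kinetic_orders))
                       for r in self.reactions],
            name=self.name,
        )

    def pair_reversibles(self) -> list[tuple[Reaction, Reaction]]:
        """Re-pair expanded reverse reactions with their forward partners."""
        by_rate = {r.rate_symbol: r for r in self.reactions}
        return [(by_rate[r.reverse_of], r) for r in self.reactions
                if r.reverse_of is not None]


# ---------------------------------------------------------------------------
# parsing


def _parse_side(text: str, line_no: int) -> dict[str, int]:
    text = text.strip()
    if text in SINK_TOKENS:
        return {}
    stoich: dict[str, int] = {}
    for term in text.split("+"):
        term = term.strip()
        if not term:
            raise ModelParseError("empty term in reaction side", line_no)
        if term in SINK_TOKENS:
            raise ModelParseError(
                "sink token cannot be combined with species", line_no)
        m = re.match(r"^(\d+)\s+(.*)$", term)
        coeff, name = (int(m.group(1)), m.group(2).strip()) if m else (1, term)
        if not _NAME_RE.match(name):
            raise ModelParseError(f"unknown token {name!r}", line_no)
        stoich[name] = stoich.get(name, 0) + coeff
    return stoich


def parse_model(text: str, name: str = "model") -> MassActionModel:
    """Parse a reaction-format document into a :class:`MassActionModel`.

    Reversible arrows ``<->`` expand into two irreversible reactions; if a
    single rate name ``k`` is given the pair becomes ``k_f`` / ``k_r``.
    """
    declared: list[str] = []
    order_seen: list[str] = []
    reactions: list[Reaction] = []

    def note(names) -> None:
        for n in names:
            if n not in order_seen:
                order_seen.append(n)

    for line_no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.lower().startswith("species:"):
            for n in line.split(":", 1)[1].split():
                if not _NAME_RE.match(n):
                    raise ModelParseError(f"unknown token {n!r}", line_no)
                if n in declared:
                    raise ModelParseError(f"duplicate species {n!r}", line_no)
                declared.append(n)
            continue
        if ";" not in line:
            raise ModelParseError("missing ';' before rate symbol(s)", line_no)
        body, rate_part = line.split(";", 1)
        reversible = "<->" in body
        arrow = "<->" if reversible else "->"
        if arrow not in body:
            raise ModelParseError("missing reaction arrow", line_no)
        lhs, rhs = body.split(arrow, 1)
        reactants = _parse_side(lhs, line_no)
        products = _parse_side(rhs, line_no)
        if not reactants and not products:
            raise ModelParseError(
                "reaction with empty reactant and product sides", line_no)

        orders: dict[str, int] = {}
        for m in _ORDER_RE.finditer(rate_part):
            orders[m.group(1)] = int(m.group(2))
        rate_part = _ORDER_RE.sub("", rate_part)
        rates = [t for t in re.split(r"[,\s]+", rate_part.strip()) if t]
        for t in rates:
            if not _NAME_RE.match(t):
                raise ModelParseError(f"unknown token {t!r}", line_no)
        if reversible:
            if len(rates) == 1:
                kf, kr = rates[0] + "_f", rates[0] + "_r"
            elif len(rates) == 2:
                kf, kr = rates
            else:
                raise ModelParseError(
                    "reversible reaction takes one or two rate symbols", line_no)
            if orders:
                raise ModelParseError(
                    "kinetic-order overrides are not supported on reversible "
                    "lines; expand the pair explicitly", line_no)
            reactions.append(Reaction(reactants, products, kf))
            reactions.append(Reaction(products, reactants, kr, reverse_of=kf))
        else:
            if len(rates) != 1:
                raise ModelParseError("exactly one rate symbol expected", line_no)
            ko = dict(reactants)
            ko.update(orders)
            ko = {n: o for n, o in ko.items() if o > 0}
            reactions.append(Reaction(reactants, products, rates[0],
                                      kinetic_orders=ko))
        note(reactants)
        note(products)
        note(orders)

    if not reactions:
        raise ModelParseError("no reactions")
    for n in order_seen:
        if declared and n not in declared:
            raise ModelParseError(f"species {n!r} used but not declared")
    names = declared if declared else order_seen
    model = MassActionModel([Species(n) for n in names], reactions, name=name)

    N = model.stoichiometric_matrix()
    for j in range(model.n_reactions):
        if all(N[i, j] == 0 for i in range(model.n_species)):
            raise ModelParseError(
                f"reaction {model.reactions[j].rate_symbol!r} is a pure "
                "pass-through (zero stoichiometric column)")
    return model


# ---------------------------------------------------------------------------
# linear models and transition systems


def is_linear_model(model: MassActionModel, frozen: set[str] | frozenset[str] = frozenset()
                    ) -> tuple[bool, list[str]]:
    """Test whether the model is linear once *frozen* species are held fixed.

    A linear model has, after deleting the frozen species' rows, exactly one
    +1 and one -1 in every stoichiometric column, and every velocity of
    degree 1 in the remaining concentrations. Returns ``(flag, witness)``
    where *witness* lists the rate symbols of violating reactions.
    """
    frozen = set(frozen)
    unknown = frozen - set(model.species_names)
    if unknown:
        raise ValueError(f"frozen species not in model: {sorted(unknown)}")
    N = model.stoichiometric_matrix()
    keep = [i for i, s in enumerate(model.species) if s.name not in frozen]
    witness: list[str] = []
    for j, r in enumerate(model.reactions):
        col = [N[i, j] for i in keep]
        ok_stoich = sorted(col) == [-1] + [0] * (len(keep) - 2) + [1] if len(keep) >= 2 else False
        deg = sum(o for n, o in r.kinetic_orders.items() if n not in frozen)
        if not (ok_stoich and deg == 1):
            witness.append(r.rate_symbol)
    return (not witness, witness)


@dataclass
class TransitionSystem:
    """Pseudo-first-order transition form ``dx/dt = K @ x`` of a linear model.

    ``K[i, j]`` for ``i != j`` is the transition rate constant from species
    ``j`` to species ``i`` (a rate constant times any folded frozen
    concentrations); diagonal entries are minus the column sums, so every
    column of ``K`` sums to zero.
    """

    species: list[str]
    K: sp.Matrix
    graph: nx.DiGraph

    @property
    def n(self) -> int:
        return len(self.species)

    def is_connected(self) -> bool:
        return nx.is_weakly_connected(self.graph)

    def edge_weight(self, src: str, dst: str) -> sp.Expr:
        return self.graph.edges[src, dst]["kappa"]


class NonlinearModelError(ValueError):
    pass


def transition_system(model: MassActionModel,
                      frozen: set[str] | frozenset[str] = frozenset()
                      ) -> TransitionSystem:
    """Build the transition matrix ``K`` and graph of a linear model.

    Frozen species' concentrations are folded into the transition rate
    constants (pseudo-first-order reduction). Raises
    :class:`NonlinearModelError` for nonlinear models: those need the
    py-substitution engine instead.
    """
    ok, witness = is_linear_model(model, frozen)
    if not ok:
        raise NonlinearModelError(
            "model is not linear under the given frozen set (offending "
            f"reactions: {witness}); use the substitution engine instead")
    frozen = set(frozen)
    names = [s.name for s in model.species if s.name not in frozen]
    idx = {n: i for i, n in enumerate(names)}
    K = sp.zeros(len(names), len(names))
    g = nx.DiGraph()
    g.add_nodes_from(names)
    N = model.stoichiometric_matrix()
    for j, r in enumerate(model.reactions):
        src = next(n for n in names if N[model.species_index(n), j] == -1)
        dst = next(n for n in names if N[model.species_index(n), j] == +1)
        kappa: sp.Expr = r.k
        for n, o in r.kinetic_orders.items():
            if n in frozen:
                kappa *= concentration_symbol(n) ** o
        K[idx[dst], idx[src]] += kappa
        K[idx[src], idx[src]] -= kappa
        if g.has_edge(src, dst):
            g.edges[src, dst]["kappa"] += kappa
        else:
            g.add_edge(src, dst, kappa=kappa)
    return TransitionSystem(names, K, g)
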