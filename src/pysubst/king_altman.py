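"""King-Altman solution of linear models and equivalence with py-substitution.

For a linear model ``dx/dt = K @ x``, the steady-state concentration of
species ``i`` is proportional to the principal minor ``M_ii`` of ``-K``
(row and column ``i`` deleted). King and Altman observed that ``M_ii``
equals the sum, over all directed spanning trees of the transition graph
rooted *into* ``i`` (the King-Altman patterns), of the product of the
transition rate constants along the tree's edges. Concentrations are
reported normalized so that they sum to a total-concentration symbol,
mirroring the conservation constraint implicit in the minor formulation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import sympy as sp

from .model import TransitionSystem, concentration_symbol
from .substitution import SteadyStateSolution

__all__ = [
    "KingAltmanResult",
    "DisconnectedGraphError",
    "DegenerateNetworkError",
    "enumerate_patterns",
    "pattern_minor",
    "determinant_minor",
    "ka_steady_state",
    "equivalence_check",
]


class DisconnectedGraphError(ValueError):
    """The transition graph is not weakly connected: no spanning patterns."""


class DegenerateNetworkError(ValueError):
    pass


def enumerate_patterns(ts: TransitionSystem, root: str
                       ) -> list[frozenset[tuple[str, str]]]:
    """All King-Altman patterns for *root*: directed spanning trees with
    every edge oriented towards the root.

    Each pattern has ``n - 1`` edges, every non-root vertex out-degree 1,
    the root out-degree 0, and no cycles. Parallel transitions between the
    same ordered species pair are merged (their rate constants add).
    """
    if root not in ts.species:
        raise ValueError(f"unknown root species {root!r}")
    if not ts.is_connected():
        raise DisconnectedGraphError(
            "transition graph is disjoint; no spanning patterns exist")
    others = [v for v in ts.species if v != root]
    out_edges = {v: list(ts.graph.successors(v)) for v in others}
    patterns: set[frozenset[tuple[str, str]]] = set()
    for choice in itertools.product(*(out_edges[v] for v in others)):
        succ = dict(zip(others, choice))
        # acyclic functional graph <=> every vertex reaches the root
        ok = True
        for v in others:
            seen = set()
            w = v
            while w != root:
                if w in seen:
                    ok = False
                    break
                seen.add(w)
                w = succ[w]
            if not ok:
                break
        if ok:
            patterns.add(frozenset(succ.items()))
    return sorted(patterns, key=lambda p: sorted(p))


def pattern_minor(ts: TransitionSystem, root: str) -> sp.Expr:
    """``M_ii`` as the King-Altman pattern sum of edge-rate products."""
    total = sp.Integer(0)
    for pattern in enumerate_patterns(ts, root):
        term = sp.Integer(1)
        for src, dst in pattern:
            term *= ts.edge_weight(src, dst)
        total += term
    return sp.expand(total)


def determinant_minor(ts: TransitionSystem, root: str) -> sp.Expr:
    """``M_ii`` computed directly as the principal minor of ``-K``.

    The sign convention matches the positive pattern sum: deleting row and
    column ``i`` of ``-K`` gives a matrix whose determinant is the sum of
    rooted spanning-tree weights (matrix-tree theorem).
    """
    i = ts.species.index(root)
    keep = [j for j in range(ts.n) if j != i]
    return sp.expand((-ts.K)[keep, keep].det())


@dataclass
class KingAltmanResult:
    species: list[str]
    patterns: dict[str, list[frozenset[tuple[str, str]]]]
    minors: dict[str, sp.Expr]
    concentrations: dict[str, sp.Expr]
    normalization: sp.Symbol

    @property
    def pattern_counts(self) -> dict[str, int]:
        return {s: len(p) for s, p in self.patterns.items()}


def ka_steady_state(ts: TransitionSystem,
                    total_symbol: sp.Symbol | str = "E_total"
                    ) -> KingAltmanResult:
    """Steady-state concentrations by the King-Altman method.

    ``xbar_i = total * M_ii / sum_j M_jj``; the concentrations therefore
    sum to the total-concentration symbol and every ratio is invariant
    under uniform scaling of the rate constants.
    """
    if isinstance(total_symbol, str):
        total_symbol = sp.Symbol(total_symbol, positive=True)
    patterns = {s: enumerate_patterns(ts, s) for s in ts.species}
    minors: dict[str, sp.Expr] = {}
    for s in ts.species:
        term_sum = sp.Integer(0)
        for pattern in patterns[s]:
            term = sp.Integer(1)
            for src, dst in pattern:
                term *= ts.edge_weight(src, dst)
            term_sum += term
        minors[s] = sp.expand(term_sum)
    denom = sp.expand(sum(minors.values()))
    if denom == 0:
        raise DegenerateNetworkError("all minors vanish: degenerate network")
    conc = {s: total_symbol * minors[s] / denom for s in ts.species}
    return KingAltmanResult(species=list(ts.species), patterns=patterns,
                            minors=minors, concentrations=conc,
                            normalization=total_symbol)


@dataclass
class EquivalenceVerdict:
    equivalent: bool
    certificate: dict[str, sp.Expr]   # simplified differences, must all be 0

    def __bool__(self) -> bool:
        return self.equivalent


def equivalence_check(ka: KingAltmanResult, py: SteadyStateSolution
                      ) -> EquivalenceVerdict:
    """Verify that the King-Altman and py-substitution solutions agree.

    The py solution of a linear model leaves exactly one concentration
    free (its q = 1 null space); imposing the same total-concentration
    constraint ``sum xbar = total`` eliminates it, after which every
    concentration must match the King-Altman expression symbolically.
    """
    species = ka.species
    missing = [s for s in species
               if concentration_symbol(s) not in py.backward_map]
    if missing:
        raise ValueError(
            f"structural mismatch: py solution lacks species {missing}")
    exprs = {s: py.backward_map[concentration_symbol(s)] for s in species}
    free = [s for s in species
            if exprs[s] == concentration_symbol(s)]
    if len(free) != 1:
        raise ValueError(
            "expected exactly one free concentration in the py solution "
            f"of a linear model, found {free}")
    fs = concentration_symbol(free[0])
    total_eq = sp.together(sum(exprs.values()) - ka.normalization)
    sols = sp.solve(total_eq, fs)
    if len(sols) != 1:
        raise ValueError("total-concentration constraint did not pin the "
                         "free concentration uniquely")
    pin = {fs: sols[0]}
    certificate: dict[str, sp.Expr] = {}
    ok = True
    for s in species:
        diff = sp.cancel(sp.together(exprs[s].subs(pin) - ka.concentrations[s]))
        diff = sp.simplify(diff) if diff != 0 else diff
        certificate[s] = diff
        ok = ok and diff == 0
    return EquivalenceVerdict(equivalent=ok, certificate=certificate)
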