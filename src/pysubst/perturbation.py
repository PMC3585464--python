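"""Numeric realization of symbolic steady states and perturbation-response
analysis: simulation, dose thresholds, half-max times, and normalized
parameter sensitivities.

Workflow: a :class:`~pysubst.substitution.SteadyStateSolution` is realized
by assigning positive numbers to every independent parameter; the
dependent quantities follow from the steady-state map sigma, so the
realized state is a fixed point of ``dx/dt = N @ v`` by construction (the
residual is checked). Perturbations (fold or step changes to a species
abundance or rate constant) are then integrated with a stiff-capable
adaptive solver, and response metrics are computed:

* ``L_min`` -- the minimal input fold-change that triggers a switch event,
  found by bisection on the log fold-change;
* ``T_d`` -- the time at which a designated output first crosses 50% of
  its maximum over the horizon (linearly interpolated);
* backward-finite-difference sensitivities of either metric to the
  steady-state value of each independent quantity, with sigma-mediated
  compensation keeping the system at steady state, normalized to the
  largest observed magnitude.

Time is measured in hours; the default 48 h horizon suits apoptosis-style
switch dynamics.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import sympy as sp
from scipy.integrate import solve_ivp

from .model import MassActionModel
from .substitution import SteadyStateSolution

__all__ = [
    "NumericRealization",
    "Trajectory",
    "ThresholdResult",
    "RealizationError",
    "realize",
    "simulate",
    "response_threshold",
    "time_of_half_max",
    "sensitivity_coefficients",
    "steady_state_scan",
    "half_max_event",
]

#: default absolute residual tolerance for a realized steady state
ATOL = 1e-8
RTOL = 1e-6


class RealizationError(ValueError):
    pass


@dataclass
class NumericRealization:
    solution: SteadyStateSolution
    parameter_values: dict[str, float]          # independents, by name
    derived_values: dict[str, float]            # dependents, by name
    residual: float
    feasible: bool
    branch_id: int
    infeasible_quantities: list[str] = field(default_factory=list)

    def value(self, name: str) -> float:
        if name in self.parameter_values:
            return self.parameter_values[name]
        return self.derived_values[name]

    @property
    def all_values(self) -> dict[str, float]:
        return {**self.parameter_values, **self.derived_values}

    def state_vector(self, model: MassActionModel | None = None) -> np.ndarray:
        model = model or self.solution.model
        return np.array([self.value(s.name) for s in model.species
                         if not s.is_pseudo], dtype=float)

    def rate_values(self, model: MassActionModel | None = None) -> dict[str, float]:
        model = model or self.solution.model
        return {r.rate_symbol: self.value(r.rate_symbol)
                for r in model.reactions}


def _symbol_name(pm, sym: sp.Symbol) -> str:
    name = sym.name
    return name[2:] if name.startswith("x_") else name


def realize(solution: SteadyStateSolution, values: dict[str, float],
            atol: float = ATOL) -> NumericRealization:
    """Evaluate the steady-state map at numeric independent values.

    *values* must cover every independent parameter (species by name,
    rate constants by symbol). A negative dependent marks the realization
    infeasible (the branch does not describe a physical steady state);
    a division by zero is an error naming the offending expression.
    """
    pm = solution.partition
    subs: dict[sp.Symbol, sp.Float] = {}
    parameter_values: dict[str, float] = {}
    missing = []
    for sym in solution.independents:
        name = _symbol_name(pm, sym)
        if name not in values:
            missing.append(name)
            continue
        parameter_values[name] = float(values[name])
        subs[sym] = sp.Float(values[name])
    if missing:
        raise RealizationError(
            f"missing values for independent parameters: {sorted(missing)}")

    derived_values: dict[str, float] = {}
    infeasible: list[str] = []
    for sym, expr in solution.dependents.items():
        name = _symbol_name(pm, sym)
        val = expr.xreplace(subs)
        val = complex(val) if not val.is_real else float(val)
        if isinstance(val, complex):
            if abs(val.imag) > 1e-12 * max(1.0, abs(val.real)):
                infeasible.append(name)
                val = math.nan
            else:
                val = val.real
        if not math.isfinite(val):
            if math.isnan(val):
                derived_values[name] = val
                continue
            raise RealizationError(
                f"division by zero evaluating {name} = {expr}")
        derived_values[name] = val
        if val <= 0:
            infeasible.append(name)

    feasible = not infeasible
    model = solution.model
    # residual of the mass-balance equations at the realized state
    residual = 0.0
    if feasible:
        all_vals = {**parameter_values, **derived_values}
        conc = {s.symbol: all_vals[s.name] for s in model.species
                if not s.is_pseudo}
        rates = {r.k: all_vals[r.rate_symbol] for r in model.reactions}
        N = np.array(model.stoichiometric_matrix(), dtype=float)
        v = np.array([float(r.velocity().xreplace({**conc, **rates}))
                      for r in model.reactions])
        frozen = pm.frozen
        dx = N @ v
        keep = [i for i, s in enumerate(model.species) if s.name not in frozen]
        residual = float(np.max(np.abs(dx[keep]))) if keep else 0.0
        scale = max(1.0, float(np.max(np.abs(v)))) if len(v) else 1.0
        feasible = residual <= atol * scale
    return NumericRealization(solution=solution,
                              parameter_values=parameter_values,
                              derived_values=derived_values,
                              residual=residual, feasible=feasible,
                              branch_id=solution.branch_id,
                              infeasible_quantities=infeasible)


# ---------------------------------------------------------------------------
# simulation


@dataclass
class Trajectory:
    t: np.ndarray
    x: np.ndarray                      # shape (n_times, n_species)
    species: list[str]

    def series(self, name: str) -> np.ndarray:
        return self.x[:, self.species.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.x, columns=self.species)
        df.insert(0, "time_h", self.t)
        return df

    def max_relative_drift(self, x0: np.ndarray) -> float:
        scale = np.maximum(np.abs(x0), 1e-30)
        return float(np.max(np.abs(self.x - x0[None, :]) / scale[None, :]))


def _rhs_function(model: MassActionModel, rate_values: dict[str, float],
                  frozen: frozenset[str]):
    species = [s for s in model.species if not s.is_pseudo]
    names = [s.name for s in species]
    conc_syms = [s.symbol for s in species]
    subs = {sp.Symbol(k, positive=True): float(v)
            for k, v in rate_values.items()}
    N = model.stoichiometric_matrix()
    keep = [i for i, s in enumerate(model.species) if not s.is_pseudo]
    dx = (N[keep, :] * model.velocity_vector()).xreplace(subs)
    frozen_idx = [i for i, n in enumerate(names) if n in frozen]
    f = sp.lambdify(conc_syms, list(dx), modules="numpy")

    def rhs(t, x):
        out = np.asarray(f(*x), dtype=float)
        for i in frozen_idx:
            out[i] = 0.0
        return out

    return rhs, names


def simulate(model: MassActionModel, realization: NumericRealization,
             perturbation: dict | None = None, horizon: float = 48.0,
             n_points: int = 481, rtol: float = RTOL, atol: float = ATOL
             ) -> Trajectory:
    """Integrate ``dx/dt = N @ v`` from the realized steady state.

    *perturbation* is ``{"quantity": name, "fold": f}`` or
    ``{"quantity": name, "step": delta}``; the quantity may be a species
    abundance (initial-condition change) or a rate constant. With no
    perturbation the trajectory stays at the fixed point.
    """
    rate_values = realization.rate_values(model)
    species = [s for s in model.species if not s.is_pseudo]
    x0 = np.array([realization.value(s.name) for s in species], dtype=float)
    if perturbation:
        name = perturbation["quantity"]
        if name in rate_values:
            base = rate_values[name]
            rate_values[name] = (base * perturbation["fold"]
                                 if "fold" in perturbation
                                 else base + perturbation["step"])
        else:
            i = [s.name for s in species].index(name)
            x0[i] = (x0[i] * perturbation["fold"] if "fold" in perturbation
                     else x0[i] + perturbation["step"])
    rhs, names = _rhs_function(model, rate_values,
                               realization.solution.partition.frozen)
    t_eval = np.linspace(0.0, horizon, n_points)
    res = solve_ivp(rhs, (0.0, horizon), x0, method="LSODA",
                    t_eval=t_eval, rtol=rtol, atol=atol)
    if not res.success:
        raise RuntimeError(f"integrator failure: {res.message}")
    return Trajectory(t=res.t, x=res.y.T, species=names)


# ---------------------------------------------------------------------------
# response metrics


def time_of_half_max(trajectory: Trajectory, output: str) -> float | None:
    """First time the output crosses half of its horizon maximum.

    Linear interpolation between samples; ``None`` when no crossing
    occurs (e.g. a monotonically decreasing output).
    """
    y = trajectory.series(output)
    t = trajectory.t
    half = 0.5 * float(np.max(y))
    if y[0] >= half:
        # output starts at or above half-max: no upward crossing exists
        return None
    above = np.nonzero(y >= half)[0]
    if len(above) == 0:
        return None
    i = above[0]
    y0, y1 = y[i - 1], y[i]
    return float(t[i - 1] + (half - y0) / (y1 - y0) * (t[i] - t[i - 1]))


def half_max_event(output: str, reference: float):
    """Event predicate: the output exceeds 50% of *reference* at any time."""

    def predicate(trajectory: Trajectory) -> bool:
        return bool(np.max(trajectory.series(output)) >= 0.5 * reference)

    return predicate


@dataclass
class ThresholdResult:
    found: bool
    L_min: float | None
    bracket: tuple[float, float]
    n_iterations: int
    message: str = ""
    warning: str | None = None


def response_threshold(model: MassActionModel,
                       realization: NumericRealization,
                       input_quantity: str, event_predicate,
                       bracket: tuple[float, float] = (1.0, 1e6),
                       rel_tol: float = 0.01, horizon: float = 48.0,
                       verify_grid: int | None = None) -> ThresholdResult:
    """Minimal input fold-change triggering the switch event (``L_min``).

    Binary search on the log2 fold-change to a 1% relative tolerance; the
    event predicate must be false at the lower bracket and true at the
    upper one, otherwise the condition is reported without searching.
    With *verify_grid* set, the predicate is additionally evaluated on a
    log-spaced grid and a non-monotone pattern attaches a warning.
    """

    def fires(fold: float) -> bool:
        traj = simulate(model, realization,
                        {"quantity": input_quantity, "fold": fold},
                        horizon=horizon)
        return bool(event_predicate(traj))

    lo, hi = bracket
    if fires(lo):
        return ThresholdResult(False, None, bracket, 0,
                               "event already fires at the lower bracket")
    if not fires(hi):
        return ThresholdResult(False, None, bracket, 0,
                               "no threshold in bracket")
    n = 0
    while hi / lo > 1.0 + rel_tol:
        mid = math.exp2(0.5 * (math.log2(lo) + math.log2(hi)))
        if fires(mid):
            hi = mid
        else:
            lo = mid
        n += 1
    warning = None
    if verify_grid:
        grid = np.exp2(np.linspace(math.log2(bracket[0]),
                                   math.log2(bracket[1]), verify_grid))
        flags = [fires(g) for g in grid]
        switches = sum(1 for a, b in zip(flags, flags[1:]) if a != b)
        if switches > 1:
            warning = ("event predicate is non-monotone across the "
                       "verification grid")
            warnings.warn(warning)
    return ThresholdResult(True, hi, (lo, hi), n, warning=warning)


def sensitivity_coefficients(solution: SteadyStateSolution,
                             realization: NumericRealization, metric,
                             quantities: list[str], rel_step: float = 0.01
                             ) -> dict[str, float | None]:
    """Normalized backward-finite-difference sensitivities of a metric.

    For each quantity (an independent parameter, typically a steady-state
    abundance), its value is reduced by *rel_step*, the dependent
    quantities are recomputed through sigma (so the perturbed system is
    again at steady state), and the metric is re-evaluated. Coefficients
    ``(m(b) - m(b - db)) / db`` are normalized by the largest magnitude,
    so ``max |coefficient| = 1``; an undefined metric yields ``None``.
    """
    base_metric = metric(realization)
    if base_metric is None:
        raise RealizationError("metric undefined at the base point")
    raw: dict[str, float | None] = {}
    for name in quantities:
        if name not in realization.parameter_values:
            raise RealizationError(
                f"{name!r} is not an independent parameter of this solution")
        base = realization.parameter_values[name]
        values = dict(realization.parameter_values)
        values[name] = base * (1.0 - rel_step)
        pert = realize(solution, values)
        m = metric(pert) if pert.feasible else None
        raw[name] = (None if m is None
                     else (base_metric - m) / (base * rel_step))
    mags = [abs(v) for v in raw.values() if v is not None]
    if not mags or max(mags) == 0.0:
        return raw
    top = max(mags)
    return {k: (None if v is None else v / top) for k, v in raw.items()}


@dataclass
class ScanPoint:
    abundance: float
    metric: float | None
    feasible: bool


def steady_state_scan(solution: SteadyStateSolution,
                      realization: NumericRealization, species: str,
                      metric, fold_range: float = 100.0, n_points: int = 7
                      ) -> list[ScanPoint]:
    """Evaluate a metric while varying one steady-state abundance.

    The abundance is swept over *fold_range* on a log-spaced grid centered
    geometrically on its base value (endpoints ``base/10`` and
    ``base*10`` for the default 100-fold range). At each point the
    compensating dependent quantities are recomputed from sigma so the
    state remains a steady state; infeasible points are flagged and the
    scan continues.
    """
    if species not in realization.parameter_values:
        raise RealizationError(
            f"steady abundance of {species!r} is not an independent "
            "parameter; choose a partition (or select_independent targets) "
            "that makes it one")
    base = realization.parameter_values[species]
    half = math.sqrt(fold_range)
    grid = base * np.exp(np.linspace(math.log(1 / half), math.log(half),
                                     n_points))
    curve: list[ScanPoint] = []
    for a in grid:
        values = dict(realization.parameter_values)
        values[species] = float(a)
        pert = realize(solution, values)
        if not pert.feasible:
            curve.append(ScanPoint(float(a), None, False))
            continue
        curve.append(ScanPoint(float(a), metric(pert), True))
    return curve
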