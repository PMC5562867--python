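"""Flux balance analysis and derived optimizations.

All entry points reduce to a single linear program

    optimize  c' v   subject to   S v = 0,  l <= v <= u

solved through a narrow backend interface (scipy's HiGHS by default) so the
solver can be swapped via configuration.  Only the objective value of an FBA
solution is contract-guaranteed; individual fluxes are solver-dependent under
degeneracy and should be interrogated through flux-variability ranges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize as scipy_opt
from scipy import sparse

from .model import Direction, MetabolicModel, build_stoichiometric_matrix

#: numerical tolerances (standard LP practice)
FEASIBILITY_TOL = 1e-9
STEADY_STATE_TOL = 1e-6
OPTIMALITY_TOL = 1e-8


class SolverError(RuntimeError):
    """Numerical failure inside the LP backend."""


@dataclass
class FBASolution:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float
    fluxes: dict[str, float]
    objective_reaction: str
    direction: Direction
    extra: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class TitrationCurve:
    parameter_name: str
    parameter_values: list[float]
    objective_values: list[float]

    def __post_init__(self) -> None:
        if len(self.parameter_values) != len(self.objective_values):
            raise ValueError("titration curve arrays must have equal length")


# -- backend --------------------------------------------------------------


def solve_lp(
    c: np.ndarray,
    A_eq: sparse.spmatrix,
    bounds: list[tuple[float, float]],
    solver: str = "highs",
) -> tuple[str, float, np.ndarray | None]:
    """Minimize c'v subject to A_eq v = 0 and box bounds.

    Returns (status, objective, x).  Status is one of "optimal",
    "infeasible", "unbounded"; any other solver condition raises SolverError.
    """
    if A_eq.shape[1] == 0:
        return "optimal", 0.0, np.zeros(0)
    res = scipy_opt.linprog(
        c,
        A_eq=A_eq,
        b_eq=np.zeros(A_eq.shape[0]),
        bounds=bounds,
        method=solver,
    )
    if res.status == 0:
        return "optimal", float(res.fun), np.asarray(res.x, dtype=float)
    if res.status == 2:
        return "infeasible", math.nan, None
    if res.status == 3:
        return "unbounded", math.nan, None
    raise SolverError(f"LP backend failed with status {res.status}: {res.message}")


def _model_lp_parts(model: MetabolicModel):
    S = build_stoichiometric_matrix(model)
    lb, ub = model.bounds_vectors()
    bounds = list(zip(lb.tolist(), ub.tolist()))
    return S, bounds


def solve_fba(
    model: MetabolicModel,
    objective_reaction: str,
    direction: Direction = Direction.MAXIMIZE,
    solver: str = "highs",
) -> FBASolution:
    """Optimize the flux through one reaction at steady state.

    Infeasibility or unboundedness is reported in ``status``, not raised.
    """
    model.get_reaction(objective_reaction)
    S, bounds = _model_lp_parts(model)
    rxn_idx = model.reaction_index()
    c = np.zeros(model.n_reactions)
    sign = -1.0 if direction is Direction.MAXIMIZE else 1.0
    c[rxn_idx[objective_reaction]] = sign

    status, fun, x = solve_lp(c, S, bounds, solver=solver)
    if status != "optimal":
        return FBASolution(status, math.nan, {}, objective_reaction, direction)
    # linprog minimizes; for maximization fun = -v_obj.
    obj = -fun if direction is Direction.MAXIMIZE else fun
    fluxes = dict(zip(model.reactions.keys(), x.tolist()))
    return FBASolution("optimal", float(obj), fluxes, objective_reaction, direction)


def max_flux(model: MetabolicModel, reaction_id: str, solver: str = "highs") -> float:
    sol = solve_fba(model, reaction_id, Direction.MAXIMIZE, solver=solver)
    return sol.objective_value if sol.optimal else math.nan


def min_flux(model: MetabolicModel, reaction_id: str, solver: str = "highs") -> float:
    sol = solve_fba(model, reaction_id, Direction.MINIMIZE, solver=solver)
    return sol.objective_value if sol.optimal else math.nan


def lexicographic_optimize(
    model: MetabolicModel,
    primary: tuple[str, Direction],
    secondary: tuple[str, Direction],
    solver: str = "highs",
) -> FBASolution:
    """Two-stage LP: optimize ``primary``, pin it, then optimize ``secondary``.

    Stage 2 constrains the primary flux to its optimum within a band of
    +/- OPTIMALITY_TOL * max(1, |opt|) to avoid an empty feasible set from
    round-off.  The returned solution is the stage-2 solution; the stage-1
    optimum is stored under ``extra['primary_value']``.
    """
    p_rxn, p_dir = primary
    s_rxn, s_dir = secondary
    stage1 = solve_fba(model, p_rxn, p_dir, solver=solver)
    if not stage1.optimal:
        return stage1

    band = OPTIMALITY_TOL * max(1.0, abs(stage1.objective_value))
    pinned = model.copy()
    rxn = pinned.reactions[p_rxn]
    lo = stage1.objective_value - band
    hi = stage1.objective_value + band
    rxn.lower_bound = max(rxn.lower_bound, lo)
    rxn.upper_bound = min(rxn.upper_bound, hi)
    if rxn.lower_bound > rxn.upper_bound:  # band fell outside original box
        rxn.lower_bound, rxn.upper_bound = lo, hi

    stage2 = solve_fba(pinned, s_rxn, s_dir, solver=solver)
    stage2.extra["primary_reaction"] = p_rxn
    stage2.extra["primary_value"] = stage1.objective_value
    return stage2


def titration_scan(
    model: MetabolicModel,
    exchange_reaction: str,
    lower_bounds: list[float],
    objective: tuple[str, Direction],
    solver: str = "highs",
) -> TitrationCurve:
    """Optimal objective as a function of one exchange lower bound.

    The model passed in is never mutated; each point is solved on a copy with
    the exchange lower bound replaced.  Non-optimal points are recorded as NaN.
    """
    model.get_reaction(exchange_reaction)
    obj_rxn, obj_dir = objective
    values: list[float] = []
    work = model.copy()
    original = (
        work.reactions[exchange_reaction].lower_bound,
        work.reactions[exchange_reaction].upper_bound,
    )
    for lb in lower_bounds:
        work.reactions[exchange_reaction].lower_bound = float(lb)
        sol = solve_fba(work, obj_rxn, obj_dir, solver=solver)
        values.append(sol.objective_value if sol.optimal else math.nan)
    work.reactions[exchange_reaction].lower_bound = original[0]
    return TitrationCurve(exchange_reaction, [float(v) for v in lower_bounds], values)


def flux_variability(
    model: MetabolicModel,
    reaction_ids: list[str],
    objective: tuple[str, Direction] | None = None,
    fraction_of_optimum: float = 1.0,
    solver: str = "highs",
) -> dict[str, tuple[float, float]]:
    """Min/max flux of each listed reaction, optionally at a pinned optimum.

    With an objective, the objective flux is first constrained to
    ``fraction_of_optimum`` of its optimal value (plus the standard
    optimality band) before ranging the listed reactions.
    """
    work = model.copy()
    if objective is not None:
        obj_rxn, obj_dir = objective
        base = solve_fba(work, obj_rxn, obj_dir, solver=solver)
        if not base.optimal:
            raise SolverError(f"objective {obj_rxn} not optimal: {base.status}")
        opt = base.objective_value
        band = OPTIMALITY_TOL * max(1.0, abs(opt))
        rxn = work.reactions[obj_rxn]
        if obj_dir is Direction.MAXIMIZE:
            rxn.lower_bound = max(rxn.lower_bound, fraction_of_optimum * opt - band)
        else:
            rxn.upper_bound = min(rxn.upper_bound, fraction_of_optimum * opt + band)
    out: dict[str, tuple[float, float]] = {}
    for rid in reaction_ids:
        out[rid] = (min_flux(work, rid, solver=solver), max_flux(work, rid, solver=solver))
    return out


def check_solution(model: MetabolicModel, solution: FBASolution) -> bool:
    """Verify steady state (inf-norm <= 1e-6) and bounds (tol 1e-9)."""
    if not solution.optimal:
        return False
    S = build_stoichiometric_matrix(model)
    v = np.array([solution.fluxes[r] for r in model.reactions], dtype=float)
    lb, ub = model.bounds_vectors()
    if np.max(np.abs(S @ v)) > STEADY_STATE_TOL:
        return False
    if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
        return False
    return True
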