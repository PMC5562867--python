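"""LP/FBA solver layer, checked against an independent vertex oracle."""

import math

import numpy as np
import pytest

from enteroflux import (
    Direction,
    build_stoichiometric_matrix,
    flux_variability,
    lexicographic_optimize,
    max_flux,
    min_flux,
    solve_fba,
    titration_scan,
)
from enteroflux.fba import check_solution, solve_lp

from conftest import (
    assert_close,
    make_branch_model,
    make_chain_model,
    make_oxygen_model,
    vertex_optimum_for,
)


def test_chain_max_matches_hand_value(chain_model):
    sol = solve_fba(chain_model, "EX_b", Direction.MAXIMIZE)
    assert sol.optimal
    assert_close(sol.objective_value, 5.0)
    # entire chain carries the same flux
    for rid in ("T_a", "CONV", "T_b", "EX_b"):
        assert_close(sol.fluxes[rid], 5.0)
    assert_close(sol.fluxes["EX_a"], -5.0)


@pytest.mark.parametrize("maker,objective,direction", [
    (make_chain_model, "EX_b", Direction.MAXIMIZE),
    (make_chain_model, "EX_a", Direction.MINIMIZE),
    (make_branch_model, "EX_b", Direction.MAXIMIZE),
    (make_branch_model, "R1", Direction.MAXIMIZE),
    (make_branch_model, "R1", Direction.MINIMIZE),
    (make_oxygen_model, "EX_p", Direction.MAXIMIZE),
    (make_oxygen_model, "EX_o2", Direction.MINIMIZE),
])
def test_optimum_equals_vertex_oracle(maker, objective, direction):
    model = maker()
    sol = solve_fba(model, objective, direction)
    assert sol.optimal
    oracle = vertex_optimum_for(model, objective,
                                maximize=direction is Direction.MAXIMIZE)
    assert oracle is not None
    assert_close(sol.objective_value, oracle, tol=1e-8)


@pytest.mark.parametrize("maker,objective,direction", [
    (make_chain_model, "EX_b", Direction.MAXIMIZE),
    (make_branch_model, "EX_b", Direction.MAXIMIZE),
    (make_oxygen_model, "EX_p", Direction.MAXIMIZE),
])
def test_optimal_solution_satisfies_steady_state(maker, objective, direction):
    model = maker()
    sol = solve_fba(model, objective, direction)
    S = build_stoichiometric_matrix(model)
    v = np.array([sol.fluxes[r] for r in model.reactions])
    assert np.max(np.abs(S @ v)) <= 1e-6
    assert check_solution(model, sol)


def test_infeasible_status():
    model = make_chain_model()
    # force production with no possible supply
    model.reactions["EX_a"].lower_bound = 0.0
    model.reactions["EX_b"].lower_bound = 1.0
    sol = solve_fba(model, "EX_b", Direction.MAXIMIZE)
    assert not sol.optimal
    assert sol.status == "infeasible"


def test_unbounded_status():
    model = make_chain_model()
    model.reactions["EX_a"].lower_bound = -math.inf
    model.reactions["T_a"].upper_bound = math.inf
    model.reactions["CONV"].upper_bound = math.inf
    model.reactions["T_b"].upper_bound = math.inf
    model.reactions["EX_b"].upper_bound = math.inf
    sol = solve_fba(model, "EX_b", Direction.MAXIMIZE)
    assert not sol.optimal
    assert sol.status == "unbounded"


def test_max_and_min_flux_helpers(chain_model):
    assert_close(max_flux(chain_model, "EX_b"), 5.0)
    assert_close(min_flux(chain_model, "EX_a"), -5.0)
    assert_close(min_flux(chain_model, "EX_b"), 0.0)


def test_lexicographic_min_oxygen(oxygen_model):
    lex = lexicographic_optimize(
        oxygen_model,
        ("EX_p", Direction.MAXIMIZE),
        ("EX_o2", Direction.MAXIMIZE),
    )
    assert lex.optimal
    assert_close(lex.extra["primary_value"], 10.0)
    # 2 O2 per product unit: least uptake is 20, i.e. exchange flux -20
    assert_close(lex.objective_value, -20.0, tol=1e-6)


def test_lexicographic_preserves_primary(oxygen_model):
    lex = lexicographic_optimize(
        oxygen_model,
        ("EX_p", Direction.MAXIMIZE),
        ("EX_o2", Direction.MAXIMIZE),
    )
    assert_close(lex.fluxes["EX_p"], 10.0, tol=1e-6)


def test_titration_scan_linear_then_plateau(chain_model):
    # cap the internal conversion at 4 so the curve saturates there
    chain_model.reactions["CONV"].upper_bound = 4.0
    levels = [0.0, -1.0, -2.0, -5.0, -8.0]
    curve = titration_scan(chain_model, "EX_a", levels,
                           ("EX_b", Direction.MAXIMIZE))
    expected = [0.0, 1.0, 2.0, 4.0, 4.0]
    for got, want in zip(curve.objective_values, expected):
        assert_close(got, want, tol=1e-7)
    # scan must not mutate the input model
    assert chain_model.reactions["EX_a"].lower_bound == -5.0


def test_flux_variability_on_branch(branch_model):
    result = flux_variability(branch_model, ["R1", "R2"],
                              objective=("EX_b", Direction.MAXIMIZE))
    # total optimum is 10; each branch can carry between 4 and its cap 6
    for rid in ("R1", "R2"):
        lo, hi = result[rid]
        assert_close(lo, 4.0, tol=1e-6)
        assert_close(hi, 6.0, tol=1e-6)


def test_solve_lp_direct():
    import scipy.sparse as sp
    # minimize -z with x + y - z = 0, x <= 3, y <= 2: optimum z = 5
    S = sp.csr_matrix(np.array([[1.0, 1.0, -1.0]]))
    bounds = [(0.0, 3.0), (0.0, 2.0), (0.0, 10.0)]
    c = np.array([0.0, 0.0, -1.0])
    status, fun, x = solve_lp(c, S, bounds)
    assert status == "optimal"
    assert_close(-fun, 5.0)
    assert_close(float(x[2]), 5.0)


def test_every_micro_lp_matches_oracle_exhaustively():
    """All single-reaction max and min problems on every micro model."""
    for maker in (make_chain_model, make_branch_model, make_oxygen_model):
        model = maker()
        for rid in model.reactions:
            for direction in (Direction.MAXIMIZE, Direction.MINIMIZE):
                sol = solve_fba(model, rid, direction)
                assert sol.optimal, (maker.__name__, rid, direction)
                oracle = vertex_optimum_for(
                    model, rid, maximize=direction is Direction.MAXIMIZE)
                assert oracle is not None, (maker.__name__, rid)
                assert_close(sol.objective_value, oracle, tol=1e-8)
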