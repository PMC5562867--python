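"""Shared fixtures and an independent brute-force LP oracle.

The oracle enumerates basic feasible solutions (vertices) of the flux
polytope directly from the stoichiometric matrix and bounds, so it shares no
code with the solver under test.  It is exponential in the number of
reactions and is only used on micro models (<= 12 reactions, all bounds
finite).
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from enteroflux import (
    Compartment,
    CompartmentSide,
    MetabolicModel,
    Metabolite,
    Reaction,
    build_stoichiometric_matrix,
    build_toy_model,
    study_diets,
)


def vertex_optimum(S, lb, ub, c, maximize=True):
    """Optimal objective value of max/min c'v s.t. S v = 0, lb <= v <= ub,
    found by enumerating candidate vertices.

    A vertex of the polytope pins (n - rank(S)) variables at a bound; the
    rest solve the square-ish linear system.  Returns the best objective
    value over all consistent, feasible candidates, or None when no feasible
    vertex exists.
    """
    S = np.asarray(S.todense() if hasattr(S, "todense") else S, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    c = np.asarray(c, dtype=float)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if S.size else 0
    k = n - rank
    best = None
    for pinned in itertools.combinations(range(n), k):
        free = [i for i in range(n) if i not in pinned]
        A = S[:, free]
        for pattern in itertools.product((0, 1), repeat=k):
            vals = np.array([lb[i] if p == 0 else ub[i]
                             for i, p in zip(pinned, pattern)])
            if not np.all(np.isfinite(vals)):
                continue
            b = -S[:, list(pinned)] @ vals if k else np.zeros(m)
            if free:
                sol, *_ = np.linalg.lstsq(A, b, rcond=None)
            else:
                sol = np.zeros(0)
            v = np.zeros(n)
            v[list(pinned)] = vals
            v[free] = sol
            if np.max(np.abs(S @ v), initial=0.0) > 1e-7:
                continue
            if np.any(v < lb - 1e-9) or np.any(v > ub + 1e-9):
                continue
            val = float(c @ v)
            if best is None:
                best = val
            elif maximize:
                best = max(best, val)
            else:
                best = min(best, val)
    return best


def vertex_optimum_for(model, reaction_id, maximize=True):
    """Vertex-enumeration optimum of a single reaction's flux on a model."""
    S = build_stoichiometric_matrix(model)
    lb, ub = model.bounds_vectors()
    c = np.zeros(model.n_reactions)
    c[model.reaction_index()[reaction_id]] = 1.0
    return vertex_optimum(S, lb, ub, c, maximize=maximize)


def _compartments(model):
    model.add_compartment(
        Compartment("u", "lumen", CompartmentSide.APICAL_LUMEN))
    model.add_compartment(
        Compartment("c", "cytosol", CompartmentSide.INTRACELLULAR))
    model.add_compartment(
        Compartment("e", "extracellular",
                     CompartmentSide.BASOLATERAL_EXTRACELLULAR))


def make_chain_model():
    """EX_A (uptake <= 5) -> transport -> conversion -> EX_B.

    Max EX_B flux is 5 by construction (uptake-limited linear chain).
    """
    m = MetabolicModel("chain")
    _compartments(m)
    for mid, base, comp in [("a[u]", "a", "u"), ("a[c]", "a", "c"),
                            ("b[c]", "b", "c"), ("b[e]", "b", "e")]:
        m.add_metabolite(Metabolite(mid, base, comp))
    m.add_reactions([
        Reaction("EX_a", {"a[u]": -1.0}, -5.0, 0.0, is_exchange=True),
        Reaction("T_a", {"a[u]": -1.0, "a[c]": 1.0}, 0.0, 100.0),
        Reaction("CONV", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, 100.0),
        Reaction("T_b", {"b[c]": -1.0, "b[e]": 1.0}, 0.0, 100.0),
        Reaction("EX_b", {"b[e]": -1.0}, 0.0, 100.0, is_exchange=True),
    ])
    return m


def make_branch_model():
    """Two parallel routes a->b with different capacities (FVA exercise)."""
    m = MetabolicModel("branch")
    _compartments(m)
    for mid, base, comp in [("a[c]", "a", "c"), ("b[c]", "b", "c")]:
        m.add_metabolite(Metabolite(mid, base, comp))
    m.add_reactions([
        Reaction("EX_a", {"a[c]": -1.0}, -10.0, 0.0, is_exchange=True),
        Reaction("R1", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, 6.0),
        Reaction("R2", {"a[c]": -1.0, "b[c]": 1.0}, 0.0, 6.0),
        Reaction("EX_b", {"b[c]": -1.0}, 0.0, 100.0, is_exchange=True),
    ])
    return m


def make_oxygen_model():
    """Product formation requiring 2 O2 per unit (lexicographic exercise).

    Max EX_p = 10 (substrate-limited); at that optimum the least O2 uptake
    is exactly 20, i.e. max EX_o2 flux = -20.
    """
    m = MetabolicModel("oxy")
    _compartments(m)
    for mid, base, comp in [("s[c]", "s", "c"), ("o2[c]", "o2", "c"),
                            ("p[c]", "p", "c"), ("w[c]", "w", "c")]:
        m.add_metabolite(Metabolite(mid, base, comp))
    m.add_reactions([
        Reaction("EX_s", {"s[c]": -1.0}, -10.0, 0.0, is_exchange=True),
        Reaction("EX_o2", {"o2[c]": -1.0}, -100.0, 0.0, is_exchange=True),
        Reaction("OXID", {"s[c]": -1.0, "o2[c]": -2.0, "p[c]": 1.0,
                          "w[c]": 1.0}, 0.0, 100.0),
        Reaction("SPILL", {"o2[c]": -1.0, "w[c]": 1.0}, 0.0, 100.0),
        Reaction("EX_p", {"p[c]": -1.0}, 0.0, 100.0, is_exchange=True),
        Reaction("EX_w", {"w[c]": -1.0}, 0.0, 1000.0, is_exchange=True),
    ])
    return m


@pytest.fixture
def chain_model():
    return make_chain_model()


@pytest.fixture
def branch_model():
    return make_branch_model()


@pytest.fixture
def oxygen_model():
    return make_oxygen_model()


@pytest.fixture(scope="session")
def toy_model():
    return build_toy_model()


@pytest.fixture(scope="session")
def diets():
    return study_diets()


@pytest.fixture(scope="session")
def diet10(diets):
    return diets[0]


def assert_close(a, b, tol=1e-8):
    assert math.isfinite(a) and math.isfinite(b), (a, b)
    assert abs(a - b) <= tol, f"{a} != {b} (tol {tol})"
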