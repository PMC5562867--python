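"""Core data structures for compartmentalized constraint-based metabolic models.

A model is a set of metabolites distributed over compartments and a set of
reactions with stoichiometry, flux bounds and (optional) Boolean gene rules.
The stoichiometric matrix S (metabolites x reactions) is the central object:
steady-state flux vectors v satisfy S @ v = 0 with l <= v <= u.

Sign convention: negative stoichiometric coefficients denote consumption,
positive denote production.  Exchange reactions are written as single-
metabolite boundary reactions ``met <=> (nothing)`` so that uptake is a
negative flux and secretion a positive one.
"""

from __future__ import annotations

import copy
import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

#: COBRA-style default magnitude for unconstrained fluxes, mmol/gdw/h.
DEFAULT_BOUND = 1000.0

#: Compartment suffix tokens (human sIEC dialect): cytosol, nucleus,
#: mitochondrion, peroxisome, Golgi, ER, lumen/apical, extracellular/basolateral.
COMPARTMENT_SUFFIXES = ("c", "n", "m", "x", "g", "r", "u", "e")


class CompartmentSide(enum.Enum):
    INTRACELLULAR = "intracellular"
    APICAL_LUMEN = "apical_lumen"
    BASOLATERAL_EXTRACELLULAR = "basolateral_extracellular"


class Direction(enum.Enum):
    MAXIMIZE = "maximize"
    MINIMIZE = "minimize"


class ModelStructureError(ValueError):
    """Raised when a model violates a structural invariant."""


class UnknownReactionError(KeyError):
    """Raised when a reaction id does not resolve."""


@dataclass(frozen=True)
class Compartment:
    id: str
    name: str
    side: CompartmentSide


@dataclass(frozen=True)
class Metabolite:
    """A chemical species instantiated in one compartment.

    ``id`` is the compartment-qualified token (e.g. ``glc[c]``); ``base_id``
    is shared across compartments (``glc``).
    """

    id: str
    base_id: str
    compartment: str
    name: str = ""
    formula: str | None = None

    def carbon_count(self) -> int | None:
        """Number of carbon atoms from the elemental formula, if declared."""
        if not self.formula:
            return None
        m = re.search(r"C(\d*)(?![a-z])", self.formula)
        if not m:
            return 0
        return int(m.group(1)) if m.group(1) else 1


_GPR_TOKEN = re.compile(r"[A-Za-z0-9_.\-]+")


@dataclass(frozen=True)
class GeneRule:
    """Boolean AND/OR expression over gene tokens.

    The expression is stored as text; ``genes`` is derived from its leaves.
    An empty expression denotes an orphan or diffusion reaction.
    """

    expression: str = ""

    @property
    def genes(self) -> frozenset[str]:
        tokens = _GPR_TOKEN.findall(self.expression)
        return frozenset(t for t in tokens if t.lower() not in ("and", "or"))

    def is_empty(self) -> bool:
        return not self.expression.strip()


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: GeneRule = field(default_factory=GeneRule)
    subsystem: str = ""
    is_exchange: bool = False
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelStructureError(f"reaction {self.id!r} has empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            gene_rule=self.gene_rule,
            subsystem=self.subsystem,
            is_exchange=self.is_exchange,
            name=self.name,
            metadata=copy.deepcopy(self.metadata),
        )


@dataclass
class ValidationReport:
    dead_end_metabolites: list[str] = field(default_factory=list)
    blocked_reactions: list[str] = field(default_factory=list)
    bound_violations: list[str] = field(default_factory=list)

    @property
    def has_holes(self) -> bool:
        return bool(self.dead_end_metabolites or self.blocked_reactions)

    @property
    def ok(self) -> bool:
        return not self.has_holes and not self.bound_violations


class MetabolicModel:
    """Compartmentalized reaction network with a stoichiometric-matrix view.

    Metabolites, reactions and compartments are kept in insertion order so
    the matrix layout is deterministic.
    """

    def __init__(self, model_id: str = "model") -> None:
        self.id = model_id
        self.compartments: dict[str, Compartment] = {}
        self.metabolites: dict[str, Metabolite] = {}
        self.reactions: dict[str, Reaction] = {}
        self.objective: tuple[str, Direction] | None = None
        self.annotations: dict = {}

    # -- construction -----------------------------------------------------

    def add_compartment(self, comp: Compartment) -> None:
        if comp.id in self.compartments:
            raise ModelStructureError(f"duplicate compartment id {comp.id!r}")
        self.compartments[comp.id] = comp

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelStructureError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelStructureError(
                f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                f"upper bound {rxn.upper_bound}"
            )
        for met_id in rxn.stoichiometry:
            if met_id not in self.metabolites:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
        if rxn.is_exchange and len(rxn.stoichiometry) != 1:
            raise ModelStructureError(
                f"exchange reaction {rxn.id!r} must touch exactly one metabolite"
            )
        self.reactions[rxn.id] = rxn

    def add_reactions(self, rxns: Iterable[Reaction]) -> None:
        for r in rxns:
            self.add_reaction(r)

    def set_objective(self, reaction_id: str, direction: Direction) -> None:
        self.get_reaction(reaction_id)  # existence check
        self.objective = (reaction_id, direction)

    # -- access -----------------------------------------------------------

    def get_reaction(self, reaction_id: str) -> Reaction:
        try:
            return self.reactions[reaction_id]
        except KeyError:
            raise UnknownReactionError(f"unknown reaction id {reaction_id!r}") from None

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite_index(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.metabolites)}

    def reaction_index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.reactions)}

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.is_exchange]

    def copy(self) -> "MetabolicModel":
        new = MetabolicModel(self.id)
        new.compartments = dict(self.compartments)
        new.metabolites = dict(self.metabolites)
        new.reactions = {rid: r.copy() for rid, r in self.reactions.items()}
        new.objective = self.objective
        new.annotations = copy.deepcopy(self.annotations)
        return new

    def bounds_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions.values()], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions.values()], dtype=float)
        return lb, ub


# -- operations -----------------------------------------------------------


def build_stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """Assemble S (m x n): S[i, j] = coefficient of metabolite i in reaction j.

    Row order follows metabolite insertion order, column order reaction
    insertion order.
    """
    met_idx = model.metabolite_index()
    rows, cols, vals = [], [], []
    for j, rxn in enumerate(model.reactions.values()):
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in met_idx:
                raise ModelStructureError(
                    f"reaction {rxn.id!r} references unknown metabolite {met_id!r}"
                )
            rows.append(met_idx[met_id])
            cols.append(j)
            vals.append(float(coeff))
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(model.n_metabolites, model.n_reactions)
    )


def knock_out(model: MetabolicModel, reaction_id: str) -> MetabolicModel:
    """Return a copy of the model with both bounds of ``reaction_id`` set to 0.

    The input model is left untouched; repeated application is idempotent.
    """
    model.get_reaction(reaction_id)
    new = model.copy()
    rxn = new.reactions[reaction_id]
    rxn.lower_bound = 0.0
    rxn.upper_bound = 0.0
    return new


def validate_model(model: MetabolicModel, flux_tolerance: float = 1e-9) -> ValidationReport:
    """Structural and functional integrity report.

    Dead ends: metabolites only producible or only consumable given bounds
    (a reversible reaction counts as both).  Blocked reactions: reactions
    that cannot carry flux in either direction when every exchange reaction
    is opened to +/- DEFAULT_BOUND.  "No holes" means both lists are empty.
    """
    report = ValidationReport()
    for rxn in model.reactions.values():
        if rxn.lower_bound > rxn.upper_bound:
            report.bound_violations.append(
                f"{rxn.id}: lb {rxn.lower_bound} > ub {rxn.upper_bound}"
            )

    # Open a working copy: exchanges fully reversible so dietary context does
    # not mask structural gaps.
    open_model = model.copy()
    for rxn in open_model.reactions.values():
        if rxn.is_exchange:
            rxn.lower_bound = -DEFAULT_BOUND
            rxn.upper_bound = DEFAULT_BOUND

    producers: dict[str, int] = {m: 0 for m in open_model.metabolites}
    consumers: dict[str, int] = {m: 0 for m in open_model.metabolites}
    for rxn in open_model.reactions.values():
        fwd = rxn.upper_bound > 0
        rev = rxn.lower_bound < 0
        for met_id, coeff in rxn.stoichiometry.items():
            produced = (coeff > 0 and fwd) or (coeff < 0 and rev)
            consumed = (coeff < 0 and fwd) or (coeff > 0 and rev)
            if produced:
                producers[met_id] += 1
            if consumed:
                consumers[met_id] += 1
    for met_id in open_model.metabolites:
        if producers[met_id] == 0 or consumers[met_id] == 0:
            report.dead_end_metabolites.append(met_id)

    # Blocked-reaction scan by per-reaction flux maximization/minimization.
    from .fba import max_flux, min_flux  # local import to avoid cycle

    for rxn_id in open_model.reactions:
        hi = max_flux(open_model, rxn_id)
        lo = min_flux(open_model, rxn_id)
        span = max(abs(hi), abs(lo))
        if not np.isfinite(span) or span < max(flux_tolerance, 1e-9):
            report.blocked_reactions.append(rxn_id)
    return report


def reactions_from_matrix(
    matrix,
    metabolite_ids: list[str],
    reaction_ids: list[str],
) -> list[dict[str, float]]:
    """Inverse of :func:`build_stoichiometric_matrix` for stoichiometry only.

    Returns one ``{metabolite_id: coefficient}`` mapping per reaction column,
    in column order.
    """
    mat = sparse.csc_matrix(matrix)
    out: list[dict[str, float]] = []
    for j, _rid in enumerate(reaction_ids):
        col = mat.getcol(j).tocoo()
        out.append({metabolite_ids[i]: float(v) for i, v in zip(col.row, col.data)})
    return out


def carbon_balance(model_or_mets: Mapping[str, Metabolite] | MetabolicModel, rxn: Reaction) -> float | None:
    """Net carbon of a reaction (sum coeff * C-count); None if any formula missing."""
    mets = (
        model_or_mets.metabolites
        if isinstance(model_or_mets, MetabolicModel)
        else model_or_mets
    )
    total = 0.0
    for met_id, coeff in rxn.stoichiometry.items():
        c = mets[met_id].carbon_count()
        if c is None:
            return None
        total += coeff * c
    return total
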