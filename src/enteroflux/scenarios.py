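"""The four headline simulation experiments over a (model, diet) pair.

Each scenario applies the diet-derived exchange bounds, adjusts the
transporter/pathway settings it studies, runs the relevant optimizations and
returns a :class:`ScenarioResult` with full settings provenance.

Conventions: "apical absorption" of a hexose is the net luminal uptake,
i.e. minus the (minimized) flux of its luminal exchange reaction;
"basolateral secretion" is the maximized flux of the basolateral export
step.  Oxygen uptake is the magnitude of the (negative) basolateral O2
exchange flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .config import RunConfig
from .diet import BodyParameters, DietComposition, apply_bounds, diet_to_bounds
from .fba import (
    Direction,
    TitrationCurve,
    lexicographic_optimize,
    max_flux,
    min_flux,
    solve_fba,
    titration_scan,
)
from .lipids import chylomicron_fa_composition
from .model import MetabolicModel


class ScenarioConfigError(KeyError):
    """A transporter/pathway reaction id required by a scenario is missing."""


@dataclass
class ScenarioResult:
    diet_name: str
    scenario: str
    settings: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    curves: dict[str, TitrationCurve] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "diet_name": self.diet_name,
            "scenario": self.scenario,
            "settings": self.settings,
            "outputs": self.outputs,
        }
        if self.curves:
            out["curves"] = {
                k: {"parameter_values": c.parameter_values,
                    "objective_values": c.objective_values}
                for k, c in self.curves.items()
            }
        return out


def _require(model: MetabolicModel, *reaction_ids: str) -> None:
    missing = [r for r in reaction_ids if r not in model.reactions]
    if missing:
        raise ScenarioConfigError(
            f"model lacks required reaction id(s): {', '.join(missing)}"
        )


def _prepare(
    model: MetabolicModel,
    diet: DietComposition,
    config: RunConfig,
    apical_glut2: bool,
) -> MetabolicModel:
    """Diet-constrained working copy with apical GLUT2 toggled.

    Absence of apical GLUT2 is implemented by zeroing the reaction's bounds,
    not removing it, so reaction indices stay comparable across settings.
    """
    bound_set = diet_to_bounds(diet, config.body, config.nutrient_exchange_map)
    work = apply_bounds(model, bound_set, strict=False)
    glut2a = config.transporter_ids["GLUT2_apical"]
    if apical_glut2:
        _require(work, glut2a)
    elif glut2a in work.reactions:
        work.reactions[glut2a].lower_bound = 0.0
        work.reactions[glut2a].upper_bound = 0.0
    return work


def glucose_transport_scenario(
    model: MetabolicModel,
    diet: DietComposition,
    apical_glut2: bool,
    config: RunConfig | None = None,
) -> ScenarioResult:
    """Maximal apical absorption and basolateral secretion of glucose and
    fructose under one diet, with or without apically located GLUT2."""
    config = config or RunConfig()
    ids = config.transporter_ids
    work = _prepare(model, diet, config, apical_glut2)
    _require(work, ids["SGLT1"], ids["GLUT2_basolateral"], ids["GLUT5"],
             ids["EX_glucose"], ids["EX_fructose"])

    outputs = {
        "glucose_max_apical_absorption":
            -min_flux(work, ids["EX_glucose"], config.solver),
        "glucose_max_basolateral_secretion":
            max_flux(work, ids["GLUT2_basolateral"], config.solver),
        "fructose_max_apical_absorption":
            -min_flux(work, ids["EX_fructose"], config.solver),
        "fructose_max_basolateral_secretion":
            max_flux(work, ids["EX_fructose_baso"], config.solver),
    }
    return ScenarioResult(diet.name, "glucose_transport",
                          {"apical_glut2": apical_glut2}, outputs)


def sodium_titration_scenario(
    model: MetabolicModel,
    diet: DietComposition,
    apical_glut2: bool,
    na_levels: list[float],
    config: RunConfig | None = None,
) -> ScenarioResult:
    """Maximal glucose absorption as a function of luminal Na+ availability.

    ``na_levels`` are Na+ availabilities in mol per mouse per day (diet
    scale); they are converted to exchange lower bounds internally.  Also
    reports the minimal Na+ availability achieving >= 99.9% of the
    unconstrained-Na+ maximum, and its ratio to dietary Na+.
    """
    config = config or RunConfig()
    ids = config.transporter_ids
    work = _prepare(model, diet, config, apical_glut2)
    _require(work, ids["EX_Na"], ids["EX_glucose"])
    A = diet_to_bounds(diet, config.body, config.nutrient_exchange_map).conversion_factor

    objective = (ids["EX_glucose"], Direction.MINIMIZE)
    curve_raw = titration_scan(
        work, ids["EX_Na"], [-lvl * A for lvl in na_levels], objective,
        solver=config.solver,
    )
    curve = TitrationCurve("Na+ availability (mol/mouse/day)",
                           list(na_levels),
                           [-v for v in curve_raw.objective_values])

    # plateau value: absorption with unconstrained luminal Na+
    open_model = work.copy()
    open_model.reactions[ids["EX_Na"]].lower_bound = -1000.0
    plateau = -min_flux(open_model, ids["EX_glucose"], config.solver)

    required = _minimal_na_for_fraction(
        work, ids["EX_Na"], objective, plateau, 0.999, config.solver)
    dietary_na = diet.nutrient_intakes.get("na", 0.0)
    outputs = {
        "plateau_absorption": plateau,
        "required_na_mol_per_day": required / A if required is not None else math.nan,
        "dietary_na_mol_per_day": dietary_na,
        "required_to_dietary_na_ratio":
            (required / A) / dietary_na if required is not None and dietary_na > 0
            else math.nan,
    }
    return ScenarioResult(diet.name, "sodium_titration",
                          {"apical_glut2": apical_glut2}, outputs,
                          curves={"glucose_absorption_vs_na": curve})


def _minimal_na_for_fraction(model, ex_na, objective, plateau, fraction, solver,
                             iterations: int = 50) -> float | None:
    """Bisect the Na+ uptake bound for the smallest supply reaching
    ``fraction`` of the plateau absorption.  Returns a bound magnitude in
    model flux units, or 0.0 if no Na+ is needed at all."""
    if not (plateau > 0) or math.isnan(plateau):
        return None
    target = fraction * plateau

    def absorption(na_bound_mag: float) -> float:
        work = model.copy()
        work.reactions[ex_na].lower_bound = -na_bound_mag
        rxn, direction = objective
        sol = solve_fba(work, rxn, direction, solver=solver)
        return -sol.objective_value if sol.optimal else math.nan

    lo, hi = 0.0, 1000.0
    if absorption(lo) >= target:
        return 0.0
    for _ in range(iterations):
        mid = 0.5 * (lo + hi)
        if absorption(mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def gluconeogenesis_scenario(
    model: MetabolicModel,
    diet: DietComposition,
    apical_glut2: bool,
    config: RunConfig | None = None,
) -> ScenarioResult:
    """Gluconeogenic potential: secretion capacity beyond absorption capacity.

    The contributor report re-computes the surplus with each amino-acid
    uptake individually zeroed (exhaustive single-nutrient ablation).
    """
    config = config or RunConfig()
    ids = config.transporter_ids
    work = _prepare(model, diet, config, apical_glut2)
    _require(work, ids["EX_glucose"], ids["GLUT2_basolateral"])

    def surplus_of(m: MetabolicModel) -> tuple[float, float, float]:
        absorption = -min_flux(m, ids["EX_glucose"], config.solver)
        secretion = max_flux(m, ids["GLUT2_basolateral"], config.solver)
        return absorption, secretion, secretion - absorption

    absorption, secretion, surplus = surplus_of(work)

    contributors: dict[str, float] = {}
    for rxn in work.exchange_reactions():
        if rxn.metadata.get("nutrient_class") != "amino_acid":
            continue
        if rxn.lower_bound >= 0:
            continue
        ablated = work.copy()
        ablated.reactions[rxn.id].lower_bound = 0.0
        contributors[rxn.id] = surplus_of(ablated)[2]

    outputs = {
        "max_absorption": absorption,
        "max_secretion": secretion,
        "gluconeogenic_surplus": surplus,
        "surplus_without_nutrient": contributors,
    }
    return ScenarioResult(diet.name, "gluconeogenesis",
                          {"apical_glut2": apical_glut2}, outputs)


def chylomicron_oxygen_scenario(
    model: MetabolicModel,
    diet: DietComposition,
    cholesterol_source: str = "none",
    config: RunConfig | None = None,
    apical_glut2: bool = True,
) -> ScenarioResult:
    """Chylomicron secretion capacity and its oxygen requirement.

    ``cholesterol_source``:

    * ``"none"`` — no intracellular cholesterol supply: secretion is zero
      because cholesteryl esters cannot be formed;
    * ``"luminal"`` — the intracellular cholesterol source is opened,
      emulating absorption of (biliary) luminal cholesterol;
    * ``"biosynthesis"`` — endogenous cholesterol biosynthesis is enabled
      and the minimal basolateral O2 uptake sustaining maximal secretion is
      computed by two-stage (lexicographic) optimization.
    """
    if cholesterol_source not in ("none", "luminal", "biosynthesis"):
        raise ValueError(f"unknown cholesterol_source {cholesterol_source!r}")
    config = config or RunConfig()
    ids = config.transporter_ids
    work = _prepare(model, diet, config, apical_glut2)
    _require(work, ids["CHYLOMGE"], ids["EX_O2"],
             ids["cholesterol_synthesis"], ids["cholesterol_source"])

    chol_syn = work.reactions[ids["cholesterol_synthesis"]]
    chol_src = work.reactions[ids["cholesterol_source"]]
    if cholesterol_source == "biosynthesis":
        chol_src.lower_bound = chol_src.upper_bound = 0.0
    elif cholesterol_source == "luminal":
        chol_syn.lower_bound = chol_syn.upper_bound = 0.0
        chol_src.lower_bound, chol_src.upper_bound = -1000.0, 0.0
    else:
        chol_syn.lower_bound = chol_syn.upper_bound = 0.0
        chol_src.lower_bound = chol_src.upper_bound = 0.0

    outputs: dict = {}
    sol = solve_fba(work, ids["CHYLOMGE"], Direction.MAXIMIZE, config.solver)
    secretion = sol.objective_value if sol.optimal else 0.0
    outputs["max_chylomicron_secretion"] = secretion

    if secretion > 1e-9:
        try:
            profile = chylomicron_fa_composition(sol, work)
            outputs["chylomicron_fa_fractions"] = dict(profile.fa_fractions)
        except Exception:  # degenerate flux pattern: composition undefined
            outputs["chylomicron_fa_fractions"] = None

    if cholesterol_source == "biosynthesis":
        lex = lexicographic_optimize(
            work,
            (ids["CHYLOMGE"], Direction.MAXIMIZE),
            (ids["EX_O2"], Direction.MAXIMIZE),  # least-negative O2 exchange
            solver=config.solver,
        )
        if lex.optimal:
            min_o2_flux = max(0.0, -lex.objective_value)
            A = diet_to_bounds(diet, config.body,
                               config.nutrient_exchange_map).conversion_factor
            outputs["minimal_o2_flux"] = min_o2_flux
            outputs["minimal_o2_mol_per_day"] = min_o2_flux / A
        else:
            outputs["minimal_o2_flux"] = math.nan
            outputs["minimal_o2_mol_per_day"] = math.nan

    return ScenarioResult(
        diet.name, "chylomicron_oxygen",
        {"cholesterol_source": cholesterol_source, "apical_glut2": apical_glut2},
        outputs,
    )
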