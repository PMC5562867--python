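"""Single-reaction deletion screen, impact classification and dietary rescue.

For a chosen metabolic task (e.g. basolateral glucose secretion or
chylomicron secretion) every non-exchange reaction is knocked out in turn
and the task re-optimized.  Reactions are classified by impact:

* Type I   — deletion leaves the task essentially unaffected (<= 5% loss);
* Type II  — deletion blocks the task completely;
* Type III — deletion reduces the task by more than 5% without blocking it.

Type III impairments are candidates for dietary rescue: scaling a nutrient
class's uptake bounds over a grid and reporting the modification that best
restores the task.  Exchange reactions are excluded from the screen by
default (deleting a dietary input is a diet change, not an enzymopathy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .fba import Direction, solve_fba
from .model import MetabolicModel, knock_out

#: relative reduction above which an impairment counts as Type III
TYPE_III_THRESHOLD = 0.05
#: fraction of the baseline below which the task counts as fully blocked
BLOCKAGE_EPS = 1e-6


class BaselineError(RuntimeError):
    """The task carries no flux before screening."""


@dataclass
class KnockoutRecord:
    reaction_id: str
    baseline: float
    ko_value: float
    reduction_fraction: float
    ko_class: str  # "I" | "II" | "III"
    rescue: tuple[str, float] | None = None  # (modification, recovered_fraction)
    warning: str | None = None


def classify(baseline: float, ko_value: float,
             type_iii_threshold: float = TYPE_III_THRESHOLD,
             blockage_eps: float = BLOCKAGE_EPS) -> tuple[str, float]:
    """Three-way classification of a knockout outcome.

    Returns (class, reduction_fraction).  The reduction is clipped to [0, 1]
    (a deletion can only restrict the feasible set).  The >5% rule is strict:
    a reduction of exactly the threshold still counts as Type I.
    """
    if math.isnan(ko_value):
        ko_value = 0.0
    reduction = 1.0 - ko_value / baseline
    reduction = min(1.0, max(0.0, reduction))
    if ko_value < blockage_eps * baseline:
        return "II", reduction
    # small slack so a reduction of exactly the threshold (up to round-off
    # in ko_value/baseline) stays Type I, per the strict ">" rule
    if reduction > type_iii_threshold + 1e-9:
        return "III", reduction
    return "I", reduction


def screen_knockouts(
    model: MetabolicModel,
    task: tuple[str, Direction],
    diet_bounds=None,
    include_exchanges: bool = False,
    solver: str = "highs",
    type_iii_threshold: float = TYPE_III_THRESHOLD,
    blockage_eps: float = BLOCKAGE_EPS,
) -> list[KnockoutRecord]:
    """Knock out each (non-exchange) reaction and re-optimize the task.

    ``diet_bounds`` (an :class:`~enteroflux.diet.ExchangeBoundSet`) is applied
    first when given.  Records come back in model reaction order; the baseline
    is computed once.  Raises :class:`BaselineError` when the task is
    infeasible or carries zero flux before any deletion.
    """
    task_rxn, task_dir = task
    work = model
    if diet_bounds is not None:
        from .diet import apply_bounds

        work = apply_bounds(model, diet_bounds, strict=False)

    base_sol = solve_fba(work, task_rxn, task_dir, solver=solver)
    if not base_sol.optimal or abs(base_sol.objective_value) <= 1e-12:
        raise BaselineError(
            f"task {task_rxn} infeasible before screening "
            f"(status {base_sol.status}, value {base_sol.objective_value})"
        )
    baseline = base_sol.objective_value

    records: list[KnockoutRecord] = []
    for rxn in work.reactions.values():
        if rxn.is_exchange and not include_exchanges:
            continue
        ko_model = knock_out(work, rxn.id)
        ko_sol = solve_fba(ko_model, task_rxn, task_dir, solver=solver)
        ko_value = ko_sol.objective_value if ko_sol.optimal else 0.0
        ko_class, reduction = classify(baseline, ko_value,
                                       type_iii_threshold, blockage_eps)
        records.append(KnockoutRecord(rxn.id, baseline, ko_value,
                                      reduction, ko_class))
    return records


#: default rescue grid: each macronutrient-class uptake scaled up
DEFAULT_RESCUE_SCALES = (1.5, 2.0, 5.0, 10.0)
DEFAULT_RESCUE_CLASSES = ("lipid", "carbohydrate", "amino_acid", "mineral")


def dietary_rescue(
    model: MetabolicModel,
    record: KnockoutRecord,
    diet_bounds=None,
    modification_grid: list[tuple[str, float]] | None = None,
    solver: str = "highs",
    task: tuple[str, Direction] | None = None,
) -> KnockoutRecord:
    """Scan diet modifications for the best recovery of a Type III impairment.

    Each grid entry ``(nutrient_class, scale)`` multiplies the uptake bound
    (the negative lower bound) of every exchange reaction tagged with that
    nutrient class, re-applies the knockout and re-optimizes the task.  The
    record is updated in place with the best ``(modification, recovered
    fraction)``; the class is never changed.  Applied to a Type I/II record
    the scan is a no-op flagged through ``record.warning``.
    """
    if record.ko_class != "III":
        record.warning = f"rescue skipped: record is Type {record.ko_class}"
        return record
    if modification_grid is None:
        modification_grid = list(product(DEFAULT_RESCUE_CLASSES,
                                         DEFAULT_RESCUE_SCALES))
    if not modification_grid:
        return record
    if task is None:
        raise ValueError("dietary_rescue requires the task used for screening")

    work = model
    if diet_bounds is not None:
        from .diet import apply_bounds

        work = apply_bounds(model, diet_bounds, strict=False)

    task_rxn, task_dir = task
    best: tuple[str, float] | None = None
    for nutrient_class, scale in modification_grid:
        modified = work.copy()
        touched = False
        for rxn in modified.exchange_reactions():
            if rxn.metadata.get("nutrient_class") == nutrient_class and rxn.lower_bound < 0:
                rxn.lower_bound *= scale
                touched = True
        if not touched:
            continue
        ko_model = knock_out(modified, record.reaction_id)
        sol = solve_fba(ko_model, task_rxn, task_dir, solver=solver)
        value = sol.objective_value if sol.optimal else 0.0
        recovered = value / record.baseline
        label = f"{nutrient_class} uptake x{scale:g}"
        if best is None or recovered > best[1]:
            best = (label, recovered)
    if best is not None:
        record.rescue = best
    return record


def records_to_frame(records: list[KnockoutRecord]) -> pd.DataFrame:
    """Screen results as a tidy table (TSV-ready)."""
    rows = []
    for r in records:
        rows.append({
            "reaction_id": r.reaction_id,
            "baseline": r.baseline,
            "ko_value": r.ko_value,
            "reduction": r.reduction_fraction,
            "class": r.ko_class,
            "best_rescue": r.rescue[0] if r.rescue else "",
            "recovered_fraction": r.rescue[1] if r.rescue else math.nan,
        })
    return pd.DataFrame(rows)
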