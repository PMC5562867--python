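"""Conversion of diet composition and feed intake into exchange-flux bounds.

Nutrient intakes (mol per mouse per day) are rescaled to enterocyte-specific
fluxes (mmol per g dry weight per h) with the conversion factor

    A = 1000 mmol / (enterocyte dry mass [g] * 24 h)

where the enterocyte dry mass per mouse is

    small-intestine wet weight * (1 - water fraction) * enterocyte cell fraction
    = 1.094 g * 0.24 * 0.552 = 0.1449 g

giving A = 2.8749e2 with the default body parameters.  Uptake follows the
exchange-reaction sign convention: the (negative) uptake rate -intake * A is
set as the lower bound of the corresponding luminal exchange reaction; upper
bounds are left at the model default so that secretion back into the lumen
remains possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import MetabolicModel


class DietValidationError(ValueError):
    pass


class UnmappedNutrientError(KeyError):
    def __init__(self, nutrients: list[str]):
        self.nutrients = list(nutrients)
        super().__init__(
            "nutrients without an exchange-reaction mapping: "
            + ", ".join(sorted(self.nutrients))
        )


@dataclass
class DietComposition:
    """Per-day nutrient intakes of one diet.

    ``nutrient_intakes`` are in mol per mouse per day; ``energy_fractions``
    records the macronutrient kcal split (fat/carbohydrate/protein).
    """

    name: str
    nutrient_intakes: dict[str, float]
    energy_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for nutrient, intake in self.nutrient_intakes.items():
            if intake < 0:
                raise DietValidationError(
                    f"{self.name}: negative intake for {nutrient!r}"
                )
        if self.energy_fractions:
            total = sum(self.energy_fractions.values())
            if abs(total - 1.0) > 0.01:
                raise DietValidationError(
                    f"{self.name}: energy fractions sum to {total:.4f}, not 1"
                )

    def scaled(self, factor: float) -> "DietComposition":
        return DietComposition(
            self.name,
            {n: v * factor for n, v in self.nutrient_intakes.items()},
            dict(self.energy_fractions),
        )


@dataclass(frozen=True)
class BodyParameters:
    """Anatomical constants for the flux normalization.

    Defaults: mouse small-intestine wet weight 1.094 g, 76% water,
    enterocytes 55.2% of small-intestinal cells, 24 h per day.
    """

    si_wet_weight: float = 1.094
    water_fraction: float = 0.76
    enterocyte_cell_fraction: float = 0.552
    hours_per_day: float = 24.0

    def __post_init__(self) -> None:
        for attr in ("water_fraction", "enterocyte_cell_fraction"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise DietValidationError(f"{attr} = {v} outside [0, 1]")
        if self.si_wet_weight <= 0 or self.hours_per_day <= 0:
            raise DietValidationError("wet weight and hours must be positive")


@dataclass
class ExchangeBoundSet:
    """Exchange-reaction bounds derived from one diet, plus provenance."""

    bounds: dict[str, tuple[float, float | None]]
    conversion_factor: float
    diet_name: str = ""
    unmodeled_nutrients: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.bounds)


def enterocyte_dry_mass(p: BodyParameters = BodyParameters()) -> float:
    """Enterocyte dry mass per mouse in grams."""
    return p.si_wet_weight * (1.0 - p.water_fraction) * p.enterocyte_cell_fraction


def conversion_factor(dry_mass: float, hours: float = 24.0) -> float:
    """A = 1000 / (dry_mass * hours): (mmol/gdw/h) per (mol/mouse/day)."""
    if dry_mass <= 0 or hours <= 0:
        raise DietValidationError("dry mass and hours must be positive")
    return 1000.0 / (dry_mass * hours)


def diet_to_bounds(
    diet: DietComposition,
    p: BodyParameters = BodyParameters(),
    nutrient_exchange_map: dict[str, str | None] | None = None,
) -> ExchangeBoundSet:
    """Map nutrient intakes to luminal exchange lower bounds.

    ``nutrient_exchange_map`` maps nutrient tokens to exchange-reaction ids;
    an explicit ``None`` value marks a nutrient known to be absent from the
    model (it is reported, not silently dropped).  A nutrient missing from
    the map entirely raises :class:`UnmappedNutrientError`.
    """
    if nutrient_exchange_map is None:
        from .synthetic import default_nutrient_exchange_map

        nutrient_exchange_map = default_nutrient_exchange_map()

    missing = [n for n in diet.nutrient_intakes if n not in nutrient_exchange_map]
    if missing:
        raise UnmappedNutrientError(missing)

    A = conversion_factor(enterocyte_dry_mass(p), p.hours_per_day)
    bounds: dict[str, tuple[float, float | None]] = {}
    unmodeled: list[str] = []
    for nutrient, intake in diet.nutrient_intakes.items():
        exchange_id = nutrient_exchange_map[nutrient]
        if exchange_id is None:
            unmodeled.append(nutrient)
            continue
        # upper bound None = leave at the model default (secretion permitted)
        bounds[exchange_id] = (-intake * A, None)
    return ExchangeBoundSet(bounds, A, diet.name, unmodeled)


def apply_bounds(
    model: MetabolicModel,
    bound_set: ExchangeBoundSet,
    strict: bool = True,
) -> MetabolicModel:
    """Return a model copy with the exchange bounds applied.

    With ``strict`` (default) every bounded exchange id must exist in the
    model; otherwise missing ids are skipped (toy models carry only a subset
    of the full exchange complement).
    """
    new = model.copy()
    for rxn_id, (lb, ub) in bound_set.bounds.items():
        if rxn_id not in new.reactions:
            if strict:
                raise KeyError(f"exchange reaction {rxn_id!r} not in model")
            continue
        rxn = new.reactions[rxn_id]
        rxn.lower_bound = lb
        if ub is not None:
            rxn.upper_bound = ub
    new.annotations["diet"] = bound_set.diet_name
    return new


def intakes_from_grams(
    grams_per_day: dict[str, float], molar_masses: dict[str, float]
) -> dict[str, float]:
    """Helper for the g/day input path: grams -> mol per mouse per day."""
    out = {}
    for nutrient, g in grams_per_day.items():
        if nutrient not in molar_masses:
            raise DietValidationError(f"no molar mass for nutrient {nutrient!r}")
        out[nutrient] = g / molar_masses[nutrient]
    return out


# -- CSV interface (Diet Composition layout) ------------------------------


def read_diet_csv(path, name: str | None = None) -> DietComposition:
    """Read a diet table with columns nutrient, intake_mol_per_mouse_per_day."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    if "nutrient" not in cols or "intake_mol_per_mouse_per_day" not in cols:
        raise DietValidationError(
            f"{path}: expected columns 'nutrient' and "
            "'intake_mol_per_mouse_per_day'"
        )
    intakes = dict(
        zip(df[cols["nutrient"]].astype(str),
            df[cols["intake_mol_per_mouse_per_day"]].astype(float))
    )
    import os

    return DietComposition(name or os.path.splitext(os.path.basename(str(path)))[0],
                           intakes)


def write_diet_csv(diet: DietComposition, path) -> None:
    df = pd.DataFrame(
        {"nutrient": list(diet.nutrient_intakes),
         "intake_mol_per_mouse_per_day": list(diet.nutrient_intakes.values())}
    )
    df.to_csv(path, index=False)
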