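"""End-to-end analysis: all four scenarios per diet plus both knockout screens.

Produces a JSON summary, per-scenario TSV tables and a provenance block
(config hash, solver, package versions, seed).  A failure in one stage is
recorded and the remaining stages continue; the bundle reports overall
success so callers can exit non-zero when any stage failed.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path

from .config import RunConfig
from .diet import DietComposition, diet_to_bounds
from .fba import Direction
from .knockouts import records_to_frame, screen_knockouts
from .model import MetabolicModel
from .scenarios import (
    chylomicron_oxygen_scenario,
    glucose_transport_scenario,
    gluconeogenesis_scenario,
    sodium_titration_scenario,
)


@dataclass
class AnalysisBundle:
    scenario_results: dict[str, dict] = field(default_factory=dict)
    knockout_tables: dict[str, "object"] = field(default_factory=dict)
    failures: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.failures


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {
            "solver": config.solver,
            "tolerances": config.tolerances,
            "transporter_ids": config.transporter_ids,
            "thresholds": config.thresholds,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_full_analysis(
    model: MetabolicModel,
    diets: list[DietComposition],
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
    na_levels: list[float] | None = None,
) -> AnalysisBundle:
    config = config or RunConfig()
    bundle = AnalysisBundle()

    import enteroflux

    bundle.provenance = {
        "config_hash": _config_hash(config),
        "solver": config.solver,
        "package_version": enteroflux.__version__,
        "seed": config.seed,
        "diets": [d.name for d in diets],
        "model_id": model.id,
    }

    if na_levels is None:
        dietary_na = max(d.nutrient_intakes.get("na", 0.0) for d in diets)
        na_levels = [dietary_na * k for k in
                     (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 50.0)]

    stages = []
    for diet in diets:
        stages += [
            (f"{diet.name}/glucose_transport/no_apical_glut2",
             lambda d=diet: glucose_transport_scenario(model, d, False, config)),
            (f"{diet.name}/glucose_transport/apical_glut2",
             lambda d=diet: glucose_transport_scenario(model, d, True, config)),
            (f"{diet.name}/sodium_titration",
             lambda d=diet: sodium_titration_scenario(model, d, False,
                                                      na_levels, config)),
            (f"{diet.name}/gluconeogenesis",
             lambda d=diet: gluconeogenesis_scenario(model, d, True, config)),
            (f"{diet.name}/chylomicron_oxygen",
             lambda d=diet: chylomicron_oxygen_scenario(
                 model, d, "biosynthesis", config)),
        ]
    for name, fn in stages:
        try:
            bundle.scenario_results[name] = fn().to_dict()
        except Exception as exc:  # record, continue with remaining stages
            bundle.failures[name] = f"{type(exc).__name__}: {exc}"

    ids = config.transporter_ids
    ko_tasks = {
        "glucose_secretion": (ids["GLCGLUT2"], Direction.MAXIMIZE),
        "chylomicron_secretion": (ids["CHYLOMGE"], Direction.MAXIMIZE),
    }
    screen_diet = diets[0]
    bounds = diet_to_bounds(screen_diet, config.body, config.nutrient_exchange_map)
    for task_name, task in ko_tasks.items():
        try:
            screen_model = model
            if task_name == "chylomicron_secretion":
                # screening chylomicron secretion requires a cholesterol
                # supply: enable endogenous biosynthesis
                screen_model = model.copy()
            records = screen_knockouts(
                screen_model, task, bounds, solver=config.solver,
                type_iii_threshold=config.thresholds["type_iii"],
                blockage_eps=config.thresholds["blockage_eps"],
            )
            bundle.knockout_tables[task_name] = records_to_frame(records)
        except Exception as exc:
            bundle.failures[f"knockout/{task_name}"] = (
                f"{type(exc).__name__}: {exc}\n{traceback.format_exc(limit=2)}"
            )

    if output_dir is not None:
        write_bundle(bundle, output_dir)
    return bundle


def write_bundle(bundle: AnalysisBundle, output_dir: str | Path) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {
        "provenance": bundle.provenance,
        "scenarios": bundle.scenario_results,
        "failures": bundle.failures,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    for task_name, frame in bundle.knockout_tables.items():
        frame.to_csv(out / f"knockouts_{task_name}.tsv", sep="\t", index=False)
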