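"""Run configuration: solver choice, tolerances, reaction-id roles, thresholds.

Defaults match the bundled synthetic enterocyte model; for another model
(e.g. a full genome-scale reconstruction) the transporter ids and the
nutrient-to-exchange mapping are overridden from a YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .diet import BodyParameters


def default_transporter_ids() -> dict[str, str]:
    return {
        "SGLT1": "SGLT1",
        "GLUT2_apical": "GLUT2A",
        "GLUT2_basolateral": "GLCGLUT2",
        "GLCGLUT2": "GLCGLUT2",
        "GLUT5": "GLUT5A",
        "CHYLOMGE": "CHYLOMGE",
        "EX_Na": "EX_na_u",
        "EX_O2": "EX_o2_e",
        "EX_glucose": "EX_glc_u",
        "EX_fructose": "EX_fru_u",
        "EX_fructose_baso": "EX_fru_e",
        "cholesterol_synthesis": "CHOLSYN",
        "cholesterol_source": "EX_chol_src",
    }


@dataclass
class RunConfig:
    solver: str = "highs"
    tolerances: dict[str, float] = field(
        default_factory=lambda: {
            "feasibility": 1e-9, "steady_state": 1e-6, "optimality": 1e-8,
        }
    )
    transporter_ids: dict[str, str] = field(default_factory=default_transporter_ids)
    nutrient_exchange_map: dict[str, str | None] | None = None  # None = default
    thresholds: dict[str, float] = field(
        default_factory=lambda: {"type_iii": 0.05, "blockage_eps": 1e-6}
    )
    body: BodyParameters = field(default_factory=BodyParameters)
    output_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        for key, value in self.thresholds.items():
            if not 0 < value < 1:
                raise ValueError(f"threshold {key!r} = {value} outside (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "solver" in raw:
            cfg.solver = raw["solver"]
        if "tolerances" in raw:
            cfg.tolerances.update(raw["tolerances"])
        if "transporter_ids" in raw:
            cfg.transporter_ids.update(raw["transporter_ids"])
        if "nutrient_exchange_map" in raw:
            cfg.nutrient_exchange_map = raw["nutrient_exchange_map"]
        if "thresholds" in raw:
            cfg.thresholds.update(raw["thresholds"])
            cfg.__post_init__()
        if "body" in raw:
            cfg.body = BodyParameters(**raw["body"])
        if "output_dir" in raw:
            cfg.output_dir = raw["output_dir"]
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "solver": self.solver,
            "tolerances": self.tolerances,
            "transporter_ids": self.transporter_ids,
            "nutrient_exchange_map": self.nutrient_exchange_map,
            "thresholds": self.thresholds,
            "body": {
                "si_wet_weight": self.body.si_wet_weight,
                "water_fraction": self.body.water_fraction,
                "enterocyte_cell_fraction": self.body.enterocyte_cell_fraction,
                "hours_per_day": self.body.hours_per_day,
            },
            "output_dir": self.output_dir,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
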