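"""Generator for a miniature enterocyte model and four study-like diets.

The toy model reproduces, at auditable scale, the transport and pathway
topology of enterocyte carbohydrate and lipid handling: apical SGLT1
(Na+-coupled, configurable stoichiometry), apical and basolateral GLUT2,
GLUT5, the basolateral Na+/K+-ATPase, lumped glycolysis and mitochondrial
oxidation with a declared P:O yield, a switchable glutamine-fed
gluconeogenesis lump, the full species-resolved lipid ladder from
:mod:`enteroflux.lipids`, cholesterol biosynthesis with a declared ATP cost,
and chylomicron assembly/secretion.  Every optimum is computable by hand
from the declared stoichiometric constants.

Deliberate lumping choices (documented in the methods note): glycolysis is
written without net ATP so that all ATP synthesis is oxygen-coupled through
the respiratory lump — this keeps the oxygen accounting of chylomicron
secretion a closed-form function of the ATP demand; phospholipid and
apolipoprotein supplies are generic demands, not acyl- or residue-resolved.

The diet generator emulates the four semi-purified study diets: 10/20/30/45
energy% fat, fixed 20 en% protein, carbohydrate as the balance, six fatty
acid species from a palm/soy oil blend in which the soy contribution stays
constant while palm oil displaces starch, and no cholesterol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .diet import DietComposition
from .lipids import (
    ChylomicronProfile,
    DEFAULT_COMPONENT_MASS_FRACTIONS,
    FattyAcidSpecies,
    assembly_metabolites,
    build_chylomicron_assembly,
    dietary_fa_species,
    generate_lipid_reactions,
)
from .model import (
    Compartment,
    CompartmentSide,
    GeneRule,
    MetabolicModel,
    Metabolite,
    Reaction,
)


class ToySpecError(ValueError):
    pass


# ======================================================================
# toy model
# ======================================================================


@dataclass
class ToyModelSpec:
    include_apical_glut2: bool = True
    na_glucose_stoichiometry: float = 2.0  # SGLT1 Na+ : glucose
    include_gluconeogenesis: bool = True
    fa_species: list[FattyAcidSpecies] = field(default_factory=dietary_fa_species)
    atp_per_cholesterol: float = 36.0  # ATP per cholesterol synthesized
    p_to_o_yield: float = 2.5  # ATP per O atom reduced
    na_per_atp: float = 3.0  # Na+/K+-ATPase: Na+ pumped per ATP
    acetyl_per_cholesterol: float = 18.0
    component_mass_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_MASS_FRACTIONS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.na_glucose_stoichiometry <= 0:
            raise ToySpecError("na_glucose_stoichiometry must be positive")
        if self.atp_per_cholesterol <= 0 or self.p_to_o_yield <= 0:
            raise ToySpecError("ATP cost and P:O yield must be positive")
        if self.component_mass_fractions and not self.fa_species:
            raise ToySpecError("chylomicron assembly requires fa_species")


_CORE_METS = [
    # (base, compartment, formula)
    ("glc", "u", "C6H12O6"), ("glc", "c", "C6H12O6"), ("glc", "e", "C6H12O6"),
    ("fru", "u", "C6H12O6"), ("fru", "c", "C6H12O6"), ("fru", "e", "C6H12O6"),
    ("na", "u", "Na"), ("na", "c", "Na"), ("na", "e", "Na"),
    ("pyr", "c", "C3H4O3"), ("pyr", "m", "C3H4O3"),
    ("lac", "c", "C3H6O3"), ("lac", "e", "C3H6O3"),
    ("nadh", "m", None),
    ("accoa", "c", "C23H38N7O17P3S"),
    ("o2", "e", "O2"), ("o2", "c", "O2"),
    ("co2", "c", "CO2"), ("co2", "e", "CO2"),
    ("gln", "u", "C5H10N2O3"), ("gln", "c", "C5H10N2O3"),
    ("nh4", "c", "H4N"), ("nh4", "e", "H4N"),
    ("chylo", "e", None),
]


def _exchange(rid: str, met_id: str, lb: float, ub: float,
              nutrient_class: str | None = None) -> Reaction:
    r = Reaction(rid, {met_id: -1.0}, lb, ub, is_exchange=True,
                 subsystem="exchange")
    if nutrient_class:
        r.metadata["nutrient_class"] = nutrient_class
    return r


def build_toy_model(spec: ToyModelSpec | None = None) -> MetabolicModel:
    """Build the miniature enterocyte model described in the module docstring."""
    spec = spec or ToyModelSpec()
    if not spec.fa_species:
        raise ToySpecError("fa_species must be non-empty")

    model = MetabolicModel("toy_enterocyte")
    for cid, name, side in [
        ("u", "intestinal lumen (apical)", CompartmentSide.APICAL_LUMEN),
        ("c", "cytosol", CompartmentSide.INTRACELLULAR),
        ("m", "mitochondrion", CompartmentSide.INTRACELLULAR),
        ("r", "endoplasmic reticulum", CompartmentSide.INTRACELLULAR),
        ("e", "extracellular (basolateral)", CompartmentSide.BASOLATERAL_EXTRACELLULAR),
    ]:
        model.add_compartment(Compartment(cid, name, side))

    # lipid pathway (species-resolved) supplies the lipid metabolites and
    # the ATP/CoA/cholesterol cofactor pool
    lipid_set = generate_lipid_reactions(spec.fa_species)
    for met in lipid_set.metabolites:
        if met.id not in model.metabolites:
            model.add_metabolite(met)
    for base, comp, formula in _CORE_METS:
        # ammonium only appears with the gluconeogenesis lump (its sole
        # producer); keeping it otherwise would leave a dead-end metabolite
        if base == "nh4" and not spec.include_gluconeogenesis:
            continue
        mid = f"{base}[{comp}]"
        if mid not in model.metabolites:
            model.add_metabolite(Metabolite(mid, base, comp, base, formula))
    for met in assembly_metabolites():
        if met.id not in model.metabolites:
            model.add_metabolite(met)

    model.add_reactions(lipid_set.reactions)

    # one single-species assembly per FA species: chylomicron composition is
    # then an FBA outcome (a mixture of particles), not a baked-in constant
    for sp in spec.fa_species:
        profile = ChylomicronProfile({sp.code: 1.0},
                                     dict(spec.component_mass_fractions))
        model.add_reaction(
            build_chylomicron_assembly(profile, reaction_id=f"CHYLOASM_{sp.token}")
        )

    s = spec.na_glucose_stoichiometry
    p2o = spec.p_to_o_yield
    core: list[Reaction] = [
        Reaction("SGLT1",
                 {"glc[u]": -1, f"na[u]": -s, "glc[c]": 1, "na[c]": s},
                 0, 1000, GeneRule("Slc5a1"), "carbohydrate transport",
                 name="Na+-coupled apical glucose transport"),
        Reaction("GLCGLUT2", {"glc[c]": -1, "glc[e]": 1}, -1000, 1000,
                 GeneRule("Slc2a2"), "carbohydrate transport",
                 name="GLUT2-mediated basolateral glucose export"),
        Reaction("GLUT5A", {"fru[u]": -1, "fru[c]": 1}, -1000, 1000,
                 GeneRule("Slc2a5"), "carbohydrate transport"),
        Reaction("GLUT5B", {"fru[c]": -1, "fru[e]": 1}, -1000, 1000,
                 GeneRule("Slc2a5"), "carbohydrate transport"),
        Reaction("NAKATPASE",
                 {"na[c]": -spec.na_per_atp, "atp[c]": -1,
                  "na[e]": spec.na_per_atp, "adp[c]": 1, "pi[c]": 1},
                 0, 1000, GeneRule("Atp1a1"), "ion homeostasis",
                 name="basolateral Na+/K+-ATPase"),
        # glycolysis lump written ATP-neutral: all net ATP synthesis is
        # routed through the oxygen-coupled respiratory lump below
        Reaction("GLYC", {"glc[c]": -1, "pyr[c]": 2}, 0, 1000,
                 GeneRule("Gck and Pfkl and Pklr"), "glycolysis"),
        Reaction("LDH", {"pyr[c]": -1, "lac[c]": 1}, 0, 1000,
                 GeneRule("Ldha"), "fermentation"),
        Reaction("LACT", {"lac[c]": -1, "lac[e]": 1}, 0, 1000,
                 GeneRule("Slc16a1"), "transport"),
        Reaction("PYRT", {"pyr[c]": -1, "pyr[m]": 1}, 0, 1000,
                 GeneRule("Mpc1 and Mpc2"), "mitochondrial transport",
                 name="mitochondrial pyruvate carrier"),
        Reaction("TCAOX", {"pyr[m]": -1, "co2[c]": 3, "nadh[m]": 5}, 0, 1000,
                 GeneRule("Pdha1 and Cs"), "TCA cycle (lumped)"),
        Reaction("RESP",
                 {"nadh[m]": -1, "o2[c]": -0.5,
                  "adp[c]": -p2o, "pi[c]": -p2o, "atp[c]": p2o},
                 0, 1000, GeneRule("mt-Nd1 and mt-Co1 and Atp5a1"),
                 "oxidative phosphorylation (lumped)",
                 name=f"respiratory chain, P:O = {p2o}"),
        Reaction("O2T", {"o2[e]": -1, "o2[c]": 1}, 0, 1000,
                 subsystem="gas diffusion"),
        Reaction("CO2T", {"co2[c]": -1, "co2[e]": 1}, 0, 1000,
                 subsystem="gas diffusion"),
        Reaction("GLNUP", {"gln[u]": -1, "gln[c]": 1}, 0, 1000,
                 GeneRule("Slc1a5"), "amino acid transport"),
        # citrate shuttle + ATP-citrate lyase lump: cytosolic acetyl-CoA
        Reaction("ACL",
                 {"pyr[m]": -1, "coa[c]": -1, "atp[c]": -1,
                  "accoa[c]": 1, "co2[c]": 1, "adp[c]": 1, "pi[c]": 1,
                  "nadh[m]": 1},
                 0, 1000, GeneRule("Acly"), "lipogenic precursor supply"),
        Reaction("CHOLSYN",
                 {"accoa[c]": -spec.acetyl_per_cholesterol,
                  "atp[c]": -spec.atp_per_cholesterol,
                  "chol[r]": 1,
                  "coa[c]": spec.acetyl_per_cholesterol,
                  "co2[c]": 9.0,
                  "adp[c]": spec.atp_per_cholesterol,
                  "pi[c]": spec.atp_per_cholesterol},
                 0, 1000, GeneRule("Hmgcr and Sqle and Dhcr7"),
                 "cholesterol biosynthesis (lumped)",
                 name=f"cholesterol biosynthesis, {spec.atp_per_cholesterol} ATP"),
        Reaction("PLSYN", {"glc[c]": -1, "atp[c]": -1,
                           "pl[r]": 1, "adp[c]": 1, "pi[c]": 1},
                 0, 1000, GeneRule("Chka and Pcyt1a"),
                 "phospholipid supply (lumped)"),
        Reaction("APOBSYN", {"gln[c]": -4, "atp[c]": -4,
                             "apob[r]": 1, "adp[c]": 4, "pi[c]": 4},
                 0, 1000, GeneRule("Apob"),
                 "apolipoprotein B-48 supply (lumped)"),
        Reaction("COAR", {"coa[r]": -1, "coa[c]": 1}, 0, 1000,
                 subsystem="cofactor recycling"),
        Reaction("CHYLOSEC", {"chylo[r]": -1, "chylo[e]": 1}, 0, 1000,
                 GeneRule("Sar1b"), "chylomicron secretion",
                 name="chylomicron exocytosis (basolateral)"),
    ]
    if spec.include_apical_glut2:
        core.append(
            Reaction("GLUT2A", {"glc[u]": -1, "glc[c]": 1}, -1000, 1000,
                     GeneRule("Slc2a2"), "carbohydrate transport",
                     name="apical GLUT2 (facilitated glucose uptake)")
        )
    if spec.include_gluconeogenesis:
        core += [
            Reaction("GNG",
                     {"gln[c]": -2, "glc[c]": 1, "co2[c]": 4, "nh4[c]": 4},
                     0, 1000, GeneRule("Pck1 and G6pc"),
                     "gluconeogenesis (lumped)",
                     name="gluconeogenesis from glutamine"),
            Reaction("NH4T", {"nh4[c]": -1, "nh4[e]": 1}, 0, 1000,
                     subsystem="transport"),
        ]
    model.add_reactions(core)

    # exchanges: luminal nutrient uptakes (diet sets lower bounds),
    # basolateral products, basolateral O2 uptake, cholesterol sink/source
    exchanges = [
        _exchange("EX_glc_u", "glc[u]", 0, 1000, "carbohydrate"),
        _exchange("EX_fru_u", "fru[u]", 0, 1000, "carbohydrate"),
        _exchange("EX_na_u", "na[u]", 0, 1000, "mineral"),
        _exchange("EX_gln_u", "gln[u]", 0, 1000, "amino_acid"),
        _exchange("EX_glc_e", "glc[e]", 0, 1000),
        _exchange("EX_fru_e", "fru[e]", 0, 1000),
        _exchange("EX_na_e", "na[e]", 0, 1000),
        _exchange("EX_lac_e", "lac[e]", 0, 1000),
        *([_exchange("EX_nh4_e", "nh4[e]", 0, 1000)]
          if spec.include_gluconeogenesis else []),
        _exchange("EX_co2_e", "co2[e]", 0, 1000),
        _exchange("EX_o2_e", "o2[e]", -1000, 0),
        _exchange("CHYLOMGE", "chylo[e]", 0, 1000),
        # intracellular cholesterol source, closed by default; opening it
        # emulates luminal absorption of biliary cholesterol
        _exchange("EX_chol_src", "chol[r]", 0, 0),
    ]
    for sp in spec.fa_species:
        t = sp.token
        exchanges += [
            _exchange(f"EX_tag_{t}_u", f"tag_{t}[u]", 0, 1000, "lipid"),
            _exchange(f"EX_ffa_{t}_u", f"ffa_{t}[u]", 0, 1000, "lipid"),
            _exchange(f"EX_mag_{t}_u", f"mag_{t}[u]", 0, 1000, "lipid"),
        ]
    model.add_reactions(exchanges)

    model.annotations["toy_spec"] = {
        "include_apical_glut2": spec.include_apical_glut2,
        "na_glucose_stoichiometry": s,
        "include_gluconeogenesis": spec.include_gluconeogenesis,
        "fa_species": [sp.code for sp in spec.fa_species],
        "atp_per_cholesterol": spec.atp_per_cholesterol,
        "p_to_o_yield": p2o,
        "na_per_atp": spec.na_per_atp,
        "acetyl_per_cholesterol": spec.acetyl_per_cholesterol,
    }
    return model


# ======================================================================
# synthetic diets
# ======================================================================

#: energy densities, kcal per gram (standard nutrition constants)
KCAL_PER_G = {"carbohydrate": 4.0, "protein": 4.0, "fat": 9.0}

#: fraction of total kcal supplied as sucrose, identical across diets
SUCROSE_KCAL_FRACTION = 0.10

#: soy oil supplies half of the fat in the 10 en% diet and stays constant
#: in absolute amount while added palm oil raises the fat content
SOY_FRACTION_OF_10EN_FAT = 0.5

#: lipid form split of dietary fat mass: mostly intact TAG with a small
#: pre-hydrolyzed free fatty acid / monoacylglycerol fraction
LIPID_FORM_MASS_SPLIT = {"tag": 0.94, "ffa": 0.03, "mag": 0.03}

#: dietary sodium per kcal of feed (semi-purified rodent diet scale)
NA_MOL_PER_KCAL = 1.2e-5

#: approximate fatty acid mass profiles of the two dietary oils
PALM_OIL_FA = {"C14:0": 0.011, "C16:0": 0.440, "C18:0": 0.045,
               "C18:1": 0.390, "C18:2": 0.100, "C18:3": 0.004}
SOY_OIL_FA = {"C14:0": 0.001, "C16:0": 0.110, "C18:0": 0.040,
              "C18:1": 0.230, "C18:2": 0.530, "C18:3": 0.070}

#: casein-like amino acid mass fractions (18 amino acids)
CASEIN_AA_MASS_FRACTIONS = {
    "glu": 0.120, "gln": 0.100, "pro": 0.100, "leu": 0.090, "lys": 0.075,
    "asp": 0.063, "val": 0.060, "tyr": 0.055, "ser": 0.055, "ile": 0.049,
    "phe": 0.048, "thr": 0.042, "arg": 0.035, "his": 0.028, "ala": 0.030,
    "met": 0.026, "gly": 0.018, "trp": 0.011,
}

AA_MOLAR_MASS = {
    "ala": 89.09, "arg": 174.20, "asp": 133.10, "gln": 146.15, "glu": 147.13,
    "gly": 75.07, "his": 155.15, "ile": 131.17, "leu": 131.17, "lys": 146.19,
    "met": 149.21, "phe": 165.19, "pro": 115.13, "ser": 105.09, "thr": 119.12,
    "trp": 204.23, "tyr": 181.19, "val": 117.15,
}

GLUCOSE_MOLAR_MASS = 180.16
FRUCTOSE_MOLAR_MASS = 180.16
SODIUM_MOLAR_MASS = 22.99

STUDY_FAT_EN_PERCENTS = (10, 20, 30, 45)


class DietSpecError(ValueError):
    pass


@dataclass
class SyntheticDietSpec:
    fat_en_percent: float = 10
    protein_en_percent: float = 20
    total_kcal_per_day: float = 12.0
    fa_profile: dict[str, float] | None = None  # mass fractions override
    cholesterol_free: bool = True
    allow_custom_en: bool = False
    jitter_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fat_en_percent not in STUDY_FAT_EN_PERCENTS and not self.allow_custom_en:
            raise DietSpecError(
                f"fat_en_percent {self.fat_en_percent} not one of "
                f"{STUDY_FAT_EN_PERCENTS}; pass allow_custom_en=True to override"
            )
        if self.fat_en_percent + self.protein_en_percent >= 100:
            raise DietSpecError("fat + protein energy exceeds 100%")
        if not self.cholesterol_free:
            raise DietSpecError("study diets are cholesterol-free")

    @property
    def carbohydrate_en_percent(self) -> float:
        return 100.0 - self.fat_en_percent - self.protein_en_percent

    @property
    def name(self) -> str:
        return f"{self.fat_en_percent:g}en%"


def _normalized(d: dict[str, float]) -> dict[str, float]:
    total = sum(d.values())
    return {k: v / total for k, v in d.items()}


def blend_fa_profile(fat_en_percent: float, total_kcal: float) -> dict[str, float]:
    """Palm/soy blend mass fractions for a given fat level.

    The soy-oil amount is pinned to half of the 10 en% diet's fat and stays
    constant; palm oil provides the rest, so higher-fat diets are
    palmitate-enriched.
    """
    fat_g = fat_en_percent / 100.0 * total_kcal / KCAL_PER_G["fat"]
    soy_g = SOY_FRACTION_OF_10EN_FAT * (10.0 / 100.0 * total_kcal / KCAL_PER_G["fat"])
    soy_g = min(soy_g, fat_g)
    palm_g = fat_g - soy_g
    palm = _normalized(PALM_OIL_FA)
    soy = _normalized(SOY_OIL_FA)
    profile = {
        code: (palm_g * palm[code] + soy_g * soy[code]) / fat_g
        for code in palm
    }
    return _normalized(profile)


def build_synthetic_diet(spec: SyntheticDietSpec | None = None) -> DietComposition:
    """Generate a study-like diet as mol-per-mouse-per-day nutrient intakes."""
    spec = spec or SyntheticDietSpec()
    kcal = spec.total_kcal_per_day

    intakes: dict[str, float] = {}

    # carbohydrate: fixed sucrose share (-> glucose + fructose), remainder
    # (starch/dextrose) counted as glucose equivalents
    carb_g = spec.carbohydrate_en_percent / 100.0 * kcal / KCAL_PER_G["carbohydrate"]
    sucrose_g = min(SUCROSE_KCAL_FRACTION * kcal / KCAL_PER_G["carbohydrate"], carb_g)
    glc_g = carb_g - sucrose_g / 2.0
    fru_g = sucrose_g / 2.0
    intakes["glc"] = glc_g / GLUCOSE_MOLAR_MASS
    intakes["fru"] = fru_g / FRUCTOSE_MOLAR_MASS

    # protein: casein amino acid profile
    protein_g = spec.protein_en_percent / 100.0 * kcal / KCAL_PER_G["protein"]
    aa_fracs = _normalized(CASEIN_AA_MASS_FRACTIONS)
    for aa, frac in aa_fracs.items():
        intakes[aa] = protein_g * frac / AA_MOLAR_MASS[aa]

    # fat: six FA species split over TAG / free FA / MAG forms
    fat_g = spec.fat_en_percent / 100.0 * kcal / KCAL_PER_G["fat"]
    profile = spec.fa_profile or blend_fa_profile(spec.fat_en_percent, kcal)
    profile = _normalized(profile)
    species = {sp.code: sp for sp in dietary_fa_species()}
    for code, frac in profile.items():
        sp = species[code]
        mass = fat_g * frac
        t = sp.token
        intakes[f"tag_{t}"] = LIPID_FORM_MASS_SPLIT["tag"] * mass / sp.tag_mass
        intakes[f"ffa_{t}"] = LIPID_FORM_MASS_SPLIT["ffa"] * mass / sp.ffa_mass
        intakes[f"mag_{t}"] = LIPID_FORM_MASS_SPLIT["mag"] * mass / sp.mag_mass

    # minerals: sodium scaled to energy intake
    intakes["na"] = NA_MOL_PER_KCAL * kcal

    if spec.jitter_fraction > 0:
        rng = np.random.default_rng(spec.seed)
        for k in intakes:
            intakes[k] *= 1.0 + rng.uniform(-spec.jitter_fraction,
                                            spec.jitter_fraction)

    return DietComposition(
        spec.name,
        intakes,
        {
            "fat": spec.fat_en_percent / 100.0,
            "carbohydrate": spec.carbohydrate_en_percent / 100.0,
            "protein": spec.protein_en_percent / 100.0,
        },
    )


def study_diets(total_kcal_per_day: float = 12.0) -> list[DietComposition]:
    """The four study-like diets (10/20/30/45 en% fat)."""
    return [
        build_synthetic_diet(SyntheticDietSpec(fat_en_percent=p,
                                               total_kcal_per_day=total_kcal_per_day))
        for p in STUDY_FAT_EN_PERCENTS
    ]


def default_nutrient_exchange_map() -> dict[str, str | None]:
    """Nutrient token -> luminal exchange reaction id, for every diet nutrient.

    Covers all 39 synthetic-diet nutrients (2 hexoses, 18 amino acids,
    6 FA x 3 lipid forms, sodium).  Ids follow the toy-model convention
    ``EX_<token>_u``; on the toy model the amino acid exchanges other than
    glutamine are absent and are skipped by non-strict bound application.
    """
    mapping: dict[str, str | None] = {
        "glc": "EX_glc_u",
        "fru": "EX_fru_u",
        "na": "EX_na_u",
    }
    for aa in CASEIN_AA_MASS_FRACTIONS:
        mapping[aa] = f"EX_{aa}_u"
    for sp in dietary_fa_species():
        t = sp.token
        mapping[f"tag_{t}"] = f"EX_tag_{t}_u"
        mapping[f"ffa_{t}"] = f"EX_ffa_{t}_u"
        mapping[f"mag_{t}"] = f"EX_mag_{t}_u"
    return mapping
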