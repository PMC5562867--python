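"""Fatty-acid-species-resolved lipid pathway generation.

Dietary triacylglycerol (TAG) is resolved into individual fatty-acid (FA)
species; every TAG/DAG/MAG molecule carries three/two/one identical acyl
chains (uniform-FA simplification — luminal hydrolysis reduces TAG to common
building blocks anyway, so mixed-acyl enantiomers are deliberately not
modelled).  For each species the generator emits:

* 1 luminal hydrolysis (lipase):        TAG -> MAG + 2 FFA
* 3 absorption reactions:               FFA carrier transport, FFA diffusion,
                                        MAG transport (apical)
* 6 re-synthesis reactions (template):  acyl-CoA activation, acyl-CoA
                                        transport to ER, MAG transport to ER,
                                        MGAT (MAG -> DAG), DGAT (DAG -> TAG),
                                        MTTP lipidation (TAG -> chylomicron-
                                        ready TAG)
* 1 cholesteryl-ester formation (ACAT): acyl-CoA + cholesterol -> CE

With six dietary species this yields 18 absorption, 36 re-synthesis and 6
cholesteryl-ester reactions.  The 3-per-species absorption and 6-per-species
re-synthesis templates are documented constants so the totals are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import GeneRule, Metabolite, Reaction

# -- fatty acid species ---------------------------------------------------

#: The six dietary fatty acids (palm/soy oil blends): code -> trivial name.
DIETARY_FA_CODES = {
    "C14:0": "myristic acid",
    "C16:0": "palmitic acid",
    "C18:0": "stearic acid",
    "C18:1": "oleic acid",
    "C18:2": "linoleic acid",
    "C18:3": "linolenic acid",
}

_ATOMIC = {"C": 12.011, "H": 1.008, "O": 15.999}
GLYCEROL_MASS = 92.094
WATER_MASS = 18.015
CHOLESTEROL_MASS = 386.654  # C27H46O
CHOLESTEROL_CARBONS = 27


class LipidSpeciesError(ValueError):
    """Invalid or inconsistent fatty-acid species input."""


@dataclass(frozen=True)
class FattyAcidSpecies:
    code: str
    name: str
    carbon_count: int
    double_bonds: int

    def __post_init__(self) -> None:
        try:
            c_part, d_part = self.code.lstrip("C").split(":")
            c, d = int(c_part), int(d_part)
        except (ValueError, AttributeError):
            raise LipidSpeciesError(f"malformed fatty acid code {self.code!r}") from None
        if (c, d) != (self.carbon_count, self.double_bonds):
            raise LipidSpeciesError(
                f"{self.code}: carbon/double-bond fields ({self.carbon_count}, "
                f"{self.double_bonds}) inconsistent with code"
            )

    @property
    def token(self) -> str:
        """Lower-case id-safe token, e.g. 'c18_1'."""
        return self.code.lower().replace(":", "_")

    @property
    def ffa_mass(self) -> float:
        """Molar mass of the free acid CnH(2n-2d)O2, g/mol."""
        n, d = self.carbon_count, self.double_bonds
        return _ATOMIC["C"] * n + _ATOMIC["H"] * (2 * n - 2 * d) + 2 * _ATOMIC["O"]

    @property
    def mag_mass(self) -> float:
        return self.ffa_mass + GLYCEROL_MASS - WATER_MASS

    @property
    def dag_mass(self) -> float:
        return 2 * self.ffa_mass + GLYCEROL_MASS - 2 * WATER_MASS

    @property
    def tag_mass(self) -> float:
        return 3 * self.ffa_mass + GLYCEROL_MASS - 3 * WATER_MASS

    @property
    def ce_mass(self) -> float:
        return self.ffa_mass + CHOLESTEROL_MASS - WATER_MASS

    def _formula(self, c: int, h: int, o: int, extra: str = "") -> str:
        return f"C{c}H{h}O{o}{extra}"

    def ffa_formula(self) -> str:
        n, d = self.carbon_count, self.double_bonds
        return self._formula(n, 2 * n - 2 * d, 2)

    def mag_formula(self) -> str:
        n, d = self.carbon_count, self.double_bonds
        return self._formula(n + 3, 2 * n - 2 * d + 6, 4)

    def dag_formula(self) -> str:
        n, d = self.carbon_count, self.double_bonds
        return self._formula(2 * n + 3, 4 * n - 4 * d + 4, 5)

    def tag_formula(self) -> str:
        n, d = self.carbon_count, self.double_bonds
        return self._formula(3 * n + 3, 6 * n - 6 * d + 2, 6)

    def facoa_formula(self) -> str:
        # acyl-CoA = FFA + CoA (C21H36N7O16P3S) - H2O
        n, d = self.carbon_count, self.double_bonds
        return self._formula(n + 21, 2 * n - 2 * d + 34, 17, "N7P3S")

    def ce_formula(self) -> str:
        # cholesteryl ester = FFA + cholesterol (C27H46O) - H2O
        n, d = self.carbon_count, self.double_bonds
        return self._formula(n + 27, 2 * n - 2 * d + 44, 2)


def dietary_fa_species() -> list[FattyAcidSpecies]:
    """The six fatty acids of the palm/soy-oil study diets."""
    out = []
    for code, name in DIETARY_FA_CODES.items():
        c, d = code.lstrip("C").split(":")
        out.append(FattyAcidSpecies(code, name, int(c), int(d)))
    return out


# -- reaction generation --------------------------------------------------

#: per-species reaction counts implied by the templates below
ABSORPTION_PER_SPECIES = 3
RESYNTHESIS_PER_SPECIES = 6
CHOLESTERYL_ESTER_PER_SPECIES = 1


@dataclass
class LipidReactionSet:
    reactions: list[Reaction]
    metabolites: list[Metabolite]
    category_counts: dict[str, int] = field(default_factory=dict)

    def by_category(self, category: str) -> list[Reaction]:
        return [r for r in self.reactions if r.metadata.get("lipid_category") == category]


_COFACTOR_FORMULAS = {
    "atp": "C10H12N5O13P3",
    "adp": "C10H12N5O10P2",
    "pi": "HO4P",
    "coa": "C21H36N7O16P3S",
    "chol": "C27H46O",
}


def _cofactor_metabolites() -> list[Metabolite]:
    mets = []
    for base, comp in [
        ("atp", "c"), ("adp", "c"), ("pi", "c"), ("coa", "c"),
        ("coa", "r"), ("chol", "r"),
    ]:
        mets.append(
            Metabolite(f"{base}[{comp}]", base, comp, base.upper(),
                       _COFACTOR_FORMULAS[base])
        )
    return mets


def _species_metabolites(sp: FattyAcidSpecies) -> list[Metabolite]:
    t = sp.token
    specs = [
        (f"tag_{t}", "u", sp.tag_formula()),
        (f"mag_{t}", "u", sp.mag_formula()),
        (f"ffa_{t}", "u", sp.ffa_formula()),
        (f"ffa_{t}", "c", sp.ffa_formula()),
        (f"mag_{t}", "c", sp.mag_formula()),
        (f"facoa_{t}", "c", sp.facoa_formula()),
        (f"facoa_{t}", "r", sp.facoa_formula()),
        (f"mag_{t}", "r", sp.mag_formula()),
        (f"dag_{t}", "r", sp.dag_formula()),
        (f"tag_{t}", "r", sp.tag_formula()),
        (f"tagchy_{t}", "r", sp.tag_formula()),
        (f"ce_{t}", "r", sp.ce_formula()),
    ]
    return [
        Metabolite(f"{base}[{comp}]", base, comp, f"{base} ({sp.name})", formula)
        for base, comp, formula in specs
    ]


def _species_reactions(sp: FattyAcidSpecies) -> list[Reaction]:
    t = sp.token
    up = sp.name

    def rxn(rid, stoich, category, gene="", subsystem="lipid metabolism"):
        r = Reaction(
            rid, stoich, 0.0, 1000.0,
            gene_rule=GeneRule(gene), subsystem=subsystem,
            name=f"{rid} ({up})",
        )
        r.metadata["lipid_category"] = category
        r.metadata["fa_species"] = sp.code
        return r

    return [
        # luminal hydrolysis
        rxn(f"LIPASE_{t}",
            {f"tag_{t}[u]": -1, f"mag_{t}[u]": 1, f"ffa_{t}[u]": 2},
            "hydrolysis", gene="Pnlip", subsystem="luminal digestion"),
        # absorption (3 per species)
        rxn(f"FFAT_{t}", {f"ffa_{t}[u]": -1, f"ffa_{t}[c]": 1},
            "absorption", gene="Cd36 or Slc27a4"),
        rxn(f"FFAD_{t}", {f"ffa_{t}[u]": -1, f"ffa_{t}[c]": 1}, "absorption"),
        rxn(f"MAGT_{t}", {f"mag_{t}[u]": -1, f"mag_{t}[c]": 1}, "absorption"),
        # re-synthesis (6 per species)
        rxn(f"FACOA_{t}",
            {f"ffa_{t}[c]": -1, "atp[c]": -1, "coa[c]": -1,
             f"facoa_{t}[c]": 1, "adp[c]": 1, "pi[c]": 1},
            "resynthesis", gene="Acsl5"),
        rxn(f"FACOATR_{t}", {f"facoa_{t}[c]": -1, f"facoa_{t}[r]": 1},
            "resynthesis"),
        rxn(f"MAGTR_{t}", {f"mag_{t}[c]": -1, f"mag_{t}[r]": 1}, "resynthesis"),
        rxn(f"MGAT_{t}",
            {f"mag_{t}[r]": -1, f"facoa_{t}[r]": -1,
             f"dag_{t}[r]": 1, "coa[r]": 1},
            "resynthesis", gene="Mogat2"),
        rxn(f"DGAT_{t}",
            {f"dag_{t}[r]": -1, f"facoa_{t}[r]": -1,
             f"tag_{t}[r]": 1, "coa[r]": 1},
            "resynthesis", gene="Dgat1 or Dgat2"),
        rxn(f"MTTP_{t}", {f"tag_{t}[r]": -1, f"tagchy_{t}[r]": 1},
            "resynthesis", gene="Mttp"),
        # cholesteryl ester formation (1 per species)
        rxn(f"ACAT_{t}",
            {f"facoa_{t}[r]": -1, "chol[r]": -1,
             f"ce_{t}[r]": 1, "coa[r]": 1},
            "cholesteryl_ester", gene="Soat2"),
    ]


def generate_lipid_reactions(species: list[FattyAcidSpecies]) -> LipidReactionSet:
    """Generate the species-resolved lipid pathway for a list of FA species.

    Raises :class:`LipidSpeciesError` for an empty list or duplicate codes.
    """
    if not species:
        raise LipidSpeciesError("species list must be non-empty")
    codes = [sp.code for sp in species]
    if len(set(codes)) != len(codes):
        raise LipidSpeciesError(f"duplicate fatty acid species in {codes}")

    metabolites = _cofactor_metabolites()
    reactions: list[Reaction] = []
    for sp in species:
        metabolites.extend(_species_metabolites(sp))
        reactions.extend(_species_reactions(sp))

    counts = {"hydrolysis": 0, "absorption": 0, "resynthesis": 0,
              "cholesteryl_ester": 0, "chylomicron": 0}
    for r in reactions:
        counts[r.metadata["lipid_category"]] += 1
    return LipidReactionSet(reactions, metabolites, counts)


# -- chylomicron assembly -------------------------------------------------

#: documented toy constants for converting mass fractions to molar coefficients
CHYLOMICRON_PARTICLE_MASS = 1.0e5  # g/mol reference particle (scaled down)
PHOSPHOLIPID_MOLAR_MASS = 775.0    # POPC-like average
APOB_MOLAR_MASS = 5.0e4            # generic apolipoprotein drain

#: postprandial chylomicron composition by mass (TAG ~95%, phospholipid ~4%,
#: cholesteryl ester ~1%, protein ~2%), normalized to sum to one.
DEFAULT_COMPONENT_MASS_FRACTIONS = {
    "TAG": 0.95 / 1.02,
    "phospholipid": 0.04 / 1.02,
    "cholesterol_ester": 0.01 / 1.02,
    "protein": 0.02 / 1.02,
}


class ChylomicronProfileError(ValueError):
    pass


class CompositionError(RuntimeError):
    """Chylomicron composition undefined (no TAG flux into assembly)."""


@dataclass
class ChylomicronProfile:
    """Target chylomicron composition.

    ``fa_fractions`` are mole fractions over FA species; the component mass
    fractions describe the particle's TAG/phospholipid/CE/protein split.
    """

    fa_fractions: dict[str, float]  # species code -> mole fraction
    component_mass_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_MASS_FRACTIONS)
    )

    def __post_init__(self) -> None:
        if abs(sum(self.fa_fractions.values()) - 1.0) > 1e-9:
            raise ChylomicronProfileError("fa_fractions must sum to 1")
        if abs(sum(self.component_mass_fractions.values()) - 1.0) > 1e-9:
            raise ChylomicronProfileError("component mass fractions must sum to 1")
        for k in ("TAG", "phospholipid", "cholesterol_ester", "protein"):
            if k not in self.component_mass_fractions:
                raise ChylomicronProfileError(f"missing component fraction {k!r}")


def _species_by_code() -> dict[str, FattyAcidSpecies]:
    return {sp.code: sp for sp in dietary_fa_species()}


def build_chylomicron_assembly(
    profile: ChylomicronProfile,
    reaction_id: str = "CHYLOASM",
) -> Reaction:
    """Single ER pseudo-reaction assembling one chylomicron particle.

    Consumes chylomicron-ready TAG and cholesteryl esters per species (mole
    fractions from the profile), phospholipid and an apolipoprotein precursor,
    and produces one ``chylo[r]`` particle.  Component mass fractions are
    converted to molar coefficients with the documented molar-mass constants
    and the reference particle mass.
    """
    registry = _species_by_code()
    active = {c: f for c, f in profile.fa_fractions.items() if f > 0}
    for code in active:
        if code not in registry:
            raise ChylomicronProfileError(f"unknown fatty acid code {code!r}")

    w = profile.component_mass_fractions
    M = CHYLOMICRON_PARTICLE_MASS
    mean_tag = sum(f * registry[c].tag_mass for c, f in active.items())
    mean_ce = sum(f * registry[c].ce_mass for c, f in active.items())
    nu_tag_total = w["TAG"] * M / mean_tag
    nu_ce_total = w["cholesterol_ester"] * M / mean_ce
    nu_pl = w["phospholipid"] * M / PHOSPHOLIPID_MOLAR_MASS
    nu_apob = w["protein"] * M / APOB_MOLAR_MASS

    stoich: dict[str, float] = {}
    for code, f in active.items():
        t = registry[code].token
        stoich[f"tagchy_{t}[r]"] = -nu_tag_total * f
        if nu_ce_total > 0:
            stoich[f"ce_{t}[r]"] = -nu_ce_total * f
    stoich["pl[r]"] = -nu_pl
    stoich["apob[r]"] = -nu_apob
    stoich["chylo[r]"] = 1.0

    rxn = Reaction(reaction_id, stoich, 0.0, 1000.0,
                   gene_rule=GeneRule("Apob and Mttp"),
                   subsystem="chylomicron assembly",
                   name="chylomicron particle assembly")
    rxn.metadata["lipid_category"] = "chylomicron"
    rxn.metadata["category"] = "chylomicron_assembly"
    rxn.metadata["fa_fractions"] = dict(active)
    rxn.metadata["component_mass_fractions"] = dict(w)
    return rxn


def assembly_metabolites() -> list[Metabolite]:
    """Shared assembly substrates/product not covered by the species set."""
    return [
        Metabolite("pl[r]", "pl", "r", "phospholipid (lumped)", None),
        Metabolite("apob[r]", "apob", "r", "apolipoprotein B-48 precursor", None),
        Metabolite("chylo[r]", "chylo", "r", "chylomicron particle", None),
    ]


def chylomicron_fa_composition(solution, model) -> ChylomicronProfile:
    """FA composition of secreted chylomicrons from an optimal flux state.

    fraction_i = (TAG flux of species i into assembly) / (total TAG flux).
    Raises :class:`CompositionError` when no TAG enters any assembly reaction.
    """
    if not solution.optimal:
        raise CompositionError("solution is not optimal")
    token_to_code = {sp.token: sp.code for sp in dietary_fa_species()}
    flux_in: dict[str, float] = {}
    mass_fractions = None
    for rxn in model.reactions.values():
        if rxn.metadata.get("category") != "chylomicron_assembly":
            continue
        v = solution.fluxes.get(rxn.id, 0.0)
        if mass_fractions is None and "component_mass_fractions" in rxn.metadata:
            mass_fractions = dict(rxn.metadata["component_mass_fractions"])
        for met_id, coeff in rxn.stoichiometry.items():
            base = model.metabolites[met_id].base_id
            if base.startswith("tagchy_") and coeff < 0:
                code = token_to_code.get(base[len("tagchy_"):])
                if code is not None:
                    flux_in[code] = flux_in.get(code, 0.0) + (-coeff) * v
    total = sum(flux_in.values())
    if total <= 1e-12:
        raise CompositionError("no TAG flux into chylomicron assembly")
    fractions = {c: f / total for c, f in flux_in.items()}
    # renormalize away round-off so the profile invariant holds exactly
    s = sum(fractions.values())
    fractions = {c: f / s for c, f in fractions.items()}
    if mass_fractions is None:
        mass_fractions = dict(DEFAULT_COMPONENT_MASS_FRACTIONS)
    return ChylomicronProfile(fractions, mass_fractions)
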