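"""The four headline simulation experiments on the synthetic model."""

import math

import pytest

from enteroflux import (
    RunConfig,
    ToyModelSpec,
    build_toy_model,
    chylomicron_oxygen_scenario,
    conversion_factor,
    enterocyte_dry_mass,
    glucose_transport_scenario,
    gluconeogenesis_scenario,
    sodium_titration_scenario,
)
from enteroflux.lipids import dietary_fa_species
from enteroflux.scenarios import ScenarioConfigError

A = conversion_factor(enterocyte_dry_mass())


# -- glucose transport -----------------------------------------------------

def test_glucose_fully_absorbed_only_with_apical_glut2(toy_model, diet10):
    with_g2 = glucose_transport_scenario(toy_model, diet10, True)
    without = glucose_transport_scenario(toy_model, diet10, False)
    dietary_glc_flux = diet10.nutrient_intakes["glc"] * A
    # apical GLUT2 present: the entire dietary glucose bolus can be taken up
    assert with_g2.outputs["glucose_max_apical_absorption"] == pytest.approx(
        dietary_glc_flux, rel=1e-6)
    # SGLT1 alone: absorption capped by luminal Na+ via the 2:1 coupling
    na_limited = diet10.nutrient_intakes["na"] * A / 2.0
    assert without.outputs["glucose_max_apical_absorption"] == pytest.approx(
        na_limited, rel=1e-6)
    assert (without.outputs["glucose_max_apical_absorption"]
            < 0.05 * dietary_glc_flux)


def test_fructose_absorption_is_na_independent(toy_model, diet10):
    without = glucose_transport_scenario(toy_model, diet10, False)
    dietary_fru_flux = diet10.nutrient_intakes["fru"] * A
    # GLUT5 is facilitated: full fructose uptake regardless of apical GLUT2
    assert without.outputs["fructose_max_apical_absorption"] == pytest.approx(
        dietary_fru_flux, rel=1e-6)


def test_sglt1_cap_scales_with_coupling_stoichiometry(diet10):
    m3 = build_toy_model(ToyModelSpec(na_glucose_stoichiometry=3.0))
    without = glucose_transport_scenario(m3, diet10, False)
    na_limited = diet10.nutrient_intakes["na"] * A / 3.0
    assert without.outputs["glucose_max_apical_absorption"] == pytest.approx(
        na_limited, rel=1e-6)


def test_missing_transporter_raises(diet10):
    m = build_toy_model()
    del m.reactions["GLUT5A"]
    with pytest.raises(ScenarioConfigError):
        glucose_transport_scenario(m, diet10, True)


# -- sodium titration ------------------------------------------------------

def na_curve(toy_model, diet, apical_glut2, levels):
    res = sodium_titration_scenario(toy_model, diet, apical_glut2, levels)
    return res, res.curves["glucose_absorption_vs_na"]


def test_na_titration_rising_then_plateau_without_apical_glut2(toy_model,
                                                               diet10):
    na = diet10.nutrient_intakes["na"]
    levels = [0.0, 0.25 * na, 0.5 * na, na, 2 * na, 500 * na, 1000 * na]
    res, curve = na_curve(toy_model, diet10, False, levels)
    vals = curve.objective_values
    # rising region: absorption = Na_supply * A / 2 (closed form, slope 1/2)
    for lvl, got in zip(levels[:5], vals[:5]):
        assert got == pytest.approx(lvl * A / 2.0, rel=1e-6, abs=1e-9)
    # plateau: dietary glucose exhausted, further Na+ adds nothing
    plateau = res.outputs["plateau_absorption"]
    assert plateau == pytest.approx(diet10.nutrient_intakes["glc"] * A,
                                    rel=1e-6)
    assert vals[-1] == pytest.approx(plateau, rel=1e-6)
    assert vals[-2] == pytest.approx(plateau, rel=1e-6)


def test_na_titration_flat_with_apical_glut2(toy_model, diet10):
    na = diet10.nutrient_intakes["na"]
    levels = [0.0, 0.5 * na, na, 10 * na]
    _, curve = na_curve(toy_model, diet10, True, levels)
    vals = curve.objective_values
    for v in vals:
        assert v == pytest.approx(vals[0], rel=1e-6)


def test_required_na_exceeds_dietary_na(toy_model, diet10):
    na = diet10.nutrient_intakes["na"]
    res, _ = na_curve(toy_model, diet10, False, [0.0, na])
    ratio = res.outputs["required_to_dietary_na_ratio"]
    assert math.isfinite(ratio)
    assert ratio > 10.0
    # consistency of the reported pieces
    assert res.outputs["required_na_mol_per_day"] == pytest.approx(
        ratio * na, rel=1e-6)


def test_required_na_matches_closed_form(toy_model, diet10):
    # with the 2:1 coupling, >=99.9% absorption needs ~2 Na+ per glucose
    res, _ = na_curve(toy_model, diet10, False,
                      [0.0, diet10.nutrient_intakes["na"]])
    required = res.outputs["required_na_mol_per_day"]
    expected = 2.0 * 0.999 * diet10.nutrient_intakes["glc"]
    assert required == pytest.approx(expected, rel=1e-2)


# -- gluconeogenesis -------------------------------------------------------

def test_gluconeogenic_surplus_positive_and_traceable(toy_model, diet10):
    res = gluconeogenesis_scenario(toy_model, diet10, True)
    surplus = res.outputs["gluconeogenic_surplus"]
    # 2 glutamine -> 1 glucose: surplus = gln_uptake * A / 2
    expected = diet10.nutrient_intakes["gln"] * A / 2.0
    assert surplus == pytest.approx(expected, rel=1e-6)
    assert res.outputs["max_secretion"] == pytest.approx(
        res.outputs["max_absorption"] + surplus, rel=1e-9)
    # single-nutrient ablation pins the surplus on glutamine uptake
    without = res.outputs["surplus_without_nutrient"]
    assert without["EX_gln_u"] == pytest.approx(0.0, abs=1e-9)


def test_surplus_zero_without_gluconeogenesis_pathway(diet10):
    m = build_toy_model(ToyModelSpec(include_gluconeogenesis=False))
    res = gluconeogenesis_scenario(m, diet10, True)
    assert res.outputs["gluconeogenic_surplus"] == pytest.approx(0.0,
                                                                 abs=1e-9)


# -- chylomicron / oxygen --------------------------------------------------

def test_no_cholesterol_source_means_no_chylomicron(toy_model, diet10):
    res = chylomicron_oxygen_scenario(toy_model, diet10, "none")
    assert res.outputs["max_chylomicron_secretion"] == pytest.approx(0.0,
                                                                     abs=1e-9)


def test_secretion_positive_with_either_cholesterol_source(toy_model, diet10):
    luminal = chylomicron_oxygen_scenario(toy_model, diet10, "luminal")
    biosyn = chylomicron_oxygen_scenario(toy_model, diet10, "biosynthesis")
    assert luminal.outputs["max_chylomicron_secretion"] > 1e-6
    assert biosyn.outputs["max_chylomicron_secretion"] > 1e-6
    # lipid supply, not the cholesterol route, limits secretion here
    assert biosyn.outputs["max_chylomicron_secretion"] == pytest.approx(
        luminal.outputs["max_chylomicron_secretion"], rel=1e-6)


def test_minimal_oxygen_monotone_in_fat_level(toy_model, diets):
    o2 = []
    for diet in diets:
        res = chylomicron_oxygen_scenario(toy_model, diet, "biosynthesis")
        o2.append(res.outputs["minimal_o2_mol_per_day"])
    assert all(math.isfinite(v) and v > 0 for v in o2)
    assert o2 == sorted(o2)
    assert o2[-1] > 2 * o2[0]


def test_minimal_oxygen_matches_atp_accounting(toy_model, diet10):
    """Hand accounting: all net ATP comes from the respiratory lump, so the
    minimal O2 equals (total ATP demand at the optimum) / (2 * P:O)."""
    from enteroflux.diet import diet_to_bounds
    from enteroflux.fba import Direction, lexicographic_optimize
    from enteroflux.scenarios import _prepare

    config = RunConfig()
    work = _prepare(toy_model, diet10, config, True)
    work.reactions["EX_chol_src"].lower_bound = 0.0
    work.reactions["EX_chol_src"].upper_bound = 0.0
    lex = lexicographic_optimize(work, ("CHYLOMGE", Direction.MAXIMIZE),
                                 ("EX_o2_e", Direction.MAXIMIZE))
    assert lex.optimal
    p2o = 2.5
    atp_consumed = 0.0
    for rid, flux in lex.fluxes.items():
        coeff = work.reactions[rid].stoichiometry.get("atp[c]", 0.0)
        if rid == "RESP":
            continue
        atp_consumed += -coeff * flux
    expected_o2 = atp_consumed / (2.0 * p2o)
    assert -lex.objective_value == pytest.approx(expected_o2, rel=1e-6)


def test_chylomicron_fa_fractions_match_diet(toy_model, diets):
    species = {s.code: s for s in dietary_fa_species()}
    for diet in diets:
        res = chylomicron_oxygen_scenario(toy_model, diet, "biosynthesis")
        fractions = res.outputs["chylomicron_fa_fractions"]
        assert fractions is not None
        # dietary acyl-group molar fractions (TAG carries 3 acyls)
        acyl = {}
        for code, sp in species.items():
            t = sp.token
            acyl[code] = (3 * diet.nutrient_intakes[f"tag_{t}"]
                          + diet.nutrient_intakes[f"ffa_{t}"]
                          + diet.nutrient_intakes[f"mag_{t}"])
        total = sum(acyl.values())
        for code in species:
            assert fractions[code] == pytest.approx(acyl[code] / total,
                                                    abs=0.01), code


def test_unknown_cholesterol_source_rejected(toy_model, diet10):
    with pytest.raises(ValueError):
        chylomicron_oxygen_scenario(toy_model, diet10, "dietary")
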