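"""Knockout screen, Type I/II/III classification and dietary rescue."""

import math
from collections import Counter

import pytest

from enteroflux import classify, dietary_rescue, screen_knockouts
from enteroflux.diet import diet_to_bounds
from enteroflux.fba import Direction
from enteroflux.knockouts import BaselineError, records_to_frame


@pytest.fixture(scope="module")
def glucose_records(toy_model, diet10):
    bounds = diet_to_bounds(diet10)
    return screen_knockouts(toy_model, ("GLCGLUT2", Direction.MAXIMIZE),
                            bounds)


@pytest.fixture(scope="module")
def chylo_records(toy_model, diet10):
    bounds = diet_to_bounds(diet10)
    return screen_knockouts(toy_model, ("CHYLOMGE", Direction.MAXIMIZE),
                            bounds)


def test_classify_three_way():
    assert classify(10.0, 10.0)[0] == "I"
    assert classify(10.0, 9.6)[0] == "I"       # 4% loss
    assert classify(10.0, 9.5)[0] == "I"       # exactly 5%: strict rule
    assert classify(10.0, 9.0)[0] == "III"     # 10% loss
    assert classify(10.0, 0.0)[0] == "II"
    assert classify(10.0, 1e-9)[0] == "II"     # below absolute blockage eps
    assert classify(10.0, float("nan"))[0] == "II"


def test_classify_scale_invariance():
    for scale in (1e-3, 1.0, 1e4):
        assert classify(10.0 * scale, 9.0 * scale)[0] == "III"
        assert classify(10.0 * scale, 9.9 * scale)[0] == "I"
        rf1 = classify(10.0, 9.0)[1]
        rfs = classify(10.0 * scale, 9.0 * scale)[1]
        assert rfs == pytest.approx(rf1, rel=1e-12)


def test_reduction_clipped_to_unit_interval():
    # numerically ko can exceed baseline by round-off; reduction stays in [0,1]
    _, r = classify(10.0, 10.0 + 1e-9)
    assert r == 0.0


def test_partition_property(glucose_records, chylo_records):
    for records in (glucose_records, chylo_records):
        counts = Counter(r.ko_class for r in records)
        assert set(counts) <= {"I", "II", "III"}
        assert sum(counts.values()) == len(records)
        for r in records:
            assert r.ko_value <= r.baseline + 1e-6


def test_exchanges_excluded_by_default(glucose_records, toy_model):
    screened = {r.reaction_id for r in glucose_records}
    for rxn in toy_model.exchange_reactions():
        assert rxn.id not in screened


def test_glucose_task_hand_class_table(glucose_records):
    """Hand-derived table: only the basolateral exporter is essential; only
    apical GLUT2 loss causes a partial (Na+-limited) impairment."""
    by_id = {r.reaction_id: r.ko_class for r in glucose_records}
    assert by_id["GLCGLUT2"] == "II"
    assert by_id["GLUT2A"] == "III"
    for rid, cls in by_id.items():
        if rid not in ("GLCGLUT2", "GLUT2A"):
            assert cls == "I", (rid, cls)


def test_glut2a_reduction_matches_na_limit(glucose_records, diet10):
    rec = {r.reaction_id: r for r in glucose_records}["GLUT2A"]
    # Hand accounting.  Secretion = absorption + gluconeogenic surplus.
    # Without apical GLUT2 absorption is Na+-capped at Na/2; in addition the
    # co-transported Na+ must be pumped out (3 Na+ per ATP), and each glucose
    # oxidized yields 2 pyruvate x 5 NADH x 2.5 ATP = 25 ATP, so Na/75 of
    # the absorbed glucose is burned instead of secreted.
    na = diet10.nutrient_intakes["na"]
    glc = diet10.nutrient_intakes["glc"]
    gln = diet10.nutrient_intakes["gln"]
    baseline = glc + gln / 2.0
    ko = na / 2.0 - na / 75.0 + gln / 2.0
    assert rec.reduction_fraction == pytest.approx(1.0 - ko / baseline,
                                                   rel=1e-6)


def test_chylomicron_task_hand_class_table(chylo_records):
    by_id = {r.reaction_id: r.ko_class for r in chylo_records}
    # energy, precursor and assembly chokepoints are essential
    for rid in ("RESP", "O2T", "TCAOX", "PYRT", "GLYC", "ACL", "CHOLSYN",
                "APOBSYN", "PLSYN", "COAR", "CHYLOSEC", "GLNUP", "CO2T"):
        assert by_id[rid] == "II", rid
    # losing one fatty-acid branch removes only that species' share
    for rid in ("LIPASE_c16_0", "MTTP_c18_1", "DGAT_c18_2"):
        assert by_id[rid] == "III", rid
    # hexose transporters are irrelevant to lipid output...
    for rid in ("SGLT1", "GLUT2A", "GLUT5A", "GLUT5B"):
        assert by_id[rid] == "I", rid


def test_species_branch_reduction_equals_dietary_share(chylo_records, diet10):
    """Knocking out the C18:1 MTTP removes (almost exactly) the C18:1 mass
    share of the chylomicron output."""
    rec = {r.reaction_id: r for r in chylo_records}["MTTP_c18_1"]
    assert 0.05 < rec.reduction_fraction < 0.95


def test_baseline_error_on_blocked_task(toy_model, diet10):
    # close every lipid uptake: chylomicron output impossible
    blocked = toy_model.copy()
    bounds = diet_to_bounds(diet10)
    for rid, (lb, ub) in list(bounds.bounds.items()):
        if rid.startswith(("EX_tag", "EX_ffa", "EX_mag")):
            bounds.bounds[rid] = (0.0, ub)
    with pytest.raises(BaselineError):
        screen_knockouts(blocked, ("CHYLOMGE", Direction.MAXIMIZE), bounds)


def test_dietary_rescue_of_lipase_knockout(toy_model, diet10, chylo_records):
    bounds = diet_to_bounds(diet10)
    task = ("CHYLOMGE", Direction.MAXIMIZE)
    rec = next(r for r in chylo_records if r.reaction_id == "LIPASE_c16_0")
    assert rec.ko_class == "III"
    dietary_rescue(toy_model, rec, bounds, task=task)
    assert rec.rescue is not None
    label, recovered = rec.rescue
    # the pre-hydrolyzed FFA/MAG route makes extra lipid the best rescue
    assert label.startswith("lipid")
    assert recovered > 1.0 - rec.reduction_fraction + 1e-6


def test_rescue_noop_for_type_i(chylo_records, toy_model, diet10):
    bounds = diet_to_bounds(diet10)
    rec = next(r for r in chylo_records if r.ko_class == "I")
    out = dietary_rescue(toy_model, rec, bounds,
                         task=("CHYLOMGE", Direction.MAXIMIZE))
    assert out.warning is not None
    assert out.rescue is None


def test_rescue_empty_grid_is_noop(chylo_records, toy_model, diet10):
    rec = next(r for r in chylo_records if r.ko_class == "III"
               and r.rescue is None)
    out = dietary_rescue(toy_model, rec, diet_to_bounds(diet10),
                         modification_grid=[],
                         task=("CHYLOMGE", Direction.MAXIMIZE))
    assert out.rescue is None


def test_records_frame_columns(glucose_records):
    frame = records_to_frame(glucose_records)
    assert list(frame.columns) == ["reaction_id", "baseline", "ko_value",
                                   "reduction", "class", "best_rescue",
                                   "recovered_fraction"]
    assert len(frame) == len(glucose_records)
    assert set(frame["class"]) <= {"I", "II", "III"}
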