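"""Dosing core: scaling, plasma adjustment, allocation, discretization."""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msud_buddy import (
    ConfigurationError,
    FormulaComposition,
    FormulaSelection,
    InfeasiblePlanError,
    KBConfig,
    PatientProfile,
    PlasmaPanel,
    StageError,
    allocate,
    apply_plasma_adjustment,
    discretize,
    new_tree,
    recommend,
    scale_allowance,
)
from msud_buddy.kb import BCAAS
from msud_buddy.rdr import Conclusion

from conftest import random_patient
from _oracles import grid_search_scoops


# ---------------------------------------------------------------------------
# scale_allowance
# ---------------------------------------------------------------------------

def test_band3_times_5kg(kb):
    a = scale_allowance(kb.lookup_allowance(3), 5.0)
    assert (a.isoleucine, a.leucine, a.valine) == (280.0, 462.5, 322.5)
    assert a.protein == pytest.approx(15.8)
    assert (a.energy, a.fluid) == (600.0, 500.0)
    assert a.adjustment_applied is None


def test_unit_weight_reproduces_per_kg_record(kb):
    per_kg = kb.lookup_allowance(2)
    a = scale_allowance(per_kg, 1.0)
    assert (a.isoleucine, a.leucine, a.valine, a.protein, a.energy, a.fluid) == (
        per_kg.isoleucine, per_kg.leucine, per_kg.valine,
        per_kg.protein, per_kg.energy, per_kg.fluid,
    )


@settings(max_examples=50, deadline=None)
@given(
    weight=st.floats(0.5, 7.5),
    band=st.integers(1, 6),
)
def test_scaling_is_linear(kb, weight, band):
    one = scale_allowance(kb.allowances[band], weight)
    two = scale_allowance(kb.allowances[band], 2 * weight)
    for field in ("isoleucine", "leucine", "valine", "protein", "energy", "fluid"):
        assert getattr(two, field) == pytest.approx(2 * getattr(one, field))


def test_nonpositive_weight_rejected(kb):
    with pytest.raises(Exception):
        scale_allowance(kb.lookup_allowance(3), 0)


# ---------------------------------------------------------------------------
# apply_plasma_adjustment
# ---------------------------------------------------------------------------

def test_in_band_panel_leaves_allowance_unchanged(kb, default_tree):
    base = scale_allowance(kb.lookup_allowance(3), 5.0)
    adjusted, flags, path = apply_plasma_adjustment(
        base, PatientProfile(3, 5.0), PlasmaPanel(80, 17, 55), default_tree
    )
    assert adjusted == base and flags == []
    assert path[0] == "root"


def test_high_leucine_halves_leucine_and_flags(kb, default_tree):
    base = scale_allowance(kb.lookup_allowance(3), 5.0)
    adjusted, flags, _ = apply_plasma_adjustment(
        base, PatientProfile(3, 5.0), PlasmaPanel(250, 17, 55), default_tree
    )
    assert adjusted.leucine == pytest.approx(base.leucine / 2)
    assert adjusted.isoleucine == base.isoleucine and adjusted.valine == base.valine
    assert adjusted.adjustment_applied == "reduce_leucine"
    assert "consult_dietitian" in flags


def test_identity_factor_changes_nothing(kb):
    tree = new_tree(Conclusion("noop", {"leucine_factor": 1.0}))
    base = scale_allowance(kb.lookup_allowance(3), 5.0)
    adjusted, flags, _ = apply_plasma_adjustment(
        base, PatientProfile(3, 5.0), PlasmaPanel(80, 17, 55), tree
    )
    assert adjusted.leucine == base.leucine
    # an explicit factor still records the adjustment and asks for review
    assert adjusted.adjustment_applied == "noop" and "consult_dietitian" in flags


@pytest.mark.parametrize("factor", [0, -0.5, 1.5, "half"])
def test_factor_outside_unit_interval_is_a_configuration_error(kb, factor):
    tree = new_tree(Conclusion("bad", {"leucine_factor": factor}))
    base = scale_allowance(kb.lookup_allowance(3), 5.0)
    with pytest.raises(ConfigurationError, match="leucine_factor"):
        apply_plasma_adjustment(base, PatientProfile(3, 5.0), PlasmaPanel(80, 17, 55), tree)


# ---------------------------------------------------------------------------
# allocate
# ---------------------------------------------------------------------------

def test_allocation_worked_example(kb):
    allowance = scale_allowance(kb.lookup_allowance(3), 5.0)
    result = allocate(allowance, kb.lookup_formula("Similac"), kb.lookup_formula("Ketonex-1"))
    assert result.commercial_grams == pytest.approx(462.5 / 10.79, rel=1e-9)  # 42.86 g
    assert result.limiting_nutrient == "leucine"
    assert result.medical_grams == pytest.approx((15.8 - (462.5 / 10.79) * 0.1083) / 0.15, rel=1e-6)


def test_bcaa_free_commercial_is_capped_by_protein(kb):
    hypothetical = FormulaComposition("NoBCAA", "commercial", 0, 0, 0, 10.0, 500.0)
    allowance = scale_allowance(kb.lookup_allowance(3), 5.0)
    result = allocate(allowance, hypothetical, kb.lookup_formula("Ketonex-1"))
    assert result.limiting_nutrient == "none"
    assert result.commercial_grams == pytest.approx(allowance.protein / 0.10)
    assert result.medical_grams == pytest.approx(0.0)


def test_zero_protein_need_yields_zero_medical(kb):
    allowance = scale_allowance(kb.lookup_allowance(3), 5.0)
    import dataclasses
    zero_protein = dataclasses.replace(allowance, protein=0.0)
    result = allocate(zero_protein, None, kb.lookup_formula("Ketonex-1"))
    assert result.medical_grams == 0.0 and result.commercial_grams == 0.0


def test_category_slots_enforced(kb):
    allowance = scale_allowance(kb.lookup_allowance(3), 5.0)
    with pytest.raises(ConfigurationError):
        allocate(allowance, kb.lookup_formula("Ketonex-1"), kb.lookup_formula("Anamix"))


def test_limiting_nutrient_tie_breaks_leucine_first(kb):
    # exactly tied ratios (all values binary-exact): each BCAA caps at 1000 g
    import dataclasses
    allowance = dataclasses.replace(
        scale_allowance(kb.lookup_allowance(3), 5.0),
        leucine=500.0, isoleucine=250.0, valine=125.0,
    )
    tied = FormulaComposition("Tied", "commercial", 50.0, 25.0, 12.5, 10.0, 500.0)
    assert allocate(allowance, tied, None).limiting_nutrient == "leucine"


# ---------------------------------------------------------------------------
# discretize
# ---------------------------------------------------------------------------

def test_discretize_worked_example(kb, default_tree):
    allowance = scale_allowance(kb.lookup_allowance(3), 5.0)
    similac = kb.lookup_formula("Similac")
    ketonex = kb.lookup_formula("Ketonex-1")
    plan = discretize(allocate(allowance, similac, ketonex), allowance, similac, ketonex, kb.config)
    assert plan.commercial_scoops == 8  # floor(42.86 / 5)
    assert plan.medical_scoops == 15  # round((15.8 - 40*0.1083)/0.15 / 5) = round(15.29)
    assert plan.water_ml == 500.0
    assert plan.delivered.leucine == pytest.approx(431.6) and plan.delivered.leucine <= 462.5
    # energy 40*5.26 + 75*4.80 = 570.4 kcal, inside the +/-10% band of 600
    assert plan.delivered.energy == pytest.approx(570.4)
    assert "energy_outside_tolerance" not in plan.flags
    assert plan.feeds_per_day == 8
    assert sum(f.commercial_scoops for f in plan.per_feed) == 8
    assert sum(f.medical_scoops for f in plan.per_feed) == 15
    assert sum(f.water_ml for f in plan.per_feed) == pytest.approx(500.0)


def test_exact_scoop_multiple_has_no_rounding_loss(kb):
    # a commercial allocation of exactly 40 g discretizes to exactly 8
    # scoops with no rounding loss
    import dataclasses
    from msud_buddy import AllocationResult

    # binary-exact contents make the leucine cap exactly 40 g
    formula = FormulaComposition("Exact", "commercial", 1000.0, 400.0, 500.0, 10.0, 500.0)
    ketonex = kb.lookup_formula("Ketonex-1")
    allowance = dataclasses.replace(
        scale_allowance(kb.lookup_allowance(3), 5.0),
        leucine=400.0, isoleucine=400.0, valine=400.0,
    )
    result = allocate(allowance, formula, ketonex)
    assert result.commercial_grams == 40.0
    plan = discretize(result, allowance, formula, ketonex, kb.config)
    assert plan.commercial_scoops == 8
    assert plan.commercial_scoops * kb.config.scoop_grams == result.commercial_grams


def test_scoop_remainders_go_to_earliest_feeds(kb):
    allowance = scale_allowance(kb.lookup_allowance(3), 5.0)
    similac = kb.lookup_formula("Similac")
    ketonex = kb.lookup_formula("Ketonex-1")
    plan = discretize(allocate(allowance, similac, ketonex), allowance, similac, ketonex, kb.config)
    # 15 medical scoops over 8 feeds: seven feeds of 2, last feed of 1
    counts = [f.medical_scoops for f in plan.per_feed]
    assert counts == sorted(counts, reverse=True)


def test_infeasible_when_no_scoop_fits(kb):
    # tiny allowance: even one scoop of Similac would exceed the leucine cap
    allowance = scale_allowance(kb.lookup_allowance(3), 5.0)
    import dataclasses
    tiny = dataclasses.replace(allowance, leucine=1.0, isoleucine=1.0, valine=1.0)
    similac = kb.lookup_formula("Similac")
    with pytest.raises(InfeasiblePlanError, match="dietitian"):
        discretize(allocate(tiny, similac, None), tiny, similac, None, kb.config)


# ---------------------------------------------------------------------------
# recommend (composition)
# ---------------------------------------------------------------------------

def test_end_to_end_worked_example(kb, default_tree, worked_example):
    profile, panel, selection = worked_example
    plan, allowance, path = recommend(profile, panel, selection, kb, default_tree)
    assert (plan.commercial_scoops, plan.medical_scoops) == (8, 15)
    assert plan.water_ml == 500.0
    assert allowance.leucine == 462.5
    assert path[0] == "root"


def test_medical_only_plan_delivers_zero_bcaas(kb, default_tree):
    profile = PatientProfile(3, 5.0)
    plan, _, _ = recommend(
        profile, PlasmaPanel(80, 17, 55),
        FormulaSelection(medical_name="Ketonex-1"), kb, default_tree,
    )
    assert plan.commercial_scoops == 0
    assert (plan.delivered.leucine, plan.delivered.isoleucine, plan.delivered.valine) == (0, 0, 0)
    assert plan.delivered.protein > 0


def test_stage_tagged_error_propagation(kb, default_tree):
    profile = PatientProfile.__new__(PatientProfile)  # bypass intake guard
    object.__setattr__(profile, "age_months", 8)
    object.__setattr__(profile, "weight_kg", 5.0)
    object.__setattr__(profile, "height_cm", None)
    with pytest.raises(StageError, match=r"\[lookup_allowance\]"):
        recommend(
            profile, PlasmaPanel(80, 17, 55),
            FormulaSelection("Similac", "Ketonex-1"), kb, default_tree,
        )


# ---------------------------------------------------------------------------
# Randomized properties
# ---------------------------------------------------------------------------

def _plan_for(kb, tree, profile, panel, commercial_name, medical_name):
    from msud_buddy.recommend import allocate as _alloc, apply_plasma_adjustment as _adj

    per_kg = kb.lookup_allowance(profile.age_months)
    base = scale_allowance(per_kg, profile.weight_kg)
    allowance, flags, _ = _adj(base, profile, panel, tree)
    commercial = kb.lookup_formula(commercial_name) if commercial_name else None
    medical = kb.lookup_formula(medical_name) if medical_name else None
    result = _alloc(allowance, commercial, medical)
    plan = discretize(result, allowance, commercial, medical, kb.config, tuple(flags))
    return plan, allowance, result, commercial, medical


def test_safety_and_oracle_on_random_patients(kb, default_tree):
    """Delivered BCAAs never exceed the (adjusted) allowance, and scoop
    counts equal the exhaustive grid-search result, over a random cohort
    crossed with every commercial/medical formula pair."""
    rng = random.Random(2024)
    pairs = [(c, m) for c in kb.formula_names("commercial") for m in kb.formula_names("medical")]
    for _ in range(150):
        profile, panel = random_patient(rng)
        for cname, mname in pairs:
            plan, allowance, result, commercial, medical = _plan_for(
                kb, default_tree, profile, panel, cname, mname
            )
            for b in BCAAS:
                assert getattr(plan.delivered, b) <= allowance.bcaa(b)
            expected = grid_search_scoops(allowance, commercial, medical, kb.config.scoop_grams)
            assert (plan.commercial_scoops, plan.medical_scoops) == expected


def test_commercial_grams_monotone_in_weight(kb):
    rng = random.Random(5)
    similac = kb.lookup_formula("Similac")
    ketonex = kb.lookup_formula("Ketonex-1")
    for _ in range(100):
        band = rng.randint(1, 6)
        w1 = rng.uniform(2, 9)
        w2 = w1 + rng.uniform(0, 1)
        a1 = scale_allowance(kb.allowances[band], w1)
        a2 = scale_allowance(kb.allowances[band], w2)
        g1 = allocate(a1, similac, ketonex).commercial_grams
        g2 = allocate(a2, similac, ketonex).commercial_grams
        assert g2 >= g1 - 1e-9


def test_scale_invariance_of_rounding(kb):
    """Doubling weight and scoop size together leaves scoop counts fixed."""
    rng = random.Random(11)
    big_cfg = KBConfig(scoop_grams=10.0)
    for _ in range(50):
        band = rng.randint(1, 6)
        w = rng.uniform(2, 7)
        cname = rng.choice(kb.formula_names("commercial"))
        mname = rng.choice(kb.formula_names("medical"))
        commercial, medical = kb.lookup_formula(cname), kb.lookup_formula(mname)
        a1 = scale_allowance(kb.allowances[band], w)
        a2 = scale_allowance(kb.allowances[band], 2 * w)
        p1 = discretize(allocate(a1, commercial, medical), a1, commercial, medical, kb.config)
        p2 = discretize(allocate(a2, commercial, medical), a2, commercial, medical, big_cfg)
        assert (p1.commercial_scoops, p1.medical_scoops) == (p2.commercial_scoops, p2.medical_scoops)


def test_medical_only_conservation_over_random_patients(kb, default_tree):
    rng = random.Random(17)
    for _ in range(50):
        profile, panel = random_patient(rng)
        mname = rng.choice(kb.formula_names("medical"))
        plan, _, _, _, _ = _plan_for(kb, default_tree, profile, panel, None, mname)
        assert plan.delivered.leucine == 0.0
        assert plan.delivered.isoleucine == 0.0
        assert plan.delivered.valine == 0.0
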