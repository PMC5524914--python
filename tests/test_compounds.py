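import math

import numpy as np
import pytest

from zonpbpk.compounds import (
    EXCRETION_TARGETS,
    builtin_cocktail,
    compute_partition_coefficients,
    dose_in_amount,
    load_compounds,
    serialize_compounds,
)
from zonpbpk.partition import load_tissue_composition, partition_coefficient
from zonpbpk.simulator import DoseEvent, simulate


class TestBuiltinCocktail:
    def test_nine_models(self, cocktail):
        assert len(cocktail) == 9
        parents = {n for n, m in cocktail.items() if m.dose_per_kg is not None}
        assert parents == {
            "caffeine", "midazolam", "torsemide", "codeine", "talinolol", "pravastatin",
        }

    def test_caffeine_physicochemistry(self, cocktail):
        caffeine = cocktail["caffeine"]
        assert caffeine.dose_per_kg == 5.0
        assert caffeine.fraction_unbound == 0.85
        assert caffeine.molecular_weight == 194.19

    def test_midazolam_mm_branches(self, cocktail):
        mid = cocktail["midazolam"]
        b1 = mid.clearance("CYP3A_1OH")
        b4 = mid.clearance("CYP3A_4OH")
        assert (b1.k_cat, b1.k_m) == (80.82, 0.95)
        assert (b4.k_cat, b4.k_m) == (28.73, 8.43)

    def test_metabolites_carry_no_dose(self, cocktail):
        for name in ("paraxanthine", "1-hydroxymidazolam", "hydroxytorsemide"):
            assert cocktail[name].is_metabolite

    def test_caffeine_routes_27_percent_to_paraxanthine(self, cocktail):
        (link,) = cocktail["caffeine"].metabolite_links
        assert link.metabolite == "paraxanthine"
        assert link.fraction_of_clearance == 0.27
        assert link.via == "CYP1A"

    def test_zonation_flags(self, cocktail):
        for name in ("caffeine", "midazolam", "torsemide"):
            assert cocktail[name].zonated
        for name in ("codeine", "talinolol", "pravastatin"):
            assert not cocktail[name].zonated
        assert cocktail["caffeine"].pericentral_fraction == 0.56
        assert cocktail["midazolam"].pericentral_fraction == 0.47
        assert cocktail["torsemide"].pericentral_fraction == 0.48

    def test_pravastatin_has_three_routes(self, cocktail):
        kinds = {c.kind for c in cocktail["pravastatin"].clearances}
        assert kinds == {"linear_hepatic", "linear_biliary", "linear_renal"}

    def test_roundtrip_serialization(self, cocktail):
        models = list(cocktail.values())
        text = serialize_compounds(models)
        back = load_compounds(text)
        assert back == models


class TestDoseInAmount:
    @pytest.mark.parametrize(
        "name,expected",
        [("caffeine", 5 * 0.025 / 194.19 * 1000), ("pravastatin", 20 * 0.025 / 424.53 * 1000)],
    )
    def test_unit_arithmetic(self, cocktail, name, expected):
        assert math.isclose(dose_in_amount(cocktail[name], 0.025), expected, rel_tol=1e-12)

    def test_rejects_metabolite(self, cocktail):
        with pytest.raises(ValueError, match="metabolite"):
            dose_in_amount(cocktail["paraxanthine"], 0.025)

    def test_rejects_zero_body_weight(self, cocktail):
        with pytest.raises(ValueError, match="body_weight"):
            dose_in_amount(cocktail["caffeine"], 0.0)


class TestPartitionCoefficients:
    def test_lipophilicity_monotonicity_in_fat(self, phys, cocktail):
        from dataclasses import replace

        base = cocktail["codeine"]
        low = compute_partition_coefficients(replace(base, log_lipophilicity=1.0), phys)
        high = compute_partition_coefficients(replace(base, log_lipophilicity=3.0), phys)
        assert high["adipose"] > low["adipose"]

    def test_override_contract(self, phys, cocktail):
        kps = compute_partition_coefficients(
            cocktail["caffeine"], phys, overrides={"liver": 2.0}
        )
        assert kps["liver"] == 2.0

    def test_blood_pools_are_unity(self, phys, cocktail):
        kps = compute_partition_coefficients(cocktail["caffeine"], phys)
        assert kps["venous_blood"] == 1.0 and kps["arterial_blood"] == 1.0

    def test_against_handcoded_formula(self, phys, cocktail):
        """Independent re-derivation of the tissue-composition formula."""
        caffeine = cocktail["caffeine"]
        table = load_tissue_composition()
        kps = compute_partition_coefficients(caffeine, phys)
        p = 10 ** (-0.07)
        fu = 0.85
        fut = 1 / (1 + 0.5 * (1 - fu) / fu)
        for organ in ("liver", "muscle", "adipose", "kidney", "brain"):
            tc, pl = table[organ], table["plasma"]
            num = p * (tc["neutral_lipid"] + 0.3 * tc["phospholipid"]) + (
                tc["water"] + 0.7 * tc["phospholipid"]
            )
            den = p * (pl["neutral_lipid"] + 0.3 * pl["phospholipid"]) + (
                pl["water"] + 0.7 * pl["phospholipid"]
            )
            assert math.isclose(kps[organ], num / den * fu / fut, rel_tol=1e-9)

    def test_missing_physicochemistry_named(self, phys, cocktail):
        from dataclasses import replace

        broken = replace(cocktail["caffeine"], log_lipophilicity=None)
        with pytest.raises(ValueError, match="log_lipophilicity"):
            compute_partition_coefficients(broken, phys)


class TestLiverDamageScaling:
    def test_scales_hepatic_but_not_renal(self, cocktail):
        damaged = cocktail["caffeine"].with_liver_damage(0.9)
        assert math.isclose(damaged.clearance("CYP1A").abundance, 0.1)
        assert math.isclose(damaged.clearance("other_hepatic").abundance, 0.1)
        assert damaged.clearance("renal").abundance == 1.0

    def test_rejects_damage_outside_unit_interval(self, cocktail):
        with pytest.raises(ValueError):
            cocktail["caffeine"].with_liver_damage(1.5)


class TestExcretionFractions:
    """48-h simulations recover the unchanged-urine shares used in calibration."""

    FAMILIES = {
        "caffeine": ("caffeine", "paraxanthine"),
        "torsemide": ("torsemide", "hydroxytorsemide"),
        "codeine": ("codeine",),
        "talinolol": ("talinolol",),
        "pravastatin": ("pravastatin",),
    }

    @pytest.mark.parametrize("parent", sorted(EXCRETION_TARGETS))
    def test_urinary_share_within_three_points(self, phys, cocktail, parent):
        members = [cocktail[n] for n in self.FAMILIES[parent]]
        dose = DoseEvent(parent, 0.0, dose_in_amount(cocktail[parent], phys.body_weight))
        res = simulate(phys, members, [dose], horizon=2880.0, grid=5.0)
        urine = res.amount(parent, "urine")[-1]
        remaining = (
            res.amounts[parent][: res.compartments[parent].index("urine")].sum(axis=0)[-1]
        )
        eliminated = dose.amount - remaining
        share = urine / eliminated
        assert abs(share - EXCRETION_TARGETS[parent]) <= 0.03

    def test_calibration_is_body_weight_invariant(self):
        from zonpbpk.physiology import build_default_physiology

        a = builtin_cocktail(build_default_physiology(0.020))
        b = builtin_cocktail(build_default_physiology(0.030))
        for ma, mb in zip(a, b):
            for ca, cb in zip(ma.clearances, mb.clearances):
                if ca.rate is not None:
                    assert math.isclose(ca.rate, cb.rate, rel_tol=1e-9)
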