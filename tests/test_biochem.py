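"""Biochemical calculators: exact formula oracles and degree-1 homogeneity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phycotox.biochem import (
    DBI_WEIGHTS,
    FattyAcidProfile,
    KineticTrace,
    cellular_energy_allocation,
    dbi,
    mda_concentration,
    slope_activity,
    sod_activity,
)

TIMES = np.arange(0.0, 301.0, 15.0)


def linear_trace(slope_per_min, assay="APX", start=1.0, protein=1.0, noise=0.0, seed=0):
    y = start + slope_per_min / 60.0 * TIMES
    if noise:
        y = y + noise * np.random.default_rng(seed).standard_normal(TIMES.size)
    return KineticTrace("s", "0", assay, TIMES, y, protein_mg=protein)


class TestSlopeActivity:
    def test_apx_printed_extinction_example(self):
        """slope 0.0028 a.u./min at epsilon 2.8 mM^-1 cm^-1, 1 mg protein ->
        0.001 umol min^-1 mg^-1."""
        act = slope_activity(linear_trace(-0.0028))
        assert act.activity == pytest.approx(0.001, rel=1e-6)

    def test_zero_slope_gives_zero_activity(self):
        act = slope_activity(linear_trace(0.0))
        assert act.activity == 0.0

    def test_wrong_sign_slope_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="opposite"):
            act = slope_activity(linear_trace(+0.0028))
        assert act.activity == 0.0
        assert "wrong slope sign" in act.flags

    def test_cat_uses_molar_extinction_in_mm_units(self):
        # CAT: 39.4 M^-1 cm^-1 = 0.0394 mM^-1 cm^-1
        act = slope_activity(linear_trace(-0.00394, assay="CAT"))
        assert act.activity == pytest.approx(0.1, rel=1e-6)

    def test_protein_normalization_divides(self):
        act = slope_activity(linear_trace(-0.0028, protein=2.0))
        assert act.activity == pytest.approx(0.0005, rel=1e-6)

    def test_noisy_slope_recovery_median_error_below_three_percent(self):
        """100 seeds; Gaussian trace noise with sd = 1% of the absorbance change."""
        true = 0.001
        errs = []
        for seed in range(100):
            d_abs = abs(-0.0028 / 60.0) * TIMES[-1]
            act = slope_activity(linear_trace(-0.0028, noise=0.01 * d_abs, seed=seed))
            errs.append(abs(act.activity - true) / true)
        assert np.median(errs) < 0.03


class TestSod:
    def test_equal_slopes_give_zero_inhibition(self):
        act = sod_activity(linear_trace(0.006, "SOD"), linear_trace(0.006, "SOD"))
        assert act.inhibition_percent == pytest.approx(0.0, abs=1e-9)
        assert act.activity == pytest.approx(0.0, abs=1e-9)

    def test_half_blank_slope_is_one_unit(self):
        act = sod_activity(linear_trace(0.003, "SOD"), linear_trace(0.006, "SOD"))
        assert act.inhibition_percent == pytest.approx(50.0)
        assert act.activity == pytest.approx(1.0)

    def test_nonpositive_blank_rejected(self):
        with pytest.raises(ValueError, match="autoxidation blank"):
            sod_activity(linear_trace(0.003, "SOD"), linear_trace(-0.001, "SOD"))

    def test_imposed_inhibition_recovered_under_noise(self):
        vals = []
        for seed in range(100):
            blank = linear_trace(0.0060, "SOD", noise=3e-4, seed=2 * seed)
            samp = linear_trace(0.0042, "SOD", noise=3e-4, seed=2 * seed + 1)
            vals.append(sod_activity(samp, blank).inhibition_percent)
        assert np.mean(vals) == pytest.approx(30.0, abs=3.0)


class TestMda:
    def test_printed_extinction_example(self):
        res = mda_concentration(0.775, 0.0)
        assert res.mda_um == pytest.approx(5.0, rel=1e-9)

    def test_equal_absorbances_give_zero(self):
        assert mda_concentration(0.3, 0.3).mda_um == 0.0

    def test_negative_corrected_absorbance_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="negative"):
            res = mda_concentration(0.1, 0.2)
        assert res.mda_um == 0.0

    def test_formula_inversion_round_trip(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            target_um = rng.uniform(0.1, 50.0)
            a532 = target_um / 1000.0 * 155.0 + 0.05
            res = mda_concentration(a532, 0.05, mass_fw_g=0.2, extract_volume_ml=2.0)
            assert res.mda_um == pytest.approx(target_um, rel=1e-12)
            assert res.mda_nmol_per_g_fw == pytest.approx(target_um * 2.0 / 0.2)


def profile(percents, bonds, **kw):
    return FattyAcidProfile("s", "0", percents, bonds, **kw)


class TestDbi:
    def test_all_saturated_is_zero(self):
        assert dbi(profile({"16:0": 100.0}, {"16:0": 0}))["dbi"] == 0.0

    def test_all_monoenes_weighted_two_as_printed(self):
        assert dbi(profile({"18:1": 100.0}, {"18:1": 1}))["dbi"] == pytest.approx(2.0)

    def test_dienes_plus_pentaenes_arithmetic(self):
        p = profile({"18:2": 50.0, "22:5": 50.0}, {"18:2": 2, "22:5": 5})
        assert dbi(p)["dbi"] == pytest.approx(3.5)

    def test_classic_convention_weights_monoenes_once(self):
        p = profile({"18:1": 100.0}, {"18:1": 1})
        assert dbi(p, convention="classic")["dbi"] == pytest.approx(1.0)

    def test_matches_species_by_species_brute_force(self):
        percents = {"16:0": 30.0, "16:1n-7": 5.0, "18:1": 15.0, "18:2": 10.0,
                    "18:3": 25.0, "18:4": 10.0, "22:5": 5.0}
        bonds = {"16:0": 0, "16:1n-7": 1, "18:1": 1, "18:2": 2, "18:3": 3,
                 "18:4": 4, "22:5": 5}
        weights = DBI_WEIGHTS["paper"]
        classes = {0: "saturated", 1: "monoene", 2: "diene", 3: "triene",
                   4: "tetraene", 5: "pentaene"}
        brute = sum(weights[classes[bonds[sp]]] * pct
                    for sp, pct in percents.items()) / 100.0
        assert dbi(profile(percents, bonds))["dbi"] == pytest.approx(brute, rel=1e-12)

    def test_unclassified_species_with_mass_raises_naming_it(self):
        with pytest.raises(ValueError, match="18:1"):
            dbi(profile({"16:0": 50.0, "18:1": 50.0}, {"16:0": 0}))

    def test_percentages_must_sum_to_hundred(self):
        with pytest.raises(ValueError, match="sum"):
            profile({"16:0": 50.0}, {"16:0": 0})

    def test_saturation_ratios(self):
        p = profile({"16:0": 40.0, "18:1": 20.0, "18:3": 40.0},
                    {"16:0": 0, "18:1": 1, "18:3": 3})
        r = dbi(p)
        assert r["sfa_ufa"] == pytest.approx(40.0 / 60.0)
        assert r["pufa_sfa"] == pytest.approx(40.0 / 40.0)


class TestEnergyBudget:
    def test_one_microgram_each_fraction_gives_81_mj(self):
        b = cellular_energy_allocation(0.001, 0.001, 0.001, 2.0)
        assert b.Ea_mj_per_mg_fw == pytest.approx(81.0)

    def test_two_micromol_formazan_gives_480_mj(self):
        b = cellular_energy_allocation(0.0, 0.0, 0.0, 2.0)
        assert b.Ec_mj_per_mg_fw == pytest.approx(480.0)

    def test_cea_is_ratio(self):
        b = cellular_energy_allocation(960.0 / 17_500.0, 0.0, 0.0, 4.0)
        assert b.Ea_mj_per_mg_fw == pytest.approx(960.0)
        assert b.Ec_mj_per_mg_fw == pytest.approx(960.0)
        assert b.cea == pytest.approx(1.0)

    def test_zero_consumption_gives_nan_cea_with_warning(self):
        with pytest.warns(UserWarning, match="Ec = 0"):
            b = cellular_energy_allocation(0.001, 0.001, 0.001, 0.0)
        assert np.isnan(b.cea)


class TestHomogeneity:
    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=25, deadline=None)
    def test_doubling_signals_doubles_outputs(self, k):
        a1 = slope_activity(linear_trace(-0.004)).activity
        ak = slope_activity(linear_trace(-0.004 * k)).activity
        assert ak == pytest.approx(k * a1, rel=1e-9)
        m1 = mda_concentration(0.5, 0.1).mda_um
        mk = mda_concentration(0.1 + 0.4 * k, 0.1).mda_um
        assert mk == pytest.approx(k * m1, rel=1e-9)
        e1 = cellular_energy_allocation(0.01, 0.01, 0.01, 1.0)
        ek = cellular_energy_allocation(0.01 * k, 0.01 * k, 0.01 * k, k)
        assert ek.Ea_mj_per_mg_fw == pytest.approx(k * e1.Ea_mj_per_mg_fw, rel=1e-9)
        assert ek.Ec_mj_per_mg_fw == pytest.approx(k * e1.Ec_mj_per_mg_fw, rel=1e-9)
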