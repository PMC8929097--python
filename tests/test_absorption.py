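"""Lumen transit/dissolution/absorption model against closed-form oracles."""

from dataclasses import replace

import numpy as np
import pytest

import acatpk as ap
from acatpk.absorption import simulate_oral_dose
from acatpk.params import GICompartment, GIPhysiology

from _helpers import cat_chain


@pytest.fixture(scope="module")
def solution_drug(drug):
    """Gemcitabine-like compound with effectively unlimited solubility."""
    return replace(drug, solubility=1e6)


class TestRateLaws:
    def test_dissolution_zero_cases(self, drug):
        assert ap.dissolution_rate(0.0, 0.0, drug, 250.0) == 0.0
        assert ap.dissolution_rate(100.0, drug.solubility, drug, 250.0) == 0.0

    def test_dissolution_unit_analysis_oracle(self, drug):
        # (3·D/(ρ·r²))·m·(Cs−C): 3·0.93e-5 cm²/s / (1200 mg/mL · (2.5e-3 cm)²)
        # = 3.72e-3 /s per (mg/mL) → ×100 mg ×5.01 mg/mL ×3600 = 6709.392 mg/h
        rate = ap.dissolution_rate(100.0, 0.0, drug, 250.0)
        assert rate == pytest.approx(6709.392, rel=1e-9)

    def test_precipitation_below_saturation_is_zero(self):
        assert ap.precipitation_rate(5.0, 5.01, 250.0, 900.0) == 0.0

    def test_precipitation_excess_over_time_constant(self):
        # (6 − 5.01) mg/mL · 250 mL / 0.25 h = 990 mg/h
        assert ap.precipitation_rate(6.0, 5.01, 250.0, 900.0) == pytest.approx(990.0)

    def test_precipitation_inverse_in_time_constant(self):
        r1 = ap.precipitation_rate(6.0, 5.01, 250.0, 900.0)
        r2 = ap.precipitation_rate(6.0, 5.01, 250.0, 1800.0)
        assert r1 == pytest.approx(2.0 * r2)

    def test_absorption_rate_constant_arithmetic(self, drug):
        comp = GICompartment("jejunum", 100.0, 1.75, 1.0, 6.5, 1.0)
        # 2 · 0.59e-4 cm/s · 3600 / 1.75 cm = 0.24274 1/h
        assert ap.absorption_rate_constant(drug, comp) == pytest.approx(
            0.242743, rel=1e-5
        )

    def test_absorption_scales(self, drug):
        comp = GICompartment("c", 100.0, 1.75, 1.0, 6.5, 0.0)
        assert ap.absorption_rate_constant(drug, comp) == 0.0
        comp1 = replace(comp, absorption_scale_factor=1.0)
        doubled = replace(drug, peff_jejunal=2 * drug.peff_jejunal)
        assert ap.absorption_rate_constant(doubled, comp1) == pytest.approx(
            2 * ap.absorption_rate_constant(drug, comp1)
        )


class TestSimulateOralDose:
    def test_no_permeability_means_no_absorption(self, drug, physiology):
        inert = replace(drug, peff_jejunal=0.0)
        res = simulate_oral_dose(inert, physiology, 1000.0, 250.0, sim_duration=150.0)
        assert res.fa == pytest.approx(0.0, abs=1e-9)
        # over a long horizon the whole dose transits out of the tract
        assert res.trajectory.excreted[-1] == pytest.approx(1000.0, rel=1e-3)

    def test_fast_dissolution_high_permeability_absorbs_everything(
        self, drug, physiology
    ):
        greedy = replace(drug, particle_radius=1.0, peff_jejunal=1e-2, solubility=1e3)
        res = simulate_oral_dose(greedy, physiology, 1000.0, 250.0)
        assert res.fa > 0.99

    @pytest.mark.parametrize("n_si", [1, 3, 7])
    @pytest.mark.parametrize("ka_t", [0.1, 1.0, 10.0])
    def test_transit_limit_matches_cat_closed_form(self, solution_drug, n_si, ka_t):
        # pre-dissolved drug, negligible gastric residence, no colonic
        # absorption: Fa = 1 − (1 + ka·T/n)^(−n)
        total_t = 3.32
        ka = ka_t / total_t
        phys = cat_chain(n_si, total_t, ka, solution_drug.peff_jejunal)
        res = simulate_oral_dose(
            solution_drug, phys, 1000.0, 250.0, dissolved=True
        )
        fa_closed = 1.0 - (1.0 + ka * total_t / n_si) ** (-n_si)
        assert res.fa == pytest.approx(fa_closed, rel=5e-3)

    def test_mass_balance_on_reference_dose(self, drug, physiology):
        res = simulate_oral_dose(drug, physiology, 1000.0, 250.0)
        assert res.trajectory.mass_balance_error() < 1e-3 * 1000.0
        assert res.per_compartment_absorbed.sum() == pytest.approx(
            res.fa * 1000.0, rel=1e-9
        )
        assert res.fa >= res.fdp >= res.f

    def test_fa_monotone_in_permeability_solubility_and_transit(
        self, drug, physiology
    ):
        fa_peff = [
            simulate_oral_dose(
                replace(drug, peff_jejunal=p), physiology, 1500.0, 250.0
            ).fa
            for p in (0.2e-4, 0.59e-4, 2e-4)
        ]
        assert fa_peff == sorted(fa_peff)

        fa_sol = [
            simulate_oral_dose(
                replace(drug, solubility=s), physiology, 1500.0, 250.0
            ).fa
            for s in (1.0, 5.01, 50.0)
        ]
        assert fa_sol == sorted(fa_sol)

        def stretch(phys, factor):
            comps = [
                replace(c, mean_transit_time=c.mean_transit_time * factor)
                if c.name in phys.small_intestine_names
                else c
                for c in phys.compartments
            ]
            return GIPhysiology(tuple(comps), phys.small_intestine_names)

        fa_transit = [
            simulate_oral_dose(drug, stretch(physiology, f), 1500.0, 250.0).fa
            for f in (0.5, 1.0, 2.0)
        ]
        assert fa_transit == sorted(fa_transit)

    def test_higher_dose_hits_solubility_limit(self, drug, physiology):
        # 1500 mg in 250 mL (6 mg/mL) exceeds Cs = 5.01 mg/mL; 1000 mg does not
        fa_1000 = simulate_oral_dose(drug, physiology, 1000.0, 250.0).fa
        fa_1500 = simulate_oral_dose(drug, physiology, 1500.0, 250.0).fa
        assert fa_1500 < fa_1000


class TestRegionalAbsorption:
    def test_fractions_sum_to_one(self, drug, physiology):
        res = simulate_oral_dose(drug, physiology, 1000.0, 250.0)
        frac = ap.regional_absorption_fractions(res)
        assert frac["fraction_of_absorbed"].sum() == pytest.approx(1.0, abs=1e-9)
        assert frac["percent_of_dose"].sum() == pytest.approx(100.0 * res.fa, rel=1e-9)

    def test_single_absorbing_compartment_takes_everything(self, solution_drug):
        phys = cat_chain(1, 3.32, 1.0, solution_drug.peff_jejunal)
        res = simulate_oral_dose(solution_drug, phys, 100.0, 250.0, dissolved=True)
        frac = ap.regional_absorption_fractions(res)
        assert frac.loc["si1", "fraction_of_absorbed"] == pytest.approx(1.0)

    def test_equal_chain_absorbs_monotonically_less_downstream(self, solution_drug):
        phys = cat_chain(7, 3.32, 1.0 / 3.32, solution_drug.peff_jejunal)
        res = simulate_oral_dose(solution_drug, phys, 100.0, 250.0, dissolved=True)
        frac = ap.regional_absorption_fractions(res)["fraction_of_absorbed"]
        si = frac[[f"si{i + 1}" for i in range(7)]].to_numpy()
        assert np.all(np.diff(si) < 0)

    def test_undefined_without_absorption(self, drug, physiology):
        inert = replace(drug, peff_jejunal=0.0)
        res = simulate_oral_dose(inert, physiology, 100.0, 250.0)
        with pytest.raises(ap.ValidationError):
            ap.regional_absorption_fractions(res)


class TestCalibration:
    def test_fixed_point_returns_unit_multiplier(self, drug, physiology):
        fa0 = simulate_oral_dose(drug, physiology, 1000.0, 250.0).fa
        _, info = ap.calibrate_asf(fa0, drug, physiology, 1000.0, 250.0)
        assert info["colon_multiplier"] == pytest.approx(1.0, abs=5e-3)
        assert info["global_multiplier"] == 1.0

    def test_calibrated_study_anchor(self, study):
        info = study.calibration
        assert info["achieved_fa"] == pytest.approx(0.68026, abs=1e-3)
        assert 0.0 < info["colon_multiplier"] < 1.0

    def test_multiplier_monotone_in_target(self, drug, physiology):
        _, lo = ap.calibrate_asf(0.65, drug, physiology, 1000.0, 250.0)
        _, hi = ap.calibrate_asf(0.75, drug, physiology, 1000.0, 250.0)
        assert lo["colon_multiplier"] < hi["colon_multiplier"]

    def test_unreachable_target_reports_range(self, drug, physiology):
        with pytest.raises(ap.CalibrationError, match="attainable range"):
            ap.calibrate_asf(0.05, drug, physiology, 1000.0, 250.0)
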