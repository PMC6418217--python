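"""Porosity, diffusivity, the steady-state solver and the zone inversion."""

import numpy as np
import pytest

from glacierlake import synth
from glacierlake.sediment import (MicroProfile, SECTION_VOLUME_CM3,
                                  SedimentSection, fit_consumption_zones,
                                  fit_fixed_zones, o2_free_diffusivity,
                                  porosity, sediment_diffusivity,
                                  solve_steady_profile)


class TestPorosity:
    def test_half_filled_slice(self):
        """29.04 g water in a 58.09 cm³ slice (8.6 cm tube) -> phi 0.500."""
        assert SECTION_VOLUME_CM3 == pytest.approx(58.088, abs=0.01)
        s = SedimentSection("c", 0, 1, wet_g=40.0, dry_g=40.0 - 29.045)
        assert porosity(s) == pytest.approx(0.500, abs=1e-3)

    def test_bounds(self):
        assert porosity(SedimentSection("c", 0, 1, 30.0, 30.0)) == 0.0
        assert porosity(SedimentSection("c", 0, 1, 60.0, 60.0 - 58.088)) == \
            pytest.approx(1.0, abs=1e-3)

    def test_dry_exceeds_wet_rejected(self):
        with pytest.raises(ValueError):
            SedimentSection("c", 0, 1, 10.0, 11.0)


class TestDiffusivity:
    @pytest.mark.parametrize("phi, expected_factor", [
        (1.0, 1.0),      # no tortuosity
        (0.75, 1 / 1.75),
        (0.0, 0.25),     # limiting case
    ])
    def test_tortuosity_formula(self, phi, expected_factor):
        assert sediment_diffusivity(1.0e-5, phi) == pytest.approx(
            1.0e-5 * expected_factor)

    def test_domain(self):
        with pytest.raises(ValueError):
            sediment_diffusivity(1e-5, 1.2)

    def test_d0_table_monotone(self):
        temps = np.linspace(0, 25, 11)
        d0s = [o2_free_diffusivity(t) for t in temps]
        assert np.all(np.diff(d0s) > 0)


class TestForwardSolver:
    def test_zero_consumption_is_linear(self):
        z = np.linspace(0, 1, 501)
        c, ft, fb = solve_steady_profile(z, np.full_like(z, 1e-5), [0, 1],
                                         [0.0], bc="conc-conc",
                                         c_top=300.0, c_bottom=100.0)
        assert np.allclose(c, 300.0 - 200.0 * z, atol=1e-9)
        assert ft == pytest.approx(fb)

    def test_single_zone_closed_form(self):
        """C(z) = R (L - z)² / (2 phi Ds); C(0) = 0.5 µmol/L for the stated
        unit parameters."""
        z = np.linspace(0, 1, 1001)
        w = np.full_like(z, 1e-5)
        c, ft, fb = solve_steady_profile(z, w, [0, 1], [1e-5], bc="bottomzero")
        assert c[0] == pytest.approx(0.5, rel=1e-6)
        assert np.allclose(c, 1e-5 * (1 - z) ** 2 / (2e-5), rtol=1e-5, atol=1e-9)
        assert ft == pytest.approx(1e-5)   # SWI flux equals integrated rate
        assert fb == pytest.approx(0.0, abs=1e-15)

    def test_two_zone_against_refined_grid_oracle(self):
        bounds, rates = np.array([0.0, 1.5, 3.0]), np.array([1.5e-3, 3e-4])
        z = np.linspace(0, 3.0, 301)
        zf = np.linspace(0, 3.0, 3001)
        w, wf = np.full_like(z, 9.6e-6), np.full_like(zf, 9.6e-6)
        c, *_ = solve_steady_profile(z, w, bounds, rates)
        cf, *_ = solve_steady_profile(zf, wf, bounds, rates)
        interp = np.interp(z, zf, cf)
        assert np.max(np.abs(c - interp)) / np.max(np.abs(cf)) < 1e-6

    def test_flux_conservation(self):
        """Flux in minus flux out equals depth-integrated consumption."""
        bounds, rates = np.array([0.0, 1.0, 2.5]), np.array([2e-3, 5e-4])
        z = np.linspace(0, 2.5, 1001)
        w = np.full_like(z, 8e-6)
        _, ft, fb = solve_steady_profile(z, w, bounds, rates, bc="conc-conc",
                                         c_top=350.0, c_bottom=20.0)
        integrated = 1.0 * 2e-3 + 1.5 * 5e-4
        assert ft - fb == pytest.approx(integrated, rel=1e-9)

    def test_bad_bc(self):
        z = np.linspace(0, 1, 11)
        with pytest.raises(ValueError):
            solve_steady_profile(z, np.full_like(z, 1e-5), [0, 1], [0.0],
                                 bc="conc-conc")


class TestInversion:
    def test_noiseless_single_zone_reduces_and_recovers(self):
        cfg = synth.ScenarioConfig(sediment_noise_umolL=0.0,
                                   sediment_zone_boundaries_mm=(0.0, 30.0),
                                   sediment_rates=(9e-4,))
        profile, truth = synth.gen_o2_profile(cfg)
        model = fit_consumption_zones(profile, max_zones=4)
        assert model.n_zones == 1
        assert abs(model.rates[0] - 9e-4) / 9e-4 <= 1e-3

    def test_zero_consumption_profile(self):
        """A linear (here flat-zero) profile fits zero rates in one zone."""
        cfg = synth.ScenarioConfig(sediment_noise_umolL=0.0,
                                   sediment_zone_boundaries_mm=(0.0, 30.0),
                                   sediment_rates=(0.0,))
        profile, _ = synth.gen_o2_profile(cfg)
        model = fit_consumption_zones(profile, max_zones=3)
        assert model.n_zones == 1
        assert model.rates[0] == pytest.approx(0.0, abs=1e-12)

    def test_conc_conc_recovery(self):
        cfg = synth.ScenarioConfig(sediment_noise_umolL=0.0)
        profile, truth = synth.gen_o2_profile(cfg)
        model = fit_fixed_zones(profile, 2, bc="conc-conc")
        assert np.allclose(model.rates, truth.rates, rtol=5e-3)

    def test_integrated_rate_equals_swi_flux(self):
        cfg = synth.ScenarioConfig(seed=11)
        profile, _ = synth.gen_o2_profile(cfg, np.random.default_rng(11))
        model = fit_fixed_zones(profile, 2)
        assert model.integrated_rate == pytest.approx(
            model.swi_flux - model.bottom_flux, rel=1e-2)

    def test_grid_refinement_stability(self):
        cfg = synth.ScenarioConfig(seed=12)
        profile, _ = synth.gen_o2_profile(cfg, np.random.default_rng(12))
        coarse = fit_fixed_zones(profile, 2, grid_per_mm=10)
        fine = fit_fixed_zones(profile, 2, grid_per_mm=20)
        assert np.all(np.abs(fine.rates - coarse.rates)
                      / np.abs(coarse.rates) < 5e-3)

    def test_penetration_depth_decreases_with_rate(self):
        """More consumption under fixed boundary O2 -> shallower penetration."""
        z = np.linspace(0, 6.0, 2001)
        w = np.full_like(z, 9.6e-6)
        depths = []
        for rate in [2e-4, 5e-4, 1e-3, 2e-3]:
            c, *_ = solve_steady_profile(z, w, [0, 6.0], [rate],
                                         bc="conc-conc", c_top=300.0,
                                         c_bottom=0.0)
            below = np.flatnonzero(c <= 0.0)
            depths.append(z[below[0]] if below.size else 6.0)
        assert all(a >= b for a, b in zip(depths, depths[1:]))
        assert depths[0] > depths[-1]

    def test_seasonal_contrast_qualitative(self):
        """Higher bottom-water O2 (summer mixing) supports an
        order-of-magnitude larger depth-integrated consumption."""
        summer = synth.ScenarioConfig(sediment_noise_umolL=0.0)
        spring = synth.ScenarioConfig(sediment_noise_umolL=0.0,
                                      sediment_rates=(1.3e-4, 3e-5))
        fits = {}
        for name, cfg in (("summer", summer), ("spring", spring)):
            profile, _ = synth.gen_o2_profile(cfg)
            fits[name] = (profile.c_umolL[0],
                          fit_fixed_zones(profile, 2).integrated_rate)
        assert fits["summer"][0] > fits["spring"][0]       # more bottom O2
        assert fits["summer"][1] > 5 * fits["spring"][1]   # much faster sink
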