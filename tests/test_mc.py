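"""Monte Carlo transport: interface physics, budgets, determinism."""
import math
from dataclasses import replace

import numpy as np
import pytest

from oildrop.grid import SpectralGrid, TrophicScenario
from oildrop.mc import (
    LayeredMedium,
    Layer,
    Scenario,
    fresnel_reflectance,
    mix_iops,
    sample_surface_slope,
    simulate_rrs,
)
from oildrop.phase import default_angle_grid, isotropic
from oildrop.water import build_water_iops


class TestFresnel:
    def test_normal_incidence_closed_form(self):
        r = fresnel_reflectance(0.0, 1.34)
        assert r == pytest.approx((0.34 / 2.34) ** 2, rel=1e-12)

    def test_grazing_incidence_total(self):
        assert fresnel_reflectance(90.0, 1.34) == pytest.approx(1.0)

    def test_total_internal_reflection_beyond_critical_angle(self):
        critical = math.degrees(math.asin(1 / 1.34))
        assert fresnel_reflectance(critical + 0.5, 1 / 1.34) == 1.0
        assert fresnel_reflectance(critical - 0.5, 1 / 1.34) < 1.0

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            fresnel_reflectance(-1.0, 1.34)
        with pytest.raises(ValueError):
            fresnel_reflectance(10.0, 0.0)


class TestCoxMunk:
    def test_calm_sea_variance_anchor(self):
        rng = np.random.default_rng(5)
        s = sample_surface_slope(0.0, rng, 200_000)
        var = (s**2).sum(axis=1).mean()
        assert var == pytest.approx(0.003, rel=0.02)

    def test_gentle_wind_variance(self):
        rng = np.random.default_rng(6)
        n = 1_000_000
        s = sample_surface_slope(5.0, rng, n)
        var = (s**2).sum(axis=1).mean()
        expected = 0.003 + 0.00512 * 5.0
        # chi^2-ish sampling error on the variance estimate
        tol = 3 * expected * math.sqrt(2.0 / n)
        assert abs(var - expected) <= tol

    def test_fixed_seed_reproducible(self):
        a = sample_surface_slope(5.0, np.random.default_rng(7), 10)
        b = sample_surface_slope(5.0, np.random.default_rng(7), 10)
        assert np.array_equal(a, b)


class TestMixIops:
    def test_oil_absent_single_layer_with_water_iops(self, oligotrophic_water):
        med = mix_iops(oligotrophic_water, None, Scenario())
        assert len(med.layers) == 1
        lay = med.layers[0]
        assert np.array_equal(lay.a, oligotrophic_water.a_tot)
        assert np.array_equal(lay.b, oligotrophic_water.b_tot)
        assert lay.z_bot == 1000.0

    def test_top_layer_adds_oil_iops(self, oligotrophic_water, ci_grid):
        from oildrop.mie import polydisperse_iops
        from oildrop.oils import make_oil_index, make_psd

        oil = polydisperse_iops(make_oil_index("CL", ci_grid), make_psd("CL"), ci_grid)
        med = mix_iops(oligotrophic_water, oil, Scenario(oil_ppm=2.0))
        top, deep = med.layers
        assert np.allclose(top.a, oligotrophic_water.a_tot + 2.0 * oil.a_oil)
        assert np.allclose(top.b, oligotrophic_water.b_tot + 2.0 * oil.b_oil)
        assert top.z_bot == 30.0 and deep.z_bot == 1000.0
        assert np.array_equal(deep.a, oligotrophic_water.a_tot)

    def test_zero_ppm_identical_to_absent(self, oligotrophic_water, ci_grid):
        from oildrop.mie import polydisperse_iops
        from oildrop.oils import make_oil_index, make_psd

        oil = polydisperse_iops(make_oil_index("CL", ci_grid), make_psd("CL"), ci_grid)
        med0 = mix_iops(oligotrophic_water, oil, Scenario(oil_ppm=0.0))
        med_none = mix_iops(oligotrophic_water, None, Scenario())
        assert len(med0.layers) == 1
        assert np.array_equal(med0.layers[0].a, med_none.layers[0].a)

    def test_grid_mismatch_rejected(self, oligotrophic_water):
        from oildrop.mie import OilIOPs

        other = SpectralGrid(np.array([500.0]))
        oil = OilIOPs(other, np.zeros(1), np.ones(1),
                      [isotropic(default_angle_grid())], 1.0)
        with pytest.raises(ValueError):
            mix_iops(oligotrophic_water, oil, Scenario())


def absorber_medium(grid, a=0.2, b=0.0, depth=1000.0):
    ang = default_angle_grid()
    nw = len(grid)
    return LayeredMedium(
        grid=grid,
        layers=[
            Layer(
                z_top=0.0, z_bot=depth,
                a=np.full(nw, a),
                b_water=np.full(nw, b),
                b_oil=np.zeros(nw),
                pf_water=[isotropic(ang)] * nw,
            )
        ],
    )


class TestSimulateRrs:
    def test_pure_absorber_reflects_nothing(self):
        grid = SpectralGrid(np.array([550.0]))
        sc = Scenario(n_photons=20_000, seed=1)
        res = simulate_rrs(sc, absorber_medium(grid))
        assert res.rrs[0] == 0.0
        total = res.budget["absorbed_column"] + res.budget["surface_lost"]
        assert total[0] == pytest.approx(1.0, abs=1e-9)

    def test_budget_sums_to_one(self, oligotrophic_water):
        sc = Scenario(n_photons=50_000, seed=2)
        res = simulate_rrs(sc, mix_iops(oligotrophic_water, None, sc))
        total = sum(res.budget.values())
        assert np.allclose(total, 1.0, atol=1e-6)

    def test_seed_determinism_bit_for_bit(self, oligotrophic_water):
        sc = Scenario(n_photons=30_000, seed=9)
        med = mix_iops(oligotrophic_water, None, sc)
        r1 = simulate_rrs(sc, med)
        r2 = simulate_rrs(sc, med)
        assert np.array_equal(r1.rrs, r2.rrs)
        assert np.array_equal(r1.stderr, r2.stderr)
        for key in r1.budget:
            assert np.array_equal(r1.budget[key], r2.budget[key])
        r3 = simulate_rrs(replace(sc, seed=10), med)
        assert not np.array_equal(r1.rrs, r3.rrs)

    def test_stderr_positive_for_scattering_medium(self, oligotrophic_water):
        sc = Scenario(n_photons=100_000, seed=3)
        res = simulate_rrs(sc, mix_iops(oligotrophic_water, None, sc))
        assert np.all(res.stderr > 0)

    def test_single_scattering_irradiance_oracle(self):
        """Homogeneous ocean, flat surface: E_u/E_d at 0- matches the
        classic f * b_b/(a + b_b) closed form with f = 0.33 within 35%."""
        grid = SpectralGrid(np.array([550.0]))
        ang = default_angle_grid()
        a, b = 0.1, 0.05
        med = LayeredMedium(
            grid=grid,
            layers=[Layer(0.0, 1000.0, np.array([a]), np.array([b]),
                          np.zeros(1), [isotropic(ang)])],
        )
        sc = Scenario(n_photons=200_000, seed=4, wind_speed=0.0, sun_zenith=30.0)
        res = simulate_rrs(sc, med)
        b_b = 0.5 * b  # isotropic phase function backscatters half
        expected = 0.33 * b_b / (a + b_b)
        assert res.eu_ed_ratio[0] == pytest.approx(expected, rel=0.35)

    def test_weakly_absorbing_scattering_oil_brightens_red(
        self, oligotrophic_water, ci_grid
    ):
        """Added scattering with negligible absorption cannot darken the
        red band, where water absorption dominates."""
        from oildrop.mie import polydisperse_iops
        from oildrop.oils import make_oil_index, make_psd

        oil = polydisperse_iops(make_oil_index("CL", ci_grid), make_psd("CL"), ci_grid)
        sc = Scenario(n_photons=150_000, seed=5, receiver_half_angle=15.0)
        nat = simulate_rrs(sc, mix_iops(oligotrophic_water, None, sc))
        pol = simulate_rrs(sc, mix_iops(oligotrophic_water, oil, sc))
        i = ci_grid.index_of(670)
        assert pol.rrs[i] > nat.rrs[i] - 3 * (pol.stderr[i] + nat.stderr[i])

    def test_zero_photons_rejected(self):
        with pytest.raises(ValueError):
            Scenario(n_photons=0)

    def test_nonfinite_iops_rejected(self):
        grid = SpectralGrid(np.array([550.0]))
        med = absorber_medium(grid, a=np.nan)
        with pytest.raises(FloatingPointError):
            simulate_rrs(Scenario(n_photons=10), med)


class TestScenarioValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(bottom_mirror=1.5),
            dict(bottom_diffuse=-0.1),
            dict(mixed_layer_depth=2000.0),
            dict(ocean_depth=-1.0),
            dict(sun_zenith=95.0),
            dict(wind_speed=-1.0),
            dict(oil_ppm=-0.5),
        ],
    )
    def test_invalid_scenarios_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Scenario(**kwargs)

    def test_layers_must_be_contiguous(self):
        grid = SpectralGrid(np.array([550.0]))
        ang = default_angle_grid()
        lay = Layer(5.0, 1000.0, np.ones(1), np.ones(1), np.zeros(1),
                    [isotropic(ang)])
        with pytest.raises(ValueError):
            LayeredMedium(grid=grid, layers=[lay])
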