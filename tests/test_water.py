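"""Case-1 water model: component spectra, additivity, phase functions."""
import numpy as np
import pytest

from oildrop.grid import DEFAULT_WAVELENGTHS, NAMED_BANDS, SpectralGrid, TrophicScenario
from oildrop.water import (
    DEFAULT_CONFIG,
    build_water_iops,
    cdom_absorption,
    particle_absorption,
    particle_scattering,
    pure_water_absorption,
    pure_water_scattering,
    water_phase_function,
)


class TestSpectralGrid:
    def test_default_grid_has_27_bands_including_all_named(self):
        g = SpectralGrid()
        assert len(g) == 27
        for band in NAMED_BANDS:
            assert band in g.wavelengths

    @pytest.mark.parametrize(
        "wl", [[500.0, 450.0], [399.0, 500.0], [500.0, 701.0], [500.0, 500.0]]
    )
    def test_invalid_grids_rejected(self, wl):
        with pytest.raises(ValueError):
            SpectralGrid(np.array(wl))

    def test_nearest_band_lookup_within_tolerance(self):
        g = SpectralGrid()
        assert g.wavelengths[g.index_of(443)] == 443
        assert g.wavelengths[g.index_of(412)] == 410  # 2 nm away
        with pytest.raises(KeyError):
            g.index_of(528)  # nearest default bands are 7+ nm away

    def test_trophic_classification_thresholds(self):
        assert TrophicScenario(0.05).trophic_class == "oligotrophic"
        assert TrophicScenario(0.1).trophic_class == "oligotrophic"
        assert TrophicScenario(1.0).trophic_class == "mesotrophic"
        assert TrophicScenario(1.68).trophic_class == "eutrophic"
        with pytest.raises(ValueError):
            TrophicScenario(0.0)


class TestPureWater:
    def test_absorption_identity_at_table_nodes(self):
        g = SpectralGrid(np.array([440.0, 550.0, 700.0]))
        a = pure_water_absorption(g)
        assert a == pytest.approx([0.00635, 0.0565, 0.624])

    def test_absorption_linear_interpolation_at_midpoint(self):
        # midpoint between the 440 and 445 nodes
        g = SpectralGrid(np.array([442.5]))
        a = pure_water_absorption(g)
        assert a[0] == pytest.approx(0.5 * (0.00635 + 0.00751))

    def test_red_absorbs_far_more_than_blue(self):
        g = SpectralGrid(np.array([440.0, 700.0]))
        a = pure_water_absorption(g)
        assert a[1] > a[0]

    def test_scattering_power_law_anchor_and_ratio(self):
        cfg = DEFAULT_CONFIG
        g = SpectralGrid(np.array([400.0, cfg.bw_ref_wavelength, 700.0]))
        b = pure_water_scattering(g)
        assert b[1] == pytest.approx(cfg.bw_ref)
        assert b[0] > b[2]  # blue-enhanced
        assert b[0] / b[2] == pytest.approx((700.0 / 400.0) ** cfg.bw_gamma)


class TestChlComponents:
    def test_zero_chlorophyll_gives_zero_constituents(self):
        g = SpectralGrid()
        assert np.all(particle_absorption(g, 0.0) == 0)
        assert np.all(cdom_absorption(g, 0.0) == 0)
        assert np.all(particle_scattering(g, 0.0) == 0)

    def test_negative_chlorophyll_rejected(self):
        g = SpectralGrid()
        for fn in (particle_absorption, cdom_absorption, particle_scattering):
            with pytest.raises(ValueError):
                fn(g, -1.0)

    def test_particle_absorption_power_law_closed_form(self):
        g = SpectralGrid(np.array([440.0]))
        a10 = particle_absorption(g, 10.0)[0]
        a01 = particle_absorption(g, 0.1)[0]
        # E(440) = 0.65 in the embedded table
        assert a10 / a01 == pytest.approx(100.0**0.65)

    def test_unit_chlorophyll_returns_coefficient_table(self):
        g = SpectralGrid(np.array([440.0]))
        assert particle_absorption(g, 1.0)[0] == pytest.approx(0.06)

    def test_cdom_exponential_ratio_closed_form(self):
        g = SpectralGrid(np.array([440.0, 540.0]))
        a = cdom_absorption(g, 1.0)
        assert a[1] / a[0] == pytest.approx(np.exp(-0.014 * 100.0))
        # at the reference band: f_c * a_p(440)
        assert a[0] == pytest.approx(0.2 * particle_absorption(g, 1.0)[0])

    def test_particle_scattering_anchor_and_chl_scaling(self):
        cfg = DEFAULT_CONFIG
        g = SpectralGrid(np.array([cfg.bp_ref_wavelength]))
        assert particle_scattering(g, 1.0)[0] == pytest.approx(cfg.bp_coeff)
        ratio = particle_scattering(g, 10.0)[0] / particle_scattering(g, 0.1)[0]
        assert ratio == pytest.approx(100.0**cfg.bp_exponent)

    def test_particle_scattering_blue_enhanced_in_clear_water(self):
        g = SpectralGrid(np.array([440.0, 670.0]))
        b = particle_scattering(g, 0.1)
        assert b[0] > b[1]
        # spectrally flat once chl >= 2 (Morel update)
        b_eu = particle_scattering(g, 10.0)
        assert b_eu[0] == pytest.approx(b_eu[1])

    @pytest.mark.parametrize("chl", [0.1, 1.0, 10.0])
    def test_monotone_increase_with_chl(self, chl):
        g = SpectralGrid()
        for fn in (particle_absorption, cdom_absorption, particle_scattering):
            low = fn(g, chl)
            high = fn(g, chl * 1.5)
            assert np.all(high > low)


class TestPhaseFunctionMixture:
    @pytest.mark.parametrize("chl", [0.1, 1.0, 10.0])
    @pytest.mark.parametrize("wl", [440.0, 555.0, 670.0])
    def test_normalization(self, chl, wl):
        pf = water_phase_function(chl, wl)
        assert abs(pf.integral() - 1.0) <= 1e-3

    def test_low_chl_limit_approaches_pure_seawater_shape(self):
        from oildrop.phase import default_angle_grid, rayleigh_seawater

        pf = water_phase_function(1e-6, 555.0)
        ray = rayleigh_seawater(default_angle_grid())
        # particle scattering vanishes ~ chl^0.766; outside the residual
        # forward spike the mixture collapses onto the pure-seawater shape
        side = pf.angles > 30.0
        assert np.allclose(pf.values[side], ray.values[side], rtol=2e-2)
        assert pf.backscatter_fraction() == pytest.approx(
            ray.backscatter_fraction(), rel=2e-2
        )

    def test_forward_scattering_grows_with_chl(self):
        f = [
            water_phase_function(chl, 555.0).forward_fraction(20.0)
            for chl in (0.1, 1.0, 10.0)
        ]
        assert f[0] < f[1] < f[2]

    def test_nonpositive_chl_rejected(self):
        with pytest.raises(ValueError):
            water_phase_function(0.0, 555.0)


class TestBuildWaterIOPs:
    def test_additivity_is_exact(self):
        w = build_water_iops(TrophicScenario(0.1))
        assert np.array_equal(w.a_tot, w.a_water + w.a_particle + w.a_cdom)
        assert np.array_equal(w.b_tot, w.b_water + w.b_particle)

    def test_all_spectra_nonnegative(self):
        w = build_water_iops(TrophicScenario(10.0))
        for spec in (w.a_water, w.a_particle, w.a_cdom, w.b_water, w.b_particle):
            assert np.all(spec >= 0)

    def test_particle_absorption_spectral_ordering_follows_table(self):
        # A(440)/A(670) = 1/0.595 in the embedded shape, any chl
        g = SpectralGrid(np.array([440.0, 670.0]))
        w = build_water_iops(TrophicScenario(10.0), g)
        assert w.a_particle[0] / w.a_particle[1] == pytest.approx(
            0.06 / 0.0357, rel=1e-6
        )

    def test_total_scattering_ordered_by_trophic_state(self):
        specs = [
            build_water_iops(TrophicScenario(chl)).b_tot for chl in (0.1, 1.0, 10.0)
        ]
        assert np.all(specs[2] > specs[1]) and np.all(specs[1] > specs[0])

    def test_default_grid_matches_module_default(self):
        w = build_water_iops(TrophicScenario(1.0))
        assert np.array_equal(w.grid.wavelengths, np.asarray(DEFAULT_WAVELENGTHS))
        assert len(w.pf) == 27
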