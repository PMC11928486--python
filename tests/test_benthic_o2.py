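import numpy as np
import pytest

import benthox as bx
from benthox.benthic_o2 import _build_grid
from benthox.scenarios import make_scenario

from _oracles import (
    bvp_steady_profile,
    dark_steady_profile_quadrature,
    lsoda_diel_interface,
)
from conftest import FAST


class TestSaturationConcentration:
    def test_linear_in_ppo2(self):
        half = bx.saturation_concentration(12.0, 35.0, 50.0)
        full = bx.saturation_concentration(12.0, 35.0, 100.0)
        assert half == pytest.approx(full / 2, rel=1e-12)

    def test_decreasing_in_temperature_and_salinity(self):
        temps = np.linspace(-2, 60, 40)
        sols = [bx.saturation_concentration(t, 35.0, 100.0) for t in temps]
        assert np.all(np.diff(sols) < 0)
        assert bx.saturation_concentration(10, 0, 100) > bx.saturation_concentration(10, 35, 100)

    def test_matches_published_seawater_solubility(self):
        # 10 degC, 35 PSU seawater at modern atmosphere: 281.9 uM
        # (6.315 mL/L, classical air-saturation tables)
        assert bx.saturation_concentration(10.0, 35.0, 100.0) == pytest.approx(281.9, rel=0.01)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            bx.saturation_concentration(75.0, 35.0, 100.0)
        with pytest.raises(ValueError):
            bx.saturation_concentration(10.0, 35.0, 0.0)


class TestDiffusivity:
    def test_increasing_in_temperature_and_positive(self):
        temps = np.linspace(-2, 60, 40)
        ds = [bx.diffusivity(t, 35.0) for t in temps]
        assert np.all(np.diff(ds) > 0)
        assert min(ds) > 0

    def test_matches_literature_at_20C(self):
        # O2 in water near 20 degC: ~2.1e-5 cm2/s
        assert bx.diffusivity(20.0, 35.0) / 3600.0 == pytest.approx(2.1e-5, rel=0.10)


class TestLocalRates:
    def test_production_zero_in_dark_and_in_dbl(self):
        sc = make_scenario("warm")
        dark_t = 0.6 * sc.day_length  # inside the dark phase
        assert bx.production_rate(0.05, dark_t, sc) == 0.0
        assert bx.production_rate(-0.02, 1.0, sc) == 0.0

    def test_production_q10_ratio_exact(self):
        sc0 = make_scenario(None, temperature=5.0)
        sc1 = make_scenario(None, temperature=15.0)
        r = bx.production_rate(0.03, 1.0, sc1) / bx.production_rate(0.03, 1.0, sc0)
        assert r == pytest.approx(sc0.q10_production, rel=1e-12)

    def test_respiration_limits_and_toc_scaling(self):
        sc = make_scenario("warm")
        assert bx.respiration_rate(0.05, 0.0, sc) == 0.0
        half = bx.respiration_rate(0.05, sc.k_o2, sc)
        sat = bx.respiration_rate(0.05, 1e9, sc)
        assert half == pytest.approx(sat / 2, rel=1e-6)
        lo = make_scenario("warm", c_oc=0.1)
        assert bx.respiration_rate(0.05, 10.0, sc) == pytest.approx(
            10 * bx.respiration_rate(0.05, 10.0, lo), rel=1e-12
        )
        with pytest.raises(ValueError):
            bx.respiration_rate(0.05, -1.0, sc)


class TestGrid:
    def test_layers_resolve_at_least_five_cells(self):
        for gs in (0.025, 0.05, 0.1):
            sc = make_scenario("warm", grid_spacing=gs)
            w, centres, g, n_dbl = _build_grid(sc)
            assert n_dbl >= 5
            assert (centres > 0).sum() >= 5
            assert w.sum() == pytest.approx(sc.dbl_thickness + sc.sediment_depth)

    def test_interface_cell_is_topmost_sediment_cell(self, warm_field):
        i = warm_field.depth_index(0.0)
        assert warm_field.depths[i] > 0
        assert warm_field.depths[i - 1] < 0


class TestSimulateDiel:
    def test_pure_diffusion_relaxes_to_saturation(self):
        sc = make_scenario("warm", p_max_ref=0.0, r_max_ref=0.0)
        f = bx.simulate_diel(sc, **FAST)
        assert np.max(np.abs(f.concentration - f.saturation)) < 1e-3 * f.saturation

    def test_nonnegative_everywhere(self, cold_field, warm_field):
        for f in (cold_field, warm_field):
            assert f.concentration.min() >= 0.0

    def test_top_boundary_dirichlet_under_refinement(self):
        # the Dirichlet condition is imposed at the top *face*; the top cell
        # centre deviates from saturation by the half-cell flux offset, which
        # must vanish linearly as the DBL grid refines
        devs = []
        for gs in (0.01, 0.0025):
            sc = make_scenario("warm", grid_spacing=gs)
            f = bx.simulate_diel(sc, n_cycles=1, spinup_cycles=3, dt=0.005,
                                 points_per_cycle=100)
            devs.append(np.max(np.abs(f.concentration[0] - f.saturation)))
        assert devs[1] < devs[0]
        # 4x refinement shrinks the offset ~4x (first order in cell width)
        assert devs[0] / devs[1] == pytest.approx(4.0, rel=0.25)

    def test_mass_balance_audit_closes(self, warm_field):
        a = warm_field.audit
        terms = [a["influx"], a["production"], a["respiration"]]
        residual = a["inventory_change"] - (
            a["influx"] + a["production"] - a["respiration"] - a["clamped"]
        )
        assert abs(residual) < 0.01 * max(abs(t) for t in terms)
        assert a["clamped"] == 0.0

    def test_diel_limit_cycle_reached(self, cold_field, warm_field):
        for f in (cold_field, warm_field):
            ppc = (f.times.size - 1) // 2
            c1 = f.concentration[:, 1:ppc + 1]
            c2 = f.concentration[:, ppc + 1:]
            assert np.max(np.abs(c1 - c2)) < 0.005 * f.saturation

    def test_anoxia_hours_nondecreasing_in_toc(self):
        hours = []
        for c_oc in (0.1, 0.3, 1.0):
            sc = make_scenario(None, temperature=20.0, c_oc=c_oc)
            f = bx.simulate_diel(sc, **FAST)
            t, s = bx.interface_series(f)
            m = bx.compute_diel_metrics(t, s)[-1]
            hours.append(m.anoxia_hours)
        assert all(b >= a - 0.01 for a, b in zip(hours, hours[1:])), hours
        assert hours[-1] > hours[0]

    def test_validation(self):
        with pytest.raises(ValueError):
            bx.simulate_diel(make_scenario("warm"), n_cycles=0)
        with pytest.raises(ValueError):
            bx.simulate_diel(make_scenario("warm"), n_cycles=1, points_per_cycle=10)


class TestSteadyProfile:
    def test_lit_above_dark_everywhere(self):
        sc = make_scenario("warm", grid_spacing=0.05)
        z, lit = bx.steady_profile(sc, lit=True)
        _, dark = bx.steady_profile(sc, lit=False)
        assert np.all(lit >= dark - 1e-9)

    def test_lit_warm_has_subsurface_maximum_above_saturation(self):
        sc = make_scenario("warm")
        z, c = bx.steady_profile(sc, lit=True)
        csat = bx.saturation_concentration(sc.temperature, sc.salinity, sc.ppo2)
        assert c.max() > csat
        assert z[np.argmax(c)] > 0

    def test_dark_profile_monotone_nonincreasing(self):
        sc = make_scenario("warm")
        _, c = bx.steady_profile(sc, lit=False)
        assert np.all(np.diff(c) < 1e-9)

    def test_no_sinks_gives_uniform_saturation(self):
        sc = make_scenario("warm", r_max_ref=0.0)
        _, c = bx.steady_profile(sc, lit=False)
        csat = bx.saturation_concentration(sc.temperature, sc.salinity, sc.ppo2)
        np.testing.assert_allclose(c, csat, rtol=1e-6)

    @pytest.mark.parametrize("temperature", [5.0, 15.0, 25.0])
    @pytest.mark.parametrize("c_oc", [0.1, 0.4, 0.8])
    def test_agrees_with_independent_oracles(self, temperature, c_oc):
        """Steady profiles match a collocation BVP solve (lit) and a
        first-integral quadrature (dark) to < 1% RMS on a 3x3 (T, c_oc) grid."""
        sc = make_scenario(None, temperature=temperature, c_oc=c_oc,
                           grid_spacing=0.002)
        w, centres, _, _ = _build_grid(sc)
        edges = -sc.dbl_thickness + np.concatenate([[0.0], np.cumsum(w)])
        for lit, oracle_fn in ((False, dark_steady_profile_quadrature),
                               (True, lambda s: bvp_steady_profile(s, lit=True))):
            z, c = bx.steady_profile(sc, lit=lit)
            oracle = oracle_fn(sc)
            # finite volumes carry cell averages; average the oracle likewise
            ref = np.array([
                np.mean(oracle(np.linspace(a, b, 17)))
                for a, b in zip(edges[:-1], edges[1:])
            ])
            rms = np.sqrt(np.mean((c - ref) ** 2))
            scale = np.sqrt(np.mean(ref**2))
            assert rms < 0.01 * scale, (temperature, c_oc, lit)


class TestTimeIntegrationOracle:
    def test_interface_series_matches_lsoda(self):
        """The backward-Euler stepper reproduces an adaptive stiff solver's
        diel interface trace on the same spatial grid to < 1% RMS."""
        sc = make_scenario("cold", grid_spacing=0.05)
        f = bx.simulate_diel(sc, n_cycles=1, spinup_cycles=2, dt=0.0025,
                             points_per_cycle=100)
        t_ref, s_ref = lsoda_diel_interface(sc, n_cycles=1, spinup_cycles=2,
                                            points_per_cycle=100)
        t, s = bx.interface_series(f)
        s_interp = np.interp(t_ref, t, s)
        rms = np.sqrt(np.mean((s_interp - s_ref) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(s_ref**2))
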