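import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from benthox.ecoevo import (
    GFunctionParams,
    SpeciesSpec,
    carrying_capacity,
    competition_run,
    cost_sweep,
    detect_outcomes,
    fitness_gradient,
    forcing_for_mode,
    g_function,
    simulate_ecoevo,
)
from benthox.scenarios import ForcingConfig, ForcingSeries


P = GFunctionParams()


def constant_forcing(value, n_steps=400):
    return ForcingSeries(times=np.arange(n_steps, dtype=float),
                         gamma=np.full(n_steps, float(value)))


def single_species(s=1.0, x0=5.0, u0=0.0, d=0.0):
    return GFunctionParams(d=d, species=(SpeciesSpec("solo", s=s, x0=x0, u0=u0),))


class TestCarryingCapacity:
    def test_peak_width_and_symmetry(self):
        assert carrying_capacity(0.3, 0.3, P) == P.k_m
        assert carrying_capacity(P.sigma_k, 0.0, P) == pytest.approx(
            P.k_m * np.exp(-0.5), rel=1e-12
        )
        for delta in (0.1, 1.0, 2.7):
            assert carrying_capacity(delta, 0.0, P) == pytest.approx(
                carrying_capacity(-delta, 0.0, P), rel=1e-12
            )


class TestGFunction:
    def test_hand_computed_value(self):
        # r=0.25, K(v)=100 at v=gamma, total x=50, cost d*s=0.01:
        # G = 0.25*(1 - 50/100) - 0.01 = 0.115
        params = GFunctionParams(r=0.25, k_m=100.0, d=0.01)
        g = g_function(v=0.0, u=[0.0, 0.0], x=[20.0, 30.0], gamma=0.0,
                       params=params, s=1.0)
        assert g == pytest.approx(0.115, abs=1e-12)

    def test_logistic_equilibrium_and_low_density_limits(self):
        params = GFunctionParams(d=0.0)
        assert g_function(0.0, [0.0], [params.k_m], 0.0, params, s=1.0) == pytest.approx(0.0)
        assert g_function(0.0, [0.0], [0.0], 0.0, params, s=1.0) == pytest.approx(params.r)


class TestFitnessGradient:
    def test_zero_at_optimum_and_at_zero_density(self):
        assert fitness_gradient(0.7, [10.0, 5.0], 0.7, P) == 0.0
        assert fitness_gradient(1.5, [0.0, 0.0], 0.0, P) == 0.0

    def test_points_toward_optimum(self):
        assert fitness_gradient(1.0, [50.0], 0.0, P) < 0
        assert fitness_gradient(-1.0, [50.0], 0.0, P) > 0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        v=st.floats(-2.0, 2.0),
        gamma=st.floats(-2.0, 2.0),
        x1=st.floats(0.0, 200.0),
        x2=st.floats(0.0, 200.0),
        sigma=st.floats(0.5, 2.0),
    )
    def test_matches_numerical_differentiation(self, v, gamma, x1, x2, sigma):
        """Closed-form dG/dv equals a central difference of the G function to
        1e-6 relative accuracy across the biological parameter region."""
        params = GFunctionParams(sigma_k=sigma, d=0.03)
        grad = fitness_gradient(v, [x1, x2], gamma, params)
        h = 1e-5 * sigma
        num = (
            g_function(v + h, [v, v], [x1, x2], gamma, params, s=1.0)
            - g_function(v - h, [v, v], [x1, x2], gamma, params, s=1.0)
        ) / (2 * h)
        assert grad == pytest.approx(num, rel=1e-6, abs=1e-8)


class TestSimulateEcoevo:
    def test_single_species_logistic_limit(self):
        params = single_species(s=1.0, x0=5.0, u0=0.3)
        traj = simulate_ecoevo(params, constant_forcing(0.3))
        assert traj.x[-1, 0] == pytest.approx(params.k_m, rel=1e-3)
        assert np.allclose(traj.u[:, 0], 0.3, atol=1e-9)

    @pytest.mark.parametrize("d", [0.01, 0.05, 0.1, 0.2])
    @pytest.mark.parametrize("s", [0.2, 0.5, 1.0, 2.0])
    def test_costly_sensing_equilibrium(self, d, s):
        """Single-species steady state recovers x* = K_m (1 - d s / r)."""
        params = single_species(s=s, x0=10.0, u0=0.0, d=d)
        traj = simulate_ecoevo(params, constant_forcing(0.0, n_steps=600))
        expected = params.k_m * (1 - d * s / params.r)
        if expected > 0:
            assert traj.x[-1, 0] == pytest.approx(expected, rel=1e-3)
        else:
            # cost exceeds the intrinsic growth rate: deterministic extinction
            assert traj.x[-1, 0] == 0.0

    def test_identical_species_stay_identical(self):
        params = GFunctionParams(species=(
            SpeciesSpec("a", s=1.0, x0=20.0, u0=0.4),
            SpeciesSpec("b", s=1.0, x0=20.0, u0=0.4),
        ))
        forcing = forcing_for_mode("combined", seed=5)
        traj = simulate_ecoevo(params, forcing)
        assert np.max(np.abs(traj.x[:, 0] - traj.x[:, 1])) < 1e-10
        assert np.max(np.abs(traj.u[:, 0] - traj.u[:, 1])) < 1e-10

    def test_strategy_tracking_speed_increases_with_sensing(self):
        half_lives = []
        for s in (0.5, 1.0, 2.0):
            params = single_species(s=s, x0=50.0, u0=1.0)
            traj = simulate_ecoevo(params, constant_forcing(0.0, n_steps=300))
            err = np.abs(traj.u[:, 0])
            assert np.all(np.diff(err) <= 1e-12)  # monotone approach to gamma
            half_lives.append(int(np.argmax(err < 0.5 * err[0])))
        assert half_lives[0] > half_lives[1] > half_lives[2]

    def test_bounded_for_long_runs_on_random_parameters(self, rng):
        """State stays finite over 1e5 steps with the extinction floor and
        strategy-velocity cap active, across randomised valid parameters."""
        n_steps = 100_000
        for _ in range(4):
            params = GFunctionParams(
                r=rng.uniform(0.05, 0.5),
                k_m=rng.uniform(20, 500),
                sigma_k=rng.uniform(0.3, 2.0),
                d=rng.uniform(0.0, 0.1),
                species=(
                    SpeciesSpec("pOSM", s=rng.uniform(0, 0.5), x0=rng.uniform(1, 50)),
                    SpeciesSpec("eOSM", s=rng.uniform(0.5, 4), x0=rng.uniform(1, 50)),
                ),
            )
            cfg = ForcingConfig(seed=int(rng.integers(2**31)))
            traj = simulate_ecoevo(params, forcing_for_mode("combined", seed=cfg.seed,
                                                            n_steps=n_steps, config=cfg))
            assert np.all(np.isfinite(traj.x)) and np.all(np.isfinite(traj.u))
            assert np.all(traj.x >= 0)

    def test_seed_reproducibility(self):
        a = competition_run("combined", seed=11)
        b = competition_run("combined", seed=11)
        c = competition_run("combined", seed=12)
        np.testing.assert_array_equal(a.x, b.x)
        assert not np.array_equal(a.x, c.x)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            simulate_ecoevo(P, constant_forcing(0.0), dt=0.0)


class TestDetectOutcomes:
    def _traj(self, x, params=None):
        x = np.asarray(x, dtype=float)
        T = x.shape[0]
        from benthox.ecoevo import EcoEvoTrajectory
        return EcoEvoTrajectory(
            times=np.arange(T, dtype=float),
            x=x,
            u=np.zeros_like(x),
            gamma=np.zeros(T - 1),
            params=params or P,
        )

    def test_extinction_step_located(self):
        x = np.full((400, 2), 50.0)
        x[312:, 1] = 0.0
        out = detect_outcomes(self._traj(x), extinction_floor=0.01)
        assert out.extinction_time == {"pOSM": None, "eOSM": 312}

    def test_equal_populations_never_dominate(self):
        x = np.full((100, 2), 30.0)
        out = detect_outcomes(self._traj(x))
        assert out.dominance_time is None and out.dominant is None

    def test_sustained_share_required(self):
        x = np.full((100, 2), 10.0)
        x[40:, 0] = 95.0
        x[40:, 1] = 1.0
        out = detect_outcomes(self._traj(x), dominance_share=0.9)
        assert out.dominant == "pOSM" and out.dominance_time == 40


class TestCostSweep:
    def test_costless_efficient_sensor_wins_everywhere(self):
        table = cost_sweep([0.0], "combined", replicates=5, base_seed=2)
        assert table.loc[0, "winner"] == "eOSM"
        assert table.loc[0, "win_fraction"] == 1.0

    def test_extreme_cost_flips_the_winner(self):
        table = cost_sweep([0.005, 0.12], "periodic_only", replicates=5, base_seed=2)
        assert table[table.d == 0.005]["winner"].item() == "eOSM"
        assert table[table.d == 0.12]["winner"].item() == "pOSM"

    def test_deterministic_given_base_seed(self):
        a = cost_sweep([0.01, 0.05], "stochastic_only", replicates=4, base_seed=9)
        b = cost_sweep([0.01, 0.05], "stochastic_only", replicates=4, base_seed=9)
        assert a.equals(b)

    def test_validation(self):
        with pytest.raises(ValueError):
            cost_sweep([], "combined")
        with pytest.raises(ValueError):
            cost_sweep([0.01], "sideways")
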