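"""G-function eco-evolutionary competition of oxygen-sensing strategies.

Two species (pOSM: poor oxygen sensing, eOSM: efficient oxygen sensing)
compete under Lotka--Volterra density dependence with a strategy-dependent
Gaussian carrying capacity centred on the environmental optimum gamma(t):

    dx_i/dt = x_i * G(v, u, x)|_{v=u_i}
    G(v, u, x) = (r / K(v)) [K(v) - sum_j x_j] - d * s
    K(v) = K_m exp[-(v - gamma)^2 / (2 sigma_k^2)]
    du_i/dt = s_i * dG/dv|_{v=u_i}

The strategy v is an abstract cellular-metabolism phenotype on an
anaerobic--aerobic continuum; s_i is the oxygen-sensing capacity (speed of
phenotype tracking) and d its linear per-capita fitness cost.  The species
are identical except for s (and therefore cost d*s), so any competitive
difference arises from tracking the fluctuating optimum.

Integration is fixed-step classical Runge-Kutta (dt = 0.1 pseudo-steps)
against gamma held constant within each integer pseudo-step.  Numerical
guards far outside the biological regime: the per-capita growth rate is
clipped to +/-25 per step (K(v) underflows when |v - gamma| >> sigma_k), the
strategy velocity is capped at 10 sigma_k per step, and populations below the
extinction floor are clamped to zero (absorbing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from numba import njit

from .scenarios import ForcingConfig, ForcingSeries, gamma_forcing

__all__ = [
    "SpeciesSpec",
    "GFunctionParams",
    "EcoEvoTrajectory",
    "Outcomes",
    "FORCING_MODES",
    "carrying_capacity",
    "g_function",
    "fitness_gradient",
    "forcing_for_mode",
    "simulate_ecoevo",
    "detect_outcomes",
    "competition_run",
    "cost_sweep",
]

_G_CLIP = 25.0          # |per-capita growth| bound (numerical guard)
_K_TINY = 1e-300


@dataclass(frozen=True)
class SpeciesSpec:
    """One competitor: sensing capacity s, initial population and strategy."""

    name: str
    s: float          # strategy change per unit fitness gradient per step
    x0: float = 25.0
    u0: float = 0.0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError(f"sensing capacity s must be >= 0 for {self.name}")
        if self.x0 < 0:
            raise ValueError(f"initial population x0 must be >= 0 for {self.name}")


@dataclass(frozen=True)
class GFunctionParams:
    """Parameters of the fitness-generating function and its competitors.

    Defaults are the shipped calibration: growth rate r = 0.25 per pseudo-step,
    K_m = 100, kernel width sigma_k = 1 strategy unit, sensing cost d = 0.015
    per unit s, and a 10x sensing-capacity contrast between eOSM and pOSM.
    """

    r: float = 0.25
    k_m: float = 100.0
    sigma_k: float = 1.0
    d: float = 0.015
    species: tuple[SpeciesSpec, ...] = (
        SpeciesSpec("pOSM", s=0.2),
        SpeciesSpec("eOSM", s=2.0),
    )

    def __post_init__(self) -> None:
        if self.r <= 0 or self.k_m <= 0 or self.sigma_k <= 0:
            raise ValueError("r, k_m and sigma_k must be > 0")
        if self.d < 0:
            raise ValueError("cost coefficient d must be >= 0")
        if len(self.species) < 1:
            raise ValueError("at least one species is required")
        names = [sp.name for sp in self.species]
        if len(set(names)) != len(names):
            raise ValueError("species names must be unique")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(sp.name for sp in self.species)


def carrying_capacity(v, gamma, params: GFunctionParams):
    """K(v) = K_m exp[-(v - gamma)^2 / (2 sigma_k^2)]."""
    v = np.asarray(v, dtype=float)
    dd = v - gamma
    out = params.k_m * np.exp(-(dd * dd) / (2.0 * params.sigma_k**2))
    return float(out) if out.ndim == 0 else out


def g_function(v, u, x, gamma, params: GFunctionParams, s: float):
    """Per-capita growth of a focal strategy v against residents (u, x).

    Competition uses the unweighted population sum: all individuals have the
    same adverse impact on each other regardless of strategy.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("populations must be >= 0")
    k = carrying_capacity(v, gamma, params)
    total = float(np.sum(x))
    return params.r / k * (k - total) - params.d * s


def fitness_gradient(v, x, gamma, params: GFunctionParams):
    """Closed form dG/dv = -r (sum_j x_j) (v - gamma) / (sigma_k^2 K(v)).

    Zero at v = gamma or when the total population is zero; points toward
    gamma otherwise.  When K(v) underflows the magnitude is capped (overflow
    guard; the integrator applies its own strategy-velocity cap on top).
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("populations must be >= 0")
    total = float(np.sum(x))
    dd = float(np.asarray(v, dtype=float)) - gamma
    if total == 0.0 or dd == 0.0:
        return 0.0
    k = carrying_capacity(v, gamma, params)
    if k < _K_TINY * params.k_m:
        return math.copysign(1e12, -dd)
    return -params.r * total * dd / (params.sigma_k**2 * k)


#: (amplitude, noise) post-switch multiplier selectors per forcing mode.
FORCING_MODES = ("stochastic_only", "periodic_only", "combined", "none")


def forcing_for_mode(
    mode: str,
    seed: int,
    n_steps: int = 1500,
    config: ForcingConfig | None = None,
) -> ForcingSeries:
    """gamma(t) with the flooding switch applied to noise, sinusoid, or both.

    ``stochastic_only`` multiplies only the noise SD after the switch,
    ``periodic_only`` only the sinusoid amplitude, ``combined`` both, and
    ``none`` leaves the forcing stationary.  The underlying noise stream
    depends only on the seed, so the pre-switch trajectory is identical
    across modes.
    """
    if mode not in FORCING_MODES:
        raise ValueError(f"mode must be one of {FORCING_MODES}")
    base = config or ForcingConfig()
    amp_m = base.amplitude_multiplier_post if mode in ("periodic_only", "combined") else 1.0
    noise_m = base.noise_multiplier_post if mode in ("stochastic_only", "combined") else 1.0
    cfg = replace(
        base,
        amplitude_multiplier_post=amp_m,
        noise_multiplier_post=noise_m,
        seed=int(seed),
    )
    return gamma_forcing(cfg, n_steps)


@njit(cache=True)
def _deriv(x, u, gam, r, km, sig2, d, s, cap, dx, du):
    total = 0.0
    n = x.size
    for i in range(n):
        total += x[i]
    for i in range(n):
        dd = u[i] - gam
        k = km * math.exp(-dd * dd / (2.0 * sig2))
        if k < 1e-300 * km or k == 0.0:
            g = -_G_CLIP
            grad_s = cap if dd < 0.0 else -cap
        else:
            g = r * (1.0 - total / k) - d * s[i]
            if g > _G_CLIP:
                g = _G_CLIP
            elif g < -_G_CLIP:
                g = -_G_CLIP
            grad_s = -s[i] * r * total * dd / (sig2 * k)
            if grad_s > cap:
                grad_s = cap
            elif grad_s < -cap:
                grad_s = -cap
        dx[i] = x[i] * g
        du[i] = grad_s


@njit(cache=True)
def _integrate_batch(x0, u0, s, d, gamma, r, km, sigma, dt, floor, cap,
                     out_x, out_u):
    """RK4-integrate a batch of 2-species systems against per-step gamma.

    Shapes: x0, u0, s -> (B, n); d -> (B,); gamma -> (B, T);
    out_x, out_u -> (B, T+1, n).
    """
    B, T = gamma.shape
    n = x0.shape[1]
    sig2 = sigma * sigma
    nsub = int(round(1.0 / dt))
    h = 1.0 / nsub
    k1x = np.empty(n); k1u = np.empty(n)
    k2x = np.empty(n); k2u = np.empty(n)
    k3x = np.empty(n); k3u = np.empty(n)
    k4x = np.empty(n); k4u = np.empty(n)
    tx = np.empty(n); tu = np.empty(n)
    for b in range(B):
        x = x0[b].copy()
        u = u0[b].copy()
        for i in range(n):
            out_x[b, 0, i] = x[i]
            out_u[b, 0, i] = u[i]
        for t in range(T):
            gam = gamma[b, t]
            for _ in range(nsub):
                _deriv(x, u, gam, r, km, sig2, d[b], s[b], cap, k1x, k1u)
                for i in range(n):
                    tx[i] = x[i] + 0.5 * h * k1x[i]
                    tu[i] = u[i] + 0.5 * h * k1u[i]
                _deriv(tx, tu, gam, r, km, sig2, d[b], s[b], cap, k2x, k2u)
                for i in range(n):
                    tx[i] = x[i] + 0.5 * h * k2x[i]
                    tu[i] = u[i] + 0.5 * h * k2u[i]
                _deriv(tx, tu, gam, r, km, sig2, d[b], s[b], cap, k3x, k3u)
                for i in range(n):
                    tx[i] = x[i] + h * k3x[i]
                    tu[i] = u[i] + h * k3u[i]
                _deriv(tx, tu, gam, r, km, sig2, d[b], s[b], cap, k4x, k4u)
                for i in range(n):
                    x[i] += h / 6.0 * (k1x[i] + 2.0 * k2x[i] + 2.0 * k3x[i] + k4x[i])
                    u[i] += h / 6.0 * (k1u[i] + 2.0 * k2u[i] + 2.0 * k3u[i] + k4u[i])
                    if x[i] < 0.0:
                        x[i] = 0.0
            for i in range(n):
                if x[i] < floor:
                    x[i] = 0.0
                out_x[b, t + 1, i] = x[i]
                out_u[b, t + 1, i] = u[i]


@dataclass(frozen=True)
class Outcomes:
    """Annotations of a competition run."""

    extinction_time: dict          # species name -> step or None
    dominance_time: int | None     # first step with sustained > share dominance
    dominant: str | None


@dataclass(frozen=True)
class EcoEvoTrajectory:
    """Population and strategy series of one competition run.

    ``x`` and ``u`` have shape (n_steps + 1, n_species); row t is the state
    after integrating through forcing value gamma(t-1) (row 0 is the initial
    state).  ``annotations`` are filled by :func:`detect_outcomes`.
    """

    times: np.ndarray
    x: np.ndarray
    u: np.ndarray
    gamma: np.ndarray
    params: GFunctionParams
    annotations: Outcomes | None = None

    def __post_init__(self) -> None:
        if self.x.shape != self.u.shape or self.x.shape[0] != self.times.size:
            raise ValueError("times, x and u have inconsistent shapes")
        if np.any(self.x < 0):
            raise ValueError("populations must be >= 0 at all times")

    def to_dataframe(self) -> pd.DataFrame:
        cols = {"t": self.times}
        cols["gamma"] = np.concatenate([[np.nan], self.gamma])
        for j, name in enumerate(self.params.names):
            cols[f"x_{name}"] = self.x[:, j]
        for j, name in enumerate(self.params.names):
            cols[f"u_{name}"] = self.u[:, j]
        return pd.DataFrame(cols)


def _default_floor(params: GFunctionParams) -> float:
    return 1e-4 * params.k_m


def simulate_ecoevo(
    params: GFunctionParams,
    forcing: ForcingSeries,
    dt: float = 0.1,
    extinction_floor: float | None = None,
    gradient_cap: float | None = None,
) -> EcoEvoTrajectory:
    """Integrate the coupled population/strategy dynamics against gamma(t).

    gamma is held constant within each integer pseudo-step; populations that
    fall below the extinction floor (default 1e-4 K_m) are clamped to zero.
    Deterministic given (params, forcing).
    """
    if dt <= 0 or dt > 1:
        raise ValueError("dt must be in (0, 1]")
    floor = _default_floor(params) if extinction_floor is None else extinction_floor
    cap = 10.0 * params.sigma_k if gradient_cap is None else gradient_cap
    n = len(params.species)
    T = len(forcing)
    x0 = np.array([[sp.x0 for sp in params.species]])
    u0 = np.array([[sp.u0 for sp in params.species]])
    s = np.array([[sp.s for sp in params.species]])
    d = np.array([params.d])
    gamma = np.asarray(forcing.gamma, dtype=float)[None, :]
    out_x = np.empty((1, T + 1, n))
    out_u = np.empty((1, T + 1, n))
    _integrate_batch(x0, u0, s, d, gamma, params.r, params.k_m, params.sigma_k,
                     dt, floor, cap, out_x, out_u)
    if not (np.all(np.isfinite(out_x)) and np.all(np.isfinite(out_u))):
        bad = np.argwhere(~np.isfinite(out_x))
        step = int(bad[0, 1]) if bad.size else -1
        raise FloatingPointError(f"non-finite state at pseudo-step {step}")
    traj = EcoEvoTrajectory(
        times=np.arange(T + 1, dtype=float),
        x=out_x[0],
        u=out_u[0],
        gamma=gamma[0],
        params=params,
    )
    ann = detect_outcomes(traj, extinction_floor=floor)
    return replace(traj, annotations=ann)


def detect_outcomes(
    trajectory: EcoEvoTrajectory,
    extinction_floor: float | None = None,
    dominance_share: float = 0.9,
) -> Outcomes:
    """Extinction and sustained-dominance annotations of a trajectory.

    extinction_time: first step index at and after which a species stays
    below the floor; dominance_time: first step after which one species'
    share of the total stays above ``dominance_share`` through the end.
    """
    floor = (
        _default_floor(trajectory.params)
        if extinction_floor is None
        else extinction_floor
    )
    x = trajectory.x
    names = trajectory.params.names
    ext: dict = {}
    for j, name in enumerate(names):
        below = x[:, j] < floor
        if below[-1]:
            # last index where the species was still at/above the floor
            above_idx = np.nonzero(~below)[0]
            ext[name] = int(above_idx[-1] + 1) if above_idx.size else 0
        else:
            ext[name] = None
    total = x.sum(axis=1)
    dom_time = None
    dominant = None
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, x.T / np.where(total > 0, total, 1.0), 0.0).T
    for j, name in enumerate(names):
        ok = (share[:, j] > dominance_share) & (total > 0)
        if ok[-1]:
            not_ok = np.nonzero(~ok)[0]
            start = int(not_ok[-1] + 1) if not_ok.size else 0
            if dom_time is None or start < dom_time:
                dom_time = start
                dominant = name
    return Outcomes(extinction_time=ext, dominance_time=dom_time, dominant=dominant)


def competition_run(
    mode: str,
    seed: int,
    params: GFunctionParams | None = None,
    n_steps: int = 1500,
    forcing_config: ForcingConfig | None = None,
    dt: float = 0.1,
) -> EcoEvoTrajectory:
    """Convenience wrapper: forcing for ``mode`` + simulate + annotate."""
    p = params or GFunctionParams()
    forcing = forcing_for_mode(mode, seed=seed, n_steps=n_steps, config=forcing_config)
    return simulate_ecoevo(p, forcing, dt=dt)


def _winner_index(x: np.ndarray, floor: float) -> int:
    """0/1 winner of a two-species run; -1 for an exact tie.

    The survivor wins; if both survive, the larger time-averaged population
    over the final quarter of the run wins; if both are extinct, the one that
    persisted longer wins.
    """
    alive = x[-1] >= floor
    if alive.sum() == 1:
        return int(np.argmax(alive))
    if alive.sum() == 0:
        last = [int(np.nonzero(x[:, j] >= floor)[0][-1]) if np.any(x[:, j] >= floor) else -1
                for j in range(x.shape[1])]
        if last[0] == last[1]:
            return -1
        return int(np.argmax(last))
    q = x.shape[0] // 4
    means = x[-q:].mean(axis=0)
    if means[0] == means[1]:
        return -1
    return int(np.argmax(means))


def cost_sweep(
    d_values,
    forcing_mode: str,
    replicates: int = 25,
    base_seed: int = 0,
    params: GFunctionParams | None = None,
    n_steps: int = 1000,
    forcing_config: ForcingConfig | None = None,
    dt: float = 0.1,
) -> pd.DataFrame:
    """Competition winners over a grid of sensing-cost coefficients d.

    Each competition is run in a *stationary* environment of the requested
    fluctuation type (the mode's post-switch multipliers applied from step 0),
    so the sweep characterises which strategy an environment favours rather
    than the transient switch experiment.  For each d, ``replicates`` runs
    with independent forcing seeds (shared across d values as common random
    numbers) are scored by :func:`_winner_index`; the majority winner and its
    win fraction are reported.  Deterministic for a fixed ``base_seed``.
    """
    d_values = np.asarray(list(d_values), dtype=float)
    if d_values.size == 0:
        raise ValueError("d_values must be non-empty")
    if np.any(d_values < 0):
        raise ValueError("cost coefficients must be >= 0")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    p = params or GFunctionParams()
    if len(p.species) != 2:
        raise ValueError("cost_sweep expects exactly two species")
    floor = _default_floor(p)
    cap = 10.0 * p.sigma_k

    base_cfg = forcing_config or ForcingConfig()
    stationary = replace(base_cfg, switch_time=0)
    rep_seeds = [
        int(np.random.SeedSequence([int(base_seed), rep]).generate_state(1)[0] % (2**31))
        for rep in range(replicates)
    ]
    gammas = np.stack(
        [
            forcing_for_mode(forcing_mode, seed=s, n_steps=n_steps, config=stationary).gamma
            for s in rep_seeds
        ]
    )  # (R, T)

    nd = d_values.size
    B = nd * replicates
    gamma_b = np.tile(gammas, (nd, 1))
    d_b = np.repeat(d_values, replicates)
    x0 = np.tile([[sp.x0 for sp in p.species]], (B, 1))
    u0 = np.tile([[sp.u0 for sp in p.species]], (B, 1))
    s_b = np.tile([[sp.s for sp in p.species]], (B, 1))
    out_x = np.empty((B, n_steps + 1, 2))
    out_u = np.empty((B, n_steps + 1, 2))
    _integrate_batch(x0, u0, s_b, d_b, gamma_b, p.r, p.k_m, p.sigma_k,
                     dt, floor, cap, out_x, out_u)

    names = p.names
    rows = []
    for a, d in enumerate(d_values):
        wins = np.zeros(2, dtype=int)
        for rep in range(replicates):
            wi = _winner_index(out_x[a * replicates + rep], floor)
            if wi >= 0:
                wins[wi] += 1
        maj = int(np.argmax(wins))
        rows.append(
            {
                "d": float(d),
                "winner": names[maj] if wins[maj] > 0 else "tie",
                "win_fraction": wins[maj] / replicates,
                f"wins_{names[0]}": int(wins[0]),
                f"wins_{names[1]}": int(wins[1]),
            }
        )
    return pd.DataFrame(rows)
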