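"""Independent oracles used by the test suite.

These deliberately avoid the package's own numerical paths: the steady
profile is recomputed as a two-point boundary-value problem with
``scipy.integrate.solve_bvp``, the diel time integration with the adaptive
LSODA method-of-lines driver, and the diel metrics with a brute-force dense
resampling scan.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_bvp, solve_ivp

from benthox.benthic_o2 import (
    _build_grid,
    diffusivity,
    saturation_concentration,
)


def _rates(scenario):
    q_p = scenario.q10_factor(scenario.q10_production)
    q_r = scenario.q10_factor(scenario.q10_respiration)
    p0 = scenario.p_max_ref * scenario.c_oc * q_p
    vmax = scenario.r_max_ref * scenario.c_oc * q_r
    return p0, vmax


def dark_steady_profile_quadrature(scenario):
    """Dark steady C(z) by the first-integral (energy) method — no PDE solver.

    With no production and constant D in the sediment, D C'' = R(C) admits
    the first integral (C')^2 = (2/D) V(C), V(C) = vmax [C - k ln(1 + C/k)],
    valid when the oxic front lies above the bottom (C and C' -> 0 together).
    The surface value C0 solves the scalar flux match
    sqrt(2 D V(C0)) = g_dbl (C_sat - C0), and the profile follows from
    integrating dC/dz = -sqrt(2 V(C)/D).  Returns a callable z -> C(z)
    (linear in the DBL above z = 0).
    """
    from scipy.optimize import brentq

    csat = saturation_concentration(
        scenario.temperature, scenario.salinity, scenario.ppo2
    )
    d_mol = diffusivity(scenario.temperature, scenario.salinity)
    d_sed = d_mol * scenario.sediment_diffusivity_factor
    g_dbl = d_mol / scenario.dbl_thickness
    _, vmax = _rates(scenario)
    k = scenario.k_o2

    def V(c):
        return vmax * (c - k * np.log1p(c / k))

    def mismatch(c0):
        return np.sqrt(2.0 * d_sed * V(c0)) - g_dbl * (csat - c0)

    c0 = brentq(mismatch, 1e-12, csat - 1e-12, xtol=1e-14, rtol=1e-14)

    def slope(z, c):
        return -np.sqrt(np.clip(2.0 * V(np.clip(c, 0.0, None)) / d_sed, 0.0, None))

    zs = np.linspace(0.0, scenario.sediment_depth, 4001)
    sol = solve_ivp(slope, (0.0, scenario.sediment_depth), [c0], t_eval=zs,
                    rtol=1e-10, atol=1e-12)
    assert sol.success
    prof = np.clip(sol.y[0], 0.0, None)
    # first integral assumes the front sits above the bottom boundary
    assert prof[-1] < 1e-6 * csat, "oxygen reaches the bottom; oracle invalid"

    def evaluate(zq):
        zq = np.asarray(zq, dtype=float)
        dbl = csat + (c0 - csat) * (zq + scenario.dbl_thickness) / scenario.dbl_thickness
        sed = np.interp(np.clip(zq, 0.0, None), zs, prof)
        return np.where(zq < 0.0, dbl, sed)

    return evaluate


def bvp_steady_profile(scenario, lit: bool):
    """Steady C(z) by an independent boundary-value solve.

    The sediment column is solved in (C, F) with F = D_sed C':
    C' = F/D_sed, F' = R(C) - P(z).  The diffusive boundary layer carries no
    reactions, so its steady profile is exactly linear and enters as a Robin
    condition at z = 0: F(0) = -(D_mol / L_dbl) (C_sat - C(0)).  The bottom is
    no-flux.  Returns a callable z -> C(z) valid over the whole domain
    (linear DBL segment above z = 0).
    """
    csat = saturation_concentration(
        scenario.temperature, scenario.salinity, scenario.ppo2
    )
    d_mol = diffusivity(scenario.temperature, scenario.salinity)
    d_sed = d_mol * scenario.sediment_diffusivity_factor
    g_dbl = d_mol / scenario.dbl_thickness
    p0, vmax = _rates(scenario)
    k = scenario.k_o2
    ze = scenario.production_efolding
    depth = scenario.sediment_depth

    def rhs(z, y):
        c = np.clip(y[0], 0.0, None)
        resp = vmax * c / (c + k)
        prod = (p0 * np.exp(-z / ze)) if lit else 0.0
        return np.vstack([y[1] / d_sed, resp - prod])

    def bc(ya, yb):
        # downward flux into the sediment is -D C'; it must match the linear
        # DBL transport g_dbl (C_sat - C(0))
        return np.array([ya[1] + g_dbl * (csat - ya[0]), yb[1]])

    # graded initial mesh: dense near the surface where the O2 front lives
    z = np.unique(np.concatenate([
        np.geomspace(1e-5, depth, 400) - 1e-5,
        np.linspace(0.0, depth, 100),
    ]))
    scale = np.sqrt(2 * d_sed * max(csat, 1.0) / max(vmax, 1e-9))
    y0 = np.vstack([csat * np.exp(-z / max(scale, 1e-3)), np.zeros_like(z)])
    sol = solve_bvp(rhs, bc, z, y0, max_nodes=300000, tol=1e-5)
    assert sol.success, sol.message

    def evaluate(zq):
        zq = np.asarray(zq, dtype=float)
        c0 = float(sol.sol(0.0)[0])
        dbl = csat + (c0 - csat) * (zq + scenario.dbl_thickness) / scenario.dbl_thickness
        sed = np.clip(sol.sol(np.clip(zq, 0.0, None))[0], 0.0, None)
        return np.where(zq < 0.0, dbl, sed)

    return evaluate


def lsoda_diel_interface(scenario, n_cycles=1, spinup_cycles=2, points_per_cycle=100):
    """Diel method-of-lines solve with scipy's adaptive LSODA driver.

    Shares the package's spatial discretisation (so the comparison isolates
    the time integrator) but none of its stepping code.  Returns
    (times, interface_series) for the reported cycles, interface = topmost
    sediment cell.
    """
    w, centres, g, n_dbl = _build_grid(scenario)
    csat = saturation_concentration(
        scenario.temperature, scenario.salinity, scenario.ppo2
    )
    p0, vmax_val = _rates(scenario)
    prod = np.where(
        centres > 0, p0 * np.exp(-np.clip(centres, 0, None) / scenario.production_efolding), 0.0
    )
    vmax = np.where(centres > 0, vmax_val, 0.0)
    k = scenario.k_o2
    n = w.size

    def rhs(t, c, lit):
        flux = np.empty(n + 1)
        flux[0] = g[0] * (csat - c[0])
        flux[1:n] = g[1:n] * (c[:-1] - c[1:])
        flux[n] = 0.0
        out = (flux[:-1] - flux[1:]) / w
        cpos = np.clip(c, 0.0, None)
        out -= vmax * cpos / (cpos + k)
        if lit:
            out += prod
        return out

    light_len = scenario.light_fraction * scenario.day_length
    dark_len = scenario.day_length - light_len
    c = np.full(n, csat)
    times_out, series_out = [], []
    t_base = 0.0
    for cyc in range(spinup_cycles + n_cycles):
        for lit, length in ((True, light_len), (False, dark_len)):
            record = cyc >= spinup_cycles
            t_eval = (
                np.linspace(0, length, points_per_cycle // 2 + 1)[1:] if record else None
            )
            sol = solve_ivp(
                rhs, (0.0, length), c, args=(lit,), method="LSODA",
                t_eval=t_eval, rtol=1e-8, atol=1e-6, lband=1, uband=1,
            )
            assert sol.success
            c = sol.y[:, -1]
            if record:
                times_out.append(t_base + sol.t)
                series_out.append(sol.y[n_dbl])  # topmost sediment cell
                t_base += length
    return np.concatenate(times_out), np.concatenate(series_out)


def brute_metrics(times, series, day_length, thresholds, dense=200001):
    """Brute-force scan of one cycle: per-class residence hours, evening and
    morning traverse durations, via dense linear resampling."""
    t0, t1 = times[0], times[0] + day_length
    tq = np.linspace(t0, t1, dense)
    cq = np.interp(tq, times, series)
    dt = (t1 - t0) / (dense - 1)
    hours_below = {
        "anoxic": np.mean(cq < thresholds.anoxic_max) * day_length,
        "severe": np.mean(cq < thresholds.severe_hypoxic_max) * day_length,
        "hypoxic_max": np.mean(cq < thresholds.hypoxic_max) * day_length,
    }

    def traverse(c, low, high):
        above = np.nonzero(c >= high)[0]
        if above.size == 0:
            return 0.0
        below = np.nonzero(c < low)[0]
        for b in below:
            prior = above[above <= b]
            if prior.size:
                start = prior[-1]
                return (b - start) * dt
        return 0.0

    ev = traverse(cq, thresholds.severe_hypoxic_max, thresholds.hypoxic_max)
    mo = traverse(cq[::-1], thresholds.severe_hypoxic_max, thresholds.hypoxic_max)
    return hours_below, ev, mo
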