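"""Calibration script for the shipped G-function and forcing defaults.

Evaluates a candidate (baseline amplitude, noise SD, post-switch multipliers,
default cost d) against the four regime targets the defaults were frozen on:

* combined forcing, switch at 500: pOSM extinct within 250 post-switch steps
  (majority of replicates);
* periodic-only forcing: eOSM sustained > 0.9 share within 500 post-switch
  steps;
* stochastic-only forcing: pOSM majority-wins at the default cost;
* stationary cost sweeps (0.005 grid): eOSM majority-wins up to d ~ 0.09
  under periodic fluctuations, pOSM majority-wins from d ~ 0.01 upward under
  stochastic-only fluctuations.

The shipped defaults (amplitude 0.6 sigma_k, noise 0.15, multipliers 5x
amplitude / 2x noise, d = 0.015, s = 0.2 / 2.0) are the outcome of this
scan.  Run from the repository root:

    python scripts/calibrate_ecoevo.py [A noise amp_mult noise_mult d]
"""

import sys

import numpy as np

from benthox.ecoevo import GFunctionParams, competition_run, cost_sweep
from benthox.scenarios import ForcingConfig


def regime_summary(fcfg: ForcingConfig, d: float, replicates: int = 25) -> dict:
    params = GFunctionParams(d=d)
    out = {}
    for mode in ("stochastic_only", "periodic_only", "combined"):
        ext, dom, winners = [], [], []
        for seed in range(replicates):
            tr = competition_run(mode, seed=seed, params=params, forcing_config=fcfg)
            a = tr.annotations
            e = a.extinction_time["pOSM"]
            ext.append(e - 500 if e is not None and e >= 500 else None)
            dom.append(a.dominance_time - 500
                       if a.dominance_time is not None and a.dominance_time >= 500
                       else None)
            winners.append(a.dominant or
                           ("pOSM" if tr.x[-1, 0] > tr.x[-1, 1] else "eOSM"))
        out[mode] = {
            "eosm_wins": winners.count("eOSM"),
            "median_posm_ext_post": (float(np.median([e for e in ext if e is not None]))
                                     if any(e is not None for e in ext) else None),
            "median_dom_post": (float(np.median([t for t in dom if t is not None]))
                                if any(t is not None for t in dom) else None),
        }
    return out


def sweep_summary(fcfg: ForcingConfig, replicates: int = 25) -> dict:
    d_grid = np.round(np.arange(0.005, 0.1201, 0.005), 10)
    out = {}
    per = cost_sweep(d_grid, "periodic_only", replicates=replicates, base_seed=3,
                     forcing_config=fcfg)
    eosm = per[per.winner == "eOSM"]["d"]
    out["largest_d_eOSM_wins_periodic"] = float(eosm.max()) if len(eosm) else None
    sto = cost_sweep(d_grid, "stochastic_only", replicates=replicates, base_seed=3,
                     forcing_config=fcfg)
    posm = sto[sto.winner == "pOSM"]["d"]
    out["smallest_d_pOSM_wins_stochastic"] = float(posm.min()) if len(posm) else None
    return out


def main() -> None:
    args = [float(x) for x in sys.argv[1:]]
    A, noise, amp_m, noise_m, d = args or (0.6, 0.15, 5.0, 2.0, 0.015)
    fcfg = ForcingConfig(baseline_amplitude=A, noise_sd=noise,
                         amplitude_multiplier_post=amp_m,
                         noise_multiplier_post=noise_m)
    print(f"candidate: A={A} noise={noise} mult=({amp_m}, {noise_m}) d={d}")
    for mode, row in regime_summary(fcfg, d).items():
        print(f"  {mode}: {row}")
    for key, val in sweep_summary(fcfg).items():
        print(f"  {key}: {val}")


if __name__ == "__main__":
    main()
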