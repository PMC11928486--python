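"""Calibration script for the shipped benthic rate constants.

Scans the reference production/respiration scale (p_max_ref, r_max_ref) and
the respiration half-saturation k_o2 on the fixed preset geometry and prints,
for each candidate, the quantities the defaults were frozen against:

* cold preset: weakly oxic day maximum, hypoxic (22-65 uM) night minimum,
  and ~11 h per 21-h cycle spent below the oxic threshold;
* warm preset: oxic day maximum, truly anoxic (< 0.02 uM) night minimum,
  and a dusk oxic-to-anoxia traverse well under 0.3 h;
* hot preset: same qualitative pattern as warm, larger amplitude.

The shipped defaults (p_max_ref = 17000, r_max_ref = 8500 uM/h at the 5 degC
anchor; k_o2 = 0.2 uM; Q10p = 2.6, Q10r = 3.0) are the coarse optimum of this
scan; they are package constants, not end-user knobs.  Run from the
repository root:

    python scripts/calibrate_benthic.py
"""

import itertools

import benthox as bx


def preset_summary(name: str, **overrides) -> dict:
    sc = bx.make_scenario(name, **overrides)
    field = bx.simulate_diel(sc, n_cycles=1, spinup_cycles=5)
    t, series = bx.interface_series(field)
    m = bx.compute_diel_metrics(
        t, series, sc.day_length, sc.light_fraction, transition_floor="anoxic"
    )[-1]
    return {
        "day_max": m.max_day_o2,
        "night_min": float(series.min()),
        "below_oxic_h": sc.day_length - m.class_hours["oxic"],
        "anoxia_h": m.anoxia_hours,
        "dusk_to_anoxia_h": m.transition_evening,
        "day_class": m.day_class,
    }


def main() -> None:
    grid_r = [6000.0, 8500.0, 12000.0]
    grid_ratio = [1.6, 2.0, 2.4]       # p_max_ref / r_max_ref
    grid_k = [0.2, 0.5]
    for r_ref, ratio, k in itertools.product(grid_r, grid_ratio, grid_k):
        p_ref = ratio * r_ref
        rows = {}
        for name in ("cold", "warm"):
            rows[name] = preset_summary(
                name, r_max_ref=r_ref, p_max_ref=p_ref, k_o2=k
            )
        c, w = rows["cold"], rows["warm"]
        ok = (
            c["day_max"] >= 65
            and 22 <= c["night_min"] < 65
            and abs(c["below_oxic_h"] - 11) <= 2
            and w["day_max"] >= 65
            and w["night_min"] < 0.02
            and 0 < w["dusk_to_anoxia_h"] < 0.3
        )
        print(
            f"r_ref={r_ref:7.0f} p/r={ratio:.1f} k_o2={k:.1f} | "
            f"cold day {c['day_max']:6.1f} night {c['night_min']:6.2f} "
            f"below-oxic {c['below_oxic_h']:5.2f} h | "
            f"warm day {w['day_max']:6.1f} night {w['night_min']:8.4f} "
            f"dusk {w['dusk_to_anoxia_h']:5.3f} h | {'OK' if ok else '--'}"
        )
    print("\nshipped defaults:")
    for name in ("cold", "warm", "hot"):
        print(f"  {name}: {preset_summary(name)}")


if __name__ == "__main__":
    main()
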