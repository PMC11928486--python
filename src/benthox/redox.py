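"""Redox classification and diel metrics of an interface oxygen series.

Classes follow the standard dissolved-oxygen stress bands: anoxic < 0.02 uM,
severely hypoxic 0.02-22 uM, hypoxic 22-65 uM, oxic >= 65 uM.  Class
intervals are closed below and open above, so exactly 22 uM is hypoxic and
exactly 65 uM is oxic.

Metrics are evaluated on the piecewise-linear interpolant of the sampled
series, so threshold-crossing times (and hence transition durations and
per-class residence hours) have sub-sample resolution and converge as the
output grid is refined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .benthic_o2 import OxygenField

__all__ = [
    "RedoxThresholds",
    "DielMetrics",
    "REDOX_CLASSES",
    "classify_redox",
    "interface_series",
    "compute_diel_metrics",
]

REDOX_CLASSES = ("anoxic", "severely_hypoxic", "hypoxic", "oxic")


@dataclass(frozen=True)
class RedoxThresholds:
    """Upper bounds (uM) of the anoxic, severely-hypoxic and hypoxic classes."""

    anoxic_max: float = 0.02
    severe_hypoxic_max: float = 22.0
    hypoxic_max: float = 65.0

    def __post_init__(self) -> None:
        if not 0.0 < self.anoxic_max < self.severe_hypoxic_max < self.hypoxic_max:
            raise ValueError(
                "thresholds must satisfy 0 < anoxic_max < severe_hypoxic_max "
                f"< hypoxic_max, got {self}"
            )


def classify_redox(concentration, thresholds: RedoxThresholds = RedoxThresholds()):
    """Redox class label(s) for non-negative concentration(s) in uM.

    Scalar in, string out; array in, object array of strings out.  Every
    non-negative value maps to exactly one class.
    """
    c = np.asarray(concentration, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    edges = [thresholds.anoxic_max, thresholds.severe_hypoxic_max, thresholds.hypoxic_max]
    idx = np.searchsorted(edges, c, side="right")
    labels = np.asarray(REDOX_CLASSES, dtype=object)[idx]
    if np.isscalar(concentration) or np.ndim(concentration) == 0:
        return str(labels)
    return labels


def interface_series(field: OxygenField, depth: float = 0.0):
    """Concentration trace (times, series) at the cell containing ``depth``.

    The default extracts the sediment-water interface (z = 0); pass e.g.
    ``depth=-field.scenario.dbl_thickness/2`` for the DBL mid-point.
    """
    i = field.depth_index(depth)
    return field.times, field.concentration[i]


@dataclass(frozen=True)
class DielMetrics:
    """Per-cycle summary of an interface O2 series."""

    cycle: int
    max_day_o2: float           # uM, maximum over the lit phase
    max_night_o2: float         # uM, maximum over the dark phase
    transition_time: float      # h/day spent traversing the hypoxic band
    transition_evening: float   # h, last C>=hypoxic_max -> first C<lower bound
    transition_morning: float   # h, mirror traverse at dawn
    anoxia_hours: float         # h/day with C < anoxic_max
    day_class: str              # class of the day maximum
    night_class: str            # class of the night maximum
    class_hours: dict = field(compare=False, default_factory=dict)  # h per class


def _crossing_time(t0, t1, c0, c1, thr):
    """Linear-interpolated time at which the segment crosses ``thr``."""
    return t0 + (thr - c0) * (t1 - t0) / (c1 - c0)


def _time_below(times: np.ndarray, series: np.ndarray, thr: float) -> float:
    """Measure of {t : C(t) < thr} for the piecewise-linear interpolant."""
    total = 0.0
    for j in range(times.size - 1):
        t0, t1 = times[j], times[j + 1]
        c0, c1 = series[j], series[j + 1]
        if c0 < thr and c1 < thr:
            total += t1 - t0
        elif c0 < thr or c1 < thr:
            tc = _crossing_time(t0, t1, c0, c1, thr)
            total += (tc - t0) if c0 < thr else (t1 - tc)
    return total


def _evening_traverse(times, series, high, low):
    """Duration from the last time C >= high to the first later time C < low.

    Returns 0.0 if the series never reaches ``high`` or never falls below
    ``low`` afterwards (i.e. C never leaves one class through the band).
    """
    above = series >= high
    if not above.any():
        return 0.0
    # first drop below `low` that happens after having been >= high
    last_high_t = None
    for j in range(times.size - 1):
        if above[j]:
            last_high_t = times[j]
            if series[j + 1] < high:
                last_high_t = _crossing_time(
                    times[j], times[j + 1], series[j], series[j + 1], high
                )
        if last_high_t is not None and series[j] >= low and series[j + 1] < low:
            t_low = _crossing_time(times[j], times[j + 1], series[j], series[j + 1], low)
            return t_low - last_high_t
    return 0.0


def _morning_traverse(times, series, high, low):
    """Mirror of the evening traverse: last C < low to first later C >= high.

    A morning rise through the band becomes an evening-style fall when time is
    reversed, so the scan is reused on the time-reversed series.
    """
    return _evening_traverse(-times[::-1], series[::-1], high, low)


def compute_diel_metrics(
    times: np.ndarray,
    series: np.ndarray,
    day_length: float = 21.0,
    light_fraction: float = 0.5,
    thresholds: RedoxThresholds = RedoxThresholds(),
    traverses: str = "both",
    transition_floor: str = "severe_hypoxic",
) -> list[DielMetrics]:
    """Per-cycle diel metrics of an interface series.

    Parameters
    ----------
    times, series:
        Sampled concentration trace; ``times`` start at lights-on of the first
        reported cycle and must cover at least one full ``day_length``.
    traverses:
        ``"both"`` (default) reports evening + morning traverse per day, as
        shaded in the diel-amplitude figures; ``"evening"`` reports the dusk
        traverse only (the form used by the < 1 h robustness criterion).
    transition_floor:
        Lower bound of the traverse: ``"severe_hypoxic"`` (transition complete
        once C < severe_hypoxic_max) or ``"anoxic"`` (once C < anoxic_max).
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if times.shape != series.shape or times.ndim != 1:
        raise ValueError("times and series must be 1-D arrays of equal length")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("time grid must be strictly increasing")
    if times[-1] - times[0] < day_length - 1e-9:
        raise ValueError("series must cover at least one full cycle")
    if traverses not in ("both", "evening"):
        raise ValueError("traverses must be 'both' or 'evening'")
    if transition_floor == "severe_hypoxic":
        low = thresholds.severe_hypoxic_max
    elif transition_floor == "anoxic":
        low = thresholds.anoxic_max
    else:
        raise ValueError("transition_floor must be 'severe_hypoxic' or 'anoxic'")
    high = thresholds.hypoxic_max

    n_cycles = int(np.floor((times[-1] - times[0]) / day_length + 1e-9))
    light_len = light_fraction * day_length
    out: list[DielMetrics] = []
    for k in range(n_cycles):
        t0 = times[0] + k * day_length
        t1 = t0 + day_length
        tc, cc = _window(times, series, t0, t1)
        td, cd = _window(times, series, t0, t0 + light_len)
        tn, cn = _window(times, series, t0 + light_len, t1)
        ev = _evening_traverse(tc, cc, high, low)
        mo = _morning_traverse(tc, cc, high, low)
        trans = ev + mo if traverses == "both" else ev
        max_day = float(cd.max())
        max_night = float(cn.max())
        class_hours = {}
        prev = 0.0
        for name, edge in zip(
            REDOX_CLASSES[:3],
            (thresholds.anoxic_max, thresholds.severe_hypoxic_max, thresholds.hypoxic_max),
        ):
            below = _time_below(tc, cc, edge)
            class_hours[name] = below - prev
            prev = below
        class_hours["oxic"] = (tc[-1] - tc[0]) - prev
        out.append(
            DielMetrics(
                cycle=k,
                max_day_o2=max_day,
                max_night_o2=max_night,
                transition_time=trans,
                transition_evening=ev,
                transition_morning=mo,
                anoxia_hours=_time_below(tc, cc, thresholds.anoxic_max),
                day_class=classify_redox(max_day, thresholds),
                night_class=classify_redox(max_night, thresholds),
                class_hours=class_hours,
            )
        )
    return out


def _window(times, series, t0, t1):
    """Samples in [t0, t1] with linear-interpolated endpoints added."""
    eps = 1e-12
    inside = (times > t0 + eps) & (times < t1 - eps)
    t = times[inside]
    c = series[inside]
    c0 = np.interp(t0, times, series)
    c1 = np.interp(t1, times, series)
    return (
        np.concatenate([[t0], t, [t1]]),
        np.concatenate([[c0], c, [c1]]),
    )
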