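"""Scenario construction, Monte-Carlo parameter draws and the gamma(t) forcing.

This module is the synthetic-data stage of the package: it builds fully
parameterised sediment--water scenarios (cold / warm / hot shallow-shelf
presets), samples parameter sets for the Monte-Carlo robustness ensemble,
and generates the abstract environmental-optimum forcing gamma(t) (sinusoid
plus white Gaussian noise with a "flooding switch") that drives the
eco-evolutionary competition model.

All randomness is derived from a single integer seed through
``numpy.random.SeedSequence`` sub-streams, so every operation is a pure
function of its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

__all__ = [
    "BenthicScenario",
    "ParameterRanges",
    "ForcingConfig",
    "ForcingSeries",
    "PRESETS",
    "DEFAULT_RANGES",
    "make_scenario",
    "sample_parameters",
    "gamma_forcing",
]

# Sub-stream tags so that different operations sharing one user seed draw
# from independent generators.
_STREAM_SAMPLE = 101
_STREAM_FORCING = 202

# Hard physical/validity bounds for scenario fields: (low, high, low_open, high_open)
_BOUNDS = {
    "temperature": (-2.0, 60.0, False, False),
    "salinity": (0.0, 45.0, False, False),
    "ppo2": (0.0, 150.0, True, False),
    "c_oc": (0.0, 2.0, True, False),
    "q10_production": (1.0, np.inf, False, True),
    "q10_respiration": (1.0, np.inf, False, True),
    "day_length": (0.0, np.inf, True, True),
    "light_fraction": (0.0, 1.0, True, True),
    "dbl_thickness": (0.0, np.inf, True, True),
    "sediment_depth": (0.0, np.inf, True, True),
    "grid_spacing": (0.0, np.inf, True, True),
    "p_max_ref": (0.0, np.inf, False, True),
    "r_max_ref": (0.0, np.inf, False, True),
    "k_o2": (0.0, np.inf, True, True),
    "production_efolding": (0.0, np.inf, True, True),
    "t_ref": (-2.0, 60.0, False, False),
    "sediment_diffusivity_factor": (0.0, 1.0, True, False),
}

# Volumetric rate constants at the reference temperature (5 degC anchor, c_oc = 1).
# Frozen once by scripts/calibrate_benthic.py so that the cold preset yields weakly
# oxic days with ~11 h sub-oxic nights and the warm preset yields oxic days with
# nocturnal anoxia reached in well under 0.3 h.
P_MAX_REF = 17000.0  # uM h-1, gross production at the surface, lit, t_ref, c_oc = 1
R_MAX_REF = 8500.0   # uM h-1, O2-saturated volumetric respiration at t_ref, c_oc = 1


@dataclass(frozen=True)
class BenthicScenario:
    """Full parameterisation of one sediment--water diel oxygen simulation.

    Concentrations are micromolar (uM), lengths cm, times hours, rates uM/h.
    ``ppo2`` is percent of the present atmospheric O2 level (%PAL); ``c_oc``
    scales the respiration fuel (total organic carbon) relative to the
    Phanerozoic mean.
    """

    temperature: float                  # degC
    salinity: float = 35.0              # PSU
    ppo2: float = 30.0                  # %PAL
    c_oc: float = 0.25                  # TOC adjustment factor
    q10_production: float = 2.6
    q10_respiration: float = 3.0
    day_length: float = 21.0            # h, total diel cycle (early-Palaeozoic day)
    light_fraction: float = 0.5         # fraction of the cycle that is lit
    dbl_thickness: float = 0.05         # cm, diffusive boundary layer
    sediment_depth: float = 1.25        # cm
    grid_spacing: float = 0.025         # cm, sediment-layer cell size
    p_max_ref: float = P_MAX_REF        # uM/h at t_ref, sediment surface, lit
    r_max_ref: float = R_MAX_REF        # uM/h at t_ref and c_oc = 1
    k_o2: float = 0.2                   # uM, respiration half-saturation
    production_efolding: float = 0.1    # cm, light/production depth attenuation
    t_ref: float = 5.0                  # degC, Q10 reference (cold-preset anchor)
    sediment_diffusivity_factor: float = 0.7  # porosity/tortuosity reduction, sandy

    def __post_init__(self) -> None:
        for name, (lo, hi, lo_open, hi_open) in _BOUNDS.items():
            v = getattr(self, name)
            if not np.isfinite(v) and hi != np.inf:
                raise ValueError(f"{name}={v!r} is not finite")
            bad = v < lo or v > hi or (lo_open and v == lo) or (hi_open and v == hi)
            if bad:
                lob = "(" if lo_open else "["
                hib = ")" if hi_open else "]"
                raise ValueError(
                    f"{name}={v} outside allowed range {lob}{lo}, {hi}{hib}"
                )
        if self.sediment_depth / self.grid_spacing < 5 - 1e-9:
            raise ValueError(
                "grid_spacing too coarse: sediment layer must resolve >= 5 cells "
                f"(grid_spacing={self.grid_spacing}, sediment_depth={self.sediment_depth})"
            )

    def q10_factor(self, q10: float) -> float:
        """Multiplicative Q10 rate amplification at this scenario's temperature."""
        return float(q10 ** ((self.temperature - self.t_ref) / 10.0))


#: Preset (temperature degC, TOC adjustment factor) pairs.  The cold preset is
#: a Cryogenian-like low-fertility shelf (TOC factor 0.1); the warm and hot
#: presets are Cambrian-like fertile shelves (TOC factor 1.0), spanning the
#: TOC rise between the two climate states.
PRESETS = {"cold": (5.0, 0.1), "warm": (25.0, 1.0), "hot": (40.0, 1.0)}


def make_scenario(preset: str | None = None, **overrides: float) -> BenthicScenario:
    """Build a scenario from a named preset with optional per-field overrides.

    Parameters
    ----------
    preset:
        One of ``"cold"`` (5 degC), ``"warm"`` (25 degC), ``"hot"`` (40 degC),
        or None, in which case ``temperature`` must be given explicitly.
    overrides:
        Any :class:`BenthicScenario` field, e.g. ``ppo2=20``.
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; expected one of {sorted(PRESETS)}"
            )
        t_preset, c_oc_preset = PRESETS[preset]
        overrides.setdefault("temperature", t_preset)
        overrides.setdefault("c_oc", c_oc_preset)
    if "temperature" not in overrides:
        raise ValueError("either a preset or an explicit temperature is required")
    valid = {f.name for f in fields(BenthicScenario)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown scenario field(s): {sorted(unknown)}")
    return BenthicScenario(**overrides)


@dataclass(frozen=True)
class ParameterRanges:
    """Closed sampling intervals for the Monte-Carlo varied parameters."""

    temperature: tuple[float, float] = (5.0, 40.0)
    ppo2: tuple[float, float] = (20.0, 50.0)
    c_oc: tuple[float, float] = (0.1, 1.0)
    q10_production: tuple[float, float] = (1.5, 3.0)
    q10_respiration: tuple[float, float] = (1.5, 3.0)

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = getattr(self, f.name)
            if not (np.isfinite(lo) and np.isfinite(hi)):
                raise ValueError(f"{f.name} interval ({lo}, {hi}) is not finite")
            if lo > hi:
                raise ValueError(f"{f.name} interval has low={lo} > high={hi}")
            blo, bhi, lo_open, hi_open = _BOUNDS[f.name]
            if lo < blo or hi > bhi or (lo_open and lo == blo):
                raise ValueError(
                    f"{f.name} interval ({lo}, {hi}) outside scenario bounds"
                )

    def items(self) -> list[tuple[str, tuple[float, float]]]:
        return [(f.name, getattr(self, f.name)) for f in fields(self)]


#: The documented default Monte-Carlo ranges (temperature 5-40 degC, 20-50 %PAL,
#: TOC factor 0.1-1, both Q10s 1.5-3).
DEFAULT_RANGES = ParameterRanges()


def sample_parameters(
    ranges: ParameterRanges,
    n: int,
    seed: int,
    base: BenthicScenario | None = None,
) -> list[BenthicScenario]:
    """Draw ``n`` scenarios with each varied parameter uniform over its interval.

    Non-varied fields are taken from ``base`` (default: the package defaults at
    the drawn temperature).  Identical ``(ranges, n, seed)`` give a bit-identical
    sequence of scenarios.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), _STREAM_SAMPLE]))
    names = [name for name, _ in ranges.items()]
    lows = np.array([lo for _, (lo, hi) in ranges.items()])
    highs = np.array([hi for _, (lo, hi) in ranges.items()])
    draws = lows + (highs - lows) * rng.random((n, len(names)))
    out: list[BenthicScenario] = []
    for row in draws:
        kw = dict(zip(names, (float(v) for v in row)))
        if base is not None:
            out.append(replace(base, **kw))
        else:
            out.append(BenthicScenario(**kw))
    return out


@dataclass(frozen=True)
class ForcingConfig:
    """Configuration of the gamma(t) optimal-strategy forcing.

    gamma(t) = mean_gamma + A(t) sin(2 pi t / period) + sigma(t) * z(t), with
    independent standard-normal z(t); A and sigma jump from their baseline
    values to baseline * multiplier at ``switch_time`` (the "flooding switch").
    """

    baseline_amplitude: float = 0.6
    period: float = 21.0                 # pseudo-steps per cycle (one pseudo-day)
    noise_sd: float = 0.15
    mean_gamma: float = 0.0
    switch_time: int = 500               # pre-switch window as simulated in the study
    amplitude_multiplier_post: float = 5.0
    noise_multiplier_post: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.switch_time < 0:
            raise ValueError("switch_time must be >= 0")
        if self.amplitude_multiplier_post < 1 or self.noise_multiplier_post < 1:
            raise ValueError("post-switch multipliers must be >= 1")


@dataclass(frozen=True)
class ForcingSeries:
    """The optimal-strategy series gamma(t) on integer pseudo-time steps."""

    times: np.ndarray
    gamma: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        g = np.asarray(self.gamma)
        if t.shape != g.shape or t.ndim != 1:
            raise ValueError("times and gamma must be 1-D arrays of equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "gamma", g)

    def __len__(self) -> int:
        return int(self.times.size)


def gamma_forcing(config: ForcingConfig, n_steps: int) -> ForcingSeries:
    """Generate gamma(t) for t = 0 .. n_steps-1.

    The unit-normal noise stream depends only on ``config.seed``, so runs that
    differ only in the post-switch multipliers share identical pre-switch
    trajectories (common random numbers across forcing modes).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    t = np.arange(n_steps, dtype=float)
    post = t >= config.switch_time
    amp = np.where(post, config.baseline_amplitude * config.amplitude_multiplier_post,
                   config.baseline_amplitude)
    sd = np.where(post, config.noise_sd * config.noise_multiplier_post, config.noise_sd)
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), _STREAM_FORCING])
    )
    z = rng.standard_normal(n_steps)
    gamma = config.mean_gamma + amp * np.sin(2.0 * np.pi * t / config.period) + sd * z
    return ForcingSeries(times=t, gamma=gamma)
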