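"""Plain-text (YAML) run configuration: one file drives one reproducible run.

Schema (all blocks optional unless the chosen model needs them)::

    model: benthic | metrics | ensemble | ecoevo | sweep | forcing | scenario
    seed: 0
    out: results.csv
    verbosity: 1
    scenario:
      preset: warm          # or explicit fields; overrides allowed per field
      ppo2: 30
    forcing:                # ForcingConfig fields
      baseline_amplitude: 1.0
    ecoevo:                 # GFunctionParams fields + run controls
      d: 0.02
      mode: combined
      steps: 1500
      species:
        - {name: pOSM, s: 0.2, x0: 25, u0: 0}
        - {name: eOSM, s: 2.0, x0: 25, u0: 0}
    ensemble:
      n: 2000
      criterion: fast_dusk_severe_hypoxia
      eval_depth: interface
      ranges: {temperature: [5, 40], ppo2: [20, 50], c_oc: [0.1, 1],
               q10_production: [1.5, 3], q10_respiration: [1.5, 3]}
    sweep:
      d_grid: "0.005:0.12:0.005"
      mode: periodic_only
      replicates: 25

Unknown keys are fatal; every referenced block is validated against its
module's invariants before any computation starts.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .ecoevo import FORCING_MODES, GFunctionParams, SpeciesSpec
from .ensemble import CRITERIA
from .scenarios import (
    BenthicScenario,
    ForcingConfig,
    ParameterRanges,
    make_scenario,
)

__all__ = ["RunConfig", "load_config", "dump_config", "parse_grid"]

_MODELS = ("benthic", "metrics", "ensemble", "ecoevo", "sweep", "forcing", "scenario")


def parse_grid(spec: str) -> np.ndarray:
    """Parse ``"start:stop:step"`` into an inclusive grid of values."""
    try:
        start, stop, step = (float(x) for x in str(spec).split(":"))
    except ValueError as exc:
        raise ValueError(f"grid spec {spec!r} is not 'start:stop:step'") from exc
    if step <= 0 or stop < start:
        raise ValueError(f"grid spec {spec!r} must have step > 0 and stop >= start")
    n = int(round((stop - start) / step))
    return np.round(start + step * np.arange(n + 1), 12)


@dataclass
class RunConfig:
    """Validated configuration of a single run."""

    model: str
    seed: int = 0
    out: str | None = None
    verbosity: int = 1
    scenario: BenthicScenario | None = None
    forcing: ForcingConfig | None = None
    ecoevo: GFunctionParams | None = None
    ecoevo_mode: str = "combined"
    ecoevo_steps: int = 1500
    ensemble_n: int = 2000
    ensemble_criterion: str = "fast_dusk_severe_hypoxia"
    ensemble_eval_depth: str = "interface"
    ranges: ParameterRanges | None = None
    sweep_d_grid: str = "0.005:0.12:0.005"
    sweep_mode: str = "periodic_only"
    sweep_replicates: int = 25

    def to_dict(self) -> dict:
        out: dict = {"model": self.model, "seed": self.seed, "verbosity": self.verbosity}
        if self.out is not None:
            out["out"] = self.out
        if self.scenario is not None:
            out["scenario"] = {
                f.name: getattr(self.scenario, f.name)
                for f in dc_fields(BenthicScenario)
            }
        if self.forcing is not None:
            out["forcing"] = {
                f.name: getattr(self.forcing, f.name) for f in dc_fields(ForcingConfig)
            }
        if self.ecoevo is not None:
            out["ecoevo"] = {
                "r": self.ecoevo.r,
                "k_m": self.ecoevo.k_m,
                "sigma_k": self.ecoevo.sigma_k,
                "d": self.ecoevo.d,
                "mode": self.ecoevo_mode,
                "steps": self.ecoevo_steps,
                "species": [
                    {"name": sp.name, "s": sp.s, "x0": sp.x0, "u0": sp.u0}
                    for sp in self.ecoevo.species
                ],
            }
        if self.ranges is not None or self.model == "ensemble":
            r = self.ranges or ParameterRanges()
            out["ensemble"] = {
                "n": self.ensemble_n,
                "criterion": self.ensemble_criterion,
                "eval_depth": self.ensemble_eval_depth,
                "ranges": {name: list(iv) for name, iv in r.items()},
            }
        if self.model == "sweep":
            out["sweep"] = {
                "d_grid": self.sweep_d_grid,
                "mode": self.sweep_mode,
                "replicates": self.sweep_replicates,
            }
        return out


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def load_config(path) -> RunConfig:
    """Load and fully validate a YAML run configuration."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            raw = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"{path}: parse error: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    _check_keys(
        raw,
        {"model", "seed", "out", "verbosity", "scenario", "forcing", "ecoevo",
         "ensemble", "sweep"},
        f"{path}",
    )
    model = raw.get("model")
    if model not in _MODELS:
        raise ValueError(f"{path}: model must be one of {_MODELS}, got {model!r}")
    cfg = RunConfig(
        model=model,
        seed=int(raw.get("seed", 0)),
        out=raw.get("out"),
        verbosity=int(raw.get("verbosity", 1)),
    )

    if "scenario" in raw:
        block = dict(raw["scenario"])
        preset = block.pop("preset", None)
        try:
            cfg.scenario = make_scenario(preset, **block)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: scenario: {exc}") from exc

    if "forcing" in raw:
        block = dict(raw["forcing"])
        _check_keys(block, {f.name for f in dc_fields(ForcingConfig)}, f"{path}: forcing")
        try:
            cfg.forcing = ForcingConfig(**block)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: forcing: {exc}") from exc

    if "ecoevo" in raw:
        block = dict(raw["ecoevo"])
        _check_keys(
            block, {"r", "k_m", "sigma_k", "d", "species", "mode", "steps"},
            f"{path}: ecoevo",
        )
        cfg.ecoevo_mode = block.pop("mode", cfg.ecoevo_mode)
        if cfg.ecoevo_mode not in FORCING_MODES:
            raise ValueError(f"{path}: ecoevo: mode must be one of {FORCING_MODES}")
        cfg.ecoevo_steps = int(block.pop("steps", cfg.ecoevo_steps))
        species_raw = block.pop("species", None)
        kw = dict(block)
        if species_raw is not None:
            species = []
            for sp in species_raw:
                _check_keys(dict(sp), {"name", "s", "x0", "u0"}, f"{path}: ecoevo.species")
                species.append(SpeciesSpec(**sp))
            kw["species"] = tuple(species)
        try:
            cfg.ecoevo = GFunctionParams(**kw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: ecoevo: {exc}") from exc

    if "ensemble" in raw:
        block = dict(raw["ensemble"])
        _check_keys(block, {"n", "criterion", "eval_depth", "ranges"}, f"{path}: ensemble")
        cfg.ensemble_n = int(block.get("n", cfg.ensemble_n))
        cfg.ensemble_criterion = block.get("criterion", cfg.ensemble_criterion)
        if cfg.ensemble_criterion not in CRITERIA:
            raise ValueError(
                f"{path}: ensemble: criterion must be one of {sorted(CRITERIA)}"
            )
        cfg.ensemble_eval_depth = block.get("eval_depth", cfg.ensemble_eval_depth)
        if "ranges" in block:
            rng = {k: tuple(v) for k, v in dict(block["ranges"]).items()}
            try:
                cfg.ranges = ParameterRanges(**rng)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: ensemble.ranges: {exc}") from exc

    if "sweep" in raw:
        block = dict(raw["sweep"])
        _check_keys(block, {"d_grid", "mode", "replicates"}, f"{path}: sweep")
        cfg.sweep_d_grid = str(block.get("d_grid", cfg.sweep_d_grid))
        parse_grid(cfg.sweep_d_grid)
        cfg.sweep_mode = block.get("mode", cfg.sweep_mode)
        if cfg.sweep_mode not in FORCING_MODES:
            raise ValueError(f"{path}: sweep: mode must be one of {FORCING_MODES}")
        cfg.sweep_replicates = int(block.get("replicates", cfg.sweep_replicates))

    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    """Serialise a config back to YAML (round-trips through load_config)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
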