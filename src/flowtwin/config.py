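"""Run configuration: strict-schema YAML for the end-to-end pipeline.

Every stage's knobs have defaults except the seed, which must be given
explicitly (no implicit nondeterminism).  Unknown keys are rejected to
catch typos.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .synthetic import (
    DEFAULT_DESIGN,
    INTER_NOISE,
    INTRA_NOISE,
    NoiseModel,
    SEQUENCE_NOISE_EPI,
    SEQUENCE_NOISE_SGRE,
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SolverConfig:
    rtol: float = 1e-6
    atol: float = 1e-8
    periodicity_tol: float = 1e-3
    n_cycles_max: int = 30


@dataclass(frozen=True)
class OptimizerConfig:
    n_starts: int = 20
    max_nfev: int = 60
    diff_step: float = 1e-3


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    seed: int
    out_dir: str = "flowtwin_run"
    n_subjects: int = 10
    estimate: bool = True
    solver: SolverConfig = field(default_factory=SolverConfig)
    optimizer: OptimizerConfig = field(default_factory=OptimizerConfig)
    noise_overrides: dict = field(default_factory=dict)  # preset -> field -> value
    sensitivity_grid: tuple = (-0.10, -0.075, -0.05, -0.025, 0.0,
                               0.025, 0.05, 0.075, 0.10)
    units: str = "mL, s, mmHg, cm^2, g/mL"

    def design(self) -> dict:
        """The occasion plan with any noise overrides applied."""
        presets = {
            "intra": INTRA_NOISE, "inter": INTER_NOISE,
            "sequence_sgre": SEQUENCE_NOISE_SGRE, "sequence_epi": SEQUENCE_NOISE_EPI,
        }
        for preset, over in self.noise_overrides.items():
            if preset not in presets:
                raise ConfigError(f"unknown noise preset {preset!r}")
            valid = {f.name for f in fields(NoiseModel)}
            bad = set(over) - valid
            if bad:
                raise ConfigError(f"unknown NoiseModel field(s) {sorted(bad)}")
            presets[preset] = replace(presets[preset], **over)
        return {
            "observer1_a": presets["intra"],
            "observer1_b": presets["intra"],
            "observer2": presets["inter"],
            "sgre": presets["sequence_sgre"],
            "epi": presets["sequence_epi"],
        }


def _build(cls, data: dict, ctx: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown key(s) in {ctx}: {sorted(unknown)}")
    return data


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    if "seed" not in raw:
        raise ConfigError("config must set an explicit 'seed'")
    data = dict(raw)
    solver = SolverConfig(**_build(SolverConfig, data.pop("solver", {}), "solver"))
    optimizer = OptimizerConfig(
        **_build(OptimizerConfig, data.pop("optimizer", {}), "optimizer"))
    noise = data.pop("noise", {})
    if not isinstance(noise, dict):
        raise ConfigError("'noise' must map preset names to field overrides")
    grid = tuple(data.pop("sensitivity_grid", RunConfig.sensitivity_grid))
    _build(RunConfig, data | {"solver": None, "optimizer": None,
                              "noise_overrides": None, "sensitivity_grid": None},
           "config")
    cfg = RunConfig(solver=solver, optimizer=optimizer, noise_overrides=noise,
                    sensitivity_grid=grid, **data)
    cfg.design()  # validates overrides eagerly
    return cfg


def dump_config(cfg: RunConfig, path) -> None:
    d = asdict(cfg)
    d["sensitivity_grid"] = list(cfg.sensitivity_grid)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")


__all__ = ["RunConfig", "SolverConfig", "OptimizerConfig", "ConfigError",
           "load_config", "dump_config"]
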