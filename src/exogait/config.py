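"""Run configuration: schema-validated stage sub-configs with defaults.

Configurations load from YAML or JSON; unknown keys are rejected by name
so typos fail loudly, and every field has a documented default, so an
empty file is a valid configuration.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeneratorSettings(_Strict):
    n_subjects: int = 4
    n_steps: int = 12
    noise_sd: float = 0.02
    subject_sd: float = 0.2
    protocol: Literal["slow", "pws"] = "slow"
    rate: float = 100.0


class CurveSettings(_Strict):
    order: int = 8
    sigma: float = 0.03
    target_max_abs: float = 23.0


class SpringSettings(_Strict):
    k_ham: float = 3000.0
    k_rf: float = 3000.0
    rest_length_ham: float = 0.30
    rest_length_rf: float = 0.30
    r_m: float = 0.02


class GainSettings(_Strict):
    kp_outer: float = 60.0
    kp_vel: float = 4.0
    kd_vel: float = 0.001
    saturation: float = 50.0


class EnvSettings(_Strict):
    v_min: float = 0.2
    r_alive: float = 0.1
    effort_floor: float = 0.05
    reward_form: Literal["divide", "one_minus"] = "divide"


class TrainerSettings(_Strict):
    train: bool = True
    total_timesteps: int = 2048
    update_interval: int = 512
    minibatch_size: int = 128
    reuse_epochs: int = 10
    learning_rate: float = 3e-4
    clip_ratio: float = 0.2
    entropy_coef: float = 0.01
    gamma: float = 0.99
    gae_lambda: float = 0.95


class AnalysisSettings(_Strict):
    n_points: int = 101
    outlier_mads: float | None = 3.0
    alpha: float = 0.05
    posthoc: Literal["tukey", "bonferroni"] = "tukey"


class RunConfig(_Strict):
    seed: int = 0
    generator: GeneratorSettings = GeneratorSettings()
    curve: CurveSettings = CurveSettings()
    springs: SpringSettings = SpringSettings()
    gains: GainSettings = GainSettings()
    env: EnvSettings = EnvSettings()
    trainer: TrainerSettings = TrainerSettings()
    analysis: AnalysisSettings = AnalysisSettings()


class ConfigError(ValueError):
    pass


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An absent or empty file yields all defaults.  Unknown keys or wrong
    types raise :class:`ConfigError` naming the offending key.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        data = _deep_merge(data, overrides)
    try:
        return RunConfig(**data)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(x) for x in first["loc"])
        raise ConfigError(f"invalid configuration at {loc!r}: "
                          f"{first['msg']}") from e


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def config_echo(cfg: RunConfig) -> str:
    """Full JSON echo of the effective configuration, for provenance."""
    return json.dumps(cfg.model_dump(), indent=1, sort_keys=True)
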