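"""Run configuration: schema, validation, YAML round-trip.

A run is described by one structured document with four blocks — agent,
environment, schedule, and run-level settings (replicates, seed, output
directory).  The defaults reproduce the standard mobile-paradigm setup:
49 quantiles, κ = 1, learning rate 0.03 with cosine annealing, EMA ε = 0.03,
four limbs, baseline/connect/disconnect of 200/1000/800 steps, five
replicate runs.  Unknown keys are rejected with the offending field path so
typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields

import yaml

from .environments import (
    MOBILE_PHASES,
    VOCALIZATION_PHASES,
    MobileEnvConfig,
    PhaseSchedule,
    VocalizationEnvConfig,
)

__all__ = [
    "AgentConfig",
    "ReinforcementParams",
    "RunConfig",
    "ConfigError",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """Invalid configuration; the message names the field path."""


@dataclass
class ReinforcementParams:
    init_prob: float = 0.2
    threshold: float = 2.5
    increment: float = 0.01
    decrement: float = 0.005
    prob_floor: float = 0.001
    prob_ceil: float = 1.0
    multiplicative: bool = False


@dataclass
class AgentConfig:
    """Agent family and every hyperparameter any family uses."""

    family: str = "causal"  # causal | reinforcement | controllability
    alpha: float = 0.0
    ema_eps: float = 0.03
    kappa: float = 1.0
    n_quantiles: int = 49
    lr_initial: float = 0.03
    annealing: str = "cosine"  # cosine | constant
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    surprise_source: str = "conditional"  # conditional | marginal
    reinforcement: ReinforcementParams = field(default_factory=ReinforcementParams)

    def __post_init__(self) -> None:
        if self.family not in ("causal", "reinforcement", "controllability"):
            raise ConfigError(f"agent.family: unknown family {self.family!r}")
        if self.n_quantiles < 2:
            raise ConfigError("agent.n_quantiles: must be >= 2")
        if self.kappa <= 0:
            raise ConfigError("agent.kappa: must be > 0")
        if self.alpha < 0:
            raise ConfigError("agent.alpha: must be >= 0")
        if self.annealing not in ("cosine", "constant"):
            raise ConfigError(f"agent.annealing: unknown mode {self.annealing!r}")
        if self.lr_initial < 0:
            raise ConfigError("agent.lr_initial: must be >= 0")


@dataclass
class RunConfig:
    """Top-level run description; see module docstring for the blocks."""

    agent: AgentConfig = field(default_factory=AgentConfig)
    environment: "MobileEnvConfig | VocalizationEnvConfig" = field(
        default_factory=MobileEnvConfig
    )
    environment_kind: str = "mobile"  # mobile | vocalization
    schedule: PhaseSchedule = field(default_factory=PhaseSchedule)
    n_runs: int = 5
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ConfigError("n_runs: must be >= 1")
        if self.environment_kind not in ("mobile", "vocalization"):
            raise ConfigError(
                f"environment.kind: unknown kind {self.environment_kind!r}"
            )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        env = dataclasses.asdict(self.environment)
        env["kind"] = self.environment_kind
        if "bimodal_components" in env:
            env["bimodal_components"] = [list(c) for c in env["bimodal_components"]]
        return {
            "agent": dataclasses.asdict(self.agent),
            "environment": env,
            "schedule": {
                "phases": [[label, d] for label, d in self.schedule.phases],
                "step_seconds": self.schedule.step_seconds,
            },
            "n_runs": self.n_runs,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        known = {"agent", "environment", "schedule", "n_runs", "seed", "out_dir"}
        _reject_unknown(raw, known, "")
        agent = _build(AgentConfig, raw.pop("agent", {}), "agent")
        env_raw = dict(raw.pop("environment", {}) or {})
        kind = env_raw.pop("kind", "mobile")
        if kind == "mobile":
            if "bimodal_components" in env_raw:
                env_raw["bimodal_components"] = tuple(
                    tuple(c) for c in env_raw["bimodal_components"]
                )
            env = _build(MobileEnvConfig, env_raw, "environment")
        elif kind == "vocalization":
            env = _build(VocalizationEnvConfig, env_raw, "environment")
        else:
            raise ConfigError(f"environment.kind: unknown kind {kind!r}")
        sched_raw = dict(raw.pop("schedule", {}) or {})
        _reject_unknown(sched_raw, {"phases", "step_seconds"}, "schedule")
        default_phases = VOCALIZATION_PHASES if kind == "vocalization" else MOBILE_PHASES
        try:
            schedule = PhaseSchedule(
                phases=tuple(
                    tuple(p) for p in sched_raw.get("phases", default_phases)
                ),
                step_seconds=sched_raw.get("step_seconds", 0.5),
            )
        except (ValueError, TypeError) as exc:
            raise ConfigError(f"schedule: {exc}") from exc
        return cls(
            agent=agent,
            environment=env,
            environment_kind=kind,
            schedule=schedule,
            n_runs=int(raw.pop("n_runs", 5)),
            seed=int(raw.pop("seed", 0)),
            out_dir=str(raw.pop("out_dir", "results")),
        )

    def config_hash(self) -> str:
        # out_dir is reproducibility-irrelevant and excluded from the hash
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def _reject_unknown(raw: dict, known: set, path: str) -> None:
    for key in raw:
        if key not in known:
            where = f"{path}.{key}" if path else key
            raise ConfigError(f"{where}: unknown configuration key")


def _build(cls, raw: dict, path: str):
    raw = dict(raw or {})
    names = {f.name for f in fields(cls)}
    _reject_unknown(raw, names, path)
    if cls is AgentConfig and "reinforcement" in raw:
        raw["reinforcement"] = _build(
            ReinforcementParams, raw["reinforcement"], f"{path}.reinforcement"
        )
    try:
        return cls(**raw)
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def load_config(path: str) -> RunConfig:
    """Read and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.from_dict(raw)


def save_config(config: RunConfig, path: str) -> None:
    """Echo a resolved configuration back to YAML (round-trips exactly)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
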