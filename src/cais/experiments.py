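"""Episode runner, replicate aggregation, and the named experiments.

:func:`run_episode` iterates act → observe → learn over a phase schedule
and records everything per step.  :func:`run_replicates` repeats an episode
with consecutive seeds and aggregates per-step means and standard
deviations, relabeling each run's contingently connected limb to index 0 so
"connected vs. non-connected" series can be averaged across runs whose
connected limb differed.  :func:`mean_sweep` varies the contingent outcome
mean and records the connected limb's movement probability at the final
connect-phase step per agent family.  :func:`phase_means` averages a
quantity within each phase (how the vocalization simulation is scored), and
:func:`overlay_scale` converts the step axis to minutes and optionally fits
a single least-squares magnitude factor against an empirical series.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .agents import (
    CausalAgentState,
    ControllabilityAgentState,
    ReinforcementAgentState,
    causal_agent_step,
    controllability_agent_step,
    reinforcement_agent_step,
)
from .config import AgentConfig, RunConfig
from .environments import (
    MobileEnvConfig,
    PhaseSchedule,
    VocalizationEnvConfig,
    mobile_outcome,
    vocalization_outcome,
)
from .quantile_dist import LearningSchedule, learning_rate

__all__ = [
    "SimulationTrace",
    "ExperimentReport",
    "build_agent",
    "run_episode",
    "run_replicates",
    "mean_sweep",
    "phase_means",
    "overlay_scale",
    "run_from_config",
]

logger = logging.getLogger(__name__)


@dataclass
class SimulationTrace:
    """Per-step record of one simulated episode."""

    phase: np.ndarray  # (T,) labels
    actions: np.ndarray  # (T, k)
    outcome: np.ndarray  # (T,)
    p_move: np.ndarray  # (T, k) probability for the *next* step
    engagement_raw: np.ndarray  # (T, k) pre-surprise
    engagement_smoothed: np.ndarray  # (T, k) post-surprise, EMA-smoothed
    surprise: np.ndarray  # (T, k)
    inertia: np.ndarray  # (T,)
    lr: np.ndarray  # (T,)
    seed: int = 0
    connected_limb: int | None = None
    agent_family: str = "causal"
    config_hash: str = ""

    @property
    def n_steps(self) -> int:
        return self.outcome.size

    @property
    def n_limbs(self) -> int:
        return self.actions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (step, limb)."""
        T, k = self.actions.shape
        t = np.repeat(np.arange(T), k)
        limb = np.tile(np.arange(k), T)
        return pd.DataFrame(
            {
                "t": t,
                "phase": np.repeat(self.phase, k),
                "limb": limb,
                "action": self.actions.ravel(),
                "p_move": self.p_move.ravel(),
                "engagement_raw": self.engagement_raw.ravel(),
                "engagement_smoothed": self.engagement_smoothed.ravel(),
                "surprise": self.surprise.ravel(),
                "inertia": np.repeat(self.inertia, k),
                "outcome": np.repeat(self.outcome, k),
                "lr": np.repeat(self.lr, k),
            }
        )

    def to_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(
                f"# seed={self.seed} connected_limb={self.connected_limb} "
                f"agent={self.agent_family} config={self.config_hash}\n"
            )
            self.to_frame().to_csv(fh, index=False, float_format="%.10g")


@dataclass
class ExperimentReport:
    """Replicate-aggregated per-step statistics.

    ``means``/``sds`` map quantity name → array of shape (T, k) (or (T,)
    for scalars), with limb index 0 the connected limb after relabeling.
    """

    means: dict = field(default_factory=dict)
    sds: dict = field(default_factory=dict)
    seeds: list = field(default_factory=list)
    connected_limbs: list = field(default_factory=list)
    phase: np.ndarray | None = None
    config_hash: str = ""

    @property
    def n_runs(self) -> int:
        return len(self.seeds)

    def to_json(self, path: str) -> None:
        obj = {
            "seeds": list(self.seeds),
            "connected_limbs": list(self.connected_limbs),
            "config_hash": self.config_hash,
            "phase": [str(p) for p in self.phase] if self.phase is not None else None,
            "means": {k: np.asarray(v).tolist() for k, v in self.means.items()},
            "sds": {k: np.asarray(v).tolist() for k, v in self.sds.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)


def build_agent(agent_cfg: AgentConfig, n_limbs: int):
    """Instantiate the agent state for a family described by its config."""
    if agent_cfg.family == "reinforcement":
        r = agent_cfg.reinforcement
        return ReinforcementAgentState(
            n_limbs=n_limbs,
            init_prob=r.init_prob,
            threshold=r.threshold,
            increment=r.increment,
            decrement=r.decrement,
            prob_floor=r.prob_floor,
            prob_ceil=r.prob_ceil,
            multiplicative=r.multiplicative,
        )
    cls = (
        ControllabilityAgentState
        if agent_cfg.family == "controllability"
        else CausalAgentState
    )
    return cls(
        n_limbs=n_limbs,
        n_quantiles=agent_cfg.n_quantiles,
        alpha=agent_cfg.alpha if agent_cfg.family == "causal" else 0.0,
        ema_eps=agent_cfg.ema_eps,
        kappa=agent_cfg.kappa,
        surprise_source=agent_cfg.surprise_source,
        adam_beta1=agent_cfg.adam_beta1,
        adam_beta2=agent_cfg.adam_beta2,
        adam_eps=agent_cfg.adam_eps,
    )


def run_episode(
    agent_cfg: AgentConfig,
    env_cfg: "MobileEnvConfig | VocalizationEnvConfig",
    schedule: PhaseSchedule,
    seed: int,
    config_hash: str = "",
) -> SimulationTrace:
    """Simulate one episode; deterministic given the seed.

    If the mobile environment's connected limb is unset, one is chosen
    uniformly at random with the run's own generator and recorded in the
    trace header.
    """
    rng = np.random.default_rng(seed)
    is_mobile = isinstance(env_cfg, MobileEnvConfig)
    if is_mobile:
        env_cfg = dataclasses.replace(env_cfg)
        if env_cfg.connected_limb is None:
            env_cfg.connected_limb = int(rng.integers(env_cfg.n_limbs))
        n_limbs = env_cfg.n_limbs
    else:
        n_limbs = 1

    agent = build_agent(agent_cfg, n_limbs)
    lr_schedule = LearningSchedule(
        lr_initial=agent_cfg.lr_initial,
        total_steps=schedule.total_steps,
        mode=agent_cfg.annealing,
    )
    labels = schedule.labels()
    T = schedule.total_steps

    actions = (rng.random(n_limbs) < agent.initial_probabilities()).astype(int)
    agent.last_actions = actions

    trace = SimulationTrace(
        phase=labels,
        actions=np.zeros((T, n_limbs), dtype=int),
        outcome=np.zeros(T),
        p_move=np.zeros((T, n_limbs)),
        engagement_raw=np.zeros((T, n_limbs)),
        engagement_smoothed=np.zeros((T, n_limbs)),
        surprise=np.zeros((T, n_limbs)),
        inertia=np.zeros(T),
        lr=np.zeros(T),
        seed=seed,
        connected_limb=env_cfg.connected_limb if is_mobile else None,
        agent_family=agent_cfg.family,
        config_hash=config_hash,
    )

    for t in range(T):
        phase = labels[t]
        if t == 0 or phase != labels[t - 1]:
            logger.info("seed %d: phase %r begins at step %d", seed, phase, t)
        if is_mobile:
            outcome = mobile_outcome(env_cfg, phase, actions, rng)
        else:
            outcome = vocalization_outcome(env_cfg, phase, int(actions[0]), rng)
        lr = learning_rate(lr_schedule, t)
        trace.actions[t] = actions
        trace.outcome[t] = outcome
        trace.lr[t] = lr
        if agent_cfg.family == "reinforcement":
            actions, info = reinforcement_agent_step(agent, outcome, rng)
        elif agent_cfg.family == "controllability":
            actions, info = controllability_agent_step(agent, outcome, lr, t, rng)
        else:
            actions, info = causal_agent_step(agent, outcome, lr, t, rng)
        trace.p_move[t] = info.p_move
        trace.engagement_raw[t] = info.engagement_raw
        trace.engagement_smoothed[t] = info.engagement_smoothed
        trace.surprise[t] = info.surprise
        trace.inertia[t] = info.inertia
    return trace


_REPORT_QUANTITIES = (
    "p_move",
    "engagement_raw",
    "engagement_smoothed",
    "surprise",
    "outcome",
    "inertia",
)


def _relabeled(trace: SimulationTrace, name: str) -> np.ndarray:
    """Per-limb quantity with the connected limb moved to column 0."""
    arr = getattr(trace, name)
    if arr.ndim == 1 or trace.connected_limb is None:
        return arr
    c = trace.connected_limb
    order = [c] + [k for k in range(trace.n_limbs) if k != c]
    return arr[:, order]


def run_replicates(
    agent_cfg: AgentConfig,
    env_cfg: "MobileEnvConfig | VocalizationEnvConfig",
    schedule: PhaseSchedule,
    n_runs: int = 5,
    base_seed: int = 0,
    config_hash: str = "",
    keep_traces: bool = False,
) -> "ExperimentReport | tuple[ExperimentReport, list[SimulationTrace]]":
    """Run ``n_runs`` episodes with seeds base..base+n−1 and aggregate.

    Per-limb series are aligned by relabeling each run's connected limb to
    index 0 before averaging, since runs differ in which limb is connected.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    traces = [
        run_episode(agent_cfg, env_cfg, schedule, base_seed + i, config_hash)
        for i in range(n_runs)
    ]
    report = ExperimentReport(
        seeds=[tr.seed for tr in traces],
        connected_limbs=[tr.connected_limb for tr in traces],
        phase=traces[0].phase,
        config_hash=config_hash,
    )
    for name in _REPORT_QUANTITIES:
        stack = np.stack([_relabeled(tr, name) for tr in traces])
        report.means[name] = stack.mean(axis=0)
        report.sds[name] = stack.std(axis=0)
    if keep_traces:
        return report, traces
    return report


def mean_sweep(
    families,
    mean_values,
    env_cfg: MobileEnvConfig | None = None,
    schedule: PhaseSchedule | None = None,
    n_runs: int = 5,
    base_seed: int = 0,
    agent_overrides: dict | None = None,
) -> pd.DataFrame:
    """Sensitivity of the learned contingency to the contingent outcome mean.

    For each family and each mean μ, runs replicates with the contingent
    law N(μ, baseline scale held fixed) and records the connected limb's
    movement probability at the final connect-phase step.  Returns a table
    with one row per (family, μ): columns family, mu, mean_p, sd_p.
    """
    if len(mean_values) == 0:
        raise ValueError("mean_values must be nonempty")
    env_cfg = env_cfg or MobileEnvConfig(mode="mean_sweep")
    schedule = schedule or PhaseSchedule()
    agent_overrides = agent_overrides or {}
    last_connect = schedule.ranges()["connect"][1] - 1
    rows = []
    for family in families:
        cfg = (
            family
            if isinstance(family, AgentConfig)
            else AgentConfig(family=family, **agent_overrides.get(family, {}))
        )
        for mu in mean_values:
            env = dataclasses.replace(
                env_cfg, mode="mean_sweep", contingent_mean=float(mu)
            )
            finals = []
            for i in range(n_runs):
                tr = run_episode(cfg, env, schedule, base_seed + i)
                finals.append(tr.p_move[last_connect, tr.connected_limb])
            rows.append(
                {
                    "family": cfg.family,
                    "mu": float(mu),
                    "mean_p": float(np.mean(finals)),
                    "sd_p": float(np.std(finals)),
                }
            )
    return pd.DataFrame(rows)


def phase_means(series: np.ndarray, schedule: PhaseSchedule) -> dict:
    """Arithmetic mean of a per-step series within each phase's range.

    ``series`` may be (T,) or (T, k); the leading axis must match the
    schedule length.  Returns {phase label: mean (scalar or (k,) array)}.
    """
    series = np.asarray(series)
    if series.shape[0] != schedule.total_steps:
        raise ValueError("series length does not match the schedule")
    return {
        label: series[start:stop].mean(axis=0)
        for label, (start, stop) in schedule.ranges().items()
    }


def overlay_scale(
    sim_series: np.ndarray,
    steps_per_minute: float,
    target_series: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float | None]:
    """Rescale a simulated series for overlay on empirical data.

    Returns (time axis in minutes, series, factor).  When a target series
    of the same length is supplied, a single multiplicative factor c
    minimizing Σ(target − c·sim)² is fit by least squares (closed form
    Σ(t·s)/Σ(s²)); otherwise the factor is None and magnitudes are returned
    unscaled.
    """
    if steps_per_minute <= 0:
        raise ValueError("steps_per_minute must be > 0")
    sim_series = np.asarray(sim_series, dtype=float)
    minutes = np.arange(sim_series.shape[0]) / float(steps_per_minute)
    factor = None
    if target_series is not None:
        target_series = np.asarray(target_series, dtype=float)
        if target_series.shape != sim_series.shape:
            raise ValueError("target series must match the simulated series")
        denom = float(np.sum(sim_series**2))
        factor = float(np.sum(target_series * sim_series) / denom) if denom else 0.0
    return minutes, sim_series, factor


def run_from_config(config: RunConfig, keep_traces: bool = True):
    """Convenience wrapper: replicates under a full :class:`RunConfig`."""
    return run_replicates(
        config.agent,
        config.environment,
        config.schedule,
        n_runs=config.n_runs,
        base_seed=config.seed,
        config_hash=config.config_hash(),
        keep_traces=keep_traces,
    )
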