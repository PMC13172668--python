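"""Phase-structured synthetic worlds for contingency-learning simulations.

Two paradigms are modelled.  The mobile paradigm mimics the classic crib
experiment: an infant with k binary limb actions faces an overhead mobile
whose movement magnitude m is a scalar stochastic outcome.  Outside the
connect phase m is baseline noise, N(0, 0.3); during the connect phase one
randomly chosen limb is contingently linked to the mobile and activating it
draws m from a contingent law (N(5, 0.3) in the standard setting).  Variants:

* ``inverted`` — the mobile moves by itself during connect and halts when
  the connected limb is active ("my action stops the mobile").
* ``bimodal`` — the contingent law is an equal mixture of N(−2, 1) and
  N(2, 1): acting raises outcome entropy instead of lowering it.
* ``mean_sweep`` — the contingent law is N(μ, 0.3) with configurable μ, for
  sensitivity analyses against the baseline mean of 0.

The vocalization paradigm models a contingent social-feedback experiment
with a single binary action (vocalize or stay silent) and four phases:
baseline 1 (partial feedback), social response (contingent feedback),
extinction (no feedback), baseline 2 (partial feedback).  In the baseline
phases a vocalization receives feedback with probability 0.7.

One simulation step represents 0.5 s by default; the default mobile
schedule is baseline 200 steps, connect 1000, disconnect 800 (2000 total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhaseSchedule",
    "MobileEnvConfig",
    "VocalizationEnvConfig",
    "MOBILE_PHASES",
    "VOCALIZATION_PHASES",
    "mobile_outcome",
    "vocalization_outcome",
]

MOBILE_PHASES = (("baseline", 200), ("connect", 1000), ("disconnect", 800))
VOCALIZATION_PHASES = (
    ("baseline1", 250),
    ("social", 250),
    ("extinction", 250),
    ("baseline2", 250),
)


@dataclass
class PhaseSchedule:
    """Ordered phases with durations in steps.

    ``step_seconds`` records the wall-clock meaning of one step (0.5 s by
    default) for time-axis scaling; it does not affect the dynamics.
    """

    phases: tuple = MOBILE_PHASES
    step_seconds: float = 0.5

    def __post_init__(self) -> None:
        self.phases = tuple((str(label), int(d)) for label, d in self.phases)
        if any(d <= 0 for _, d in self.phases):
            raise ValueError("phase durations must be positive")
        if self.step_seconds <= 0:
            raise ValueError("step_seconds must be positive")

    @property
    def total_steps(self) -> int:
        return sum(d for _, d in self.phases)

    def labels(self) -> np.ndarray:
        """Phase label of every step, length ``total_steps``."""
        return np.asarray(
            [label for label, d in self.phases for _ in range(d)], dtype=object
        )

    def phase_of(self, t: int) -> str:
        if not 0 <= t < self.total_steps:
            raise ValueError(f"step {t} outside schedule of {self.total_steps} steps")
        acc = 0
        for label, d in self.phases:
            acc += d
            if t < acc:
                return label
        raise AssertionError("unreachable")

    def ranges(self) -> dict[str, tuple[int, int]]:
        """Half-open step range [start, stop) per phase label."""
        out, acc = {}, 0
        for label, d in self.phases:
            out[label] = (acc, acc + d)
            acc += d
        return out


def _sd(scale: float, scale_is_variance: bool) -> float:
    return float(np.sqrt(scale)) if scale_is_variance else float(scale)


@dataclass
class MobileEnvConfig:
    """Outcome-generating rules for the mobile paradigm.

    ``connected_limb`` of None means "choose uniformly at random per run"
    (done by the experiment runner with the run's seed).  ``scale``
    parameters are standard deviations unless ``scale_is_variance`` is set,
    in which case they are read as variances.
    """

    n_limbs: int = 4
    connected_limb: int | None = None
    mode: str = "standard"  # standard | inverted | bimodal | mean_sweep
    baseline_mean: float = 0.0
    baseline_scale: float = 0.3
    contingent_mean: float = 5.0
    contingent_scale: float = 0.3
    bimodal_components: tuple = ((-2.0, 1.0), (2.0, 1.0))
    scale_is_variance: bool = False

    def __post_init__(self) -> None:
        if self.n_limbs < 1:
            raise ValueError("n_limbs must be >= 1")
        if self.mode not in ("standard", "inverted", "bimodal", "mean_sweep"):
            raise ValueError(f"unknown mobile mode: {self.mode!r}")
        if self.baseline_scale <= 0 or self.contingent_scale <= 0:
            raise ValueError("scales must be positive")
        if self.connected_limb is not None and not (
            0 <= self.connected_limb < self.n_limbs
        ):
            raise ValueError("connected_limb out of range")

    def draw_baseline(self, rng: np.random.Generator) -> float:
        return float(
            rng.normal(self.baseline_mean, _sd(self.baseline_scale, self.scale_is_variance))
        )

    def draw_contingent(self, rng: np.random.Generator) -> float:
        if self.mode == "bimodal":
            mean, scale = self.bimodal_components[
                rng.integers(len(self.bimodal_components))
            ]
            return float(rng.normal(mean, _sd(scale, self.scale_is_variance)))
        return float(
            rng.normal(
                self.contingent_mean, _sd(self.contingent_scale, self.scale_is_variance)
            )
        )


def mobile_outcome(
    config: MobileEnvConfig,
    phase: str,
    actions: np.ndarray,
    rng: np.random.Generator,
) -> float:
    """Sample the mobile-movement outcome m for one step.

    Baseline and disconnect phases draw from the baseline law regardless of
    actions.  In the connect phase the contingent law applies when the
    connected limb is active (standard/bimodal/mean_sweep) or when it is
    *inactive* (inverted — the mobile moves by itself and halts when the
    connected limb acts).
    """
    actions = np.asarray(actions)
    if actions.shape != (config.n_limbs,):
        raise ValueError(f"actions must have {config.n_limbs} binary entries")
    if phase in ("baseline", "disconnect"):
        return config.draw_baseline(rng)
    if phase != "connect":
        raise ValueError(f"unknown mobile phase: {phase!r}")
    if config.connected_limb is None:
        raise ValueError("connected_limb must be resolved before sampling")
    active = bool(actions[config.connected_limb])
    contingent = (not active) if config.mode == "inverted" else active
    return config.draw_contingent(rng) if contingent else config.draw_baseline(rng)


@dataclass
class VocalizationEnvConfig:
    """Outcome rules for the contingent-vocalization paradigm.

    One binary action (vocalize).  Feedback draws from the feedback law
    (default N(5, 0.3)); its absence from the no-feedback law (default
    N(0, 0.3)).  Baseline phases give probabilistic partial feedback to
    vocalizations at ``partial_feedback_prob`` (default 0.7, matching the
    caregiver response rate assumed for the familiarization baseline).
    """

    partial_feedback_prob: float = 0.7
    feedback_mean: float = 5.0
    feedback_scale: float = 0.3
    no_feedback_mean: float = 0.0
    no_feedback_scale: float = 0.3
    scale_is_variance: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.partial_feedback_prob <= 1:
            raise ValueError("partial_feedback_prob must be in [0, 1]")
        if self.feedback_scale <= 0 or self.no_feedback_scale <= 0:
            raise ValueError("scales must be positive")

    def draw_feedback(self, rng: np.random.Generator) -> float:
        return float(
            rng.normal(self.feedback_mean, _sd(self.feedback_scale, self.scale_is_variance))
        )

    def draw_no_feedback(self, rng: np.random.Generator) -> float:
        return float(
            rng.normal(
                self.no_feedback_mean, _sd(self.no_feedback_scale, self.scale_is_variance)
            )
        )


def vocalization_outcome(
    config: VocalizationEnvConfig,
    phase: str,
    action: int,
    rng: np.random.Generator,
) -> float:
    """Sample the feedback outcome for one vocalization step.

    Social phase: contingent feedback iff vocalizing.  Extinction: never.
    Baseline phases: vocalizations get feedback with the partial-feedback
    probability.  Silence always draws from the no-feedback law.
    """
    if phase not in ("baseline1", "social", "extinction", "baseline2"):
        raise ValueError(f"unknown vocalization phase: {phase!r}")
    vocalizing = bool(action)
    if not vocalizing or phase == "extinction":
        return config.draw_no_feedback(rng)
    if phase == "social":
        return config.draw_feedback(rng)
    # partial-feedback baselines
    if rng.random() < config.partial_feedback_prob:
        return config.draw_feedback(rng)
    return config.draw_no_feedback(rng)
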