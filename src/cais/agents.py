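"""The three agent families mapping observation history to limb movement.

*Causal agent* — maintains, per limb, one learned quantile distribution per
binary action state plus one shared marginal (2k+1 distributions; nine for
four limbs).  After each outcome it updates the marginal and, per limb, the
conditional of the state the limb actually took, recomputes the CAIS for
every state-action pair, averages a limb's two pair scores into its causal
engagement score, and normalizes that against the baseline causal inertia
(mean score over all pairs) through a sigmoid to get the limb's movement
probability for the next step.  An optional surprise term α·S_k (the
quantile-interval width of the observed outcome under the limb's taken-state
conditional) is added to the engagement before normalization; it produces
extinction bursts when a learned contingency is abruptly removed.  Scores
are smoothed with an exponential moving average (ε = 0.03, applied from the
third step on).

*Direct reinforcement agent* — the babybot-style tabular baseline: one
movement probability per limb, initialized to 0.2, bumped up by 0.01 when
the limb moved and the mobile responded beyond a threshold of 2.5, and down
by 0.005 when it moved without such a response.  Purely correlational — it
cannot represent "my action stops the mobile".

*Controllability agent* — identical pipeline to the causal agent, but the
per-limb score is the entropy-reduction heuristic mean_a[H(m) − H(m|a)]
instead of CAIS, and there is no surprise term.  It fails in the bimodal
setting where acting raises outcome entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import CausalScores, cais, quantile_entropy, surprise
from .quantile_dist import (
    AdamState,
    QuantileDistribution,
    adam_step,
    init_distribution,
    loss_gradient,
)

__all__ = [
    "CausalAgentState",
    "ReinforcementAgentState",
    "ControllabilityAgentState",
    "StepInfo",
    "causal_scores",
    "apply_surprise",
    "ema_smooth",
    "movement_probability",
    "causal_agent_step",
    "reinforcement_agent_step",
    "controllability_agent_step",
]


@dataclass
class StepInfo:
    """Per-step diagnostics emitted by an agent update."""

    engagement_raw: np.ndarray  # pre-surprise, pre-EMA
    engagement_adjusted: np.ndarray  # post-surprise, pre-EMA
    engagement_smoothed: np.ndarray  # what drives action selection
    surprise: np.ndarray
    inertia: float
    p_move: np.ndarray


@dataclass
class CausalAgentState:
    """Distributions, optimizer states and smoothed scores of a causal agent."""

    n_limbs: int = 4
    n_quantiles: int = 49
    alpha: float = 0.0  # surprise weight; 0 disables the term
    ema_eps: float = 0.03
    kappa: float = 1.0
    surprise_source: str = "conditional"  # or "marginal"
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    conditionals: list = field(default_factory=list)  # [limb][state]
    cond_opts: list = field(default_factory=list)
    marginal: QuantileDistribution | None = None
    marginal_opt: AdamState | None = None
    engagement_smoothed: np.ndarray | None = None
    inertia_smoothed: float | None = None
    last_actions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if not 0 < self.ema_eps <= 1:
            raise ValueError("ema_eps must be in (0, 1]")
        if self.surprise_source not in ("conditional", "marginal"):
            raise ValueError(f"unknown surprise_source: {self.surprise_source!r}")
        if not self.conditionals:
            self.conditionals = [
                [init_distribution(self.n_quantiles) for _ in range(2)]
                for _ in range(self.n_limbs)
            ]
            self.cond_opts = [
                [self._opt(d) for d in limb] for limb in self.conditionals
            ]
            self.marginal = init_distribution(self.n_quantiles)
            self.marginal_opt = self._opt(self.marginal)
        if self.last_actions is None:
            self.last_actions = np.zeros(self.n_limbs, dtype=int)

    def _opt(self, dist: QuantileDistribution) -> AdamState:
        return AdamState.for_distribution(
            dist, self.adam_beta1, self.adam_beta2, self.adam_eps
        )

    def initial_probabilities(self) -> np.ndarray:
        """Movement probabilities before any observation (all scores equal)."""
        return np.full(self.n_limbs, 0.5)


@dataclass
class ControllabilityAgentState(CausalAgentState):
    """Causal-agent structure with the entropy-difference score; no surprise."""

    alpha: float = 0.0


@dataclass
class ReinforcementAgentState:
    """Tabular babybot-style agent: one movement probability per limb."""

    n_limbs: int = 4
    init_prob: float = 0.2
    threshold: float = 2.5
    increment: float = 0.01
    decrement: float = 0.005
    prob_floor: float = 0.001
    prob_ceil: float = 1.0
    multiplicative: bool = False
    probs: np.ndarray | None = None
    last_actions: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.init_prob <= 1:
            raise ValueError("init_prob must be in (0, 1]")
        if not 0 <= self.prob_floor < self.prob_ceil <= 1:
            raise ValueError("need 0 <= prob_floor < prob_ceil <= 1")
        if self.probs is None:
            self.probs = np.full(self.n_limbs, self.init_prob)
        if self.last_actions is None:
            self.last_actions = np.zeros(self.n_limbs, dtype=int)

    def initial_probabilities(self) -> np.ndarray:
        return self.probs.copy()


def causal_scores(state: CausalAgentState) -> CausalScores:
    """CAIS for every state-action pair plus engagement and inertia."""
    pairs = np.array(
        [
            [cais(state.conditionals[k][s], state.marginal) for s in range(2)]
            for k in range(state.n_limbs)
        ]
    )
    return CausalScores.from_pairs(pairs)


def _controllability_scores(state: CausalAgentState) -> CausalScores:
    """Entropy-reduction scores: how much does *performing* the action
    stabilize the outcome?

    The per-limb engagement is H(m) − H(m|a^k=1), the entropy change under
    the active state.  Conditioning on inaction (a^k=0) is excluded: the
    heuristic asks whether acting yields a more predictable world, which is
    exactly the stability bias that makes it blind to actions that raise
    outcome entropy (the bimodal failure mode).  Both per-state entropy
    differences are kept as pair scores for diagnostics.
    """
    h_m = quantile_entropy(state.marginal)
    pairs = np.array(
        [
            [h_m - quantile_entropy(state.conditionals[k][s]) for s in range(2)]
            for k in range(state.n_limbs)
        ]
    )
    engagement = pairs[:, 1]
    return CausalScores(
        pair_scores=pairs, engagement=engagement, inertia=float(engagement.mean())
    )


def apply_surprise(
    scores: CausalScores, limb_surprise: np.ndarray, alpha: float
) -> CausalScores:
    """Add the weighted surprise to each limb's engagement.

    The baseline inertia is recomputed as the mean of the adjusted limb
    engagements so that it reflects the updated scores across all limbs.
    An equal surprise on every limb therefore shifts engagements and
    inertia alike and leaves the sigmoid probabilities unchanged.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    adjusted = scores.engagement + alpha * np.asarray(limb_surprise, dtype=float)
    return CausalScores(
        pair_scores=scores.pair_scores,
        engagement=adjusted,
        inertia=float(adjusted.mean()),
    )


def ema_smooth(previous, new, eps: float, t: int):
    """Exponential moving average ε·new + (1−ε)·previous, active for t > 1."""
    if not 0 < eps <= 1:
        raise ValueError("eps must be in (0, 1]")
    if t <= 1 or previous is None:
        return new
    return eps * new + (1 - eps) * previous


def movement_probability(engagement, inertia):
    """Sigmoid normalization of engagement against the baseline inertia."""
    return 1.0 / (1.0 + np.exp(np.asarray(inertia) - np.asarray(engagement)))


def _update_distributions(state: CausalAgentState, outcome: float, lr: float) -> None:
    # marginal absorbs every outcome; per limb, only the conditional of the
    # action state the limb actually took
    grad = loss_gradient(state.marginal, outcome, state.kappa)
    adam_step(state.marginal, state.marginal_opt, grad, lr)
    for k in range(state.n_limbs):
        s = int(state.last_actions[k])
        dist, opt = state.conditionals[k][s], state.cond_opts[k][s]
        adam_step(dist, opt, loss_gradient(dist, outcome, state.kappa), lr)


def _distributional_step(
    state: CausalAgentState,
    outcome: float,
    lr: float,
    t: int,
    rng: np.random.Generator,
    score_fn,
) -> tuple[np.ndarray, StepInfo]:
    if outcome is None:
        raise ValueError("an observed outcome is required before stepping")
    _update_distributions(state, outcome, lr)
    scores = score_fn(state)
    limb_surprise = np.array(
        [
            surprise(
                state.marginal
                if state.surprise_source == "marginal"
                else state.conditionals[k][int(state.last_actions[k])],
                outcome,
            )
            for k in range(state.n_limbs)
        ]
    )
    adjusted = (
        apply_surprise(scores, limb_surprise, state.alpha)
        if state.alpha > 0
        else scores
    )
    state.engagement_smoothed = ema_smooth(
        state.engagement_smoothed, adjusted.engagement, state.ema_eps, t
    )
    state.inertia_smoothed = float(
        ema_smooth(state.inertia_smoothed, adjusted.inertia, state.ema_eps, t)
    )
    p = movement_probability(state.engagement_smoothed, state.inertia_smoothed)
    actions = (rng.random(state.n_limbs) < p).astype(int)
    info = StepInfo(
        engagement_raw=scores.engagement.copy(),
        engagement_adjusted=adjusted.engagement.copy(),
        engagement_smoothed=np.asarray(state.engagement_smoothed).copy(),
        surprise=limb_surprise,
        inertia=state.inertia_smoothed,
        p_move=np.asarray(p).copy(),
    )
    state.last_actions = actions
    return actions, info


def causal_agent_step(
    state: CausalAgentState,
    outcome: float,
    lr: float,
    t: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, StepInfo]:
    """Absorb one outcome, update scores, and sample the next actions.

    Bit-reproducible given the generator state.  Exactly n_limbs + 1
    distributions receive an update per call.
    """
    return _distributional_step(state, outcome, lr, t, rng, causal_scores)


def controllability_agent_step(
    state: CausalAgentState,
    outcome: float,
    lr: float,
    t: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, StepInfo]:
    """As :func:`causal_agent_step` with the controllability score, no surprise."""
    return _distributional_step(state, outcome, lr, t, rng, _controllability_scores)


def reinforcement_agent_step(
    state: ReinforcementAgentState,
    outcome: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, StepInfo]:
    """Babybot update: reinforce moved limbs on suprathreshold outcomes.

    Every limb that moved and was followed by an outcome above the
    threshold is reinforced — including limbs whose co-occurrence with the
    mobile's response is pure coincidence, which is what produces the
    spurious-correlation behavior.  Limbs that did not move are unchanged.
    """
    moved = state.last_actions.astype(bool)
    rewarded = outcome > state.threshold
    p = state.probs.copy()
    if state.multiplicative:
        factor = (1 + state.increment) if rewarded else (1 - state.decrement)
        p[moved] *= factor
    else:
        delta = state.increment if rewarded else -state.decrement
        p[moved] += delta
    state.probs = np.clip(p, state.prob_floor, state.prob_ceil)
    actions = (rng.random(state.n_limbs) < state.probs).astype(int)
    nan = np.full(state.n_limbs, np.nan)
    info = StepInfo(
        engagement_raw=nan,
        engagement_adjusted=nan,
        engagement_smoothed=nan,
        surprise=nan,
        inertia=float("nan"),
        p_move=state.probs.copy(),
    )
    state.last_actions = actions
    return actions, info
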