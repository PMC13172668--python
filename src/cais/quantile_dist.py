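"""Online quantile-function estimation of outcome distributions.

An outcome distribution (e.g., how much the mobile moves) is represented
non-parametrically by its quantile function evaluated on a fixed grid of
quantile levels.  The quantile values are free learnable parameters — no
network, no parametric family — trained one observation at a time with the
asymmetric quantile Huber loss familiar from distributional reinforcement
learning, under an Adam optimizer and a one-cycle cosine-annealed learning
rate.  The default grid has 49 levels from 2% to 98% in 2% steps.

Because independent per-quantile updates can transiently cross (a higher
level ending up with a lower value), readers that need an ordered quantile
function (surprise, entropy, Wasserstein distances) go through
:func:`monotone_view`, which sorts at read time and leaves the learnable
parameters untouched.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantileDistribution",
    "AdamState",
    "LearningSchedule",
    "init_distribution",
    "quantile_error",
    "huber",
    "loss_gradient",
    "adam_step",
    "learning_rate",
    "monotone_view",
]


@dataclass
class QuantileDistribution:
    """A learnable quantile function q(τ) on a fixed grid of levels τ.

    Attributes
    ----------
    taus : np.ndarray
        Strictly increasing quantile levels in (0, 1).
    values : np.ndarray
        Learned quantile values, one per level, in outcome units.  Not
        guaranteed monotone during training; see :func:`monotone_view`.
    n_updates : int
        Number of observations absorbed so far.
    """

    taus: np.ndarray
    values: np.ndarray
    n_updates: int = 0

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.taus.ndim != 1 or self.taus.size < 2:
            raise ValueError("taus must be a 1-D grid with at least 2 levels")
        if np.any(np.diff(self.taus) <= 0):
            raise ValueError("taus must be strictly increasing")
        if np.any((self.taus <= 0) | (self.taus >= 1)):
            raise ValueError("taus must lie strictly inside (0, 1)")
        if self.values.shape != self.taus.shape:
            raise ValueError("values and taus must have the same length")

    def to_json(self) -> str:
        return json.dumps(
            {
                "taus": self.taus.tolist(),
                "values": self.values.tolist(),
                "n_updates": self.n_updates,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "QuantileDistribution":
        obj = json.loads(text)
        return cls(
            taus=np.asarray(obj["taus"], dtype=float),
            values=np.asarray(obj["values"], dtype=float),
            n_updates=int(obj["n_updates"]),
        )


@dataclass
class AdamState:
    """Per-quantile Adam accumulators for one distribution."""

    first_moment: np.ndarray
    second_moment: np.ndarray
    step_count: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps_stability: float = 1e-8

    @classmethod
    def for_distribution(
        cls,
        dist: QuantileDistribution,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps_stability: float = 1e-8,
    ) -> "AdamState":
        n = dist.values.size
        return cls(
            first_moment=np.zeros(n),
            second_moment=np.zeros(n),
            beta1=beta1,
            beta2=beta2,
            eps_stability=eps_stability,
        )


@dataclass
class LearningSchedule:
    """Learning-rate schedule over a simulation horizon.

    ``cosine`` mode decays the rate smoothly from ``lr_initial`` at step 0
    to exactly 0 at ``total_steps`` (one half cosine cycle); ``constant``
    holds ``lr_initial`` throughout.
    """

    lr_initial: float = 0.03
    total_steps: int = 2000
    mode: str = "cosine"

    def __post_init__(self) -> None:
        if self.lr_initial < 0:
            raise ValueError("lr_initial must be >= 0")
        if self.total_steps < 1:
            raise ValueError("total_steps must be >= 1")
        if self.mode not in ("cosine", "constant"):
            raise ValueError(f"unknown schedule mode: {self.mode!r}")


def init_distribution(
    grid_size: int, value_init: "str | float | np.ndarray" = "zeros"
) -> QuantileDistribution:
    """Create a quantile distribution on the symmetric interior grid.

    The grid places ``grid_size`` levels at i/(grid_size+1) for
    i = 1..grid_size, so 49 levels give 0.02, 0.04, ..., 0.98 and 3 levels
    give 0.25, 0.50, 0.75.

    Parameters
    ----------
    grid_size : int
        Number of quantile levels; must be at least 2.
    value_init : "zeros", scalar, or array
        Initial quantile values.  The default of all zeros matches the
        baseline outcome mean, a neutral reproducible start.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    taus = np.arange(1, grid_size + 1, dtype=float) / (grid_size + 1)
    if isinstance(value_init, str):
        if value_init != "zeros":
            raise ValueError(f"unknown initializer: {value_init!r}")
        values = np.zeros(grid_size)
    elif np.isscalar(value_init):
        values = np.full(grid_size, float(value_init))
    else:
        values = np.asarray(value_init, dtype=float).copy()
        if values.shape != taus.shape:
            raise ValueError("value_init array must have length grid_size")
    return QuantileDistribution(taus=taus, values=values)


def quantile_error(tau: float, q_tau: float, y_hat: float) -> float:
    """Asymmetric quantile error u(qτ, ŷ), nonnegative by construction.

    Over-prediction (ŷ ≤ qτ) is weighted by τ, under-prediction by 1−τ, so
    the minimizer of the expected error is the τ-quantile of the target.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    if y_hat <= q_tau:
        return tau * (q_tau - y_hat)
    return (1 - tau) * (y_hat - q_tau)


def huber(u: float, kappa: float = 1.0) -> float:
    """Huber penalty: quadratic for |u| ≤ κ, linear beyond."""
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    au = abs(u)
    if au <= kappa:
        return 0.5 * u * u
    return kappa * (au - 0.5 * kappa)


def loss_gradient(
    dist: QuantileDistribution, y_hat: float, kappa: float = 1.0
) -> np.ndarray:
    """Analytic gradient of the quantile Huber loss w.r.t. each quantile value.

    The loss for quantile i is the Huber penalty of the asymmetric quantile
    error; the chain rule through its two branches gives

        dL/dq_i = L'(u_i) * du_i/dq_i,

    with L'(u) = u for |u| ≤ κ and κ·sign(u) beyond, and du/dq = τ on the
    over-prediction branch (ŷ ≤ q) and −(1−τ) on the other.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    q = dist.values
    tau = dist.taus
    over = y_hat <= q
    u = np.where(over, tau * (q - y_hat), (1 - tau) * (y_hat - q))
    dl_du = np.where(u <= kappa, u, kappa)  # u >= 0 always
    du_dq = np.where(over, tau, -(1 - tau))
    return dl_du * du_dq


def adam_step(
    dist: QuantileDistribution,
    opt: AdamState,
    grad: np.ndarray,
    lr: float,
) -> tuple[QuantileDistribution, AdamState]:
    """One bias-corrected Adam update of the quantile values, in place.

    Increments the distribution's observation count; deterministic given
    its inputs.  Returns the (mutated) distribution and optimizer state.
    """
    grad = np.asarray(grad, dtype=float)
    if grad.shape != dist.values.shape:
        raise ValueError("gradient shape does not match quantile values")
    if lr < 0:
        raise ValueError("lr must be >= 0")
    opt.step_count += 1
    opt.first_moment = opt.beta1 * opt.first_moment + (1 - opt.beta1) * grad
    opt.second_moment = opt.beta2 * opt.second_moment + (1 - opt.beta2) * grad**2
    m_hat = opt.first_moment / (1 - opt.beta1**opt.step_count)
    v_hat = opt.second_moment / (1 - opt.beta2**opt.step_count)
    dist.values = dist.values - lr * m_hat / (np.sqrt(v_hat) + opt.eps_stability)
    dist.n_updates += 1
    return dist, opt


def learning_rate(schedule: LearningSchedule, t: int) -> float:
    """Learning rate at step t of the schedule."""
    if not 0 <= t <= schedule.total_steps:
        raise ValueError(
            f"step {t} outside schedule horizon [0, {schedule.total_steps}]"
        )
    if schedule.mode == "constant":
        return schedule.lr_initial
    return schedule.lr_initial * 0.5 * (1 + np.cos(np.pi * t / schedule.total_steps))


def monotone_view(dist: QuantileDistribution) -> np.ndarray:
    """Nondecreasing copy of the quantile values (sorted ascending).

    Independent per-quantile updates can transiently cross; sorting is the
    simplest repair and leaves the learnable parameters untouched.
    """
    return np.sort(dist.values)
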