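"""Unit tests for the learnable quantile-function estimator."""

import numpy as np
import pytest

from cais.quantile_dist import (
    AdamState,
    LearningSchedule,
    QuantileDistribution,
    adam_step,
    huber,
    init_distribution,
    learning_rate,
    loss_gradient,
    monotone_view,
    quantile_error,
)


class TestGridConstruction:
    def test_default_49_grid_spans_2_to_98_percent(self):
        dist = init_distribution(49)
        assert np.allclose(dist.taus, np.arange(1, 50) / 50.0)
        assert np.all(dist.values == 0)
        assert dist.n_updates == 0

    def test_small_grid_is_symmetric_interior(self):
        dist = init_distribution(3)
        assert np.allclose(dist.taus, [0.25, 0.5, 0.75])

    @pytest.mark.parametrize("bad", [1, 0, -3])
    def test_degenerate_grid_rejected(self, bad):
        with pytest.raises(ValueError):
            init_distribution(bad)

    def test_scalar_and_array_initializers(self):
        assert np.all(init_distribution(5, 2.0).values == 2.0)
        vals = np.arange(5.0)
        assert np.all(init_distribution(5, vals).values == vals)
        with pytest.raises(ValueError):
            init_distribution(5, np.arange(3.0))

    def test_invalid_tau_grids_rejected(self):
        with pytest.raises(ValueError):
            QuantileDistribution(taus=np.array([0.5, 0.2]), values=np.zeros(2))
        with pytest.raises(ValueError):
            QuantileDistribution(taus=np.array([0.0, 0.5]), values=np.zeros(2))

    def test_json_round_trip(self):
        dist = init_distribution(5, np.arange(5.0))
        dist.n_updates = 7
        clone = QuantileDistribution.from_json(dist.to_json())
        assert np.array_equal(clone.taus, dist.taus)
        assert np.array_equal(clone.values, dist.values)
        assert clone.n_updates == 7


class TestLossPieces:
    @pytest.mark.parametrize(
        "tau,q,y,expected",
        [(0.5, 1.0, 0.0, 0.5), (0.9, 0.0, 1.0, 0.1), (0.3, 2.0, 2.0, 0.0)],
    )
    def test_quantile_error_examples(self, tau, q, y, expected):
        assert quantile_error(tau, q, y) == pytest.approx(expected)

    def test_quantile_error_is_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tau, q, y = rng.uniform(0.01, 0.99), rng.normal(), rng.normal()
            assert quantile_error(tau, q, y) >= 0

    def test_quantile_error_rejects_boundary_tau(self):
        with pytest.raises(ValueError):
            quantile_error(0.0, 1.0, 0.0)

    @pytest.mark.parametrize(
        "u,expected", [(0.0, 0.0), (0.5, 0.125), (2.0, 1.5), (-2.0, 1.5)]
    )
    def test_huber_examples(self, u, expected):
        assert huber(u, 1.0) == pytest.approx(expected)

    def test_huber_rejects_nonpositive_kappa(self):
        with pytest.raises(ValueError):
            huber(1.0, 0.0)

    def test_gradient_vanishes_at_the_observation(self):
        dist = init_distribution(9, 3.0)
        assert np.all(loss_gradient(dist, 3.0) == 0)

    def test_gradient_single_quantile_closed_form(self):
        # τ=0.5, q=1, ŷ=0: u = 0.5, in the quadratic regime, du/dq = τ
        dist = QuantileDistribution(taus=np.array([0.4, 0.5, 0.6]),
                                    values=np.array([1.0, 1.0, 1.0]))
        grad = loss_gradient(dist, 0.0, kappa=1.0)
        assert grad[1] == pytest.approx(0.5 * 0.5)

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(42)
        dist = init_distribution(49)
        h = 1e-5
        checked = 0
        while checked < 300:
            dist.values = rng.normal(scale=3.0, size=49)
            y = rng.normal(scale=3.0)
            u = np.array(
                [quantile_error(t, q, y) for t, q in zip(dist.taus, dist.values)]
            )
            # avoid the measure-zero branch points of both piecewise pieces
            if np.any(np.abs(dist.values - y) < 1e-3) or np.any(np.abs(u - 1) < 1e-3):
                continue
            analytic = loss_gradient(dist, y)
            for i in rng.choice(49, size=4, replace=False):
                plus, minus = dist.values.copy(), dist.values.copy()
                plus[i] += h
                minus[i] -= h
                fd = (
                    huber(quantile_error(dist.taus[i], plus[i], y))
                    - huber(quantile_error(dist.taus[i], minus[i], y))
                ) / (2 * h)
                assert analytic[i] == pytest.approx(fd, abs=1e-6)
                checked += 1


class TestAdam:
    def test_zero_gradient_is_a_no_op(self):
        dist = init_distribution(5, 1.0)
        opt = AdamState.for_distribution(dist)
        adam_step(dist, opt, np.zeros(5), lr=0.03)
        assert np.all(dist.values == 1.0)
        assert opt.step_count == 1
        assert dist.n_updates == 1

    def test_zero_learning_rate_freezes_values(self):
        dist = init_distribution(5, 1.0)
        opt = AdamState.for_distribution(dist)
        adam_step(dist, opt, np.ones(5), lr=0.0)
        assert np.all(dist.values == 1.0)

    @pytest.mark.parametrize("g", [0.7, -2.0])
    def test_first_step_moves_by_lr_times_sign(self, g):
        # bias corrections cancel on step one: Δ = −lr·g/(|g| + eps)
        dist = init_distribution(2, 0.0)
        opt = AdamState.for_distribution(dist)
        adam_step(dist, opt, np.full(2, g), lr=0.03)
        assert np.allclose(dist.values, -0.03 * np.sign(g), atol=1e-6)

    def test_shape_mismatch_rejected(self):
        dist = init_distribution(5)
        opt = AdamState.for_distribution(dist)
        with pytest.raises(ValueError):
            adam_step(dist, opt, np.zeros(3), lr=0.01)


class TestLearningSchedule:
    def test_cosine_endpoints_and_midpoint(self):
        sched = LearningSchedule(lr_initial=0.03, total_steps=1000, mode="cosine")
        assert learning_rate(sched, 0) == pytest.approx(0.03)
        assert learning_rate(sched, 1000) == pytest.approx(0.0, abs=1e-15)
        assert learning_rate(sched, 500) == pytest.approx(0.015)

    def test_cosine_is_nonincreasing(self):
        sched = LearningSchedule(total_steps=200)
        rates = [learning_rate(sched, t) for t in range(201)]
        assert np.all(np.diff(rates) <= 0)

    def test_constant_mode(self):
        sched = LearningSchedule(lr_initial=0.03, total_steps=10, mode="constant")
        assert learning_rate(sched, 7) == 0.03

    def test_out_of_range_step_rejected(self):
        sched = LearningSchedule(total_steps=10)
        with pytest.raises(ValueError):
            learning_rate(sched, 11)


class TestMonotoneView:
    def test_sorted_input_is_identity(self):
        dist = init_distribution(5, np.arange(5.0))
        assert np.array_equal(monotone_view(dist), np.arange(5.0))

    def test_crossed_values_are_repaired_without_mutation(self):
        dist = init_distribution(2, np.array([1.0, 0.0]))
        assert np.array_equal(monotone_view(dist), [0.0, 1.0])
        assert np.array_equal(dist.values, [1.0, 0.0])

    def test_matches_sorting_contract(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=49)
        dist = init_distribution(49, vals)
        assert np.array_equal(monotone_view(dist), np.sort(vals))


def _train(seed, n_draws=10_000, mean=5.0, sd=0.3):
    rng = np.random.default_rng(seed)
    dist = init_distribution(49)
    opt = AdamState.for_distribution(dist)
    sched = LearningSchedule(lr_initial=0.03, total_steps=n_draws, mode="cosine")
    for t in range(n_draws):
        y = rng.normal(mean, sd)
        adam_step(dist, opt, loss_gradient(dist, y), learning_rate(sched, t))
    return monotone_view(dist)


def _huber_quantile_minimizer(tau, mean=5.0, sd=0.3, kappa=1.0):
    """Root of the expected quantile-Huber gradient under N(mean, sd).

    In the quadratic regime the asymmetric Huber composition minimizes an
    expectile-like criterion with weight ratio (τ/(1−τ))², not the exact
    quantile, so the tail levels settle beyond the true quantiles.  This
    oracle integrates the expected gradient and solves for its root.
    """
    from scipy import integrate, optimize, stats

    def expected_grad(q):
        over = integrate.quad(
            lambda y: min(tau * (q - y), kappa) * tau * stats.norm.pdf(y, mean, sd),
            mean - 8 * sd, q,
        )[0]
        under = integrate.quad(
            lambda y: min((1 - tau) * (y - q), kappa)
            * (1 - tau)
            * stats.norm.pdf(y, mean, sd),
            q, mean + 8 * sd,
        )[0]
        return over - under

    return optimize.brentq(expected_grad, mean - 8 * sd, mean + 8 * sd)


def test_parameter_recovery_from_gaussian_draws():
    """Training on 10k N(5, 0.3) draws recovers the median, and the tail
    values settle at the loss's own expected minimizers."""
    lo = min(_huber_quantile_minimizer(t) for t in (0.02, 0.98))
    hi = max(_huber_quantile_minimizer(t) for t in (0.02, 0.98))
    good = 0
    for seed in range(5):
        q = _train(seed)
        ok = (
            abs(q[24] - 5.0) < 0.1
            and abs(q[0] - lo) < 0.15
            and abs(q[-1] - hi) < 0.15
        )
        good += ok
    assert good >= 4
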