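import math

import numpy as np
import pytest
import scipy.stats as st

from helpers import dense_gaussian_loglik
from orderstates.dynamics import FirstOrderModel, InputSpec, SecondOrderModel, Trajectory, simulate
from orderstates.exceptions import ContractError, ParameterError
from orderstates.inversion import (
    OptimizerOptions,
    PriorSpec,
    default_priors,
    fit_map,
    free_energy,
    invert_both_orders,
    marginal_loglik,
    pack_params,
    param_names,
)

TR = 0.72


def _short(traj, T):
    return Trajectory(traj.times[:T], traj.inputs[:T], None, traj.observed[:T])


def _random_instance(order, n, T, seed):
    rng = np.random.default_rng(seed)
    kw = dict(
        a_diag=rng.uniform(-1.0, -0.2, n),
        c_diag=rng.uniform(0.2, 1.0, n),
        sigma_state=np.full(n, rng.uniform(0.1, 0.3)),
        sigma_obs=rng.uniform(0.1, 0.4),
        x0=rng.normal(size=n),
    )
    model = (
        SecondOrderModel(**kw, xdot0=rng.normal(size=n)) if order == 2 else FirstOrderModel(**kw)
    )
    spec = InputSpec("random_boxcar", rate=0.1, block_duration=5.0, seed=seed + 1)
    traj = simulate(model, 30 * TR, TR, spec, seed=seed + 2)
    theta = pack_params(
        order, model.a_diag, model.c_diag, model.x0,
        model.xdot0 if order == 2 else None,
        -math.log(float(model.sigma_state[0]) ** 2), -math.log(model.sigma_obs**2),
    )
    return theta, _short(traj, T)


class TestMarginalLoglik:
    @pytest.mark.parametrize("order", [1, 2])
    @pytest.mark.parametrize("T", [5, 12, 20])
    def test_kalman_equals_dense_gaussian(self, order, T):
        """Prediction-error decomposition matches the brute-force joint density."""
        for seed in (0, 7, 19):
            theta, traj = _random_instance(order, 2, T, seed)
            kf = marginal_loglik(theta, traj, order)
            dense = dense_gaussian_loglik(theta, traj, order)
            assert kf == pytest.approx(dense, abs=1e-8)

    def test_sign_symmetry_without_input(self):
        theta, traj = _random_instance(1, 2, 15, 3)
        theta = theta.copy()
        theta[2:4] = 0.0  # zero c
        theta[4:6] = 0.0  # zero x0: model mean is exactly zero
        flipped = Trajectory(traj.times, np.zeros_like(traj.inputs), None, -traj.observed)
        base = Trajectory(traj.times, np.zeros_like(traj.inputs), None, traj.observed)
        assert marginal_loglik(theta, base, 1) == pytest.approx(
            marginal_loglik(theta, flipped, 1), abs=1e-12
        )

    def test_independent_regions_factorize(self):
        """Two identical decoupled regions with duplicated data give 2x the loglik."""
        m1 = FirstOrderModel([-0.5], [0.0], [0.2], 0.3, [1.2])
        tr = simulate(m1, 20 * TR, TR, InputSpec(), seed=9)
        single = Trajectory(tr.times, tr.inputs, None, tr.observed)
        dup = Trajectory(
            tr.times, np.zeros((len(tr.times), 2)), None,
            np.column_stack([tr.observed[:, 0], tr.observed[:, 0]]),
        )
        lam = (-math.log(0.2**2), -math.log(0.3**2))
        th1 = pack_params(1, [-0.5], [0.0], [1.2], None, *lam)
        th2 = pack_params(1, [-0.5] * 2, [0.0] * 2, [1.2] * 2, None, *lam)
        assert marginal_loglik(th2, dup, 1) == pytest.approx(
            2 * marginal_loglik(th1, single, 1), abs=1e-9
        )

    def test_nonfinite_params_rejected(self):
        _, traj = _random_instance(1, 2, 10, 0)
        bad = pack_params(1, [np.nan, -0.5], [0.0] * 2, [0.0] * 2, None, 0.0, 0.0)
        with pytest.raises(ParameterError):
            marginal_loglik(bad, traj, 1)

    def test_wrong_length_rejected(self):
        _, traj = _random_instance(1, 2, 10, 0)
        with pytest.raises(ContractError):
            marginal_loglik(np.zeros(3), traj, 1)


class TestFitMap:
    def test_tight_prior_pins_posterior_to_prior_mean(self, first_order_traj):
        names = param_names(1, 3)
        priors = PriorSpec(np.full(len(names), 0.25), np.full(len(names), 1e-12), names)
        post = fit_map(first_order_traj, 1, priors, OptimizerOptions(n_restarts=0))
        assert np.max(np.abs(post.mean - 0.25)) < 1e-6

    def test_parameter_recovery_within_3sd(self):
        """Posterior of a covers the truth in >= 90% of replicates (a=-0.5, T=400)."""
        hits = 0
        n_rep = 50
        for s in range(n_rep):
            m = FirstOrderModel([-0.5], [0.0], [0.2], 0.2, [0.5])
            tr = simulate(m, 400 * TR, TR, InputSpec(), seed=1000 + s)
            post = fit_map(tr, 1, opts=OptimizerOptions(n_restarts=0, seed=0))
            i = post.names.index("a_1")
            hits += abs(post.mean[i] + 0.5) <= 3 * post.sd()[i]
        assert hits >= 0.9 * n_rep

    def test_conjugate_case_matches_closed_form(self):
        """With only x0 free the Laplace posterior is the exact conjugate posterior."""
        a, r_sd, T = -0.5, 0.3, 30
        m = FirstOrderModel([a], [0.0], [0.0], r_sd, [1.2])
        tr = simulate(m, T * TR, TR, InputSpec(), seed=4)
        fixed = {"a_1": a, "c_1": 0.0, "log_prec_state": math.inf,
                 "log_prec_obs": -math.log(r_sd**2)}
        post = fit_map(tr, 1, opts=OptimizerOptions(n_restarts=0), fixed=fixed)
        g = np.exp(a * TR) ** np.arange(T)
        y = tr.observed[:, 0]
        prec = 1.0 + g @ g / r_sd**2
        mean = (g @ y / r_sd**2) / prec
        assert post.mean[0] == pytest.approx(mean, abs=1e-6)
        assert post.covariance[0, 0] == pytest.approx(1 / prec, abs=1e-6)

    def test_posterior_covariance_is_spd(self, first_order_traj):
        post = fit_map(first_order_traj, 1, opts=OptimizerOptions(n_restarts=0))
        w = np.linalg.eigvalsh(post.covariance)
        assert np.all(w > 0)
        assert np.max(np.abs(post.covariance - post.covariance.T)) < 1e-12

    def test_deterministic_given_seed(self, first_order_traj):
        opts = OptimizerOptions(seed=5)
        p1 = fit_map(first_order_traj, 1, opts=opts)
        p2 = fit_map(first_order_traj, 1, opts=opts)
        assert np.array_equal(p1.mean, p2.mean)
        assert np.array_equal(p1.covariance, p2.covariance)


class TestFreeEnergy:
    def test_identity_and_nonnegative_complexity(self, first_order_traj, second_order_traj):
        for traj in (first_order_traj, second_order_traj):
            e1, e2 = invert_both_orders(traj, opts=OptimizerOptions(n_restarts=0))
            for ed in (e1, e2):
                assert ed.F == pytest.approx(ed.accuracy - ed.complexity, abs=1e-8)
                assert ed.complexity >= 0

    def test_posterior_equal_to_prior_gives_zero_complexity(self, first_order_traj):
        from orderstates.inversion import ParameterPosterior

        priors = default_priors(1, 3)
        post = ParameterPosterior(
            mean=priors.mean.copy(), covariance=np.diag(priors.var),
            names=priors.names, converged=True, n_iterations=0, fixed={},
        )
        ed = free_energy(post, first_order_traj, 1, priors)
        assert ed.complexity == 0.0
        assert ed.F == ed.accuracy

    def test_unit_gaussian_kl_half_nat(self):
        from orderstates.inversion import _gaussian_kl

        kl = _gaussian_kl(np.array([1.0]), np.array([[1.0]]), np.array([0.0]), np.array([1.0]))
        assert kl == pytest.approx(0.5, abs=1e-12)

    def test_conjugate_evidence_matches_closed_form(self):
        """F equals the analytic log evidence of the linear-Gaussian special case."""
        a, r_sd, T = -0.5, 0.3, 30
        m = FirstOrderModel([a], [0.0], [0.0], r_sd, [1.2])
        tr = simulate(m, T * TR, TR, InputSpec(), seed=4)
        fixed = {"a_1": a, "c_1": 0.0, "log_prec_state": math.inf,
                 "log_prec_obs": -math.log(r_sd**2)}
        post = fit_map(tr, 1, opts=OptimizerOptions(n_restarts=0), fixed=fixed)
        ed = free_energy(post, tr, 1)
        g = np.exp(a * TR) ** np.arange(T)
        Sig = r_sd**2 * np.eye(T) + np.outer(g, g)
        logev = st.multivariate_normal.logpdf(tr.observed[:, 0], np.zeros(T), Sig)
        assert ed.F == pytest.approx(logev, abs=1e-4)

    def test_occam_unused_regressor_does_not_raise_F(self):
        """With c=0 truth, supplying the input regressor costs complexity on average."""
        diffs = []
        for s in range(8):
            m = FirstOrderModel([-0.5] * 2, [0.0] * 2, [0.2] * 2, 0.2, [0.3, -0.2])
            spec = InputSpec("random_boxcar", rate=0.03, seed=100 + s)
            tr = simulate(m, 200 * TR, TR, spec, seed=s)
            no_input = Trajectory(tr.times, np.zeros_like(tr.inputs), None, tr.observed)
            opts = OptimizerOptions(n_restarts=0, seed=0)
            f_with = free_energy(fit_map(tr, 1, opts=opts), tr, 1).F
            f_without = free_energy(fit_map(no_input, 1, opts=opts), no_input, 1).F
            diffs.append(f_with - f_without)
        assert np.mean(diffs) <= 0


class TestOrderSelection:
    def test_first_order_data_prefers_order1(self, first_order_traj):
        e1, e2 = invert_both_orders(first_order_traj)
        assert e1.F > e2.F

    def test_second_order_data_prefers_order2(self, second_order_traj):
        e1, e2 = invert_both_orders(second_order_traj)
        assert e2.F > e1.F

    def test_repeat_call_identical(self, first_order_traj):
        opts = OptimizerOptions(seed=3)
        a = invert_both_orders(first_order_traj, opts=opts)
        b = invert_both_orders(first_order_traj, opts=opts)
        assert (a[0].F, a[1].F) == (b[0].F, b[1].F)
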