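import numpy as np
import pytest
from scipy.integrate import solve_ivp

from orderstates.dynamics import (
    FirstOrderModel,
    InputSpec,
    SecondOrderModel,
    Trajectory,
    companion_form,
    discretize_lti,
    make_input,
    read_trajectory,
    simulate,
    simulate_augmented,
    write_trajectory,
)
from orderstates.exceptions import ConfigurationError, FormatError, ParameterError


def _so(a, x0=1.0, xd0=0.0, sigma=0.0, sobs=0.0, c=0.0, n=1):
    return SecondOrderModel(
        a_diag=[a] * n, c_diag=[c] * n, sigma_state=[sigma] * n,
        sigma_obs=sobs, x0=[x0] * n, xdot0=[xd0] * n,
    )


class TestSimulateClosedForms:
    def test_zero_dynamics_stays_constant(self):
        m = FirstOrderModel([0.0] * 3, [0.0] * 3, [0.0] * 3, 0.0, [1.0] * 3)
        tr = simulate(m, 10.0, 1.0, InputSpec(), seed=0)
        assert np.allclose(tr.observed, 1.0, atol=0)

    def test_ou_drift_matches_exponential(self):
        m = FirstOrderModel([-1.0], [0.0], [0.0], 0.0, [1.0])
        tr = simulate(m, 5.0, 0.1, InputSpec(), seed=0)
        assert np.max(np.abs(tr.observed[:, 0] - np.exp(-tr.times))) < 1e-10

    def test_harmonic_oscillator_matches_cosine(self):
        tr = simulate(_so(-1.0), 5.0, 0.1, InputSpec(), seed=0)
        assert np.max(np.abs(tr.observed[:, 0] - np.cos(tr.times))) < 1e-8

    def test_ou_stationary_variance(self):
        # Var = sigma^2 / (2|a|) = 0.5 for a=-1, sigma=1
        m = FirstOrderModel([-1.0], [0.0], [1.0], 0.0, [0.0])
        tr = simulate(m, 2000.0, 0.5, InputSpec(), seed=1)
        assert tr.observed[:, 0].var() == pytest.approx(0.5, rel=0.1)

    def test_exact_discretization_not_euler(self):
        # one-step transition factor is e^(a dt), not 1 + a dt
        Ad, _, _ = discretize_lti(np.array([[-1.0]]), np.zeros((1, 1)), np.zeros((1, 1)), 0.5)
        assert Ad[0, 0] == pytest.approx(np.exp(-0.5), abs=1e-14)
        assert abs(Ad[0, 0] - 0.5) > 0.1


class TestCompanionForm:
    def test_known_companion_matrix(self):
        aug = companion_form(_so(-1.0))
        assert np.array_equal(aug.drift, np.array([[0.0, 1.0], [-1.0, 0.0]]))
        assert sorted(np.linalg.eigvals(aug.drift).imag.tolist()) == [-1.0, 1.0]

    @pytest.mark.parametrize("a,expected_imag", [(-4.0, 2.0), (-0.25, 0.5)])
    def test_eigenvalues_are_sqrt_a(self, a, expected_imag):
        aug = companion_form(_so(a))
        eig = np.linalg.eigvals(aug.drift)
        assert np.allclose(sorted(eig.imag), [-expected_imag, expected_imag])
        assert np.allclose(eig.real, 0.0)

    def test_noise_enters_velocity_block_only(self):
        aug = companion_form(_so(-1.0, sigma=0.3, n=2))
        assert np.allclose(aug.noise_cov[:2, :2], 0.0)
        assert np.allclose(np.diag(aug.noise_cov[2:, 2:]), 0.09)

    def test_companion_path_identical_to_simulate(self):
        # shared seed: augmented simulation is sample-for-sample identical
        m = _so(-0.6, x0=0.5, xd0=-0.2, sigma=0.2, sobs=0.1, c=0.5, n=2)
        spec = InputSpec("random_boxcar", rate=0.05, seed=3)
        tr = simulate(m, 30.0, 0.5, spec, seed=7)
        tra = simulate_augmented(companion_form(m), 30.0, 0.5, spec, seed=7)
        assert np.array_equal(tr.observed, tra.observed)
        assert np.array_equal(tr.latent, tra.latent)

    def test_noise_free_agrees_with_ode_integrator(self):
        # independent oracle: adaptive ODE integration of the second-order system
        m = _so(-0.8, x0=0.7, xd0=0.3)

        def rhs(t, z):
            return [z[1], -0.8 * z[0]]

        tr = simulate(m, 12.0, 0.25, InputSpec(), seed=0)
        sol = solve_ivp(rhs, (0, tr.times[-1]), [0.7, 0.3], t_eval=tr.times,
                        rtol=1e-12, atol=1e-13)
        assert np.max(np.abs(tr.observed[:, 0] - sol.y[0])) < 1e-10


class TestMakeInput:
    def test_none_is_zero(self):
        v = make_input(InputSpec(), np.arange(20.0), 3)
        assert not v.any()

    def test_boxcar_exact_samples(self):
        v = make_input(InputSpec("boxcar", onsets=(10.0,), durations=(5.0,)), np.arange(30.0), 2)
        assert np.array_equal(np.nonzero(v[:, 0])[0], np.arange(10, 15))
        assert np.allclose(v[10:15], 1.0)

    def test_random_boxcar_deterministic(self):
        spec = InputSpec("random_boxcar", rate=0.1, seed=5)
        t = np.arange(200.0)
        assert np.array_equal(make_input(spec, t, 3), make_input(spec, t, 3))

    def test_unknown_kind_rejected(self):
        with pytest.raises(ConfigurationError):
            make_input(InputSpec("sine"), np.arange(10.0), 1)


class TestProperties:
    def test_linearity_in_input_amplitude(self):
        m = FirstOrderModel([-0.5] * 2, [1.0] * 2, [0.0] * 2, 0.0, [0.0] * 2)
        base = InputSpec("boxcar", onsets=(5.0,), durations=(10.0,), amplitude=1.0)
        tripled = InputSpec("boxcar", onsets=(5.0,), durations=(10.0,), amplitude=3.0)
        r1 = simulate(m, 40.0, 0.5, base, seed=0).observed
        r3 = simulate(m, 40.0, 0.5, tripled, seed=0).observed
        assert np.allclose(r3, 3.0 * r1, atol=1e-12)

    def test_seed_determinism(self):
        m = FirstOrderModel([-0.5], [0.5], [0.3], 0.2, [0.1])
        spec = InputSpec("random_boxcar", rate=0.05, seed=2)
        a = simulate(m, 50.0, 0.5, spec, seed=42)
        b = simulate(m, 50.0, 0.5, spec, seed=42)
        assert np.array_equal(a.observed, b.observed)
        c = simulate(m, 50.0, 0.5, spec, seed=43)
        assert not np.array_equal(a.observed, c.observed)

    def test_observed_has_n_regions_columns_for_order2(self):
        tr = simulate(_so(-1.0, n=3, sigma=0.1, sobs=0.1), 20.0, 0.5, seed=0)
        assert tr.observed.shape[1] == 3
        assert tr.latent.shape[1] == 6


class TestValidation:
    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ParameterError):
            FirstOrderModel([np.nan], [0.0], [0.1], 0.1, [0.0])

    def test_negative_noise_rejected(self):
        with pytest.raises(ParameterError):
            FirstOrderModel([-1.0], [0.0], [-0.1], 0.1, [0.0])

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            FirstOrderModel([-1.0, -2.0], [0.0], [0.1], 0.1, [0.0])

    def test_bad_dt_and_duration_rejected(self):
        m = FirstOrderModel([-1.0], [0.0], [0.1], 0.1, [0.0])
        with pytest.raises(ConfigurationError):
            simulate(m, 10.0, -0.1, InputSpec(), seed=0)
        with pytest.raises(ConfigurationError):
            simulate(m, 0.5, 1.0, InputSpec(), seed=0)

    def test_nonuniform_times_rejected(self):
        with pytest.raises(FormatError):
            Trajectory(times=np.array([0.0, 1.0, 3.0]), inputs=None, latent=None,
                       observed=np.zeros((3, 1)))


def test_trajectory_roundtrip(tmp_path):
    m = FirstOrderModel([-0.5] * 2, [0.5] * 2, [0.2] * 2, 0.1, [0.0] * 2)
    tr = simulate(m, 20.0, 0.5, InputSpec("random_boxcar", rate=0.05, seed=1), seed=3)
    path = tmp_path / "subj.tsv"
    write_trajectory(tr, path)
    back = read_trajectory(path)
    assert np.allclose(back.times, tr.times)
    assert np.allclose(back.observed, tr.observed)
    assert np.allclose(back.inputs, tr.inputs)
    assert back.meta["order"] == 1
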