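import pytest

from orderstates.dynamics import FirstOrderModel, InputSpec, SecondOrderModel, simulate

TR = 0.72


@pytest.fixture(scope="session")
def first_order_traj():
    """Moderate-noise first-order series, 3 regions, T=400 (default protocol)."""
    model = FirstOrderModel(
        a_diag=[-0.5, -0.7, -0.3],
        c_diag=[0.5, 0.8, 0.4],
        sigma_state=[0.2] * 3,
        sigma_obs=0.2,
        x0=[0.3, -0.2, 0.1],
    )
    spec = InputSpec(kind="random_boxcar", rate=0.02, block_duration=15.0, seed=11)
    return simulate(model, 400 * TR, TR, spec, seed=21)


@pytest.fixture(scope="session")
def second_order_traj():
    model = SecondOrderModel(
        a_diag=[-0.5, -0.8, -0.2],
        c_diag=[0.5, 0.8, 0.4],
        sigma_state=[0.2] * 3,
        sigma_obs=0.2,
        x0=[0.3, -0.2, 0.1],
        xdot0=[0.0, 0.1, -0.1],
    )
    spec = InputSpec(kind="random_boxcar", rate=0.02, block_duration=15.0, seed=12)
    return simulate(model, 400 * TR, TR, spec, seed=22)
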