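"""First- and second-order linear stochastic dynamics.

The generative models are diagonal linear stochastic differential equations
over ``n`` regions.  A first-order system evolves as

    dx_i/dt = a_ii * x_i + c_ii * v_i(t) + omega_i(t)

and a second-order system as

    d^2x_i/dt^2 = a_ii * x_i + c_ii * v_i(t) + omega_i(t)

where ``a_ii`` are self-coupling strengths, ``c_ii`` gains on a known driving
input ``v(t)``, and ``omega`` is white state noise.  Regions are coupled only
to themselves (diagonal Jacobian).  Observations are the positions plus
Gaussian observation noise, for either order.

Simulation uses the exact discretization of the linear SDE: the per-step
transition matrix is the matrix exponential of the drift times ``dt`` (with
zero-order hold on the input), and the per-step process-noise covariance is
the Van Loan integrated covariance.  Second-order systems are reduced to
companion (position/velocity) form so both orders share one integrator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .exceptions import ConfigurationError, FormatError, ParameterError

__all__ = [
    "FirstOrderModel",
    "SecondOrderModel",
    "FirstOrderAugmented",
    "InputSpec",
    "Trajectory",
    "make_input",
    "companion_form",
    "discretize_lti",
    "simulate",
    "simulate_augmented",
    "write_trajectory",
    "read_trajectory",
]


def _as_vector(x, n: int, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.shape != (n,):
        raise ParameterError(f"{name} must have length {n}, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ParameterError(f"{name} contains non-finite values")
    return v


@dataclass(frozen=True)
class FirstOrderModel:
    """Diagonal first-order linear stochastic model.

    Parameters
    ----------
    a_diag
        Self-coupling rates per region (1/s).  Negative values give stable,
        mean-reverting (Ornstein-Uhlenbeck) dynamics.
    c_diag
        Input gains per region (dimensionless).
    sigma_state
        State-noise standard deviation per region (signal units per sqrt(s)).
    sigma_obs
        Observation-noise standard deviation (signal units).
    x0
        Initial state per region.
    """

    a_diag: np.ndarray
    c_diag: np.ndarray
    sigma_state: np.ndarray
    sigma_obs: float
    x0: np.ndarray

    def __post_init__(self):
        n = np.atleast_1d(np.asarray(self.a_diag)).shape[0]
        object.__setattr__(self, "a_diag", _as_vector(self.a_diag, n, "a_diag"))
        object.__setattr__(self, "c_diag", _as_vector(self.c_diag, n, "c_diag"))
        object.__setattr__(self, "sigma_state", _as_vector(self.sigma_state, n, "sigma_state"))
        object.__setattr__(self, "x0", _as_vector(self.x0, n, "x0"))
        so = float(self.sigma_obs)
        if not np.isfinite(so):
            raise ParameterError("sigma_obs must be finite")
        if so < 0 or np.any(self.sigma_state < 0):
            raise ParameterError("noise standard deviations must be non-negative")
        object.__setattr__(self, "sigma_obs", so)

    @property
    def n_regions(self) -> int:
        return self.a_diag.shape[0]

    @property
    def order(self) -> int:
        return 1


@dataclass(frozen=True)
class SecondOrderModel(FirstOrderModel):
    """Diagonal second-order linear stochastic model (adds initial velocity).

    The equation of motion is exactly second order in ``x`` with no damping
    term; with ``a_ii < 0`` each region is an undamped stochastic oscillator
    of angular frequency ``sqrt(-a_ii)``.
    """

    xdot0: np.ndarray = field(default=None)

    def __post_init__(self):
        super().__post_init__()
        if self.xdot0 is None:
            raise ParameterError("xdot0 is required for a second-order model")
        object.__setattr__(self, "xdot0", _as_vector(self.xdot0, self.n_regions, "xdot0"))

    @property
    def order(self) -> int:
        return 2


@dataclass(frozen=True)
class FirstOrderAugmented:
    """A generic first-order LTI stochastic system (companion embedding).

    ``drift`` is the state matrix A, ``input_mat`` maps the n-dimensional
    driving input into the state, ``noise_cov`` is the spectral density of the
    continuous-time state noise, ``x0`` the initial state and ``obs_indices``
    the state components that are observed (positions).
    """

    drift: np.ndarray
    input_mat: np.ndarray
    noise_cov: np.ndarray
    x0: np.ndarray
    obs_indices: np.ndarray
    sigma_obs: float


@dataclass(frozen=True)
class InputSpec:
    """Specification of the driving input v(t).

    ``kind`` is one of ``"none"``, ``"boxcar"`` (deterministic blocks, shared
    across regions) or ``"random_boxcar"`` (independent random block trains
    per region with Poisson onsets at ``rate`` events/s, each lasting
    ``block_duration`` seconds).
    """

    kind: str = "none"
    onsets: tuple = ()
    durations: tuple = ()
    amplitude: float = 1.0
    rate: float = 0.02
    block_duration: float = 15.0
    seed: int | None = None


def make_input(input_spec: InputSpec, times: np.ndarray, n_regions: int) -> np.ndarray:
    """Build the time x region driving-input matrix v(t) from a spec.

    Deterministic given the spec (and its seed for ``random_boxcar``).
    """
    times = np.asarray(times, dtype=float)
    T = times.shape[0]
    v = np.zeros((T, n_regions))
    if input_spec.kind == "none":
        return v
    if input_spec.kind == "boxcar":
        durations = np.broadcast_to(
            np.atleast_1d(np.asarray(input_spec.durations, dtype=float)),
            (len(input_spec.onsets),),
        )
        for onset, dur in zip(input_spec.onsets, durations):
            mask = (times >= onset) & (times < onset + dur)
            v[mask, :] += input_spec.amplitude
        return v
    if input_spec.kind == "random_boxcar":
        rng = np.random.default_rng(input_spec.seed)
        t_end = times[-1]
        for j in range(n_regions):
            t = rng.exponential(1.0 / input_spec.rate)
            while t < t_end:
                mask = (times >= t) & (times < t + input_spec.block_duration)
                v[mask, j] += input_spec.amplitude
                t += input_spec.block_duration + rng.exponential(1.0 / input_spec.rate)
        return v
    raise ConfigurationError(f"unknown input kind {input_spec.kind!r}")


@dataclass(frozen=True)
class Trajectory:
    """One simulated or observed multivariate series.

    ``latent`` has n columns for order 1 and 2n (positions then velocities)
    for order 2; ``observed`` always has exactly n columns.  ``latent`` and
    ``inputs`` may be None for externally observed data.
    """

    times: np.ndarray
    inputs: np.ndarray | None
    latent: np.ndarray | None
    observed: np.ndarray
    meta: dict | None = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        observed = np.asarray(self.observed, dtype=float)
        if times.ndim != 1 or times.shape[0] != observed.shape[0]:
            raise FormatError("times and observed must have matching length")
        dts = np.diff(times)
        if times.shape[0] >= 2:
            if np.any(dts <= 0):
                raise FormatError("times must be strictly increasing")
            dt = dts[0]
            if np.any(np.abs(dts - dt) > 1e-9 * max(abs(dt), 1.0)):
                raise FormatError("times must be uniformly spaced")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "observed", observed)
        if self.inputs is not None:
            object.__setattr__(self, "inputs", np.asarray(self.inputs, dtype=float))
        if self.latent is not None:
            object.__setattr__(self, "latent", np.asarray(self.latent, dtype=float))

    @property
    def n_regions(self) -> int:
        return self.observed.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


def companion_form(model: SecondOrderModel) -> FirstOrderAugmented:
    """Reduce a second-order model to its 2n-dimensional first-order form.

    The drift is the block companion matrix [[0, I], [diag(a), 0]]; state
    noise enters only the velocity block.  Its eigenvalues are the pairs
    +/- sqrt(a_ii) for each region.
    """
    n = model.n_regions
    drift = np.zeros((2 * n, 2 * n))
    drift[:n, n:] = np.eye(n)
    drift[n:, :n] = np.diag(model.a_diag)
    input_mat = np.zeros((2 * n, n))
    input_mat[n:, :] = np.diag(model.c_diag)
    noise_cov = np.zeros((2 * n, 2 * n))
    noise_cov[n:, n:] = np.diag(model.sigma_state**2)
    x0 = np.concatenate([model.x0, model.xdot0])
    return FirstOrderAugmented(
        drift=drift,
        input_mat=input_mat,
        noise_cov=noise_cov,
        x0=x0,
        obs_indices=np.arange(n),
        sigma_obs=model.sigma_obs,
    )


def _first_order_augmented(model: FirstOrderModel) -> FirstOrderAugmented:
    return FirstOrderAugmented(
        drift=np.diag(model.a_diag),
        input_mat=np.diag(model.c_diag),
        noise_cov=np.diag(model.sigma_state**2),
        x0=model.x0.copy(),
        obs_indices=np.arange(model.n_regions),
        sigma_obs=model.sigma_obs,
    )


def discretize_lti(A: np.ndarray, B: np.ndarray, Qc: np.ndarray, dt: float):
    """Exact discretization of dx = (A x + B v) dt + dW, Cov[dW] = Qc dt.

    Returns (Ad, Bd, Qd): the one-step transition matrix, zero-order-hold
    input matrix, and Van Loan integrated process-noise covariance.
    """
    m = A.shape[0]
    p = B.shape[1]
    # transition and ZOH input via a single matrix exponential
    M = np.zeros((m + p, m + p))
    M[:m, :m] = A
    M[:m, m:] = B
    E = expm(M * dt)
    Ad = E[:m, :m]
    Bd = E[:m, m:]
    # Van Loan: expm([[-A, Qc], [0, A^T]] dt)
    V = np.zeros((2 * m, 2 * m))
    V[:m, :m] = -A
    V[:m, m:] = Qc
    V[m:, m:] = A.T
    F = expm(V * dt)
    Qd = F[m:, m:].T @ F[:m, m:]
    return Ad, Bd, (Qd + Qd.T) / 2.0


def _psd_sqrt(Q: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(Q)
    return U * np.sqrt(np.clip(w, 0.0, None))


def simulate_augmented(
    aug: FirstOrderAugmented,
    duration: float,
    dt: float,
    input_spec: InputSpec = InputSpec(),
    seed: int | None = 0,
    meta: dict | None = None,
) -> Trajectory:
    """Simulate a generic first-order LTI stochastic system exactly.

    The drift is integrated via its matrix exponential and the process noise
    via the Van Loan covariance; observation noise is added independently per
    sample.  Bit-identical output for identical arguments.
    """
    if dt <= 0 or duration <= dt:
        raise ConfigurationError("need dt > 0 and duration > dt")
    n_steps = int(round(duration / dt))
    if n_steps < 10:
        raise ConfigurationError("need at least 10 samples (duration/dt >= 10)")
    times = np.arange(n_steps) * dt
    n_obs = aug.obs_indices.shape[0]
    v = make_input(input_spec, times, n_obs)
    Ad, Bd, Qd = discretize_lti(aug.drift, aug.input_mat, aug.noise_cov, dt)
    L = _psd_sqrt(Qd)
    m = aug.drift.shape[0]
    rng = np.random.default_rng(seed)
    state_noise = rng.standard_normal((n_steps - 1, m)) @ L.T
    obs_noise = aug.sigma_obs * rng.standard_normal((n_steps, n_obs))
    latent = np.empty((n_steps, m))
    latent[0] = aug.x0
    for k in range(n_steps - 1):
        latent[k + 1] = Ad @ latent[k] + Bd @ v[k] + state_noise[k]
    observed = latent[:, aug.obs_indices] + obs_noise
    return Trajectory(times=times, inputs=v, latent=latent, observed=observed, meta=meta)


def simulate(
    model: FirstOrderModel | SecondOrderModel,
    duration: float,
    dt: float,
    input_spec: InputSpec = InputSpec(),
    seed: int | None = 0,
) -> Trajectory:
    """Simulate a first- or second-order model exactly over a uniform grid.

    Second-order models are first reduced to companion form so both orders
    share one integrator.  Identical (model, duration, dt, input, seed) give
    bit-identical trajectories.
    """
    aug = companion_form(model) if model.order == 2 else _first_order_augmented(model)
    meta = {
        "order": model.order,
        "seed": seed,
        "dt": dt,
        "a_diag": model.a_diag.tolist(),
        "c_diag": model.c_diag.tolist(),
        "sigma_state": model.sigma_state.tolist(),
        "sigma_obs": model.sigma_obs,
        "x0": model.x0.tolist(),
    }
    if model.order == 2:
        meta["xdot0"] = model.xdot0.tolist()
    return simulate_augmented(aug, duration, dt, input_spec, seed, meta=meta)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as TSV (time_s, region_1..region_n) + sidecars.

    The driving input goes to ``<stem>_inputs.tsv`` with the same convention
    and metadata to ``<stem>_meta.json``.
    """
    path = Path(path)
    n = traj.n_regions
    cols = ["time_s"] + [f"region_{i + 1}" for i in range(n)]
    df = pd.DataFrame(np.column_stack([traj.times, traj.observed]), columns=cols)
    df.to_csv(path, sep="\t", index=False)
    if traj.inputs is not None:
        dfv = pd.DataFrame(np.column_stack([traj.times, traj.inputs]), columns=cols)
        dfv.to_csv(path.with_name(path.stem + "_inputs.tsv"), sep="\t", index=False)
    if traj.meta is not None:
        path.with_name(path.stem + "_meta.json").write_text(json.dumps(traj.meta, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory written by :func:`write_trajectory` (sidecars optional)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "time_s":
        raise FormatError("first column must be time_s")
    times = df["time_s"].to_numpy()
    observed = df.iloc[:, 1:].to_numpy()
    inputs = None
    vpath = path.with_name(path.stem + "_inputs.tsv")
    if vpath.exists():
        inputs = pd.read_csv(vpath, sep="\t").iloc[:, 1:].to_numpy()
    meta = None
    mpath = path.with_name(path.stem + "_meta.json")
    if mpath.exists():
        meta = json.loads(mpath.read_text())
    return Trajectory(times=times, inputs=inputs, latent=None, observed=observed, meta=meta)
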