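"""Independent oracles used by the test suite.

These deliberately avoid the package's Kalman/likelihood code paths: the
dense oracle assembles the full joint Gaussian over all observations from
the transition matrices and evaluates its density directly.
"""

import numpy as np
import scipy.stats as st

from orderstates.dynamics import Trajectory, discretize_lti


def dense_gaussian_loglik(theta: np.ndarray, traj: Trajectory, order: int) -> float:
    """Brute-force joint-Gaussian log-density of the observations.

    Builds the T*n-dimensional mean and covariance of y by propagating the
    discretized system moments, then evaluates the multivariate-normal
    density — O(T^3), usable only for small T.
    """
    n = traj.n_regions
    T = len(traj.times)
    dt = traj.dt
    a, c, x0 = theta[:n], theta[n : 2 * n], theta[2 * n : 3 * n]
    k = 3 * n if order == 1 else 4 * n
    sig2 = np.exp(-theta[k])
    r = np.exp(-theta[k + 1])
    if order == 1:
        m = n
        A, B = np.diag(a), np.diag(c)
        Qc = np.diag(np.full(n, sig2))
        z0 = x0
        H = np.eye(n)
    else:
        m = 2 * n
        xd0 = theta[3 * n : 4 * n]
        A = np.zeros((m, m))
        A[:n, n:] = np.eye(n)
        A[n:, :n] = np.diag(a)
        B = np.zeros((m, n))
        B[n:, :] = np.diag(c)
        Qc = np.zeros((m, m))
        Qc[n:, n:] = np.diag(np.full(n, sig2))
        z0 = np.concatenate([x0, xd0])
        H = np.hstack([np.eye(n), np.zeros((n, n))])
    Ad, Bd, Qd = discretize_lti(A, B, Qc, dt)
    v = traj.inputs if traj.inputs is not None else np.zeros((T, n))
    means = [z0]
    for t in range(T - 1):
        means.append(Ad @ means[-1] + Bd @ v[t])
    means = np.asarray(means)
    P = [np.zeros((m, m))]
    for t in range(T - 1):
        P.append(Ad @ P[-1] @ Ad.T + Qd)
    cov = np.zeros((T, m, T, m))
    for s in range(T):
        cov[s, :, s, :] = P[s]
        acc = P[s]
        for t in range(s + 1, T):
            acc = acc @ Ad.T
            cov[s, :, t, :] = acc
            cov[t, :, s, :] = acc.T
    Hbig = np.kron(np.eye(T), H)
    mu_y = (means @ H.T).ravel()
    Sig = Hbig @ cov.reshape(T * m, T * m) @ Hbig.T + r * np.eye(T * n)
    return float(
        st.multivariate_normal.logpdf(traj.observed.ravel(), mu_y, Sig, allow_singular=True)
    )
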