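# orderstates

Bayesian model-order selection for linear stochastic brain dynamics.

## The problem

What information constitutes the "state" of a neural system? In dynamical
systems terms, a state is whatever is sufficient to determine the system's
immediate future. For a first-order linear stochastic system

$$\dot{x}_i = a_{ii}\,x_i + c_{ii}\,v_i(t) + \omega_i(t)$$

the present signal, input and noise suffice; for a second-order system

$$\ddot{x}_i = a_{ii}\,x_i + c_{ii}\,v_i(t) + \omega_i(t)$$

the rate of change $\dot{x}$ must be added. Whether neuroimaging
timeseries are better described by first- or second-order equations of
motion is therefore an empirical question about what a brain state *is* —
and one that can be answered by Bayesian model comparison.

`orderstates` is a package for computational neuroscientists who want to ask
that question of multivariate timeseries (parcellated fMRI, gradient
projections, or simulations). It provides:

- **dynamics** — exact simulation of diagonal first-/second-order linear
  stochastic systems (matrix-exponential transition, Van Loan process-noise
  covariance, companion-form reduction for order 2);
- **inversion** — the exact discrete-time marginal likelihood via a Kalman
  prediction-error decomposition, variational-Laplace parameter estimation,
  and the variational free energy
  $F = \langle\log p(y\,|\,\theta,m)\rangle_q - \mathrm{KL}\,[q(\theta)\,\|\,p(\theta\,|\,m)]$
  (accuracy minus complexity) as the log-evidence approximation;
- **comparison** — softmax posterior model probabilities
  $p_i = e^{F_i}/(e^{F_1}+e^{F_2})$, per-subject classification and cohort
  summaries;
- **gradients** — diffusion-map embedding of a functional-connectivity
  matrix into orthogonal "gradients", per-timepoint Pearson projection of
  region timeseries onto them, circular-shift surrogate nulls, and group
  autocorrelation curves;
- **synthcohort** — a synthetic-data generator emulating parcellated
  rest/task fMRI (latent gradient-space dynamics of known order, orthonormal
  spatial maps, spatial noise), so every stage is testable without access to
  real data;
- **workflow / CLI** — end-to-end order-recovery and cohort-analysis
  experiments from a single seeded config (`orderstates` console command).

## Worked example

```python
from orderstates import (FirstOrderModel, InputSpec, simulate, classify_subject)

model = FirstOrderModel(
    a_diag=[-0.5, -0.7, -0.3],   # stable self-couplings, 1/s
    c_diag=[0.5, 0.8, 0.4],      # input gains
    sigma_state=[0.2] * 3,       # state noise SD
    sigma_obs=0.2,               # observation noise SD
    x0=[0.3, -0.2, 0.1],
)
inputs = InputSpec(kind="random_boxcar", rate=0.02, block_duration=15.0, seed=11)
traj = simulate(model, duration=400 * 0.72, dt=0.72, input_spec=inputs, seed=21)

res = classify_subject(traj, subject_id="demo")
print(f"F1 = {res.F1:.1f}, F2 = {res.F2:.1f}, winner = order {res.winner}, "
      f"p = {max(res.p1, res.p2):.4f}")
```

prints

```
F1 = -97.6, F2 = -336.2, winner = order 1, p = 1.0000
```

The series was generated by a first-order system; its free energy under the
first-order model exceeds the second-order one by ~240 nats, so the softmax
probability of the (correct) first-order model is 1.0 to four decimals.
Repeating with a second-order simulation flips the comparison.

From the shell, the same experiments run as:

```sh
orderstates recovery --out out/ --seed 1 --n-series 100
orderstates cohort-analysis --out out/ --seed 1 --n-subjects 20
```

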