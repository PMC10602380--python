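"""Synthetic cohorts emulating parcellated rest/task fMRI structure.

Subjects are generated by low-dimensional latent dynamics of known order
(first or second) living directly in gradient space, projected onto
synthetic orthonormal spatial gradient maps over ~100 regions, plus spatial
Gaussian noise.  Model parameters are randomized per subject: stable
self-couplings, input gains, noise amplitudes and block driving inputs.
Every subject is a pure function of (spec, seed) and therefore exactly
reconstructible.

This emulates the statistical structure of parcellated BOLD data (latent
gradient dynamics, spatial mixing, per-region noise) but not realistic BOLD
spectra, hemodynamic smoothing, physiological noise or motion.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .dynamics import (
    FirstOrderModel,
    InputSpec,
    SecondOrderModel,
    Trajectory,
    simulate,
)
from .exceptions import ContractError
from .gradients import GradientSet

__all__ = [
    "CohortSpec",
    "SyntheticSubject",
    "A_RANGE_ORDER1",
    "A_RANGE_ORDER2",
    "C_RANGE",
    "NOISE_SD_RANGE",
    "derive_seed",
    "sample_random_model",
    "synthetic_gradient_set",
    "make_subject",
    "make_cohort",
    "make_fc_matrix",
    "task_block_input",
]

#: stability ranges for the randomized self-couplings (1/s resp. 1/s^2)
A_RANGE_ORDER1 = (-1.0, -0.2)
A_RANGE_ORDER2 = (-1.0, -0.1)
#: input gains and noise standard deviations
C_RANGE = (0.2, 1.0)
NOISE_SD_RANGE = (0.05, 0.3)
#: initial conditions are drawn uniform on this interval
X0_RANGE = (-1.0, 1.0)
#: random driving input: Poisson block onsets (events/s) and block length (s)
INPUT_RATE = 0.02
INPUT_BLOCK_DURATION = 15.0

#: n-back-like task timing: repeated task blocks separated by baselines (s)
TASK_BLOCK_S = 27.5
TASK_BASELINE_S = 15.0


def derive_seed(master: int, *keys) -> int:
    """Stable per-item seed derived from a master seed and labels (< 2^31)."""
    parts = [int(master) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, str):
            parts.append(zlib.crc32(k.encode()))
        else:
            parts.append(int(k) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(parts).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of one synthetic cohort (one condition)."""

    n_subjects: int
    seed: int
    n_regions: int = 100
    n_timepoints: int = 400
    tr: float = 0.72
    n_gradients: int = 3
    order_mix: float = 0.5
    condition: str = "rest"
    spatial_noise_sd: float = 0.2

    def __post_init__(self):
        if not (0.0 <= self.order_mix <= 1.0):
            raise ContractError("order_mix must lie in [0, 1]")
        if min(self.n_subjects, self.n_regions, self.n_timepoints, self.n_gradients) <= 0:
            raise ContractError("all counts must be positive")


@dataclass(frozen=True)
class SyntheticSubject:
    """One synthetic subject with stored ground truth."""

    subject_id: str
    region_ts: np.ndarray
    true_order: int
    latent: Trajectory
    gradients_used: GradientSet
    condition: str
    seed: int


def sample_random_model(order: int, n: int, seed: int):
    """Draw a randomized stable model and its driving-input spec.

    Self-couplings are uniform over the declared stability range for the
    order, input gains uniform over ``C_RANGE``, state/observation noise SDs
    uniform over ``NOISE_SD_RANGE``, initial conditions uniform over
    ``X0_RANGE``; the input is an independent random block train per region.
    Returns ``(model, input_spec)``; deterministic per seed.
    """
    if order not in (1, 2):
        raise ContractError(f"order must be 1 or 2, got {order}")
    rng = np.random.default_rng(seed)
    a_lo, a_hi = A_RANGE_ORDER1 if order == 1 else A_RANGE_ORDER2
    a = rng.uniform(a_lo, a_hi, size=n)
    c = rng.uniform(*C_RANGE, size=n)
    sigma_state = np.full(n, rng.uniform(*NOISE_SD_RANGE))
    sigma_obs = float(rng.uniform(*NOISE_SD_RANGE))
    x0 = rng.uniform(*X0_RANGE, size=n)
    input_spec = InputSpec(
        kind="random_boxcar",
        rate=INPUT_RATE,
        block_duration=INPUT_BLOCK_DURATION,
        amplitude=1.0,
        seed=derive_seed(seed, "input"),
    )
    if order == 1:
        model = FirstOrderModel(a, c, sigma_state, sigma_obs, x0)
    else:
        xdot0 = rng.uniform(*X0_RANGE, size=n)
        model = SecondOrderModel(a, c, sigma_state, sigma_obs, x0, xdot0=xdot0)
    return model, input_spec


def synthetic_gradient_set(n_regions: int, n_gradients: int, seed: int) -> GradientSet:
    """Random orthonormal, zero-mean spatial gradient maps.

    Columns are orthonormal and orthogonal to the constant map (as real
    diffusion-embedding gradients are, up to the trivial component).
    Variance-explained fractions decay geometrically, mimicking the dominance
    of the leading gradients.
    """
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((n_regions, n_gradients))
    G -= G.mean(axis=0, keepdims=True)
    Q, _ = np.linalg.qr(G)
    L = Q[:, :n_gradients]
    for j in range(n_gradients):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    w = 0.5 ** np.arange(n_gradients)
    return GradientSet(
        loadings=L,
        variance_explained=w / w.sum(),
        n_regions=n_regions,
        n_gradients=n_gradients,
    )


def task_block_input(block_s: float = TASK_BLOCK_S, baseline_s: float = TASK_BASELINE_S,
                     duration: float = 288.0, amplitude: float = 1.0) -> InputSpec:
    """Shared block-design input: task blocks separated by baselines."""
    onsets = []
    t = baseline_s
    while t < duration:
        onsets.append(t)
        t += block_s + baseline_s
    return InputSpec(kind="boxcar", onsets=tuple(onsets),
                     durations=(block_s,), amplitude=amplitude)


def make_subject(
    spec: CohortSpec,
    true_order: int,
    seed: int,
    gradients: GradientSet | None = None,
) -> SyntheticSubject:
    """Generate one subject: latent dynamics in gradient space -> regions.

    A randomized model of the requested order is simulated over
    ``n_gradients`` latent dimensions; latent positions are standardized per
    dimension (amplitude normalization), projected through the orthonormal
    loadings and corrupted by spatial Gaussian noise.  The driving input
    follows the condition: none at rest, a shared block design for task.
    """
    duration = spec.n_timepoints * spec.tr
    model, input_spec = sample_random_model(true_order, spec.n_gradients, seed)
    if spec.condition == "task":
        input_spec = task_block_input(duration=duration)
    elif spec.condition == "rest":
        input_spec = InputSpec(kind="none")
    latent = simulate(model, duration, spec.tr, input_spec, seed=derive_seed(seed, "sim"))
    if gradients is None:
        gradients = synthetic_gradient_set(
            spec.n_regions, spec.n_gradients, derive_seed(seed, "gradients")
        )
    pos = latent.latent[:, : spec.n_gradients]
    sd = pos.std(axis=0)
    sd[sd == 0] = 1.0
    z = (pos - pos.mean(axis=0)) / sd
    rng = np.random.default_rng(derive_seed(seed, "spatial"))
    region_ts = z @ gradients.loadings.T
    region_ts = region_ts + spec.spatial_noise_sd * rng.standard_normal(region_ts.shape)
    return SyntheticSubject(
        subject_id=f"sub-{seed:010d}",
        region_ts=region_ts,
        true_order=true_order,
        latent=latent,
        gradients_used=gradients,
        condition=spec.condition,
        seed=seed,
    )


def make_cohort(spec: CohortSpec) -> list[SyntheticSubject]:
    """Generate a cohort of independent subjects sharing one gradient set.

    ``round(order_mix * n_subjects)`` subjects are second-order, the rest
    first-order; per-subject seeds derive deterministically from the cohort
    seed and subject index, so an identical spec reproduces the cohort.
    """
    n2 = int(round(spec.order_mix * spec.n_subjects))
    orders = [1] * (spec.n_subjects - n2) + [2] * n2
    gradients = synthetic_gradient_set(
        spec.n_regions, spec.n_gradients, derive_seed(spec.seed, "gradients")
    )
    subjects = []
    for i, order in enumerate(orders):
        s = derive_seed(spec.seed, spec.condition, i)
        subj = make_subject(spec, order, s, gradients=gradients)
        subjects.append(
            SyntheticSubject(
                subject_id=f"sub-{i + 1:03d}",
                region_ts=subj.region_ts,
                true_order=subj.true_order,
                latent=subj.latent,
                gradients_used=subj.gradients_used,
                condition=subj.condition,
                seed=s,
            )
        )
    return subjects


def make_fc_matrix(
    n_regions: int,
    n_blocks: int = 2,
    within: float = 0.9,
    between: float = 0.1,
    seed: int = 0,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Symmetric block-structured stand-in for a group FC matrix."""
    if within <= between:
        raise ContractError("within-block correlation must exceed between-block")
    labels = np.arange(n_regions) * n_blocks // n_regions
    fc = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_regions, n_regions)) * noise_sd
    fc = fc + (noise + noise.T) / 2.0
    np.fill_diagonal(fc, 1.0)
    return fc
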