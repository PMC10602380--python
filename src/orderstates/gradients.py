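"""Functional gradients, per-timepoint projections, surrogate nulls and ACF.

A functional-connectivity (FC) matrix is embedded into a few "gradients" —
orthogonal spatial axes of connectivity similarity — by a diffusion-map-style
decomposition: per-row sparsification, cosine-similarity affinity,
alpha-normalization, and eigendecomposition of the symmetric normalized
diffusion operator.  Region timeseries are projected onto the gradients by
per-timepoint Pearson correlation across regions, yielding a low-dimensional
gradient timeseries per subject.

The circular-shift surrogate rotates each region's time course independently
by a random offset: per-region spectra and autocorrelations are exactly
preserved (a rotation only permutes samples) while inter-regional temporal
dependence is destroyed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from statsmodels.tsa.stattools import acf as _sm_acf

from .exceptions import ContractError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "GradientSet",
    "GradientTimeseries",
    "diffusion_embedding",
    "gradient_timeseries",
    "circular_shift_null",
    "acf",
    "group_acf",
]


@dataclass(frozen=True)
class GradientSet:
    """Region x gradient loading matrix with variance-explained fractions."""

    loadings: np.ndarray
    variance_explained: np.ndarray
    n_regions: int
    n_gradients: int

    def __post_init__(self):
        L = np.asarray(self.loadings, dtype=float)
        ve = np.asarray(self.variance_explained, dtype=float)
        if L.shape != (self.n_regions, self.n_gradients):
            raise ContractError("loadings shape does not match n_regions x n_gradients")
        if ve.shape != (self.n_gradients,):
            raise ContractError("variance_explained length mismatch")
        if np.any(np.diff(ve) > 1e-12) or np.any(ve < -1e-12) or np.any(ve > 1 + 1e-12):
            raise ContractError("variance_explained must be descending fractions in [0,1]")
        object.__setattr__(self, "loadings", L)
        object.__setattr__(self, "variance_explained", ve)


@dataclass(frozen=True)
class GradientTimeseries:
    """Per-timepoint correlation of the spatial map with each gradient."""

    values: np.ndarray
    condition: str = ""
    shifted: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(np.abs(v) > 1.0 + 1e-12):
            raise ContractError("gradient correlations must lie in [-1, 1]")
        object.__setattr__(self, "values", np.clip(v, -1.0, 1.0))


def _diffusion_operator(fc: np.ndarray, sparsity: float, alpha: float) -> np.ndarray:
    """Sparsified cosine affinity + alpha-normalized symmetric diffusion operator."""
    R = fc.shape[0]
    W = fc.copy()
    # keep the top (1 - sparsity) fraction of entries per row
    k = int(np.floor(sparsity * R))
    if k > 0:
        # smallest kept value per row; strict inequality keeps ties at the cutoff
        thresh = np.sort(W, axis=1)[:, k]
        W[W < thresh[:, None]] = 0.0
    # cosine similarity between sparsified rows
    norms = np.linalg.norm(W, axis=1)
    norms[norms == 0] = 1.0
    Wn = W / norms[:, None]
    aff = np.clip(Wn @ Wn.T, 0.0, None)
    np.fill_diagonal(aff, 1.0)
    # alpha-normalization then symmetric normalized operator
    d = aff.sum(axis=1)
    K = aff / np.outer(d**alpha, d**alpha)
    d1 = K.sum(axis=1)
    S = K / np.outer(np.sqrt(d1), np.sqrt(d1))
    return (S + S.T) / 2.0, d1


def diffusion_embedding(
    fc: np.ndarray,
    n_components: int = 3,
    sparsity: float = 0.9,
    alpha: float = 0.5,
) -> GradientSet:
    """Diffusion-map embedding of a symmetric FC matrix into gradients.

    Rows are sparsified (top ``1 - sparsity`` fraction kept), converted to a
    cosine-similarity affinity, alpha-normalized, and the symmetric
    normalized diffusion operator is eigendecomposed.  The trivial leading
    eigenvector is dropped; components are ordered by eigenvalue, with
    variance-explained fractions from the normalized non-trivial eigenvalues.
    Columns are unit-norm and mutually orthogonal.
    """
    fc = np.asarray(fc, dtype=float)
    if fc.ndim != 2 or fc.shape[0] != fc.shape[1]:
        raise FormatError("FC matrix must be square")
    if not np.all(np.isfinite(fc)):
        raise FormatError("FC matrix must be finite")
    if np.max(np.abs(fc - fc.T)) > 1e-8:
        raise FormatError("FC matrix must be symmetric (within 1e-8)")
    R = fc.shape[0]
    if n_components >= R:
        raise ContractError("n_components must be smaller than the number of regions")
    S, d1 = _diffusion_operator((fc + fc.T) / 2.0, sparsity, alpha)
    # deflate the known stationary eigenvector (sqrt of the degree vector) so
    # the trivial component is removed even when the affinity graph is
    # disconnected and the leading eigenvalue is degenerate
    u0 = np.sqrt(d1)
    u0 /= np.linalg.norm(u0)
    S = S - (u0 @ S @ u0) * np.outer(u0, u0)
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    lam = w[:n_components]
    L = V[:, :n_components]
    # deterministic sign: largest-magnitude entry positive
    for j in range(L.shape[1]):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    pos = np.clip(w, 0.0, None)
    total = pos.sum()
    ve = np.clip(lam, 0.0, None) / total if total > 0 else np.zeros_like(lam)
    return GradientSet(
        loadings=L,
        variance_explained=ve,
        n_regions=R,
        n_gradients=n_components,
    )


def gradient_timeseries(region_ts: np.ndarray, gradients: GradientSet) -> GradientTimeseries:
    """Correlate each timepoint's spatial map with each gradient.

    Entry (t, g) is the Pearson correlation across regions between row t of
    ``region_ts`` and gradient g's loadings.  Timepoints with zero spatial
    variance map to 0 with a warning.
    """
    X = np.asarray(region_ts, dtype=float)
    if X.ndim != 2 or X.shape[1] != gradients.n_regions:
        raise ContractError("region count does not match the gradient set")
    Xc = X - X.mean(axis=1, keepdims=True)
    Lc = gradients.loadings - gradients.loadings.mean(axis=0, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    ln = np.linalg.norm(Lc, axis=0)
    bad = xn == 0
    if np.any(bad):
        logger.warning("%d timepoints have zero spatial variance; correlation set to 0",
                       int(bad.sum()))
        xn = np.where(bad, 1.0, xn)
    vals = (Xc @ Lc) / np.outer(xn, ln)
    vals[bad, :] = 0.0
    return GradientTimeseries(values=np.clip(vals, -1.0, 1.0))


def circular_shift_null(
    region_ts: np.ndarray,
    seed: int | None = None,
    offsets: np.ndarray | None = None,
) -> np.ndarray:
    """Rotate each region's time course by an independent random offset.

    Offsets are uniform over [0, T); per-region periodograms and circular
    autocovariances are exactly preserved.  ``offsets`` overrides the random
    draw (useful for forcing the identity).
    """
    X = np.asarray(region_ts, dtype=float)
    T, R = X.shape
    if T < 2:
        raise ContractError("need at least 2 timepoints")
    if offsets is None:
        rng = np.random.default_rng(seed)
        offsets = rng.integers(0, T, size=R)
    offsets = np.asarray(offsets, dtype=int)
    out = np.empty_like(X)
    for j in range(R):
        out[:, j] = np.roll(X[:, j], offsets[j] % T)
    return out


def acf(series: np.ndarray, max_lag: int) -> np.ndarray:
    """Biased-normalized sample autocorrelation for lags 0..max_lag."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ContractError("acf expects a univariate series")
    if x.shape[0] <= max_lag:
        raise ContractError("need more timepoints than max_lag")
    if np.ptp(x) == 0:
        raise ContractError("autocorrelation of a constant series is undefined")
    return _sm_acf(x, nlags=max_lag, adjusted=False, fft=True)


def group_acf(subjects, max_lag: int) -> dict[int, np.ndarray]:
    """Mean per-gradient-averaged ACF per winner group.

    ``subjects`` is a sequence of (GradientTimeseries, winner) pairs with
    winner in {1, 2}.  An empty group is flagged and absent from the result.
    """
    groups: dict[int, list[np.ndarray]] = {1: [], 2: []}
    for gts, winner in subjects:
        if winner not in groups:
            raise ContractError(f"winner label must be 1 or 2, got {winner}")
        vals = gts.values
        curves = [acf(vals[:, g], max_lag) for g in range(vals.shape[1])]
        groups[winner].append(np.mean(curves, axis=0))
    out = {}
    for label, curves in groups.items():
        if curves:
            out[label] = np.mean(curves, axis=0)
        else:
            logger.warning("group %d is empty; no ACF summary produced", label)
    return out
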