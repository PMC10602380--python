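"""Model comparison: posterior model probabilities and cohort summaries.

Free energies of the two candidate orders are converted to posterior model
probabilities with a two-model softmax, p_i = exp(F_i) / (exp(F1) + exp(F2)),
subjects are classified by the winning order, and cohorts summarized as
counts and proportions per condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .dynamics import Trajectory
from .exceptions import ContractError
from .inversion import OptimizerOptions, PriorSpec, invert_both_orders

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "CohortSummary",
    "F_TIE_TOL",
    "posterior_model_probability",
    "classify_subject",
    "summarize_cohort",
]

#: free-energy differences below this are treated as ties (won by order 1)
F_TIE_TOL = 1e-9


@dataclass(frozen=True)
class ComparisonResult:
    """Per-subject free energies, model probabilities and winning order."""

    subject_id: str
    F1: float
    F2: float
    p1: float
    p2: float
    winner: int
    condition: str = ""
    n_gradients: int | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "n_gradients": self.n_gradients,
            "F1": self.F1,
            "F2": self.F2,
            "p1": self.p1,
            "p2": self.p2,
            "winner": self.winner,
        }


@dataclass(frozen=True)
class CohortSummary:
    """Counts and proportions of first- vs second-order subjects."""

    condition: str
    n_gradients: int | None
    n_subjects: int
    n_first: int
    n_second: int
    prop_first: float
    prop_second: float


def posterior_model_probability(F1: float, F2: float) -> tuple[float, float]:
    """Two-model softmax of the free energies.

    p1 = 1 / (1 + exp(F2 - F1)) and p2 = 1 - p1, computed stably via the
    logistic function.
    """
    if not (np.isfinite(F1) and np.isfinite(F2)):
        raise ContractError("free energies must be finite")
    p1 = float(expit(F1 - F2))
    return p1, 1.0 - p1


def _winner(F1: float, F2: float) -> int:
    if abs(F1 - F2) <= F_TIE_TOL:
        logger.info("free-energy tie (|dF| <= %g); classifying as order 1", F_TIE_TOL)
        return 1
    return 1 if F1 > F2 else 2


def classify_subject(
    data: Trajectory,
    priors: dict[int, PriorSpec] | None = None,
    opts: OptimizerOptions | None = None,
    subject_id: str = "",
    condition: str = "",
    n_gradients: int | None = None,
) -> ComparisonResult:
    """Invert both orders on one subject's series and classify by higher F.

    Ties within ``F_TIE_TOL`` nats go to order 1 (parsimony) and are logged.
    Deterministic given ``opts.seed``.
    """
    e1, e2 = invert_both_orders(data, priors, opts)
    p1, p2 = posterior_model_probability(e1.F, e2.F)
    return ComparisonResult(
        subject_id=subject_id,
        F1=e1.F,
        F2=e2.F,
        p1=p1,
        p2=p2,
        winner=_winner(e1.F, e2.F),
        condition=condition,
        n_gradients=n_gradients,
    )


def summarize_cohort(
    results,
    condition: str | None = None,
    n_gradients: int | None = None,
) -> CohortSummary:
    """Exact counts and fractions of winners over a non-empty cohort."""
    results = list(results)
    if not results:
        raise ContractError("summarize_cohort requires a non-empty cohort")
    conditions = {r.condition for r in results}
    if condition is None:
        if len(conditions) > 1:
            raise ContractError(f"mixed conditions in cohort: {sorted(conditions)}")
        condition = next(iter(conditions))
    elif conditions - {condition}:
        raise ContractError("results do not all match the requested condition")
    n = len(results)
    n_first = sum(1 for r in results if r.winner == 1)
    return CohortSummary(
        condition=condition,
        n_gradients=n_gradients,
        n_subjects=n,
        n_first=n_first,
        n_second=n - n_first,
        prop_first=n_first / n,
        prop_second=(n - n_first) / n,
    )
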