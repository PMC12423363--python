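"""Dose-desirability utilities.

The mean utility of dose j is U_j = sum_k psi_k * pi_jk, a weighted average
of outcome-category probabilities with elicited scores psi_k.  The marginal
form U^M_j = pi_e,j - w * pi_t,j trades a w-unit increase in toxicity rate
for a unit increase in response rate; it embeds exactly into the mean-utility
form (see :func:`embed_marginal_as_utility`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .outcome import (
    CategoryCoding,
    DEFAULT_CODING,
    DirichletState,
    OutcomeModelError,
    posterior_mean,
)

__all__ = [
    "UtilityError",
    "UtilitySpec",
    "DoseUtility",
    "MarginalEmbedding",
    "DEFAULT_SCORES",
    "mean_utility",
    "posterior_expected_utility",
    "marginal_utility",
    "embed_marginal_as_utility",
]

#: Worked-elicitation default on a 0-100 scale: psi_1 (toxicity, no efficacy)
#: is the least desirable outcome, psi_4 (efficacy, no toxicity) the most.
DEFAULT_SCORES = (0.0, 10.0, 60.0, 100.0)

_PROB_TOL = 1e-6


class UtilityError(ValueError):
    """Invalid utility specification or probability input."""


@dataclass(frozen=True)
class UtilitySpec:
    """Elicited outcome scores psi_k defining the risk-benefit trade-off.

    Invariants (checked against the coding): the score at (Ye,Yt)=(1,0) is
    the maximum, at (0,1) the minimum, and scores are monotone in each flag
    (more efficacy never hurts, more toxicity never helps).  ``relaxed``
    marks specs (e.g. marginal embeddings with w > 1) where the clinical
    category ordering psi(1,1) >= psi(0,0) is intentionally violated.
    """

    scores: tuple[float, ...]
    coding: CategoryCoding = DEFAULT_CODING
    relaxed: bool = False

    def __post_init__(self) -> None:
        scores = tuple(float(s) for s in self.scores)
        object.__setattr__(self, "scores", scores)
        if len(scores) != self.coding.k:
            raise UtilityError(
                f"got {len(scores)} scores for K={self.coding.k} categories"
            )
        by_flags = {
            (c.efficacy_flag, c.toxicity_flag): scores[c.index - 1]
            for c in self.coding.categories
        }
        if self.coding.k == 4:
            if by_flags[(1, 0)] != max(scores) or by_flags[(0, 1)] != min(scores):
                raise UtilityError(
                    "score at (efficacy, no toxicity) must be the maximum and "
                    "at (no efficacy, toxicity) the minimum"
                )
            for t in (0, 1):
                if by_flags[(1, t)] < by_flags[(0, t)]:
                    raise UtilityError("scores must be nondecreasing in efficacy")
            for e in (0, 1):
                if by_flags[(e, 0)] < by_flags[(e, 1)]:
                    raise UtilityError("scores must be nonincreasing in toxicity")

    @property
    def scale_hint(self) -> tuple[float, float]:
        return (min(self.scores), max(self.scores))

    @property
    def scores_array(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)


@dataclass(frozen=True)
class DoseUtility:
    """A dose-desirability value, either mean-utility or marginal form."""

    dose_index: int
    value: float
    form: str  # "mean_utility" | "marginal"


def _check_probs(probs: Sequence[float], k: int) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.ndim != 1 or len(arr) != k:
        raise UtilityError(f"probability vector must have length {k}")
    if (arr < -_PROB_TOL).any():
        raise UtilityError("probabilities must be nonnegative")
    if abs(arr.sum() - 1.0) > _PROB_TOL:
        raise UtilityError(f"probabilities sum to {arr.sum():.8f}, not 1")
    return arr


def mean_utility(
    spec: UtilitySpec, probs: Sequence[float], dose_index: int = 0
) -> DoseUtility:
    """Mean utility U = sum_k psi_k pi_k for a category probability vector."""
    arr = _check_probs(probs, len(spec.scores))
    return DoseUtility(dose_index, float(spec.scores_array @ arr), "mean_utility")


def posterior_expected_utility(
    spec: UtilitySpec, state: DirichletState, dose_index: int = 0
) -> DoseUtility:
    """Posterior expectation E[U_j | D_j].

    By linearity of U in pi this equals the mean utility evaluated at the
    Dirichlet posterior mean — the plug-in and the exact posterior
    expectation coincide.
    """
    if state.k != len(spec.scores):
        raise UtilityError(f"state K={state.k} does not match {len(spec.scores)} scores")
    return mean_utility(spec, posterior_mean(state), dose_index)


def marginal_utility(pe: float, pt: float, w: float, dose_index: int = 0) -> DoseUtility:
    """Marginal utility U^M = pi_e - w * pi_t."""
    for name, p in (("pe", pe), ("pt", pt)):
        if not 0.0 <= p <= 1.0:
            raise UtilityError(f"{name} must be in [0, 1], got {p}")
    if w < 0:
        raise UtilityError("w must be nonnegative")
    return DoseUtility(dose_index, float(pe - w * pt), "marginal")


@dataclass(frozen=True)
class MarginalEmbedding:
    """A mean-utility spec equivalent to pi_e - w*pi_t, with affine constants.

    mean_utility(spec, pi) == intercept + slope * (pi_e - w * pi_t) for every
    probability vector pi, with slope > 0, so dose rankings agree exactly.
    """

    spec: UtilitySpec
    slope: float
    intercept: float
    w: float


def embed_marginal_as_utility(
    w: float,
    scale: tuple[float, float] = (0.0, 100.0),
    coding: CategoryCoding = DEFAULT_CODING,
) -> MarginalEmbedding:
    """Embed the marginal trade-off pi_e - w*pi_t as a mean-utility spec.

    Sets psi(e, t) = lo + (hi - lo) * (e - w*t), giving psi(1,0)=hi,
    psi(0,0)=lo, psi(1,1)=hi - w(hi-lo), psi(0,1)=lo - w(hi-lo).  The mean
    utility then equals lo + (hi-lo)*(pi_e - w*pi_t): an order-preserving
    affine transform of the marginal utility.  For w > 1 the embedded scores
    place (1,1) below (0,0); a warning is issued and the returned
    UtilitySpec is flagged relaxed.
    """
    lo, hi = float(scale[0]), float(scale[1])
    if hi <= lo:
        raise UtilityError("scale must satisfy hi > lo")
    if w < 0:
        raise UtilityError("w must be nonnegative")
    span = hi - lo
    scores = tuple(
        lo + span * (c.efficacy_flag - w * c.toxicity_flag)
        for c in sorted(coding.categories, key=lambda c: c.index)
    )
    relaxed = w > 1
    if relaxed:
        warnings.warn(
            f"w={w} > 1 places the (efficacy, toxicity) score below the "
            "(no efficacy, no toxicity) score; category-ordering convention relaxed",
            stacklevel=2,
        )
    spec = UtilitySpec(scores, coding=coding, relaxed=relaxed)
    return MarginalEmbedding(spec=spec, slope=span, intercept=lo, w=w)
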