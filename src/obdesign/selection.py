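"""Dose screening and selection.

Admissibility (toxicity/futility screens on Beta posterior tails), isotonic
MTD estimation via pool-adjacent-violators, optimal-biological-dose (OBD)
selection capped at the MTD, cohort assignment policies, and the BOIN
optimal-interval escalation/de-escalation boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import special
from scipy.optimize import isotonic_regression

from .outcome import BetaMarginal, CategoryCoding, DEFAULT_CODING, DirichletState, marginal
from .utility import DoseUtility

__all__ = [
    "SelectionError",
    "AdmissibilityRule",
    "AdmissibleSet",
    "BoinBoundaries",
    "AssignmentPolicy",
    "prob_exceeds",
    "prob_below",
    "admissible_set",
    "isotonic_toxicity",
    "estimate_mtd",
    "select_obd",
    "assignment_weights",
    "boin_boundaries",
    "boin_decision",
]

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


class SelectionError(ValueError):
    """Invalid input to a selection operation."""


@dataclass(frozen=True)
class AdmissibilityRule:
    """Toxicity/futility screening rule.

    A dose is inadmissible as *toxic* if Pr(pi_t > phi_t | D) > delta_t and
    as *futile* if Pr(pi_e < phi_e | D) > delta_e.  phi_t is the toxicity
    upper limit (slightly above the phase-I target DLT rate), phi_e the
    efficacy lower limit (a phase-II-style target response rate), and the
    deltas are posterior-probability cutoffs calibrated by simulation.
    """

    phi_t: float
    phi_e: float
    delta_t: float = 0.95
    delta_e: float = 0.95

    def __post_init__(self) -> None:
        for name in ("phi_t", "phi_e", "delta_t", "delta_e"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise SelectionError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class AdmissibleSet:
    """Admissible doses plus per-excluded-dose reasons."""

    doses: frozenset[int]
    reasons: Mapping[int, str]  # excluded dose -> "toxic" | "futile" | "both"
    n_doses: int

    def __post_init__(self) -> None:
        all_doses = set(range(1, self.n_doses + 1))
        if not set(self.doses) <= all_doses:
            raise SelectionError("admissible doses must lie in 1..J")
        missing = all_doses - set(self.doses) - set(self.reasons)
        if missing:
            raise SelectionError(f"excluded doses without a reason: {sorted(missing)}")

    def __contains__(self, dose: int) -> bool:
        return dose in self.doses

    @property
    def is_empty(self) -> bool:
        return len(self.doses) == 0


@dataclass(frozen=True)
class BoinBoundaries:
    """BOIN interval boundaries: escalate if DLT rate <= lambda_e, de-escalate if >= lambda_d."""

    phi: float
    phi1: float
    phi2: float
    lambda_e: float
    lambda_d: float

    def __post_init__(self) -> None:
        if not (0 < self.phi1 < self.phi < self.phi2 < 1):
            raise SelectionError("need 0 < phi1 < phi < phi2 < 1")
        if not (self.lambda_e < self.phi < self.lambda_d):
            raise SelectionError("need lambda_e < phi < lambda_d")


_POLICIES = ("deterministic_max_utility", "adaptive_randomization", "equal_randomization")


@dataclass(frozen=True)
class AssignmentPolicy:
    """How the next cohort is assigned among admissible doses."""

    kind: str = "deterministic_max_utility"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _POLICIES:
            raise SelectionError(f"policy kind must be one of {_POLICIES}")


def prob_exceeds(marg: BetaMarginal, threshold: float) -> float:
    """Pr(p > threshold) under the Beta marginal (1 - regularized incomplete beta)."""
    if not 0.0 <= threshold <= 1.0:
        raise SelectionError("threshold must be in [0, 1]")
    # BetaMarginal construction already rejects alpha/beta <= 0
    return float(1.0 - special.betainc(marg.alpha, marg.beta, threshold))


def prob_below(marg: BetaMarginal, threshold: float) -> float:
    """Pr(p < threshold) under the Beta marginal."""
    if not 0.0 <= threshold <= 1.0:
        raise SelectionError("threshold must be in [0, 1]")
    return float(special.betainc(marg.alpha, marg.beta, threshold))


def admissible_set(
    states: Sequence[DirichletState],
    rule: AdmissibilityRule,
    coding: CategoryCoding = DEFAULT_CODING,
) -> AdmissibleSet:
    """Screen every dose; both toxicity and futility checks are evaluated."""
    doses: set[int] = set()
    reasons: dict[int, str] = {}
    for j, state in enumerate(states, start=1):
        toxic = prob_exceeds(marginal(state, "toxicity", coding), rule.phi_t) > rule.delta_t
        futile = prob_below(marginal(state, "efficacy", coding), rule.phi_e) > rule.delta_e
        if toxic and futile:
            reasons[j] = "both"
        elif toxic:
            reasons[j] = "toxic"
        elif futile:
            reasons[j] = "futile"
        else:
            doses.add(j)
    return AdmissibleSet(frozenset(doses), reasons, n_doses=len(states))


def isotonic_toxicity(
    tox_means: Sequence[float], weights: Sequence[float]
) -> np.ndarray:
    """Weighted least-squares nondecreasing fit (pool-adjacent-violators)."""
    y = np.asarray(tox_means, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.shape != w.shape or y.ndim != 1:
        raise SelectionError("tox_means and weights must be 1-d vectors of equal length")
    if (w <= 0).any():
        raise SelectionError("weights must be positive")
    return np.asarray(isotonic_regression(y, weights=w, increasing=True).x)


def estimate_mtd(
    tox_means: Sequence[float], weights: Sequence[float], phi_t: float
) -> int:
    """MTD = dose whose isotonic toxicity estimate is closest to phi_t.

    Ties (within 1e-12) break toward the lower dose index.
    """
    iso = isotonic_toxicity(tox_means, weights)
    if len(iso) == 0:
        raise SelectionError("empty toxicity vector")
    dist = np.abs(iso - phi_t)
    return int(np.flatnonzero(dist <= dist.min() + _TIE_TOL)[0]) + 1


def select_obd(
    utilities: Sequence[DoseUtility], adm: AdmissibleSet, mtd: int
) -> Optional[int]:
    """OBD = argmax utility over admissible doses not above the MTD.

    Returns None when no admissible dose at or below the MTD exists (trial
    terminated without an OBD).  Ties break toward the lower dose.
    """
    by_dose = {u.dose_index: u.value for u in utilities}
    feasible = sorted(j for j in adm.doses if j <= mtd)
    missing = [j for j in feasible if j not in by_dose]
    if missing:
        raise SelectionError(f"no utility provided for admissible doses {missing}")
    if not feasible:
        return None
    best = max(by_dose[j] for j in feasible)
    return next(j for j in feasible if by_dose[j] >= best - _TIE_TOL)


def assignment_weights(
    utilities: Sequence[DoseUtility],
    adm: AdmissibleSet,
    scale_min: Optional[float] = None,
) -> dict[int, float]:
    """Adaptive-randomization weights omega_j proportional to posterior mean utility.

    Utilities must be nonnegative over the admissible set; scales admitting
    negative values (marginal embeddings with w > 1) pass ``scale_min`` so
    weights use utilities shifted by the scale minimum.  If every utility is
    zero, equal weights are returned with a logged warning.
    """
    by_dose = {u.dose_index: u.value for u in utilities}
    doses = sorted(adm.doses)
    if not doses:
        raise SelectionError("cannot compute weights over an empty admissible set")
    vals = np.array([by_dose[j] for j in doses], dtype=float)
    if scale_min is not None:
        vals = vals - scale_min
        logger.info("assignment weights use utilities shifted by scale minimum %s", scale_min)
    if (vals < 0).any():
        raise SelectionError(
            "negative utilities; pass scale_min to shift onto a nonnegative scale"
        )
    total = vals.sum()
    if total == 0:
        logger.warning("all utilities zero over the admissible set; using equal weights")
        return {j: 1.0 / len(doses) for j in doses}
    return {j: float(v / total) for j, v in zip(doses, vals)}


def boin_boundaries(
    phi: float, phi1: Optional[float] = None, phi2: Optional[float] = None
) -> BoinBoundaries:
    """BOIN optimal-interval boundaries for target DLT probability phi.

    Defaults phi1 = 0.6*phi, phi2 = 1.4*phi.  Closed form:

        lambda_e = log((1-phi1)/(1-phi)) / log(phi(1-phi1) / (phi1(1-phi)))
        lambda_d = log((1-phi)/(1-phi2)) / log(phi2(1-phi) / (phi(1-phi2)))
    """
    if not 0.0 < phi < 1.0:
        raise SelectionError("phi must be in (0, 1)")
    phi1 = 0.6 * phi if phi1 is None else phi1
    phi2 = 1.4 * phi if phi2 is None else phi2
    if not (0 < phi1 < phi < phi2 < 1):
        raise SelectionError("need 0 < phi1 < phi < phi2 < 1 (degenerate interval)")
    lam_e = math.log((1 - phi1) / (1 - phi)) / math.log(phi * (1 - phi1) / (phi1 * (1 - phi)))
    lam_d = math.log((1 - phi) / (1 - phi2)) / math.log(phi2 * (1 - phi) / (phi * (1 - phi2)))
    return BoinBoundaries(phi=phi, phi1=phi1, phi2=phi2, lambda_e=lam_e, lambda_d=lam_d)


def boin_decision(boundaries: BoinBoundaries, dlt_count: int, n_at_dose: int) -> str:
    """Interval decision from the observed DLT rate at the current dose.

    Rate <= lambda_e -> "escalate"; rate >= lambda_d -> "de_escalate";
    otherwise "stay".
    """
    if n_at_dose < 1:
        raise SelectionError("n_at_dose must be >= 1")
    if not 0 <= dlt_count <= n_at_dose:
        raise SelectionError("dlt_count must be between 0 and n_at_dose")
    rate = dlt_count / n_at_dose
    if rate <= boundaries.lambda_e:
        return "escalate"
    if rate >= boundaries.lambda_d:
        return "de_escalate"
    return "stay"
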