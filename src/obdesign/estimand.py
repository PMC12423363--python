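"""Estimand layer: intercurrent-event (ICE) handling strategies.

Patient trajectories carry time-stamped efficacy/toxicity assessments plus
ICE events (death, discontinuation due to toxicity, additional anticancer
therapy, surgery, antidrug antibodies, ...).  Before a trajectory can feed
the Dirichlet-multinomial outcome model it must be reduced to a single
(Ye, Yt) contribution — and *how* that reduction handles the ICEs is the
estimand.  Five strategies are supported per ICE type:

    treatment_policy    ICE ignored; all observations (pre and post event)
                        contribute.
    composite           the ICE is absorbed into the endpoint as a failure
                        (Ye = 0); toxicity-type events also force Yt = 1,
                        yielding the lowest relevant utility.
    while_on_treatment  only observations up to and including the event time
                        contribute.
    hypothetical        the counterfactual (no-ICE) outcome is used; only
                        available where counterfactuals exist (simulation).
    principal_stratum   the patient is excluded if they belong to the latent
                        stratum that would experience the ICE.

When a patient has several ICEs handled by different strategies, a
configured precedence (a total order on ICE types) decides which event is
decisive.  An event occurring after the efficacy endpoint has already been
achieved is not an ICE at all and is skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .outcome import (
    CategoryCoding,
    DEFAULT_CODING,
    DirichletState,
    OutcomeCounts,
    update_posterior,
)
from .selection import AdmissibilityRule, admissible_set, estimate_mtd, select_obd
from .utility import UtilitySpec, posterior_expected_utility

__all__ = [
    "EstimandError",
    "ICE_TYPES",
    "STRATEGIES",
    "ICEvent",
    "Observation",
    "PatientRecord",
    "StrategyConfig",
    "Contribution",
    "TabulationResult",
    "TippingPointResult",
    "case_study_strategies",
    "resolve_outcome",
    "tabulate",
    "compare_estimands",
    "tipping_point",
]

#: Closed taxonomy of ICE types (extensible via config with an explicit strategy).
ICE_TYPES = (
    "discontinuation_toxicity",
    "additional_therapy",
    "death",
    "surgery_clinician_choice",
    "surgery_treatment_failure",
    "surgery_external",
    "ada_occurrence",
    "progression_discontinuation",
    "nonadherence",
    "dose_switch",
)

STRATEGIES = (
    "treatment_policy",
    "composite",
    "hypothetical",
    "while_on_treatment",
    "principal_stratum",
)

#: Default precedence: ordered by clinical severity/terminality.
DEFAULT_PRECEDENCE = (
    "death",
    "discontinuation_toxicity",
    "progression_discontinuation",
    "additional_therapy",
    "surgery_treatment_failure",
    "surgery_clinician_choice",
    "surgery_external",
    "ada_occurrence",
    "dose_switch",
    "nonadherence",
)


class EstimandError(ValueError):
    """A record cannot be resolved under the configured strategies."""


@dataclass(frozen=True)
class ICEvent:
    """One intercurrent event: type, time (days from first dose), free notes."""

    type: str
    time: float
    attributes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.time < 0:
            raise EstimandError("event time must be >= 0")


@dataclass(frozen=True)
class Observation:
    """One time-stamped (efficacy, toxicity) assessment."""

    time: float
    efficacy: int
    toxicity: int

    def __post_init__(self) -> None:
        if self.time < 0:
            raise EstimandError("observation time must be >= 0")
        if self.efficacy not in (0, 1) or self.toxicity not in (0, 1):
            raise EstimandError("observation flags must be binary")


@dataclass(frozen=True)
class PatientRecord:
    """One subject's dose, assessments, ICE events and (simulated) oracles.

    ``counterfactual`` is the no-ICE (Ye, Yt) pair and ``latent_stratum`` the
    per-ICE-type would-experience indicator; both exist only for simulated
    records.  ``pending`` flags subjects whose final outcome is unresolved
    (e.g. imputed), making them shiftable in tipping-point analysis.
    """

    patient_id: str
    dose_index: int
    observations: tuple[Observation, ...] = ()
    events: tuple[ICEvent, ...] = ()
    counterfactual: Optional[tuple[int, int]] = None
    latent_stratum: Optional[Mapping[str, bool]] = None
    pending: bool = False

    def __post_init__(self) -> None:
        if self.dose_index < 1:
            raise EstimandError("dose_index must be >= 1")
        obs = tuple(sorted(self.observations, key=lambda o: o.time))
        object.__setattr__(self, "observations", obs)
        object.__setattr__(self, "events", tuple(self.events))


@dataclass(frozen=True)
class StrategyConfig:
    """The estimand: ICE-type -> strategy map plus precedence order.

    ``composite_toxicity_types`` lists the event types that also set Yt = 1
    when handled by the composite strategy (e.g. death, discontinuation due
    to toxicity); for other composite-handled types Yt stays as observed.
    """

    per_ice_strategy: Mapping[str, str]
    precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
    composite_toxicity_types: frozenset[str] = frozenset(
        {"death", "discontinuation_toxicity"}
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_ice_strategy", dict(self.per_ice_strategy))
        object.__setattr__(self, "precedence", tuple(self.precedence))
        object.__setattr__(
            self, "composite_toxicity_types", frozenset(self.composite_toxicity_types)
        )
        for t, s in self.per_ice_strategy.items():
            if s not in STRATEGIES:
                raise EstimandError(f"unknown strategy {s!r} for ICE type {t!r}")
        if len(set(self.precedence)) != len(self.precedence):
            raise EstimandError("precedence must not repeat ICE types")
        unordered = set(self.per_ice_strategy) - set(self.precedence)
        if unordered:
            raise EstimandError(
                f"ICE types missing from precedence order: {sorted(unordered)}"
            )

    def rank(self, ice_type: str) -> int:
        return self.precedence.index(ice_type)

    def strategy_for(self, ice_type: str) -> str:
        try:
            return self.per_ice_strategy[ice_type]
        except KeyError:
            raise EstimandError(f"no strategy configured for ICE type {ice_type!r}")

    def with_strategy(self, ice_type: str, strategy: str) -> "StrategyConfig":
        m = dict(self.per_ice_strategy)
        m[ice_type] = strategy
        return replace(self, per_ice_strategy=m)


def case_study_strategies() -> StrategyConfig:
    """The worked case study's strategy assignments.

    Discontinuation due to toxicity, death, progression discontinuation and
    surgery-as-treatment-failure are composite failures (the first two also
    count as toxicity); additional therapy and clinician-choice surgery are
    while-on-treatment; antidrug antibodies, dose switching and nonadherence
    follow treatment policy; externally motivated surgery is hypothetical.
    """
    return StrategyConfig(
        per_ice_strategy={
            "discontinuation_toxicity": "composite",
            "death": "composite",
            "additional_therapy": "while_on_treatment",
            "progression_discontinuation": "composite",
            "ada_occurrence": "treatment_policy",
            "dose_switch": "treatment_policy",
            "surgery_clinician_choice": "while_on_treatment",
            "surgery_treatment_failure": "composite",
            "surgery_external": "hypothetical",
            "nonadherence": "treatment_policy",
        }
    )


@dataclass(frozen=True)
class Contribution:
    """The unit feeding OutcomeCounts: include/exclude plus category."""

    patient_id: str
    dose_index: int
    included: bool
    category: Optional[int]  # category index 1..K, None when excluded
    provenance: str

    def __post_init__(self) -> None:
        if self.included and self.category is None:
            raise EstimandError("included contribution must carry a category")
        if not self.included and self.category is not None:
            raise EstimandError("excluded contribution must not carry a category")


def _flags_from(observations: Sequence[Observation]) -> tuple[int, int]:
    """Best-response reduction: any positive assessment sets the flag."""
    ye = int(any(o.efficacy for o in observations))
    yt = int(any(o.toxicity for o in observations))
    return ye, yt


def resolve_outcome(
    rec: PatientRecord,
    cfg: StrategyConfig,
    coding: CategoryCoding = DEFAULT_CODING,
) -> Contribution:
    """Reduce one trajectory to a Contribution under the configured estimand.

    Events are considered in precedence order (ties by event time); an event
    occurring at or after the time an efficacy response was already recorded
    is non-decisive and skipped.  The first decisive event's strategy
    determines the handling; a record with no decisive events contributes its
    factual best response.
    """
    for ev in rec.events:
        cfg.strategy_for(ev.type)  # fail fast listing the uncovered type

    first_response = min(
        (o.time for o in rec.observations if o.efficacy), default=float("inf")
    )
    ordered = sorted(rec.events, key=lambda e: (cfg.rank(e.type), e.time))
    decisive = next((e for e in ordered if e.time <= first_response), None)

    if decisive is None:
        ye, yt = _flags_from(rec.observations)
        note = "no decisive ICE; factual best response"
        return Contribution(
            rec.patient_id, rec.dose_index, True, coding.index_for(ye, yt),
            provenance=note,
        )

    strategy = cfg.strategy_for(decisive.type)
    tag = f"{decisive.type}@{decisive.time:g} -> {strategy}"

    if strategy == "treatment_policy":
        ye, yt = _flags_from(rec.observations)
        note = f"{tag}; all {len(rec.observations)} observations used"
    elif strategy == "composite":
        _, yt_obs = _flags_from(rec.observations)
        ye = 0
        yt = 1 if decisive.type in cfg.composite_toxicity_types else yt_obs
        note = f"{tag}; failure imputed" + (
            " with toxicity" if decisive.type in cfg.composite_toxicity_types else ""
        )
    elif strategy == "while_on_treatment":
        pre = [o for o in rec.observations if o.time <= decisive.time]
        ye, yt = _flags_from(pre)
        note = f"{tag}; {len(pre)} observation(s) at or before event time"
    elif strategy == "hypothetical":
        if rec.counterfactual is None:
            raise EstimandError(
                f"patient {rec.patient_id}: hypothetical strategy for "
                f"{decisive.type!r} requires a counterfactual outcome "
                "(only available for simulated records)"
            )
        ye, yt = rec.counterfactual
        note = f"{tag}; counterfactual outcome used"
    elif strategy == "principal_stratum":
        stratum = (rec.latent_stratum or {}).get(decisive.type)
        if stratum is None:
            raise EstimandError(
                f"patient {rec.patient_id}: principal-stratum strategy for "
                f"{decisive.type!r} requires a known latent stratum"
            )
        if not stratum:
            raise EstimandError(
                f"patient {rec.patient_id}: experienced {decisive.type!r} but "
                "latent stratum says would-not-experience (inconsistent record)"
            )
        return Contribution(
            rec.patient_id, rec.dose_index, False, None,
            provenance=f"{tag}; excluded (would-experience stratum)",
        )
    else:  # pragma: no cover - guarded by StrategyConfig validation
        raise EstimandError(f"unknown strategy {strategy!r}")

    return Contribution(
        rec.patient_id, rec.dose_index, True, coding.index_for(ye, yt), provenance=note
    )


@dataclass(frozen=True)
class TabulationResult:
    """Per-dose outcome counts plus the exclusion report."""

    counts: dict[int, OutcomeCounts]
    contributions: tuple[Contribution, ...]
    exclusions: tuple[Contribution, ...]

    @property
    def n_included(self) -> int:
        return sum(c.n_total for c in self.counts.values())

    def counts_for(self, dose: int, k: int = 4) -> OutcomeCounts:
        return self.counts.get(dose, OutcomeCounts(dose, np.zeros(k, dtype=int)))


def tabulate(
    records: Sequence[PatientRecord],
    cfg: StrategyConfig,
    n_doses: Optional[int] = None,
    coding: CategoryCoding = DEFAULT_CODING,
) -> TabulationResult:
    """Resolve every record and count included contributions per dose."""
    n_doses = n_doses or max((r.dose_index for r in records), default=0)
    contribs = tuple(resolve_outcome(r, cfg, coding) for r in records)
    counts = {
        j: np.zeros(coding.k, dtype=np.int64) for j in range(1, n_doses + 1)
    }
    for c in contribs:
        if c.included:
            counts[c.dose_index][c.category - 1] += 1
    return TabulationResult(
        counts={j: OutcomeCounts(j, v) for j, v in counts.items()},
        contributions=contribs,
        exclusions=tuple(c for c in contribs if not c.included),
    )


def _dose_summaries(
    tab: TabulationResult,
    spec: UtilitySpec,
    prior: DirichletState,
    rule: AdmissibilityRule,
    n_doses: int,
    coding: CategoryCoding = DEFAULT_CODING,
):
    """Posterior states, utilities, admissible set, MTD and OBD for tabulated data."""
    from .outcome import marginal  # local import to avoid cycle noise

    states = [
        update_posterior(prior, tab.counts_for(j, coding.k)) for j in range(1, n_doses + 1)
    ]
    utilities = [
        posterior_expected_utility(spec, s, dose_index=j)
        for j, s in enumerate(states, start=1)
    ]
    adm = admissible_set(states, rule, coding)
    tox = [marginal(s, "toxicity", coding) for s in states]
    mtd = estimate_mtd(
        [m.mean for m in tox], [m.alpha + m.beta for m in tox], rule.phi_t
    )
    obd = select_obd(utilities, adm, mtd)
    return states, utilities, adm, mtd, obd


def compare_estimands(
    records: Sequence[PatientRecord],
    configs: Mapping[str, StrategyConfig],
    spec: UtilitySpec,
    prior: DirichletState,
    rule: AdmissibilityRule,
    n_doses: Optional[int] = None,
    coding: CategoryCoding = DEFAULT_CODING,
) -> pd.DataFrame:
    """One row per named estimand: per-dose utilities, admissible set, MTD, OBD.

    The machine twin of an estimand-comparison table: the same data resolved
    under different ICE-handling configurations, summarized side by side.
    """
    n_doses = n_doses or max((r.dose_index for r in records), default=0)
    rows = []
    for name, cfg in configs.items():
        tab = tabulate(records, cfg, n_doses, coding)
        _, utilities, adm, mtd, obd = _dose_summaries(
            tab, spec, prior, rule, n_doses, coding
        )
        row: dict[str, object] = {"estimand": name}
        for u in utilities:
            row[f"utility_dose_{u.dose_index}"] = u.value
        row["admissible"] = ",".join(str(j) for j in sorted(adm.doses))
        row["mtd"] = mtd
        row["obd"] = obd if obd is not None else pd.NA
        row["n_included"] = tab.n_included
        row["n_excluded"] = len(tab.exclusions)
        rows.append(row)
    return pd.DataFrame(rows).set_index("estimand")


@dataclass(frozen=True)
class TippingPointResult:
    """Tipping-point table plus the smallest OBD-changing shift (None if robust)."""

    table: pd.DataFrame
    tipping_shift: Optional[int]
    n_shiftable: int


def tipping_point(
    records: Sequence[PatientRecord],
    cfg: StrategyConfig,
    spec: UtilitySpec,
    prior: DirichletState,
    rule: AdmissibilityRule,
    max_shift: int,
    n_doses: Optional[int] = None,
    coding: CategoryCoding = DEFAULT_CODING,
) -> TippingPointResult:
    """Missing-data sensitivity: flip favorable unresolved outcomes to failures.

    Records flagged ``pending`` (unresolved/imputed final outcomes) are
    shiftable.  For shift s = 0..max_shift the s most favorable shiftable
    contributions are moved to the least favorable category (toxicity and no
    efficacy) and the OBD recomputed; the result reports the smallest s that
    changes the OBD, or None if the conclusion is robust to all shifts.
    """
    import warnings

    n_doses = n_doses or max((r.dose_index for r in records), default=0)
    base = tabulate(records, cfg, n_doses, coding)
    scores = spec.scores_array
    worst_cat = int(np.argmin(scores)) + 1

    shiftable = [
        (c, r)
        for c, r in zip(base.contributions, records)
        if r.pending and c.included
    ]
    # most favorable first; ties broken by patient id for determinism
    shiftable.sort(key=lambda cr: (-scores[cr[0].category - 1], cr[0].patient_id))
    if max_shift > len(shiftable):
        warnings.warn(
            f"max_shift={max_shift} exceeds the {len(shiftable)} shiftable records; capped",
            stacklevel=2,
        )
        max_shift = len(shiftable)

    rows = []
    baseline_obd: Optional[int] = None
    tipping: Optional[int] = None
    for s in range(max_shift + 1):
        counts = {j: base.counts_for(j, coding.k).counts.copy() for j in range(1, n_doses + 1)}
        for c, _ in shiftable[:s]:
            counts[c.dose_index][c.category - 1] -= 1
            counts[c.dose_index][worst_cat - 1] += 1
        tab = TabulationResult(
            counts={j: OutcomeCounts(j, v) for j, v in counts.items()},
            contributions=base.contributions,
            exclusions=base.exclusions,
        )
        _, utilities, adm, mtd, obd = _dose_summaries(
            tab, spec, prior, rule, n_doses, coding
        )
        if s == 0:
            baseline_obd = obd
        elif tipping is None and obd != baseline_obd:
            tipping = s
        row: dict[str, object] = {"shift": s}
        for u in utilities:
            row[f"utility_dose_{u.dose_index}"] = u.value
        row["obd"] = obd if obd is not None else pd.NA
        rows.append(row)
    return TippingPointResult(
        table=pd.DataFrame(rows).set_index("shift"),
        tipping_shift=tipping,
        n_shiftable=len(shiftable),
    )
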