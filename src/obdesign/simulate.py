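"""Synthetic-trial simulator.

Generates patient trajectories under a per-dose four-category multinomial
truth with superimposed intercurrent events (ICEs), counterfactual outcomes
and latent strata, and runs full adaptive trials — utility-guided (BOIN12
style) or toxicity-only interval (BOIN) mode — to produce operating
characteristics and pretabulated decision tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .estimand import ICEvent, Observation, PatientRecord, StrategyConfig, tabulate
from .outcome import (
    CategoryCoding,
    DEFAULT_CODING,
    DirichletState,
    OutcomeCounts,
    make_prior,
    marginal,
    update_posterior,
)
from .selection import (
    AdmissibilityRule,
    AssignmentPolicy,
    BoinBoundaries,
    SelectionError,
    admissible_set,
    assignment_weights,
    boin_decision,
    estimate_mtd,
    select_obd,
)
from .utility import UtilitySpec, posterior_expected_utility

__all__ = [
    "SimulationError",
    "Scenario",
    "DesignParams",
    "TrialResult",
    "OCResult",
    "generate_patient",
    "run_trial",
    "operating_characteristics",
    "pretabulate_decisions",
]

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]

_PRETAB_ROW_CAP = 100_000


class SimulationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class Scenario:
    """Data-generating truth for one simulation scenario.

    ``category_probs`` is the (J, K) matrix of true outcome-category
    probabilities per dose.  ICE occurrence is Bernoulli per type and dose;
    event times follow exponential laws truncated to the assessment window.
    ``followup_prob`` is the probability that assessments after a (non-fatal)
    ICE remain available — post-ICE responses exist only through this channel.
    """

    category_probs: np.ndarray
    ice_probs: Mapping[str, np.ndarray] = field(default_factory=dict)
    ice_time_mean: Mapping[str, float] = field(default_factory=dict)
    followup_prob: float = 0.5
    assess_window: float = 56.0
    dlt_window: float = 28.0

    def __post_init__(self) -> None:
        probs = np.atleast_2d(np.asarray(self.category_probs, dtype=float))
        if (probs < 0).any() or not np.allclose(probs.sum(axis=1), 1.0, atol=1e-8):
            raise SimulationError("each per-dose category probability vector must sum to 1")
        object.__setattr__(self, "category_probs", probs)
        norm: dict[str, np.ndarray] = {}
        for t, p in self.ice_probs.items():
            arr = np.broadcast_to(np.asarray(p, dtype=float), (self.n_doses,)).copy()
            if ((arr < 0) | (arr > 1)).any():
                raise SimulationError(f"ICE probabilities for {t!r} must be in [0, 1]")
            norm[t] = arr
        object.__setattr__(self, "ice_probs", norm)
        object.__setattr__(self, "ice_time_mean", dict(self.ice_time_mean))
        if not 0.0 <= self.followup_prob <= 1.0:
            raise SimulationError("followup_prob must be in [0, 1]")

    @property
    def n_doses(self) -> int:
        return self.category_probs.shape[0]

    @property
    def k(self) -> int:
        return self.category_probs.shape[1]


@dataclass(frozen=True)
class DesignParams:
    """Trial design: dose grid, cohorting, caps, screening rule and policy."""

    n_doses: int
    cohort_size: int
    max_n: int
    rule: AdmissibilityRule
    spec: UtilitySpec
    policy: AssignmentPolicy = AssignmentPolicy()
    mode: str = "utility_boin12"  # or "toxicity_boin"
    boundaries: Optional[BoinBoundaries] = None
    per_dose_cap: int = 12
    start_dose: int = 1
    accelerated_titration: bool = False
    titration_trigger_dose: int = 5
    dlt_window_days: float = 28.0  # protocol metadata; binary engine does not use it

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise SimulationError("cohort_size must be >= 1")
        if self.max_n < self.cohort_size:
            raise SimulationError("max_n must be >= cohort_size")
        if self.per_dose_cap > self.max_n:
            raise SimulationError("per_dose_cap must be <= max_n")
        if not 1 <= self.start_dose <= self.n_doses:
            raise SimulationError("start_dose must be in 1..n_doses")
        if self.mode not in ("utility_boin12", "toxicity_boin"):
            raise SimulationError("mode must be 'utility_boin12' or 'toxicity_boin'")
        if self.mode == "toxicity_boin" and self.boundaries is None:
            raise SimulationError("toxicity_boin mode requires BOIN boundaries")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one simulated trial."""

    assignment_history: tuple[tuple[int, int], ...]  # (cohort index, dose)
    final_counts: dict[int, OutcomeCounts]
    admissible_final: object
    mtd: int
    obd: Optional[int]
    terminated_early: bool
    n_enrolled: int
    n_per_dose: np.ndarray


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _truncated_exp(rng: np.random.Generator, mean: float, upper: float) -> float:
    """Exponential(mean) conditioned on (0, upper] by inverse CDF."""
    u = rng.random()
    return float(-mean * math.log1p(-u * (1.0 - math.exp(-upper / mean))))


def generate_patient(
    dose: int,
    scenario: Scenario,
    rng: SeedLike,
    patient_id: str = "p1",
    coding: CategoryCoding = DEFAULT_CODING,
) -> PatientRecord:
    """Draw one synthetic trajectory at a dose.

    The factual category is multinomial with the dose's true probabilities
    and is also stored as the counterfactual (ICEs here affect which
    assessments are *observable*, not the latent outcome).  Each ICE type
    occurs independently with its configured probability; the per-type
    occurrence draws are recorded as the latent strata.  Assessments are laid
    out at the response time, the toxicity time, and the window end, with
    cumulative flags; observations after a fatal event are dropped, and
    observations after any other decisive-time ICE survive only with the
    scenario's follow-up probability.
    """
    rng = _rng(rng)
    if not 1 <= dose <= scenario.n_doses:
        raise SimulationError(f"dose {dose} out of range 1..{scenario.n_doses}")
    probs = scenario.category_probs[dose - 1]
    cat_index = int(rng.choice(scenario.k, p=probs)) + 1
    c = coding.category(cat_index)
    ye, yt = c.efficacy_flag, c.toxicity_flag

    t_eff = float(rng.uniform(0, scenario.assess_window)) if ye else math.inf
    t_tox = float(rng.uniform(0, scenario.dlt_window)) if yt else math.inf

    events: list[ICEvent] = []
    strata: dict[str, bool] = {}
    for ice_type in sorted(scenario.ice_probs):
        occurs = bool(rng.random() < scenario.ice_probs[ice_type][dose - 1])
        strata[ice_type] = occurs
        if occurs:
            mean = scenario.ice_time_mean.get(ice_type, scenario.assess_window / 2.0)
            events.append(
                ICEvent(ice_type, _truncated_exp(rng, mean, scenario.assess_window))
            )

    times = sorted({t for t in (t_eff, t_tox, scenario.assess_window) if math.isfinite(t)})
    obs = [
        Observation(t, int(ye and t_eff <= t), int(yt and t_tox <= t)) for t in times
    ]

    death_time = min((e.time for e in events if e.type == "death"), default=math.inf)
    obs = [o for o in obs if o.time <= death_time]
    other_time = min((e.time for e in events if e.type != "death"), default=math.inf)
    if math.isfinite(other_time) and rng.random() >= scenario.followup_prob:
        obs = [o for o in obs if o.time <= other_time]
    cutoff = min(death_time, other_time)
    if not obs and math.isfinite(cutoff):
        # everything fell after the truncation point: record status at the event
        obs = [
            Observation(
                cutoff, int(ye and t_eff <= cutoff), int(yt and t_tox <= cutoff)
            )
        ]
    if not obs:  # pragma: no cover - window end is always finite
        obs = [Observation(scenario.assess_window, ye, yt)]

    return PatientRecord(
        patient_id=patient_id,
        dose_index=dose,
        observations=tuple(obs),
        events=tuple(events),
        counterfactual=(ye, yt),
        latent_stratum=strata,
    )


def _posterior_states(
    records: Sequence[PatientRecord],
    strategies: StrategyConfig,
    prior: DirichletState,
    n_doses: int,
    coding: CategoryCoding,
):
    tab = tabulate(records, strategies, n_doses, coding)
    states = [
        update_posterior(prior, tab.counts_for(j, coding.k)) for j in range(1, n_doses + 1)
    ]
    return tab, states


def run_trial(
    design: DesignParams,
    scenario: Scenario,
    strategies: StrategyConfig,
    seed: SeedLike,
    prior: Optional[DirichletState] = None,
    coding: CategoryCoding = DEFAULT_CODING,
) -> TrialResult:
    """Run one adaptive trial to completion.

    Utility mode: after each cohort is resolved through the estimand layer
    and the per-dose posteriors refreshed, the next cohort goes to the
    assignment-policy choice among admissible doses below the per-dose cap —
    with the safety constraint that untried doses open one level at a time.
    Toxicity mode: BOIN interval moves of at most one level.  The trial stops
    at max_n, when every dose is inadmissible (early termination), or when no
    dose remains assignable.
    """
    if design.n_doses != scenario.n_doses:
        raise SimulationError("design and scenario disagree on the number of doses")
    rng = _rng(seed)
    prior = prior or make_prior(coding.k, "vague")
    j = design.start_dose
    records: list[PatientRecord] = []
    history: list[tuple[int, int]] = []
    n_per_dose = np.zeros(design.n_doses, dtype=int)
    titrating = design.accelerated_titration
    terminated_early = False
    cohort = 0

    while len(records) < design.max_n:
        cohort += 1
        size = 1 if titrating else design.cohort_size
        size = min(size, design.max_n - len(records), design.per_dose_cap - n_per_dose[j - 1])
        if size <= 0:
            break
        new = [
            generate_patient(j, scenario, rng, patient_id=f"c{cohort}_{i}", coding=coding)
            for i in range(size)
        ]
        records.extend(new)
        n_per_dose[j - 1] += size
        history.append((cohort, j))

        tab, states = _posterior_states(records, strategies, prior, design.n_doses, coding)
        if titrating:
            any_tox = any(
                coding.category(c.category).toxicity_flag
                for c in tab.contributions
                if c.included
            )
            if any_tox or j >= min(design.titration_trigger_dose, design.n_doses):
                titrating = False

        adm = admissible_set(states, design.rule, coding)
        if adm.is_empty:
            terminated_early = True
            break
        if len(records) >= design.max_n:
            break

        max_tried = int(np.max(np.flatnonzero(n_per_dose > 0))) + 1
        open_doses = [
            d
            for d in sorted(adm.doses)
            if d <= max_tried + 1 and n_per_dose[d - 1] < design.per_dose_cap
        ]

        if design.mode == "toxicity_boin":
            # observed DLT count at current dose from resolved contributions
            dlt = sum(
                coding.category(c.category).toxicity_flag
                for c in tab.contributions
                if c.included and c.dose_index == j
            )
            n_at = sum(
                1 for c in tab.contributions if c.included and c.dose_index == j
            )
            move = boin_decision(design.boundaries, dlt, max(n_at, 1))
            target = j + (move == "escalate") - (move == "de_escalate")
            target = int(np.clip(target, 1, design.n_doses))
            candidates = [target, j, j - 1]
            j_next = next(
                (
                    d
                    for d in candidates
                    if 1 <= d <= design.n_doses and n_per_dose[d - 1] < design.per_dose_cap
                ),
                None,
            )
            if j_next is None:
                break
            j = j_next
        else:
            if not open_doses:
                break
            utilities = [
                posterior_expected_utility(design.spec, states[d - 1], dose_index=d)
                for d in open_doses
            ]
            if design.policy.kind == "deterministic_max_utility":
                best = max(u.value for u in utilities)
                j = next(u.dose_index for u in utilities if u.value >= best - 1e-12)
            elif design.policy.kind == "adaptive_randomization":
                sub_adm = admissible_set(states, design.rule, coding)
                open_set = type(sub_adm)(
                    frozenset(open_doses),
                    {d: "closed" for d in range(1, design.n_doses + 1) if d not in open_doses},
                    design.n_doses,
                )
                w = assignment_weights(
                    utilities, open_set, scale_min=min(0.0, design.spec.scale_hint[0])
                )
                doses = sorted(w)
                j = int(rng.choice(doses, p=[w[d] for d in doses]))
            else:  # equal_randomization
                j = int(rng.choice(open_doses))

    tab, states = _posterior_states(records, strategies, prior, design.n_doses, coding)
    adm = admissible_set(states, design.rule, coding)
    tox = [marginal(s, "toxicity", coding) for s in states]
    mtd = estimate_mtd([m.mean for m in tox], [m.alpha + m.beta for m in tox], design.rule.phi_t)
    if design.mode == "toxicity_boin":
        obd = None
    else:
        utilities = [
            posterior_expected_utility(design.spec, s, dose_index=d)
            for d, s in enumerate(states, start=1)
        ]
        obd = None if terminated_early else select_obd(utilities, adm, mtd)
    return TrialResult(
        assignment_history=tuple(history),
        final_counts=tab.counts,
        admissible_final=adm,
        mtd=mtd,
        obd=obd,
        terminated_early=terminated_early,
        n_enrolled=len(records),
        n_per_dose=n_per_dose,
    )


@dataclass(frozen=True)
class OCResult:
    """Operating characteristics over repeated simulated trials."""

    by_dose: pd.DataFrame
    early_termination_pct: float
    mean_sample_size: float
    n_sims: int

    @property
    def selection_pct(self) -> np.ndarray:
        return self.by_dose["selection_pct"].to_numpy()


def operating_characteristics(
    design: DesignParams,
    scenario: Scenario,
    strategies: StrategyConfig,
    n_sims: int,
    seed: SeedLike,
    prior: Optional[DirichletState] = None,
    coding: CategoryCoding = DEFAULT_CODING,
) -> OCResult:
    """Selection percentages, patient allocation and termination rate.

    Per-dose selection percentages plus the early-termination percentage
    partition the replicates (they sum to 100 when every non-terminated trial
    selects a dose).  Reproducible given the seed: replicate streams come
    from spawned child seed sequences.
    """
    if n_sims < 1:
        raise SimulationError("n_sims must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_sims)
    selections = np.zeros(design.n_doses, dtype=int)
    n_treated = np.zeros(design.n_doses, dtype=float)
    terminated = 0
    sizes = []
    for child in children:
        res = run_trial(design, scenario, strategies, child, prior=prior, coding=coding)
        key = res.mtd if design.mode == "toxicity_boin" else res.obd
        if design.mode == "toxicity_boin" and res.terminated_early:
            key = None
        if key is None:
            terminated += 1
        else:
            selections[key - 1] += 1
        n_treated += res.n_per_dose
        sizes.append(res.n_enrolled)
    by_dose = pd.DataFrame(
        {
            "dose": np.arange(1, design.n_doses + 1),
            "selection_pct": 100.0 * selections / n_sims,
            "mean_n_treated": n_treated / n_sims,
        }
    ).set_index("dose")
    return OCResult(
        by_dose=by_dose,
        early_termination_pct=100.0 * terminated / n_sims,
        mean_sample_size=float(np.mean(sizes)),
        n_sims=n_sims,
    )


def pretabulate_decisions(
    design: DesignParams,
    n_max_at_dose: int,
    coding: CategoryCoding = DEFAULT_CODING,
) -> pd.DataFrame:
    """Exhaustive protocol decision table for counts up to n_max_at_dose.

    Toxicity mode: one row per (n treated, DLT count) with the interval
    decision.  Utility mode: one row per category-count configuration with
    the admissibility verdict (toxic/futile flags) under the design's
    screening rule and a vague prior.
    """
    if n_max_at_dose < 1:
        raise SimulationError("n_max_at_dose must be >= 1")
    if design.mode == "toxicity_boin":
        rows = [
            {
                "n_at_dose": n,
                "dlt_count": d,
                "decision": boin_decision(design.boundaries, d, n),
            }
            for n in range(1, n_max_at_dose + 1)
            for d in range(n + 1)
        ]
        return pd.DataFrame(rows)

    k = coding.k
    total = sum(math.comb(n + k - 1, k - 1) for n in range(1, n_max_at_dose + 1))
    if total > _PRETAB_ROW_CAP:
        raise SimulationError(
            f"{total} count configurations exceed the cap ({_PRETAB_ROW_CAP}); "
            "reduce n_max_at_dose"
        )
    prior = make_prior(k, "vague")
    rows = []
    for n in range(1, n_max_at_dose + 1):
        for combo in itertools.combinations(range(n + k - 1), k - 1):
            bounds = (-1,) + combo + (n + k - 1,)
            counts = np.array([bounds[i + 1] - bounds[i] - 1 for i in range(k)])
            state = update_posterior(prior, OutcomeCounts(1, counts))
            adm = admissible_set([state], design.rule, coding)
            reason = adm.reasons.get(1, "")
            rows.append(
                {
                    "n_at_dose": n,
                    **{f"n_cat{i + 1}": int(c) for i, c in enumerate(counts)},
                    "toxic": reason in ("toxic", "both"),
                    "futile": reason in ("futile", "both"),
                    "admissible": 1 in adm.doses,
                }
            )
    return pd.DataFrame(rows)
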