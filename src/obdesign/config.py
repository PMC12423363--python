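"""Design-configuration schema and validation.

A single YAML/JSON document with sections ``design``, ``utility``,
``strategies`` and (optionally) ``scenario`` describes a trial protocol.
Validation checks every type invariant and the cross-section constraints
(psi length equals K, every ICE type mapped, probability bounds) and returns
fully constructed engine objects with defaults filled in.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .estimand import (
    DEFAULT_PRECEDENCE,
    STRATEGIES,
    StrategyConfig,
    case_study_strategies,
)
from .outcome import DirichletState, make_prior
from .selection import AdmissibilityRule, AssignmentPolicy, boin_boundaries
from .simulate import DesignParams, Scenario
from .utility import DEFAULT_SCORES, UtilitySpec

__all__ = ["ConfigError", "ValidatedConfig", "validate_config", "dump_config"]


class ConfigError(ValueError):
    """Itemized configuration validation failure."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {p}" for p in problems))


class _Boin(BaseModel):
    model_config = ConfigDict(extra="forbid")
    phi: float = Field(gt=0, lt=1)
    phi1: Optional[float] = None
    phi2: Optional[float] = None


class _Design(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_doses: int = Field(ge=1)
    cohort_size: int = Field(default=3, ge=1)
    max_n: int = Field(ge=1)
    per_dose_cap: int = Field(default=12, ge=1)
    start_dose: int = Field(default=1, ge=1)
    mode: str = "utility_boin12"
    policy: str = "deterministic_max_utility"
    accelerated_titration: bool = False
    titration_trigger_dose: int = Field(default=5, ge=1)
    phi_t: float = Field(gt=0, lt=1)
    phi_e: float = Field(gt=0, lt=1)
    delta_t: float = Field(default=0.95, gt=0, lt=1)
    delta_e: float = Field(default=0.95, gt=0, lt=1)
    prior: str = "vague"
    boin: Optional[_Boin] = None
    dlt_window_days: float = Field(default=28.0, gt=0)


class _Utility(BaseModel):
    model_config = ConfigDict(extra="forbid")
    scores: list[float] = Field(default_factory=lambda: list(DEFAULT_SCORES))


class _Strategies(BaseModel):
    model_config = ConfigDict(extra="forbid")
    per_ice_strategy: Optional[dict[str, str]] = None
    precedence: Optional[list[str]] = None
    composite_toxicity_types: Optional[list[str]] = None

    @model_validator(mode="after")
    def _known_strategies(self):
        for t, s in (self.per_ice_strategy or {}).items():
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r} for ICE type {t!r}")
        return self


class _Scenario(BaseModel):
    model_config = ConfigDict(extra="forbid")
    category_probs: list[list[float]]
    ice_probs: dict[str, Union[float, list[float]]] = Field(default_factory=dict)
    ice_time_mean: dict[str, float] = Field(default_factory=dict)
    followup_prob: float = Field(default=0.5, ge=0, le=1)
    assess_window: float = Field(default=56.0, gt=0)
    dlt_window: float = Field(default=28.0, gt=0)


class _Root(BaseModel):
    model_config = ConfigDict(extra="forbid")
    design: _Design
    utility: _Utility = Field(default_factory=_Utility)
    strategies: _Strategies = Field(default_factory=_Strategies)
    scenario: Optional[_Scenario] = None


@dataclass(frozen=True)
class ValidatedConfig:
    """Engine objects built from one validated protocol document."""

    design: DesignParams
    strategies: StrategyConfig
    spec: UtilitySpec
    rule: AdmissibilityRule
    prior: DirichletState
    scenario: Optional[Scenario]
    raw: dict


def validate_config(raw: Union[str, dict]) -> ValidatedConfig:
    """Parse and validate a protocol document (YAML text or mapping).

    Raises :class:`ConfigError` naming every violated invariant.
    """
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw)
        except yaml.YAMLError as exc:
            raise ConfigError([f"unparseable YAML: {exc}"])
    if not isinstance(raw, dict):
        raise ConfigError(["configuration must be a mapping"])

    try:
        root = _Root.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(
            [
                f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
                for err in exc.errors()
            ]
        )

    problems: list[str] = []
    d = root.design
    k = len(root.utility.scores)
    if k != 4:
        problems.append(f"utility.scores must have length 4 (K=4 coding), got {k}")
    if d.start_dose > d.n_doses:
        problems.append("design.start_dose exceeds design.n_doses")
    if d.per_dose_cap > d.max_n:
        problems.append("design.per_dose_cap exceeds design.max_n")
    if d.phi_e >= 1 - 1e-12 or d.phi_t <= 0:
        problems.append("design.phi_t / design.phi_e must be interior probabilities")
    if d.mode == "toxicity_boin" and d.boin is None:
        problems.append("design.mode=toxicity_boin requires a design.boin section")
    if d.prior not in ("vague", "haldane"):
        problems.append("design.prior must be 'vague' or 'haldane'")

    strategies = case_study_strategies()
    s = root.strategies
    if s.per_ice_strategy is not None:
        merged = dict(strategies.per_ice_strategy)
        merged.update(s.per_ice_strategy)
        precedence = tuple(s.precedence) if s.precedence else DEFAULT_PRECEDENCE
        extra = [t for t in merged if t not in precedence]
        precedence = precedence + tuple(sorted(extra))
        ctt = (
            frozenset(s.composite_toxicity_types)
            if s.composite_toxicity_types is not None
            else strategies.composite_toxicity_types
        )
        try:
            strategies = StrategyConfig(merged, precedence, ctt)
        except ValueError as exc:
            problems.append(str(exc))
    elif s.precedence or s.composite_toxicity_types:
        try:
            strategies = StrategyConfig(
                strategies.per_ice_strategy,
                tuple(s.precedence) if s.precedence else DEFAULT_PRECEDENCE,
                frozenset(s.composite_toxicity_types)
                if s.composite_toxicity_types is not None
                else strategies.composite_toxicity_types,
            )
        except ValueError as exc:
            problems.append(str(exc))

    spec = rule = None
    try:
        spec = UtilitySpec(tuple(root.utility.scores))
    except ValueError as exc:
        problems.append(f"utility.scores: {exc}")
    try:
        rule = AdmissibilityRule(d.phi_t, d.phi_e, d.delta_t, d.delta_e)
    except ValueError as exc:
        problems.append(str(exc))

    scenario = None
    if root.scenario is not None:
        sc = root.scenario
        try:
            scenario = Scenario(
                category_probs=np.asarray(sc.category_probs, dtype=float),
                ice_probs={t: np.asarray(p, dtype=float) for t, p in sc.ice_probs.items()},
                ice_time_mean=sc.ice_time_mean,
                followup_prob=sc.followup_prob,
                assess_window=sc.assess_window,
                dlt_window=sc.dlt_window,
            )
        except ValueError as exc:
            problems.append(f"scenario: {exc}")
        else:
            if scenario.n_doses != d.n_doses:
                problems.append(
                    f"scenario has {scenario.n_doses} dose rows but design.n_doses={d.n_doses}"
                )
            if scenario.k != k:
                problems.append(
                    f"scenario category vectors have length {scenario.k}, expected K={k}"
                )
            for t in scenario.ice_probs:
                if t not in strategies.per_ice_strategy:
                    problems.append(f"scenario ICE type {t!r} has no configured strategy")

    boundaries = None
    if d.boin is not None:
        try:
            boundaries = boin_boundaries(d.boin.phi, d.boin.phi1, d.boin.phi2)
        except ValueError as exc:
            problems.append(f"design.boin: {exc}")

    if problems:
        raise ConfigError(problems)

    design = DesignParams(
        n_doses=d.n_doses,
        cohort_size=d.cohort_size,
        max_n=d.max_n,
        rule=rule,
        spec=spec,
        policy=AssignmentPolicy(kind=d.policy),
        mode=d.mode,
        boundaries=boundaries,
        per_dose_cap=d.per_dose_cap,
        start_dose=d.start_dose,
        accelerated_titration=d.accelerated_titration,
        titration_trigger_dose=d.titration_trigger_dose,
        dlt_window_days=d.dlt_window_days,
    )
    prior = make_prior(k if k else 4, d.prior)
    echoed = root.model_dump(exclude_none=True)
    return ValidatedConfig(
        design=design,
        strategies=strategies,
        spec=spec,
        rule=rule,
        prior=prior,
        scenario=scenario,
        raw=echoed,
    )


def dump_config(cfg: ValidatedConfig) -> str:
    """Canonical YAML rendering of a validated config (round-trips)."""
    return yaml.safe_dump(cfg.raw, sort_keys=True)
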