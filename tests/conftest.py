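from __future__ import annotations

import numpy as np
import pytest

import obdesign as od


def category_probs(pe: float, pt: float) -> list[float]:
    """K=4 category probabilities for independent efficacy/toxicity marginals."""
    return [(1 - pe) * pt, (1 - pe) * (1 - pt), pe * pt, pe * (1 - pt)]


@pytest.fixture
def vague_prior() -> od.DirichletState:
    return od.make_prior(4, "vague")


@pytest.fixture
def default_spec() -> od.UtilitySpec:
    return od.UtilitySpec(od.DEFAULT_SCORES)


@pytest.fixture
def rule() -> od.AdmissibilityRule:
    return od.AdmissibilityRule(phi_t=0.35, phi_e=0.25, delta_t=0.95, delta_e=0.95)


@pytest.fixture
def fig2_record() -> od.PatientRecord:
    """Stable disease with toxicity at discontinuation (day 30), complete
    response at a follow-up assessment (day 90)."""
    return od.PatientRecord(
        "p1",
        dose_index=2,
        observations=(od.Observation(30, 0, 1), od.Observation(90, 1, 0)),
        events=(od.ICEvent("discontinuation_toxicity", 30),),
    )
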