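"""Dirichlet–multinomial model for joint efficacy–toxicity outcome categories.

Each patient contributes one of K outcome categories coded by a pair of
binary flags (Ye, Yt): efficacy (e.g. objective response) and toxicity
(e.g. dose-limiting toxicity).  For K = 4 the coding is fixed:

    Y = 1  <->  (Ye, Yt) = (0, 1)   toxicity, no efficacy   (worst)
    Y = 2  <->  (Ye, Yt) = (0, 0)   neither
    Y = 3  <->  (Ye, Yt) = (1, 1)   efficacy with toxicity
    Y = 4  <->  (Ye, Yt) = (1, 0)   efficacy, no toxicity   (best)

Per dose, category counts follow a multinomial law whose probability vector
carries a Dirichlet prior; the posterior is conjugate (Dirichlet with
concentrations a_k + n_jk).  Marginal toxicity/efficacy probabilities are
exact Beta laws obtained by the Dirichlet aggregation property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "OutcomeModelError",
    "ImproperPosteriorError",
    "OutcomeCategory",
    "CategoryCoding",
    "DEFAULT_CODING",
    "OutcomeCounts",
    "DirichletState",
    "BetaMarginal",
    "make_prior",
    "update_posterior",
    "marginal",
    "posterior_mean",
]


class OutcomeModelError(ValueError):
    """Invalid input to the outcome model."""


class ImproperPosteriorError(OutcomeModelError):
    """A Dirichlet component has zero concentration and cannot be evaluated."""


@dataclass(frozen=True)
class OutcomeCategory:
    """One multinomial outcome category and its (Ye, Yt) flag pair."""

    index: int
    efficacy_flag: int
    toxicity_flag: int

    def __post_init__(self) -> None:
        if self.index < 1:
            raise OutcomeModelError(f"category index must be >= 1, got {self.index}")
        for name in ("efficacy_flag", "toxicity_flag"):
            if getattr(self, name) not in (0, 1):
                raise OutcomeModelError(f"{name} must be binary")


#: The fixed four-category coding (Y = 1..4).
CATEGORIES_K4 = (
    OutcomeCategory(1, 0, 1),
    OutcomeCategory(2, 0, 0),
    OutcomeCategory(3, 1, 1),
    OutcomeCategory(4, 1, 0),
)


@dataclass(frozen=True)
class CategoryCoding:
    """Bijective map between category index and (Ye, Yt) flags.

    For K = 4 use :data:`DEFAULT_CODING`.  For generalized outcome spaces
    (K > 4, e.g. graded toxicity) the caller must supply the full list of
    categories; the map index <-> flags need not be a bijection then, but
    indices must still be 1..K with no gaps.
    """

    categories: tuple[OutcomeCategory, ...]

    def __post_init__(self) -> None:
        idx = [c.index for c in self.categories]
        if sorted(idx) != list(range(1, len(idx) + 1)):
            raise OutcomeModelError("category indices must be exactly 1..K")
        if self.k == 4:
            flags = {(c.efficacy_flag, c.toxicity_flag) for c in self.categories}
            if len(flags) != 4:
                raise OutcomeModelError("K=4 coding must be a bijection onto flag pairs")

    @property
    def k(self) -> int:
        return len(self.categories)

    def category(self, index: int) -> OutcomeCategory:
        for c in self.categories:
            if c.index == index:
                return c
        raise OutcomeModelError(f"no category with index {index}")

    def index_for(self, efficacy_flag: int, toxicity_flag: int) -> int:
        """Category index for a flag pair (first match in index order)."""
        for c in sorted(self.categories, key=lambda c: c.index):
            if (c.efficacy_flag, c.toxicity_flag) == (efficacy_flag, toxicity_flag):
                return c.index
        raise OutcomeModelError(f"no category for flags ({efficacy_flag}, {toxicity_flag})")

    def flag_mask(self, kind: str) -> np.ndarray:
        """Boolean mask (in index order 1..K) of categories with the flag set."""
        if kind not in ("toxicity", "efficacy"):
            raise OutcomeModelError(f"kind must be 'toxicity' or 'efficacy', got {kind!r}")
        attr = "toxicity_flag" if kind == "toxicity" else "efficacy_flag"
        ordered = sorted(self.categories, key=lambda c: c.index)
        return np.array([bool(getattr(c, attr)) for c in ordered])


DEFAULT_CODING = CategoryCoding(CATEGORIES_K4)


@dataclass(frozen=True)
class OutcomeCounts:
    """Per-dose category counts n_jk over the K outcome categories."""

    dose_index: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 1:
            raise OutcomeModelError("counts must be a 1-d vector")
        if (arr < 0).any():
            raise OutcomeModelError("counts must be nonnegative")
        object.__setattr__(self, "counts", arr)
        if self.dose_index < 1:
            raise OutcomeModelError("dose_index must be >= 1")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        return len(self.counts)

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        if other.dose_index != self.dose_index or other.k != self.k:
            raise OutcomeModelError("can only add counts at the same dose with matching K")
        return OutcomeCounts(self.dose_index, self.counts + other.counts)


_SCHEMES = ("vague", "haldane", "custom")


@dataclass(frozen=True)
class DirichletState:
    """Dirichlet concentrations for one dose (prior or posterior)."""

    concentrations: np.ndarray
    scheme_label: str = "custom"

    def __post_init__(self) -> None:
        arr = np.asarray(self.concentrations, dtype=np.float64)
        if arr.ndim != 1 or len(arr) < 2:
            raise OutcomeModelError("concentrations must be a vector of length >= 2")
        if (arr < 0).any():
            raise OutcomeModelError("concentrations must be nonnegative")
        if self.scheme_label not in _SCHEMES:
            raise OutcomeModelError(f"scheme_label must be one of {_SCHEMES}")
        if self.scheme_label == "vague" and not (arr > 0).all():
            raise OutcomeModelError("vague scheme requires strictly positive concentrations")
        object.__setattr__(self, "concentrations", arr)

    @property
    def k(self) -> int:
        return len(self.concentrations)

    @property
    def total(self) -> float:
        return float(self.concentrations.sum())

    def to_json(self) -> str:
        return json.dumps(
            {"concentrations": self.concentrations.tolist(), "scheme": self.scheme_label}
        )

    @classmethod
    def from_json(cls, text: str) -> "DirichletState":
        d = json.loads(text)
        return cls(np.asarray(d["concentrations"], dtype=float), d["scheme"])


@dataclass(frozen=True)
class BetaMarginal:
    """Exact Beta marginal law of the toxicity or efficacy probability."""

    alpha: float
    beta: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("toxicity", "efficacy"):
            raise OutcomeModelError("kind must be 'toxicity' or 'efficacy'")
        if self.alpha <= 0 or self.beta <= 0:
            raise ImproperPosteriorError(
                f"improper Beta marginal (alpha={self.alpha}, beta={self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def make_prior(
    k: int, scheme: str = "vague", custom: Optional[Sequence[float]] = None
) -> DirichletState:
    """Construct a Dirichlet prior over the K outcome categories.

    ``vague`` sets every concentration to 1/K (prior sample size of 1);
    ``haldane`` sets all to 0 (an improper limit used for prior-sensitivity
    analysis); ``custom`` takes the supplied vector verbatim.
    """
    if k < 2:
        raise OutcomeModelError("K must be >= 2")
    if scheme == "vague":
        return DirichletState(np.full(k, 1.0 / k), "vague")
    if scheme == "haldane":
        return DirichletState(np.zeros(k), "haldane")
    if scheme == "custom":
        if custom is None:
            raise OutcomeModelError("custom scheme requires a concentration vector")
        arr = np.asarray(custom, dtype=float)
        if len(arr) != k:
            raise OutcomeModelError(f"custom vector has length {len(arr)}, expected {k}")
        if (arr < 0).any():
            raise OutcomeModelError("custom concentrations must be nonnegative")
        return DirichletState(arr, "custom")
    raise OutcomeModelError(f"unknown prior scheme {scheme!r}")


def update_posterior(prior: DirichletState, data: OutcomeCounts) -> DirichletState:
    """Conjugate update: posterior concentrations are a_k + n_jk.

    With a Haldane (all-zero) prior, a category with zero observed count has
    an improper posterior component; this raises instead of silently
    regularizing, since the Haldane prior exists here for sensitivity
    analysis and hidden smoothing would defeat its purpose.
    """
    if prior.k != data.k:
        raise OutcomeModelError(f"prior K={prior.k} does not match counts K={data.k}")
    improper = (prior.concentrations == 0) & (data.counts == 0)
    if improper.any():
        bad = np.flatnonzero(improper) + 1
        raise ImproperPosteriorError(
            f"zero prior concentration with zero count in categories {bad.tolist()}; "
            "posterior component is improper"
        )
    return DirichletState(prior.concentrations + data.counts, prior.scheme_label)


def marginal(
    state: DirichletState, kind: str, coding: CategoryCoding = DEFAULT_CODING
) -> BetaMarginal:
    """Exact Beta marginal of the toxicity (or efficacy) probability.

    By the Dirichlet aggregation property, the sum of category probabilities
    over the flagged partition is Beta(sum of flagged concentrations,
    sum of unflagged concentrations).
    """
    if coding.k != state.k:
        raise OutcomeModelError(f"coding K={coding.k} does not match state K={state.k}")
    mask = coding.flag_mask(kind)
    alpha = float(state.concentrations[mask].sum())
    beta = float(state.concentrations[~mask].sum())
    return BetaMarginal(alpha=alpha, beta=beta, kind=kind)


def posterior_mean(state: DirichletState) -> np.ndarray:
    """Dirichlet mean vector a_k / sum(a); entries sum to 1."""
    total = state.total
    if total <= 0:
        raise ImproperPosteriorError("total concentration must be > 0")
    return state.concentrations / total
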