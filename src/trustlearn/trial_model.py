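"""Domain types for the modified repeated Trust Game.

The task: on each trial a participant (trustor) holds a 4-Euro endowment and
either invests it all with a partner or keeps 2 Euro (the partner then gets
2 Euro and the trial ends). An invested endowment is doubled; the partner
either reciprocates half of it (the participant ends with 4 Euro) or defects
(0 Euro). Partners belong to five categories crossing ethnicity (White/Arab)
with behavioural fairness (fair = 75% reciprocation, unfair = 25%), plus a
faceless lottery at 50%. Crucially the partner's decision is revealed on
*every* trial — on keep trials as counterfactual feedback — so learning is
possible regardless of the participant's choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping


class CategoryId(str, Enum):
    """The five partner conditions."""

    fair_white = "fair_white"
    fair_arab = "fair_arab"
    unfair_white = "unfair_white"
    unfair_arab = "unfair_arab"
    lottery = "lottery"


class Ethnicity(str, Enum):
    white = "white"
    arab = "arab"
    none = "none"


class Fairness(str, Enum):
    fair = "fair"
    unfair = "unfair"
    lottery = "lottery"


class Choice(str, Enum):
    invest = "invest"
    keep = "keep"


class OutcomeClass(str, Enum):
    """Trial outcome taxonomy.

    ``true_gain``/``true_loss`` arise on invest trials (the money was really
    at stake); ``relative_gain``/``relative_loss`` arise on keep trials where
    the counterfactual reveal shows what would have happened. Keeping while
    the partner would have defected is a *relative gain* (the right call);
    keeping while they would have reciprocated is a *relative loss*.
    """

    true_gain = "true_gain"
    true_loss = "true_loss"
    relative_gain = "relative_gain"
    relative_loss = "relative_loss"


# Reciprocation rates are a fixed property of the design.
_RATES = {Fairness.fair: 0.75, Fairness.unfair: 0.25, Fairness.lottery: 0.50}


@dataclass(frozen=True)
class PartnerCategory:
    id: CategoryId
    ethnicity: Ethnicity
    fairness: Fairness

    @property
    def reciprocation_rate(self) -> float:
        return _RATES[self.fairness]


CATEGORIES: Mapping[CategoryId, PartnerCategory] = {
    CategoryId.fair_white: PartnerCategory(CategoryId.fair_white, Ethnicity.white, Fairness.fair),
    CategoryId.fair_arab: PartnerCategory(CategoryId.fair_arab, Ethnicity.arab, Fairness.fair),
    CategoryId.unfair_white: PartnerCategory(CategoryId.unfair_white, Ethnicity.white, Fairness.unfair),
    CategoryId.unfair_arab: PartnerCategory(CategoryId.unfair_arab, Ethnicity.arab, Fairness.unfair),
    CategoryId.lottery: PartnerCategory(CategoryId.lottery, Ethnicity.none, Fairness.lottery),
}

#: Canonical category ordering used for compiled arrays and CSV output.
CATEGORY_ORDER: tuple[CategoryId, ...] = (
    CategoryId.fair_white,
    CategoryId.fair_arab,
    CategoryId.unfair_white,
    CategoryId.unfair_arab,
    CategoryId.lottery,
)

#: The four categories with faces (and hence trustworthiness ratings).
FACE_CATEGORIES: tuple[CategoryId, ...] = CATEGORY_ORDER[:4]


def classify_outcome(choice: Choice, gamma: int) -> OutcomeClass:
    """Classify a trial by (choice, partner response).

    ``gamma`` is 1 when the partner reciprocated (or would have) and 0 when
    they defected (or would have).
    """
    choice = Choice(choice)
    if gamma not in (0, 1):
        raise ValueError(f"partner response must be 0 or 1, got {gamma!r}")
    if choice is Choice.invest:
        return OutcomeClass.true_gain if gamma else OutcomeClass.true_loss
    return OutcomeClass.relative_loss if gamma else OutcomeClass.relative_gain


def trial_payoff(choice: Choice, gamma: int) -> int:
    """Participant payoff in Euro: 4 (invest, reciprocate), 0 (invest, defect), 2 (keep)."""
    choice = Choice(choice)
    if gamma not in (0, 1):
        raise ValueError(f"partner response must be 0 or 1, got {gamma!r}")
    if choice is Choice.invest:
        return 4 if gamma else 0
    return 2


def normalize_rating(mean_rating: float, scheme: str = "affine") -> float:
    """Map a 1-7 Likert (mean) rating onto a [0, 1] reciprocation probability.

    ``scheme="affine"`` maps endpoints to endpoints, (r - 1) / 6 (default);
    ``scheme="ratio"`` divides by the scale maximum, r / 7.
    """
    if not 1.0 <= mean_rating <= 7.0:
        raise ValueError(f"rating must lie in [1, 7], got {mean_rating!r}")
    if scheme == "affine":
        return (mean_rating - 1.0) / 6.0
    if scheme == "ratio":
        return mean_rating / 7.0
    raise ValueError(f"unknown normalization scheme {scheme!r}")


@dataclass(frozen=True)
class TrialRecord:
    """One Trust Game trial in long format.

    ``partner_response`` is present on every trial; on keep trials it is the
    counterfactual reveal. ``payoff`` must be consistent with
    (choice, partner_response).
    """

    participant_id: str
    block: int
    trial_index: int
    category: CategoryId
    choice: Choice
    partner_response: int
    payoff: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", CategoryId(self.category))
        object.__setattr__(self, "choice", Choice(self.choice))
        if self.block < 1:
            raise ValueError(f"block must be >= 1, got {self.block}")
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        if self.partner_response not in (0, 1):
            raise ValueError(f"partner_response must be 0/1, got {self.partner_response}")
        expected = trial_payoff(self.choice, self.partner_response)
        if self.payoff != expected:
            raise ValueError(
                f"payoff {self.payoff} inconsistent with ({self.choice.value}, "
                f"gamma={self.partner_response}); expected {expected}"
            )

    @property
    def outcome(self) -> OutcomeClass:
        return classify_outcome(self.choice, self.partner_response)


@dataclass
class RatingSet:
    """Per-participant face-trustworthiness ratings at one timepoint.

    ``ratings`` maps face id -> integer Likert rating (1-7); ``face_category``
    maps face id -> the category that face belongs to. The lottery condition
    has no faces and never appears here.
    """

    participant_id: str
    timepoint: str  # "pre" | "post"
    ratings: dict[str, int] = field(default_factory=dict)
    face_category: dict[str, CategoryId] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in ("pre", "post"):
            raise ValueError(f"timepoint must be 'pre' or 'post', got {self.timepoint!r}")
        for face, r in self.ratings.items():
            if r not in range(1, 8):
                raise ValueError(f"rating for face {face!r} must be an integer in 1..7, got {r!r}")
            if face not in self.face_category:
                raise ValueError(f"face {face!r} has a rating but no category")
            if CategoryId(self.face_category[face]) is CategoryId.lottery:
                raise ValueError("lottery has no faces to rate")

    @property
    def category_means(self) -> dict[CategoryId, float]:
        sums: dict[CategoryId, list[int]] = {}
        for face, r in self.ratings.items():
            sums.setdefault(CategoryId(self.face_category[face]), []).append(r)
        return {cat: sum(v) / len(v) for cat, v in sums.items()}

    def category_mean(self, category: CategoryId) -> float:
        means = self.category_means
        category = CategoryId(category)
        if category not in means:
            raise ValueError(f"no ratings for category {category.value!r}")
        return means[category]
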