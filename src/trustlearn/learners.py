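"""Reinforcement-learning model family for trust learning.

All models share the same belief architecture: for each partner category *i*
the learner tracks an expected reciprocation probability ``ep_i`` (initialised
from the participant's normalised pre-game trustworthiness ratings), converts
it to an expected value of investing ``ev_i = 4 * ep_i`` Euro, and chooses via
a softmax between ``ev_i`` and the sure 2 Euro of keeping:

    P(invest) = exp(beta * ev) / (exp(beta * ev) + exp(beta * 2))

After every trial (the partner's response gamma in {0, 1} is revealed even on
keep trials) the belief is nudged by a Rescorla-Wagner update,

    ep_i <- ep_i + alpha * (gamma - ep_i),

where the learning rate ``alpha`` applied depends on the model: the members of
the family differ only in how they partition (trial outcome class x partner
category) into learning-rate slots, or — for the no-learning baselines — in
pinning ``ep`` to a fixed value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Optional, Sequence

from .trial_model import (
    CATEGORIES,
    CATEGORY_ORDER,
    FACE_CATEGORIES,
    CategoryId,
    Choice,
    Ethnicity,
    Fairness,
    OutcomeClass,
    RatingSet,
    TrialRecord,
    classify_outcome,
    normalize_rating,
)

# Parameter bounds: alpha is a rate in (0, 1); beta is unbounded above in
# principle, capped at a value comfortably beyond any fitted estimate.
ALPHA_BOUNDS = (1e-6, 1.0 - 1e-6)
BETA_MAX = 1e5
BETA_BOUNDS = (1e-6, BETA_MAX)


@dataclass(frozen=True)
class Params:
    """Free parameters of one model: per-slot learning rates and softmax beta."""

    alphas: tuple[float, ...]
    beta: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        for a in self.alphas:
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"learning rate out of [0, 1]: {a}")
        if not self.beta >= 0.0:
            raise ValueError(f"beta must be >= 0, got {self.beta}")


class ModelSpec(NamedTuple):
    """One member of the model family.

    ``rate_slot(outcome, category)`` returns the index into ``Params.alphas``
    used on that trial, or None when the model assigns no rate there (only
    legal for no-learning models or excluded conditions).
    """

    name: str
    slot_names: tuple[str, ...]
    rate_slot: Callable[[OutcomeClass, CategoryId], Optional[int]]
    fixed_ep_rule: Optional[str] = None  # None | "optimal" | "bias"

    @property
    def n_alpha_slots(self) -> int:
        return len(self.slot_names)

    @property
    def n_params(self) -> int:
        # beta is always free; no-learning models fit beta only.
        return self.n_alpha_slots + 1

    @property
    def learns(self) -> bool:
        return self.fixed_ep_rule is None


def _by_outcome(mapping: dict[OutcomeClass, int]) -> Callable:
    return lambda outcome, category: mapping[outcome]


def _reputation_slot(outcome: OutcomeClass, category: CategoryId) -> int:
    # keyed by gamma only: reciprocate (true_gain / relative_loss) vs defect
    return 0 if outcome in (OutcomeClass.true_gain, OutcomeClass.relative_loss) else 1


def _ethnicity_slot(outcome: OutcomeClass, category: CategoryId) -> Optional[int]:
    eth = CATEGORIES[category].ethnicity
    if eth is Ethnicity.arab:
        return 0
    if eth is Ethnicity.white:
        return 1
    return None  # lottery: no ethnicity — excluded by default (see fitting)


def _fairness_slot(outcome: OutcomeClass, category: CategoryId) -> Optional[int]:
    fair = CATEGORIES[category].fairness
    if fair is Fairness.fair:
        return 0
    if fair is Fairness.unfair:
        return 1
    return None


def _ethnicity_slot3(outcome: OutcomeClass, category: CategoryId) -> int:
    s = _ethnicity_slot(outcome, category)
    return 2 if s is None else s


def _fairness_slot3(outcome: OutcomeClass, category: CategoryId) -> int:
    s = _fairness_slot(outcome, category)
    return 2 if s is None else s


def _no_slot(outcome: OutcomeClass, category: CategoryId) -> Optional[int]:
    return None


#: Model registry, in canonical (tie-breaking) order.
MODELS: dict[str, ModelSpec] = {
    "L2G2": ModelSpec(
        "L2G2",
        ("G", "L", "G-rel", "L-rel"),
        _by_outcome(
            {
                OutcomeClass.true_gain: 0,
                OutcomeClass.true_loss: 1,
                OutcomeClass.relative_gain: 2,
                OutcomeClass.relative_loss: 3,
            }
        ),
    ),
    "LGK": ModelSpec(
        "LGK",
        ("G", "L", "K"),
        _by_outcome(
            {
                OutcomeClass.true_gain: 0,
                OutcomeClass.true_loss: 1,
                OutcomeClass.relative_gain: 2,
                OutcomeClass.relative_loss: 2,
            }
        ),
    ),
    "LG": ModelSpec(
        "LG",
        ("G", "L"),
        _by_outcome(
            {
                OutcomeClass.true_gain: 0,
                OutcomeClass.relative_gain: 0,
                OutcomeClass.true_loss: 1,
                OutcomeClass.relative_loss: 1,
            }
        ),
    ),
    "Reputation": ModelSpec("Reputation", ("R", "D"), _reputation_slot),
    "SimpleLearn": ModelSpec("SimpleLearn", ("A",), lambda o, c: 0),
    "NoLearnOptimal": ModelSpec("NoLearnOptimal", (), _no_slot, fixed_ep_rule="optimal"),
    "NoLearnBias": ModelSpec("NoLearnBias", (), _no_slot, fixed_ep_rule="bias"),
    "SimpleLearnEthnicity": ModelSpec("SimpleLearnEthnicity", ("Arab", "White"), _ethnicity_slot),
    "SimpleLearnFairness": ModelSpec("SimpleLearnFairness", ("Fair", "Unfair"), _fairness_slot),
    # variants that give the lottery its own rate instead of excluding it
    "SimpleLearnEthnicity3": ModelSpec(
        "SimpleLearnEthnicity3", ("Arab", "White", "Lottery"), _ethnicity_slot3
    ),
    "SimpleLearnFairness3": ModelSpec(
        "SimpleLearnFairness3", ("Fair", "Unfair", "Lottery"), _fairness_slot3
    ),
}

#: The seven models compared in the main analysis, registry order.
MAIN_MODELS: tuple[str, ...] = (
    "L2G2",
    "LGK",
    "LG",
    "Reputation",
    "SimpleLearn",
    "NoLearnOptimal",
    "NoLearnBias",
)


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; known: {', '.join(MODELS)}") from None


@dataclass
class LearnerState:
    """Belief state: expected reciprocation probability per category."""

    ep: dict[CategoryId, float]

    @property
    def ev(self) -> dict[CategoryId, float]:
        return {cat: 4.0 * p for cat, p in self.ep.items()}

    def copy(self) -> "LearnerState":
        return LearnerState(dict(self.ep))


def init_state(
    pre_ratings: RatingSet, spec: ModelSpec, normalization: str = "affine"
) -> LearnerState:
    """Initial beliefs.

    Learning models (and the biased non-learner) start from the participant's
    normalised mean pre-game rating per face category; the lottery starts at
    its advertised 0.5. The optimal non-learner pins ep at the true
    reciprocation rates instead.
    """
    if spec.fixed_ep_rule == "optimal":
        ep = {cat: CATEGORIES[cat].reciprocation_rate for cat in CATEGORY_ORDER}
        return LearnerState(ep)
    means = pre_ratings.category_means
    missing = [c.value for c in FACE_CATEGORIES if c not in means]
    if missing:
        raise ValueError(f"pre-ratings missing category means for: {missing}")
    ep = {cat: normalize_rating(means[cat], normalization) for cat in FACE_CATEGORIES}
    ep[CategoryId.lottery] = 0.5
    return LearnerState(ep)


def prediction_error(ep: float, gamma: int) -> float:
    """Rescorla-Wagner prediction error gamma - ep, on the probability scale."""
    return gamma - ep


def update_ep(
    state: LearnerState, trial: TrialRecord, params: Params, spec: ModelSpec
) -> LearnerState:
    """Apply one trial's belief update; returns a new state.

    Only the trial's category changes. No-learning models return the state
    unchanged.
    """
    if not spec.learns:
        return state.copy()
    outcome = classify_outcome(trial.choice, trial.partner_response)
    slot = spec.rate_slot(outcome, trial.category)
    if slot is None:
        raise ValueError(
            f"model {spec.name} assigns no learning rate to "
            f"({outcome.value}, {trial.category.value})"
        )
    new = state.copy()
    cat = trial.category
    new.ep[cat] = state.ep[cat] + params.alphas[slot] * prediction_error(
        state.ep[cat], trial.partner_response
    )
    return new


def invest_probability(ev: float, beta: float) -> float:
    """Softmax probability of investing given expected value ``ev`` (Euro).

    Equals 1 / (1 + exp(-beta * (ev - 2))); numerically stable for any beta.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    x = beta * (ev - 2.0)
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x)) if x < 700 else 1.0
    e = math.exp(x) if x > -700 else 0.0
    return e / (1.0 + e)


class TrajectoryStep(NamedTuple):
    """Per-trial snapshot: belief *before* the trial's update and the choice probability."""

    category: CategoryId
    ep: float
    ev: float
    p_invest: float


def run_learner(
    trials: Sequence[TrialRecord],
    pre_ratings: RatingSet,
    params: Params,
    spec: ModelSpec,
    normalization: str = "affine",
) -> list[TrajectoryStep]:
    """Run a model forward over one participant's trial sequence.

    The probability reported for trial *t* uses the belief state before *t*'s
    update (choice precedes learning on each trial).
    """
    if len(params.alphas) != spec.n_alpha_slots:
        raise ValueError(
            f"model {spec.name} needs {spec.n_alpha_slots} learning rate(s), "
            f"got {len(params.alphas)}"
        )
    pids = {t.participant_id for t in trials}
    if len(pids) > 1:
        raise ValueError(f"trials span multiple participants: {sorted(pids)}")
    keys = [(t.block, t.trial_index) for t in trials]
    if keys != sorted(keys):
        raise ValueError("trials must be sorted by (block, trial_index)")
    state = init_state(pre_ratings, spec, normalization)
    out: list[TrajectoryStep] = []
    for trial in trials:
        ep = state.ep[trial.category]
        ev = 4.0 * ep
        out.append(TrajectoryStep(trial.category, ep, ev, invest_probability(ev, params.beta)))
        state = update_ep(state, trial, params, spec)
    return out


# ---------------------------------------------------------------------------
# Compiled fast path used by the fitter (identical arithmetic to run_learner,
# with trials pre-resolved to flat index arrays).
# ---------------------------------------------------------------------------

_CAT_INDEX = {cat: i for i, cat in enumerate(CATEGORY_ORDER)}


class CompiledTrials(NamedTuple):
    cat_idx: tuple[int, ...]
    slot_idx: tuple[int, ...]  # -1 where no update applies
    gamma: tuple[int, ...]
    invested: tuple[int, ...]
    scored: tuple[int, ...]  # 1 if the trial contributes to the likelihood


def compile_trials(
    trials: Sequence[TrialRecord],
    spec: ModelSpec,
    scored: Optional[Sequence[bool]] = None,
) -> CompiledTrials:
    cat_idx, slot_idx, gamma, invested = [], [], [], []
    for t in trials:
        cat_idx.append(_CAT_INDEX[t.category])
        gamma.append(t.partner_response)
        invested.append(1 if t.choice is Choice.invest else 0)
        if spec.learns:
            slot = spec.rate_slot(classify_outcome(t.choice, t.partner_response), t.category)
            if slot is None:
                raise ValueError(
                    f"model {spec.name} assigns no learning rate to trial in "
                    f"category {t.category.value}; exclude those trials before fitting"
                )
            slot_idx.append(slot)
        else:
            slot_idx.append(-1)
    sc = tuple(1 if s else 0 for s in scored) if scored is not None else (1,) * len(trials)
    if len(sc) != len(trials):
        raise ValueError("scored mask length mismatch")
    return CompiledTrials(tuple(cat_idx), tuple(slot_idx), tuple(gamma), tuple(invested), sc)


def initial_ep_vector(
    pre_ratings: RatingSet, spec: ModelSpec, normalization: str = "affine"
) -> tuple[float, ...]:
    state = init_state(pre_ratings, spec, normalization)
    return tuple(state.ep[cat] for cat in CATEGORY_ORDER)


def nll_compiled(
    alphas: Sequence[float],
    beta: float,
    ep0: Sequence[float],
    ct: CompiledTrials,
    floor: float = 1e-12,
) -> float:
    """Negative log-likelihood over compiled trials (tight scalar loop)."""
    ep = list(ep0)
    exp = math.exp
    log = math.log
    total = 0.0
    for c, s, g, inv, sc in zip(ct.cat_idx, ct.slot_idx, ct.gamma, ct.invested, ct.scored):
        if sc:
            x = beta * (4.0 * ep[c] - 2.0)
            if x >= 0:
                p = 1.0 / (1.0 + exp(-x)) if x < 700 else 1.0
            else:
                p = exp(x) / (1.0 + exp(x)) if x > -700 else 0.0
            pc = p if inv else 1.0 - p
            if pc < floor:
                pc = floor
            total -= log(pc)
        if s >= 0:
            ep[c] += alphas[s] * (g - ep[c])
    return total
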