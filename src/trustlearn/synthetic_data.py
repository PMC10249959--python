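"""Synthetic cohorts with known ground truth.

Emulates the study design end to end: 73 participants, 3 blocks of 60 trials
(12 trials for each of the 5 partner conditions, pseudorandomised within
block), exact per-block reciprocation counts (9/12 fair, 3/12 unfair, 6/12
lottery), counterfactual reveal on every trial, 1-7 Likert pre-ratings with a
configurable pro-White (ingroup) bias, and choices generated by a named
learning model with known parameters. Everything is deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .learners import ModelSpec, Params, get_model, init_state, invest_probability
from .trial_model import (
    CATEGORIES,
    CATEGORY_ORDER,
    FACE_CATEGORIES,
    CategoryId,
    Choice,
    Ethnicity,
    RatingSet,
    TrialRecord,
    classify_outcome,
    trial_payoff,
)

#: ground-truth defaults for cohort generation: the population-level
#: single-rate learner estimates (alpha, beta) and the observed baseline
#: White-minus-Arab rating gap on a 1-7 scale.
DEFAULT_TRUE_ALPHA = 0.16
DEFAULT_TRUE_BETA = 0.62
DEFAULT_RATING_BIAS = 0.43
DEFAULT_RATING_CENTER = 4.375
DEFAULT_RATING_SD = 1.0
FACES_PER_CATEGORY = 3  # 6 White + 6 Arab faces, 3 per fairness level


@dataclass(frozen=True)
class ScheduleConfig:
    n_blocks: int = 3
    trials_per_condition: int = 12
    mode: str = "exact_count"  # or "bernoulli"
    max_run_length: int = 3

    def __post_init__(self) -> None:
        if self.mode not in ("exact_count", "bernoulli"):
            raise ValueError(f"unknown reciprocation mode {self.mode!r}")
        if self.mode == "exact_count":
            for cat in CATEGORY_ORDER:
                c = CATEGORIES[cat].reciprocation_rate * self.trials_per_condition
                if abs(c - round(c)) > 1e-9:
                    raise ValueError(
                        f"exact_count infeasible: rate x {self.trials_per_condition} "
                        f"not integral for {cat.value}"
                    )
        if self.max_run_length < 1:
            raise ValueError("max_run_length must be >= 1")

    @property
    def block_length(self) -> int:
        return self.trials_per_condition * len(CATEGORY_ORDER)


def _order_block(rng: np.random.Generator, config: ScheduleConfig) -> list[CategoryId]:
    """Pseudorandom condition order for one block: exact counts per condition,
    no run of one condition longer than max_run_length."""
    cats = list(CATEGORY_ORDER)
    L = config.max_run_length

    def run_ok(seq: list[CategoryId]) -> bool:
        run = 1
        for a, b in zip(seq, seq[1:]):
            run = run + 1 if a is b else 1
            if run > L:
                return False
        return True

    base = [c for c in cats for _ in range(config.trials_per_condition)]
    for _ in range(200):
        seq = list(base)
        rng.shuffle(seq)  # type: ignore[arg-type]
        if run_ok(seq):
            return seq
    # constructive fallback: greedily place the condition with the most trials
    # remaining among those allowed (random tie-break); handles tight
    # constraints such as max_run_length=1.
    remaining = {c: config.trials_per_condition for c in cats}
    seq = []
    while sum(remaining.values()) > 0:
        tail_run = 1
        allowed = []
        if seq:
            last = seq[-1]
            i = len(seq) - 1
            while i > 0 and seq[i - 1] is last:
                tail_run += 1
                i -= 1
        for c in cats:
            if remaining[c] == 0:
                continue
            if seq and c is seq[-1] and tail_run >= L:
                continue
            allowed.append(c)
        if not allowed:
            raise ValueError("schedule constraints infeasible")
        top = max(remaining[c] for c in allowed)
        pool = [c for c in allowed if remaining[c] == top]
        pick = pool[int(rng.integers(len(pool)))]
        seq.append(pick)
        remaining[pick] -= 1
    return seq


def generate_schedule(
    config: ScheduleConfig, rng: np.random.Generator
) -> list[list[tuple[CategoryId, int]]]:
    """Generate the per-block (category, gamma) sequence.

    In exact_count mode each condition reciprocates on exactly
    rate * trials_per_condition trials per block; in bernoulli mode each
    trial's gamma is an independent draw at the condition's rate.
    """
    blocks: list[list[tuple[CategoryId, int]]] = []
    for _ in range(config.n_blocks):
        order = _order_block(rng, config)
        gammas: dict[CategoryId, list[int]] = {}
        for cat in CATEGORY_ORDER:
            n = config.trials_per_condition
            rate = CATEGORIES[cat].reciprocation_rate
            if config.mode == "exact_count":
                g = [1] * round(rate * n) + [0] * (n - round(rate * n))
                rng.shuffle(g)
            else:
                g = list((rng.random(n) < rate).astype(int))
            gammas[cat] = g
        block = [(cat, int(gammas[cat].pop(0))) for cat in order]
        blocks.append(block)
    return blocks


def generate_pre_ratings(
    participant_id: str,
    rng: np.random.Generator,
    bias: float = DEFAULT_RATING_BIAS,
    noise_sd: float = DEFAULT_RATING_SD,
    center: float = DEFAULT_RATING_CENTER,
    n_faces: int = FACES_PER_CATEGORY,
) -> RatingSet:
    """Pre-game Likert ratings with an ingroup bias.

    White faces are centred at ``center + bias/2`` and Arab faces at
    ``center - bias/2``; face-level Gaussian noise is added, then ratings are
    rounded and clipped to 1..7. With many participants the empirical
    White - Arab mean difference approaches ``bias``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ratings: dict[str, int] = {}
    face_category: dict[str, CategoryId] = {}
    for cat in FACE_CATEGORIES:
        shift = bias / 2.0 if CATEGORIES[cat].ethnicity is Ethnicity.white else -bias / 2.0
        for j in range(n_faces):
            face = f"{cat.value}_f{j + 1}"
            r = center + shift + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            ratings[face] = int(min(7, max(1, round(r))))
            face_category[face] = cat
    return RatingSet(participant_id, "pre", ratings, face_category)


def simulate_agent(
    spec: ModelSpec,
    params: Params,
    schedule: Sequence[Sequence[tuple[CategoryId, int]]],
    pre_ratings: RatingSet,
    rng: np.random.Generator,
    normalization: str = "affine",
    participant_id: Optional[str] = None,
) -> list[TrialRecord]:
    """Simulate one agent's choices over a schedule.

    Choices are Bernoulli draws from the softmax invest probability given the
    evolving belief state; gamma comes from the schedule regardless of the
    choice (counterfactual reveal), and payoffs are filled in. Conditions the
    model assigns no learning rate to simply leave the belief untouched.
    """
    if len(params.alphas) != spec.n_alpha_slots:
        raise ValueError(f"model {spec.name} needs {spec.n_alpha_slots} learning rate(s)")
    pid = participant_id or pre_ratings.participant_id
    state = init_state(pre_ratings, spec, normalization)
    ep = dict(state.ep)
    records: list[TrialRecord] = []
    for b, block in enumerate(schedule, start=1):
        for t, (cat, gamma) in enumerate(block, start=1):
            p = invest_probability(4.0 * ep[cat], params.beta)
            choice = Choice.invest if rng.random() < p else Choice.keep
            records.append(
                TrialRecord(pid, b, t, cat, choice, gamma, trial_payoff(choice, gamma))
            )
            if spec.learns:
                slot = spec.rate_slot(classify_outcome(choice, gamma), cat)
                if slot is not None:
                    ep[cat] += params.alphas[slot] * (gamma - ep[cat])
    return records


def generate_post_ratings(
    participant_id: str,
    final_ep: dict[CategoryId, float],
    rng: np.random.Generator,
    noise_sd: float = 0.5,
    n_faces: int = FACES_PER_CATEGORY,
) -> RatingSet:
    """Post-game ratings read off the agent's final beliefs.

    Each face's rating is the Likert image of the category's final ep
    (1 + 6*ep) plus Gaussian noise, rounded and clipped — i.e., after the game
    the agent reports what it learned, so fairness dominates ethnicity.
    """
    ratings: dict[str, int] = {}
    face_category: dict[str, CategoryId] = {}
    for cat in FACE_CATEGORIES:
        target = 1.0 + 6.0 * final_ep[cat]
        for j in range(n_faces):
            face = f"{cat.value}_f{j + 1}"
            r = target + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            ratings[face] = int(min(7, max(1, round(r))))
            face_category[face] = cat
    return RatingSet(participant_id, "post", ratings, face_category)


@dataclass
class AgentRecord:
    participant_id: str
    model: str
    params: Params
    pre_ratings: RatingSet
    post_ratings: RatingSet
    trials: list[TrialRecord]


@dataclass
class SyntheticCohort:
    """A generated cohort with full ground truth and provenance."""

    members: list[AgentRecord]
    seed: int
    config: ScheduleConfig
    rating_bias: float
    rating_noise_sd: float

    @property
    def trials_by_participant(self) -> dict[str, list[TrialRecord]]:
        return {m.participant_id: m.trials for m in self.members}

    @property
    def pre_ratings_by_participant(self) -> dict[str, RatingSet]:
        return {m.participant_id: m.pre_ratings for m in self.members}

    @property
    def post_ratings_by_participant(self) -> dict[str, RatingSet]:
        return {m.participant_id: m.post_ratings for m in self.members}

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_participants": len(self.members),
            "schedule": {
                "n_blocks": self.config.n_blocks,
                "trials_per_condition": self.config.trials_per_condition,
                "mode": self.config.mode,
                "max_run_length": self.config.max_run_length,
            },
            "rating_bias": self.rating_bias,
            "rating_noise_sd": self.rating_noise_sd,
            "truth": {
                m.participant_id: {
                    "model": m.model,
                    "alphas": list(m.params.alphas),
                    "beta": m.params.beta,
                }
                for m in self.members
            },
        }


def generate_cohort(
    n_participants: int = 73,
    model: str = "SimpleLearn",
    alphas: Sequence[float] = (DEFAULT_TRUE_ALPHA,),
    beta: float = DEFAULT_TRUE_BETA,
    seed: int = 0,
    schedule_config: ScheduleConfig = ScheduleConfig(),
    rating_bias: float = DEFAULT_RATING_BIAS,
    rating_noise_sd: float = DEFAULT_RATING_SD,
    post_noise_sd: float = 0.5,
    normalization: str = "affine",
) -> SyntheticCohort:
    """Generate a full cohort from one generating model.

    Every participant gets their own pseudorandomised schedule, own biased
    pre-ratings, simulated trials, and post-ratings derived from their final
    belief state.
    """
    spec = get_model(model)
    params = Params(tuple(alphas), beta)
    members: list[AgentRecord] = []
    root = np.random.SeedSequence(seed)
    for i, child in enumerate(root.spawn(n_participants)):
        rng = np.random.default_rng(child)
        pid = f"p{i + 1:03d}"
        pre = generate_pre_ratings(pid, rng, bias=rating_bias, noise_sd=rating_noise_sd)
        schedule = generate_schedule(schedule_config, rng)
        trials = simulate_agent(spec, params, schedule, pre, rng, normalization, pid)
        # recover final beliefs by replaying the log
        state = init_state(pre, spec, normalization)
        ep = dict(state.ep)
        if spec.learns:
            for tr in trials:
                slot = spec.rate_slot(classify_outcome(tr.choice, tr.partner_response), tr.category)
                if slot is not None:
                    ep[tr.category] += params.alphas[slot] * (tr.partner_response - ep[tr.category])
        post = generate_post_ratings(pid, ep, rng, noise_sd=post_noise_sd)
        members.append(AgentRecord(pid, model, params, pre, post, trials))
    return SyntheticCohort(members, seed, schedule_config, rating_bias, rating_noise_sd)
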