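import numpy as np
import pytest

from trustlearn import (
    CategoryId,
    Params,
    RatingSet,
    ScheduleConfig,
    generate_schedule,
    get_model,
    simulate_agent,
)
from trustlearn.trial_model import FACE_CATEGORIES


def make_ratings(pid="p1", timepoint="pre", means=None, n_faces=3):
    """RatingSet whose integer face ratings hit the requested category means
    (means must be multiples of 1/n_faces away from integers; default all 4)."""
    means = means or {}
    ratings, face_category = {}, {}
    for cat in FACE_CATEGORIES:
        target = means.get(cat, 4.0)
        total = round(target * n_faces)
        base, extra = divmod(total, n_faces)
        vals = [base + 1] * extra + [base] * (n_faces - extra)
        for j, v in enumerate(vals):
            if v not in range(1, 8):
                raise ValueError(f"target mean {target} not reachable with integers")
            face = f"{cat.value}_f{j + 1}"
            ratings[face] = v
            face_category[face] = cat
    return RatingSet(pid, timepoint, ratings, face_category)


@pytest.fixture
def neutral_pre():
    return make_ratings()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def grid_search_simple_learn(trials, pre, n_alpha=200, n_beta=200, beta_max=10.0):
    """Independent oracle for the single-rate learner: dense grid over
    (alpha, beta). The belief path depends only on alpha, so the beta axis is
    vectorised; returns the minimal negative log-likelihood on the grid."""
    from trustlearn.learners import compile_trials, initial_ep_vector

    spec = get_model("SimpleLearn")
    ct = compile_trials(trials, spec)
    ep0 = initial_ep_vector(pre, spec)
    betas = np.linspace(beta_max / n_beta, beta_max, n_beta)
    best = np.inf
    for alpha in np.linspace(1e-3, 1 - 1e-3, n_alpha):
        ep = list(ep0)
        evs = np.empty(len(ct.cat_idx))
        for i, (c, g) in enumerate(zip(ct.cat_idx, ct.gamma)):
            evs[i] = 4.0 * ep[c]
            ep[c] += alpha * (g - ep[c])
        x = np.outer(betas, evs - 2.0)  # (n_beta, n_trials)
        logp_invest = -np.logaddexp(0.0, -x)
        logp_keep = -np.logaddexp(0.0, x)
        inv = np.asarray(ct.invested, dtype=bool)
        nll = -(logp_invest[:, inv].sum(axis=1) + logp_keep[:, ~inv].sum(axis=1))
        best = min(best, float(nll.min()))
    return best


@pytest.fixture(scope="session")
def simple_learn_agent():
    """One SimpleLearn agent at the population-level parameter means, with a
    full 3-block schedule."""
    rng = np.random.default_rng(7)
    pre = make_ratings("agent1")
    schedule = generate_schedule(ScheduleConfig(), rng)
    trials = simulate_agent(
        get_model("SimpleLearn"), Params((0.16,), 0.62), schedule, pre, rng, participant_id="agent1"
    )
    return pre, trials
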