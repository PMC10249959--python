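"""Per-participant maximum-likelihood fitting and BIC model comparison.

Each model is fit to each participant separately by minimising the negative
log-likelihood of their choices, LL = sum_t -log P(choice_t), with a bounded
quasi-Newton optimiser started from many random points to escape local
minima. Models are then compared by BIC = 2*negLL + k*ln(n) — averaged across
participants and by counting, per participant, which model fits best.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .learners import (
    ALPHA_BOUNDS,
    BETA_BOUNDS,
    MODELS,
    CompiledTrials,
    ModelSpec,
    Params,
    compile_trials,
    get_model,
    initial_ep_vector,
    nll_compiled,
)
from .trial_model import CategoryId, RatingSet, TrialRecord

LIKELIHOOD_FLOOR = 1e-12
#: starting-point ranges: alpha uniform on (0,1), beta log-uniform on this range
BETA_START_RANGE = (1e-2, 1e2)
SCOPES = ("block1", "block2", "block3", "composite")


@dataclass(frozen=True)
class FitResult:
    participant_id: str
    model: str
    scope: str
    params: Params
    neg_ll: float
    bic: float
    n_trials: int
    n_params: int
    n_restarts: int
    n_converged: int
    best_start: tuple[float, ...]
    seed: Optional[int] = None

    def as_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "model": self.model,
            "scope": self.scope,
            "beta": self.params.beta,
            "neg_ll": self.neg_ll,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "n_params": self.n_params,
            "n_restarts": self.n_restarts,
            "n_converged": self.n_converged,
            "seed": self.seed,
        }
        slot_names = get_model(self.model).slot_names
        for name, a in zip(slot_names, self.params.alphas):
            row[f"alpha_{name}"] = a
        return row


class FittingError(RuntimeError):
    pass


def compute_bic(neg_ll: float, k: int, n_trials: int) -> float:
    """BIC = 2*negLL + k*ln(n); lower is better."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return 2.0 * neg_ll + k * math.log(n_trials)


def _select_trials(
    trials: Sequence[TrialRecord],
    scope: str,
    carry_state: bool,
    exclude_lottery: bool,
) -> tuple[list[TrialRecord], list[bool]]:
    """Trials entering the learner, with a mask of which are scored.

    For block scopes, ``carry_state=True`` feeds earlier blocks through the
    learner unscored (beliefs carry over); otherwise beliefs re-initialise
    from pre-ratings and only that block's trials are used.
    """
    if scope == "composite":
        kept = list(trials)
        scored = [True] * len(kept)
    elif scope in ("block1", "block2", "block3"):
        b = int(scope[-1])
        if carry_state:
            kept = [t for t in trials if t.block <= b]
            scored = [t.block == b for t in kept]
        else:
            kept = [t for t in trials if t.block == b]
            scored = [True] * len(kept)
    else:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    if exclude_lottery:
        pairs = [(t, s) for t, s in zip(kept, scored) if t.category is not CategoryId.lottery]
        kept = [t for t, _ in pairs]
        scored = [s for _, s in pairs]
    return kept, scored


def negative_log_likelihood(
    params: Params,
    trials: Sequence[TrialRecord],
    pre_ratings: RatingSet,
    spec: ModelSpec,
    normalization: str = "affine",
    exclude_lottery: bool = False,
) -> float:
    """Sum over trials of -log P(observed choice) under the model."""
    if len(params.alphas) != spec.n_alpha_slots:
        raise ValueError(
            f"model {spec.name} needs {spec.n_alpha_slots} learning rate(s), "
            f"got {len(params.alphas)}"
        )
    kept, scored = _select_trials(trials, "composite", False, exclude_lottery)
    ct = compile_trials(kept, spec, scored)
    ep0 = initial_ep_vector(pre_ratings, spec, normalization)
    value = nll_compiled(params.alphas, params.beta, ep0, ct, LIKELIHOOD_FLOOR)
    if not math.isfinite(value):
        raise FloatingPointError(f"non-finite negLL for model {spec.name}")
    return value


def _draw_starts(rng: np.random.Generator, n_restarts: int, n_alphas: int) -> np.ndarray:
    lo, hi = math.log(BETA_START_RANGE[0]), math.log(BETA_START_RANGE[1])
    betas = np.exp(rng.uniform(lo, hi, size=n_restarts))
    alphas = rng.uniform(0.0, 1.0, size=(n_restarts, n_alphas))
    return np.column_stack([alphas, betas])


def fit_participant(
    trials: Sequence[TrialRecord],
    pre_ratings: RatingSet,
    spec: ModelSpec,
    n_restarts: int = 50,
    rng_seed: int | np.random.Generator | None = 0,
    scope: str = "composite",
    normalization: str = "affine",
    exclude_lottery: bool = False,
    carry_state: bool = False,
    extra_starts: Optional[Iterable[Sequence[float]]] = None,
) -> FitResult:
    """Multistart bounded MLE for one participant and one model.

    Parameter vector is (alpha_1..alpha_m, beta); no-learning models fit beta
    only. ``extra_starts`` lets callers warm-start from, e.g., a nested
    model's solution.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    kept, scored = _select_trials(trials, scope, carry_state, exclude_lottery)
    n_scored = sum(scored)
    if n_scored < 1:
        raise ValueError(f"no scored trials for scope {scope!r}")
    ct = compile_trials(kept, spec, scored)
    ep0 = initial_ep_vector(pre_ratings, spec, normalization)

    m = spec.n_alpha_slots
    if isinstance(rng_seed, np.random.Generator):
        rng, seed = rng_seed, None
    else:
        rng, seed = np.random.default_rng(rng_seed), rng_seed
    starts = _draw_starts(rng, n_restarts, m)
    start_list = [np.asarray(s, dtype=float) for s in starts]
    if extra_starts is not None:
        for s in extra_starts:
            s = np.asarray(s, dtype=float)
            if s.shape != (m + 1,):
                raise ValueError(f"extra start has wrong length {s.shape}, need {m + 1}")
            start_list.append(np.clip(s, [ALPHA_BOUNDS[0]] * m + [BETA_BOUNDS[0]],
                                      [ALPHA_BOUNDS[1]] * m + [BETA_BOUNDS[1]]))

    bounds = [ALPHA_BOUNDS] * m + [BETA_BOUNDS]

    def objective(theta: np.ndarray) -> float:
        return nll_compiled(theta[:m], theta[m], ep0, ct, LIKELIHOOD_FLOOR)

    best_val = math.inf
    best_theta: Optional[np.ndarray] = None
    best_start: Optional[np.ndarray] = None
    n_converged = 0
    messages: list[str] = []
    for x0 in start_list:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds, tol=1e-8)
        if res.success:
            n_converged += 1
        else:
            messages.append(str(res.message))
        if math.isfinite(res.fun) and res.fun < best_val:
            best_val = float(res.fun)
            best_theta = np.asarray(res.x)
            best_start = x0
    if best_theta is None or n_converged == 0:
        raise FittingError(
            f"all {len(start_list)} restarts failed for {spec.name} / "
            f"{pre_ratings.participant_id}: {messages[:3]}"
        )
    params = Params(tuple(best_theta[:m]), float(best_theta[m]))
    return FitResult(
        participant_id=pre_ratings.participant_id,
        model=spec.name,
        scope=scope,
        params=params,
        neg_ll=best_val,
        bic=compute_bic(best_val, spec.n_params, n_scored),
        n_trials=n_scored,
        n_params=spec.n_params,
        n_restarts=len(start_list),
        n_converged=n_converged,
        best_start=tuple(best_start),
        seed=seed,
    )


def _expand_start(from_model: str, to_model: str, theta: Sequence[float]) -> list[float]:
    """Map a fitted (alphas, beta) vector of a nested model into a richer
    model's slot space by replicating the shared rate; returns a warm start."""
    src, dst = get_model(from_model), get_model(to_model)
    theta = list(theta)
    alphas, beta = theta[:-1], theta[-1]
    if src.name == "SimpleLearn":
        return [alphas[0]] * dst.n_alpha_slots + [beta]
    if src.name == "LG" and dst.name == "L2G2":
        # (G, L) -> (G, L, G-rel, L-rel)
        return [alphas[0], alphas[1], alphas[0], alphas[1], beta]
    raise ValueError(f"no nesting map from {from_model} to {to_model}")


NESTING_CHAIN = ("SimpleLearn", "LG", "L2G2")


def fit_cohort(
    cohort_trials: dict[str, Sequence[TrialRecord]],
    pre_ratings: dict[str, RatingSet],
    models: Sequence[str],
    scopes: Sequence[str] = ("composite",),
    n_restarts: int = 50,
    seed: int = 0,
    normalization: str = "affine",
    exclude_lottery: bool = False,
    carry_state: bool = False,
    warm_start_nested: bool = True,
) -> list[FitResult]:
    """Fit every requested model to every participant at every scope.

    When ``warm_start_nested`` is on, richer members of the nesting chain
    SimpleLearn ⊂ LG ⊂ L2G2 additionally start from the poorer member's
    solution, which enforces the nesting inequality up to optimiser tolerance.
    """
    results: list[FitResult] = []
    ss = np.random.SeedSequence(seed)
    for p_idx, pid in enumerate(sorted(cohort_trials)):
        if pid not in pre_ratings:
            raise ValueError(f"no pre-ratings for participant {pid!r}")
        for scope in scopes:
            chain_best: dict[str, tuple[float, ...]] = {}
            for m_idx, name in enumerate(models):
                spec = get_model(name)
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=ss.entropy, spawn_key=(p_idx, m_idx, SCOPES.index(scope))
                    )
                )
                extra = None
                if warm_start_nested and name in NESTING_CHAIN:
                    extra = []
                    for prev in NESTING_CHAIN[: NESTING_CHAIN.index(name)]:
                        if prev in chain_best:
                            extra.append(_expand_start(prev, name, chain_best[prev]))
                fr = fit_participant(
                    cohort_trials[pid],
                    pre_ratings[pid],
                    spec,
                    n_restarts=n_restarts,
                    rng_seed=rng,
                    scope=scope,
                    normalization=normalization,
                    exclude_lottery=exclude_lottery,
                    carry_state=carry_state,
                    extra_starts=extra,
                )
                results.append(fr)
                if name in NESTING_CHAIN:
                    chain_best[name] = tuple(fr.params.alphas) + (fr.params.beta,)
    return results


@dataclass
class ComparisonTable:
    """Mean-BIC and winner-count comparison across participants at one scope."""

    scope: str
    table: pd.DataFrame  # index: model; columns: mean_bic, sd_bic, winner_count, n
    delta_top2: float  # mean-BIC gap between the two best models
    ties: list[tuple[str, ...]] = field(default_factory=list)

    @property
    def best_model(self) -> str:
        return str(self.table["mean_bic"].idxmin())


def compare_models(
    fits: Iterable[FitResult], scope: str = "composite", tie_tol: float = 1e-9
) -> ComparisonTable:
    """Build the comparison table from per-participant fits at one scope.

    Winner counts use the strictly lowest BIC per participant; ties within
    ``tie_tol`` go to the earlier model in registry order and are recorded.
    """
    rows = [f for f in fits if f.scope == scope]
    if not rows:
        raise ValueError(f"no fits at scope {scope!r}")
    df = pd.DataFrame([{"participant_id": f.participant_id, "model": f.model, "bic": f.bic}
                       for f in rows])
    models = list(dict.fromkeys(f.model for f in rows))
    order = sorted(models, key=list(MODELS).index)
    pivot = df.pivot_table(index="participant_id", columns="model", values="bic")
    missing = pivot.isna()
    if missing.any().any():
        gaps = [
            f"{pid}:{model}"
            for pid in pivot.index
            for model in pivot.columns
            if missing.loc[pid, model]
        ]
        raise ValueError(f"missing fits for: {', '.join(gaps)}")
    pivot = pivot[order]

    winners = {m: 0 for m in order}
    ties: list[tuple[str, ...]] = []
    for pid, row in pivot.iterrows():
        lo = row.min()
        tied = tuple(m for m in order if row[m] <= lo + tie_tol)
        if len(tied) > 1:
            ties.append((str(pid),) + tied)
        winners[tied[0]] += 1

    table = pd.DataFrame(
        {
            "mean_bic": pivot.mean(axis=0),
            "sd_bic": pivot.std(axis=0, ddof=1),
            "winner_count": pd.Series(winners),
            "n": len(pivot),
        }
    ).loc[order]
    means = table["mean_bic"].sort_values()
    delta = float(means.iloc[1] - means.iloc[0]) if len(means) > 1 else float("nan")
    return ComparisonTable(scope=scope, table=table, delta_top2=delta, ties=ties)
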