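"""Posterior-predictive checks, investment curves, and recovery harnesses.

The central diagnostic is the investment curve: for each partner condition,
the proportion of invest choices at each within-condition trial index
(1..36, counted contiguously across blocks), pooled over participants and —
for model checks — over simulations. A fitted model is validated by
simulating many replicates per participant from their own fitted parameters
and pre-ratings and comparing the simulated curve to the observed one; the
discrepancy is summarised as mean absolute deviation per condition.
Parameter- and model-recovery harnesses close the loop on the synthetic side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.stats.proportion import proportion_confint

from .fitting import FitResult, fit_participant
from .learners import Params, get_model
from .synthetic_data import (
    ScheduleConfig,
    generate_pre_ratings,
    generate_schedule,
    simulate_agent,
)
from .trial_model import CATEGORY_ORDER, CategoryId, Choice, RatingSet, TrialRecord


def _proportion_ci(k: int, n: int) -> tuple[float, float]:
    # normal approximation; Wilson at the boundaries where normal degenerates
    method = "wilson" if k in (0, n) else "normal"
    lo, hi = proportion_confint(k, n, alpha=0.05, method=method)
    return float(lo), float(hi)


def invest_curve(
    trials_by_participant: Mapping[str, Sequence[TrialRecord]],
    population: str = "observed",
) -> pd.DataFrame:
    """Pooled invest proportion per condition and within-condition trial index.

    Returns a frame with columns category, cond_trial, prop, ci_low, ci_high,
    n, population. Indices with no trials in any participant are flagged by
    their absence (each participant contributes at most one choice per index).
    """
    if not trials_by_participant:
        raise ValueError("empty cohort")
    counts: dict[tuple[CategoryId, int], list[int]] = {}
    for pid, trials in trials_by_participant.items():
        per_cat: dict[CategoryId, int] = {}
        for t in sorted(trials, key=lambda t: (t.block, t.trial_index)):
            idx = per_cat.get(t.category, 0) + 1
            per_cat[t.category] = idx
            counts.setdefault((t.category, idx), []).append(
                1 if t.choice is Choice.invest else 0
            )
    rows = []
    for cat in CATEGORY_ORDER:
        indices = sorted(i for c, i in counts if c is cat)
        for i in indices:
            votes = counts[(cat, i)]
            k, n = sum(votes), len(votes)
            lo, hi = _proportion_ci(k, n)
            rows.append(
                {
                    "category": cat.value,
                    "cond_trial": i,
                    "prop": k / n,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n": n,
                    "population": population,
                }
            )
    return pd.DataFrame(rows)


def _schedule_from_trials(
    trials: Sequence[TrialRecord],
) -> list[list[tuple[CategoryId, int]]]:
    """Recover the (category, gamma) schedule from an observed log — possible
    because the partner response is revealed on every trial."""
    blocks: dict[int, list[tuple[int, CategoryId, int]]] = {}
    for t in trials:
        blocks.setdefault(t.block, []).append((t.trial_index, t.category, t.partner_response))
    return [
        [(cat, g) for _, cat, g in sorted(blocks[b])] for b in sorted(blocks)
    ]


@dataclass
class PosteriorPredictiveResult:
    model: str
    observed_curve: pd.DataFrame
    simulated_curve: pd.DataFrame
    mad_per_condition: dict[str, float]
    n_sims: int

    @property
    def mad_overall(self) -> float:
        return float(np.mean(list(self.mad_per_condition.values())))


def posterior_predictive(
    fits: Iterable[FitResult],
    pre_ratings: Mapping[str, RatingSet],
    trials_by_participant: Mapping[str, Sequence[TrialRecord]],
    n_sims: int = 100,
    rng: np.random.Generator | int | None = 0,
    normalization: str = "affine",
) -> dict[str, PosteriorPredictiveResult]:
    """Simulate each participant from their own fitted parameters and compare
    pooled curves to the observed data.

    ``fits`` may contain several models; one result is returned per model.
    Each participant is replayed on their own schedule (read off their log)
    ``n_sims`` times.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    by_model: dict[str, list[FitResult]] = {}
    for f in fits:
        by_model.setdefault(f.model, []).append(f)
    observed = invest_curve(trials_by_participant, population="observed")
    out: dict[str, PosteriorPredictiveResult] = {}
    for model, model_fits in by_model.items():
        spec = get_model(model)
        missing = [pid for pid in trials_by_participant if pid not in {f.participant_id for f in model_fits}]
        if missing:
            raise ValueError(f"no {model} fit for participants: {missing}")
        sim_logs: dict[str, list[TrialRecord]] = {}
        for f in sorted(model_fits, key=lambda f: f.participant_id):
            pid = f.participant_id
            if pid not in trials_by_participant:
                continue
            schedule = _schedule_from_trials(trials_by_participant[pid])
            for s in range(n_sims):
                sim = simulate_agent(
                    spec, f.params, schedule, pre_ratings[pid], rng,
                    normalization, participant_id=f"{pid}~sim{s}",
                )
                sim_logs[f"{pid}~sim{s}"] = sim
        simulated = invest_curve(sim_logs, population="simulated")
        merged = observed.merge(
            simulated, on=["category", "cond_trial"], suffixes=("_obs", "_sim")
        )
        mad = {
            str(cat): float(np.mean(np.abs(grp["prop_obs"] - grp["prop_sim"])))
            for cat, grp in merged.groupby("category")
        }
        out[model] = PosteriorPredictiveResult(model, observed, simulated, mad, n_sims)
    return out


@dataclass
class RecoveryReport:
    """Truth-vs-estimate pairs plus per-parameter summaries.

    ``pairs`` has one row per (agent, parameter); ``summary`` one row per
    parameter with bias, RMSE and Spearman rank correlation; ``flags`` lists
    identifiability warnings (e.g., alpha is flat when beta = 0).
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame
    flags: list[str] = field(default_factory=list)


def parameter_recovery(
    model: str,
    truth_grid: Sequence[Params],
    n_agents: int,
    schedule_config: ScheduleConfig = ScheduleConfig(),
    seed: int = 0,
    n_restarts: int = 50,
    normalization: str = "affine",
) -> RecoveryReport:
    """Simulate ``n_agents`` agents per truth point, refit, and summarise.

    Rank correlations are computed over the pooled truth/estimate pairs and
    are only meaningful when the grid varies the parameter.
    """
    spec = get_model(model)
    param_names = [f"alpha_{s}" for s in spec.slot_names] + ["beta"]
    rows = []
    flags: list[str] = []
    root = np.random.SeedSequence(seed)
    agent = 0
    for truth in truth_grid:
        if truth.beta == 0 and spec.n_alpha_slots > 0:
            flags.append(
                f"beta=0 at truth {tuple(truth.alphas)}: likelihood is flat in alpha "
                "(choices are coin flips); alpha estimates are not interpretable"
            )
        for _ in range(n_agents):
            rng = np.random.default_rng(root.spawn(1)[0])
            pid = f"rec{agent:04d}"
            pre = generate_pre_ratings(pid, rng)
            schedule = generate_schedule(schedule_config, rng)
            trials = simulate_agent(spec, truth, schedule, pre, rng, normalization, pid)
            fit = fit_participant(
                trials, pre, spec, n_restarts=n_restarts, rng_seed=rng,
                normalization=normalization,
            )
            truth_vec = list(truth.alphas) + [truth.beta]
            est_vec = list(fit.params.alphas) + [fit.params.beta]
            for name, tv, ev in zip(param_names, truth_vec, est_vec):
                rows.append({"agent": pid, "param": name, "truth": tv, "estimate": ev})
            agent += 1
    pairs = pd.DataFrame(rows, columns=["agent", "param", "truth", "estimate"])
    summaries = []
    for name in param_names if not pairs.empty else []:
        sub = pairs[pairs["param"] == name]
        err = sub["estimate"] - sub["truth"]
        if sub["truth"].nunique() > 1:
            rc = float(spearmanr(sub["truth"], sub["estimate"]).statistic)
        else:
            rc = float("nan")
        summaries.append(
            {
                "param": name,
                "bias": float(err.mean()),
                "rmse": float(np.sqrt((err**2).mean())),
                "rank_corr": rc,
                "n": len(sub),
            }
        )
    summary = pd.DataFrame(summaries, columns=["param", "bias", "rmse", "rank_corr", "n"])
    return RecoveryReport(pairs=pairs, summary=summary, flags=flags)


def model_recovery(
    models: Sequence[str],
    params_per_model: Mapping[str, Params],
    n_agents: int,
    fit_models: Optional[Sequence[str]] = None,
    schedule_config: ScheduleConfig = ScheduleConfig(),
    seed: int = 0,
    n_restarts: int = 10,
    normalization: str = "affine",
) -> pd.DataFrame:
    """Generate agents from each model, fit all candidates, count BIC winners.

    Returns the confusion matrix (rows: generating model, columns: winning
    model by lowest BIC); each row sums to ``n_agents``.
    """
    if len(models) < 2 and fit_models is None:
        raise ValueError("need at least two models to compare")
    fit_models = list(fit_models) if fit_models is not None else list(models)
    confusion = pd.DataFrame(0, index=list(models), columns=fit_models, dtype=int)
    root = np.random.SeedSequence(seed)
    for gen_name in models:
        gen_spec = get_model(gen_name)
        truth = params_per_model[gen_name]
        for a in range(n_agents):
            rng = np.random.default_rng(root.spawn(1)[0])
            pid = f"{gen_name}_a{a:03d}"
            pre = generate_pre_ratings(pid, rng)
            schedule = generate_schedule(schedule_config, rng)
            trials = simulate_agent(gen_spec, truth, schedule, pre, rng, normalization, pid)
            best_name, best_bic = None, np.inf
            for cand in fit_models:
                fit = fit_participant(
                    trials, pre, get_model(cand), n_restarts=n_restarts,
                    rng_seed=rng, normalization=normalization,
                )
                if fit.bic < best_bic:
                    best_name, best_bic = cand, fit.bic
            confusion.loc[gen_name, best_name] += 1
    return confusion
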