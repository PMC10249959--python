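"""Trustworthiness-bias statistics.

The behavioural endpoint of the pipeline: per-participant mean Likert ratings
by partner category, the White-minus-Arab bias score, paired t-tests across
the pre/post contrast set with step-down Holm correction, and Hedges g
(small-sample-corrected Cohen's d) with a noncentral-t confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .trial_model import CATEGORIES, CategoryId, Ethnicity, Fairness, RatingSet

_WHITE = [c for c in CategoryId if c is not CategoryId.lottery
          and CATEGORIES[c].ethnicity is Ethnicity.white]
_ARAB = [c for c in CategoryId if c is not CategoryId.lottery
         and CATEGORIES[c].ethnicity is Ethnicity.arab]


def bias_score(ratings: RatingSet) -> float:
    """White-minus-Arab mean trustworthiness rating (positive = pro-ingroup
    for a White sample)."""
    means = ratings.category_means
    missing = [c.value for c in _WHITE + _ARAB if c not in means]
    if missing:
        raise ValueError(f"ratings missing categories: {missing}")
    white = float(np.mean([means[c] for c in _WHITE]))
    arab = float(np.mean([means[c] for c in _ARAB]))
    return white - arab


def hedges_g(diff: np.ndarray) -> float:
    """Hedges g for paired data: d = mean(diff)/sd(diff) times the
    small-sample correction J = 1 - 3/(4*df - 1)."""
    diff = np.asarray(diff, dtype=float)
    df = len(diff) - 1
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences: effect size undefined")
    d = diff.mean() / sd
    return d * (1.0 - 3.0 / (4.0 * df - 1.0))


def _g_ci_noncentral(diff: np.ndarray, conf: float = 0.95) -> tuple[float, float]:
    """CI for paired-design g by pivoting the noncentral t distribution.

    The observed t is noncentral-t with df = n-1 and noncentrality
    delta = d*sqrt(n); the limits on delta are mapped back to d and scaled by
    the bias-correction factor J. Falls back to a normal approximation if the
    pivot fails to bracket.
    """
    diff = np.asarray(diff, dtype=float)
    n = len(diff)
    df = n - 1
    t_obs = diff.mean() / (diff.std(ddof=1) / np.sqrt(n))
    if t_obs < 0:
        lo, hi = _g_ci_noncentral(-diff, conf)
        return (-hi, -lo)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    alpha = 1.0 - conf
    span = 10.0 + 2.0 * abs(t_obs)

    def cdf(nc: float) -> float:
        v = stats.nct.cdf(t_obs, df, nc)
        # scipy underflows to NaN far in the upper tail of nc; there the true
        # cdf is ~0
        return 0.0 if np.isnan(v) else float(v)

    def solve(q: float) -> float:
        f = lambda nc: cdf(nc) - q
        try:
            return optimize.brentq(f, t_obs - span, t_obs + span, xtol=1e-8)
        except ValueError:
            # normal-approximation fallback
            d = t_obs / np.sqrt(n)
            se = np.sqrt(1.0 / n + d**2 / (2.0 * df))
            z = stats.norm.ppf(q)
            return (d - z * se) * np.sqrt(n)  # back on nc scale

    nc_hi = solve(alpha / 2.0)  # upper limit: nc with P(T<=t_obs)=alpha/2
    nc_lo = solve(1.0 - alpha / 2.0)
    return (J * nc_lo / np.sqrt(n), J * nc_hi / np.sqrt(n))


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    hedges_g: float
    g_ci: tuple[float, float]


def paired_test(x: Sequence[float], y: Sequence[float]) -> PairedTestResult:
    """Two-sided paired t-test of x - y with Hedges g and its 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D, paired by participant")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    diff = x - y
    if diff.std(ddof=1) == 0:
        # identical vectors are a well-defined null result; a constant nonzero
        # shift has no finite effect size
        if diff.mean() == 0:
            return PairedTestResult(0.0, len(x) - 1, 1.0, 0.0, 0.0, (0.0, 0.0))
        raise ValueError("zero variance of paired differences")
    res = stats.ttest_rel(x, y)
    return PairedTestResult(
        t=float(res.statistic),
        df=len(x) - 1,
        p=float(res.pvalue),
        mean_diff=float(diff.mean()),
        hedges_g=hedges_g(diff),
        g_ci=_g_ci_noncentral(diff),
    )


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Step-down Holm adjustment; order-preserving, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(p, method="holm")[1])


# The contrast set mirroring the pre/post rating analysis. Each entry:
# (label, (timepoint_a, categories_a), (timepoint_b, categories_b)) comparing
# participant-level means a - b.
_FAIR = [c for c in CategoryId if c is not CategoryId.lottery
         and CATEGORIES[c].fairness is Fairness.fair]
_UNFAIR = [c for c in CategoryId if c is not CategoryId.lottery
           and CATEGORIES[c].fairness is Fairness.unfair]

DEFAULT_CONTRASTS: list[tuple[str, tuple[str, list[CategoryId]], tuple[str, list[CategoryId]]]] = [
    ("baseline_white_vs_arab", ("pre", _WHITE), ("pre", _ARAB)),
    ("change_fair_white", ("post", [CategoryId.fair_white]), ("pre", [CategoryId.fair_white])),
    ("change_fair_arab", ("post", [CategoryId.fair_arab]), ("pre", [CategoryId.fair_arab])),
    ("change_unfair_white", ("post", [CategoryId.unfair_white]), ("pre", [CategoryId.unfair_white])),
    ("change_unfair_arab", ("post", [CategoryId.unfair_arab]), ("pre", [CategoryId.unfair_arab])),
    ("post_fair_vs_unfair", ("post", _FAIR), ("post", _UNFAIR)),
    ("post_white_vs_arab_fair", ("post", [CategoryId.fair_white]), ("post", [CategoryId.fair_arab])),
    ("post_white_vs_arab_unfair", ("post", [CategoryId.unfair_white]), ("post", [CategoryId.unfair_arab])),
]


def _participant_mean(rs: RatingSet, cats: Sequence[CategoryId]) -> float:
    means = rs.category_means
    return float(np.mean([means[c] for c in cats]))


def trust_bias_table(
    pre: Mapping[str, RatingSet],
    post: Mapping[str, RatingSet],
    contrasts=None,
    families: Optional[Sequence[Sequence[str]]] = None,
) -> pd.DataFrame:
    """Run the full contrast set and Holm-adjust within correction families.

    By default all contrasts form one family; pass ``families`` (lists of
    contrast labels) to partition them. Returns one row per contrast with t,
    df, raw and adjusted p, Hedges g and its CI.
    """
    contrasts = contrasts if contrasts is not None else DEFAULT_CONTRASTS
    pids = sorted(pre)
    if sorted(post) != pids:
        raise ValueError("pre and post cover different participants")
    sets = {"pre": pre, "post": post}
    rows = []
    for label, (tp_a, cats_a), (tp_b, cats_b) in contrasts:
        a = [_participant_mean(sets[tp_a][pid], cats_a) for pid in pids]
        b = [_participant_mean(sets[tp_b][pid], cats_b) for pid in pids]
        r = paired_test(a, b)
        rows.append(
            {
                "contrast": label,
                "mean_diff": r.mean_diff,
                "t": r.t,
                "df": r.df,
                "p_raw": r.p,
                "hedges_g": r.hedges_g,
                "g_ci_low": r.g_ci[0],
                "g_ci_high": r.g_ci[1],
            }
        )
    out = pd.DataFrame(rows)
    out["p_holm"] = np.nan
    if families is None:
        families = [list(out["contrast"])]
    for fam in families:
        mask = out["contrast"].isin(fam)
        out.loc[mask, "p_holm"] = holm_adjust(list(out.loc[mask, "p_raw"]))
    return out
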