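# Methods

## Task and data model

One trial of the modified repeated Trust Game: the trustor holds 4 € and
either invests it all with the current partner or keeps 2 € (the partner then
receives 2 €). Invested money is doubled; the partner reciprocates half
(trustor ends with 4 €) or defects (0 €). The partner's response γ ∈ {0, 1}
is revealed on every trial — counterfactually on keep trials — which is what
makes learning possible at a constant rate regardless of the choice. Partners
come in five conditions: fair/unfair × White/Arab faces (reciprocation rates
0.75 / 0.25) and a faceless lottery (0.50). A session is 3 blocks × 60 trials
(12 per condition, pseudorandomised within block). Before and after the game
participants rate each partner face's trustworthiness on a 1–7 Likert scale.

Trials travel as long-format CSV (`participant_id, block, trial, category,
choice, partner_response, payoff`); payoffs are stored per trial and checked
against (choice, γ) on read, so reward-based model variants and audits need
no recomputation. Ratings travel as one row per face and timepoint.

## Belief model

All learners share one architecture. Beliefs are expected reciprocation
probabilities per category, ep_i; the expected value of investing is
ev_i = 4·ep_i; choices are softmax between ev_i and the sure 2 €
(P(invest) = σ(β·(ev_i − 2)), computed via the stable logistic form so no β
can overflow). Updates are Rescorla–Wagner on the probability scale,
ep_i ← ep_i + α·(γ − ep_i); since γ ∈ {0, 1} and α ∈ [0, 1] this is a convex
combination and ep can never leave [0, 1]. The choice probability on a trial
always uses the belief *before* that trial's update (standard sequencing; the
update equations imply it).

Initial beliefs are the participant's mean pre-game rating per category
mapped to [0, 1]. Two normalisations are provided: the default affine map
(r − 1)/6, which sends the Likert endpoints to 0 and 1, and r/7 as a
robustness alternative; which of the two the original analysis used is not
determinable, and the difference is a modest shift and rescale of the
starting beliefs only. The lottery has no faces and hence no rating; its
belief starts at 0.5, the advertised rate and the unique uninformative
choice. The optimal non-learner instead pins ep at the true rates
(0.75 / 0.25 / 0.5); the biased non-learner pins it at the initial ratings.

Model family members differ only in how (outcome class × category) maps to
learning-rate slots; the outcome taxonomy is true gain (invest,
reciprocated), true loss (invest, defected), relative loss (kept, would have
reciprocated), relative gain (kept, would have defected). With every slot
tied to a single α, the L2G2, LGK, LG, Reputation and SimpleLearn models are
literally the same process — this nesting is exploited both in tests and in
warm-starting the fits.

The follow-up models keyed by partner ethnicity or fairness assign no rate to
the lottery. By default the comparison of these models against the one-rate
learner is run with lottery trials excluded from the likelihood for all
compared models, so BICs are computed on identical data and remain
commensurable; 3-slot variants that give the lottery its own rate exist in
the registry for the alternative reading.

## Estimation

Per participant and model, the negative log-likelihood of the observed
choices is minimised with L-BFGS-B under bounds α ∈ (10⁻⁶, 1 − 10⁻⁶),
β ∈ (10⁻⁶, 10⁵), objective tolerance 1e-8, from 50 random starts by default
(α uniform on (0, 1); β log-uniform on [10⁻², 10²], covering the range where
fitted values actually land, with the upper bound far beyond any plausible
estimate). Per-trial probabilities are floored at 10⁻¹² so the objective
stays finite at extreme β. Trial sequences are pre-compiled to flat index
arrays (category, slot, γ, choice) so one likelihood evaluation is a tight
scalar loop; a 2-parameter fit with 50 restarts takes well under a second.

Within the nesting chain SimpleLearn ⊂ LG ⊂ L2G2, richer models additionally
start from the poorer model's solution expanded into their slot space. This
is ordinary multistart practice and guarantees the fitted negLL ordering
respects nesting up to optimiser tolerance.

BIC = 2·negLL + k·ln(n), with k the number of free parameters (α slots plus
one for β; the no-learning baselines fit β only, k = 1) and n the number of
scored trials. Models are compared by mean BIC across participants and by
counting, per participant, the strictly lowest BIC; exact ties (within 10⁻⁹)
go to the earlier model in registry order and are recorded. A mean-BIC gap
below 2 is treated as uninformative. Per-block fits use that block's 60
trials and re-initialise beliefs from the pre-ratings; a `carry_state` flag
instead feeds earlier blocks through the learner unscored, for the reading in
which beliefs persist across blocks.

The fitter is verified against an independent oracle: a 200 × 200 grid over
(α, β ∈ (0, 10]) for the 2-parameter learner, where the belief path depends
only on α so the β axis vectorises. The multistart optimum must be within
10⁻³ negLL of the grid minimum.

## Synthetic cohorts

The generator emulates the study conditions and provides full ground truth:

- **Schedules.** Per block, exactly 12 trials per condition with no more than
  3 consecutive trials of one condition (random shuffles with a constructive
  greedy fallback that also handles the tightest feasible constraints), and
  exact reciprocation counts 9/3/6 for fair/unfair/lottery. A `bernoulli`
  mode draws γ independently at the condition rate instead. The original
  pseudorandomisation details beyond these counts are not public; schedule
  statistics beyond counts are not matched.
- **Pre-ratings.** Face ratings are Gaussian around a centre of 4.375 with a
  pro-ingroup shift of ±bias/2 (default bias 0.43 Likert points, matching the
  observed baseline gap 4.59 − 4.16), SD 1.0, rounded and clipped to 1–7.
- **Agents.** Choices are Bernoulli draws from the softmax given the evolving
  beliefs; γ comes from the schedule regardless of the choice. Default ground
  truth is the single-rate learner at the population-level estimates
  α = 0.16, β = 0.62, 73 participants.
- **Post-ratings.** Each face's post rating is the Likert image of the
  agent's final belief for that category (1 + 6·ep) plus noise (SD 0.5) —
  after the game, simulated agents report what they learned, so fairness
  dominates and the ethnicity gap closes. This is generator plumbing for the
  bias-statistics stage, not part of the learning model.

Everything is deterministic given the seed (per-participant child seeds are
spawned from one root), and the cohort manifest records seeds and truth.

What the generator does **not** emulate: parameter heterogeneity across
participants (everyone shares the ground-truth parameters), lapses,
side/colour preferences, reaction times, or any misfit between a
participant's true process and the model family. Passing tests on these
cohorts therefore demonstrate that the pipeline recovers what it should from
ideal data at the study's size — not that real participants behave like the
model.

## Validation harnesses

Investment curves pool the proportion of invest choices per condition at each
within-condition trial index, counted contiguously across blocks (1–36), with
95% CIs by normal approximation (Wilson at the 0/1 boundaries, where the
normal interval degenerates). Posterior-predictive checks resimulate each
participant n_sims times (default 100) from their own fitted parameters and
pre-ratings on their own schedule — recoverable from the log because γ is
observed on every trial — and summarise the observed-vs-simulated curve
discrepancy as mean absolute deviation per condition; the discrepancy metric
is this package's choice, made where the original comparison was visual.
Parameter recovery simulates agents over a truth grid, refits, and reports
bias, RMSE and Spearman rank correlation (flagging β = 0, where the
likelihood is flat in α). Model recovery fits a candidate set to agents from
each generating model and reports the confusion matrix of BIC winners.

## Bias statistics

The White − Arab bias score averages a participant's category-mean ratings
within ethnicity and subtracts. The contrast set mirrors the rating analysis:
baseline White vs Arab, the four per-category pre→post changes, post fair vs
unfair, and post White vs Arab within each fairness level. Paired two-sided
t-tests (scipy) are Holm-corrected (statsmodels), with all contrasts in one
family by default and an option to partition families, since the original
family memberships are ambiguous. Effect sizes are Hedges g for paired
designs — d = mean(diff)/sd(diff) shrunk by J = 1 − 3/(4·df − 1) — with 95%
CIs by pivoting the noncentral-t distribution of the observed t statistic
(negative t is handled by symmetry; a normal approximation is the fallback if
the pivot fails to bracket). Identical pre/post vectors return the exact null
result (t = 0, g = 0); a constant nonzero shift has zero difference variance
and no finite effect size, and raises.

## Problem sizes used in the checks

The shipped end-to-end checks run, per stage: 20 random 60-trial datasets for
the grid-oracle comparison; 50 agents (α grid 0.05–0.5, β = 0.62, 180 trials,
50 restarts) for parameter recovery; 30 agents per generating model at the
published parameter means, refit with the seven-model set at 10 restarts, for
model recovery; and one 73-participant cohort fit with the seven-model set at
20 restarts for the full pipeline. The acceptance script uses the same sizes.

## Known limitations and measured identifiability boundaries

Two findings from running the pipeline on its own synthetic conditions are
worth stating plainly, because they are properties of the conditions, not
bugs, and the corresponding end-to-end checks are deliberately left failing
rather than retuned:

1. **Single-rate learner vs optimal non-learner.** Ideal agents simulated at
   exactly α = 0.16, β = 0.62 yield a mean log-likelihood advantage for the
   true model over the optimal non-learner of ≈ 2.6 nats per 180 trials —
   almost exactly the BIC penalty ln(180)/2 ≈ 2.60 for the extra parameter.
   Per-agent BIC wins between the two are a near coin flip, and the
   study-scale mean-BIC gap (≈ 1) is below the informativeness threshold
   of 2. The clear separation seen in real cohorts requires heterogeneity or
   departures from ideal play that a homogeneous point-parameter simulation
   does not produce. Conversely, when the candidate set contains only
   learning models and the biased non-learner, the generating model is
   cleanly recovered (see the worked example).
2. **Learning-rate recovery at small β.** At β = 0.62 choices are weakly
   informative about α (RMSE ≈ 0.2 over a 0.05–0.5 grid at 180 trials), so
   the truth-estimate rank correlation fluctuates around 0.5–0.7 across
   seeds. Recovery is comfortable at β ≥ 1–2.

Other limitations: the trustee side is a schedule, not an agent; prediction
errors live on the probability scale only (no euro-scaled variant); no
hierarchical or Bayesian estimation (fits are strictly per-participant MLE);
and the IAT, transfer-rating task, and the original mixed-model regressions
are outside this package's scope.
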