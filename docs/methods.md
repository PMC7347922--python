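# Methods

## Task model

Four options cross reward r ∈ {20, 80} points with handling time t ∈ {2, 8} s
(the final handling second displays the reward). Each trial opens with a 2-s
encounter screen; accepting costs the handling time and pays r, rejecting
costs nothing beyond the encounter, and a missed response costs an 8-s
timeout. Offers are drawn as shuffled 7-trial cycles: rich = {best×4, each
other×1}, poor = {worst×4, each other×1}; a degenerate block offers only the
worst option. Sessions are two blocks of 900 s ("exp1"), two of 600 s
("exp2"), or three of 600 s with the single-option block between rich and
poor ("exp3"); block order is counterbalanced (RichPoor/PoorRich). Blocks are
terminated by the clock: a trial may start any time before the block duration
elapses and runs to completion, so blocks can overrun by at most one trial;
trials are contiguous in session time (no modelled inter-block gap).

Forced-choice trials (attention checks) fill a deterministic quota of one per
consecutive four-trial window at a uniformly random position, making the 25%
fraction exact over complete windows. The forced direction is accept or
reject with probability 0.5 each (configurable); both choices are possible
regardless of the option shown.

The MVT solver enumerates all acceptance subsets; the long-run rate of a
policy is (Σ counts·accepted rewards) / (Σ counts·encounter + Σ
counts·accepted handling) per cycle, and the returned set is the
MVT-consistent one {i : r_i ≥ ρ*·t_i}, ties accepted.

## Learning models

ρ (points/s) is updated by ρ ← ρ + α(r_t − ρ) at every elapsed second —
encounter, handling and timeout seconds alike (cadence configurable to
handling-only). The final handling second of an accepted option carries two
updates: delay (δ = 0 − ρ) then reward (δ = r_i − ρ); the order can be
swapped. The symmetric model uses one α; the asymmetric model applies α⁺ on
reward seconds (r_t > 0) and α⁻ otherwise. With α⁺ = α⁻ the models coincide
exactly (nesting is preserved by the shared code path).

Choice: P(accept) = 1/(1 + exp(β₀ − β₁(r_i − ρ·t_i))), evaluated after the
final encounter second's update (the convention could equally be "before";
it is fixed, documented, and identical in simulation and replay).
Probabilities are computed in log-sum form, stable for extreme arguments.

ρ is initialised to the session's average reward rate assuming every offer is
accepted — the unweighted arithmetic mean of the per-block accept-all cycle
rates (7.74 pts/s for exp1) — and carries across blocks without resetting.
The accept-all policy is a convenience default (configurable), not a process
claim.

One numerical consequence worth knowing: because the reward second carries
two updates, the delta rule's stationary mean is reward-per-*update*, not
reward-per-second. Under accept-all on the worst option the fixed point is
20/11 ≈ 1.82 pts/s against a true per-second rate of 2.0 — a ~9% systematic
understatement that is a property of the update scheme itself.

## Likelihood replay and kernels

`replay_loglik` deterministically rebuilds ρ from a trial log (forced and
missed trials contribute their elapsed seconds and rewards) and sums log
P(choice) over scored trials. The per-second recursion is sequential, so it
is implemented as a jitted kernel (numba, with a pure-Python fallback) that
applies the identical delta-rule arithmetic in the identical order as the
simulator; simulator and replay traces agree bit-for-bit. A forward-mode
companion kernel carries dρ/dα⁺ and dρ/dα⁻ through the recursion to give
analytic likelihood gradients (verified against central differences to ~1e-9
relative error).

Forced-trial choices are *excluded* from the likelihood by default
(`include_forced=True` reverses this). Rationale: mandated responses are not
generated by the softmax, and scoring them misspecifies the model — in
generate-and-refit checks, inclusion biased β₀/β₁ group means by roughly a
factor of three and broke the null calibration of the learning-bias z-test
(rejections at ~60-70% instead of ~5%, with a systematic negative bias),
while exclusion recovers all four parameters and calibrates the test. Forced
trials always shape the ρ trajectory either way. Missed trials never carry a
likelihood term; synthetic subjects never miss.

## Synthetic cohorts

Subject parameters are drawn independently from Gaussian group distributions
in the transformed space (logit for learning rates, identity for β₀, β₁) and
mapped back. Transformed means are the images of the reference group-average
estimates per experiment variant. Between-subject spread has no reference
value: β₀/β₁ SDs are backed out of the 95% CIs of the mean accompanying the
estimates (sd = SEM·√N), and the
learning-rate logit SD is set to 0.63, calibrated once so that ~90% of
(α⁺, α⁻) draws preserve α⁺ > α⁻ — the typical individual-level
prevalence of the positive bias. These SDs are calibrated defaults, not
measurements; treat cohort-level variance statements accordingly.

Seeding: the cohort master seed spawns one stream for parameter draws and one
per subject, so cohorts are reproducible and subjects independent. Condition
allocation is deterministic by subject index (parameters are i.i.d., so this
is distributionally identical to random assignment).

What the generator does *not* emulate: missed responses, reaction times,
attrition, within-subject parameter drift, and any deviation from the softmax
choice rule. Passing recovery tests therefore certify the estimation
machinery under the model's own assumptions, not the model's adequacy for
human data.

## Hierarchical fitting

Per-subject MAP estimates maximise log-likelihood plus a Gaussian group prior
in the transformed space (multistart L-BFGS with analytic gradients; default
5 starts, first at the prior mean). The Hessian of the negative log joint is
obtained by central finite differences of the gradient (step 1e-4) and feeds
a Laplace approximation of the subject's marginal likelihood.

EM alternates the subject-level E-step with the closed-form M-step
(group mean = mean of MAPs; diagonal group variance = mean of squared
deviations plus Laplace variances, floored at 1e-4), to tolerance 1e-3 on the
group mean, max 200 iterations; after the first iteration subjects are
warm-started from their previous MAPs. The covariance of the group-mean
estimate — used by the learning-bias contrast — is
(1/N²)·Σᵢ[Hᵢ⁻¹ + (θᵢ−μ)(θᵢ−μ)ᵀ], i.e. sampling variance of the mean with the
Laplace posterior uncertainty added back (MAPs are shrunken, so the raw
between-subject scatter alone would understate it).

LOOcv refits the group prior to the cohort minus each subject (EM
warm-started from the full-cohort posterior, capped fold iterations) and
scores the held-out subject by the negative Laplace log marginal likelihood
under that prior. Scores are compared between models with a paired two-tailed
t-test. The learning-bias z-test evaluates the contrast α⁺ − α⁻ on the
transformed-space group means (z = c'μ/√(c'Σ_μ c)); the logit is monotone, so
the sign agrees with the natural-space difference.

Degenerate-input behavior: non-positive Hessian curvature is eigenvalue-
clipped at 1e-8 before inversion/log-determinants; zero-variance score
vectors are flagged degenerate rather than producing spurious t statistics;
priors with non-positive variance are rejected.

## Behavioral analyses

Acceptance tables exclude forced and missed trials; the collapsed
"intermediate" rate pools LDLR and HDHR trials (a percentage of decisions,
not a mean of two rates). Difference scores are the per-subject mean over
the four options of (poor − rich) acceptance. The previous-offer analysis
partitions current free-trial responses by the option offered on the
immediately preceding trial (forced offers count as history; the first trial
of each block is excluded; current forced trials are excluded by default).

The mixed-design repeated-measures ANOVA is a classical sums-of-squares
decomposition supporting one or two within factors and an optional
between-subject factor, each within effect tested against its own
subject-interaction error term, with partial η² = SS_effect/(SS_effect +
SS_error). It requires a balanced within design (one value per subject per
cell); group sizes may differ (weighted-means solution). It is implemented
in-package because no installed library covers two within factors plus a
between factor; it is verified against statsmodels' AnovaRM (pure within)
and pingouin's mixed ANOVA (one within + between) on the designs those
cover. Sphericity corrections are deliberately not applied.

Exclusion screens are the standard a-priori data-quality criteria: ≥20 missed
responses, ≥10 incorrect forced responses, worst option accepted more often
than the best (free trials), or accepting/rejecting every free trial; the
"did not finish" criterion is structurally false for synthetic data.

## Simulation experiments and problem sizes

The order-effect experiment simulates replicate cohorts (default 1000 × 40
subjects, half per block order), averages per-subject difference scores
within order condition, then across replicates. The asymmetry-cost
experiment (default 500 replicates) gives every subject its model's
group-average learning rates and β₁ with β₀ = 0, counts free-trial earnings,
and compares the models with an independent t-test; subject slots share
seeds across models, so identical parameterisations tie exactly. The
recovery experiment regenerates cohorts, refits them, and reports group-mean
errors, the Spearman correlation of true vs recovered per-subject bias, the
bias-sign recovery rate, the z-test (null calibration when generating
symmetrically), and optional LOOcv model selection.

The test suite runs the same pipelines at reduced sizes chosen as the
smallest that leave the qualitative contrasts far from their decision
boundaries: 50 replicates for the order effect, one 40-subject cohort for
recovery/LOOcv, fifteen 20-subject cohorts for null calibration. Replicate
counts scale Monte Carlo error only; directions are unaffected.

## Known limitations

- The Laplace approximation can misstate marginal likelihoods for
  near-boundary or weakly identified subjects; an importance-sampling
  refinement is a natural extension and is not implemented.
- The group covariance is diagonal; parameter correlations (e.g. between β₀
  and the learning rates) are absorbed into the means only.
- Variants that learn r_i and t_i from experience are out of scope and would
  slot in as alternative update rules behind the same replay interface.
- Published group-mean parameter tables are the only anchor for the
  generator; fitted estimates from the original human data cannot be
  reproduced here and are not targeted.
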