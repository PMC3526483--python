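# Methods

## The model

`modmind` decomposes performance variation in a multi-species cognitive
task battery. Every response a subject gives on a task is assumed to be
driven by a latent performance variable

```
theta[i,k] = mu_k + a_s(i) + b_s(i),d(k) + c_i + e_i,d(k) + eps[i,k]
```

where `mu_k` is a task-difficulty intercept, `a` a species random effect
(a domain-general, "G-like" factor at the species level), `b` a
species-by-domain interaction (the domain-specific signal), `c` an
individual effect, `e` an individual-by-domain interaction, and `eps` a
latent error. All random effects are zero-mean Gaussian with their own
variances; the error variance is either one scalar shared by all tasks
("constant", label `0`) or task-specific with the per-task variances tied
together hierarchically through a shared inverse-gamma scale with a Gamma
hyperprior (label `J`, hierarchy depth 1).

Observation layers:

* **Binomial tasks** — each of the task's `n_trials` outcomes is
  Bernoulli with success probability `Phi(theta)` (probit link). In the
  augmented representation each trial carries a Gaussian variable
  `z ~ N(theta, 1)` whose sign is the outcome; the unit trial noise fixes
  the latent scale.
* **Rank tasks** — the real-valued scores (ratio measures, indifference
  points) enter only through their within-task weak ordering across
  subjects: rank 1 is best and corresponds to the largest latent value,
  and tied ranks impose no constraint. The likelihood is therefore
  invariant to any strictly increasing transform of the scores. Because
  an ordering carries neither location nor scale information, rank
  tasks' intercepts are fixed at zero and their latent error scale is
  fixed at 1 (the standard rank-likelihood convention); their ordering
  still informs every shared random effect. Leaving these free is not
  merely wasteful — a shared error variance lets the order-constrained
  latent block compress onto the linear predictor (any ordering is
  satisfiable with arbitrarily small gaps) and certify a near-zero error
  variance, a degenerate mode the augmented sampler cannot leave.

The reported quantity is the *variance proportion*: per posterior draw,
each active variance divided by the sum of active variances (for `J`
variants the error component enters as the mean of the per-task
variances). Proportions are scale-free, which matters because the
absolute latent scale is only identified through the unit trial noise.

Nine variants form the comparison grid — effect subsets {}, {S}, {S,SD},
{S,I}, {S,SD,I,ID} crossed with the two error structures, minus the
no-effect/task-specific cell: `M0 (0,0)` … `M8 (SDID,J)`.

## Gibbs sampler

One sweep updates, in fixed order: trial augmentation variables
(truncated normals); rank-task latents (truncated normals bounded by the
neighbouring rank groups — the chain of groups is updated in two
alternating parity blocks, which are conditionally independent because
only adjacent groups constrain each other, and tied subjects are
excluded from each other's bounds); the error variance *jointly with*
the binomial-cell latents — the variance is drawn first from its
conditional with those latents integrated out analytically (given a
cell's augmentation vector, marginalizing its latent leaves an
equicorrelated normal, so the variance has a cheap one-dimensional
target sampled by slice sampling in log-variance), then the latents from
their conjugate normal (precision `1/sigma2_E + n_trials`); each active
effect block (Normal, precision = prior precision + summed residual
precisions); task intercepts; effect variances (inverse gamma, or the
half-Cauchy scale-mixture pair); and, under `J`, the shared error
scale. The blocked error-variance/latent update matters: the naive
conditional pair forms a near-absorbing feedback loop (a small error
variance pins the latents to the model mean, which in turn certifies a
small error variance) that can trap entire chains in a degenerate mode.

Entities are iterated in sorted canonical order, so a fit is
bit-reproducible from a seed regardless of input row order. The
truncated-normal sampler is inverse-CDF, always evaluating the CDF in
the numerically small tail (`ndtr(-x)`), which keeps truncation regions
exact out to ~36 SDs; beyond that it switches to Robert's exponential
rejection sampler, so even the extreme-variance excursions a Cauchy
prior tail permits never produce draws that violate their constraint.

Initialization is data-informed by default: task intercepts at the
empirical probit of task success rates, effects at zero, variances at
0.5, rank-task latents at normal scores consistent with the observed
ordering. A `prior_draw` mode exists for the correctness checks below.

**Correctness oracles.** Three independent routes guard the sampler:
(1) conjugate full conditionals are compared coefficient-by-coefficient
against finite differences of the Gaussian-layer joint log-density;
(2) the rank-latent update was validated against brute-force rejection
sampling of order-constrained normals; (3) successive-conditional
("getting it right") simulations alternate the Gibbs kernel with a
data-regeneration step and compare chain moments (or, for the
half-Cauchy prior, tail probabilities) with exact prior values. One
subtlety the last check exposed: an observed ranking is a deterministic
coarsening of the rank-task latents, so the data step must redraw those
latents together with the ordering from their conditional given the
linear predictor — otherwise the ordering is absorbing and the chain
quietly targets the posterior given the initial ranking.

## Priors

Effect variances default to a half-Cauchy prior on each effect SD
(scale 1, i.e. the total latent scale), implemented as a conjugate
inverse-gamma scale mixture so the sampler stays fully Gibbs. The choice
is driven by calibration: this battery mixes components living on very
different scales — a weakly identified 7-level species variance near
0.17 next to individual terms near 0.01 — and in calibrated recovery
experiments no single inverse-gamma scale serves both (a small scale
lets the species share collapse into the interaction row-means, a large
one inflates the near-zero components; the half-Cauchy's mass at zero
plus slow tail recovered every component essentially unbiased except the
structurally soft one below). Plain Inverse-Gamma(shape, scale) priors
remain available as `Priors(effect_var_prior="inv_gamma")`. The error
variance keeps Inverse-Gamma(1, 0.01); with ~1,400 binomial cells the
prior is immaterial. Task intercepts get Normal(0, 100); rank-task
intercepts are fixed at zero. Under `J`, per-task variances are
Inverse-Gamma(2, b_E) with `b_E ~ Gamma(1, 1)`. A sensitivity test
checks that the recovered species share moves by < 0.08 across these
prior families.

Even with weak priors, the individual-by-domain variance is the softest
spot of the design: its 396 coefficients each see only the 2–6 tasks of
one domain, and the latent noise of few-trial cells flattens the exchange
ridge between that component and the error term. Its posterior mean is
therefore right-skewed upward (an independent REML cross-check on
probit-transformed cell scores shows the same behaviour), which is worth
remembering when reading small interaction shares.

## Pivotal-discrepancy model checking

Model adequacy is assessed by targeted discrepancy statistics with known
null reference distributions, not by information criteria. For each
posterior draw, standardized latent residuals `(theta - fitted mean) /
sigma_E` are aggregated into pivots aimed at one assumption:

* **missing effect (level L)** — group means of the standardized
  residuals over L's groups, scaled by `sqrt(n_group)`;
* **equal error variances** — per-task sums of squared standardized
  residuals, mapped through their chi-square CDF;
* **domain assignment** — residuals centred within species-by-domain
  groups under the audited map, then species-by-task cell means scaled by
  their null SEs (a misassigned task shows up as a species-specific
  deviation its domain effect cannot absorb; tasks that exhaust their
  domain cell drop out).

Missing-effect and domain pivots are mapped through the chi-square(1)
probability transform onto a one-sided magnitude scale: under the null
this is again exactly standard normal (measured pivot SD 1.00), while a
violation inflates pivot magnitudes of either sign, so the signal
accumulates in the upper bins instead of splitting across both tails.
The pivots are then dropped into `n_bins` equal-probability normal cells
(default `ceil(min(10, sqrt(#pivots)))`) and summarised by the classic
count statistic `sum (m_b - G p_b)^2 / (G p_b)`, referenced to
chi-square(n_bins - 1).

The posterior trajectory of the statistic yields a feasible *upper bound*
on the PPP p-value: with `q` the gamma-quantile (default gamma 0.5) of
the draws, `bound = min(1, P(chi2 >= q) / gamma)`. The bound is valid for
any fixed gamma; by convention a bound below **0.25** — not 0.05 — flags
significant lack of fit. Because the residual pivots use fitted
parameters they are mildly under-dispersed under the null, making the
checks conservative.

**Selection workflow**: fit every grid model (grid order = parsimony
order), check each for every effect it omits plus, for constant-error
variants, the equal-variance assumption, and select the first model with
no bound below 0.25. If everything is flagged, the model whose worst
bound is largest is returned with an explicit warning.

## Synthetic data generator

`generate` draws the effects and error i.i.d. Gaussian in a documented
fixed order (species, species-by-domain, individual,
individual-by-domain, cell error, then binomial trials cell-major) from
one seeded RNG stream, builds `theta`, emits Bernoulli(`Phi(theta)`)
trials for binomial tasks and the latent value itself as the rank-task
score, and respects the design's participation set. Variance inputs are
most conveniently given as proportions of a total latent scale; the
default total of 1 places effect variances on the scale of the unit
probit trial noise (the absolute scale is a free choice; proportions are
invariant to it). Task intercepts default to 0 — real batteries differ in
difficulty, and the model estimates `mu_k` precisely to keep task
difficulty out of the domain effects, but recovery experiments do not
need non-zero intercepts.

`calibrate_realized=True` rescales each drawn effect vector so its sample
variance equals the nominal component variance. Recovery experiments use
this: a 7-level species effect drawn i.i.d. realizes a variance that is
routinely off by half, and without calibration a recovery experiment
mostly measures that realization luck. The default stays plain i.i.d.

What the generator does *not* emulate: real species' actual performance
levels, experimenter effects, learning across trials, or any
non-Gaussian effect structure. Passing recovery tests therefore show that
the estimator recovers the model's own generative structure at realistic
design sizes — not that real batteries satisfy that structure.

## Experiment sizes and numerical choices

Routine fits and all recovery experiments use the desk preset — 2,000
burn-in plus 20,000 iterations, thinned by 5 (4,000 stored draws; ~25 s
per fit on the full battery) — with split R-hat below 1.05 for every
variance parameter. A full-precision preset (50,000 + 3,000,000) exists
behind `McmcConfig.full()`. Discrepancy and selection experiments use
300 + 1,500-iteration fits, which calibration tests show are adequate for
the binned statistics. Recovery experiments average five independent
generation/fit replicates; power experiments for the discrepancy
machinery generate a decisively large omitted interaction (species 0.10,
species-by-domain 0.30, error 0.60), since at small effect sizes the
per-replicate realized effect — not the test — dominates the outcome.

Degenerate inputs are rejected early with typed errors: effects requiring
fewer than 2 levels, rank tasks with no scores, maps not covering the
task set, individual effects in the species-level re-analysis. Ties in
rank tasks use competition ranking ("1, 1, 3"); only the weak ordering
reaches the likelihood, so any tie convention with the same ordering is
equivalent. Species-level means for the ranks-of-means re-analysis are
unweighted means over subjects of per-subject success proportions (or
scores); because averaging precedes ranking, that analysis is invariant
to positive affine — not arbitrary monotone — rescalings of rank-task
scores.

## Known limitations

* The individual-by-domain variance is weakly identified at this design's
  trial counts (see Priors); treat small interaction shares as upper-ish
  estimates.
* The discrepancy groupings are this package's construction of the cited
  pivotal-binning framework; other targeted groupings are possible and
  would give different absolute bounds.
* The equal-error-variance check has limited power against mild
  task-specific heteroscedasticity (its pivots are two-sided by nature).
* Rank tasks contribute no information about the latent scale or
  location, only about ordering; their intercepts and error scale are
  fixed by convention, and the error-variance estimate comes from the
  binomial tasks alone.
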