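# Methods

This note documents the models, estimation machinery, and design choices
behind `pragint`, in the spirit of a statistical package's model
documentation. Nothing here states an empirical result beyond what the
test suite and `scripts/acceptance.py` compute.

## 1. The listener models

The world is a two-alternative reference game: referents
{novel, familiar}, utterances {novel word, familiar word}, and two
possible lexica for the literal listener — *known* (the familiar word is
true of the familiar object only) and *unknown* (the familiar word means
nothing). The novel word is literally true of both objects in every
lexicon, so everything it conveys is pragmatic.

All listener quantities are computed by exact enumeration; there is no
sampling anywhere in `pragint.rsa`. For the novel word the pragmatic
listener reduces to the closed form

    P_L1(novel) ∝ prior · [theta · 1 + (1 − theta)/2]
    P_L1(familiar) ∝ (1 − prior) · [theta · 0.5^alpha / (0.5^alpha + 1) + (1 − theta)/2]

which the vectorized kernel (`p_novel_pragmatic`) evaluates for whole
arrays; the scalar API enumerates the same structures object by object,
and the two are cross-checked against each other and against an
independent brute-force oracle in the tests.

Lexical uncertainty is marginalized at L1 (the listener mixes speakers
addressing knowledgeable vs ignorant literal listeners with weight
theta). Marginalizing inside S1 instead is a coherent alternative the
package does not implement; with two lexica and two utterances the two
choices differ only at intermediate theta, and the L1 mixture is the one
that reproduces the intended limiting behaviors exactly (theta = 0 gives
the prior; the mutual-exclusivity inference strengthens monotonically in
theta and alpha — both are property-tested).

Corner conventions, chosen so every distribution is defined everywhere:
0^alpha = 0 for alpha > 0 and 0^0 = 1 (making alpha → 0 continuous); an
utterance true of no referent yields a uniform L0; an all-zero speaker
score vector yields a uniform speaker; a zero-mass L1 numerator yields a
uniform posterior. Negative alpha is a domain error.

## 2. Task likelihoods

Each task maps realized parameters to a Bernoulli success probability
(responses coded 1 = novel / discourse-new / correct):

| task | probability | informs |
|---|---|---|
| mutual exclusivity | P_L1(novel) with flat prior | alpha, theta |
| discourse novelty | rho | rho |
| comprehension (6AFC) | theta + (1 − theta)/6 | theta |
| production | theta · gamma | theta, gamma |
| combination | P_model(novel) with prior rho (congruent) or 1 − rho (incongruent) | all |

Comprehension is modeled on binarized correctness with a 1/6 guessing
floor rather than as a 6-way categorical choice; the two are equivalent
for the correctness likelihood and the distractor identities carry no
model content. Production scoring (acceptable-label lists) happens
upstream of the package; the trial table carries 0/1. Missing trials are
simply absent rows; likelihoods sum over what is present. A predicted
probability of exactly 0 or 1 contradicted by a response contributes
−inf to the log likelihood (a visible flag) instead of raising.

## 3. The hierarchy

Trajectories regress each parameter family on a latent developmental age
anchored at standardized chronological age (youngest child = 0 years;
the fit stores the reference so held-out predictions reuse the same
origin). Units: latent and chronological ages in years; theta/rho
coefficients on the logit scale; alpha coefficients on alpha's natural
scale (rectified at zero so the speaker exponent stays admissible —
this also preserves the alpha = 0 lesion as a limiting case).

**Latent layout.** The model has exactly eleven population-level
parameters: (mu0, mu1, sigma0, sigma1) for the item trajectories,
(b0, b1, sigma_i) for alpha and for rho, and gamma. Because theta and
alpha are estimated jointly from the same tasks, the default layout
(`latent_mode="joint_me"`) gives each child two latents: one shared by
the theta and alpha families (dispersion sigma_i_alpha) and one for rho
(dispersion sigma_i_rho). This keeps every latent's dispersion a defined
model parameter. Alternatives are available: `"separate"` adds a third,
theta-specific latent whose dispersion is a fixed configuration value
(`sigma_theta_latent`, default 0.5 — deliberately not sampled, since no
data would identify it separately), and `"single"` shares one latent
across all families. Per-child theta dispersion beyond the latent age
arises only through the item trajectories; there is no extra
child-by-item noise term.

**Hyperpriors** (configurable via `HyperpriorConfig`): Normal(0, 2) on
all trajectory intercepts and slopes — weakly informative at the scale
of logistic coefficients — half-Normal(1) on all dispersions, and
Uniform(0, 1) on gamma.

## 4. Posterior sampling

`fit_part1` targets log prior + joint Part-1 log likelihood with an
adaptive Metropolis-within-Gibbs sampler written for this model's
structure (the contract is the target density, split-R-hat/ESS
diagnostics, and seed determinism — not any particular algorithm):

- **Blocked conditional independence.** Given population parameters,
  children are independent, and so are items; all child latents in a
  family (and all item trajectories) are proposed simultaneously and
  accepted per child (per item).
- **Non-centered latents.** Latents and item effects are sampled as
  standardized deviates, so dispersion updates move realized parameters
  through the likelihood — the usual remedy for weakly identified
  hierarchical scales.
- **Interweaving for the item moments.** Items are data-rich (about 180
  observations each), where the centered parameterization mixes better;
  the theta population moments therefore get an additional
  centered-coordinate update per sweep with realized item effects held
  fixed (ancillarity–sufficiency interweaving).
- **Joint intercept/slope proposals.** Age is not centered (the intercept
  is pinned to the youngest age by design), so each trajectory's
  intercept and slope are strongly anticorrelated; the three pairs get
  2-D random-walk proposals with a warmup-estimated covariance.
- **Adaptation** of every proposal scale is Robbins–Monro toward 0.44
  (scalars) / 0.3 (pairs) acceptance, active during warmup only, so the
  sampling phase satisfies detailed balance. Dispersions are sampled on
  the log scale and gamma on the logit scale with Jacobian corrections.

Defaults (3 chains × 1500 draws after 1500 warmup) converge on
study-scale data (N = 60, worst split-R-hat ≈ 1.03, minimum
hyperparameter ESS near 100) in well under a minute on one CPU. A fit
whose worst R-hat exceeds the threshold (default 1.05) is flagged in
its diagnostics, never silently accepted. Correctness of the sampler is
verified two ways: posterior means against exact 3-D grid integration in
a one-child, one-item configuration with all population parameters
pinned (agreement well within 0.05), and hyperparameter recovery from
synthetic data at study scale.

## 5. Prediction and evaluation

For each combination trial the Part-1 posterior induces a distribution
over the model's choice probability. The MAP of that distribution is the
mode of a Gaussian kernel density (Silverman bandwidth, 512-point grid
on [0, 1]); degenerate draw sets return their common value and grid ties
break toward the posterior mean — a deterministic rule given draws.
Binary predictions are weighted coin flips on the MAP; because the flip
is stochastic, the match rate is recomputed over 1000 runs by default and
the first run is reported alongside the run distribution. Match rates
are compared to chance (0.5) with a default-prior JZS Bayes factor
(Cauchy scale 0.707) over per-child proportions, plus a bootstrap 95% CI
of the mean. Group-level fit is the Pearson correlation between observed
choice proportions and MAP predictions aggregated by (trial, whole-year
age bin); constant predictions make r undefined and are flagged.

## 6. Model comparison

Evidence for a model is its posterior-predictive marginal likelihood of
the combination data: the Part-2 likelihood averaged over Part-1
posterior draws, computed per child with log-sum-exp. All three models
share the same Part-1 fit and differ only in the parameter-to-prediction
map, so this integral is the natural out-of-sample evidence; group-level
evidence is defined as the sum of per-child log marginal likelihoods
(asserted as an invariant). Monte-Carlo error is reported as the SD of
the log-mean-exp over bootstrap resamples of draws — relevant when a
Bayes factor sits near a threshold. Censuses use the conventional
1/3/10/100 thresholds, strictly greater.

## 7. The synthetic-data generator

`simulate` mirrors the study design: N = 60 children by default, ages
uniform on [3.06, 4.93] (the empirical age distribution is not public;
uniform over the observed range is the simplest defensible stand-in and
is configurable), 16 familiar items, 16/12/16/16 sensitivity trials and
8 + 8 combination trials with a fixed item-to-condition assignment shared
by all children (even-indexed items congruent — a stand-in for the
study's matched pairs). Trajectory truth defaults to the reported
population modes: alpha (1.56, 1.18), rho (1.96, −0.43), theta
(−1.21, 1.10). The dispersions and gamma are **not** reported quantities;
the defaults (0.5, 0.25, 0.5, 0.5, gamma = 0.8) are placeholders chosen
once to produce visible individual differences at these trial counts,
exposed in `NON_REPORTED_DEFAULTS` and overridable.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: drop-out and inclusion rules, side/order
counterbalancing, response times, perceptual salience or familiarity
effects on the prior, any deviation of real children from the
generating model (e.g. heuristic responders), and non-uniform age
distributions. Recovery and identifiability results are
internal-consistency checks of the pipeline, not evidence about
children.

## 8. Known limitations

- Evidence is conditional on the Part-1 fit; prior-marginal likelihoods
  (bridge/nested sampling) are out of scope.
- No deeper recursion (L2/S2), more referents/utterances, or continuous
  meaning spaces.
- The alpha trajectory's intercept/slope pair is weakly identified from
  16 binary trials per child; its posterior is wide at study scale (the
  shared-latent layout and the rectification make this benign for
  prediction).
- Longitudinal (within-child over time) modeling is not attempted.
- `latent_mode="single"` leaves sigma_i_rho informed only by its prior;
  its posterior then just reproduces the prior, which the diagnostics
  make visible.

## 9. Problem sizes used by tests and the acceptance script

The test suite fits one shared study-scale world (N = 60, 3 × 1200
draws), several small fits (N ≤ 6), and a pinned one-child fit for the
grid cross-check; the acceptance script uses N = 60 with 3 × 1500 draws,
600 retained draws for prediction, and 1000 coin-flip runs. These sizes
were chosen so the full pipeline, including repetition, runs comfortably
on a single CPU while keeping Monte-Carlo error far below the effect
sizes being checked.
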