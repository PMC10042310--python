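# pragint

Rational-integration models of pragmatic word learning, built to predict
**individual children's trial-by-trial behavior** — not just group averages.

When a speaker uses a novel word in a scene with a novel and a familiar
object, a child can draw on at least three information sources: their
semantic knowledge of the familiar word (mutual exclusivity), their
expectation that speakers communicate informatively, and the common ground
shared with the speaker (which object is new to the conversation). This
package implements a Rational Speech Act (RSA) account in which these
sources are integrated by Bayesian inference, with child-specific
sensitivity parameters, and tests that account by out-of-sample prediction
and Bayes-factor comparison against lesioned alternatives. It is aimed at
computational cognitive modelers and developmental researchers who want a
fully testable, end-to-end pipeline for individual-differences RSA
analyses.

## The model

A pragmatic listener L1 infers the referent *r* of an utterance *u* by
inverting a speaker model and weighing a common-ground prior:

    P_L1(r | u; rho_i, alpha_i, theta_ij)  ∝  P_S1(u | r; alpha_i, theta_ij) · P(r | rho_i)

The speaker S1 chooses utterances in proportion to their informativity for
a literal listener L0, raised to a power alpha (expected speaker
informativeness):

    P_S1(u | r)  ∝  P_L0(r | u; theta_ij)^alpha_i

L0 interprets words by their lexicon; the listener is uncertain whether
the familiar word has been acquired, holding the "known" lexicon with
probability theta_ij (lexical uncertainty). Two lesioned listeners serve
as alternatives: **no speaker informativeness** (alpha = 0; the posterior
is just the prior P(r | rho_i)) and **no common ground** (uniform prior;
pure mutual-exclusivity reasoning). All three are computed by exact
enumeration over the two-object, two-utterance, two-lexicon world
(`pragint.rsa`).

Child-specific parameters follow hierarchical developmental trajectories
on a latent age *i* anchored at chronological age *k* (standardized so the
youngest child is 0):

    theta_ij = logistic(b0_theta[j] + i · b1_theta[j]),  b0/b1_theta[j] ~ N(mu, sigma)
    alpha_i  = max(0, b0_alpha + i · b1_alpha),          i ~ N(k, sigma_i_alpha)
    rho_i    = logistic(b0_rho + i · b1_rho),            i ~ N(k, sigma_i_rho)

Part 1 estimates these from four tasks (mutual exclusivity, discourse
novelty, word comprehension with a 1/6 guessing floor, word production
with a shared retrieval probability gamma) by MCMC (`pragint.fitting`).
Part 2 pushes the posterior through each listener to predict every trial
of a held-out combination task, binarizes via a MAP-weighted coin flip,
and compares models by posterior-predictive marginal likelihood
(`pragint.predict`, `pragint.compare`). A synthetic-data generator
(`pragint.simulate`) emulates the full study design from known ground
truth so every stage is testable.

## Worked example

`examples/` contains one narrative script per capability. Running
`python examples/04_predict_and_compare.py` (30 simulated children) prints:

```
held-out match rates (first coin-flip run, mean over 500 runs):
  rational: 0.762 (mean 0.748)
     no_cg: 0.537 (mean 0.535)
     no_si: 0.748 (mean 0.738)

per-child Bayes-factor census (fraction of children with BF above):
  rational_vs_no_cg: >1: 90%  >3: 70%  >10: 60%  >100: 47%
  rational_vs_no_si: >1: 60%  >3: 27%  >10: 10%  >100: 0%
```

The match rate is the share of combination trials where the binarized
model prediction equals the child's response; the census is the fraction
of children whose per-child Bayes factor favors the rational-integration
model beyond each conventional evidence threshold. Because these
responses were generated by a rational-integration listener, that model
correctly out-predicts both lesions.

`python examples/03_fit_hierarchy.py` shows parameter recovery, e.g. the
common-ground trajectory intercept (truth 1.96 on the logit scale,
choice probability logistic(1.96) = 0.88 at the youngest age) recovered
with 90% CI [1.81, 3.04], and prints the implied developmental curves.

There is also a thin CLI mirroring the pipeline stages:

```sh
pragint simulate --scenario paper_scale --out data/
pragint run --scenario tiny --out out/ && pragint report out/
```

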