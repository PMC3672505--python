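# Methods

## The model

`ltarisk` implements categorical latent variable mixture modeling for
injection-risk behavior in a two-arm behavioral intervention trial with
young injection drug users.

**Measurement model (latent class analysis).** Seven 3-category ordinal
indicators x_1..x_7 (sharing syringes, cookers, cottons, rinse water;
using a new sterile syringe to divide drugs and bleach-cleaning, both
reverse-scored; number of syringe-sharing partners) are modeled as
conditionally independent multinomials given a latent class k:

    P(x) = Σ_k λ_k Π_j π_{kj x_j}

with class proportions λ and item-response probabilities π. The
parameterization is unrestricted per-class multinomial probabilities (not
ordinal threshold logits); "threshold" invariance constraints are
therefore expressed as equality constraints on π tables, which carries the
same invariance semantics with a simpler, fully identified parameter
space.

**Transition model (latent transition analysis).** Two waves (baseline and
6-month follow-up) are linked by a first-order Markov structure. With
trial arm g observed (a "known class"), the likelihood of participant i
in arm g is

    Σ_a Σ_b δ_a τ_g[a,b] Π_j π^{(1)}_{aj x1_j} Π_j π^{(2)}_{bj x2_j}

where δ is the baseline class distribution (shared across arms, by
randomization) and τ_g the arm-specific transition matrix. Constraint
toggles: full time invariance (π^{(1)} = π^{(2)}, the accepted model),
partial non-invariance (selected classes' wave-2 tables freed), and
arm-specific measurement (for the arm-invariance comparison).

**Missing data.** Missing items are marginalized out of the row's factor
(full-information ML, valid under MAR). A participant lost to follow-up
contributes only the wave-1 factor: the follow-up class and items are
summed out. Because the generator's attrition depends only on (baseline
class, arm), attrition is ignorable for these fits. A row with *all*
items missing gets a uniform posterior with a warning — a deliberate
"no information" contract rather than the prior λ.

## Estimation

EM with random multi-start. The E-step computes pattern-collapsed
responsibilities (LCA) or the N×K×K joint posterior over class pairs
(LTA); the M-step is closed-form multinomial updating with equality
constraints enforced by pooling sufficient statistics across the
constrained tables. Per-iteration observed-data log-likelihood ascent is
a tested contract. Convergence: relative log-likelihood change below
`tol` (default 1e-7), `max_iter` 1000. Estimated probabilities are
floored at 1e-6 and renormalized to keep the log-likelihood finite when
the truth has structural zeros.

LTA starts are warm-started from a wave-1 LCA fit (δ and π) with
noise-perturbed uniform transition rows; further starts perturb the warm
start. Fitting a general model `init`-ialized from a nested restricted
fit guarantees the nested log-likelihood ordering by EM monotonicity.

**Label switching.** Classes are relabeled to a canonical order:
ascending expected syringe-sharing score, ties broken by cooker sharing.
Scores are snapped to a 0.25 grid so the two syringe-abstinent classes
(low-risk and equipment-sharing) tie reliably and the cooker item
separates them. This reproduces the low / equipment / moderate / high
ordering regardless of start seed. Modal assignments break posterior ties
toward the lowest class index.

**Diagnostics.** Relative entropy E = 1 − Σ(−p log p)/(N log K); K×K
average-posterior-by-modal-class table; AIC, BIC, and sample-size-adjusted
BIC with n* = (N+2)/24. The bootstrap likelihood ratio test (K vs K−1)
simulates `n_boot` datasets from the fitted (K−1)-class model, refits
both, and applies the add-one-corrected p-value; non-converged replicates
are dropped and counted (warning above 5%). The replicate count is
configurable (default 100) since no canonical value exists.

**Scaled difference test.** `sb_scaled_difference` implements the
Satorra-Bentler difference statistic TRd = −2(L0 − L1)/cd with
cd = (d0·c0 − d1·c1)/(d0 − d1), erroring when cd ≤ 0 (the known pathology
of the uncorrected form). `scaling_correction` computes c = tr(A⁻¹B)/d
with per-observation scores obtained analytically through Fisher's
identity (E-step responsibilities) and A as a central-difference Jacobian
of the total score in an unconstrained multinomial-logit
parameterization; with a correctly specified model c ≈ 1, a tested
property.

## Effects stage

Classify-analyze, as in the trial: modal baseline class and modal
follow-up low-risk membership are treated as observed; classification
uncertainty is *not* propagated (a known limitation of the 2-step
practice). The outcome model is an ML logit of follow-up low-risk
membership on arm, baseline-class dummies and their interaction (optional
covariates), restricted to participants with an observed follow-up; the
complete-case toggle further requires all items observed. The average
marginal effect of arm within a baseline class is the within-class mean
of P̂(low|arm=1,x) − P̂(low|arm=0,x) (Stata's dy/dx convention — average
over subjects, not at means), with delta-method standard errors over the
full coefficient covariance and normal 95% intervals; the within-class
odds ratio is exp(β_arm + β_{arm×class}). Multinomial class-membership
regressions report relative-risk ratios (exponentiated multinomial-logit
coefficients) with a likelihood-ratio χ² against the intercept-only
model. Attrition and trial-participation checks use Pearson χ² without
continuity correction. No multiplicity adjustment is applied (per-class
tests are reported as such).

## Synthetic cohort generator

The generator forward-simulates exactly the assumed model — the point is
that every downstream stage is checkable by parameter recovery. Defaults
are anchored at published values: trial baseline class mix
δ = (0.32, 0.23, 0.21, 0.24) (full-sample mix 33/22/19/27% as printed,
normalized); per-arm transition matrices as published (e.g. high→low 37%
control / 53% peer-education, low→low 87%/95%); follow-up dropout 13%
(high-risk, control) vs 4% (high-risk, PEI), 8% elsewhere (an
implementer's choice consistent with the reported overall retention); the
within-class item percentages quoted in the results text (low-risk cooker
sharing 0/0.11; equipment-class cooker 0.03/0.57/0.40 with no syringe
sharing; moderate class all sharing syringes, 89% at low frequency, 29%
always bleaching). Profile cells not numerically quoted are generator
choices matching the verbal class descriptions, *not* published facts.
Covariate distributions (sex, age, race, site, homelessness) are loosely
matched to the published baseline table and exist only to exercise the
regression stage. Categories are emitted as raw 7-point Likert responses
(uniform within the collapsed band, reverse-scored items flipped) so
generated cohorts exercise the recoding stage; a single seeded RNG stream
consumes draws in a fixed documented order, making cohorts bit-identical
given (config, seed).

What the generator does **not** emulate: within-class item dependence
(off by default; a `dependence` switch induces it for robustness
studies), non-ignorable attrition given class, the 3-month wave, and
site-specific class mixes. Passing recovery tests therefore demonstrates
the estimator's correctness under the model's assumptions, not robustness
to their violation in real data.

## Numerical and design choices

- Likert orientation 1="always" … 7="never"; reversal as 8 − raw;
  categories 7→never, 5–6→less than half, 1–4→half or more (the midpoint
  4 carries the "half the time" label, hence upper category). The 5–6 vs
  1–4 cut is a documented package decision — only the midpoint's label is
  dictated by the instrument.
- Missing sentinel −1, never 0 (which codes "never").
- LCA defaults: 50 starts, tol 1e-7, max_iter 1000; LTA: 3 starts over a
  warm start.
- Degenerate inputs: fewer distinct patterns than classes is an error;
  parameter counts above the pattern-count bound warn; empty modal
  classes yield NaN rows with a warning; zero-margin contingency tables
  error.

## Problem sizes used by the test and acceptance suites

Recovery of transition parameters uses cohorts of n = 200,000 (single
fit, about half a minute), baseline class-mix recovery n = 50,000 with 50
starts, class enumeration 20 cohorts of n = 1,569 (the trial's baseline
size) with a 50-replicate bootstrap LRT, and level/coverage studies 200
replications at n = 1,000–1,200.

## A measured finite-sample caution on the invariance LRT

The package's own simulations show that the *naive* likelihood-ratio test
for measurement invariance in the 4-class, 7-item model is liberal at
moderate samples: at n = 1,000 the full time-noninvariance comparison
(56 df) rejected a true-invariant null in about 18% of replications at
the 5% level (mean statistic 64.7), and a one-class comparison (14 df)
in about 9%; at n = 8,000 the same test is essentially exact (mean 56.3,
3% rejection). The driver is the small number of effective observations
per freed response cell (tens), a Bartlett-type effect — and the classic
reason scaled difference tests are preferred in practice. The level
acceptance test therefore checks the LRT machinery in a regime where the
chi-square reference is accurate at n = 1,000 (a 2-class generator with
roughly 150 observations per cell); analysts comparing invariance
constraints in the full model at trial-sized samples should prefer
`sb_scaled_difference` with `scaling_correction`, or larger samples.

## Known limitations

- Classify-analyze propagates no classification error (no 3-step
  BCH/ML correction); with entropy near 0.9 the attenuation is small but
  real.
- Exactly two waves per joint model; no mover-stayer or higher-order
  Markov variants.
- Covariates do not enter the measurement model (no one-step
  regression-on-class).
- The BLRT's refits use reduced starts for tractability; pathological
  multimodality in a bootstrap replicate could in principle leak into the
  null distribution (non-convergent replicates are dropped and counted).
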