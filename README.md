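# ltarisk

Latent class and latent transition analysis of injection-related HIV/HCV
risk behavior, with class-specific intervention-effect estimation and a
synthetic cohort generator for end-to-end verification.

## The problem

Behavioral trials with people who inject drugs report an *average*
intervention effect, but injection risk behavior is highly heterogeneous:
some participants share syringes frequently, some share only cookers,
cottons, and rinse water, and many exhibit little risk at all. `ltarisk`
is for biostatisticians and epidemiologists who want to (1) identify
discrete risk profiles from categorical behavior indicators, (2) model
movement between profiles across trial waves, and (3) ask *for whom* an
intervention worked.

The measurement model is a latent class analysis of seven 3-category
indicators (syringe, cooker, cotton, and rinse-water sharing; new-syringe
drug splitting and bleach cleaning, reverse-scored; number of
syringe-sharing partners):

    P(x) = Σ_k λ_k Π_j π_{kj x_j}

Two waves are linked by a Markov transition matrix with trial arm as a
known class — arm-specific transitions τ_g[a,b], a shared baseline class
distribution δ, and measurement-invariance constraints on π over time and
arm, compared by likelihood-ratio tests (including the Satorra-Bentler
scaled difference). The effect stage follows the classify-analyze
convention: a logit of follow-up low-risk membership on arm × baseline
class, with delta-method average marginal effects (dy/dx) of the
intervention within each baseline class.

Estimation is by multi-start EM with full-information handling of missing
items and missing follow-up waves (MAR). Classes are canonically ordered
(low, equipment-sharing, moderate, high) by expected syringe-sharing
risk, so labels are reproducible across runs.

## Worked example

Generate a two-wave synthetic trial cohort at the package's default
(literature-anchored) configuration, fit the invariant-measurement LTA
with arm-specific transitions, and estimate per-class intervention
effects:

```python
import numpy as np
import ltarisk as lr
from ltarisk import simulate as sim, lta, effects

cfg = sim.default_paper_config(n=5000, seed=11)
coh = sim.generate(cfg)
X1, X2, arm = sim.two_wave_matrices(coh.records)

m = lr.fit_lta(X1, X2, arm, K=4, n_starts=2, seed=3)
w1, w2 = lr.marginal_class_probs(m)
print(np.round(m.tau_for("pei"), 3))

post = lta.posterior_lta(m, X1, X2, arm)
keep = post.has_wave2
glm = effects.lowrisk_glm((post.modal2 == 0)[keep].astype(float),
                          (np.asarray(arm) == "pei")[keep].astype(float),
                          post.modal1[keep])
labels = sim.CLASS_LABELS
for a in effects.average_marginal_effects(glm):
    print(f"AME {labels[a.baseline_class]:9s} dy/dx={a.dydx:+.3f}  "
          f"95% CI ({a.ci_low:+.3f}, {a.ci_high:+.3f})  "
          f"z={a.z:.2f}  p={a.p_value:.4f}")
```

Output (abridged):

```
tau pei:
[[0.959 0.    0.036 0.005]
 [0.666 0.263 0.033 0.038]
 [0.63  0.045 0.227 0.097]
 [0.524 0.196 0.174 0.107]]
AME low       dy/dx=+0.091  95% CI (+0.062, +0.119)  z=6.30  p=0.0000
AME equipment dy/dx=-0.032  95% CI (-0.089, +0.025)  z=-1.09  p=0.2759
AME moderate  dy/dx=+0.020  95% CI (-0.040, +0.079)  z=0.65  p=0.5177
AME high      dy/dx=+0.143  95% CI (+0.083, +0.203)  z=4.69  p=0.0000
```

Reading the output: the fitted PEI-arm transition matrix says a baseline
low-risk participant stays low-risk with probability 0.96, and a baseline
high-risk participant moves to low-risk with probability 0.52. The
average marginal effects say the peer-education arm raises the
probability of ending up low-risk by about 14 percentage points for
baseline high-risk participants (significant), with no detectable effect
in the equipment-sharing and moderate classes — the heterogeneous-effect
pattern the model is designed to expose. At this n the estimates carry
visible sampling noise; the acceptance run below uses n = 200,000.

A command-line interface wraps the same stages:

```
lta-risk simulate --n 2000 --seed 7 --out run/
lta-risk recode --in run/cohort.csv --out run/indicators.csv
lta-risk lca --in run/indicators.csv --k-min 2 --k-max 6 --seed 7 --out run/fit.csv
lta-risk run --seed 7 --n 2000 --out run/full/
```

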