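# lbalink

Bayesian linking of decision urgency to early-life adversity.

`lbalink` implements a complete analysis pipeline for the question: *do
adults who experienced more adversity in childhood make simple perceptual
decisions more urgently?*  It is written for cognitive-modelling
researchers who fit evidence-accumulation models to two-alternative
forced-choice data and relate the fitted parameters to external measures.

## The model

Choice and response time are modelled with the linear ballistic
accumulator (LBA).  Two accumulators race to a threshold *b*; evidence for
accumulator *i* grows linearly at a rate drawn once per trial from
Normal(*v<sub>i</sub>*, *s*), from a start point Uniform[0, *A*]; the
response time adds a non-decision offset *t*<sub>0</sub>.  The quantity of
interest is **decision urgency**

> *b* − *A*/2,

the mean evidence required to respond.  We fix *s* = 1 (scaling
constraint) and sample *k* = *b* − *A* > 0.  Per-participant posteriors
are estimated by differential-evolution MCMC (18 chains × 4000 iterations,
2000 burn-in) under weakly informative priors.

Adversity is measured from a distressing-life-events survey as an
event-type × age (0–18) matrix: **ELA** is the number of distinct cells
experienced; **CSD** weights each cell by its 0–100 SUDS distress rating.
Both come in early (≤7) and late (8–18) windows, plus a 28-item material
deprivation score used as a partialled covariate.

The association is assessed three ways, all one-sided (H₁: ρ < 0):

1. **Plug-in correlations** between log posterior-median urgency and
   log(ELA+1): Pearson and Kendall τ-b, with p-values and Bayes factors
   (exact reduced-likelihood integration against a uniform(−1, 0) prior).
2. **A posterior sweep** repeating the correlation over 500 random
   posterior samples of urgency, showing how strongly plug-in inference
   depends on the chosen point estimate.
3. **Joint models**: a hierarchical bivariate-normal layer over
   (ln urgency, ln ELA) estimated *simultaneously* with every
   participant's LBA parameters, propagating threshold uncertainty into
   the correlation ρ.  Savage-Dickey Bayes factors are computed under a
   conservative uniform(−1, 0) prior, a peaked truncated-Normal(0, 0.1)
   prior, and an estimation prior uniform(−1, 1); a partial-correlation
   variant removes variance attributable to material deprivation.

Because the study's human data are not publicly deposited, the package
ships a first-class synthetic-study generator with known ground truth
(`lbalink.synth`) that emulates the study conditions (126 participants,
5 × 40 trials, ELA mean 15 / SD 24, CSD mean 52 / SD 88, deprivation mean
1.8 / SD 0.586) and exercises every pipeline stage, including the <60%
accuracy exclusion.  See `docs/methods.md` for modelling details and
limitations.

## Worked example

```python
import numpy as np
from lbalink import (GeneratorConfig, generate_study, fit_participant,
                     median_urgency, SamplerConfig, pearson_one_tailed,
                     fit_joint, JointPriorSpec)
from lbalink.adversity import log_transform, profiles_from_frame

study = generate_study(GeneratorConfig(n_participants=30, seed=3))
profiles = profiles_from_frame(study.event_reports)
ela = np.array([profiles[p].ela if p in profiles else 0
                for p in study.participants], float)

urg = [median_urgency(fit_participant(study.trial_tables[p],
                                      config=SamplerConfig(n_chains=9, n_iter=1500,
                                                           burn_in=750, seed=i)))
       for i, p in enumerate(study.participants)]

res = pearson_one_tailed(log_transform(ela, 1.0), np.log(urg))
print(f"r = {res.r:.3f}, one-tailed p = {res.p_one_tailed:.3f}, BF10 = {res.bf10:.2f}")

joint = fit_joint([study.trial_tables[p] for p in study.participants],
                  log_transform(ela, 1.0),
                  prior=JointPriorSpec("estimation"),
                  config=SamplerConfig(n_chains=9, n_iter=1000, burn_in=500, seed=7))
print(f"rho mean = {joint.rho_flat.mean():.3f}, 95% CI = "
      f"[{joint.ci95[0]:.2f}, {joint.ci95[1]:.2f}], BF10 = {joint.bf10:.2f}")
```

Output (seeds as shown):

```
r = -0.351, one-tailed p = 0.029, BF10 = 2.47
rho mean = -0.365, 95% CI = [-0.70, 0.09], BF10 = 1.22
```

On 30 participants the plug-in correlation between log adversity and log
median urgency is weakly negative (r = −0.35) with modest Bayesian
evidence; the joint model, which also carries the trial-level uncertainty
in each threshold, centers slightly farther from zero with a wide credible
interval.  At the full 126 participants the interval narrows and the
evidence sharpens correspondingly.

## Command line

```bash
lbalink run --seed 1 --outdir run1          # full synthetic-study pipeline
lbalink validate --trials trials.csv        # schema checks on input files
```

Subcommands `generate`, `fit`, `indices`, `correlate`, `sweep`, `joint`
run individual stages; `--config cfg.yaml` supplies a structured
configuration (sampler settings, joint-model variants, paths to real data
in the `participant,trial,stimulus,response,rt,correct` /
`participant,event_type,age_spec,suds` / `participant,item_1..item_28`
formats).

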