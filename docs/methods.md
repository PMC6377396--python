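# Methods

## Scientific problem

Does early-life adversity relate to how *urgently* adults make simple
perceptual decisions?  The analysis links two measurement models:

1. **Decision urgency** from two-alternative forced-choice behaviour,
   measured as the mean evidence required to trigger a response in a linear
   ballistic accumulator (LBA), `b - A/2`, where `b` is the decision
   threshold and `A` the start-point range.  Lower values mean faster,
   less cautious responding.
2. **Early-life adversity** from a distressing-life-events survey: the
   count of distinct (event type, age 0–18) cells a participant reports
   (ELA), and a SUDS-weighted version (Childhood Subjective Distress, CSD)
   that distinguishes few severe events from many mild ones.

The directional hypothesis is a *negative* correlation between log
adversity and log urgency.  All analyses are one-sided accordingly.

## LBA model and identification

Each trial is a race between two accumulators (stimulus-matching drift
`v_c`, mismatching drift `v_e`).  Start points are Uniform[0, A]; drifts
are Normal(v_i, s) across trials; within-trial accumulation is
deterministic, giving closed-form first-passage densities and a defective
trial likelihood f_winner(t − t0) · (1 − F_loser(t − t0)).  No
renormalization is applied for the event that neither drift is positive
(standard defective-likelihood practice); the simulator resamples such
trials, and simulation-vs-density tests renormalize analytically by
1 / (1 − Φ(−v_c/s) Φ(−v_e/s)).

Identification: the LBA likelihood is invariant under joint rescaling of
{v_c, v_e, A, b, s}, so one parameter must fix the scale.  **We fix s = 1
for both accumulators.**  We also sample the threshold offset k = b − A
(> 0) instead of b, which enforces b > A by the support alone; results are
reported as b and the urgency b − A/2 = k + A/2.

A consequence worth stating plainly: at ~200 trials the scale direction
(v, A, k jointly up or down) is only weakly constrained, so per-participant
posterior medians of urgency carry irreducible noise of roughly 0.2
evidence units.  Parameter-recovery simulations (see `tests/`) put the
correlation between generating and recovered urgency near 0.87 across a
design spanning the plausible parameter range — good, but a hard
information limit of the design rather than an estimator defect (the
posterior median typically attains a *higher* likelihood than the
generating truth).

## Per-participant estimation

Non-hierarchical Bayesian estimation, deliberately: hierarchical shrinkage
pulls per-participant estimates together and biases a second-stage
correlation toward detecting effects.  Priors (defaults; evaluable in log
space):

| parameter | prior | support |
|---|---|---|
| v_c | Normal(3, 3) | ℝ |
| v_e | Normal(1, 3) | ℝ |
| A | Normal(1, 1) | (0, ∞) |
| k | Normal(0.5, 1) | (0, ∞) |
| t0 | Normal(0.3, 0.3) | (0.02, min observed rt) |

Sampling is DE-MCMC (proposals θ* = θ_i + γ(θ_j − θ_k) + U(−ε, ε), γ =
2.38/√(2d), ε = 1e-4), 18 chains × 4000 iterations with the first 2000
discarded, chains initialized from independent prior draws re-drawn until
the log-posterior is finite.  No migration or crossover steps.  Convergence
is monitored with split-chain rank-normalized R-hat (warn above 1.05).
The plug-in urgency estimate is the posterior median of k + A/2.

## Adversity indices

Event reports carry an age-span string ("8, 12-14"; hyphen or en-dash) and
one SUDS rating (0–100).  The event×age matrix uses ages 0–18 inclusive
(19 columns; the published count tables begin at age 1, but the stated
range is 0–18 — we keep age 0).  Ages outside 0–18 are dropped.  When two
reports place the same event type at the same age with different SUDS, the
cell keeps the maximum (most distressing experience of that event-year).
ELA = sum of binary cells; CSD = sum of SUDS-weighted cells; early/late
windows are ages 0–7 and 8–18 and partition the totals exactly.  The
28-item material-deprivation score is the mean after reverse-scoring
(r → 6 − r).  Because ELA = 0 occurs, count-like indices are
log-transformed as ln(x + 1); urgency is strictly positive and uses ln(x).

## Correlation analyses

Frequentist: Pearson (lower-tailed t) and Kendall τ-b (tie-corrected
asymptotic normal, lower tail).  Bayesian: the Pearson BF integrates the
exact reduced likelihood of the sample correlation r given ρ (the
sufficient-statistic likelihood of default Bayesian correlation tests)
against the width-1 stretched-beta prior restricted to ρ < 0 — i.e. a
uniform prior on (−1, 0) — by adaptive quadrature (rtol 1e-8).  The
Kendall BF uses the asymptotic Normal(τ, 2(2n+5)/(9n(n−1))) likelihood of
τ̂ with the same prior mapped through τ = (2/π) asin(ρ); software using a
different Kendall method will produce slightly different numbers even on
identical data.  Partial correlations use OLS residuals on the deprivation
covariate (log-deprivation for log variants).  The posterior sweep redoes
the Pearson analysis 500 times, sampling one urgency draw per participant
per iteration (independent across participants and iterations, seeded).

## Joint models

The joint model replaces the plug-in step: for participant p,

    (ln urgency_p, ln ELA_p) ~ BivariateNormal(μ, Σ(σ₁, σ₂, ρ)),

ln ELA_p observed, ln urgency_p sampled directly as the participant-level
latent (so the hierarchical layer is linear in the sampled quantity), and
the participant's trials entering through the LBA likelihood with k =
exp(ln urgency) − A/2.  Other LBA parameters keep their independent
priors.  Group-level nuisance priors: μ ~ Normal(0, 10), σ ~ half-Normal(5),
regression slopes ~ Normal(0, 5).  The partial-correlation variant adds a
regression layer on centered deprivation m_p —
ln urgency_p = μ₁ + β₁ m_p + ε₁, ln ELA_p = μ₂ + β₂ m_p + ε₂, (ε₁, ε₂)
bivariate normal — so ρ is the partial correlation; this regression
parameterization is our reading of "removing the variance attributed to"
the covariate.

Priors on ρ: uniform on (−1, 0) (conservative), Normal(0, 0.1) truncated
to (−1, 0) (peaked), and uniform on (−1, 1) (estimation).  Prior density
at ρ = 0 is analytic: 1, 2φ(0; 0, 0.1) ≈ 7.98, and 0.5.

### Blocked sampler

Each iteration updates (i) every participant's 5-dimensional block by a DE
proposal, all chains × participants evaluated in one vectorized (compiled)
likelihood call; (ii) an ancillary **scale–translation move** that jointly
maps the latent urgencies and (μ₁, σ₁) via x′ = μ′ + c(x − mean_p) with
log c and the translation drawn symmetrically, accepted with the Jacobian
c^(N+1) — the group scale and the latents form a hierarchical funnel that
coordinate-wise updates traverse very slowly; (iii) several cheap
group-block DE sub-updates (the group conditional touches only N bivariate
terms).  A likelihood-only warm-up stage (default 300 iterations) first
moves each participant block near its own non-hierarchical posterior.

Calibration: simulation-based calibration at N=30 participants × 100
trials (ρ drawn uniformly, 60 replicates, 9 chains × 1000 iterations)
gives a rank histogram consistent with uniformity (χ² p = 0.21); the test
suite reruns a 20-replicate scaled version.  Note the joint model
*disattenuates*: its ρ posterior is typically farther from zero than the
plug-in correlation, which is the point — the plug-in estimate is biased
toward zero by estimation noise in the urgencies.

### Savage-Dickey Bayes factors

BF₁₀ = prior density at ρ = 0 ÷ posterior density at ρ = 0.  The posterior
density at zero is estimated on the z = atanh(ρ) scale (Jacobian 1 at 0)
with a boundary-respecting log-polynomial estimator: bin the draws, fit a
degree-4 polynomial log-density by Poisson maximum likelihood, evaluate at
0.  Kernel and reflection estimators are biased at a boundary where the
density has slope; the Poisson-polynomial fit is exact for truncated-normal
shapes.  A reflected Gaussian KDE is the fallback if the fit fails.  When
no draws fall near zero the BF is effectively a lower bound and a warning
is raised.  Credible intervals are central quantile intervals (2.5–97.5%).

## Synthetic data generator

The generator emulates the study conditions: 126 participants, 5 × 40 =
200 trials; ELA as a shifted lognormal (moment-matched on the log scale to
mean 15, SD 24, reproducing the strong positive skew); CSD calibrated via
a scaled-beta SUDS distribution toward mean 52, SD 88; material
deprivation Normal(1.8, 0.586) clipped to the 1–5 scale; a trivariate
normal over (ln urgency, ln(ELA+1), deprivation) with configurable
correlations (default ρ = −0.2 between the first two, −0.1 and 0.35 for
deprivation).  ln urgency ~ Normal(0.2, 0.25).  Population distributions
for the other LBA parameters: v_c ~ N(2.8, 0.8) (floored at 0.2),
v_e ~ N(1, 0.5), A ~ N(0.8, 0.25), t0 ~ N(0.25, 0.05) clipped to
[0.08, 0.5].  The wide v_c spread produces occasional near-chance
performers, so the <60% accuracy exclusion is exercised organically.

Survey realization places each participant's ELA count of (event type,
age) cells without replacement with probabilities proportional to packaged
event-type and age weights mirroring the published table's marginal shapes
(cell frequencies are stylized, not reproduced).  Contiguous ages of one
event type merge into one report with a single SUDS rating, so rebuilding
profiles from the files reproduces ELA and CSD exactly.  Deprivation items
are constructed so the reversed mean equals the latent score to within
1/56.

What the generator does **not** emulate: response omissions and fast
guesses, within-session drift (fatigue/practice), recall error in the
survey, item-level deprivation structure, and demographic covariates.
Passing tests therefore show the pipeline recovers truth when the model
family is correct — not that the model family is correct for human data.

## Problem sizes and numerical choices

- Per-participant sampling defaults: 18 × 4000/2000 (the analysis
  setting).  Test and script runs use 9 × 1500/750, which we verified
  changes posterior medians by less than Monte-Carlo error.
- Joint fits in tests use 9 chains × 1000 iterations (500 burn-in) plus
  300 warm-up, the scaled replicate size; coverage and SBC checks run 20
  replicates.  The acceptance script fits 126-participant joint models at
  the same scaled settings.
- Φ terms inside log-densities are clipped at 1e-300; decision times
  rt ≤ t0 yield −∞ (rejection), never exceptions.
- A < 1e-10 switches to the closed-form A → 0 density.
- Ties in Kendall τ use the τ-b variant with tie-corrected variance.
- The compiled likelihood kernel (numba, fastmath) agrees with the
  reference numpy path to ~1e-6 in summed log-likelihood; the numpy path
  is the one cross-checked against quadrature and simulation.

## Known limitations

- Urgency recovery at 200 trials is information-limited (scale ridge under
  s = 1); correlations with generating urgency plateau near 0.87.  The
  joint model is the mitigation: it propagates exactly this uncertainty.
- Savage-Dickey BFs degrade when the posterior leaves no mass near ρ = 0
  (they become lower bounds; flagged by a warning).
- Kendall Bayes factors use an asymptotic likelihood; exact-method
  software will differ by a few percent.
- The partial-correlation joint model fixes a regression (not a full
  trivariate-correlation) parameterization.
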