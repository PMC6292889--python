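# Methods

This note documents the models, the synthetic-data generator, the
numerical choices, and the limits of what the test suite demonstrates.

## Data model and cleaning

Records are binned into **financial years** (July–June); the label of a
financial year is its starting calendar year, matching the austral-summer
peak of shark catches. A date belongs to exactly one financial year; the
binning is tested as a partition property.

**Length filtering.** Total lengths are checked against a maximum
plausible length per group or species (species-level bounds take
precedence when a species label is present; records predating
species-level identification fall back to the group bound) and against a
lower floor (default 30 cm) that catches probable imperial-unit entries —
a length of "5" is almost certainly feet. Every exclusion is logged with
its reason and the bound applied, so the rule is auditable. Records with
missing lengths are kept: they still count for catch-rate analyses and
simply drop out of size analyses. The default bound table ships with two
published hammerhead maxima (scalloped 430 cm, great 610 cm); all other
defaults are synthetic, literature-plausible stand-ins intended for
simulated data and replaceable via CSV.

**Unknown-gear allocation.** Early records sometimes lack a gear label.
Unknowns are assigned to net or drumline in proportion to the known-gear
catch within each (group, region) cell — the only reading of
"proportional to the odds of catch by gear" that yields well-defined
per-record probabilities. Two modes: *deterministic* (largest-remainder
apportionment, ties to net, records taken in stable date order) makes
counts exact and reproducible without randomness; *stochastic* draws each
record Bernoulli(net share) under a seed. Total catch per cell is
conserved exactly in both.

**CPUE.** catch/effort per site × year × gear × group cell. Cells with
effort and no catch are zeros, not missing; catch in a cell without
positive effort is a data error and raises.

## The trend model

See the README for the likelihood. Design choices that were genuinely
open:

- **RW2 constraint.** Each RW2 trajectory is constrained to sum to zero
  (sampled in a Helmert basis of the sum-to-zero subspace), separating
  the trend's level from the intercept and region effects. No
  orthogonality-to-linear-time constraint is imposed: the model contains
  no linear fixed effect, so the long-term slope must live in the trend
  itself — removing it would remove the decline the model exists to
  estimate. The linear direction of the intrinsic prior is improper and
  is identified by the data.
- **Priors.** PC (exponential-on-σ) priors with $P(\sigma>u)=\alpha$:
  $(0.1, 0.01)$ for the RW2 scale, $(1, 0.01)$ for region and site
  effect scales. Fixed effects get N(0, 10²). Overdispersion is
  parameterized as $\kappa = 1/\theta$ with an Exponential(1) prior,
  shrinking toward the Poisson base model; near-Poisson data push the
  posterior of θ into the hundreds, which the tests exploit. A
  sensitivity test refits across $(u,\alpha) \in \{0.1,1\}\times\{0.01,
  0.05\}$ and checks that WAIC and the headline decline barely move.
- **One θ per fitted model**, shared across sites and years.
- **Gear-specific CPUE curves** come from predicting at unit effort of
  each gear via the gear fixed effect; the percent decline of the smooth
  is identical across gears by construction (the gear effect cancels in
  the endpoint ratio).
- **Zero-catch probability.** For each posterior draw and each site with
  effort in a year, the probability of catching nothing at that beach is
  the product of $(\theta/(\theta+\mu))^\theta$ over the site's deployed
  gear cells, with μ at the cell's actual effort. Site values are
  averaged within regions, and region averages are averaged for
  program-wide curves; site-level output is also returned, since "no
  sharks at a given beach" and "at a given site within a region" are both
  defensible readings.
- **Percent decline** defaults to the endpoint ratio of the fitted
  smooth (region-averaged prediction); any pair of years can be
  requested.

## Sampler

All posteriors are drawn by blocked MCMC written for this package:

- **Coefficient and latent blocks** use Metropolis–Hastings with the
  Gaussian full-conditional approximation obtained by second-order
  Taylor expansion of the count log-likelihood around the current state
  (the classic GMRF one-block proposal). Acceptance rates are high and
  the moves are near-independence. The year-incidence structure of the
  trend design is exploited so the proposal precision costs
  O(n + T·dim²) rather than a dense product.
- **Hyperparameters** (log σ's, log θ) use adaptive random-walk steps
  tuned toward 0.44 acceptance during warmup, with truncated support
  (log σ ∈ [−6, 5]) that keeps chains out of the degenerate σ→0 funnel
  tip. The RW2 scale additionally gets a **joint update**: a random-walk
  step on log σ together with a refresh of every trend block from its
  Gaussian proposal under the proposed precision, accepted jointly.
  Without this move the hyperparameter and the field move in lockstep
  and the scale's effective sample size collapses. The θ and RW2-scale
  updates run twice per iteration; they are the slowest-mixing scalars.
- **Warm start.** Chains start from an approximate joint mode found by
  damped Newton sweeps. Taylor proposals made from a far-off start have
  vanishing reverse-proposal density and can leave a chain stuck at its
  initial state for an entire run; mode-finding plus per-chain jitter
  removes the failure mode.
- **Convergence contract.** Default 4 chains × (500 warmup + 500 kept);
  split R-hat < 1.05 and bulk ESS > 400 (via arviz) on the monitored
  scalars (intercept, gear effect, log θ, log RW2-scale). Fits that miss
  the contract are flagged (`converged=False`), never silently accepted;
  `require_converged` raises on demand. Replicate simulation studies use
  2 chains × (300 + 300) without diagnostics for speed — their checks
  are calibration rates across replicates, not single-fit inference.

WAIC is computed from the stored pointwise log-likelihood matrix as
$-2(\mathrm{lppd} - p_{\mathrm{WAIC}})$ with the sample-variance (ddof 1)
penalty; the test suite pins the hand-computed two-draw case and
reconciles with arviz's ddof-0 convention explicitly.

## Depletion analysis

Initial catch records are five-year window **sums** of catch and effort
(not means of annual ratios), so the Poisson GLMM response is a true
count with a log-effort offset; the descriptive mean-CPUE statistic is
kept alongside for plotting. Nets and drumlines are fitted separately.
The percent change in initial CPUE between installation years $y_0, y_1$
is $100(1 - e^{\beta_1 (y_1 - y_0)})$ per draw; increases come out
negative. Short windows (installation near the end of the data) are
flagged rather than dropped. The five-year window is taken in financial
years, consistent with the rest of the pipeline; partial first years are
not treated specially.

## Size and maturity models

The size model is a REML linear mixed model on individual lengths (year
slope in cm/yr, gear and sex fixed effects, nested region/site random
intercepts). The marginal covariance is handled by the Woodbury identity
(random-effect dimension is small), variance ratios are optimized on the
log scale by Nelder–Mead, and σ² is profiled in closed form. With no
grouping factors the fit reduces exactly to OLS, which the tests pin to
10⁻⁶; the nested fit is cross-checked against lme4 via Rscript. Wald
z-tests give the significance stars (\*\*\* p<0.001, \*\* p<0.01,
\* p<0.05). Boundary fits (a variance ratio → 0) are reported via a
`singular` flag. Fitting uses individual records, not annual means, as
the mixed-model structure implies.

Maturity is classified per record as length ≥ the (species, sex) cutoff —
boundary inclusive, a documented convention. Cutoffs are configuration
data; the shipped defaults are synthetic stand-ins. The maturity trend is
a Laplace-approximate logistic mixed model fitted separately per
species × sex (no sex-interaction model), with endpoint-year predicted
probabilities and Wald bands on the linear predictor. Complete separation
is detected and flagged. Records with unknown sex never reach the
sex-stratified models.

## Synthetic program generator

The generator draws from exactly the structures the models assume:

- latent relative abundance per region × group, either geometric decline
  $N_t = N_0 (1-r)^{t-t_0}$ or, optionally, harvest feedback
  $N_{t+1} = \max(0, N_t(1-r) - c\,\mathrm{catch}_t)$. Both mechanisms
  are exposed as scenarios without asserting which drives real declines;
- counts per cell from NB(mean = catchability × effort × $N_t$, size θ)
  in the same mean–size parameterization the model fits;
- truncated-normal lengths (rejection sampling — the bounds are wide, so
  acceptance is high and exactness is preferred over a ppf transform)
  with a linear year trend; Bernoulli sex; species labels only from a
  configurable year (default 1996) to mimic the species-identification
  era;
- contamination processes: a configurable fraction of records relabelled
  gear-unknown (default 2.41%) and optional imperial-unit length
  corruption (length ÷ 2.54 or ÷ 30.48).

The default program (five regions, 20 beaches installed 1962–1998,
1962–2017 span) uses year-one CPUEs of 9.5/0.25 (hammerhead net/drum),
18.3/2.3 (whaler), 2.3/1.4 (tiger), 0.7/0.1 (white shark) per gear-year,
decline rates giving endpoint declines of ~92/82/74/92%, θ = 2, and size
trends of +0.20, −0.49, −1.04, −0.50 cm/yr — magnitudes typical of
long-running control programs. A fixed seed yields byte-identical tables.

What the generator does **not** emulate: spatial movement and
home-range structure, environmental covariates, gear changes within a
site's history, within-year seasonality, species misidentification, or
measurement-bias incentives (e.g. bounty-era size exaggeration). Passing
tests therefore demonstrate that the estimators recover truth when the
model family matches the generating process at realistic noise levels —
not that real program data satisfy those assumptions.

## Study designs (tests and acceptance script)

- **Percent-decline coverage:** 50 programs of 4 regions × 3 sites × 40
  years, true endpoint decline 80%, θ = 2; the shared-trend variant is
  fitted (the generating decline is region-common) and the 95% interval
  should cover the truth in ≥ 90% of replicates.
- **Intercept recovery:** 100 single-site, constant-rate programs
  (8 years); interval coverage of the true log CPUE.
- **WAIC selection:** 20 programs of 4 regions × 2 sites × 30 years with
  per-region decline rates (0, 0.03, 0.06, 0.09); the region-specific
  variant should win in ≥ 80%.
- **Depletion directionality:** one 4-region × 6-beach program with
  staggered installations and 6%/yr decline; P(β₁ < 0) ≥ 0.95.
- **Depletion null coverage:** 100 stable programs at near-Poisson
  dispersion — generated from the model being checked, since the check
  is interval calibration, not robustness to overdispersion.

Replicate counts and sizes are chosen so the full suite runs in minutes
on one CPU while leaving the acceptance thresholds comfortable margins.

## Known limitations

- The MCMC is exact but not gradient-based; very long series or many
  regions would benefit from sparse-matrix GMRF solvers or a
  Laplace-approximation fast path, neither of which is implemented.
- The RW2-scale ESS sits closest to the convergence contract; raising
  `draws` is the remedy when a fit flags.
- The Poisson depletion model inherits the original analysis's choice of
  likelihood; under strong overdispersion its intervals are anti-
  conservative (visible in the generator when θ is small).
- Maturity cutoff and length-bound defaults are stand-ins, not sourced
  values; real analyses must supply their own CSV tables.
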