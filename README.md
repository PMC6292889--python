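# sharkcpue

Reconstruction and hierarchical Bayesian analysis of multi-decade
shark-control-program catch records.

Shark control programs (beach meshing and baited drumlines) have operated
continuously off some coastlines since the early 1960s, and their
contractor logbooks — who caught what, where, with which gear, how big —
are among the only fisheries-independent records long enough to measure
how apex shark populations have changed over half a century. `sharkcpue`
is a toolkit for analysts of such programs: it standardizes catch records
into catch-per-unit-effort (CPUE), fits hierarchical count models to
recover long-term abundance trends, quantifies serial regional depletion
through the catch rates of newly installed beaches, and tracks shifts in
body size and the probability of encountering mature animals.

Because real program data are typically restricted-access, the package
includes a first-class synthetic program generator that reproduces the
statistical structure of such datasets — staggered beach installations
across regions, two gear types with different catchabilities, declining
latent abundance, overdispersed counts, size trends, and the contamination
a cleaning pipeline must handle (unknown gear labels, imperial-unit length
entries). All tests and reported results run against this generator.

## The model

Catch counts $y_i$ per site × financial-year × gear cell follow a
negative binomial GLMM with the deployed effort $E_i$ (gear-years) as an
offset, so predictions are CPUE:

$$
y_i \sim \mathrm{NB}(\mu_i,\ \theta), \qquad
\log \mu_i = \log E_i + \beta_0 + \beta_{\text{gear}} + u_{r(i)} +
v_{s(i)} + f_{t(i)},
$$

with variance $\mu + \mu^2/\theta$, iid normal region effects $u_r$ and
site-within-region effects $v_s$, and a latent temporal trend $f_t$
modelled as an order-2 random walk (RW2) — the count-model analogue of a
cubic smoothing spline. Two variants are fitted and compared by WAIC: a
per-region trend with shared smoothing hyperparameter (`regional_rw`) and
a single shared trend plus additive region effects (`global_rw`). The RW2
standard deviation carries a penalized-complexity prior,
$P(\sigma > u) = \alpha$ with default $(u, \alpha) = (0.1, 0.01)$.

Posterior sampling is blocked MCMC implemented in-repo: Taylor-expanded
Gaussian (GMRF) proposals for the coefficient and latent-trend blocks,
adaptive random-walk steps for hyperparameters, and a joint
hyperparameter–field update that keeps the smoothing parameter mixing.
Derived statistics include fitted CPUE trajectories with credible bands,
percent declines between endpoint years, annual zero-catch probabilities
$(\theta/(\theta+\mu))^\theta$, and their fold changes.

Around the core model sit:

- **depletion analysis** — initial CPUE (mean over the first five years
  after a beach's installation) regressed on installation year via a
  Bayesian Poisson GLMM with a region random effect and effort offset;
- **size and maturity trends** — REML linear mixed models for total
  length (year slope, gear and sex fixed effects, nested region/site
  intercepts) and Laplace-approximate binomial mixed models for
  P(mature), classified against species- and sex-specific
  length-at-maturity cutoffs supplied as configuration data.

## Worked example

```python
from sharkcpue import default_config
from sharkcpue.synthetic import simulate_program
from sharkcpue.records import (allocate_unknown_gear, compute_cpue,
                               count_catches, filter_lengths)
from sharkcpue.size_maturity import DEFAULT_TL_MAX
from sharkcpue.trend import (SamplerConfig, TrendModelSpec, compute_waic,
                             fit_trend_model, percent_decline_from_fit,
                             zero_catch_curve)

cfg = default_config(seed=7)                   # 5 regions, 20 beaches, 1962-2017
catch, effort = simulate_program(cfg)
kept, excluded = filter_lengths(catch, DEFAULT_TL_MAX)
clean = allocate_unknown_gear(kept, mode="deterministic")
grid = compute_cpue(count_catches(clean), effort)

data = grid[grid["group"] == "hammerhead"][
    ["region", "site", "financial_year", "gear", "catch", "effort"]]
fit = fit_trend_model(data, TrendModelSpec(variant="regional_rw"),
                      SamplerConfig(chains=4, warmup=500, draws=500, seed=7))
res = percent_decline_from_fit(fit, gear="net")
curve = zero_catch_curve(fit)
```

which prints, with the summaries shown:

```
simulated 22699 catch records at 20 beaches
cleaning: 0 length exclusions, 511 unknown-gear records allocated
converged: True (max R-hat 1.005, min ESS 410)
WAIC: 5074.9
net CPUE decline 1962-2017: 94% (95% CI 92-95%)
zero-catch probability: 0.003 (1962) -> 0.414 (2017)
```

The generator was configured with a 92% hammerhead decline over the
55-year span; the fitted smooth recovers it (94%, interval covering the
truth), and the annual probability of a beach catching no hammerheads
rises as the population thins — the same depletion signature the model is
designed to detect in real program data.

A command-line surface wraps the same functions
(`sharkcpue simulate | clean | cpue | fit-trend | fit-depletion |
fit-size | fit-maturity | report`); `sharkcpue report --out DIR` runs the
whole pipeline and writes tables, figures, and a run manifest.

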