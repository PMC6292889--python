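"""Serial-depletion analysis: initial CPUE of new installations vs time.

When a control program expands into new beaches, the catch rate over the
first few years of operation ("initial CPUE") samples the local standing
stock. If regional abundance is declining, beaches installed later start
from a lower baseline, so regressing initial catch on installation year
gives a direct, CPUE-standardization-free depletion signal.

The model is a Bayesian Poisson GLMM on windowed totals: catch summed over
the first five years after installation, with the summed effort as an
offset, a linear installation-year effect, and a region random intercept:

.. math::

   y_{s} \\sim \\mathrm{Poisson}(\\mu_s), \\quad
   \\log \\mu_s = \\beta_0 + \\beta_1 (year_s - year_{ref}) + u_{r(s)}
                 + \\log E_s

Window *sums* (not means of annual ratios) are used as response/offset so
the Poisson count model is exact; the descriptive mean-CPUE statistic is
still carried for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .families import Poisson
from .mcmc import (AdaptiveScalar, gaussian_mh_update, newton_mode,
                   split_diagnostics)
from .records import initial_cpue
from .rw2 import pc_prior_rate
from .trend import SamplerConfig


def build_initial_records(
    series: pd.DataFrame,
    schedule: pd.DataFrame,
    window: int = 5,
    max_install_year: int | None = None,
) -> pd.DataFrame:
    """One row per site x gear x group with first-``window``-year totals.

    ``series`` is a CPUE grid (see :func:`sharkcpue.records.compute_cpue`)
    and ``schedule`` an installation table with columns (region, site, gear,
    installed), e.g. from :func:`sharkcpue.records.installation_years`.
    Sites installed after ``max_install_year`` (when given) are dropped,
    mirroring an analysis restricted to the program's expansion era.
    """
    table = initial_cpue(series, schedule, window=window)
    if max_install_year is not None:
        table = table[table["installed"] <= max_install_year]
    return table.reset_index(drop=True)


@dataclass
class InitialTrendFit:
    """Posterior draws for the initial-CPUE Poisson GLMM."""

    year_ref: int
    regions: list[str]
    beta0: np.ndarray
    beta1: np.ndarray
    u: np.ndarray            # (S, R) region effects (empty if single region)
    sigma_region: np.ndarray
    loglik: np.ndarray       # (S, n)
    diagnostics: pd.DataFrame | None = None
    converged: bool | None = None

    @property
    def n_draws(self) -> int:
        return self.beta0.size


def fit_initial_trend(
    records: pd.DataFrame,
    seed: int = 0,
    year_ref: int | None = None,
    sampler: SamplerConfig | None = None,
    beta_sd: float = 10.0,
    sigma_re_u: float = 1.0,
    sigma_re_alpha: float = 0.01,
) -> InitialTrendFit:
    """Sample the Poisson GLMM posterior for initial catch vs install year."""
    sampler = sampler or SamplerConfig(seed=seed, warmup=400, draws=400)
    needed = {"region", "installed", "initial_catch", "initial_effort"}
    missing = needed - set(records.columns)
    if missing:
        raise DataError(f"initial records lack columns {sorted(missing)}")
    if (records["initial_effort"] <= 0).any():
        raise DataError("initial_effort must be > 0")
    install = records["installed"].to_numpy(dtype=int)
    if len(np.unique(install)) < 2:
        raise ConfigError(
            "need >= 2 distinct installation years to identify a slope"
        )
    year_ref = int(install.min()) if year_ref is None else int(year_ref)
    y = np.round(records["initial_catch"].to_numpy(dtype=float))
    offset = np.log(records["initial_effort"].to_numpy(dtype=float))
    x_year = (install - year_ref).astype(float)
    regions = sorted(records["region"].unique())
    include_u = len(regions) >= 2
    region_idx = pd.Categorical(records["region"], categories=regions).codes

    n = len(records)
    cols = [np.ones(n), x_year]
    names = ["beta0", "beta1"]
    if include_u:
        for r_i, r in enumerate(regions):
            cols.append((region_idx == r_i).astype(float))
            names.append(f"region[{r}]")
    X = np.column_stack(cols)
    p = X.shape[1]
    lam_re = pc_prior_rate(sigma_re_u, sigma_re_alpha)
    fam = Poisson()

    S_keep = sampler.chains * sampler.draws
    beta0_out = np.empty(S_keep)
    beta1_out = np.empty(S_keep)
    u_out = np.empty((S_keep, len(regions) if include_u else 0))
    sig_out = np.empty(S_keep)
    ll_out = np.empty((S_keep, n))
    chains_b1 = np.empty((sampler.chains, sampler.draws))
    chains_b0 = np.empty((sampler.chains, sampler.draws))

    ss = np.random.SeedSequence(sampler.seed)
    keep = 0
    for chain, cs in enumerate(ss.spawn(sampler.chains)):
        rng = np.random.default_rng(cs)
        psi = np.zeros(p)
        psi[0] = np.log(max(y.sum(), 0.5) / np.exp(offset).sum())
        ls = AdaptiveScalar(np.log(0.5) + 0.1 * rng.standard_normal(), step=0.3)
        prec0 = np.full(p, 1.0 / beta_sd ** 2)
        if include_u:
            prec0[2:] = np.exp(-2 * ls.value)
        psi, _ = newton_mode(psi, X, np.diag(prec0), offset, y, fam)
        psi = psi + 0.02 * rng.standard_normal(p)
        for it in range(sampler.warmup + sampler.draws):
            adapt = it < sampler.warmup
            prec = np.full(p, 1.0 / beta_sd ** 2)
            if include_u:
                prec[2:] = np.exp(-2 * ls.value)
            psi, _, _ = gaussian_mh_update(psi, X, np.diag(prec), offset, y,
                                           fam, rng)
            if include_u:
                u = psi[2:]

                def lp(ls_v):
                    return (-0.5 * float(u @ u) * np.exp(-2 * ls_v)
                            - u.size * ls_v - lam_re * np.exp(ls_v) + ls_v)

                ls.update(lp, rng, adapt)
            if not adapt:
                d = it - sampler.warmup
                beta0_out[keep] = psi[0]
                beta1_out[keep] = psi[1]
                if include_u:
                    u_out[keep] = psi[2:]
                sig_out[keep] = np.exp(ls.value)
                ll_out[keep] = fam.loglik_pointwise(y, offset + X @ psi)
                chains_b0[chain, d] = psi[0]
                chains_b1[chain, d] = psi[1]
                keep += 1

    fit = InitialTrendFit(
        year_ref=year_ref, regions=regions,
        beta0=beta0_out, beta1=beta1_out, u=u_out,
        sigma_region=sig_out, loglik=ll_out,
    )
    if sampler.compute_diagnostics and sampler.chains >= 2:
        fit.diagnostics = split_diagnostics(
            {"beta0": chains_b0, "beta1": chains_b1})
        fit.converged = bool(
            (fit.diagnostics["rhat"] < sampler.rhat_max).all()
            and (fit.diagnostics["ess"] > sampler.ess_min).all()
        )
    return fit


def initial_decline_percent(
    fit: InitialTrendFit,
    year0: int = 1963,
    year1: int = 1998,
) -> dict:
    """Posterior percent change in initial CPUE between two install years.

    ``100 (1 - exp(beta1 (year1 - year0)))`` per draw; negative values mean
    initial catch rates *rose* with installation year.
    """
    span = year1 - year0
    draws = 100.0 * (1.0 - np.exp(fit.beta1 * span))
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {
        "mean": float(draws.mean()),
        "median": float(np.median(draws)),
        "lo": float(lo),
        "hi": float(hi),
        "headline": int(round(float(np.median(draws)))),
        "prob_decline": float(np.mean(fit.beta1 < 0)),
        "draws": draws,
    }
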