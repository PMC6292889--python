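"""Hierarchical negative-binomial CPUE trend model with an RW2 latent trend.

The model for catch count :math:`y_i` in cell *i* (site x financial year x
gear) with effort :math:`E_i` is

.. math::

   y_i \\sim \\mathrm{NB}(\\mu_i, \\theta), \\qquad
   \\log \\mu_i = \\log E_i + \\beta_0 + \\beta_{gear} + u_{r(i)} + v_{s(i)}
                 + f_{t(i)}

with iid normal region effects :math:`u_r`, site-within-region effects
:math:`v_s`, and an order-2 random-walk trend :math:`f_t` — either one
trajectory per region sharing a single smoothing hyperparameter
(``regional_rw``) or a single shared trajectory plus the additive region
effect (``global_rw``). Effort enters as an offset so predictions are CPUE.
The RW2 standard deviation carries a penalized-complexity (exponential)
prior with tail probability ``P(sigma > u) = alpha``; fixed effects get
vague normals, remaining standard deviations PC priors, and the NB
overdispersion ``1/theta`` an exponential prior (shrinking toward Poisson).

Each RW2 trajectory is constrained to sum to zero (sampled in a Helmert
basis of the sum-to-zero subspace), which separates the trend's level from
the intercept and region effects while leaving the long-term slope to be
identified by the data.

Posterior sampling is blocked MCMC: Taylor-expanded Gaussian proposals for
the coefficient and latent-trend blocks, adaptive random-walk steps for the
log standard deviations and log dispersion. Derived quantities (fitted CPUE
trajectories, percent decline, annual zero-catch probabilities, WAIC) are
computed from the stored draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import NET
from .errors import ConfigError, ConvergenceError, DataError
from .families import NegativeBinomial, nb_zero_probability
from scipy.linalg import solve_triangular

from .mcmc import (AdaptiveScalar, DenseOperator, IndicatorBasisOperator,
                   _log_q as _logq_gauss, _proposal as _trend_proposal,
                   gaussian_mh_update, newton_mode, split_diagnostics)
from .rw2 import pc_prior_rate, structure_matrix, sumzero_basis

REGIONAL_RW = "regional_rw"
GLOBAL_RW = "global_rw"


@dataclass(frozen=True)
class TrendModelSpec:
    """Model variant and prior settings."""

    variant: str = REGIONAL_RW
    #: PC prior (u, alpha) on the RW2 standard deviation: P(sigma > u) = alpha
    pc_u: float = 0.1
    pc_alpha: float = 0.01
    #: sd of the vague normal prior on fixed effects
    beta_sd: float = 10.0
    #: PC prior on region/site random-effect standard deviations
    sigma_re_u: float = 1.0
    sigma_re_alpha: float = 0.01
    #: exponential rate on 1/theta (overdispersion shrinks toward Poisson)
    inv_theta_rate: float = 1.0

    def __post_init__(self):
        if self.variant not in (REGIONAL_RW, GLOBAL_RW):
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.pc_u <= 0 or not (0 < self.pc_alpha < 1):
            raise ConfigError("invalid PC prior parameters")


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    compute_diagnostics: bool = True
    rhat_max: float = 1.05
    ess_min: float = 400.0


@dataclass
class TrendFit:
    """Posterior draws and bookkeeping for one fitted trend model."""

    spec: TrendModelSpec
    sampler: SamplerConfig
    data: pd.DataFrame
    years: np.ndarray
    regions: list[str]
    sites: list[tuple[str, str]]
    gears: list[str]
    reference_gear: str
    psi_names: list[str]
    psi: np.ndarray          # (S, p) flattened draws
    f: np.ndarray            # (S, n_trends, T); n_trends = regions or 1
    theta: np.ndarray        # (S,)
    sigma: dict[str, np.ndarray]
    eta: np.ndarray          # (S, n) linear predictor incl. offset
    loglik: np.ndarray       # (S, n) pointwise log-likelihood
    scalar_draws: dict[str, np.ndarray] = field(default_factory=dict)
    diagnostics: pd.DataFrame | None = None
    converged: bool | None = None

    @property
    def n_draws(self) -> int:
        return self.psi.shape[0]

    def psi_column(self, name: str) -> np.ndarray:
        return self.psi[:, self.psi_names.index(name)]

    def gear_coefficient(self, gear: str) -> np.ndarray:
        """Posterior draws of the gear contrast (0 for the reference gear)."""
        if gear == self.reference_gear:
            return np.zeros(self.n_draws)
        return self.psi_column(f"gear[{gear}]")

    def trend_for_region(self, region: str) -> np.ndarray:
        """(S, T) draws of the latent trend relevant to ``region``."""
        if self.f.shape[1] == 1:
            return self.f[:, 0, :]
        return self.f[:, self.regions.index(region), :]


def _check_data(data: pd.DataFrame) -> pd.DataFrame:
    required = {"region", "site", "financial_year", "gear", "catch", "effort"}
    missing = required - set(data.columns)
    if missing:
        raise DataError(f"trend-model data lacks columns {sorted(missing)}")
    if (data["effort"] <= 0).any():
        bad = data[data["effort"] <= 0].iloc[0]
        raise DataError(
            f"non-positive effort at (site={bad['site']!r}, "
            f"year={bad['financial_year']})"
        )
    y = data["catch"].to_numpy()
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise DataError("catch must be non-negative integers")
    return data.reset_index(drop=True)


def fit_trend_model(
    data: pd.DataFrame,
    spec: TrendModelSpec | None = None,
    sampler: SamplerConfig | None = None,
) -> TrendFit:
    """Sample the posterior of the NB-RW2 trend model on tidy cell data.

    ``data`` has one row per observed (region, site, financial_year, gear)
    cell with columns ``catch`` (count) and ``effort`` (> 0, gear-years).
    """
    spec = spec or TrendModelSpec()
    sampler = sampler or SamplerConfig()
    data = _check_data(data)

    y = data["catch"].to_numpy(dtype=float)
    offset = np.log(data["effort"].to_numpy(dtype=float))
    n = len(data)

    regions = sorted(data["region"].unique())
    site_pairs = sorted(set(zip(data["region"], data["site"])))
    gears = sorted(data["gear"].unique())
    if spec.variant == REGIONAL_RW and len(regions) < 2:
        raise ConfigError("regional_rw variant needs >= 2 regions")

    years_obs = data["financial_year"].to_numpy(dtype=int)
    year_grid = np.arange(years_obs.min(), years_obs.max() + 1)
    T = len(year_grid)
    use_trend = T >= 3
    year_idx = years_obs - year_grid[0]
    region_idx = pd.Categorical(data["region"], categories=regions).codes
    site_idx = np.array([site_pairs.index(p)
                         for p in zip(data["region"], data["site"])])

    # --- coefficient block design -----------------------------------------
    reference_gear = NET if NET in gears else gears[0]
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    for g in gears:
        if g != reference_gear:
            cols.append((data["gear"] == g).to_numpy(dtype=float))
            names.append(f"gear[{g}]")
    include_regions = len(regions) >= 2
    include_sites = len(site_pairs) > len(regions)
    u_slice = v_slice = slice(0, 0)
    if include_regions:
        start = len(names)
        for r_i, r in enumerate(regions):
            cols.append((region_idx == r_i).astype(float))
            names.append(f"region[{r}]")
        u_slice = slice(start, len(names))
    if include_sites:
        start = len(names)
        for s_i, (r, s) in enumerate(site_pairs):
            cols.append((site_idx == s_i).astype(float))
            names.append(f"site[{r}:{s}]")
        v_slice = slice(start, len(names))
    X = np.column_stack(cols)
    p = X.shape[1]
    n_fixed = len(names) - (u_slice.stop - u_slice.start) \
        - (v_slice.stop - v_slice.start)

    # --- latent trend design ----------------------------------------------
    if use_trend:
        B = sumzero_basis(T)
        K = B.T @ structure_matrix(T) @ B
        if spec.variant == REGIONAL_RW:
            M_trend = [IndicatorBasisOperator(
                year_idx, B, rows=np.flatnonzero(region_idx == r_i))
                for r_i in range(len(regions))]
        else:
            M_trend = [IndicatorBasisOperator(year_idx, B)]
        rank = T - 2
    else:
        B = K = None
        M_trend = []
        rank = 0
    n_trends = len(M_trend)
    X_op = DenseOperator(X)

    lam_rw = pc_prior_rate(spec.pc_u, spec.pc_alpha)
    lam_re = pc_prior_rate(spec.sigma_re_u, spec.sigma_re_alpha)

    S_keep = sampler.chains * sampler.draws
    psi_out = np.empty((S_keep, p))
    f_out = np.zeros((S_keep, max(n_trends, 1), T if use_trend else 0))
    theta_out = np.empty(S_keep)
    eta_out = np.empty((S_keep, n))
    ll_out = np.empty((S_keep, n))
    sig_out = {k: np.empty(S_keep) for k in ("sigma_region", "sigma_site",
                                             "sigma_rw")}
    scalar_chains: dict[str, np.ndarray] = {
        name: np.empty((sampler.chains, sampler.draws))
        for name in (["intercept", "log_theta", "log_sigma_rw"]
                     + (["gear"] if len(gears) > 1 else []))
    }

    ss = np.random.SeedSequence(sampler.seed)
    chain_seeds = ss.spawn(sampler.chains)
    base_intercept = np.log(max(y.sum(), 0.5) / data["effort"].sum())

    keep_i = 0
    for chain in range(sampler.chains):
        rng = np.random.default_rng(chain_seeds[chain])
        psi = np.zeros(p)
        psi[0] = base_intercept
        g_blocks = [np.zeros(T - 1) for _ in range(n_trends)]
        # warm start at the approximate joint mode, then jitter per chain
        fam0 = NegativeBinomial(1.0)
        prec0 = np.full(p, 1.0 / spec.beta_sd ** 2)
        prec0[n_fixed:] = 4.0
        eta0 = offset + X @ psi
        for _sweep in range(3):
            rest = eta0 - X @ psi
            psi, eta0 = newton_mode(psi, X_op, np.diag(prec0), rest, y, fam0)
            for b in range(n_trends):
                rest = eta0 - M_trend[b].dot(g_blocks[b])
                g_blocks[b], eta0 = newton_mode(
                    g_blocks[b], M_trend[b], 100.0 * K + 1e-6 * np.eye(T - 1),
                    rest, y, fam0)
        psi = psi + 0.05 * rng.standard_normal(p)
        g_blocks = [g + 0.01 * rng.standard_normal(T - 1) for g in g_blocks]
        ls_region = AdaptiveScalar(np.log(0.5) + 0.1 * rng.standard_normal(),
                                   step=0.3)
        ls_site = AdaptiveScalar(np.log(0.5) + 0.1 * rng.standard_normal(),
                                 step=0.3)
        ls_rw = AdaptiveScalar(np.log(0.1) + 0.1 * rng.standard_normal(),
                               step=0.3)
        ls_rw_scale = AdaptiveScalar(0.0, step=0.3, target=0.3)  # joint move
        lt = AdaptiveScalar(0.1 * rng.standard_normal(), step=0.3,
                            bounds=(-6.0, 14.0))

        trend_dot = (lambda g_list: sum(M.dot(g) for M, g
                                        in zip(M_trend, g_list))) \
            if use_trend else (lambda g_list: 0.0)
        eta_cur = offset + X @ psi + trend_dot(g_blocks)

        for it in range(sampler.warmup + sampler.draws):
            adapt = it < sampler.warmup
            theta = float(np.exp(lt.value))
            fam = NegativeBinomial(theta)

            # coefficient block
            prec = np.full(p, 1.0 / spec.beta_sd ** 2)
            if include_regions:
                prec[u_slice] = np.exp(-2 * ls_region.value)
            if include_sites:
                prec[v_slice] = np.exp(-2 * ls_site.value)
            lam = np.diag(prec)
            eta_rest = eta_cur - X @ psi
            psi, eta_cur, _ = gaussian_mh_update(
                psi, X_op, lam, eta_rest, y, fam, rng, eta_cur=eta_cur)

            # latent trend blocks
            if use_trend:
                tau = float(np.exp(-2 * ls_rw.value))
                for b in range(n_trends):
                    contrib = M_trend[b].dot(g_blocks[b])
                    eta_rest = eta_cur - contrib
                    g_blocks[b], eta_cur, _ = gaussian_mh_update(
                        g_blocks[b], M_trend[b], tau * K, eta_rest, y, fam,
                        rng, eta_cur=eta_cur)

            # hyperparameters
            if include_regions:
                u = psi[u_slice]

                def lp_region(ls):
                    s2 = np.exp(2 * ls)
                    return (-0.5 * float(u @ u) / s2 - u.size * ls
                            - lam_re * np.exp(ls) + ls)

                ls_region.update(lp_region, rng, adapt)
            if include_sites:
                v = psi[v_slice]

                def lp_site(ls):
                    s2 = np.exp(2 * ls)
                    return (-0.5 * float(v @ v) / s2 - v.size * ls
                            - lam_re * np.exp(ls) + ls)

                ls_site.update(lp_site, rng, adapt)
            for _rep in range(2 if use_trend else 0):
                qf = sum(float(g @ (K @ g)) for g in g_blocks)

                def lp_rw(ls):
                    tau_ = np.exp(-2 * ls)
                    return (-n_trends * rank * ls - 0.5 * tau_ * qf
                            - lam_rw * np.exp(ls) + ls)

                ls_rw.update(lp_rw, rng, adapt)

                # joint (sigma_rw, f) update: random-walk step on log sigma,
                # then refresh every trend block from its Gaussian proposal
                # under the proposed precision, accepting jointly — without
                # this the hyperparameter and the field move in lockstep
                ls_cur = ls_rw.value
                ls_new = ls_cur + np.exp(ls_rw_scale.log_step) \
                    * rng.standard_normal()
                in_support = ls_rw.bounds[0] <= ls_new <= ls_rw.bounds[1]
                tau_cur = np.exp(-2 * ls_cur)
                tau_new = np.exp(-2 * ls_new)
                g_new = []
                eta_work = eta_cur
                logq_fwd = logq_rev = 0.0
                try:
                    if not in_support:
                        raise np.linalg.LinAlgError  # reject out of support
                    for b in range(n_trends):
                        contrib = M_trend[b].dot(g_blocks[b])
                        eta_rest = eta_work - contrib
                        m_f, L_f = _trend_proposal(
                            g_blocks[b], M_trend[b], tau_new * K, eta_work,
                            y, fam)
                        gb_new = m_f + solve_triangular(
                            L_f.T, rng.standard_normal(T - 1), lower=False)
                        eta_prop = eta_rest + M_trend[b].dot(gb_new)
                        logq_fwd += _logq_gauss(L_f, gb_new, m_f)
                        m_r, L_r = _trend_proposal(
                            gb_new, M_trend[b], tau_cur * K, eta_prop, y,
                            fam)
                        logq_rev += _logq_gauss(L_r, g_blocks[b], m_r)
                        g_new.append(gb_new)
                        eta_work = eta_prop
                    qf_cur = sum(float(g @ (K @ g)) for g in g_blocks)
                    qf_new = sum(float(g @ (K @ g)) for g in g_new)
                    log_alpha = (
                        fam.loglik_eta(y, eta_work)
                        - fam.loglik_eta(y, eta_cur)
                        + (-n_trends * rank * ls_new - 0.5 * tau_new * qf_new)
                        - (-n_trends * rank * ls_cur - 0.5 * tau_cur * qf_cur)
                        - lam_rw * (np.exp(ls_new) - np.exp(ls_cur))
                        + (ls_new - ls_cur)          # log-sigma Jacobian
                        + logq_rev - logq_fwd
                    )
                except np.linalg.LinAlgError:
                    log_alpha = -np.inf  # ill-conditioned proposal: reject
                accepted = np.log(rng.random()) < log_alpha
                if accepted:
                    ls_rw.value = ls_new
                    g_blocks = g_new
                    eta_cur = eta_work
                if adapt:
                    ls_rw_scale.adapt(accepted)

            def lp_theta(t):
                return (NegativeBinomial(float(np.exp(t))).loglik(y, eta_cur)
                        - spec.inv_theta_rate * np.exp(-t) - t)

            lt.update(lp_theta, rng, adapt)
            lt.update(lp_theta, rng, adapt)

            if not adapt:
                d = it - sampler.warmup
                theta = float(np.exp(lt.value))
                psi_out[keep_i] = psi
                for b in range(n_trends):
                    f_out[keep_i, b] = B @ g_blocks[b]
                theta_out[keep_i] = theta
                eta_out[keep_i] = eta_cur
                ll_out[keep_i] = NegativeBinomial(theta).loglik_pointwise(
                    y, eta_cur)
                sig_out["sigma_region"][keep_i] = np.exp(ls_region.value)
                sig_out["sigma_site"][keep_i] = np.exp(ls_site.value)
                sig_out["sigma_rw"][keep_i] = np.exp(ls_rw.value)
                scalar_chains["intercept"][chain, d] = psi[0]
                if len(gears) > 1:
                    scalar_chains["gear"][chain, d] = psi[1]
                scalar_chains["log_theta"][chain, d] = lt.value
                scalar_chains["log_sigma_rw"][chain, d] = ls_rw.value
                keep_i += 1

    fit = TrendFit(
        spec=spec, sampler=sampler, data=data,
        years=year_grid, regions=regions, sites=site_pairs, gears=gears,
        reference_gear=reference_gear, psi_names=names,
        psi=psi_out, f=f_out, theta=theta_out, sigma=sig_out,
        eta=eta_out, loglik=ll_out, scalar_draws=scalar_chains,
    )
    if sampler.compute_diagnostics and sampler.chains >= 2:
        fit.diagnostics = split_diagnostics(scalar_chains)
        fit.converged = bool(
            (fit.diagnostics["rhat"] < sampler.rhat_max).all()
            and (fit.diagnostics["ess"] > sampler.ess_min).all()
        )
    return fit


# --- derived quantities ----------------------------------------------------

def compute_waic(loglik: np.ndarray) -> tuple[float, float, float]:
    """WAIC from a (draws x observations) pointwise log-likelihood matrix.

    Returns ``(waic, lppd, p_waic)`` with ``lppd = sum_i log mean_s exp(ll)``,
    ``p_waic = sum_i var_s(ll)`` (sample variance), and
    ``waic = -2 (lppd - p_waic)``.
    """
    ll = np.asarray(loglik, dtype=float)
    if ll.ndim != 2 or ll.shape[0] < 2:
        raise DataError("need a (draws >= 2) x observations matrix")
    if not np.all(np.isfinite(ll)):
        raise DataError("non-finite log-likelihood values")
    S = ll.shape[0]
    m = ll.max(axis=0)
    lppd = float(np.sum(np.log(np.mean(np.exp(ll - m), axis=0)) + m))
    p_waic = float(np.sum(ll.var(axis=0, ddof=1)))
    return -2.0 * (lppd - p_waic), lppd, p_waic


def predicted_cpue(
    fit: TrendFit,
    gear: str,
    region: str | None = None,
) -> pd.DataFrame:
    """Posterior fitted CPUE at unit effort of ``gear``, per year.

    For a region, ``exp(b0 + gear + u_r + f_{r,t})`` per draw; program-wide
    (``region=None``), the arithmetic mean of the region-level curves.
    Returns a DataFrame with posterior mean and central 95% interval.
    """
    draws = cpue_draws(fit, gear, region)
    lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "financial_year": fit.years,
        "cpue_mean": draws.mean(axis=0),
        "cpue_lo": lo,
        "cpue_hi": hi,
    })


def cpue_draws(fit: TrendFit, gear: str, region: str | None = None) -> np.ndarray:
    """(S, T) draws of fitted unit-effort CPUE for ``gear``."""
    if gear not in fit.gears:
        raise DataError(f"gear {gear!r} not in fitted data")
    base = fit.psi_column("intercept") + fit.gear_coefficient(gear)
    region_list = [region] if region is not None else fit.regions
    curves = []
    for r in region_list:
        if r not in fit.regions:
            raise DataError(f"region {r!r} not in fitted data")
        level = base.copy()
        name = f"region[{r}]"
        if name in fit.psi_names:
            level = level + fit.psi_column(name)
        curves.append(np.exp(level[:, None] + fit.trend_for_region(r)))
    return np.mean(curves, axis=0)


def percent_decline(mu_first, mu_last=None, **kwargs):
    """Percent decline ``100 (1 - mu_last / mu_first)``.

    Two call forms: with scalar endpoint means (returns a float), or with a
    :class:`TrendFit` as the first argument (returns a posterior summary
    dict; see :func:`percent_decline_from_fit` for keywords).
    """
    if isinstance(mu_first, TrendFit):
        return percent_decline_from_fit(mu_first, **kwargs)
    if mu_first <= 0:
        raise DataError("mu_first must be > 0")
    return 100.0 * (1.0 - mu_last / mu_first)


def percent_decline_from_fit(
    fit: TrendFit,
    gear: str | None = None,
    region: str | None = None,
    year0: int | None = None,
    year1: int | None = None,
) -> dict:
    """Posterior percent decline between two years of the fitted smooth."""
    gear = gear or fit.reference_gear
    draws = cpue_draws(fit, gear, region)
    i0 = 0 if year0 is None else int(np.where(fit.years == year0)[0][0])
    i1 = len(fit.years) - 1 if year1 is None else \
        int(np.where(fit.years == year1)[0][0])
    pd_draws = 100.0 * (1.0 - draws[:, i1] / draws[:, i0])
    lo, hi = np.percentile(pd_draws, [2.5, 97.5])
    return {
        "mean": float(pd_draws.mean()),
        "median": float(np.median(pd_draws)),
        "lo": float(lo),
        "hi": float(hi),
        "headline": int(round(float(np.median(pd_draws)))),
        "draws": pd_draws,
    }


def fold_change(p_first: float, p_last: float) -> float:
    """Ratio ``p_last / p_first`` (e.g. rise in zero-catch probability)."""
    if p_first <= 0:
        raise DataError("p_first must be > 0")
    return p_last / p_first


def zero_catch_probability(fit: TrendFit, year: int, region: str) -> dict:
    """Posterior annual zero-catch probability for a region's sites.

    For each draw and each site with effort in ``year``, the probability of
    catching no sharks at that site across its deployed gear is the product
    over the site's cells of ``(theta / (theta + mu))^theta`` with ``mu``
    evaluated at the cell's actual effort. Site values are averaged within
    the region; posterior means and central 95% intervals are returned for
    both levels.
    """
    if region not in fit.regions:
        raise DataError(f"region {region!r} not in fitted data")
    if year not in set(fit.years):
        raise DataError(f"year {year} outside fitted span")
    sel = (fit.data["region"] == region) & (fit.data["financial_year"] == year)
    rows = np.flatnonzero(sel.to_numpy())
    if rows.size == 0:
        raise DataError(f"no effort cells for {region!r} in {year}")
    mu = np.exp(fit.eta[:, rows])                       # (S, cells)
    p0_cells = nb_zero_probability(mu, fit.theta[:, None])
    sites = fit.data.loc[sel, "site"].to_numpy()
    site_names = sorted(set(sites))
    site_p0 = np.empty((fit.n_draws, len(site_names)))
    for j, s in enumerate(site_names):
        site_p0[:, j] = np.prod(p0_cells[:, sites == s], axis=1)
    region_draws = site_p0.mean(axis=1)
    lo, hi = np.percentile(region_draws, [2.5, 97.5])
    site_lo, site_hi = np.percentile(site_p0, [2.5, 97.5], axis=0)
    return {
        "region": region,
        "year": int(year),
        "mean": float(region_draws.mean()),
        "lo": float(lo),
        "hi": float(hi),
        "draws": region_draws,
        "sites": pd.DataFrame({
            "site": site_names,
            "mean": site_p0.mean(axis=0),
            "lo": site_lo,
            "hi": site_hi,
        }),
    }


def zero_catch_curve(fit: TrendFit) -> pd.DataFrame:
    """Program-wide zero-catch probability per year.

    Region averages of site-level zero-catch probabilities, averaged across
    regions, per posterior draw.
    """
    rows = []
    for year in fit.years:
        per_region = []
        for region in fit.regions:
            sel = ((fit.data["region"] == region)
                   & (fit.data["financial_year"] == year))
            if not sel.any():
                continue
            per_region.append(zero_catch_probability(fit, year, region)["draws"])
        if not per_region:
            continue
        draws = np.mean(per_region, axis=0)
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append((int(year), float(draws.mean()), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["financial_year", "p_zero_mean",
                                       "p_zero_lo", "p_zero_hi"])


def require_converged(fit: TrendFit) -> TrendFit:
    """Raise :class:`ConvergenceError` if the fit failed its contract."""
    if fit.converged is False:
        worst = fit.diagnostics.sort_values("rhat", ascending=False).iloc[0]
        raise ConvergenceError(
            f"chains not converged: worst R-hat {worst['rhat']:.3f} "
            f"({worst['parameter']}), min ESS "
            f"{fit.diagnostics['ess'].min():.0f}"
        )
    return fit
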