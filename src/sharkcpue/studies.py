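"""Simulation studies: parameter recovery, model selection, depletion.

Each study simulates programs from :mod:`sharkcpue.synthetic` under known
truth, runs the corresponding estimator, and reports recovery/selection
rates. Problem sizes are deliberately modest (a few regions and sites,
30--40 year spans, hundreds of posterior draws per replicate) so full
replicate suites run on a single CPU in minutes; the replicate counts and
thresholds quoted in the docstrings refer to those scaled study designs.
"""

from __future__ import annotations

import numpy as np

from .config import (BeachSpec, GroupSpec, ProgramConfig, RegionSpec,
                     SizeModel)
from .depletion import build_initial_records, fit_initial_trend
from .records import compute_cpue, count_catches, installation_years
from .synthetic import simulate_program
from .trend import (GLOBAL_RW, REGIONAL_RW, SamplerConfig, TrendModelSpec,
                    compute_waic, fit_trend_model, percent_decline_from_fit)

_SIZE = SizeModel(intercept_cm=200.0, slope_cm_per_yr=0.0, sd_cm=40.0,
                  min_tl=60.0, max_tl=400.0)


def _study_config(
    n_regions: int,
    n_sites: int,
    n_years: int,
    decline_rate: float,
    catchability: dict[str, float],
    theta: float,
    seed: int,
    region_decline: list[float] | None = None,
    staggered: bool = False,
    year0: int = 1962,
) -> ProgramConfig:
    """One-group program used across the studies."""
    regions = []
    span = (year0, year0 + n_years - 1)
    for r in range(n_regions):
        beaches = []
        for s in range(n_sites):
            if staggered:
                frac = (r * n_sites + s) / max(n_regions * n_sites - 1, 1)
                installed = year0 + int(round(frac * (n_years - 1) * 0.65))
            else:
                installed = year0
            beaches.append(BeachSpec(
                name=f"r{r}_s{s}", installed=installed,
                net_effort=1.0,
                drumline_effort=1.0 if "drumline" in catchability else 0.0,
            ))
        override = None
        if region_decline is not None:
            override = {"g": region_decline[r]}
        regions.append(RegionSpec(name=f"r{r}", beaches=tuple(beaches),
                                  decline_rate=override))
    groups = {"g": GroupSpec(decline_rate=decline_rate, dispersion=theta,
                             catchability=catchability, size=_SIZE)}
    return ProgramConfig(years=span, regions=tuple(regions), groups=groups,
                         unknown_gear_rate=0.0, species_recorded_from=None,
                         seed=seed)


def _trend_data(config: ProgramConfig):
    catch, effort = simulate_program(config)
    grid = compute_cpue(count_catches(catch, groups=["g"]), effort)
    return grid[["region", "site", "financial_year", "gear", "catch",
                 "effort"]], effort, grid


_FAST = dict(chains=2, warmup=300, draws=300, compute_diagnostics=False)


def decline_coverage_study(
    n_replicates: int = 50,
    seed: int = 0,
    true_decline: float = 80.0,
    n_regions: int = 4,
    n_sites: int = 3,
    n_years: int = 40,
    theta: float = 2.0,
) -> dict:
    """Coverage of the percent-decline posterior interval under known truth.

    Programs decline geometrically so that the endpoint CPUE ratio equals
    ``1 - true_decline/100``; each replicate fits the shared-trend model
    variant and checks whether the central 95% interval covers the truth.
    """
    rate = 1.0 - (1.0 - true_decline / 100.0) ** (1.0 / (n_years - 1))
    ss = np.random.SeedSequence([seed, 2025])
    covered = 0
    estimates = []
    for rep, child in enumerate(ss.spawn(n_replicates)):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = _study_config(n_regions, n_sites, n_years, rate,
                            {"net": 10.0, "drumline": 2.5}, theta, rep_seed)
        data, _, _ = _trend_data(cfg)
        fit = fit_trend_model(
            data, TrendModelSpec(variant=GLOBAL_RW),
            SamplerConfig(seed=rep_seed, **_FAST))
        res = percent_decline_from_fit(fit, gear="net")
        covered += int(res["lo"] <= true_decline <= res["hi"])
        estimates.append(res["median"])
    return {
        "coverage": covered / n_replicates,
        "covered": covered,
        "n": n_replicates,
        "true_decline": true_decline,
        "median_estimate": float(np.median(estimates)),
    }


def intercept_recovery_study(
    n_replicates: int = 100,
    seed: int = 0,
    cpue_truth: float = 5.0,
    n_years: int = 8,
    theta: float = 2.0,
) -> dict:
    """Single-site constant-rate programs: does the 95% interval for the
    intercept (log CPUE) cover the truth?"""
    ss = np.random.SeedSequence([seed, 7])
    covered = 0
    truth = np.log(cpue_truth)
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = _study_config(1, 1, n_years, 0.0, {"net": cpue_truth}, theta,
                            rep_seed)
        data, _, _ = _trend_data(cfg)
        fit = fit_trend_model(
            data, TrendModelSpec(variant=GLOBAL_RW),
            SamplerConfig(seed=rep_seed, chains=2, warmup=200, draws=200,
                          compute_diagnostics=False))
        draws = fit.psi_column("intercept")
        lo, hi = np.percentile(draws, [2.5, 97.5])
        covered += int(lo <= truth <= hi)
    return {"coverage": covered / n_replicates, "covered": covered,
            "n": n_replicates}


def gear_effect_recovery(seed: int = 0, log_ratio: float = np.log(2.0)) -> dict:
    """Recover a known gear catchability contrast (drumline vs net)."""
    cfg = _study_config(1, 3, 20, 0.02,
                        {"net": 4.0, "drumline": 4.0 * np.exp(log_ratio)},
                        2.0, seed)
    data, _, _ = _trend_data(cfg)
    fit = fit_trend_model(data, TrendModelSpec(variant=GLOBAL_RW),
                          SamplerConfig(seed=seed, **_FAST))
    draws = fit.psi_column("gear[drumline]")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return {"truth": float(log_ratio), "mean": float(draws.mean()),
            "lo": float(lo), "hi": float(hi),
            "covered": bool(lo <= log_ratio <= hi)}


def dispersion_recovery(seed: int = 0) -> dict:
    """Near-Poisson data: the NB size posterior should sit above 50."""
    cfg = _study_config(1, 8, 40, 0.0, {"net": 12.0}, 1e6, seed)
    data, _, _ = _trend_data(cfg)
    fit = fit_trend_model(data, TrendModelSpec(variant=GLOBAL_RW),
                          SamplerConfig(seed=seed, **_FAST))
    return {"theta_median": float(np.median(fit.theta)),
            "theta_p25": float(np.percentile(fit.theta, 25))}


def waic_selection_study(
    n_simulations: int = 20,
    seed: int = 0,
    region_declines: tuple[float, ...] = (0.0, 0.03, 0.06, 0.09),
    n_sites: int = 2,
    n_years: int = 30,
) -> dict:
    """How often WAIC prefers the generating (region-specific trend) variant
    over the shared-trend variant on strongly divergent regional data."""
    ss = np.random.SeedSequence([seed, 99])
    preferred = 0
    for child in ss.spawn(n_simulations):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = _study_config(len(region_declines), n_sites, n_years, 0.0,
                            {"net": 8.0, "drumline": 2.0}, 2.0, rep_seed,
                            region_decline=list(region_declines))
        data, _, _ = _trend_data(cfg)
        waics = {}
        for variant in (REGIONAL_RW, GLOBAL_RW):
            fit = fit_trend_model(data, TrendModelSpec(variant=variant),
                                  SamplerConfig(seed=rep_seed, **_FAST))
            waics[variant] = compute_waic(fit.loglik)[0]
        preferred += int(waics[REGIONAL_RW] <= waics[GLOBAL_RW])
    return {"preference_rate": preferred / n_simulations,
            "preferred": preferred, "n": n_simulations}


def _depletion_fit(config: ProgramConfig, seed: int):
    _, effort, grid = _trend_data(config)
    schedule = installation_years(effort)
    sub = grid[grid["gear"] == "net"]
    records = build_initial_records(sub, schedule[schedule["gear"] == "net"])
    return fit_initial_trend(
        records, sampler=SamplerConfig(seed=seed, chains=2, warmup=300,
                                       draws=300,
                                       compute_diagnostics=False))


def depletion_directional_study(seed: int = 0) -> dict:
    """Declining program with staggered installations: the initial-CPUE
    slope should be negative with high posterior probability."""
    cfg = _study_config(4, 6, 40, 0.06, {"net": 12.0}, 5.0, seed,
                        staggered=True)
    fit = _depletion_fit(cfg, seed)
    return {"beta1_mean": float(fit.beta1.mean()),
            "prob_negative": float(np.mean(fit.beta1 < 0))}


def depletion_null_coverage_study(
    n_replicates: int = 100,
    seed: int = 0,
) -> dict:
    """Stable programs: the slope interval should cover zero ~95% of runs.

    Counts are generated at near-Poisson dispersion so the replicates match
    the Poisson likelihood being checked; overdispersed programs would test
    model misspecification, not interval calibration.
    """
    ss = np.random.SeedSequence([seed, 17])
    covered = 0
    for child in ss.spawn(n_replicates):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        cfg = _study_config(3, 4, 30, 0.0, {"net": 6.0}, 1e6, rep_seed,
                            staggered=True)
        fit = _depletion_fit(cfg, rep_seed)
        lo, hi = np.percentile(fit.beta1, [2.5, 97.5])
        covered += int(lo <= 0.0 <= hi)
    return {"coverage": covered / n_replicates, "covered": covered,
            "n": n_replicates}
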