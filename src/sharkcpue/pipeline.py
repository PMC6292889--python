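"""End-to-end orchestration: simulate -> clean -> CPUE -> models -> report.

Each stage logs record counts in and out, failures halt with a stage-named
error, and every run writes a manifest (config hash, seed, versions, input
digests) so reported numbers are traceable. Rerunning with the same config
and seed reproduces the tables byte for byte (the manifest's timestamp is
the only field that differs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .config import ProgramConfig
from .depletion import build_initial_records, fit_initial_trend, \
    initial_decline_percent
from .errors import SharkCPUEError
from . import io
from .records import (allocate_unknown_gear, compute_cpue, count_catches,
                      filter_lengths, installation_years)
from .size_maturity import (DEFAULT_MATURITY_CUTOFFS, DEFAULT_TL_MAX,
                            fit_maturity_trend, fit_size_trend)
from .synthetic import simulate_program
from .trend import (SamplerConfig, TrendModelSpec, compute_waic, fold_change,
                    fit_trend_model, percent_decline_from_fit, predicted_cpue,
                    zero_catch_curve)

log = logging.getLogger("sharkcpue")


@dataclass
class PipelineOptions:
    groups: list[str] | None = None
    variants: tuple[str, ...] = ("regional_rw", "global_rw")
    sampler: SamplerConfig = field(default_factory=lambda: SamplerConfig(
        chains=2, warmup=400, draws=400, compute_diagnostics=True,
    ))
    trend_spec: TrendModelSpec = field(default_factory=TrendModelSpec)
    tl_max: dict = field(default_factory=lambda: dict(DEFAULT_TL_MAX))
    maturity_cutoffs: dict = field(
        default_factory=lambda: dict(DEFAULT_MATURITY_CUTOFFS))
    min_tl: float = 30.0
    depletion_window: int = 5
    depletion_max_install_year: int | None = None
    make_figures: bool = True


class StageError(SharkCPUEError):
    """A pipeline stage failed; the stage name prefixes the message."""


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kwargs)
            except SharkCPUEError as exc:
                raise StageError(f"[{name}] {exc}") from exc
        return wrapper
    return deco


def run_pipeline(
    config: ProgramConfig,
    outdir,
    options: PipelineOptions | None = None,
    catch: pd.DataFrame | None = None,
    effort: pd.DataFrame | None = None,
) -> dict:
    """Run the full analysis; returns the in-memory report bundle.

    With ``catch``/``effort`` omitted, tables are simulated from ``config``.
    """
    opts = options or PipelineOptions()
    out = io.ensure_dir(outdir)
    bundle: dict = {"outdir": str(out)}

    if catch is None or effort is None:
        catch, effort = _simulate(config)
    io.write_catch_csv(catch, out / "catch.csv")
    io.write_effort_csv(effort, out / "effort.csv")

    kept, exclusions, allocated = _clean(catch, opts)
    exclusions.to_csv(out / "exclusions.csv", index=False)
    bundle["cleaning"] = {
        "records_in": len(catch),
        "excluded_length": len(exclusions),
        "unknown_gear_allocated": int((catch["gear"] == "unknown").sum()),
        "unknown_gear_fraction": float((catch["gear"] == "unknown").mean())
        if len(catch) else 0.0,
    }
    log.info("cleaning: %d in, %d length exclusions, %d unknown-gear "
             "records allocated", *[bundle["cleaning"][k] for k in
                                    ("records_in", "excluded_length",
                                     "unknown_gear_allocated")])

    groups = opts.groups or sorted(allocated["group"].unique())
    cpue = _cpue(allocated, effort, groups)
    cpue.to_csv(out / "cpue.csv", index=False)
    bundle["cpue"] = cpue

    bundle["trend"] = {}
    for group in groups:
        bundle["trend"][group] = _trend_stage(cpue, group, opts, out)

    bundle["depletion"] = _depletion_stage(cpue, effort, groups, opts, out)
    bundle["size_maturity"] = _size_stage(kept, groups, opts, out)

    manifest = io.build_manifest(
        config.to_dict(), config.seed,
        inputs={"catch.csv": io.file_digest(out / "catch.csv"),
                "effort.csv": io.file_digest(out / "effort.csv")},
        extra={"groups": groups,
               "convergence": {
                   g: {v: bundle["trend"][g][v]["converged"]
                       for v in bundle["trend"][g]}
                   for g in bundle["trend"]}},
    )
    io.write_json(manifest, out / "manifest.json")
    bundle["manifest"] = manifest

    if opts.make_figures:
        try:
            _figures(bundle, out)
        except Exception as exc:  # figures are non-contractual
            log.warning("figure generation failed: %s", exc)
    return bundle


@_stage("simulate")
def _simulate(config):
    return simulate_program(config)


@_stage("clean")
def _clean(catch, opts):
    kept, exclusions = filter_lengths(catch, opts.tl_max, min_tl=opts.min_tl)
    allocated = allocate_unknown_gear(kept, mode="deterministic")
    return kept, exclusions, allocated


@_stage("cpue")
def _cpue(allocated, effort, groups):
    counts = count_catches(allocated, groups=groups)
    return compute_cpue(counts, effort)


@_stage("trend")
def _trend_stage(cpue, group, opts, out: Path):
    data = cpue[cpue["group"] == group][
        ["region", "site", "financial_year", "gear", "catch", "effort"]]
    results = {}
    for variant in opts.variants:
        spec = replace(opts.trend_spec, variant=variant)
        fit = fit_trend_model(data, spec, opts.sampler)
        waic, lppd, p_waic = compute_waic(fit.loglik)
        entry = {
            "variant": variant,
            "waic": waic, "lppd": lppd, "p_waic": p_waic,
            "converged": fit.converged,
            "percent_decline": {},
        }
        for gear in fit.gears:
            pdec = percent_decline_from_fit(fit, gear=gear)
            entry["percent_decline"][gear] = {
                k: pdec[k] for k in ("mean", "median", "lo", "hi", "headline")}
            predicted_cpue(fit, gear).to_csv(
                out / f"fitted_cpue_{group}_{gear}_{variant}.csv", index=False)
        curve = zero_catch_curve(fit)
        curve.to_csv(out / f"zero_catch_{group}_{variant}.csv", index=False)
        if len(curve) >= 2 and curve["p_zero_mean"].iloc[0] > 0:
            entry["zero_catch_fold_change"] = fold_change(
                float(curve["p_zero_mean"].iloc[0]),
                float(curve["p_zero_mean"].iloc[-1]))
        entry["_fit"] = fit
        entry["_curve"] = curve
        results[variant] = entry
        io.write_json({k: v for k, v in entry.items()
                       if not k.startswith("_")},
                      out / f"trend_{group}_{variant}.json")
    if len(results) > 1:
        best = min(results, key=lambda v: results[v]["waic"])
        for v in results:
            results[v]["waic_preferred"] = (v == best)
    return results


@_stage("depletion")
def _depletion_stage(cpue, effort, groups, opts, out: Path):
    schedule = installation_years(effort)
    results = {}
    for group in groups:
        series = cpue[cpue["group"] == group]
        for gear in sorted(series["gear"].unique()):
            sub_sched = schedule[schedule["gear"] == gear]
            sub = series[series["gear"] == gear]
            if not len(sub):
                continue
            records = build_initial_records(
                sub, sub_sched, window=opts.depletion_window,
                max_install_year=opts.depletion_max_install_year)
            key = f"{group}_{gear}"
            records.to_csv(out / f"initial_cpue_{key}.csv", index=False)
            if records["installed"].nunique() < 2:
                log.info("depletion %s: single installation year, skipped",
                         key)
                continue
            fit = fit_initial_trend(records, sampler=opts.sampler)
            decl = initial_decline_percent(
                fit,
                year0=int(records["installed"].min()),
                year1=int(records["installed"].max()))
            results[key] = {
                "beta1_mean": float(fit.beta1.mean()),
                "prob_decline": decl["prob_decline"],
                "initial_decline_percent": {
                    k: decl[k] for k in ("mean", "median", "lo", "hi",
                                         "headline")},
                "converged": fit.converged,
                "_records": records,
            }
            io.write_json({k: v for k, v in results[key].items()
                           if not k.startswith("_")},
                          out / f"depletion_{key}.json")
    return results


@_stage("size_maturity")
def _size_stage(kept, groups, opts, out: Path):
    results: dict = {"size": {}, "maturity": {}}
    sized = kept.dropna(subset=["total_length_cm"])
    if not len(sized):
        log.info("size/maturity: no length data, stages skipped")
        return results
    for group in groups:
        sub = sized[sized["group"] == group]
        if len(sub) < 30 or sub["financial_year"].nunique() < 2:
            log.info("size %s: insufficient data, skipped", group)
            continue
        fit = fit_size_trend(sub)
        years = sub["financial_year"]
        first, last = int(years.min()), int(years.max())
        results["size"][group] = {
            "slope_cm_per_yr": fit.slope_cm_per_yr,
            "se": fit.slope_se,
            "p": fit.slope_p,
            "stars": fit.stars,
            "mean_first": fit.mean_length(first),
            "mean_last": fit.mean_length(last),
            "n": fit.n_records,
            "singular": fit.lmm.singular,
        }
        io.write_json(results["size"][group], out / f"size_{group}.json")
    with_species = sized[sized["species"] != ""]
    for (species, sex), cutoff in opts.maturity_cutoffs.items():
        sub = with_species[(with_species["species"] == species)
                           & (with_species["sex"] == sex)]
        if len(sub) < 30 or sub["financial_year"].nunique() < 2:
            continue
        mature = sub["total_length_cm"] >= cutoff
        if mature.all() or not mature.any():
            continue
        fit = fit_maturity_trend(sub, species, sex, opts.maturity_cutoffs)
        first = int(sub["financial_year"].min())
        last = int(sub["financial_year"].max())
        results["maturity"][f"{species}_{sex}"] = {
            "slope_per_yr": fit.slope_per_yr,
            "p_first": fit.predicted_probability(first),
            "p_last": fit.predicted_probability(last),
            "separation": fit.glmm.separation,
            "n": fit.n_records,
        }
        io.write_json(results["maturity"][f"{species}_{sex}"],
                      out / f"maturity_{species}_{sex}.json")
    return results


def _figures(bundle, out: Path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for group, variants in bundle["trend"].items():
        entry = next(iter(variants.values()))
        fit = entry["_fit"]
        fig, axes = plt.subplots(1, 2, figsize=(9, 3.2), sharex=True)
        for ax, gear in zip(axes, fit.gears):
            pred = predicted_cpue(fit, gear)
            ax.fill_between(pred["financial_year"], pred["cpue_lo"],
                            pred["cpue_hi"], alpha=0.3)
            ax.plot(pred["financial_year"], pred["cpue_mean"])
            ax.set_title(f"{group} ({gear})")
            ax.set_xlabel("financial year")
            ax.set_ylabel("CPUE (sharks / gear-year)")
        fig.tight_layout()
        fig.savefig(out / f"fig_cpue_{group}.png", dpi=110)
        plt.close(fig)

    for key, entry in bundle.get("depletion", {}).items():
        rec = entry["_records"]
        fig, ax = plt.subplots(figsize=(4.5, 3.2))
        ax.scatter(rec["installed"], rec["initial_cpue"], s=12)
        ax.set_xlabel("installation year")
        ax.set_ylabel("initial CPUE")
        ax.set_title(key)
        fig.tight_layout()
        fig.savefig(out / f"fig_initial_cpue_{key}.png", dpi=110)
        plt.close(fig)
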