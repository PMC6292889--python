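"""Synthetic shark-control-program generator.

Generates effort and catch tables with the statistical structure the
downstream analyses assume: staggered beach installations across regions,
two gear types with different catchabilities, latent abundance declining
either geometrically or through explicit harvest feedback, negative-binomial
catch counts per (site, year, gear, group) cell, truncated-normal total
lengths with a linear temporal trend, and optional contamination (unknown
gear labels, imperial-unit length entries) for the cleaning rules to find.

The negative binomial is parameterized by (mean ``mu``, size ``theta``) with
``Var = mu + mu^2/theta`` — the same parameterization the trend model fits.
All randomness flows from ``config.seed`` through a single
``numpy.random.Generator``; a fixed seed yields byte-identical tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import UNKNOWN, ProgramConfig, RegionSpec
from .errors import ConfigError, DataError

EFFORT_COLUMNS = ["region", "site", "financial_year", "gear", "effort"]
CATCH_COLUMNS = [
    "date", "region", "site", "gear", "group", "species",
    "total_length_cm", "sex", "financial_year",
]


def build_installation_schedule(config: ProgramConfig) -> pd.DataFrame:
    """Effort table implied by the configured installation schedule.

    One row per (site, financial year, gear) with positive standing effort,
    from each beach's installation year through the end of the span. Beaches
    contribute nothing before installation.
    """
    config.validate()
    rows = []
    for region in config.regions:
        for beach in region.beaches:
            for year in range(beach.installed, config.years[1] + 1):
                for gear, effort in beach.gear_effort.items():
                    if effort > 0:
                        rows.append((region.name, beach.name, year, gear, effort))
    return pd.DataFrame(rows, columns=EFFORT_COLUMNS)


def simulate_latent_abundance(
    config: ProgramConfig,
    region: RegionSpec | str,
    group: str,
    catches: dict[int, float] | None = None,
) -> pd.Series:
    """Latent relative abundance of ``group`` in ``region``, per year.

    Without harvest feedback the series is geometric,
    ``N_t = N_0 (1 - r)^(t - t0)``. With feedback enabled, realized catch is
    removed: ``N_{t+1} = max(0, N_t (1 - r) - c * catch_t)`` where ``c`` is
    the removal coefficient and ``catch_t`` the region-wide catch of the
    group in year ``t`` (zero where ``catches`` has no entry).
    """
    if isinstance(region, str):
        try:
            region = next(r for r in config.regions if r.name == region)
        except StopIteration:
            raise ConfigError(f"unknown region {region!r}") from None
    if group not in config.groups:
        raise ConfigError(f"unknown group {group!r}")
    rate = config.decline_rate(region, group)
    if not (0.0 <= rate < 1.0):
        raise ConfigError(f"decline_rate {rate} outside [0, 1)")
    n0 = region.abundance0
    if n0 <= 0:
        raise ConfigError("abundance0 must be > 0")
    years = list(config.year_range)
    feedback = config.harvest_feedback
    values = np.empty(len(years))
    n = float(n0)
    for i, year in enumerate(years):
        values[i] = n
        if feedback.enabled:
            removed = feedback.removal_coeff * (catches or {}).get(year, 0.0)
            n = max(0.0, n * (1.0 - rate) - removed)
        else:
            n = n * (1.0 - rate)
    return pd.Series(values, index=pd.Index(years, name="financial_year"), name=group)


def _truncated_normal(rng, mean, sd, lo, hi):
    """Rejection sampler for elementwise-truncated normals (bounds are wide,
    so acceptance is high and exactness is preferred over a ppf transform)."""
    mean = np.asarray(mean, dtype=float)
    out = rng.normal(mean, sd)
    bad = (out < lo) | (out > hi)
    guard = 0
    while bad.any():
        out[bad] = rng.normal(mean[bad], sd)
        bad = (out < lo) | (out > hi)
        guard += 1
        if guard > 10_000:  # pathological config: bounds exclude nearly all mass
            raise ConfigError("size-model truncation bounds reject all samples")
    return out


def _financial_year_start(year: int) -> pd.Timestamp:
    return pd.Timestamp(year=year, month=7, day=1)


def simulate_catches(
    config: ProgramConfig,
    effort: pd.DataFrame,
    abundance: dict[tuple[str, str], pd.Series] | None = None,
) -> pd.DataFrame:
    """Draw a catch table conditional on an effort table.

    Per (site, year, gear, group) cell the catch count is
    ``NegBin(mean = catchability * effort * N_t, size = theta)``; each shark
    receives a truncated-normal total length, a Bernoulli sex, a species
    label (where the group has a species mix and the year is at or past
    ``species_recorded_from``) and a uniform date within the financial year.

    When harvest feedback is enabled, abundance is propagated year by year
    using realized catches summed within region; a pre-supplied ``abundance``
    mapping overrides the internal dynamics (keys ``(region, group)``).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    t0 = config.years[0]
    effort = effort.sort_values(["region", "site", "financial_year", "gear"],
                                kind="mergesort").reset_index(drop=True)

    precomputed = abundance is not None
    if not precomputed and not config.harvest_feedback.enabled:
        abundance = {
            (r.name, g): simulate_latent_abundance(config, r, g)
            for r in config.regions
            for g in config.groups
        }
        precomputed = True

    records: list[tuple] = []
    group_names = list(config.groups)
    # feedback state: current abundance per (region, group)
    state = {(r.name, g): r.abundance0 for r in config.regions for g in config.groups}
    region_by_name = {r.name: r for r in config.regions}

    for year in config.year_range:
        year_rows = effort[effort["financial_year"] == year]
        catch_totals: dict[tuple[str, str], float] = {}
        for row in year_rows.itertuples(index=False):
            region = region_by_name.get(row.region)
            if region is None:
                raise DataError(f"effort row references unknown region {row.region!r}")
            for group in group_names:
                gspec = config.groups[group]
                if precomputed:
                    series = abundance[(row.region, group)]
                    if year not in series.index:
                        raise DataError(
                            f"abundance series for ({row.region}, {group}) "
                            f"missing year {year}"
                        )
                    n_t = float(series.loc[year])
                else:
                    n_t = state[(row.region, group)]
                q = gspec.catchability.get(row.gear, 0.0)
                mu = q * row.effort * n_t
                if mu <= 0:
                    continue
                theta = gspec.dispersion
                count = int(rng.negative_binomial(theta, theta / (theta + mu)))
                if count == 0:
                    continue
                catch_totals[(row.region, group)] = (
                    catch_totals.get((row.region, group), 0.0) + count
                )
                sm = gspec.size
                mean_tl = sm.intercept_cm + sm.slope_cm_per_yr * (year - t0)
                lengths = _truncated_normal(
                    rng, np.full(count, mean_tl), sm.sd_cm, sm.min_tl, sm.max_tl
                )
                sexes = np.where(rng.random(count) < gspec.sex_ratio, "F", "M")
                days = rng.integers(0, 365, size=count)
                start = _financial_year_start(year)
                record_species = (
                    gspec.species_mix is not None
                    and (config.species_recorded_from is None
                         or year >= config.species_recorded_from)
                )
                if record_species:
                    labels = list(gspec.species_mix)
                    probs = np.array([gspec.species_mix[s] for s in labels], float)
                    probs = probs / probs.sum()
                    species = rng.choice(labels, size=count, p=probs)
                else:
                    species = np.full(count, "", dtype=object)
                for k in range(count):
                    records.append((
                        (start + pd.Timedelta(days=int(days[k]))).date().isoformat(),
                        row.region, row.site, row.gear, group,
                        str(species[k]), float(lengths[k]), str(sexes[k]), year,
                    ))
        if not precomputed:
            for key, n_t in state.items():
                region = region_by_name[key[0]]
                rate = config.decline_rate(region, key[1])
                removed = (config.harvest_feedback.removal_coeff
                           * catch_totals.get(key, 0.0))
                state[key] = max(0.0, n_t * (1.0 - rate) - removed)

    catch = pd.DataFrame(records, columns=CATCH_COLUMNS)

    if config.unknown_gear_rate > 0 and len(catch):
        mask = rng.random(len(catch)) < config.unknown_gear_rate
        catch.loc[mask, "gear"] = UNKNOWN
    if config.imperial_error_rate > 0 and len(catch):
        mask = rng.random(len(catch)) < config.imperial_error_rate
        divisor = np.where(rng.random(len(catch)) < 0.5, 2.54, 30.48)
        catch.loc[mask, "total_length_cm"] = (
            catch.loc[mask, "total_length_cm"] / divisor[mask]
        )
    return catch


def simulate_program(config: ProgramConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: installation schedule plus a catch realization."""
    effort = build_installation_schedule(config)
    catch = simulate_catches(config, effort)
    return catch, effort
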