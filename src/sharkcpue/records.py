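"""Catch-record data model and cleaning.

Implements the bookkeeping between raw contractor-style catch records and
the tables the models consume: financial-year binning (July--June), length
plausibility filtering with an auditable exclusion log, allocation of
"unknown"-gear records in proportion to known-gear catch, CPUE computation,
and initial (first-five-year) CPUE summaries.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np
import pandas as pd

from .config import DRUMLINE, NET, UNKNOWN
from .errors import ConfigError, DataError

#: default lower plausibility bound: lengths below this are treated as
#: probable imperial-unit entries (e.g. feet recorded as centimetres)
DEFAULT_MIN_TL = 30.0

REASON_ABOVE_MAX = "above maximum total length"
REASON_BELOW_MIN = "below minimum plausible length"


def assign_financial_year(date) -> int:
    """Financial-year label of a date under the July--June rule.

    Dates in [1 July Y, 30 June Y+1] map to label Y; e.g. July 1962 through
    June 1963 is financial year 1962.
    """
    if isinstance(date, str):
        date = _dt.date.fromisoformat(date)
    if isinstance(date, pd.Timestamp):
        date = date.date()
    if not isinstance(date, _dt.date):
        raise DataError(f"not a date: {date!r}")
    return date.year if date.month >= 7 else date.year - 1


def assign_financial_years(dates: pd.Series) -> pd.Series:
    """Vectorized :func:`assign_financial_year` for a datetime-like column."""
    ts = pd.to_datetime(dates)
    return (ts.dt.year - (ts.dt.month < 7).astype(int)).astype(int)


def filter_lengths(
    records: pd.DataFrame,
    tl_max: dict[str, float],
    min_tl: float = DEFAULT_MIN_TL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop implausible total lengths; log every exclusion with its reason.

    ``tl_max`` maps group and/or species labels to maximum plausible total
    length (cm). A record is checked against its species-level bound when a
    species label is present and listed; otherwise against its group-level
    bound (records predating species-level identification carry no species).
    Records above the bound, or below ``min_tl`` (suspected imperial-unit
    entries), are excluded. Records with missing length are kept — they still
    count for catch-rate analyses — and are simply absent from size analyses,
    which drop missing lengths.

    Returns ``(kept, exclusion_log)``; the log has one row per excluded
    record with columns of the original plus ``reason`` and ``bound``.
    """
    if "group" not in records.columns:
        raise DataError("records table lacks a 'group' column")
    lengths = pd.to_numeric(records.get("total_length_cm"), errors="coerce")
    has_length = lengths.notna()

    species = records.get("species")
    if species is None:
        species = pd.Series("", index=records.index)
    species = species.fillna("").astype(str)

    labels = pd.Series(
        np.where((species != "") & species.isin(tl_max.keys()),
                 species, records["group"].astype(str)),
        index=records.index,
    )
    bounds = labels.map(tl_max)
    missing = bounds.isna() & has_length
    if missing.any():
        bad = sorted(labels[missing].unique())
        raise ConfigError(f"no maximum-length entry for group/species {bad}")
    bounds = bounds.to_numpy(dtype=float, na_value=np.nan)

    too_long = has_length.to_numpy() & (lengths.to_numpy() > bounds)
    too_short = has_length.to_numpy() & (lengths.to_numpy() < min_tl)

    log_rows = []
    for idx, (long_, short_, bound) in zip(records.index,
                                           zip(too_long, too_short, bounds)):
        if short_:
            log_rows.append((idx, REASON_BELOW_MIN, min_tl))
        elif long_:
            log_rows.append((idx, REASON_ABOVE_MAX, bound))
    excluded_idx = [r[0] for r in log_rows]
    log = records.loc[excluded_idx].copy()
    log["reason"] = [r[1] for r in log_rows]
    log["bound"] = [r[2] for r in log_rows]
    kept = records.drop(index=excluded_idx)
    return kept, log


def allocate_unknown_gear(
    records: pd.DataFrame,
    mode: str = "deterministic",
    seed: int | None = None,
) -> pd.DataFrame:
    """Resolve gear == "unknown" in proportion to known-gear catch.

    Within each (group, region) cell, unknown-gear records are assigned to
    net or drumline so that expected assigned proportions equal the cell's
    known-gear catch proportions (net share ``n_net / (n_net + n_drum)``).

    ``deterministic`` mode apportions by largest remainder (ties to net) and
    assigns the first records in stable (date, site) order to net, making
    counts exact and reproducible without randomness; ``stochastic`` mode
    draws each record's gear as Bernoulli(net share) with ``seed``.

    Total catch per (group, region) is conserved exactly.
    """
    if mode not in ("deterministic", "stochastic"):
        raise ConfigError(f"unknown allocation mode {mode!r}")
    out = records.copy()
    unknown = out["gear"] == UNKNOWN
    if not unknown.any():
        return out
    rng = np.random.default_rng(seed)
    for (group, region), cell in out[unknown].groupby(["group", "region"],
                                                      sort=True):
        known = out[(~unknown) & (out["group"] == group)
                    & (out["region"] == region)]
        n_net = int((known["gear"] == NET).sum())
        n_drum = int((known["gear"] == DRUMLINE).sum())
        if n_net + n_drum == 0:
            raise DataError(
                f"cannot allocate unknown gear for (group={group!r}, "
                f"region={region!r}): no known-gear catch in that cell"
            )
        p_net = n_net / (n_net + n_drum)
        cell_idx = cell.sort_values(["date", "site"], kind="mergesort").index
        m = len(cell_idx)
        if mode == "deterministic":
            q_net = m * p_net
            k_net = int(np.floor(q_net))
            k_drum = int(np.floor(m - q_net))
            if k_net + k_drum < m:  # one seat left: larger remainder, tie to net
                if (q_net - k_net) >= ((m - q_net) - k_drum):
                    k_net += 1
            assign_net = np.zeros(m, dtype=bool)
            assign_net[:k_net] = True
        else:
            assign_net = rng.random(m) < p_net
        out.loc[cell_idx, "gear"] = np.where(assign_net, NET, DRUMLINE)
    return out


def count_catches(
    catch: pd.DataFrame,
    groups: list[str] | None = None,
) -> pd.DataFrame:
    """Aggregate a record table to counts per (region, site, year, gear, group)."""
    df = catch
    if groups is not None:
        df = df[df["group"].isin(groups)]
    counts = (
        df.groupby(["region", "site", "financial_year", "gear", "group"],
                   sort=True, observed=True)
        .size()
        .rename("catch")
        .reset_index()
    )
    return counts


def compute_cpue(catch_counts: pd.DataFrame, effort: pd.DataFrame) -> pd.DataFrame:
    """Standardize catch by effort: one row per effort cell x group.

    The output grid is the cross of positive-effort cells with the groups in
    ``catch_counts``: cells with effort but no catch appear with catch 0
    (zeros are data); cells with zero or missing effort are omitted — unless
    they carry catch, which is a contract violation and raises
    :class:`DataError` naming the cell.
    """
    keys = ["region", "site", "financial_year", "gear"]
    eff = effort[effort["effort"] > 0]
    merged = catch_counts.merge(eff[keys + ["effort"]], on=keys, how="left")
    orphans = merged[merged["effort"].isna() & (merged["catch"] > 0)]
    if len(orphans):
        first = orphans.iloc[0]
        raise DataError(
            "catch with no matching positive effort at "
            f"(site={first['site']!r}, year={first['financial_year']}, "
            f"gear={first['gear']!r}) and {len(orphans) - 1} other cell(s)"
        )
    groups = sorted(catch_counts["group"].unique())
    grid = eff.loc[eff.index.repeat(len(groups))].copy()
    grid["group"] = np.tile(groups, len(eff))
    grid = grid.merge(catch_counts, on=keys + ["group"], how="left")
    grid["catch"] = grid["catch"].fillna(0).astype(int)
    grid["cpue"] = grid["catch"] / grid["effort"]
    return grid[keys[:2] + ["gear", "group", "financial_year",
                            "catch", "effort", "cpue"]].reset_index(drop=True)


def installation_years(effort: pd.DataFrame) -> pd.DataFrame:
    """First financial year with positive effort per (site, gear)."""
    pos = effort[effort["effort"] > 0]
    return (
        pos.groupby(["region", "site", "gear"], sort=True)["financial_year"]
        .min()
        .rename("installed")
        .reset_index()
    )


def initial_cpue(
    series: pd.DataFrame,
    installation: pd.DataFrame | dict[str, int],
    window: int = 5,
) -> pd.DataFrame:
    """Mean CPUE over the first ``window`` years after gear installation.

    ``series`` is a CPUE grid from :func:`compute_cpue`; ``installation``
    maps (site, gear) to installation financial year (a DataFrame from
    :func:`installation_years`, or a plain site -> year mapping applied to
    both gears). The mean is the unweighted average of the annual CPUE
    values over the first ``min(window, available)`` years with effort;
    sites with fewer than ``window`` such years are flagged
    ``short_window``. Sites with no post-installation effort raise.
    """
    if isinstance(installation, dict):
        inst = {(site, gear): yr for site, yr in installation.items()
                for gear in (NET, DRUMLINE)}
    else:
        inst = {(r.site, r.gear): int(r.installed)
                for r in installation.itertuples(index=False)}
    rows = []
    for (region, site, gear, group), sub in series.groupby(
            ["region", "site", "gear", "group"], sort=True):
        key = (site, gear)
        if key not in inst:
            raise DataError(f"site {site!r} ({gear}) absent from schedule")
        year0 = inst[key]
        sub = sub[sub["financial_year"] >= year0].sort_values("financial_year")
        if not len(sub):
            raise DataError(
                f"site {site!r} ({gear}) has no post-installation effort years"
            )
        win = sub.head(window)
        rows.append((
            region, site, gear, group, year0,
            float(win["cpue"].mean()),
            float(win["catch"].sum()), float(win["effort"].sum()),
            len(win), len(win) < window,
        ))
    return pd.DataFrame(rows, columns=[
        "region", "site", "gear", "group", "installed",
        "initial_cpue", "initial_catch", "initial_effort",
        "n_years", "short_window",
    ])
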