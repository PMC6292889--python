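"""Long-term size-structure and maturity-probability analyses.

Size trends are linear mixed models on individual total lengths with a
year slope and gear/sex fixed effects, region and site-within-region random
intercepts, fitted by REML (:mod:`sharkcpue.mixed`). Maturity trends are
logistic mixed models on a mature/immature classification derived from
species- and sex-specific length-at-maturity cutoffs, with predicted
probabilities at the endpoint years.

Cutoffs and maximum-length bounds are configuration data (CSV), not model
output. The defaults shipped here carry the two published hammerhead
maximum lengths (scalloped 430 cm, great 610 cm); every other default value
is a synthetic, literature-plausible stand-in intended for simulated data
and should be replaced with sourced values for real analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .errors import ConfigError, DataError
from .mixed import BinomialGLMMResult, LMMResult, fit_binomial_glmm, fit_lmm

#: maximum plausible total length (cm) per group/species; values other than
#: the two published hammerhead entries are synthetic stand-ins
DEFAULT_TL_MAX = {
    "scalloped_hammerhead": 430.0,
    "great_hammerhead": 610.0,
    "hammerhead": 610.0,
    "whaler": 360.0,
    "tiger": 550.0,
    "white": 640.0,
}

#: (species, sex) -> length at maturity (cm); synthetic stand-ins
DEFAULT_MATURITY_CUTOFFS = {
    ("scalloped_hammerhead", "F"): 200.0,
    ("scalloped_hammerhead", "M"): 180.0,
    ("great_hammerhead", "F"): 228.0,
    ("great_hammerhead", "M"): 210.0,
    ("tiger", "F"): 287.0,
    ("tiger", "M"): 292.0,
}


def load_tl_max(path) -> dict[str, float]:
    """Read a label -> TL_max table from CSV (columns label, tl_max_cm)."""
    df = pd.read_csv(path)
    return {str(r.label): float(r.tl_max_cm) for r in df.itertuples()}


def load_maturity_cutoffs(path) -> dict[tuple[str, str], float]:
    """Read (species, sex) -> cutoff from CSV (species, sex, cutoff_cm)."""
    df = pd.read_csv(path)
    return {(str(r.species), str(r.sex)): float(r.cutoff_cm)
            for r in df.itertuples()}


def classify_maturity(length, species: str, sex: str, cutoffs=None) -> bool:
    """Mature iff length >= the (species, sex) cutoff (boundary inclusive)."""
    cutoffs = DEFAULT_MATURITY_CUTOFFS if cutoffs is None else cutoffs
    key = (species, sex)
    if key not in cutoffs:
        raise ConfigError(f"no maturity cutoff for species={species!r}, "
                          f"sex={sex!r}")
    return bool(length >= cutoffs[key])


@dataclass
class SizeTrendFit:
    """Year slope (cm/yr) and companions from the size LMM."""

    lmm: LMMResult
    year_ref: int
    n_records: int

    @property
    def slope_cm_per_yr(self) -> float:
        return float(self.lmm.beta[self.lmm.names.index("year")])

    @property
    def slope_se(self) -> float:
        return float(self.lmm.se[self.lmm.names.index("year")])

    @property
    def slope_p(self) -> float:
        return float(self.lmm.p_values[self.lmm.names.index("year")])

    @property
    def stars(self) -> str:
        from .mixed import significance_stars
        return significance_stars(self.slope_p)

    def mean_length(self, year: int) -> float:
        """Fixed-effect predicted mean length at reference covariates."""
        b = dict(zip(self.lmm.names, self.lmm.beta))
        return float(b["intercept"] + b["year"] * (year - self.year_ref))


def _grouping(records: pd.DataFrame) -> dict[str, np.ndarray]:
    groups: dict[str, np.ndarray] = {}
    regions = sorted(records["region"].unique())
    pairs = sorted(set(zip(records["region"], records["site"])))
    if len(regions) >= 2:
        groups["region"] = pd.Categorical(
            records["region"], categories=regions).codes.astype(int)
    if len(pairs) > max(len(regions), 1):
        idx = {p: i for i, p in enumerate(pairs)}
        groups["site"] = np.array(
            [idx[p] for p in zip(records["region"], records["site"])])
    return groups


def fit_size_trend(
    records: pd.DataFrame,
    year_ref: int | None = None,
    use_gear: bool = True,
    use_sex: bool = True,
) -> SizeTrendFit:
    """REML size-trend fit on individual records with cleaned lengths.

    Records must carry ``total_length_cm`` (missing dropped), and when the
    sex fixed effect is used, records with unknown sex are excluded.
    """
    df = records.dropna(subset=["total_length_cm"]).copy()
    df = df[df["total_length_cm"] > 0]
    if use_sex:
        df = df[df["sex"].isin(["F", "M"])]
    if df["financial_year"].nunique() < 2:
        raise DataError("need >= 2 distinct years for a size trend")
    year_ref = int(df["financial_year"].min()) if year_ref is None \
        else int(year_ref)
    cols = [np.ones(len(df)),
            (df["financial_year"] - year_ref).to_numpy(dtype=float)]
    names = ["intercept", "year"]
    if use_gear and df["gear"].nunique() > 1:
        ref = sorted(df["gear"].unique())[0]
        for g in sorted(df["gear"].unique())[1:]:
            cols.append((df["gear"] == g).to_numpy(dtype=float))
            names.append(f"gear[{g}]")
    if use_sex and df["sex"].nunique() > 1:
        cols.append((df["sex"] == "M").to_numpy(dtype=float))
        names.append("sex[M]")
    X = np.column_stack(cols)
    lmm = fit_lmm(df["total_length_cm"].to_numpy(dtype=float), X, names,
                  _grouping(df))
    return SizeTrendFit(lmm=lmm, year_ref=year_ref, n_records=len(df))


def percent_change(first: float, last: float) -> float:
    """Relative change ``100 (last - first) / first`` (positive = increase)."""
    if first <= 0:
        raise ConfigError("first value must be > 0")
    return 100.0 * (last - first) / first


def decline_rate_cm_per_decade(first_mean_cm: float, last_mean_cm: float,
                               span_years: float) -> float:
    """``10 (first - last) / span``: positive values are shrinking sizes."""
    if span_years <= 0:
        raise ConfigError("span must be > 0")
    return 10.0 * (first_mean_cm - last_mean_cm) / span_years


@dataclass
class MaturityTrendFit:
    """Logistic maturity-vs-year fit for one species x sex."""

    glmm: BinomialGLMMResult
    year_ref: int
    species: str
    sex: str
    n_records: int

    @property
    def slope_per_yr(self) -> float:
        return float(self.glmm.beta[1])

    def predicted_probability(self, year: int, level: float = 0.95) -> dict:
        """Population-level P(mature) at ``year`` with a Wald band."""
        x = np.array([1.0, float(year - self.year_ref)])
        eta = float(x @ self.glmm.beta)
        # Wald band on the linear predictor, mapped through the inverse link
        se = float(np.sqrt(x @ (self.glmm.cov_beta @ x)))
        zq = norm.ppf(0.5 + level / 2.0)
        return {
            "probability": float(expit(eta)),
            "lo": float(expit(eta - zq * se)),
            "hi": float(expit(eta + zq * se)),
        }


def fit_maturity_trend(
    records: pd.DataFrame,
    species: str,
    sex: str,
    cutoffs=None,
    year_ref: int | None = None,
) -> MaturityTrendFit:
    """Fit P(mature) ~ year with nested random intercepts.

    Records are filtered to the given species and sex with a present
    length; each is classified against the (species, sex) cutoff.
    Complete separation is detected by the underlying GLMM and flagged.
    """
    cutoffs = DEFAULT_MATURITY_CUTOFFS if cutoffs is None else cutoffs
    df = records.dropna(subset=["total_length_cm"])
    df = df[(df["species"] == species) & (df["sex"] == sex)]
    if not len(df):
        raise DataError(f"no records for species={species!r}, sex={sex!r}")
    key = (species, sex)
    if key not in cutoffs:
        raise ConfigError(f"no maturity cutoff for species={species!r}, "
                          f"sex={sex!r}")
    mature = (df["total_length_cm"] >= cutoffs[key]).astype(float).to_numpy()
    year_ref = int(df["financial_year"].min()) if year_ref is None \
        else int(year_ref)
    X = np.column_stack([
        np.ones(len(df)),
        (df["financial_year"] - year_ref).to_numpy(dtype=float),
    ])
    glmm = fit_binomial_glmm(mature, X, ["intercept", "year"], _grouping(df))
    return MaturityTrendFit(glmm=glmm, year_ref=year_ref, species=species,
                            sex=sex, n_records=len(df))
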