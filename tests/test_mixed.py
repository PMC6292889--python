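"""Mixed models against independent oracles (OLS, logistic ML, lme4)."""

import json
import subprocess

import numpy as np
import pandas as pd
import pytest

from sharkcpue.errors import ConfigError, DataError
from sharkcpue.mixed import (fit_binomial_glmm, fit_lmm, significance_stars)
from sharkcpue.size_maturity import (DEFAULT_MATURITY_CUTOFFS,
                                     classify_maturity,
                                     decline_rate_cm_per_decade,
                                     fit_maturity_trend, fit_size_trend,
                                     percent_change)


def nested_data(n_regions=3, sites_per_region=3, n_per_site=40,
                slope=-1.0, sd_region=8.0, sd_site=5.0, sd_resid=20.0,
                seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_regions):
        ur = rng.normal(0, sd_region)
        for s in range(sites_per_region):
            vs = rng.normal(0, sd_site)
            for _ in range(n_per_site):
                year = rng.integers(0, 30)
                y = 220 + slope * year + ur + vs + rng.normal(0, sd_resid)
                rows.append((f"r{r}", f"r{r}s{s}", year, y))
    return pd.DataFrame(rows, columns=["region", "site", "year", "length"])


class TestLMM:
    def test_reduces_to_ols_without_groups(self):
        import statsmodels.api as sm
        df = nested_data(1, 1, 200, seed=1)
        X = np.column_stack([np.ones(len(df)), df["year"]])
        res = fit_lmm(df["length"].to_numpy(), X, ["intercept", "year"], {})
        ols = sm.OLS(df["length"].to_numpy(), X).fit()
        np.testing.assert_allclose(res.beta, ols.params, rtol=1e-10)
        np.testing.assert_allclose(res.se, ols.bse, rtol=1e-10)
        assert res.sigma2 == pytest.approx(ols.mse_resid, rel=1e-10)

    def test_matches_lme4(self, tmp_path):
        """REML estimates agree with lme4 on a nested two-factor design."""
        df = nested_data(seed=2)
        codes_r = pd.Categorical(df["region"]).codes
        codes_s = pd.Categorical(df["site"]).codes
        X = np.column_stack([np.ones(len(df)), df["year"]])
        mine = fit_lmm(df["length"].to_numpy(), X, ["intercept", "year"],
                       {"region": codes_r, "site": codes_s})

        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "out.json"
        script = tmp_path / "fit.R"
        script.write_text(f"""
library(lme4); library(jsonlite)
d <- read.csv("{csv}")
m <- lmer(length ~ year + (1|region) + (1|site), data=d, REML=TRUE)
vc <- as.data.frame(VarCorr(m))
res <- list(beta=unname(fixef(m)), se=unname(coef(summary(m))[, "Std. Error"]),
            vc_grp=vc$grp, vc_val=vc$vcov)
cat(toJSON(res, digits=12), file="{out}")
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        oracle = json.loads(out.read_text())
        vc = dict(zip(oracle["vc_grp"], oracle["vc_val"]))
        np.testing.assert_allclose(mine.beta, oracle["beta"], rtol=1e-4)
        np.testing.assert_allclose(mine.se, oracle["se"], rtol=1e-3)
        assert mine.sigma2 == pytest.approx(vc["Residual"], rel=1e-3)
        assert mine.variance_components["region"] == pytest.approx(
            vc["region"], rel=1e-2, abs=1e-3)
        assert mine.variance_components["site"] == pytest.approx(
            vc["site"], rel=1e-2, abs=1e-3)

    def test_shift_equivariance(self):
        df = nested_data(seed=3)
        codes_r = pd.Categorical(df["region"]).codes
        X = np.column_stack([np.ones(len(df)), df["year"]])
        groups = {"region": codes_r}
        base = fit_lmm(df["length"].to_numpy(), X, ["intercept", "year"],
                       groups)
        shifted = fit_lmm(df["length"].to_numpy() + 50.0, X,
                          ["intercept", "year"], groups)
        assert shifted.beta[1] == pytest.approx(base.beta[1], rel=1e-8)
        assert shifted.beta[0] == pytest.approx(base.beta[0] + 50.0,
                                                rel=1e-8)

    def test_slope_recovery_large_n(self):
        df = nested_data(4, 3, 420, slope=-1.04, sd_resid=30.0, seed=4)
        codes_r = pd.Categorical(df["region"]).codes
        codes_s = pd.Categorical(df["site"]).codes
        X = np.column_stack([np.ones(len(df)), df["year"]])
        res = fit_lmm(df["length"].to_numpy(), X, ["intercept", "year"],
                      {"region": codes_r, "site": codes_s})
        i = res.names.index("year")
        assert abs(res.beta[i] - (-1.04)) < 3 * res.se[i]


class TestSizeTrend:
    def _records(self, years, lengths, site="s1", sexes=None, gears=None):
        n = len(years)
        return pd.DataFrame({
            "region": "a", "site": site, "financial_year": years,
            "gear": gears if gears is not None else ["net"] * n,
            "sex": sexes if sexes is not None else ["F", "M"] * (n // 2),
            "group": "tiger", "species": "tiger",
            "total_length_cm": lengths,
        })

    def test_exact_on_noise_free_linear_data(self):
        years = np.repeat(np.arange(1970, 1980), 2)
        lengths = 200.0 + 2.0 * (years - 1970)
        rec = self._records(years, lengths)
        fit = fit_size_trend(rec, use_gear=False, use_sex=False)
        assert fit.slope_cm_per_yr == pytest.approx(2.0, abs=1e-8)

    def test_recovery_with_noise(self):
        rng = np.random.default_rng(8)
        years = rng.integers(1962, 2017, size=5000)
        lengths = 272.0 - 1.04 * (years - 1962) + rng.normal(0, 30, 5000)
        rec = self._records(years, lengths,
                            sexes=list(rng.choice(["F", "M"], 5000)))
        fit = fit_size_trend(rec)
        assert abs(fit.slope_cm_per_yr - (-1.04)) < 3 * fit.slope_se
        assert fit.stars == "***"

    def test_mean_length_prediction(self):
        years = np.repeat(np.arange(1970, 1980), 2)
        lengths = 200.0 + 2.0 * (years - 1970)
        fit = fit_size_trend(self._records(years, lengths),
                             use_gear=False, use_sex=False)
        assert fit.mean_length(1975) == pytest.approx(210.0, abs=1e-6)


class TestHeadlineArithmetic:
    @pytest.mark.parametrize("first,last,span,expected", [
        (272.0, 215.0, 55.0, 10.4),   # long-dataset tiger rate, 1 d.p.
        (210.0, 210.0, 20.0, 0.0),
        (274.0, 215.0, 20.0, 29.5),
    ])
    def test_cm_per_decade(self, first, last, span, expected):
        assert round(decline_rate_cm_per_decade(first, last, span), 1) \
            == expected

    def test_cm_per_decade_domain(self):
        with pytest.raises(ConfigError):
            decline_rate_cm_per_decade(1.0, 1.0, 0.0)

    @pytest.mark.parametrize("first,last,expected", [
        (210.0, 221.0, 5), (274.0, 215.0, -22), (272.0, 215.0, -21),
    ])
    def test_percent_change(self, first, last, expected):
        assert round(percent_change(first, last)) == expected

    @pytest.mark.parametrize("p,stars", [
        (0.0001, "***"), (0.005, "**"), (0.03, "*"), (0.2, "ns"),
    ])
    def test_stars(self, p, stars):
        assert significance_stars(p) == stars


class TestBinomialGLMM:
    def test_reduces_to_logistic_ml(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        n = 600
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(0.4 + 0.8 * x)))
        y = (rng.random(n) < p).astype(float)
        X = np.column_stack([np.ones(n), x])
        mine = fit_binomial_glmm(y, X, ["b0", "b1"], {})
        oracle = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(mine.beta, oracle.params, atol=1e-4)
        np.testing.assert_allclose(mine.se, oracle.bse, atol=1e-4)

    def test_matches_glmer(self, tmp_path):
        """Laplace estimates agree with lme4::glmer (nAGQ = 1)."""
        rng = np.random.default_rng(6)
        rows = []
        for r in range(4):
            ur = rng.normal(0, 0.8)
            for _ in range(150):
                x = rng.normal(0, 1)
                p = 1 / (1 + np.exp(-(-0.3 + 0.6 * x + ur)))
                rows.append((f"r{r}", x, int(rng.random() < p)))
        df = pd.DataFrame(rows, columns=["region", "x", "y"])
        X = np.column_stack([np.ones(len(df)), df["x"]])
        mine = fit_binomial_glmm(
            df["y"].to_numpy(dtype=float), X, ["b0", "b1"],
            {"region": pd.Categorical(df["region"]).codes})
        csv = tmp_path / "d.csv"; df.to_csv(csv, index=False)
        out = tmp_path / "out.json"
        script = tmp_path / "fit.R"
        script.write_text(f"""
library(lme4); library(jsonlite)
d <- read.csv("{csv}")
m <- glmer(y ~ x + (1|region), data=d, family=binomial)
res <- list(beta=unname(fixef(m)), se=unname(coef(summary(m))[, "Std. Error"]),
            var_region=unname(as.data.frame(VarCorr(m))$vcov[1]))
cat(toJSON(res, digits=12), file="{out}")
""")
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True)
        oracle = json.loads(out.read_text())
        np.testing.assert_allclose(mine.beta, oracle["beta"], atol=5e-3)
        np.testing.assert_allclose(mine.se, oracle["se"], rtol=2e-2)
        assert mine.variance_components["region"] == pytest.approx(
            float(np.asarray(oracle["var_region"]).ravel()[0]),
            rel=5e-2, abs=5e-3)

    def test_separation_flagged(self):
        y = np.array([0.0] * 20 + [1.0] * 20)
        x = np.concatenate([np.linspace(-2, -0.1, 20),
                            np.linspace(0.1, 2, 20)])
        X = np.column_stack([np.ones(40), x])
        res = fit_binomial_glmm(y, X, ["b0", "b1"], {})
        assert res.separation

    def test_single_class_rejected(self):
        X = np.ones((10, 1))
        with pytest.raises(DataError):
            fit_binomial_glmm(np.ones(10), X, ["b0"], {})


class TestMaturity:
    def test_boundary_inclusive(self):
        cutoff = DEFAULT_MATURITY_CUTOFFS[("tiger", "F")]
        assert classify_maturity(cutoff, "tiger", "F")
        assert not classify_maturity(cutoff - 1.0, "tiger", "F")

    def test_monotone_in_length(self):
        lengths = np.linspace(100, 400, 31)
        flags = [classify_maturity(l, "tiger", "M") for l in lengths]
        assert flags == sorted(flags)

    def test_missing_cutoff_raises(self):
        with pytest.raises(ConfigError, match="whale shark"):
            classify_maturity(300.0, "whale shark", "F")

    def _maturity_records(self, p_first, p_last, n_years=20, n_per_year=500,
                          seed=0):
        """Binary maturity realized through lengths around a 200 cm cutoff."""
        rng = np.random.default_rng(seed)
        b0 = np.log(p_first / (1 - p_first))
        b1 = (np.log(p_last / (1 - p_last)) - b0) / (n_years - 1)
        rows = []
        for t in range(n_years):
            p = 1 / (1 + np.exp(-(b0 + b1 * t)))
            mature = rng.random(n_per_year) < p
            for m in mature:
                rows.append(("a", "s1", 1997 + t, "net", "F",
                             "scalloped_hammerhead",
                             250.0 if m else 150.0))
        return pd.DataFrame(rows, columns=[
            "region", "site", "financial_year", "gear", "sex", "species",
            "total_length_cm"])

    def test_endpoint_probability_recovery(self):
        rec = self._maturity_records(0.54, 0.14, seed=9)
        fit = fit_maturity_trend(rec, "scalloped_hammerhead", "F")
        for year, truth in ((1997, 0.54), (2016, 0.14)):
            pred = fit.predicted_probability(year)
            se = (pred["hi"] - pred["lo"]) / (2 * 1.96)
            assert abs(pred["probability"] - truth) < 3 * se + 0.01

    def test_flat_truth_gives_equal_endpoints(self):
        rec = self._maturity_records(0.4, 0.4, seed=10)
        fit = fit_maturity_trend(rec, "scalloped_hammerhead", "F")
        p0 = fit.predicted_probability(1997)
        p1 = fit.predicted_probability(2016)
        assert p0["lo"] - 0.02 < p1["probability"] < p0["hi"] + 0.02

    def test_curve_monotone_when_slope_nonzero(self):
        rec = self._maturity_records(0.6, 0.2, seed=11)
        fit = fit_maturity_trend(rec, "scalloped_hammerhead", "F")
        probs = [fit.predicted_probability(y)["probability"]
                 for y in range(1997, 2017)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))
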