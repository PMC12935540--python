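"""Mixed-model fitting, predictions, contrasts and R-squared."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rotanutri.model import (
    RotationOutputModel,
    fit_output_model,
    mvt_adjust,
)


def _exact_outputs(n_sites=3, n_years=8, beta=None):
    """Noise-free data generated exactly on the sqrt-scale fixed structure."""
    beta = beta or {
        "intercept": 3.3,
        "t": -0.8,
        "t2": 0.5,
        "fr1C": -0.29,
        "fr1C:t": 1.5,
        "fr1C:t2": -1.45,
        "fr3": 1.7,
        "fr3:t": 1.68,
        "fr3:t2": -2.35,
    }
    rows = []
    tmax = n_years - 1
    for s in range(n_sites):
        for t in range(n_years):
            ts = t / tmax
            for fr in ("1M", "1C", "3"):
                mu = beta["intercept"] + beta["t"] * ts + beta["t2"] * ts**2
                if fr != "1M":
                    mu += (
                        beta[f"fr{fr}"]
                        + beta[f"fr{fr}:t"] * ts
                        + beta[f"fr{fr}:t2"] * ts**2
                    )
                rows.append(
                    {
                        "site": f"S{s}",
                        "group": "A1",
                        "calendar_year": 2000 + t,
                        "fr_label": fr,
                        "time_since_start": t,
                        "nutrient": "calorie",
                        "O": mu**2,
                    }
                )
    return pd.DataFrame(rows), beta, float(tmax)


class TestFitting:
    def test_exact_data_recovers_coefficients_to_numerical_tolerance(self):
        df, beta, tmax = _exact_outputs()
        m = RotationOutputModel(time_scale=tmax).fit(df)
        for name, truth in beta.items():
            assert m.coef_[name] == pytest.approx(truth, abs=1e-6)

    def test_row_permutation_invariance(self, recovery_outputs):
        cfg, out = recovery_outputs
        m1 = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        shuffled = out.sample(frac=1.0, random_state=1).reset_index(drop=True)
        m2 = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(shuffled)
        pd.testing.assert_series_equal(m1.coef_, m2.coef_, rtol=1e-6)
        assert m1.vc_ == pytest.approx(m2.vc_, rel=1e-4)

    def test_negative_output_raises(self):
        df, _, tmax = _exact_outputs()
        df.loc[0, "O"] = -1.0
        with pytest.raises(ValueError, match="negative"):
            RotationOutputModel(time_scale=tmax).fit(df)

    def test_mixed_nutrients_rejected(self):
        df, _, tmax = _exact_outputs()
        df.loc[0, "nutrient"] = "fat"
        with pytest.raises(ValueError, match="one model per nutrient"):
            RotationOutputModel(time_scale=tmax).fit(df)

    def test_matches_statsmodels_mixedlm(self, recovery_outputs):
        """Independent oracle: crossed variance-components fit in statsmodels."""
        import statsmodels.formula.api as smf

        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)

        df = out.copy()
        df["sqrtO"] = np.sqrt(df["O"])
        df["ts"] = df["time_since_start"] / cfg.effective_time_scale()
        df["fr"] = pd.Categorical(df["fr_label"], categories=["1M", "1C", "2", "3"])
        df["sg"] = df["site"].astype(str) + "/" + df["group"].astype(str)
        df["one"] = 1
        vcf = {
            "site": "0+C(site)",
            "grp": "0+C(sg)",
            "year": "0+C(calendar_year)",
        }
        fit = smf.mixedlm(
            "sqrtO ~ ts + I(ts**2) + fr + fr:ts + fr:I(ts**2)",
            df,
            groups="one",
            vc_formula=vcf,
            re_formula="0",
        ).fit(reml=True, method="lbfgs", maxiter=500)

        assert m.coef_["intercept"] == pytest.approx(fit.fe_params["Intercept"], rel=1e-5)
        assert m.coef_["fr3"] == pytest.approx(fit.fe_params["fr[T.3]"], rel=1e-4)
        assert m.coef_["t"] == pytest.approx(fit.fe_params["ts"], rel=1e-3)
        assert m.sigma2_ == pytest.approx(fit.scale, rel=1e-3)
        assert m.loglik_ == pytest.approx(fit.llf, abs=1e-3)
        sm_vc = dict(zip(["grp", "site", "year"], fit.vcomp))
        assert m.vc_["site"] == pytest.approx(sm_vc["site"], rel=1e-2, abs=1e-3)
        assert m.vc_["group"] == pytest.approx(sm_vc["grp"], rel=1e-2, abs=1e-3)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_lmerTest_reference(self, recovery_outputs, tmp_path):
        """Independent oracle: lme4/lmerTest REML fit and Satterthwaite df."""
        cfg, out = recovery_outputs
        tscale = cfg.effective_time_scale()
        m = RotationOutputModel(time_scale=tscale).fit(out)
        my = m.satterthwaite_coef()

        df = out.copy()
        df["sqrtO"] = np.sqrt(df["O"])
        df["ts"] = df["time_since_start"] / tscale
        df["sg"] = df["site"].astype(str) + "/" + df["group"].astype(str)
        csv = tmp_path / "fixture.csv"
        df.to_csv(csv, index=False)
        script = tmp_path / "check.R"
        script.write_text(
            f"""
            suppressMessages({{library(lme4); library(lmerTest)}})
            d <- read.csv("{csv}")
            d$fr <- relevel(factor(d$fr_label), ref="1M")
            m <- lmer(sqrtO ~ ts + I(ts^2) + fr + fr:ts + fr:I(ts^2) +
                      (1|site) + (1|sg) + (1|calendar_year), data=d, REML=TRUE)
            s <- coef(summary(m))
            write.csv(data.frame(name=rownames(s), s), "{tmp_path}/ref.csv",
                      row.names=FALSE)
            """
        )
        subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, timeout=300
        )
        ref = pd.read_csv(tmp_path / "ref.csv").set_index("name")
        name_map = {
            "intercept": "(Intercept)",
            "t": "ts",
            "t2": "I(ts^2)",
            "fr1C": "fr1C",
            "fr3": "fr3",
            "fr1C:t": "ts:fr1C",
            "fr3:t2": "I(ts^2):fr3",
        }
        for mine, theirs in name_map.items():
            assert my.loc[mine, "estimate"] == pytest.approx(
                ref.loc[theirs, "Estimate"], rel=1e-4, abs=1e-6
            )
            assert my.loc[mine, "se"] == pytest.approx(
                ref.loc[theirs, "Std..Error"], rel=1e-3
            )
            assert my.loc[mine, "df"] == pytest.approx(ref.loc[theirs, "df"], rel=0.02)


class TestPrediction:
    def test_intercept_only_prediction_squares_beta0(self):
        df, _, tmax = _exact_outputs(
            beta={
                "intercept": 3.3, "t": 0.0, "t2": 0.0,
                "fr1C": 0.0, "fr1C:t": 0.0, "fr1C:t2": 0.0,
                "fr3": 0.0, "fr3:t": 0.0, "fr3:t2": 0.0,
            }
        )
        m = RotationOutputModel(time_scale=tmax).fit(df)
        for t in (0.0, 3.0, 7.0):
            cell = m.predict_cells("1M", t)
            assert cell.prediction == pytest.approx(3.3**2, abs=1e-5)

    def test_interval_brackets_prediction_and_is_nonnegative(self, recovery_outputs):
        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        for fr in ("1M", "3"):
            cell = m.predict_cells(fr, 5.0)
            assert 0.0 <= cell.lower <= cell.prediction <= cell.upper

    def test_random_component_widens_interval(self, recovery_outputs):
        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        narrow = m.predict_cells("1M", 5.0, include_random=False)
        wide = m.predict_cells("1M", 5.0, include_random=True)
        assert wide.upper - wide.lower > narrow.upper - narrow.lower

    def test_extrapolation_warns(self, recovery_outputs):
        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        with pytest.warns(UserWarning, match="extrapolation"):
            m.predict_cells("1M", 1000.0)

    def test_predict_frame(self, recovery_outputs):
        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        X = pd.DataFrame({"fr_label": ["1M", "3"], "time_since_start": [0.0, 5.0]})
        preds = m.predict(X)
        assert preds.shape == (2,) and (preds >= 0).all()


class TestContrasts:
    def test_time_baseline_contrast_is_zero(self, recovery_outputs):
        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        res = m.contrast_time("3", times=(0.0, 5.0), baseline_time=0.0)
        assert res[0].estimate == pytest.approx(0.0, abs=1e-12)

    def test_adjusted_p_at_least_raw_everywhere(self, recovery_outputs):
        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        results = m.contrast_fr(5.0) + m.contrast_time("1M", times=(5.0, 10.0))
        for r in results:
            assert r.p_adj >= r.p_raw
            assert 0.0 <= r.p_raw <= 1.0 and 0.0 <= r.p_adj <= 1.0
            assert r.df > 0

    def test_family_of_one_adjustment_is_identity(self):
        p = mvt_adjust([2.0], df=30.0, corr=np.eye(1))
        assert p[0] == pytest.approx(2 * stats.t.sf(2.0, 30.0), abs=1e-12)

    def test_mvt_adjustment_deterministic_and_calibrated(self):
        corr = np.full((3, 3), 0.5) + 0.5 * np.eye(3)
        a = mvt_adjust([2.0, -1.0, 0.5], df=50.0, corr=corr, seed=4)
        b = mvt_adjust([2.0, -1.0, 0.5], df=50.0, corr=corr, seed=4)
        assert np.array_equal(a, b)
        # with independent contrasts the adjustment approaches Sidak
        p_one = 2 * stats.t.sf(2.5, 200.0)
        sidak = 1 - (1 - p_one) ** 3
        adj = mvt_adjust([2.5, 2.5, 2.5], df=200.0, corr=np.eye(3), seed=0)
        assert adj[0] == pytest.approx(sidak, abs=0.005)

    def test_contrast_estimate_matches_coefficients(self, recovery_outputs):
        cfg, out = recovery_outputs
        tscale = cfg.effective_time_scale()
        m = RotationOutputModel(time_scale=tscale).fit(out)
        res = {r.description: r for r in m.contrast_fr(0.0)}
        assert res["FR3@0y - FR1M@0y"].estimate == pytest.approx(m.coef_["fr3"])


class TestRSquared:
    def test_bounds_and_ordering(self, recovery_outputs):
        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        r2m, r2c = m.r2_marginal_conditional()
        assert 0.0 <= r2m <= r2c <= 1.0

    def test_no_random_variance_makes_marginal_equal_conditional(self):
        df, _, tmax = _exact_outputs()
        rng = np.random.default_rng(0)
        df["O"] = (np.sqrt(df["O"]) + rng.normal(0, 0.05, len(df))) ** 2
        m = RotationOutputModel(time_scale=tmax).fit(df)
        r2m, r2c = m.r2_marginal_conditional()
        # no random structure was generated: components pin near zero
        assert sum(m.vc_.values()) < 0.05 * m.sigma2_ + 1e-6
        assert r2c == pytest.approx(r2m, abs=1e-2)

    def test_variance_partition_recovered_in_simulation(self, recovery_outputs):
        """Known variance shares from the generator are reproduced closely."""
        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        _, r2c = m.r2_marginal_conditional()
        truth_random = cfg.site_sd**2 + cfg.group_sd**2 + cfg.year_sd**2
        got_random = sum(m.vc_.values())
        # random-effect variance share of the non-fixed variance
        truth_share = truth_random / (truth_random + cfg.residual_sd**2)
        got_share = got_random / (got_random + m.sigma2_)
        assert got_share == pytest.approx(truth_share, abs=0.15)

    def test_serialisation_round_trip(self, recovery_outputs, tmp_path):
        import json

        cfg, out = recovery_outputs
        m = RotationOutputModel(time_scale=cfg.effective_time_scale()).fit(out)
        path = tmp_path / "model.json"
        m.to_json(path)
        d = json.loads(path.read_text())
        assert d["time_scale"] == cfg.effective_time_scale()
        assert d["coefficients"]["intercept"] == pytest.approx(m.coef_["intercept"])
        assert set(d["variance_components"]) == {"site", "group", "year"}
        assert 0 <= d["r2_marginal"] <= d["r2_conditional"] <= 1


def test_fit_output_model_wrapper_filters_nutrient(recovery_outputs):
    cfg, out = recovery_outputs
    m = fit_output_model(out, "calorie", time_scale=cfg.effective_time_scale())
    assert m.nutrient_ == "calorie"
    with pytest.raises(ValueError, match="no rows"):
        fit_output_model(out, "unobtainium")
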