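"""Mixed-effects analysis of whole-rotation nutritional outputs.

For each nutrient the square-rooted annual whole-rotation output is fitted
against functional richness (FR, categorical with the cereal monoculture
"1M" as reference) and scaled time since rotation implementation, with a
quadratic time trend and full FR x time interactions:

    sqrt(O) = b0 + bt*t + btt*t^2
              + sum_i [ b_FRi + b_FRi_t * t + b_FRi_tt * t^2 ] * FRi

Random intercepts: site, group nested in site (treatment x replicate) and
calendar year (crossed with site), so year-to-year growing conditions shared
across rotations are separated from the continuous time trend.  Fitting is
by REML (:mod:`rotanutri._reml`).

Time is entered as ``time_since_start`` divided by a scaling constant
(default: the maximum time in the fitted data), recorded on the fitted model
as ``time_scale_``; raw-year coefficients are therefore not comparable across
datasets without that divisor.  Predictions are back-transformed by squaring,
with 5-95% intervals from the sqrt-scale linear predictor whose variance
includes fixed-coefficient uncertainty and, optionally, the summed
random-intercept variances.  Post hoc contrasts use Satterthwaite degrees of
freedom and a seeded Monte-Carlo multivariate-t multiplicity adjustment over
each contrast family.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from numpy.random import default_rng
from scipy import linalg, stats
from sklearn.base import BaseEstimator

from ._reml import ConvergenceError, VarCompLMM

__all__ = [
    "RotationOutputModel",
    "PredictionCell",
    "ContrastResult",
    "fit_output_model",
    "mvt_adjust",
    "ConvergenceError",
]

FR_ORDER = ("1M", "1C", "2", "3")


@dataclass(frozen=True)
class PredictionCell:
    """Back-transformed model prediction for one FR level at one time."""

    fr: str
    time: float
    prediction: float
    lower: float
    upper: float
    conf_level: float
    includes_random: bool


@dataclass(frozen=True)
class ContrastResult:
    """A sqrt-scale linear contrast with Satterthwaite df and adjusted p."""

    description: str
    estimate: float
    se: float
    df: float
    t_value: float
    p_raw: float
    p_adj: float


def mvt_adjust(
    t_values, df: float, corr: np.ndarray, draws: int = 100_000, seed: int = 0
) -> np.ndarray:
    """Equicoordinate multivariate-t familywise p values by Monte Carlo.

    For each observed statistic ``t_i`` the adjusted p is
    ``P(max_j |T_j| >= |t_i|)`` under ``T ~ t_nu(0, R)`` with the family's
    correlation matrix ``R`` and common df ``nu``.  Deterministic for a
    fixed seed; Monte-Carlo standard error is about ``sqrt(p(1-p)/draws)``.
    """
    t_values = np.atleast_1d(np.asarray(t_values, dtype=float))
    k = len(t_values)
    if k == 1:
        return np.array([2.0 * stats.t.sf(abs(t_values[0]), df)])
    corr = np.asarray(corr, dtype=float)
    rng = default_rng(seed)
    L = linalg.cholesky(corr + 1e-10 * np.eye(k), lower=True)
    Z = rng.standard_normal((draws, k)) @ L.T
    s = np.sqrt(rng.chisquare(df, draws) / df)
    maxabs = np.abs(Z / s[:, None]).max(axis=1)
    return np.array([float(np.mean(maxabs >= abs(t))) for t in t_values])


def _design_row(t_scaled: float, fr: str, levels: list, baseline: str) -> np.ndarray:
    row = [1.0, t_scaled, t_scaled**2]
    for lvl in levels:
        ind = 1.0 if fr == lvl else 0.0
        row += [ind, ind * t_scaled, ind * t_scaled**2]
    return np.array(row)


class RotationOutputModel(BaseEstimator):
    """Mixed model of sqrt whole-rotation output vs FR and time.

    Parameters
    ----------
    time_scale : "max" or float
        Divisor applied to ``time_since_start`` before fitting.  "max" uses
        the maximum time observed in the fitted data.
    conf_level : float
        Two-sided interval coverage for predictions (0.90 gives 5-95%).
    include_random : bool
        Whether prediction intervals add the summed random-intercept
        variances to the fixed-coefficient variance on the sqrt scale.
    mc_draws, random_state : int
        Monte-Carlo budget and seed of the multivariate-t adjustment.
    response : str
        Column of the output table holding the annual output ``O``.

    Fitted attributes (trailing underscore): ``coef_``, ``vcov_``, ``vc_``
    (site / group / year variances), ``sigma2_``, ``time_scale_``,
    ``levels_``, ``baseline_``, ``n_obs_``, ``loglik_``, ``converged_``,
    ``pinned_`` (variance components estimated on the zero boundary),
    ``nutrient_``.
    """

    def __init__(
        self,
        time_scale="max",
        conf_level: float = 0.90,
        include_random: bool = True,
        mc_draws: int = 100_000,
        random_state: int = 0,
        response: str = "O",
    ):
        self.time_scale = time_scale
        self.conf_level = conf_level
        self.include_random = include_random
        self.mc_draws = mc_draws
        self.random_state = random_state
        self.response = response

    # -- fitting -------------------------------------------------------------

    def fit(self, X: pd.DataFrame, y=None):
        """Fit on a whole-rotation output table for a single nutrient.

        ``X`` needs columns site, group, calendar_year, fr_label,
        time_since_start and the response (unless ``y`` is given).
        """
        req = {"site", "group", "calendar_year", "fr_label", "time_since_start"}
        missing = req - set(X.columns)
        if missing:
            raise ValueError(f"output table is missing columns: {sorted(missing)}")
        if y is None:
            if self.response not in X.columns:
                raise ValueError(f"no response column {self.response!r} in table")
            y = X[self.response].to_numpy(dtype=float)
        else:
            y = np.asarray(y, dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValueError("outputs contain NaN or infinite values")
        if np.any(y < 0):
            raise ValueError(
                "negative outputs encountered; sqrt transform undefined"
            )
        if "nutrient" in X.columns:
            nuts = X["nutrient"].unique()
            if len(nuts) > 1:
                raise ValueError(
                    f"one model per nutrient: table mixes {sorted(nuts)}"
                )
            self.nutrient_ = str(nuts[0])
        else:
            self.nutrient_ = None

        t_raw = X["time_since_start"].to_numpy(dtype=float)
        if self.time_scale == "max":
            self.time_scale_ = float(t_raw.max()) or 1.0
        else:
            self.time_scale_ = float(self.time_scale)
        ts = t_raw / self.time_scale_
        self.time_range_ = (float(t_raw.min()), float(t_raw.max()))

        fr = X["fr_label"].astype(str).to_numpy()
        present = [lvl for lvl in FR_ORDER if lvl in set(fr)]
        present += [lvl for lvl in sorted(set(fr)) if lvl not in present]
        self.baseline_ = "1M" if "1M" in present else present[0]
        if self.baseline_ != "1M":
            warnings.warn(
                f"reference level 1M absent; using {self.baseline_!r} as baseline"
            )
        self.levels_ = [lvl for lvl in present if lvl != self.baseline_]

        Xmat = np.vstack(
            [_design_row(t, f, self.levels_, self.baseline_) for t, f in zip(ts, fr)]
        )
        names = ["intercept", "t", "t2"]
        for lvl in self.levels_:
            names += [f"fr{lvl}", f"fr{lvl}:t", f"fr{lvl}:t2"]
        self.coef_names_ = names

        site = X["site"].astype(str)
        site_group = site + "/" + X["group"].astype(str)
        factors = {
            "site": pd.factorize(site)[0],
            "group": pd.factorize(site_group)[0],
            "year": pd.factorize(X["calendar_year"])[0],
        }
        core = VarCompLMM(Xmat, np.sqrt(y), factors).fit()
        self._core = core
        self.coef_ = pd.Series(core.beta_, index=names)
        self.vcov_ = pd.DataFrame(core.cov_beta_, index=names, columns=names)
        self.vc_ = dict(core.vc_)
        self.sigma2_ = core.sigma2_
        self.pinned_ = {
            n: bool(p) for n, p in zip(core.factor_names, core.pinned_)
        }
        self.loglik_ = core.loglik_
        self.converged_ = core.converged_
        self.n_obs_ = len(y)
        self._var_fixed = float(np.var(Xmat @ core.beta_))
        return self

    def _check_fitted(self):
        if not hasattr(self, "coef_"):
            raise RuntimeError("model is not fitted")

    # -- prediction ----------------------------------------------------------

    def _row(self, fr: str, time: float) -> np.ndarray:
        if fr != self.baseline_ and fr not in self.levels_:
            raise ValueError(f"FR level {fr!r} was not in the fitted data")
        return _design_row(time / self.time_scale_, fr, self.levels_, self.baseline_)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Back-transformed point predictions for rows with fr_label and time."""
        self._check_fitted()
        beta = self.coef_.to_numpy()
        mu = np.array(
            [
                float(self._row(str(f), float(t)) @ beta)
                for f, t in zip(X["fr_label"], X["time_since_start"])
            ]
        )
        return np.clip(mu, 0.0, None) ** 2

    def predict_cells(
        self, fr: str, time: float, include_random: bool | None = None
    ) -> PredictionCell:
        """Prediction with a back-transformed 5-95% (by default) interval."""
        self._check_fitted()
        if include_random is None:
            include_random = self.include_random
        lo_t, hi_t = self.time_range_
        if not lo_t <= time <= hi_t:
            warnings.warn(
                f"time {time} outside the fitted range [{lo_t}, {hi_t}]; "
                "prediction is an extrapolation"
            )
        h = self._row(fr, time)
        mu = float(h @ self.coef_.to_numpy())
        var = float(h @ self.vcov_.to_numpy() @ h)
        if include_random:
            var += sum(self.vc_.values())
        se, df = self._core.satterthwaite(h)
        tq = stats.t.ppf(0.5 + self.conf_level / 2.0, df)
        half = tq * np.sqrt(var)
        lo = max(mu - half, 0.0)
        hi = max(mu + half, 0.0)
        return PredictionCell(
            fr=fr,
            time=float(time),
            prediction=max(mu, 0.0) ** 2,
            lower=lo**2,
            upper=hi**2,
            conf_level=self.conf_level,
            includes_random=bool(include_random),
        )

    # -- contrasts -----------------------------------------------------------

    def _contrast_family(self, rows: list, descriptions: list) -> list:
        beta = self.coef_.to_numpy()
        V = self.vcov_.to_numpy()
        nmp = float(self._core.n - self._core.p)
        null = [bool(np.allclose(c, 0.0)) for c in rows]
        ests, ses, dfs = [], [], []
        for c, is_null in zip(rows, null):
            if is_null:
                ests.append(0.0)
                ses.append(0.0)
                dfs.append(nmp)
                continue
            se, df = self._core.satterthwaite(c)
            if se == 0.0:
                raise ValueError("rank-deficient contrast (zero variance)")
            ests.append(float(c @ beta))
            ses.append(se)
            dfs.append(df)
        live = [i for i, is_null in enumerate(null) if not is_null]
        tvals = np.zeros(len(rows))
        p_raw = np.ones(len(rows))
        p_adj = np.ones(len(rows))
        if live:
            C = np.vstack([rows[i] for i in live])
            cov = C @ V @ C.T
            d = np.sqrt(np.diag(cov))
            corr = cov / np.outer(d, d)
            tv = np.array([ests[i] / ses[i] for i in live])
            dfv = np.array([dfs[i] for i in live])
            pr = 2.0 * stats.t.sf(np.abs(tv), dfv)
            pa = mvt_adjust(
                tv, float(min(dfv)), corr, draws=self.mc_draws, seed=self.random_state
            )
            pa = np.minimum(np.maximum(pa, pr), 1.0)
            tvals[live], p_raw[live], p_adj[live] = tv, pr, pa
        return [
            ContrastResult(
                description=desc,
                estimate=e,
                se=s,
                df=df,
                t_value=float(t),
                p_raw=float(pr),
                p_adj=float(pa),
            )
            for desc, e, s, df, t, pr, pa in zip(
                descriptions, ests, ses, dfs, tvals, p_raw, p_adj
            )
        ]

    def contrast_fr(self, time: float, baseline: str | None = None) -> list:
        """FR contrasts at a fixed time, against the monoculture baseline.

        Family: every other fitted FR level at ``time`` minus ``baseline``
        at the same time, jointly adjusted via the multivariate t.
        """
        self._check_fitted()
        baseline = baseline or self.baseline_
        others = [l for l in [self.baseline_] + self.levels_ if l != baseline]
        rows = [self._row(l, time) - self._row(baseline, time) for l in others]
        desc = [f"FR{l}@{time:g}y - FR{baseline}@{time:g}y" for l in others]
        return self._contrast_family(rows, desc)

    def contrast_time(
        self, fr: str, times=(5.0, 10.0, 20.0), baseline_time: float = 0.0
    ) -> list:
        """Within-FR contrasts of each time against ``baseline_time``."""
        self._check_fitted()
        rows = [self._row(fr, t) - self._row(fr, baseline_time) for t in times]
        desc = [f"FR{fr}@{t:g}y - FR{fr}@{baseline_time:g}y" for t in times]
        return self._contrast_family(rows, desc)

    # -- summaries -----------------------------------------------------------

    def r2_marginal_conditional(self) -> tuple:
        """Variance-partition (Nakagawa-style) marginal and conditional R^2."""
        self._check_fitted()
        vf = self._var_fixed
        vr = sum(self.vc_.values())
        denom = vf + vr + self.sigma2_
        return vf / denom, (vf + vr) / denom

    def satterthwaite_coef(self) -> pd.DataFrame:
        """Per-coefficient estimate, SE, Satterthwaite df and two-sided p."""
        self._check_fitted()
        rows = []
        for i, name in enumerate(self.coef_names_):
            c = np.zeros(len(self.coef_names_))
            c[i] = 1.0
            se, df = self._core.satterthwaite(c)
            est = float(self.coef_.iloc[i])
            tval = est / se if se > 0 else np.nan
            rows.append(
                {
                    "coef": name,
                    "estimate": est,
                    "se": se,
                    "df": df,
                    "t": tval,
                    "p": 2.0 * stats.t.sf(abs(tval), df),
                }
            )
        return pd.DataFrame(rows).set_index("coef")

    def to_dict(self) -> dict:
        self._check_fitted()
        r2m, r2c = self.r2_marginal_conditional()
        return {
            "nutrient": self.nutrient_,
            "coefficients": self.coef_.to_dict(),
            "vcov": self.vcov_.to_numpy().tolist(),
            "coef_names": self.coef_names_,
            "variance_components": self.vc_,
            "residual_variance": self.sigma2_,
            "pinned": self.pinned_,
            "time_scale": self.time_scale_,
            "baseline": self.baseline_,
            "levels": self.levels_,
            "n_obs": self.n_obs_,
            "loglik": self.loglik_,
            "converged": self.converged_,
            "r2_marginal": r2m,
            "r2_conditional": r2c,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def plot_residuals(self, ax=None):
        """Basic residuals-vs-fitted diagnostic plot (sqrt scale)."""
        self._check_fitted()
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        core = self._core
        fitted = core._X @ core.beta_
        resid = core._y - fitted
        ax.scatter(fitted, resid, s=6, alpha=0.5)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel("fitted (sqrt scale)")
        ax.set_ylabel("marginal residual")
        return ax


def fit_output_model(
    outputs: pd.DataFrame, nutrient: str | None = None, **options
) -> RotationOutputModel:
    """Fit the rotation-output mixed model for one nutrient.

    Thin wrapper over :class:`RotationOutputModel`: filters ``outputs`` to
    ``nutrient`` when given and fits on the ``O`` column.
    """
    if nutrient is not None:
        outputs = outputs[outputs["nutrient"] == nutrient]
        if outputs.empty:
            raise ValueError(f"no rows for nutrient {nutrient!r}")
    return RotationOutputModel(**options).fit(outputs)


def contrast_results_frame(results: list) -> pd.DataFrame:
    """Tabulate a list of :class:`ContrastResult` as a DataFrame."""
    return pd.DataFrame([asdict(r) for r in results])
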