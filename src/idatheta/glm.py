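"""Lognormal GLM for trial-level theta power and AIC model comparison.

The response (positive theta power) is modelled as

    log theta_i ~ Normal(b0 + x_i' b, sigma_log^2),

i.e. maximum likelihood for a lognormal response with a linear predictor
on the log scale, which coincides with OLS on log(theta) plus the ML
dispersion.  The log-likelihood includes the Jacobian term
-sum(log theta_i), so AIC values are comparable with any other density
fitted to theta on its original scale.  Candidate predictor sets are the
z-scored trial-level measures: I (surprise), LR (local redundancy) and
T (trial number); models are ranked by AIC with delta-AIC relative to the
best model, all fitted on an identical trial set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

#: short predictor-set names -> z-scored columns of the predictor table
PREDICTOR_COLUMNS = {
    "I": "z_surprise",
    "LR": "z_redundancy",
    "T": "z_trialnum",
}
DEFAULT_SPECS = ("I,T", "LR,T", "T", "I", "LR")


@dataclass(frozen=True)
class ModelSpec:
    """A predictor subset; the intercept is always included."""

    predictors: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = set(self.predictors) - set(PREDICTOR_COLUMNS)
        if unknown:
            raise ValueError(
                f"unknown predictors {sorted(unknown)}; "
                f"choose from {sorted(PREDICTOR_COLUMNS)}")

    @classmethod
    def parse(cls, text: str) -> "ModelSpec":
        parts = tuple(p.strip() for p in text.split(",") if p.strip())
        return cls(predictors=parts)

    @property
    def name(self) -> str:
        return ", ".join(self.predictors) if self.predictors else "(intercept)"

    @property
    def columns(self) -> list[str]:
        return [PREDICTOR_COLUMNS[p] for p in self.predictors]


class LognormalGLM:
    """Lognormal regression model for positive trial-level theta power.

    Parameters
    ----------
    endog : array-like, positive response (theta power per trial).
    exog : array-like (n, p) design matrix *without* intercept, or None
        for the intercept-only model.
    exog_names : names for the exog columns.

    Use :meth:`from_dataframe` to build from a predictor table.
    """

    def __init__(self, endog, exog=None, exog_names=None):
        y = np.asarray(endog, dtype=float).ravel()
        if len(y) == 0:
            raise ValueError("empty response")
        if np.any(~np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if np.any(y <= 0):
            raise ValueError(
                "lognormal response must be strictly positive; normalize "
                "theta with a positivity-preserving transform first")
        if exog is None:
            x = np.empty((len(y), 0))
        else:
            x = np.asarray(exog, dtype=float)
            if x.ndim == 1:
                x = x[:, None]
        if np.any(~np.isfinite(x)):
            raise ValueError("design matrix contains non-finite values")
        if x.shape[0] != len(y):
            raise ValueError("endog and exog lengths differ")
        self.endog = y
        self.exog = np.column_stack([np.ones(len(y)), x])
        names = list(exog_names) if exog_names is not None else [
            f"x{i + 1}" for i in range(x.shape[1])]
        if len(names) != x.shape[1]:
            raise ValueError("exog_names length mismatch")
        self.exog_names = ["const"] + names
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("rank-deficient design matrix")
        if len(y) <= self.exog.shape[1] + 1:
            raise ValueError("need more observations than parameters")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, spec: ModelSpec | str,
                       response: str = "theta_power") -> "LognormalGLM":
        if isinstance(spec, str):
            spec = ModelSpec.parse(spec)
        cols = spec.columns
        sub = data[[response] + cols].dropna()
        return cls(sub[response], sub[cols] if cols else None,
                   exog_names=list(spec.predictors))

    def loglike(self, params: np.ndarray, sigma_log: float) -> float:
        """Lognormal log-likelihood at given coefficients and dispersion."""
        mu = self.exog @ params
        logy = np.log(self.endog)
        return float(sps.norm.logpdf(logy, mu, sigma_log).sum() - logy.sum())

    def fit(self) -> "LognormalGLMResults":
        logy = np.log(self.endog)
        params, _, _, _ = np.linalg.lstsq(self.exog, logy, rcond=None)
        resid = logy - self.exog @ params
        n, p = self.exog.shape
        sigma_ml = float(np.sqrt((resid ** 2).mean()))
        sigma_ml = max(sigma_ml, 1e-12)
        # classical OLS covariance (unbiased dispersion) for the SEs
        s2 = (resid ** 2).sum() / (n - p)
        cov = s2 * np.linalg.inv(self.exog.T @ self.exog)
        llf = self.loglike(params, sigma_ml)
        return LognormalGLMResults(self, params, np.sqrt(np.diag(cov)),
                                   sigma_ml, llf)


class LognormalGLMResults:
    """Fitted lognormal GLM: estimates, uncertainties, AIC, summary."""

    def __init__(self, model: LognormalGLM, params, bse, sigma_log, llf):
        self.model = model
        self.params = pd.Series(params, index=model.exog_names)
        self.bse = pd.Series(bse, index=model.exog_names)
        self.sigma_log = float(sigma_log)
        self.llf = float(llf)
        self.nobs = len(model.endog)
        self.df_model = model.exog.shape[1] - 1

    @property
    def k_params(self) -> int:
        """Coefficients (incl. intercept) + dispersion."""
        return len(self.params) + 1

    @property
    def aic(self) -> float:
        return 2 * self.k_params - 2 * self.llf

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        df = self.nobs - len(self.params)
        return pd.Series(2 * sps.t.sf(np.abs(self.tvalues), df),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        df = self.nobs - len(self.params)
        q = sps.t.isf(alpha / 2, df)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Lognormal GLM (log link on the response scale)",
            f"  nobs = {self.nobs}, k = {self.k_params}, "
            f"sigma_log = {self.sigma_log:.4f}",
            f"  loglik = {self.llf:.3f}, AIC = {self.aic:.2f}",
            "",
            f"  {'term':<14}{'coef':>10}{'se':>10}{'t':>9}{'p':>10}"
            f"{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.params.index:
            lines.append(
                f"  {name:<14}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>9.3f}{self.pvalues[name]:>10.4f}"
                f"{ci.loc[name, 'lower']:>10.4f}{ci.loc[name, 'upper']:>10.4f}")
        return "\n".join(lines)


def distribution_diagnostics(values) -> dict:
    """Shape diagnostics of a theta-power sample (Cullen-Frey style).

    Reports sample skewness and excess kurtosis alongside the theoretical
    lognormal point for the log-scale sigma fitted to the positive values.
    Informational only — the modelling family is fixed to lognormal.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if len(v) < 10:
        raise ValueError("need at least 10 values")
    if v.std() == 0:
        raise ValueError("zero variance sample")
    pos = v[v > 0]
    out = {
        "n": int(len(v)),
        "n_nonpositive": int((v <= 0).sum()),
        "skewness": float(sps.skew(v)),
        "excess_kurtosis": float(sps.kurtosis(v)),
    }
    if len(pos) >= 10:
        s2 = np.log(pos).var()
        w = np.exp(s2)
        out["sigma_log_fit"] = float(np.sqrt(s2))
        out["lognormal_skewness"] = float((w + 2) * np.sqrt(w - 1))
        out["lognormal_excess_kurtosis"] = float(
            w ** 4 + 2 * w ** 3 + 3 * w ** 2 - 6)
    return out


def normalize_theta(df: pd.DataFrame, value: str = "theta_power",
                    by: str = "subject", method: str = "subject_median",
                    shift_floor: float = 0.05) -> pd.Series:
    """Standardize trial theta across subjects before pooled fitting.

    ``subject_median`` (default) divides each trial by its subject's
    median — positivity-preserving, absorbs subject offsets on the log
    scale.  ``zscore_shift`` z-scores within subject and shifts the pooled
    values so the minimum equals ``shift_floor`` (> 0); provided for
    comparability with pipelines that z-transform before fitting, at the
    cost of an arbitrary shift.
    """
    if method == "subject_median":
        med = df.groupby(by)[value].transform("median")
        if (med <= 0).any():
            raise ValueError("non-positive subject medians")
        return df[value] / med
    if method == "zscore_shift":
        z = df.groupby(by)[value].transform(
            lambda s: (s - s.mean()) / s.std(ddof=0))
        return z - z.min() + shift_floor
    raise ValueError("method must be 'subject_median' or 'zscore_shift'")


def compare_models(data: pd.DataFrame, specs=DEFAULT_SPECS,
                   response: str = "theta_power"
                   ) -> tuple[pd.DataFrame, dict[str, LognormalGLMResults]]:
    """Fit each candidate predictor set and rank by AIC.

    All models are fitted on the identical trial set (listwise deletion
    over the union of all predictor columns first).  Returns the ranked
    table (model, k, loglik, aic, delta_aic) and the fit objects.
    """
    specs = [ModelSpec.parse(s) if isinstance(s, str) else s for s in specs]
    all_cols = sorted({c for s in specs for c in s.columns})
    common = data[[response] + all_cols].dropna().reset_index(drop=True)
    if common.empty:
        raise ValueError("no complete cases across the candidate models")
    fits: dict[str, LognormalGLMResults] = {}
    rows = []
    nobs = set()
    for spec in specs:
        res = LognormalGLM.from_dataframe(common, spec, response=response).fit()
        fits[spec.name] = res
        rows.append({"model": spec.name, "k": res.k_params,
                     "loglik": res.llf, "aic": res.aic})
        nobs.add(res.nobs)
    if len(nobs) != 1:
        raise AssertionError(
            "internal error: candidate fits used differing case counts")
    table = (pd.DataFrame(rows)
             .sort_values("aic", kind="stable").reset_index(drop=True))
    table["delta_aic"] = table["aic"] - table["aic"].min()
    return table, fits
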