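"""Group-level inference for the theta-power design.

One-way repeated-measures ANOVA (factor: condition) with partial eta
squared, Bonferroni-corrected per-channel follow-ups with paired t tests,
partial correlations between subject-level theta and behavioral outcomes,
and Monte-Carlo power for the three-condition within-subject design under
compound symmetry.

The ANOVA is the classical two-way (subject x condition) decomposition
without sphericity correction; Greenhouse-Geisser epsilon is available as
an optional diagnostic.  The F statistic is computed by a vectorised
sums-of-squares routine so the power simulation can evaluate thousands of
cohorts in one shot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

BONFERRONI_CHANNELS = ("Fz", "FCz", "Cz")


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    channel: str | None = None
    gg_epsilon: float | None = None

    def __str__(self) -> str:
        ch = f" at {self.channel}" if self.channel else ""
        return (f"RM-ANOVA{ch}: F({self.df_effect},{self.df_error}) = "
                f"{self.F:.3f}, p = {self.p:.4f}, "
                f"partial eta^2 = {self.partial_eta_sq:.3f}")


@dataclass(frozen=True)
class PartialCorrResult:
    r: float
    df: int
    p: float
    n: int
    n_controls: int

    def __str__(self) -> str:
        return f"r({self.df}) = {self.r:.3f}, p = {self.p:.4f}"


@dataclass(frozen=True)
class PowerResult:
    power: float
    se: float
    n_sims: int
    n_subjects: int
    effect_size_f: float
    rho: float
    alpha: float


def _anova_f(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched classical within-subject decomposition.

    ``y`` has shape (..., n_subjects, n_conditions); returns (F, SS pair
    (effect, error)) broadcast over leading axes.
    """
    gm = y.mean(axis=(-2, -1), keepdims=True)
    cond_means = y.mean(axis=-2, keepdims=True)
    subj_means = y.mean(axis=-1, keepdims=True)
    n, c = y.shape[-2], y.shape[-1]
    ss_cond = (n * (cond_means - gm) ** 2).sum(axis=(-2, -1))
    ss_subj = (c * (subj_means - gm) ** 2).sum(axis=(-2, -1))
    ss_total = ((y - gm) ** 2).sum(axis=(-2, -1))
    ss_err = ss_total - ss_cond - ss_subj
    df_c, df_e = c - 1, (n - 1) * (c - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_cond / df_c) / (ss_err / df_e)
    return f, np.stack([ss_cond, ss_err], axis=-1)


def _to_wide(theta: pd.DataFrame, value: str = "theta_power") -> pd.DataFrame:
    if isinstance(theta, pd.DataFrame) and {"subject", "condition"} <= set(theta.columns):
        wide = theta.pivot_table(index="subject", columns="condition",
                                 values=value, aggfunc="mean")
    else:
        wide = pd.DataFrame(theta)
    if wide.isna().any().any():
        missing = wide[wide.isna().any(axis=1)].index.tolist()
        raise ValueError(
            f"missing condition cells for subjects {missing}; complete cases "
            "are required (no imputation)")
    return wide


def gg_epsilon(y: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon for an n x c score matrix."""
    y = np.asarray(y, dtype=float)
    s = np.cov(y, rowvar=False)
    c = s.shape[0]
    mean_diag = np.trace(s) / c
    mean_all = s.mean()
    num = (c * (mean_diag - mean_all)) ** 2
    den = (c - 1) * ((s ** 2).sum() - 2 * c * (s.mean(axis=1) ** 2).sum()
                     + c ** 2 * mean_all ** 2)
    return float(num / den)


def rm_anova(theta: pd.DataFrame | np.ndarray, channel: str | None = None,
             value: str = "theta_power", with_gg: bool = False) -> RmAnovaResult:
    """One-way repeated-measures ANOVA over conditions.

    Accepts a long table with columns subject, condition, ``value``
    (optionally pre-filtered to one channel) or an n x c wide matrix.
    Reports uncorrected degrees of freedom; partial eta squared satisfies
    pes = (df_e * F) / (df_e * F + df_err) identically.
    """
    if isinstance(theta, pd.DataFrame) and channel is not None and "channel" in theta:
        theta = theta[theta["channel"] == channel]
    wide = _to_wide(theta, value=value)
    y = wide.to_numpy(dtype=float)
    if y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    f, ss = _anova_f(y)
    n, c = y.shape
    df_c, df_e = c - 1, (n - 1) * (c - 1)
    f = float(f)
    if not np.isfinite(f):
        # degenerate 0/0 case (no condition and no error variance)
        f = 0.0
    p = float(sps.f.sf(f, df_c, df_e))
    pes = float(ss[0] / (ss[0] + ss[1])) if (ss[0] + ss[1]) > 0 else 0.0
    return RmAnovaResult(F=f, df_effect=df_c, df_error=df_e, p=p,
                         partial_eta_sq=pes, channel=channel,
                         gg_epsilon=gg_epsilon(y) if with_gg else None)


def bonferroni_followups(theta: pd.DataFrame,
                         channels: tuple[str, ...] = BONFERRONI_CHANNELS,
                         alpha: float = 0.05) -> dict:
    """Per-channel ANOVAs at Bonferroni-corrected alpha + paired t tests.

    The correction (alpha / number of channels, 0.05/3 = 0.0167) is
    applied to the channel ANOVAs; the pairwise paired t tests are
    reported at uncorrected p, flagged as such.
    """
    n_subj = theta["subject"].nunique()
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")
    alpha_corr = alpha / len(channels)
    anovas: dict[str, RmAnovaResult] = {}
    pairwise_rows = []
    for ch in channels:
        res = rm_anova(theta, channel=ch)
        anovas[ch] = res
        wide = _to_wide(theta[theta["channel"] == ch])
        conds = list(wide.columns)
        for i in range(len(conds)):
            for j in range(i + 1, len(conds)):
                a, b = wide[conds[i]], wide[conds[j]]
                if np.allclose(a, b):
                    t, p = 0.0, 1.0
                else:
                    t, p = sps.ttest_rel(a, b)
                pairwise_rows.append({
                    "channel": ch, "a": conds[i], "b": conds[j],
                    "t": float(t), "df": len(a) - 1, "p": float(p),
                    "mean_diff": float((a - b).mean())})
    return {
        "alpha_corrected": alpha_corr,
        "anovas": anovas,
        "significant_channels": [ch for ch, r in anovas.items()
                                 if r.p < alpha_corr],
        "pairwise": pd.DataFrame(pairwise_rows),
        "note": "channel ANOVAs evaluated at Bonferroni-corrected alpha; "
                "pairwise paired t tests reported at uncorrected p",
    }


def partial_correlation(x, y, controls=None) -> PartialCorrResult:
    """Partial correlation via the residual method.

    ``controls`` is an (n, k) array / DataFrame (or None for a plain
    Pearson correlation).  r is the correlation of the residuals of x and
    y after linear removal of the controls (with intercept);
    p comes from t = r * sqrt(df / (1 - r^2)), df = n - 2 - k.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    if len(y) != n:
        raise ValueError("x and y must have equal length")
    if controls is None:
        z = np.ones((n, 1))
        k = 0
    else:
        c = np.asarray(controls, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        k = c.shape[1]
        z = np.column_stack([np.ones(n), c])
    if n <= k + 2:
        raise ValueError(f"need n > n_controls + 2 (n={n}, controls={k})")
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise ValueError("control variables are collinear")
    rx = x - z @ np.linalg.lstsq(z, x, rcond=None)[0]
    ry = y - z @ np.linalg.lstsq(z, y, rcond=None)[0]
    tol_x = 1e-10 * max(1.0, x.std())
    tol_y = 1e-10 * max(1.0, y.std())
    sx, sy = rx.std(), ry.std()
    if sx <= tol_x or sy <= tol_y:
        raise ValueError("zero residual variance after removing controls "
                         "(a control is collinear with x or y)")
    r = float(np.clip((rx * ry).mean() / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r ** 2))
        p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrResult(r=r, df=df, p=p, n=n, n_controls=k)


def partial_correlation_from_cov(cov: np.ndarray) -> float:
    """Closed-form first-order partial correlation from a 3x3 covariance
    (variables ordered x, y, z): (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))."""
    d = np.sqrt(np.diag(cov))
    r = cov / np.outer(d, d)
    return float((r[0, 1] - r[0, 2] * r[1, 2])
                 / np.sqrt((1 - r[0, 2] ** 2) * (1 - r[1, 2] ** 2)))


def power_rm_anova(n: int, f: float, rho: float, alpha: float = 0.05,
                   n_sims: int = 5000, seed: int = 0,
                   n_conditions: int = 3) -> PowerResult:
    """Monte-Carlo power of the one-way RM-ANOVA under compound symmetry.

    Condition scores are multivariate normal with unit total SD, pairwise
    correlation ``rho`` and a fixed mean pattern scaled so that Cohen's f
    (SD of condition means / within-cell SD) equals ``f``.  Because the
    within-subject error variance is (1 - rho) * sigma^2, the standard
    1/(1 - rho) effective effect-size inflation of the within design
    arises naturally.  Returns the rejection rate with its binomial SE.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    if f < 0:
        raise ValueError("effect size f must be nonnegative")
    c = n_conditions
    pattern = np.arange(c, dtype=float)
    pattern -= pattern.mean()
    sd = np.sqrt((pattern ** 2).mean())
    means = f * pattern / sd if sd > 0 else pattern * 0.0
    rng = np.random.default_rng(seed)
    crit = sps.f.isf(alpha, c - 1, (n - 1) * (c - 1))
    rejections = 0
    batch = max(1, min(n_sims, int(2e7 // (n * c))))
    done = 0
    while done < n_sims:
        b = min(batch, n_sims - done)
        g = rng.standard_normal((b, n, 1))
        e = rng.standard_normal((b, n, c))
        y = np.sqrt(rho) * g + np.sqrt(1 - rho) * e + means
        fstat, _ = _anova_f(y)
        rejections += int((fstat > crit).sum())
        done += b
    power = rejections / n_sims
    se = float(np.sqrt(power * (1 - power) / n_sims))
    return PowerResult(power=power, se=se, n_sims=n_sims, n_subjects=n,
                       effect_size_f=f, rho=rho, alpha=alpha)
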