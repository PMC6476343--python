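"""Statistical chain: within-subject MANOVA, mixed-model moderation, slopes.

The behavioral analysis runs in two stages.  A repeated-measures MANOVA on
within-participant contrast scores (Pillai's trace with exact F for
single-df effects) checks that risk and reward move the dependent-variable
triplet (response time, success proportion, earnings), followed by paired
post hoc t tests with Bonferroni correction and Cohen's d.

The moderation analysis fits a linear mixed-effects model of response time
with a random intercept per participant (REML) and the full fixed-effect
structure risk, reward, SCR, impulsivity (BIS) and their two- and three-way
interactions.  Conditional SCR slopes at chosen impulsivity values (simple
slopes) and the impulsivity region where the SCR slope is significant
(Johnson-Neyman) are derived from the fitted coefficient vector and its
covariance.

Coding conventions: risk and reward are 0/1 indicators (low = 0), the SCR
covariate is z-standardized within sample, and BIS stays on its raw scale so
moderator values are interpretable questionnaire totals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "FIXED_TERMS",
    "MixedFit",
    "fit_mixed_model",
    "SimpleSlope",
    "simple_slopes",
    "JNInterval",
    "johnson_neyman",
    "ManovaResult",
    "rm_manova",
    "posthoc_contrasts",
    "build_design",
]

#: Fixed-effect terms of the moderation model, in design-matrix order.
FIXED_TERMS: tuple[str, ...] = (
    "Intercept",
    "reward",
    "scr",
    "bis",
    "risk",
    "reward:scr",
    "reward:bis",
    "scr:bis",
    "risk:scr",
    "risk:bis",
    "reward:scr:bis",
    "risk:scr:bis",
)


def build_design(
    risk: np.ndarray, reward: np.ndarray, scr: np.ndarray, bis: np.ndarray
) -> pd.DataFrame:
    """Design matrix with the full interaction structure of the model."""
    cols = {
        "Intercept": np.ones_like(scr, dtype=float),
        "reward": reward,
        "scr": scr,
        "bis": bis,
        "risk": risk,
        "reward:scr": reward * scr,
        "reward:bis": reward * bis,
        "scr:bis": scr * bis,
        "risk:scr": risk * scr,
        "risk:bis": risk * bis,
        "reward:scr:bis": reward * scr * bis,
        "risk:scr:bis": risk * scr * bis,
    }
    return pd.DataFrame(cols, columns=list(FIXED_TERMS))


@dataclass
class MixedFit:
    """Random-intercept mixed-model fit of response time."""

    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame  # columns: lower, upper
    cov: pd.DataFrame  # fixed-effect covariance matrix
    re_var: float  # random-intercept variance
    re_sd: float
    resid_var: float
    df_resid: float
    n_obs: int
    n_groups: int
    converged: bool
    # covariate bookkeeping used by the moderation layer
    scr_mean: float = 0.0
    scr_sd: float = 1.0
    bis_mean: float = np.nan
    bis_sd: float = np.nan
    bis_range: tuple[float, float] = (np.nan, np.nan)

    def term(self, *factors: str) -> str:
        """Resolve the design-matrix name of a term from its factor set."""
        want = set(factors)
        for t in self.terms:
            if set(t.split(":")) == want:
                return t
        raise KeyError(f"term with factors {sorted(want)} not in the fit")


def fit_mixed_model(
    table: pd.DataFrame,
    *,
    rt_col: str = "rt_ms",
    standardize_scr: bool = True,
) -> MixedFit:
    """REML random-intercept model of RT on risk, reward, SCR, BIS + interactions.

    Expects a long table with one row per participant x condition and columns
    ``participant_id, risk_level, reward_level, scr_integral, bis_total`` and
    the response-time column.  t tests use residual degrees of freedom
    ``n_obs - n_fixed - n_groups + 1`` (a containment-style approximation).
    """
    required = {"participant_id", "risk_level", "reward_level", "scr_integral", "bis_total", rt_col}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    df = table.copy()
    n_groups = df["participant_id"].nunique()
    if n_groups < 8:
        raise ValueError("need at least 8 participants")
    for col in ("scr_integral", "bis_total", rt_col):
        if not np.all(np.isfinite(df[col].to_numpy(dtype=float))):
            raise ValueError(f"non-finite values in {col}")

    risk = (df["risk_level"].astype(str) == "high").to_numpy(dtype=float)
    reward = (df["reward_level"].astype(str) == "high").to_numpy(dtype=float)
    scr_raw = df["scr_integral"].to_numpy(dtype=float)
    bis = df["bis_total"].to_numpy(dtype=float)
    if standardize_scr:
        scr_mean, scr_sd = float(scr_raw.mean()), float(scr_raw.std(ddof=1))
        if scr_sd == 0:
            raise ValueError("SCR covariate has zero variance")
        scr = (scr_raw - scr_mean) / scr_sd
    else:
        scr_mean, scr_sd = 0.0, 1.0
        scr = scr_raw

    X = build_design(risk, reward, scr, bis)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    y = df[rt_col].to_numpy(dtype=float)

    # Degenerate noiseless data (zero residual and random-effect variance)
    # admits an exact linear solve; the REML optimizer has nothing to
    # estimate there and is skipped.
    Xa = X.to_numpy()
    beta_ols, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    ssr = float(np.sum((y - Xa @ beta_ols) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if ssr <= 1e-10 * max(sst, 1.0):
        k = Xa.shape[1]
        zero = pd.Series(0.0, index=list(FIXED_TERMS))
        return MixedFit(
            terms=FIXED_TERMS,
            params=pd.Series(beta_ols, index=FIXED_TERMS),
            bse=zero.copy(),
            tvalues=pd.Series(np.nan, index=list(FIXED_TERMS)),
            pvalues=pd.Series(np.nan, index=list(FIXED_TERMS)),
            conf_int=pd.DataFrame(
                {"lower": pd.Series(beta_ols, index=FIXED_TERMS),
                 "upper": pd.Series(beta_ols, index=FIXED_TERMS)}
            ),
            cov=pd.DataFrame(
                np.zeros((k, k)), index=FIXED_TERMS, columns=FIXED_TERMS
            ),
            re_var=0.0,
            re_sd=0.0,
            resid_var=0.0,
            df_resid=float(len(y) - k - n_groups + 1),
            n_obs=len(y),
            n_groups=int(n_groups),
            converged=True,
            scr_mean=scr_mean,
            scr_sd=scr_sd,
            bis_mean=float(bis.mean()),
            bis_sd=float(bis.std(ddof=1)),
            bis_range=(float(bis.min()), float(bis.max())),
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=df["participant_id"].to_numpy())
        result = model.fit(reml=True)
        if not result.converged:
            # one retry with a different optimizer before giving up
            result = model.fit(reml=True, method="cg")
    if not result.converged:
        raise RuntimeError(
            "mixed model did not converge (REML); "
            f"n_obs={len(y)}, n_groups={n_groups}"
        )

    k = X.shape[1]
    fe = pd.Series(np.asarray(result.fe_params), index=FIXED_TERMS)
    bse = pd.Series(np.asarray(result.bse_fe), index=FIXED_TERMS)
    cov = pd.DataFrame(
        np.asarray(result.cov_params())[:k, :k], index=FIXED_TERMS, columns=FIXED_TERMS
    )
    df_resid = len(y) - k - n_groups + 1
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = fe / bse
    pvals = pd.Series(2.0 * sps.t.sf(np.abs(tvals), df_resid), index=FIXED_TERMS)
    tcrit = sps.t.ppf(0.975, df_resid)
    ci = pd.DataFrame(
        {"lower": fe - tcrit * bse, "upper": fe + tcrit * bse}, index=FIXED_TERMS
    )
    re_var = float(np.asarray(result.cov_re)[0, 0])

    return MixedFit(
        terms=FIXED_TERMS,
        params=fe,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        conf_int=ci,
        cov=cov,
        re_var=re_var,
        re_sd=float(np.sqrt(re_var)),
        resid_var=float(result.scale),
        df_resid=float(df_resid),
        n_obs=len(y),
        n_groups=int(n_groups),
        converged=bool(result.converged),
        scr_mean=scr_mean,
        scr_sd=scr_sd,
        bis_mean=float(bis.mean()),
        bis_sd=float(bis.std(ddof=1)),
        bis_range=(float(bis.min()), float(bis.max())),
    )


# ---------------------------------------------------------------------------
# simple slopes and Johnson-Neyman
# ---------------------------------------------------------------------------


@dataclass
class SimpleSlope:
    stratum_value: float
    moderator_value: float
    slope: float
    se: float
    t: float
    p: float
    label: str = ""


def _slope_gradient(
    fit: MixedFit,
    focal: str,
    moderator: str,
    stratum: Optional[str],
    stratum_value: float,
    w: float,
) -> np.ndarray:
    """Gradient of the conditional focal slope w.r.t. the coefficient vector."""
    c = pd.Series(0.0, index=list(fit.terms))
    c[fit.term(focal)] = 1.0
    c[fit.term(focal, moderator)] = w
    if stratum is not None and stratum_value != 0.0:
        c[fit.term(stratum, focal)] = stratum_value
        c[fit.term(stratum, focal, moderator)] = stratum_value * w
    return c.to_numpy()


def simple_slopes(
    fit: MixedFit,
    *,
    focal: str = "scr",
    moderator: str = "bis",
    moderator_values: Optional[Sequence[float]] = None,
    stratum: Optional[str] = "risk",
    stratum_values: Sequence[float] = (0.0, 1.0),
) -> pd.DataFrame:
    """Conditional focal slopes at chosen moderator values, per stratum.

    Defaults probe the SCR slope at BIS mean and mean +/- 1 SD within each
    risk level, i.e. slope(w) = b_scr + b_scr:bis * w (+ risk terms under
    high risk), with SEs from the coefficient-covariance quadratic form.
    """
    if moderator_values is None:
        m, s = fit.bis_mean, fit.bis_sd
        moderator_values = [m - s, m, m + s]
        labels = ["-1 SD", "Mean", "+1 SD"]
    else:
        labels = [""] * len(moderator_values)
    b = fit.params.to_numpy()
    cov = fit.cov.to_numpy()
    rows = []
    for s_val in stratum_values:
        for w, lab in zip(moderator_values, labels):
            c = _slope_gradient(fit, focal, moderator, stratum, float(s_val), float(w))
            slope = float(c @ b)
            se = float(np.sqrt(c @ cov @ c))
            t = slope / se if se > 0 else np.nan
            p = 2.0 * sps.t.sf(abs(t), fit.df_resid) if np.isfinite(t) else np.nan
            rows.append(
                {
                    "stratum": stratum,
                    "stratum_value": float(s_val),
                    "moderator_value": float(w),
                    "label": lab,
                    "slope": slope,
                    "se": se,
                    "t": t,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class JNInterval:
    """Johnson-Neyman significance region of the focal slope."""

    boundaries: list  # real roots inside the moderator range, ascending
    significant_regions: list  # list of (lo, hi) sub-intervals of the range
    t_crit: float
    alpha: float
    moderator_range: tuple[float, float]
    all_roots: list = field(default_factory=list)  # roots of the quadratic


def johnson_neyman(
    fit: MixedFit,
    *,
    focal: str = "scr",
    moderator: str = "bis",
    stratum: Optional[str] = "risk",
    stratum_value: float = 1.0,
    alpha: float = 0.05,
    moderator_range: Optional[tuple[float, float]] = None,
) -> JNInterval:
    """Moderator region where the conditional focal slope is significant.

    Solves slope(w)^2 = t_crit^2 * Var(slope(w)) -- a quadratic in the
    moderator w -- and intersects the resulting region with the observed
    moderator range.  A negative discriminant means the slope is either
    significant everywhere or nowhere in the range; that is reported as a
    full or empty region, not an error.
    """
    if moderator_range is None:
        moderator_range = fit.bis_range
    lo, hi = map(float, moderator_range)

    b = fit.params
    cov = fit.cov.to_numpy()
    idx = {t: i for i, t in enumerate(fit.terms)}

    g0 = np.zeros(len(fit.terms))
    g0[idx[fit.term(focal)]] = 1.0
    g1 = np.zeros(len(fit.terms))
    g1[idx[fit.term(focal, moderator)]] = 1.0
    if stratum is not None and stratum_value != 0.0:
        g0[idx[fit.term(stratum, focal)]] = stratum_value
        g1[idx[fit.term(stratum, focal, moderator)]] = stratum_value

    A = float(g0 @ b.to_numpy())
    B = float(g1 @ b.to_numpy())
    q0 = float(g0 @ cov @ g0)
    q1 = float(g0 @ cov @ g1)
    q2 = float(g1 @ cov @ g1)

    t_crit = float(sps.t.ppf(1.0 - alpha / 2.0, fit.df_resid))
    t2 = t_crit**2
    # (A + Bw)^2 - t2 (q0 + 2 q1 w + q2 w^2) = 0
    a2 = B**2 - t2 * q2
    a1 = 2.0 * (A * B - t2 * q1)
    a0 = A**2 - t2 * q0

    roots: list[float] = []
    if abs(a2) > 0:
        disc = a1**2 - 4.0 * a2 * a0
        if disc >= 0:
            r = np.sort(np.roots([a2, a1, a0]).real)
            roots = [float(v) for v in r]
    elif abs(a1) > 0:
        roots = [float(-a0 / a1)]

    def significant(w: float) -> bool:
        num = (A + B * w) ** 2
        den = t2 * (q0 + 2 * q1 * w + q2 * w**2)
        return num >= den

    inner = [r for r in roots if lo < r < hi]
    edges = [lo] + sorted(inner) + [hi]
    regions = []
    for a, bnd in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a + bnd)
        if significant(mid):
            regions.append((a, bnd))
    # merge touching regions
    merged: list[tuple[float, float]] = []
    for reg in regions:
        if merged and np.isclose(merged[-1][1], reg[0]):
            merged[-1] = (merged[-1][0], reg[1])
        else:
            merged.append(reg)

    return JNInterval(
        boundaries=sorted(inner),
        significant_regions=merged,
        t_crit=t_crit,
        alpha=alpha,
        moderator_range=(lo, hi),
        all_roots=roots,
    )


# ---------------------------------------------------------------------------
# repeated-measures MANOVA and post hocs
# ---------------------------------------------------------------------------

DEFAULT_DVS = ("mean_rt_ms", "success_prop", "earnings_cents")

_EFFECTS = ("risk", "reward", "risk:reward")


@dataclass
class ManovaResult:
    """Pillai's trace tests of the within-subject effects."""

    effects: pd.DataFrame  # rows: effect; columns pillai, F, df1, df2, p, partial_eta_sq
    n_complete: int
    n_dropped: int
    dvs: tuple[str, ...] = DEFAULT_DVS


def _contrast_scores(wide: pd.DataFrame, dv: str, effect: str) -> np.ndarray:
    """Per-participant contrast score of one DV for one within effect."""
    def cell(r: str, w: str) -> np.ndarray:
        return wide[(dv, r, w)].to_numpy(dtype=float)

    if effect == "risk":
        return 0.5 * (cell("high", "low") + cell("high", "high")) - 0.5 * (
            cell("low", "low") + cell("low", "high")
        )
    if effect == "reward":
        return 0.5 * (cell("low", "high") + cell("high", "high")) - 0.5 * (
            cell("low", "low") + cell("high", "low")
        )
    if effect == "risk:reward":
        return (cell("high", "high") - cell("high", "low")) - (
            cell("low", "high") - cell("low", "low")
        )
    raise ValueError(f"unknown effect {effect!r}")


def _pivot_complete(table: pd.DataFrame, dvs: Sequence[str]) -> tuple[pd.DataFrame, int]:
    wide = table.pivot_table(
        index="participant_id",
        columns=["risk_level", "reward_level"],
        values=list(dvs),
        aggfunc="mean",
    )
    n_total = len(wide)
    wide = wide.dropna()
    return wide, n_total - len(wide)


def rm_manova(table: pd.DataFrame, dvs: Sequence[str] = DEFAULT_DVS) -> ManovaResult:
    """Pillai's trace MANOVA of the 2x2 within-subject design.

    Each single-df within effect reduces to a one-sample multivariate test on
    per-participant contrast scores: with H = n ybar ybar' and E the centered
    cross-product matrix, Pillai's trace V = tr(H (H+E)^-1) has the exact F
    transform F = V/(1-V) * (n-p)/p on (p, n-p) degrees of freedom.
    Participants with any missing cell are dropped listwise.
    """
    wide, n_dropped = _pivot_complete(table, dvs)
    n = len(wide)
    p = len(dvs)
    if n <= p:
        raise ValueError(f"need more than {p} complete participants, have {n}")
    rows = []
    for effect in _EFFECTS:
        Y = np.column_stack([_contrast_scores(wide, dv, effect) for dv in dvs])
        ybar = Y.mean(axis=0)
        centered = Y - ybar
        H = n * np.outer(ybar, ybar)
        E = centered.T @ centered
        V = float(np.trace(H @ np.linalg.pinv(H + E)))
        F = (V / (1.0 - V)) * (n - p) / p if V < 1.0 else np.inf
        df1, df2 = p, n - p
        pval = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        rows.append(
            {
                "effect": effect,
                "pillai": V,
                "F": F,
                "df1": df1,
                "df2": df2,
                "p": pval,
                "partial_eta_sq": V,
            }
        )
    return ManovaResult(
        effects=pd.DataFrame(rows).set_index("effect"),
        n_complete=n,
        n_dropped=n_dropped,
        dvs=tuple(dvs),
    )


def posthoc_contrasts(
    table: pd.DataFrame,
    effect: str = "risk",
    dvs: Sequence[str] = DEFAULT_DVS,
) -> pd.DataFrame:
    """Paired t tests per DV for one main effect, Bonferroni-corrected.

    The contrast is the participant-level high-minus-low difference averaged
    over the other factor.  Adjusted p multiplies the raw p by the family
    size (the number of DVs tested), capped at 1.  Cohen's d is the mean
    difference divided by the SD of the paired differences; zero-variance
    differences yield d = NaN with ``degenerate = True``.
    """
    if effect not in ("risk", "reward"):
        raise ValueError("effect must be 'risk' or 'reward'")
    wide, _ = _pivot_complete(table, dvs)
    family = len(dvs)
    rows = []
    for dv in dvs:
        diff = _contrast_scores(wide, dv, effect)
        mean_diff = float(diff.mean())
        sd_diff = float(diff.std(ddof=1))
        degenerate = sd_diff == 0.0
        if degenerate:
            t, p_raw, d = np.nan, np.nan, np.nan
        else:
            t, p_raw = sps.ttest_1samp(diff, 0.0)
            d = mean_diff / sd_diff
        rows.append(
            {
                "dv": dv,
                "effect": effect,
                "mean_difference": mean_diff,
                "sd_difference": sd_diff,
                "t": float(t) if np.isfinite(t) else np.nan,
                "p_raw": float(p_raw) if not degenerate else np.nan,
                "p_bonferroni": min(float(p_raw) * family, 1.0) if not degenerate else np.nan,
                "cohens_d": float(d) if not degenerate else np.nan,
                "n": len(diff),
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)
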