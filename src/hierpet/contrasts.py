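"""Group-level inference utilities.

Contrast extraction from hierarchical fits, the raphe-vs-projection
comparison, the univariate linear mixed-effects comparator, plasma-free-
fraction drift analysis, prior-mass calculations for the skeptical
group-difference prior, per-subgroup correlation-matrix comparison, and
the sample-size / probability-of-superiority utilities.

Percent differences are always reported as ``100 (exp(beta) - 1)`` of the
log-scale contrast, never as arithmetic differences of means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import HierFit, InferenceSettings, fit_hierarchical
from .simba import HierarchicalModelSpec, build_simba_model

__all__ = [
    "GroupContrast",
    "EffectSizeReport",
    "group_contrasts",
    "rn_vs_projection",
    "fit_univariate_lme",
    "fp_drift_analysis",
    "prior_mass",
    "power_n_per_group",
    "prob_superiority",
    "subgroup_correlations",
]

_DEFAULT_COMPARISONS = ("NRM-HV", "AE-HV", "NRM-AE")


@dataclass
class GroupContrast:
    """One regional group contrast on the percent scale."""

    region: str
    comparison: str
    percent: float          # 100 (exp(beta) - 1) at the point estimate
    lo80: float
    hi80: float
    lo95: float
    hi95: float
    p_positive: float       # P[beta > 0]

    def __post_init__(self):
        if not (self.lo95 <= self.lo80 <= self.hi80 <= self.hi95):
            raise ValueError("80% interval must nest inside the 95% interval")


@dataclass
class EffectSizeReport:
    """Effect size with the sample size needed to detect it."""

    cohens_d: float
    d_lo95: float
    d_hi95: float
    n_per_group: int
    power: float
    alpha: float
    prob_superiority: float


def _pct(b):
    return 100.0 * np.expm1(b)


def _summarize_beta_draws(draws: np.ndarray, region, comparison) -> GroupContrast:
    q = np.percentile(draws, [2.5, 10, 90, 97.5])
    return GroupContrast(
        region=region, comparison=comparison,
        percent=float(_pct(np.mean(draws))),
        lo80=float(_pct(q[1])), hi80=float(_pct(q[2])),
        lo95=float(_pct(q[0])), hi95=float(_pct(q[3])),
        p_positive=float(np.mean(draws > 0)))


def _beta_draws_for(gamma: pd.DataFrame, comparison: str, region: str):
    a, b = comparison.split("-")
    def col(g):
        if g == "HV":
            return np.zeros(len(gamma))
        name = f"{g}:{region}"
        if name not in gamma.columns:
            raise KeyError(f"fit lacks coefficient {name}")
        return gamma[name].to_numpy()
    return col(a) - col(b)


def group_contrasts(fit: HierFit,
                    comparisons: Sequence[str] = _DEFAULT_COMPARISONS,
                    regions: Optional[Sequence[str]] = None
                    ) -> List[GroupContrast]:
    """Regional group contrasts on BP from a hierarchical fit's draws."""
    gamma = fit.gamma_draws()
    regions = list(regions) if regions is not None else fit.model.region_names
    out = []
    for comparison in comparisons:
        for region in regions:
            draws = _beta_draws_for(gamma, comparison, region)
            out.append(_summarize_beta_draws(draws, region, comparison))
    return out


def contrasts_to_frame(contrasts: List[GroupContrast]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in contrasts])


def rn_vs_projection(study, outcome: str = "bpnd",
                     settings: Optional[InferenceSettings] = None,
                     fit: Optional[HierFit] = None,
                     comparison: str = "NRM-HV") -> dict:
    """Raphe effect versus mean projection-region effect.

    Refits the hierarchical model with fixed effects for the overall group
    difference in the raphe and in the serotonin projection regions, with
    random slopes allowing regional variation around the projection mean.
    Reports P[beta_RN - beta_proj > 0], both contrasts, and the posterior
    summary of the projection random-slope SD.
    """
    if fit is None:
        spec = HierarchicalModelSpec(outcome=outcome,
                                     contrast_mode="rn_projection")
        model = build_simba_model(study, spec)
        fit = fit_hierarchical(model, settings)
    gamma = fit.gamma_draws()
    g = comparison.split("-")[0]
    if f"{g}:RN" not in gamma.columns:
        raise KeyError(f"model has no raphe coefficient for group {g}")
    b_rn = gamma[f"{g}:RN"].to_numpy()
    b_proj = gamma[f"{g}:PROJ"].to_numpy()
    ref = comparison.split("-")[1]
    if ref != "HV":
        b_rn = b_rn - gamma[f"{ref}:RN"].to_numpy()
        b_proj = b_proj - gamma[f"{ref}:PROJ"].to_numpy()
    slope_sd = fit.slope_sd_draws()
    return {
        "comparison": comparison,
        "p_rn_gt_proj": float(np.mean(b_rn - b_proj > 0)),
        "rn": _summarize_beta_draws(b_rn, "RN", comparison),
        "projection_mean": _summarize_beta_draws(b_proj, "PROJ", comparison),
        "slope_sd_mean": float(np.mean(slope_sd)),
        "slope_sd_hi95": float(np.percentile(slope_sd, 97.5)),
        "fit": fit,
    }


# ---------------------------------------------------------------------------
# univariate LME comparator
# ---------------------------------------------------------------------------

def fit_univariate_lme(logbp: pd.DataFrame,
                       comparisons: Sequence[str] = _DEFAULT_COMPARISONS,
                       reference_group: str = "HV") -> dict:
    """Linear mixed model on one log BP value per subject x region.

    Fixed effects: region + sex + age + group:region (no overall group
    term), random intercept per subject; Wald normal intervals.  Input
    columns: subject_id, region, group, age, sex, value.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    df = logbp.copy()
    regions = sorted(df["region"].unique())
    groups = [g for g in df["group"].unique() if g != reference_group]
    age_c = (df["age"] - df["age"].mean()) / 10.0
    sexn = (df["sex"] == "M").astype(float)
    cols = {"const": np.ones(len(df)), "age": age_c, "sex": sexn}
    for r in regions[1:]:
        cols[f"region[{r}]"] = (df["region"] == r).astype(float)
    for g in sorted(groups):
        for r in regions:
            cols[f"{g}:{r}"] = ((df["group"] == g) &
                                (df["region"] == r)).astype(float)
    X = pd.DataFrame(cols, index=df.index)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = MixedLM(df["value"].to_numpy(), X.to_numpy(),
                      groups=df["subject_id"].to_numpy()).fit(reml=True)
    params = pd.Series(res.fe_params, index=X.columns)
    bse = pd.Series(res.bse_fe, index=X.columns)
    k = len(X.columns)
    cov = pd.DataFrame(np.asarray(res.cov_params())[:k, :k],
                       index=X.columns, columns=X.columns)

    def wald(comparison, region):
        a, b = comparison.split("-")
        if a == reference_group or b == reference_group:
            g = a if b == reference_group else b
            sign = 1.0 if b == reference_group else -1.0
            est = sign * params[f"{g}:{region}"]
            se = bse[f"{g}:{region}"]
        else:
            ca, cb = f"{a}:{region}", f"{b}:{region}"
            est = params[ca] - params[cb]
            se = np.sqrt(cov.loc[ca, ca] + cov.loc[cb, cb]
                         - 2 * cov.loc[ca, cb])
        z80, z95 = stats.norm.ppf(0.9), stats.norm.ppf(0.975)
        return GroupContrast(
            region=region, comparison=comparison,
            percent=float(_pct(est)),
            lo80=float(_pct(est - z80 * se)), hi80=float(_pct(est + z80 * se)),
            lo95=float(_pct(est - z95 * se)), hi95=float(_pct(est + z95 * se)),
            p_positive=float(stats.norm.cdf(est / se)))

    contrasts = [wald(c, r) for c in comparisons for r in regions]
    return {"result": res, "contrasts": contrasts,
            "converged": bool(getattr(res, "converged", True))}


# ---------------------------------------------------------------------------
# fP drift analysis
# ---------------------------------------------------------------------------

def _bspline_basis(x, df):
    from scipy.interpolate import BSpline
    k = 3
    n_inner = df - k - 1
    xs = np.sort(x)
    qs = np.linspace(0, 1, n_inner + 2)[1:-1]
    inner = np.quantile(xs, qs) if n_inner > 0 else np.array([])
    lo, hi = xs[0] - 1e-9, xs[-1] + 1e-9
    t = np.r_[[lo] * (k + 1), inner, [hi] * (k + 1)]
    return BSpline.design_matrix(x, t, k).toarray()


def fp_drift_analysis(fp: np.ndarray, dates: np.ndarray, groups: np.ndarray,
                      df_smooth: int = 10) -> dict:
    """Group differences in log fP with and without a scan-date smooth.

    Fits a penalized cubic B-spline (basis size ``df_smooth``, second-
    difference penalty with the smoothing parameter chosen by generalized
    cross-validation) for experimental drift in log fP, and reports the
    group F-test both without and with the smooth term — the drift-versus-
    group confounding diagnostic.
    """
    fp = np.asarray(fp, float)
    dates = np.asarray(dates, float)
    groups = np.asarray(groups)
    if fp.size < 20:
        raise ValueError("need at least 20 observations")
    if np.ptp(dates) <= 0:
        raise ValueError("all dates identical; drift not estimable")
    y = np.log(fp)
    n = y.size
    glabels = sorted(set(groups))
    G = np.column_stack([np.ones(n)] +
                        [(groups == g).astype(float) for g in glabels[1:]])
    q_group = len(glabels) - 1

    # model without smooth: plain OLS F-test for group
    def ols_rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    rss_g, p_g = ols_rss(G)
    rss_0, p_0 = ols_rss(G[:, :1])
    f_plain = ((rss_0 - rss_g) / q_group) / (rss_g / (n - p_g))
    p_plain = float(stats.f.sf(f_plain, q_group, n - p_g))

    # penalized smooth of date
    x01 = (dates - dates.min()) / np.ptp(dates)
    B = _bspline_basis(x01, df_smooth)
    B = B - B.mean(axis=0, keepdims=True)   # centre: identifiable with const
    D = np.diff(np.eye(B.shape[1]), n=2, axis=0)
    P = D.T @ D

    def fit_pen(X_par, lam):
        X = np.hstack([X_par, B])
        q = X_par.shape[1]
        Pen = np.zeros((X.shape[1], X.shape[1]))
        Pen[q:, q:] = lam * P
        A = X.T @ X + Pen
        beta = np.linalg.solve(A, X.T @ y)
        H = X @ np.linalg.solve(A, X.T)
        edf = float(np.trace(H))
        r = y - X @ beta
        return float(r @ r), edf

    lams = np.logspace(-4, 4, 25)
    gcvs = []
    for lam in lams:
        rss, edf = fit_pen(G, lam)
        gcvs.append(n * rss / (n - edf) ** 2)
    lam = float(lams[int(np.argmin(gcvs))])
    rss_full, edf_full = fit_pen(G, lam)
    rss_red, edf_red = fit_pen(G[:, :1], lam)
    df_resid = n - edf_full
    f_smooth = ((rss_red - rss_full) / q_group) / (rss_full / df_resid)
    f_smooth = max(f_smooth, 0.0)
    p_smooth = float(stats.f.sf(f_smooth, q_group, df_resid))
    edf_smooth = edf_full - (q_group + 1)
    return {
        "f_group_plain": float(f_plain), "p_group_plain": p_plain,
        "f_group_with_smooth": float(f_smooth), "p_group_with_smooth": p_smooth,
        "smooth_edf": float(edf_smooth), "lambda": lam,
        "group_means_logfp": {g: float(y[groups == g].mean())
                              for g in glabels},
    }


# ---------------------------------------------------------------------------
# prior mass and power utilities
# ---------------------------------------------------------------------------

def prior_mass(sd: float, pct: float, sided: str = "two_sided_log") -> float:
    """Prior probability assigned to group differences of a given size.

    Under the skeptical Normal(0, sd) prior on the log-scale contrast,
    ``two_sided_log`` returns P(|beta| < log(1 + pct)) — the mass on
    percent differences smaller than ``pct`` in either direction —
    ``one_sided`` returns P(beta > log(1 + pct)), and ``half`` returns the
    one-direction share P(0 < beta < log(1 + pct)) (half the two-sided
    mass; both conventions appear in practice for small thresholds).
    """
    if sd <= 0 or pct <= 0:
        raise ValueError("sd and pct must be positive")
    z = np.log1p(pct) / sd
    if sided == "two_sided_log":
        return float(2 * stats.norm.cdf(z) - 1)
    if sided == "one_sided":
        return float(stats.norm.sf(z))
    if sided == "half":
        return float(stats.norm.cdf(z) - 0.5)
    raise ValueError(f"unknown sided {sided!r}")


def _t_power(n: int, d: float, alpha: float) -> float:
    df = 2 * n - 2
    if df < 1:
        return 0.0
    nc = d * np.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def power_n_per_group(d: float, power: float = 0.8,
                      alpha: float = 0.05) -> int:
    """Smallest n per group for a two-sided two-sample t-test.

    Uses the noncentral-t power function directly (noncentrality
    d sqrt(n/2), df 2n-2), increasing n until the target power is met.
    """
    if d <= 0:
        raise ValueError("effect size d must be positive")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    n = 2
    while _t_power(n, d, alpha) < power:
        n += 1
        if n > 10_000_000:
            raise RuntimeError("required n exceeds 1e7")
    return n


def prob_superiority(d: float) -> float:
    """P(random member of group A exceeds random member of B): Phi(d/sqrt 2)."""
    return float(stats.norm.cdf(d / np.sqrt(2.0)))


def effect_size_report(d: float, d_lo95: float, d_hi95: float,
                       power: float = 0.8,
                       alpha: float = 0.05) -> EffectSizeReport:
    return EffectSizeReport(
        cohens_d=d, d_lo95=d_lo95, d_hi95=d_hi95,
        n_per_group=power_n_per_group(d, power, alpha),
        power=power, alpha=alpha,
        prob_superiority=prob_superiority(d))


# ---------------------------------------------------------------------------
# subgroup correlation matrices
# ---------------------------------------------------------------------------

def subgroup_correlations(fits_by_group: Dict[str, HierFit]) -> dict:
    """Compare individual-level correlation matrices across subgroup fits.

    Input: independently fitted hierarchical models per subgroup.  Returns
    posterior-mean correlation matrices plus the maximum absolute
    elementwise difference and Frobenius distance across group pairs.
    """
    mats = {g: f.corr_matrix_draws().mean(axis=0)
            for g, f in fits_by_group.items()}
    names = sorted(mats)
    max_abs = 0.0
    frob = 0.0
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = mats[a] - mats[b]
            off = diff[~np.eye(diff.shape[0], dtype=bool)]
            max_abs = max(max_abs, float(np.max(np.abs(off))))
            frob = max(frob, float(np.linalg.norm(off)))
    return {"matrices": mats, "max_abs_diff": max_abs,
            "max_frobenius": frob}
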