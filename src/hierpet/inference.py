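"""Shared machinery for the hierarchical multivariate models.

Both the simultaneous TAC-level model (all time-activity curves fitted at
once, :mod:`hierpet.simba`) and the multivariate analysis of pre-estimated
kinetic parameters (:mod:`hierpet.pumba`) share the same multilevel
structure: each TAC's vector of log kinetic parameters is composed as

``theta[t] = mu + covariates + group-contrast design (BP only)
            + region deviation + individual deviation + TAC deviation``

with region and TAC deviations independent across parameters, and
individual deviations correlated across parameters through a full
correlation matrix (Cholesky-parameterized via tanh canonical partial
correlations).  Deviations are kept in the *centred* parameterization:
the mode of the joint posterior over deviations and their scales then
behaves like penalized maximum likelihood of the variance components,
which is what makes the posterior mode a usable point estimator (in the
non-centred form the joint mode degenerates toward inflated scales).
Scale parameters are log-transformed and their closed-form updates are
clipped away from the zero-variance funnel spike.

Inference is maximum a posteriori (L-BFGS-B with an exact chain-rule
gradient assembled from per-TAC likelihood derivatives) followed by a
Laplace (Gaussian curvature) approximation of the posterior from which
draws are taken.  Point summaries are posterior modes; intervals are
Laplace credible intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import minimize

__all__ = [
    "IndexMap",
    "PriorSpec",
    "InferenceSettings",
    "HierModel",
    "HierFit",
    "fit_hierarchical",
]

class IndexMap:
    """Maps named parameter blocks to slices of the flat vector."""

    def __init__(self):
        self.size = 0
        self._slices: Dict[str, slice] = {}
        self._shapes: Dict[str, tuple] = {}
        self.order: List[str] = []

    def add(self, name: str, shape) -> slice:
        shape = (shape,) if np.isscalar(shape) else tuple(shape)
        n = int(np.prod(shape))
        s = slice(self.size, self.size + n)
        self._slices[name] = s
        self._shapes[name] = shape
        self.order.append(name)
        self.size += n
        return s

    def slc(self, name: str) -> slice:
        return self._slices[name]

    def get(self, x: np.ndarray, name: str) -> np.ndarray:
        return x[self._slices[name]].reshape(self._shapes[name])

    def put(self, x: np.ndarray, name: str, value) -> None:
        x[self._slices[name]] = np.asarray(value).ravel()


@dataclass
class PriorSpec:
    """Prior settings for the hierarchical models.

    ``mu_centers`` default to pooled conventional-NLS estimates of the
    cohort (computed at model build time) with a wide SD; the group-contrast
    coefficients get the skeptical Normal(0, 0.2) prior on the log scale
    (about 64% prior mass on group differences below 20%).  Random-effect
    SDs have half-normal priors whose scales exclude implausibly large
    variation on the log scale.
    """

    mu_centers: Optional[np.ndarray] = None
    mu_sd: float = 0.5
    gamma_sd: float = 0.2
    beta_sd: float = 0.3
    sd_scale_region: Optional[np.ndarray] = None
    sd_scale_indiv: Optional[np.ndarray] = None
    sd_scale_tac: Optional[np.ndarray] = None
    corr_scale: float = 0.5
    slope_sd_scale: float = 0.1

    def resolved_scales(self, default: np.ndarray):
        out = []
        for v in (self.sd_scale_region, self.sd_scale_indiv, self.sd_scale_tac):
            out.append(np.asarray(v, float) if v is not None else default)
        return out


@dataclass
class InferenceSettings:
    """Optimizer and posterior-draw settings."""

    seed: int = 0
    maxiter: int = 3000
    outer_iters: int = 5
    draws: int = 500
    chains: int = 4
    compute_draws: bool = True
    fd_step: float = 1e-5
    hess_step: float = 1e-4


# ---------------------------------------------------------------------------
# correlation Cholesky via tanh canonical partial correlations
# ---------------------------------------------------------------------------

def corr_chol_from_unconstrained(y: np.ndarray, d: int) -> np.ndarray:
    """Lower-Cholesky factor of a correlation matrix from d(d-1)/2 reals."""
    z = np.tanh(y)
    L = np.zeros((d, d))
    L[0, 0] = 1.0
    k = 0
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            L[i, j] = z[k] * np.sqrt(rem)
            rem *= 1.0 - z[k] ** 2
            k += 1
        L[i, i] = np.sqrt(max(rem, 1e-12))
    return L


def n_corr_params(d: int) -> int:
    return d * (d - 1) // 2


def corr_unconstrained_from_matrix(C: np.ndarray) -> np.ndarray:
    """Inverse of :func:`corr_chol_from_unconstrained`."""
    d = C.shape[0]
    L = np.linalg.cholesky(C)
    y = []
    for i in range(1, d):
        rem = 1.0
        for j in range(i):
            z = float(np.clip(L[i, j] / np.sqrt(max(rem, 1e-12)),
                              -0.999, 0.999))
            y.append(np.arctanh(z))
            rem *= 1.0 - z ** 2
    return np.array(y)


def _sd_mode_update(a: float, n: int, scale: float,
                    lo: float = 1e-3, hi: float = 3.0) -> float:
    """Stationary point of the centred-MAP profile in one SD.

    Solves ``a/v - n - v/scale^2 + 1 = 0`` for ``v = sd^2`` where ``a`` is
    the sum of squared deviations over ``n`` elements and ``scale`` the
    half-normal prior scale.
    """
    s2 = scale * scale
    v = 0.5 * s2 * (-(n - 1.0) + np.sqrt((n - 1.0) ** 2 + 4.0 * a / s2))
    return float(np.clip(np.sqrt(max(v, 0.0)), lo, hi))


# ---------------------------------------------------------------------------
# model base
# ---------------------------------------------------------------------------

class HierModel:
    """Base class: multilevel design, priors, composition and gradients.

    Subclasses set the data (``predict`` / ``loglik_given_pred`` /
    error-parameter blocks) and the design arrays listed in ``_setup``.
    """

    # ---- to be provided by subclasses ------------------------------------
    param_names: Tuple[str, ...]
    bp_index: int

    def predict(self, theta):  # (T, P) -> prediction object
        raise NotImplementedError

    def loglik_given_pred(self, pred, ep):  # -> (T,) per-TAC loglik
        raise NotImplementedError

    def eparam_logprior(self, ep) -> float:
        raise NotImplementedError

    def eparam_grad(self, pred, ep, base_terms):
        """Gradient of sum(loglik)+logprior w.r.t. error params (analytic
        or cheap FD using the cached prediction)."""
        raise NotImplementedError

    def init_eparams(self) -> np.ndarray:
        raise NotImplementedError

    def eparam_fixed_indices(self):
        """Error-param coords updated in the outer (EB) step, not by L-BFGS."""
        return []

    def theta_curvature(self, theta, ep, h: float = 1e-2) -> np.ndarray:
        """Diagonal curvature of the negative log likelihood in theta.

        Second differences per composed parameter, used only to Jacobi-
        precondition the inner optimization."""
        base = self._per_tac_loglik(theta, ep)
        c = np.empty((self.T, self.P))
        for p in range(self.P):
            dt = np.zeros_like(theta)
            dt[:, p] = h
            lp = self._per_tac_loglik(theta + dt, ep)
            lm = self._per_tac_loglik(theta - dt, ep)
            c[:, p] = (2.0 * base - lp - lm) / h ** 2
        return np.clip(c, 1e-8, None)

    def eparam_curvature(self, ep) -> np.ndarray:
        """Rough diagonal curvature for error params (preconditioning)."""
        return np.ones(self.n_eparams)

    def eparam_outer_update(self, ep: np.ndarray) -> None:
        """Closed-form update of the fixed error-param coords (in place)."""

    # ---- shared construction ---------------------------------------------

    def _setup(self, subj_idx, region_idx, groups, age_c, sex,
               region_names, subject_ids, priors: PriorSpec,
               covariate_params: List[int],
               contrast_mode: str = "group_region",
               rn_region: str = "RN",
               reference_group: str = "HV",
               nonref_groups: Tuple[str, ...] = ("NRM", "AE")):
        P = len(self.param_names)
        self.P = P
        self.T = len(subj_idx)
        self.subj_idx = np.asarray(subj_idx, dtype=int)
        self.region_idx = np.asarray(region_idx, dtype=int)
        self.S = int(self.subj_idx.max()) + 1
        self.R = int(self.region_idx.max()) + 1
        self.region_names = list(region_names)
        self.subject_ids = list(subject_ids)
        self.groups = np.asarray(groups)
        self.priors = priors
        self.contrast_mode = contrast_mode
        age_c = np.asarray(age_c, float)
        sex = np.asarray(sex, float)

        # fixed covariates (age per decade, sex 0/1) on selected parameters
        self.beta_param = []
        self.beta_labels = []
        cols = []
        for p in covariate_params:
            for cname, cvals in (("age", age_c), ("sex", sex)):
                cols.append(cvals[self.subj_idx])
                self.beta_param.append(p)
                self.beta_labels.append(f"{cname}_{self.param_names[p]}")
        self.Xc = np.array(cols).T if cols else np.zeros((self.T, 0))
        self.beta_param = np.asarray(self.beta_param, dtype=int)

        # group-contrast design on the BP parameter
        grp_of_tac = self.groups[self.subj_idx]
        reg_of_tac = np.asarray(self.region_names)[self.region_idx]
        self.gamma_labels = []
        gcols = []
        self.Zs = None
        self.slope_labels = []
        if contrast_mode == "group_region":
            for g in nonref_groups:
                for r in self.region_names:
                    gcols.append(((grp_of_tac == g) & (reg_of_tac == r))
                                 .astype(float))
                    self.gamma_labels.append(f"{g}:{r}")
        elif contrast_mode == "rn_projection":
            proj = [r for r in self.region_names
                    if r not in (rn_region, "CGM", "CWM")]
            scols = []
            for g in nonref_groups:
                gcols.append(((grp_of_tac == g) & (reg_of_tac == rn_region))
                             .astype(float))
                self.gamma_labels.append(f"{g}:RN")
                gcols.append(((grp_of_tac == g) & np.isin(reg_of_tac, proj))
                             .astype(float))
                self.gamma_labels.append(f"{g}:PROJ")
                for r in proj:
                    scols.append(((grp_of_tac == g) & (reg_of_tac == r))
                                 .astype(float))
                    self.slope_labels.append(f"{g}:{r}")
            self.Zs = np.array(scols).T
        else:
            raise ValueError(f"unknown contrast_mode {contrast_mode!r}")
        self.Xg = (np.array(gcols).T if gcols
                   else np.zeros((self.T, 0)))

        default_scale = np.where(
            np.isin(self.param_names, ("k4", "vB", "k2prime")), 0.2, 0.3)
        (self.scale_region, self.scale_indiv,
         self.scale_tac) = priors.resolved_scales(default_scale)

        # flat-vector layout (centred deviations)
        idx = IndexMap()
        idx.add("mu", P)
        idx.add("beta", len(self.beta_labels))
        idx.add("gamma", len(self.gamma_labels))
        idx.add("ls_region", P)
        idx.add("u_region", (self.R, P))
        idx.add("ls_indiv", P)
        idx.add("corr", n_corr_params(P))
        idx.add("u_indiv", (self.S, P))
        if self.has_tac_level:
            idx.add("ls_tac", P)
            idx.add("u_tac", (self.T, P))
        if self.Zs is not None:
            idx.add("ls_slope", 1)
            idx.add("u_slope", self.Zs.shape[1])
        self.ep_slice = idx.add("eparams", self.n_eparams)
        self.idx = idx

    has_tac_level = True  # overridden by models whose residual is TAC level
    n_eparams = 0

    # ---- composition ------------------------------------------------------

    def compose(self, x):
        """theta (T, P) and a cache of intermediates for the gradient."""
        idx = self.idx
        mu = idx.get(x, "mu")
        beta = idx.get(x, "beta")
        gamma = idx.get(x, "gamma")
        u_reg = idx.get(x, "u_region")
        u_ind = idx.get(x, "u_indiv")
        theta = mu[None, :] + u_reg[self.region_idx] + u_ind[self.subj_idx]
        if beta.size:
            contrib = self.Xc * beta[None, :]
            for j, p in enumerate(self.beta_param):
                theta[:, p] += contrib[:, j]
        if gamma.size:
            theta[:, self.bp_index] += self.Xg @ gamma
        cache = dict(mu=mu, beta=beta, gamma=gamma, u_reg=u_reg, u_ind=u_ind,
                     sig_reg=np.exp(idx.get(x, "ls_region")),
                     sig_ind=np.exp(idx.get(x, "ls_indiv")),
                     L=corr_chol_from_unconstrained(idx.get(x, "corr"),
                                                    self.P))
        if self.has_tac_level:
            u_tac = idx.get(x, "u_tac")
            theta = theta + u_tac
            cache.update(u_tac=u_tac, sig_tac=np.exp(idx.get(x, "ls_tac")))
        if self.Zs is not None:
            u_sl = idx.get(x, "u_slope")
            theta[:, self.bp_index] += self.Zs @ u_sl
            cache.update(u_sl=u_sl,
                         sig_sl=float(np.exp(idx.get(x, "ls_slope")[0])))
        cache["eparams"] = idx.get(x, "eparams")
        return theta, cache

    # ---- priors ------------------------------------------------------------

    @staticmethod
    def _diag_level_logp(u, sig, scale):
        """Centred N(0, sig) deviations + half-normal(scale) prior on sig."""
        n = u.shape[0]
        ls = np.log(sig)
        quad = -0.5 * np.sum((u / sig[None, :]) ** 2)
        logdet = -n * np.sum(ls)
        hn = np.sum(-0.5 * (sig / scale) ** 2 + ls)
        return quad + logdet + hn

    def _indiv_solve(self, cache):
        """w_i = Sigma^{-1} u_i for the correlated individual level."""
        M = cache["sig_ind"][:, None] * cache["L"]  # Cholesky of Sigma
        U = cache["u_ind"]
        half = solve_triangular(M, U.T, lower=True)
        w = solve_triangular(M.T, half, lower=False).T
        return w, half, M

    def _logprior(self, x, cache) -> float:
        pr = self.priors
        lp = 0.0
        lp += -0.5 * np.sum(((cache["mu"] - pr.mu_centers) / pr.mu_sd) ** 2)
        lp += -0.5 * np.sum((cache["beta"] / pr.beta_sd) ** 2)
        lp += -0.5 * np.sum((cache["gamma"] / pr.gamma_sd) ** 2)
        lp += -0.5 * np.sum(self.idx.get(x, "corr") ** 2 / pr.corr_scale ** 2)
        lp += self._diag_level_logp(cache["u_reg"], cache["sig_reg"],
                                    self.scale_region)
        # correlated individual level
        _, half, M = self._indiv_solve(cache)
        lp += (-0.5 * np.sum(half ** 2)
               - self.S * np.sum(np.log(np.diag(M))))
        sig = cache["sig_ind"]
        lp += np.sum(-0.5 * (sig / self.scale_indiv) ** 2 + np.log(sig))
        if self.has_tac_level:
            lp += self._diag_level_logp(cache["u_tac"], cache["sig_tac"],
                                        self.scale_tac)
        if self.Zs is not None:
            u, s = cache["u_sl"], cache["sig_sl"]
            lp += (-0.5 * np.sum((u / s) ** 2) - u.size * np.log(s)
                   - 0.5 * (s / pr.slope_sd_scale) ** 2 + np.log(s))
        lp += self.eparam_logprior(cache["eparams"])
        return lp

    def logpost(self, x) -> float:
        theta, cache = self.compose(x)
        pred = self.predict(theta)
        ll = float(np.sum(self.loglik_given_pred(pred, cache["eparams"])))
        return ll + self._logprior(x, cache)

    def _per_tac_loglik(self, theta, ep):
        return self.loglik_given_pred(self.predict(theta), ep)

    # ---- gradient ----------------------------------------------------------

    def grad(self, x, fd_step: float = 1e-5) -> np.ndarray:
        """Exact chain-rule gradient; per-TAC likelihood sensitivities to
        the P composed parameters come from central differences (the
        composition is linear in all deviation blocks)."""
        idx = self.idx
        theta, cache = self.compose(x)
        ep = cache["eparams"]
        pred = self.predict(theta)
        base_terms = self.loglik_given_pred(pred, ep)

        g = np.empty((self.T, self.P))
        for p in range(self.P):
            dt = np.zeros_like(theta)
            dt[:, p] = fd_step
            lp = self._per_tac_loglik(theta + dt, ep)
            lm = self._per_tac_loglik(theta - dt, ep)
            g[:, p] = (lp - lm) / (2.0 * fd_step)

        out = np.zeros_like(x)
        pr = self.priors
        out[idx.slc("mu")] = (g.sum(axis=0)
                              - (cache["mu"] - pr.mu_centers) / pr.mu_sd ** 2)
        if cache["beta"].size:
            gb = np.array([np.sum(self.Xc[:, j] * g[:, p])
                           for j, p in enumerate(self.beta_param)])
            out[idx.slc("beta")] = gb - cache["beta"] / pr.beta_sd ** 2
        if cache["gamma"].size:
            out[idx.slc("gamma")] = (self.Xg.T @ g[:, self.bp_index]
                                     - cache["gamma"] / pr.gamma_sd ** 2)
        # region level (diagonal)
        G_reg = np.zeros((self.R, self.P))
        np.add.at(G_reg, self.region_idx, g)
        u, sig = cache["u_reg"], cache["sig_reg"]
        out[idx.slc("u_region")] = (G_reg - u / sig[None, :] ** 2).ravel()
        out[idx.slc("ls_region")] = (np.sum((u / sig[None, :]) ** 2, axis=0)
                                     - self.R
                                     - (sig / self.scale_region) ** 2 + 1.0)
        # individual level (correlated)
        G_ind = np.zeros((self.S, self.P))
        np.add.at(G_ind, self.subj_idx, g)
        w, _, _ = self._indiv_solve(cache)
        out[idx.slc("u_indiv")] = (G_ind - w).ravel()
        sig = cache["sig_ind"]
        out[idx.slc("ls_indiv")] = (np.sum(w * cache["u_ind"], axis=0)
                                    - self.S
                                    - (sig / self.scale_indiv) ** 2 + 1.0)
        # correlation parameters: cheap FD through the prior term only
        ycorr = idx.get(x, "corr")
        gcorr = np.empty_like(ycorr)
        hc = 1e-6
        U = cache["u_ind"]
        for c in range(ycorr.size):
            vals = []
            for sgn in (+1, -1):
                yp = ycorr.copy()
                yp[c] += sgn * hc
                Lc = corr_chol_from_unconstrained(yp, self.P)
                Mc = sig[:, None] * Lc
                halfc = solve_triangular(Mc, U.T, lower=True)
                vals.append(-0.5 * np.sum(halfc ** 2)
                            - self.S * np.sum(np.log(np.diag(Mc))))
            gcorr[c] = (vals[0] - vals[1]) / (2 * hc)
        out[idx.slc("corr")] = gcorr - ycorr / pr.corr_scale ** 2
        # TAC level
        if self.has_tac_level:
            u, sig = cache["u_tac"], cache["sig_tac"]
            out[idx.slc("u_tac")] = (g - u / sig[None, :] ** 2).ravel()
            out[idx.slc("ls_tac")] = (np.sum((u / sig[None, :]) ** 2, axis=0)
                                      - self.T
                                      - (sig / self.scale_tac) ** 2 + 1.0)
        if self.Zs is not None:
            u, s = cache["u_sl"], cache["sig_sl"]
            gz = self.Zs.T @ g[:, self.bp_index]
            out[idx.slc("u_slope")] = gz - u / s ** 2
            out[idx.slc("ls_slope")] = (np.sum((u / s) ** 2) - u.size
                                        - (s / pr.slope_sd_scale) ** 2 + 1.0)
        out[self.ep_slice] = self.eparam_grad(pred, ep, base_terms)
        return out

    # ---- starting point and bounds -----------------------------------------

    def initial_point(self) -> np.ndarray:
        x0 = np.zeros(self.idx.size)
        self.idx.put(x0, "mu", self.priors.mu_centers)
        self.idx.put(x0, "ls_region", np.log(self.scale_region / 2.0))
        self.idx.put(x0, "ls_indiv", np.log(self.scale_indiv / 2.0))
        if self.has_tac_level:
            self.idx.put(x0, "ls_tac", np.log(self.scale_tac / 3.0))
        if self.Zs is not None:
            self.idx.put(x0, "ls_slope",
                         np.log(self.priors.slope_sd_scale / 2))
        self.idx.put(x0, "eparams", self.init_eparams())
        return x0

# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class HierFit:
    """MAP estimate with Laplace-approximation posterior draws."""

    model: HierModel
    x_map: np.ndarray
    logpost: float
    draws: Optional[np.ndarray]   # (n_draws, dim) or None
    diagnostics: dict

    # -- block access --------------------------------------------------------

    def _stack(self, name):
        """Draw stack for a block (falls back to the MAP point)."""
        xs = self.draws if self.draws is not None else self.x_map[None, :]
        return xs[:, self.model.idx.slc(name)]

    def map_block(self, name):
        return self.model.idx.get(self.x_map, name)

    def gamma_draws(self) -> pd.DataFrame:
        return pd.DataFrame(self._stack("gamma"),
                            columns=self.model.gamma_labels)

    def tau_draws(self, parameter: str) -> np.ndarray:
        """(n_draws, S) individual-level deviations of one parameter."""
        m = self.model
        p = m.param_names.index(parameter)
        return self._stack("u_indiv").reshape(-1, m.S, m.P)[:, :, p]

    def upsilon_draws(self, parameter: str) -> np.ndarray:
        """(n_draws, R) region-level deviations of one parameter."""
        m = self.model
        p = m.param_names.index(parameter)
        return self._stack("u_region").reshape(-1, m.R, m.P)[:, :, p]

    def corr_matrix_draws(self) -> np.ndarray:
        """(n_draws, P, P) individual-level correlation matrices."""
        m = self.model
        ys = self._stack("corr")
        out = np.empty((ys.shape[0], m.P, m.P))
        for i, y in enumerate(ys):
            L = corr_chol_from_unconstrained(y, m.P)
            out[i] = L @ L.T
        return out

    def slope_sd_draws(self) -> np.ndarray:
        return np.exp(self._stack("ls_slope")[:, 0])

    # -- persistence ---------------------------------------------------------

    def named_draws(self) -> pd.DataFrame:
        """Interpretable posterior draws, long format.

        Columns: draw, chain, parameter, value.  Covers the group
        contrasts, covariate effects, global intercepts, random-effect SDs
        and individual-level correlations.
        """
        m = self.model
        cols = {}
        for j, name in enumerate(m.gamma_labels):
            cols[f"gamma[{name}]"] = self._stack("gamma")[:, j]
        for j, name in enumerate(m.beta_labels):
            cols[f"beta[{name}]"] = self._stack("beta")[:, j]
        for j, name in enumerate(m.param_names):
            cols[f"mu[{name}]"] = self._stack("mu")[:, j]
            for lvl in ("region", "indiv") + (
                    ("tac",) if m.has_tac_level else ()):
                cols[f"sd_{lvl}[{name}]"] = np.exp(
                    self._stack(f"ls_{lvl}")[:, j])
        corr = self.corr_matrix_draws()
        for a in range(m.P):
            for b in range(a + 1, m.P):
                cols[f"corr_indiv[{m.param_names[a]},{m.param_names[b]}]"] = \
                    corr[:, a, b]
        n = len(next(iter(cols.values())))
        chains = int(self.diagnostics.get("chains", 1))
        per = max(n // max(chains, 1), 1)
        rows = []
        for pname, vals in cols.items():
            for i, v in enumerate(vals):
                rows.append((i % per, i // per, pname, float(v)))
        return pd.DataFrame(rows, columns=["draw", "chain", "parameter",
                                           "value"])

    def summary(self) -> dict:
        """Posterior summaries (mean, sd, 95% interval) per named scalar,
        plus split-half R-hat on the draws and the fit diagnostics."""
        tab = self.named_draws()
        out = {}
        for pname, grp in tab.groupby("parameter"):
            v = grp["value"].to_numpy()
            half = v.size // 2
            if half >= 2 and np.std(v) > 0:
                means = np.array([v[:half].mean(), v[half:].mean()])
                w = 0.5 * (v[:half].var(ddof=1) + v[half:].var(ddof=1))
                b = half * means.var(ddof=1)
                rhat = float(np.sqrt(((half - 1) / half * w + b / half)
                                     / max(w, 1e-300)))
            else:
                rhat = 1.0
            out[pname] = {
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "q2.5": float(np.percentile(v, 2.5)),
                "q97.5": float(np.percentile(v, 97.5)),
                "rhat": rhat,
            }
        return {"parameters": out, "diagnostics": self.diagnostics}

    def to_files(self, out_dir) -> None:
        """Persist draws as CSV (draw, chain, parameter, value) and the
        summary as JSON."""
        import json
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.named_draws().to_csv(out / "draws.csv", index=False)
        (out / "summary.json").write_text(
            json.dumps(self.summary(), indent=1, default=float))


def _fd_hessian(grad_fn, x, mask, step):
    cols = np.nonzero(mask)[0]
    n = cols.size
    H = np.empty((n, n))
    for k, j in enumerate(cols):
        xp = x.copy(); xp[j] += step
        xm = x.copy(); xm[j] -= step
        H[:, k] = ((grad_fn(xp) - grad_fn(xm)) / (2.0 * step))[cols]
    return 0.5 * (H + H.T)


def _free_mask(model: HierModel) -> np.ndarray:
    """Coords optimized by the inner L-BFGS (everything except the variance
    components, which get closed-form outer updates)."""
    mask = np.ones(model.idx.size, dtype=bool)
    for name in model.idx.order:
        if name.startswith("ls_") or name == "corr":
            mask[model.idx.slc(name)] = False
    s = model.ep_slice
    for j in model.eparam_fixed_indices():
        mask[s.start + j] = False
    return mask


def _coord_scales(model: HierModel, x: np.ndarray) -> np.ndarray:
    """Jacobi preconditioner: 1/sqrt(likelihood + prior curvature) per coord.

    The likelihood part is the per-TAC diagonal curvature in the composed
    parameters, accumulated through the (linear) design onto each block."""
    idx = model.idx
    pr = model.priors
    theta, cache = model.compose(x)
    c = model.theta_curvature(theta, cache["eparams"])  # (T, P)
    s = np.ones(idx.size)

    def inv_sqrt(curv):
        return 1.0 / np.sqrt(np.clip(curv, 1e-8, None))

    s[idx.slc("mu")] = inv_sqrt(c.sum(axis=0) + 1.0 / pr.mu_sd ** 2)
    if len(model.beta_labels):
        bc = np.array([np.sum(model.Xc[:, j] ** 2 * c[:, p])
                       for j, p in enumerate(model.beta_param)])
        s[idx.slc("beta")] = inv_sqrt(bc + 1.0 / pr.beta_sd ** 2)
    if len(model.gamma_labels):
        gc = model.Xg.T @ c[:, model.bp_index]
        s[idx.slc("gamma")] = inv_sqrt(gc + 1.0 / pr.gamma_sd ** 2)
    sig_reg = np.exp(idx.get(x, "ls_region"))
    C_reg = np.zeros((model.R, model.P))
    np.add.at(C_reg, model.region_idx, c)
    s[idx.slc("u_region")] = inv_sqrt(
        C_reg + 1.0 / sig_reg[None, :] ** 2).ravel()
    sig_ind = np.exp(idx.get(x, "ls_indiv"))
    C_ind = np.zeros((model.S, model.P))
    np.add.at(C_ind, model.subj_idx, c)
    s[idx.slc("u_indiv")] = inv_sqrt(
        C_ind + 1.0 / sig_ind[None, :] ** 2).ravel()
    if model.has_tac_level:
        sig_tac = np.exp(idx.get(x, "ls_tac"))
        s[idx.slc("u_tac")] = inv_sqrt(
            c + 1.0 / sig_tac[None, :] ** 2).ravel()
    if model.Zs is not None:
        sc = model.Zs.T @ c[:, model.bp_index]
        sig_sl = np.exp(idx.get(x, "ls_slope")[0])
        s[idx.slc("u_slope")] = inv_sqrt(sc + 1.0 / sig_sl ** 2)
    s[model.ep_slice] = inv_sqrt(model.eparam_curvature(
        idx.get(x, "eparams")))
    return s


def _outer_update(model: HierModel, x: np.ndarray) -> None:
    """Closed-form update of SDs and the individual-level correlation."""
    idx = model.idx

    def upd_diag(u_name, ls_name, scales, n):
        u = idx.get(x, u_name)
        sds = [_sd_mode_update(float(np.sum(u[:, p] ** 2)), n, scales[p])
               for p in range(model.P)]
        idx.put(x, ls_name, np.log(sds))

    upd_diag("u_region", "ls_region", model.scale_region, model.R)
    upd_diag("u_indiv", "ls_indiv", model.scale_indiv, model.S)
    if model.has_tac_level:
        upd_diag("u_tac", "ls_tac", model.scale_tac, model.T)
    if model.Zs is not None:
        u = idx.get(x, "u_slope")
        sd = _sd_mode_update(float(np.sum(u ** 2)), u.size,
                             model.priors.slope_sd_scale)
        idx.put(x, "ls_slope", [np.log(sd)])
    # moderated sample correlation of the individual deviations
    U = idx.get(x, "u_indiv")
    sig = np.exp(idx.get(x, "ls_indiv"))
    Z = U / np.maximum(sig[None, :], 1e-8)
    kappa = 4.0  # pseudo-observations pulling toward independence
    C = (Z.T @ Z + kappa * np.eye(model.P)) / (model.S + kappa)
    d = np.sqrt(np.clip(np.diag(C), 1e-12, None))
    C = C / d[None, :] / d[:, None]
    idx.put(x, "corr", corr_unconstrained_from_matrix(C))
    ep = idx.get(x, "eparams").copy()
    model.eparam_outer_update(ep)
    idx.put(x, "eparams", ep)


def fit_hierarchical(model: HierModel,
                     settings: Optional[InferenceSettings] = None) -> HierFit:
    """MAP fit by expectation-conditional-maximization, then Laplace draws.

    Inner step: L-BFGS over global effects, contrasts and (preconditioned)
    deviations with the variance components held fixed.  Outer step:
    closed-form posterior-mode updates of the random-effect SDs and a
    moderated update of the individual-level correlation matrix.  Posterior
    draws come from the Laplace (curvature) approximation around the final
    point with the variance components held at their estimates, as in
    classical empirical-Bayes / REML-Wald practice.
    """
    settings = settings or InferenceSettings()
    x = model.initial_point()
    mask = _free_mask(model)
    n_outer = max(settings.outer_iters, 1)
    total_iter = 0
    last = None
    for outer in range(n_outer):
        scales = _coord_scales(model, x)
        sm = scales[mask]
        x_fixed = x.copy()

        def fun(y):
            xf = x_fixed.copy()
            xf[mask] = y * sm
            return -model.logpost(xf)

        def jac(y):
            xf = x_fixed.copy()
            xf[mask] = y * sm
            return -(model.grad(xf, settings.fd_step) * scales)[mask]

        inner_iter = settings.maxiter if outer == 0 else settings.maxiter // 2
        res = minimize(fun, x[mask] / sm, jac=jac, method="L-BFGS-B",
                       options=dict(maxiter=inner_iter, maxcor=30,
                                    ftol=1e-11, gtol=1e-6))
        x[mask] = res.x * sm
        total_iter += int(res.nit)
        lp = float(-res.fun)
        _outer_update(model, x)
        if last is not None and abs(lp - last) < 1e-6 * max(1.0, abs(lp)):
            last = lp
            break
        last = lp
    lp_final = float(model.logpost(x))
    gfinal = model.grad(x, settings.fd_step) * _coord_scales(model, x)
    diagnostics = dict(method="map_laplace_ecm",
                       opt_converged=bool(res.success),
                       opt_message=str(res.message),
                       n_iter=total_iter, n_outer=outer + 1,
                       chains=settings.chains,
                       draws_per_chain=settings.draws,
                       grad_norm=float(np.max(np.abs(gfinal[mask]))))
    draws = None
    if settings.compute_draws:
        H = _fd_hessian(lambda xx: -model.grad(xx, settings.fd_step),
                        x, mask, settings.hess_step)
        evals, evecs = np.linalg.eigh(H)
        floor = max(evals.max(), 1.0) * 1e-10
        n_clipped = int(np.sum(evals < floor))
        evals = np.clip(evals, floor, None)
        diagnostics.update(hessian_min_eig=float(evals.min()),
                           hessian_clipped=n_clipped)
        rng = np.random.default_rng(settings.seed)
        zdr = rng.standard_normal((settings.draws * settings.chains,
                                   int(mask.sum())))
        draws = np.tile(x, (zdr.shape[0], 1))
        draws[:, mask] += (zdr / np.sqrt(evals)[None, :]) @ evecs.T
    if not res.success and res.nit >= settings.maxiter:
        warnings.warn("MAP optimizer hit maxiter without convergence",
                      stacklevel=2)
    return HierFit(model=model, x_map=x, logpost=lp_final,
                   draws=draws, diagnostics=diagnostics)
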