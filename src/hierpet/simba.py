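"""Simultaneous hierarchical multivariate quantification of all TACs.

Every time-activity curve in the study is fitted at once under the 2TCM:
the five log kinetic parameters of each TAC (log K1, log V_ND, log BP,
log k4, log vB, with BP one of BP_ND / BP_P / BP_F depending on the
outcome parameterization) are decomposed into a global intercept, fixed
age/sex effects (on K1, V_ND and BP), a skeptical group-by-region contrast
on BP only (Normal(0, 0.2) prior on the log scale), and partially pooled
region, individual and TAC deviations.  Individual deviations are
correlated across all five parameters; this multivariate shrinkage is what
stabilises the directly estimated binding outcomes.

Measurement model: Student-t residuals (dof estimated, lower-bounded at 3)
whose per-frame scale is a per-TAC log-normal scale divided by the
conventional frame weights, mirroring the weighting used for NLS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from ._conv import conv_frame_integrals, curve_frame_integrals
from .inference import (
    HierFit,
    HierModel,
    InferenceSettings,
    PriorSpec,
    fit_hierarchical,
)
from .kinetic import build_model_grid, compute_weights
from .nls import fit_2tcm_nls

__all__ = [
    "HierarchicalModelSpec",
    "SimbaModel",
    "build_simba_model",
    "fit_simba",
    "extract_individual_effects",
    "region_vnd_deviations",
]

_PARAMS = ("K1", "VND", "BP", "k4", "vB")


@dataclass
class HierarchicalModelSpec:
    """Structure of the hierarchical model.

    ``outcome`` selects the binding parameterization; the BP fixed-effects
    formula is region + sex + age + group:region (no overall group term),
    with age and sex also fixed effects on log K1 and log V_ND.
    ``contrast_mode='rn_projection'`` replaces the per-region group
    coefficients by a raphe coefficient plus a mean projection-region
    coefficient with random projection slopes.
    """

    outcome: str = "bpnd"
    contrast_mode: str = "group_region"
    rn_region: str = "RN"
    reference_group: str = "HV"
    regions: Optional[Sequence[str]] = None

    def __post_init__(self):
        if self.outcome not in ("bpnd", "bpp", "bpf"):
            raise ValueError(f"unknown outcome {self.outcome!r}")


class SimbaModel(HierModel):
    """Joint hierarchical 2TCM likelihood over all TACs of a study."""

    param_names = _PARAMS
    bp_index = 2
    has_tac_level = True

    def __init__(self, study, spec: HierarchicalModelSpec,
                 priors: PriorSpec):
        self.spec = spec
        regions = list(spec.regions) if spec.regions is not None \
            else list(study.regions)
        parts = study.participants
        missing = [c for c in ("group", "age", "sex", "fP")
                   if parts[c].isna().any()]
        if missing:
            raise ValueError(f"missing metadata in columns {missing}")
        subject_ids = list(parts["subject_id"])
        s_of = {s: i for i, s in enumerate(subject_ids)}
        r_of = {r: j for j, r in enumerate(regions)}

        schedule = study.schedule
        self.schedule = schedule
        # common knot grid across all subjects' input curves
        all_t = np.unique(np.concatenate(
            [study.aifs[s].times for s in subject_ids]))
        knots, seg_frame = build_model_grid(schedule, all_t)
        self.knots, self.seg_frame = knots, seg_frame
        scale_fp = spec.outcome == "bpf"
        u_rows, wp_int = [], []
        for s in subject_ids:
            aif = study.aifs[s]
            cp = aif.cp_parent(knots)
            if scale_fp:
                cp = cp * aif.fP
            u_rows.append(cp)
            wp_int.append(curve_frame_integrals(
                knots, aif.c_wholeplasma(knots)[None, :], seg_frame,
                schedule.n_frames)[0])
        self.u_all = np.array(u_rows)
        self.wp_int = np.array(wp_int)

        y, W, A, subj_idx, region_idx = [], [], [], [], []
        for s in subject_ids:
            for r in regions:
                if r not in study.tacs[s]:
                    raise ValueError(f"subject {s} lacks region {r}")
                tac = study.tacs[s][r]
                if tac.schedule.n_frames != schedule.n_frames:
                    raise ValueError("mismatched frame schedules")
                y.append(tac.activity)
                # zero weights (non-positive noisy frames) would imply an
                # infinite residual scale; floor them at a small value
                W.append(np.maximum(compute_weights(schedule, tac), 0.05))
                A.append(max(np.mean(np.abs(tac.activity)), 1e-9))
                subj_idx.append(s_of[s])
                region_idx.append(r_of[r])
        self.y = np.array(y)
        self.W = np.array(W)
        self.A = np.array(A)
        self.n_eparams = 3 + self.y.shape[0]
        self._ls0_center = np.log(0.05)

        age_c = (parts["age"].to_numpy() - parts["age"].mean()) / 10.0
        sex = (parts["sex"].to_numpy() == "M").astype(float)
        self._setup(subj_idx, region_idx, parts["group"].to_numpy(),
                    age_c, sex, regions, subject_ids, priors,
                    covariate_params=[0, 1, 2],
                    contrast_mode=spec.contrast_mode,
                    rn_region=spec.rn_region,
                    reference_group=spec.reference_group)

    # ---- initialization ----------------------------------------------------

    def set_warm_start(self, theta_nls: np.ndarray):
        """Initialize the hierarchy from per-TAC NLS estimates.

        The global intercepts and the region/individual deviations start at
        robust aggregates of the NLS estimates; TAC-level deviations start
        at zero so residual noise is initially carried by the likelihood.
        """
        theta_nls = np.asarray(theta_nls, float)
        if theta_nls.shape != (self.T, self.P):
            raise ValueError("theta_nls must be (T, P)")
        self._warm = theta_nls

    _warm = None

    def initial_point(self):
        x0 = super().initial_point()
        if self._warm is None:
            return x0
        th = self._warm
        mu = np.median(th, axis=0)
        self.idx.put(x0, "mu", mu)
        resid = th - mu[None, :]
        u_reg = np.zeros((self.R, self.P))
        for r in range(self.R):
            rows = self.region_idx == r
            if rows.any():
                u_reg[r] = np.median(resid[rows], axis=0)
        self.idx.put(x0, "u_region", u_reg)
        resid = resid - u_reg[self.region_idx]
        u_ind = np.zeros((self.S, self.P))
        for s in range(self.S):
            rows = self.subj_idx == s
            if rows.any():
                u_ind[s] = np.clip(np.median(resid[rows], axis=0), -1.0, 1.0)
        self.idx.put(x0, "u_indiv", u_ind)
        return x0

    # ---- forward model ----------------------------------------------------

    def predict(self, theta):
        th = np.clip(theta, -30.0, 10.0)
        K1 = np.exp(th[:, 0])
        VND = np.exp(th[:, 1])
        BP = np.exp(th[:, 2])
        k4 = np.exp(th[:, 3])
        vB = np.minimum(np.exp(th[:, 4]), 0.95)
        k2 = K1 / VND
        k3 = BP * k4 if self.spec.outcome == "bpnd" else BP * k4 / VND
        s = k2 + k3 + k4
        r = np.sqrt(np.maximum(s * s - 4.0 * k2 * k4, 0.0))
        r = np.maximum(r, 1e-12 * np.maximum(s, 1e-30))
        a1, a2 = 0.5 * (s - r), 0.5 * (s + r)
        phi1 = K1 * (k3 + k4 - a1) / (a2 - a1)
        phi2 = K1 * (a2 - k3 - k4) / (a2 - a1)
        alphas = np.stack([a1, a2], axis=1)
        phis = np.stack([phi1, phi2], axis=1)
        tissue = conv_frame_integrals(self.knots, self.u_all, self.subj_idx,
                                      alphas, phis, self.seg_frame,
                                      self.schedule.n_frames)
        pred = ((1.0 - vB)[:, None] * tissue
                + vB[:, None] * self.wp_int[self.subj_idx])
        return pred / self.schedule.duration[None, :]

    # ---- measurement model -------------------------------------------------

    def _unpack_ep(self, ep):
        ls0, ls_delta = ep[0], ep[1]
        delta = ep[2:2 + self.T]
        eta_nu = ep[2 + self.T]
        return ls0, ls_delta, delta, eta_nu

    def loglik_given_pred(self, pred, ep):
        ls0, ls_delta, delta, eta_nu = self._unpack_ep(ep)
        scale = np.exp(np.clip(ls0 + delta, -30, 10)) * self.A
        sig = scale[:, None] / self.W
        nu = 3.0 + np.exp(eta_nu)
        r2 = ((self.y - pred) / sig) ** 2
        const = (gammaln((nu + 1) / 2) - gammaln(nu / 2)
                 - 0.5 * np.log(nu * np.pi))
        terms = const - np.log(sig) - 0.5 * (nu + 1) * np.log1p(r2 / nu)
        return terms.sum(axis=1)

    def eparam_logprior(self, ep):
        ls0, ls_delta, delta, eta_nu = self._unpack_ep(ep)
        sd_d = np.exp(ls_delta)
        return (-0.5 * ((ls0 - self._ls0_center) / 1.5) ** 2
                - 0.5 * np.sum((delta / sd_d) ** 2) - self.T * ls_delta
                - 0.5 * (sd_d / 0.5) ** 2 + ls_delta
                - 0.5 * (eta_nu - np.log(27.0)) ** 2)

    def eparam_grad(self, pred, ep, base_terms):
        ls0, ls_delta, delta, eta_nu = self._unpack_ep(ep)
        scale = np.exp(np.clip(ls0 + delta, -30, 10)) * self.A
        sig = scale[:, None] / self.W
        nu = 3.0 + np.exp(eta_nu)
        r2 = ((self.y - pred) / sig) ** 2
        u = r2 / nu
        dls = (-1.0 + (nu + 1.0) * u / (1.0 + u)).sum(axis=1)  # per TAC
        g = np.empty_like(ep)
        sd_d = np.exp(ls_delta)
        g[0] = dls.sum() - (ls0 - self._ls0_center) / 1.5 ** 2
        g[1] = (np.sum((delta / sd_d) ** 2) - self.T
                - (sd_d / 0.5) ** 2 + 1.0)
        g[2:2 + self.T] = dls - delta / sd_d ** 2
        h = 1e-5
        ep_p = ep.copy(); ep_p[-1] += h
        ep_m = ep.copy(); ep_m[-1] -= h
        g[-1] = ((np.sum(self.loglik_given_pred(pred, ep_p))
                  - np.sum(self.loglik_given_pred(pred, ep_m))) / (2 * h)
                 - (eta_nu - np.log(27.0)))
        return g

    def init_eparams(self):
        ep = np.zeros(self.n_eparams)
        ep[0] = self._ls0_center
        ep[1] = np.log(0.3)
        ep[-1] = np.log(27.0)
        return ep

    def eparam_fixed_indices(self):
        return [1]  # the delta-scale gets the closed-form outer update

    def eparam_curvature(self, ep):
        F = self.y.shape[1]
        sd_d = np.exp(ep[1])
        c = np.ones(self.n_eparams)
        c[0] = 2.0 * F * self.T                     # global log-scale
        c[2:2 + self.T] = 2.0 * F + 1.0 / sd_d ** 2  # per-TAC log-scales
        c[-1] = max(0.02 * self.T * F, 1.0)          # dof (weakly informed)
        return c

    def eparam_outer_update(self, ep):
        from .inference import _sd_mode_update
        delta = ep[2:2 + self.T]
        ep[1] = np.log(_sd_mode_update(float(np.sum(delta ** 2)), self.T,
                                       0.5, lo=1e-2, hi=2.0))


# ---------------------------------------------------------------------------
# build / fit / extract
# ---------------------------------------------------------------------------

def _auto_mu_centers(study, spec, max_tacs: int = 6) -> np.ndarray:
    """Pooled conventional-NLS estimates used as global intercept priors."""
    subs = study.subject_ids
    pick_subjects = subs[:: max(1, len(subs) // 3)][:3]
    regions = [r for r in study.regions if r not in ("CGM", "CWM")]
    pick_regions = [regions[0]]
    if spec.rn_region in regions and spec.rn_region != regions[0]:
        pick_regions.append(spec.rn_region)
    ests = []
    for s in pick_subjects:
        for r in pick_regions:
            if len(ests) >= max_tacs:
                break
            res = fit_2tcm_nls(study.tacs[s][r], study.aifs[s],
                               variant=spec.outcome, n_starts=2, seed=0)
            if np.all(np.isfinite(res.estimates_log)):
                ests.append(res.estimates_log)
    if not ests:
        return np.log(np.array([0.1, 0.35, 3.0, 0.03, 0.05]))
    return np.median(np.array(ests), axis=0)


def build_simba_model(study, spec: Optional[HierarchicalModelSpec] = None,
                      priors: Optional[PriorSpec] = None) -> SimbaModel:
    """Assemble the joint model for a study (computing data-driven global
    intercept priors from pooled NLS fits unless supplied)."""
    spec = spec or HierarchicalModelSpec()
    priors = priors or PriorSpec()
    if priors.mu_centers is None:
        priors.mu_centers = _auto_mu_centers(study, spec)
    return SimbaModel(study, spec, priors)


def fit_simba(model: SimbaModel,
              settings: Optional[InferenceSettings] = None) -> HierFit:
    """Fit the joint model (MAP + Laplace draws per the settings)."""
    return fit_hierarchical(model, settings)


def extract_individual_effects(fit: HierFit,
                               parameter: str = "BP") -> pd.DataFrame:
    """Partially pooled individual-level deviations of one parameter.

    One row per subject with the posterior mean and SD of that subject's
    deviation after global, covariate and region effects are removed.
    """
    if parameter not in fit.model.param_names:
        raise KeyError(f"unknown parameter {parameter!r}; "
                       f"have {fit.model.param_names}")
    tau = fit.tau_draws(parameter)
    return pd.DataFrame({
        "subject_id": fit.model.subject_ids,
        "mean": tau.mean(axis=0),
        "sd": tau.std(axis=0, ddof=1) if tau.shape[0] > 1 else 0.0,
    })


def region_vnd_deviations(fit: HierFit) -> pd.DataFrame:
    """Regional V_ND deviations as percent from the regional mean.

    Deviations are centred across regions within each draw (so they sum to
    zero per draw) and reported as 100 (exp(u) - 1) with 95% intervals.
    """
    ups = fit.upsilon_draws("VND")
    ups = ups - ups.mean(axis=1, keepdims=True)
    pct = 100.0 * np.expm1(ups)
    lo, hi = np.percentile(pct, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "region": fit.model.region_names,
        "pct_mean": pct.mean(axis=0),
        "pct_lo95": lo,
        "pct_hi95": hi,
    })
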