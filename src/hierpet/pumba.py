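"""Multivariate hierarchical analysis of pre-estimated kinetic parameters.

Instead of a TAC likelihood, each subject x region contributes its vector
of conventionally estimated (NLS) log kinetic parameters — for SRTM:
log R1, log k2prime, log BP_ND — treated as a multivariate response.  The
same multilevel decomposition as the simultaneous model applies (global
intercepts, age/sex on log k2prime and log BP, skeptical group-by-region
contrasts on BP, partially pooled region and correlated individual
deviations); the TAC-level deviation is the residual, modelled as
multivariate normal with a full 3x3 covariance estimated from the data.

Estimation uncertainty of the NLS inputs is not propagated: estimates are
treated as data, which is the standard trade-off of this two-stage
approach (see the methods note).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular

from .inference import (
    HierFit,
    HierModel,
    InferenceSettings,
    PriorSpec,
    corr_chol_from_unconstrained,
    fit_hierarchical,
)
from .simba import HierarchicalModelSpec

__all__ = ["PumbaModel", "build_pumba_model", "fit_pumba"]


class PumbaModel(HierModel):
    """Multivariate-normal response model for NLS parameter vectors."""

    bp_index = 2
    has_tac_level = False   # the residual covariance plays the TAC role

    def __init__(self, y, subj_idx, region_idx, groups, age, sex,
                 region_names, subject_ids, spec, priors: PriorSpec,
                 param_names=("R1", "k2prime", "BPND")):
        self.param_names = tuple(param_names)
        P = len(self.param_names)
        self.spec = spec
        self.y = np.asarray(y, dtype=float)
        if self.y.shape[1] != P or not np.all(np.isfinite(self.y)):
            raise ValueError("response must be complete (T, P) log estimates")
        self.n_eparams = P + P * (P - 1) // 2
        resid0 = self.y - np.median(self.y, axis=0)
        self._ls_res_center = np.log(np.maximum(
            1.4826 * np.median(np.abs(resid0), axis=0), 1e-3))
        age_c = (np.asarray(age, float) - np.mean(age)) / 10.0
        sexn = (np.asarray(sex) == "M").astype(float)
        # age+sex enter the efflux (k2prime) and BP regressions
        self._setup(subj_idx, region_idx, groups, age_c, sexn,
                    region_names, subject_ids, priors,
                    covariate_params=[1, 2],
                    contrast_mode=spec.contrast_mode,
                    rn_region=spec.rn_region,
                    reference_group=spec.reference_group)

    def predict(self, theta):
        return theta

    def _resid_chol(self, ep):
        P = self.P
        D = np.exp(np.clip(ep[:P], -12, 6))
        L = corr_chol_from_unconstrained(ep[P:], P)
        return D[:, None] * L  # Cholesky of the residual covariance

    def loglik_given_pred(self, pred, ep):
        M = self._resid_chol(ep)
        e = self.y - pred
        w = solve_triangular(M, e.T, lower=True)
        logdet = np.sum(np.log(np.diag(M)))
        return (-0.5 * (w ** 2).sum(axis=0) - logdet
                - 0.5 * self.P * np.log(2 * np.pi))

    def eparam_logprior(self, ep):
        P = self.P
        return (-0.5 * np.sum(((ep[:P] - self._ls_res_center) / 1.5) ** 2)
                - 0.5 * np.sum(ep[P:] ** 2 / 0.5 ** 2))

    def eparam_grad(self, pred, ep, base_terms):
        g = np.empty_like(ep)
        h = 1e-6
        for j in range(ep.size):
            epp = ep.copy(); epp[j] += h
            epm = ep.copy(); epm[j] -= h
            g[j] = (np.sum(self.loglik_given_pred(pred, epp))
                    - np.sum(self.loglik_given_pred(pred, epm))) / (2 * h)
        P = self.P
        g[:P] -= (ep[:P] - self._ls_res_center) / 1.5 ** 2
        g[P:] -= ep[P:] / 0.5 ** 2
        return g

    def init_eparams(self):
        return np.concatenate([self._ls_res_center,
                               np.zeros(self.n_eparams - self.P)])


def build_pumba_model(param_table: pd.DataFrame, metadata: pd.DataFrame,
                      spec: Optional[HierarchicalModelSpec] = None,
                      priors: Optional[PriorSpec] = None,
                      param_names: Sequence[str] = ("R1", "k2prime", "BPND"),
                      require_converged: bool = False) -> PumbaModel:
    """Build the model from a tidy NLS parameter table plus metadata.

    ``param_table`` is the long output of :func:`hierpet.nls.fit_cohort_nls`
    (columns subject_id, region, parameter, estimate_log, converged);
    ``metadata`` must carry subject_id, group, age, sex.
    """
    spec = spec or HierarchicalModelSpec()
    priors = priors or PriorSpec()
    tab = param_table
    if require_converged:
        tab = tab[tab["converged"]]
    wide = tab.pivot_table(index=["subject_id", "region"],
                           columns="parameter", values="estimate_log")
    missing = [p for p in param_names if p not in wide.columns]
    if missing:
        raise ValueError(f"parameter table lacks {missing}")
    wide = wide[list(param_names)].dropna().reset_index()
    meta = metadata.set_index("subject_id")
    unknown = set(wide["subject_id"]) - set(meta.index)
    if unknown:
        raise ValueError(f"metadata missing subjects: {sorted(unknown)}")
    subject_ids = sorted(wide["subject_id"].unique())
    region_names = (list(spec.regions) if spec.regions is not None
                    else sorted(wide["region"].unique()))
    wide = wide[wide["region"].isin(region_names)]
    s_of = {s: i for i, s in enumerate(subject_ids)}
    r_of = {r: j for j, r in enumerate(region_names)}
    y = wide[list(param_names)].to_numpy()
    subj_idx = wide["subject_id"].map(s_of).to_numpy()
    region_idx = wide["region"].map(r_of).to_numpy()
    groups = meta.loc[subject_ids, "group"].to_numpy()
    age = meta.loc[subject_ids, "age"].to_numpy()
    sex = meta.loc[subject_ids, "sex"].to_numpy()
    if priors.mu_centers is None:
        priors.mu_centers = np.median(y, axis=0)
    return PumbaModel(y, subj_idx, region_idx, groups, age, sex,
                      region_names, subject_ids, spec, priors,
                      param_names=tuple(param_names))


def fit_pumba(param_table: pd.DataFrame, metadata: pd.DataFrame,
              spec: Optional[HierarchicalModelSpec] = None,
              priors: Optional[PriorSpec] = None,
              settings: Optional[InferenceSettings] = None,
              **build_kwargs) -> HierFit:
    """Build and fit the multivariate parameter-level model."""
    model = build_pumba_model(param_table, metadata, spec, priors,
                              **build_kwargs)
    return fit_hierarchical(model, settings)
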