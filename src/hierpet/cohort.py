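"""Seeded generator of synthetic [11C]WAY100635-like PET studies.

Stands in for clinical data that cannot be shared: three participant groups
(healthy volunteers HV, not-recently-medicated patients NRM, and
antidepressant-exposed patients AE, default sizes 57/50/53), a 20-frame
110-minute schedule, region-specific group effects on log binding potential
that are largest in a raphe-like region (RN) with projection-region effects
half as large on the log scale, plasma-free-fraction (fP) structure that can
be generated either as true group offsets or as smooth scan-date drift
confounded with inhomogeneous group sampling over time, and heteroscedastic
TAC noise largest in the smallest (raphe) region.

All kinetic parameters are drawn on the natural-log scale from a
multivariate hierarchy (region means + correlated individual deviations +
TAC-level jitter); TACs are generated with the analytic 2TCM forward model
and everything is reproducible bit-for-bit from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .kinetic import (
    ArterialInput,
    FrameSchedule,
    TimeActivityCurve,
    TwoTCMParams,
    compute_weights,
    solve_2tcm,
)

__all__ = [
    "CohortConfig",
    "SyntheticStudy",
    "simulate_aif",
    "simulate_fp",
    "simulate_cohort",
    "PARAM_NAMES",
]

PARAM_NAMES = ("K1", "VND", "BPND", "k4", "vB")

PROJECTION_REGIONS = ("DLPFC", "MPFC", "ACC", "PCC", "INS", "HIP", "AMY")

# region mean log-parameters: plausible [11C]WAY100635-like character
# (low non-displaceable uptake everywhere; small, noisy raphe; cerebellar
# white matter with low VND and a small specific-binding contamination).
_REGION_MEANS = {
    #            logK1       logVND      logBPND     logk4      logvB
    "DLPFC": (np.log(0.090), np.log(0.35), np.log(3.5), np.log(0.014), np.log(0.044)),
    "MPFC":  (np.log(0.095), np.log(0.35), np.log(4.5), np.log(0.014), np.log(0.044)),
    "ACC":   (np.log(0.095), np.log(0.36), np.log(4.2), np.log(0.014), np.log(0.044)),
    "PCC":   (np.log(0.090), np.log(0.36), np.log(4.0), np.log(0.014), np.log(0.044)),
    "INS":   (np.log(0.090), np.log(0.35), np.log(4.0), np.log(0.014), np.log(0.044)),
    "HIP":   (np.log(0.075), np.log(0.33), np.log(5.5), np.log(0.013), np.log(0.044)),
    "AMY":   (np.log(0.070), np.log(0.33), np.log(4.5), np.log(0.013), np.log(0.044)),
    "RN":    (np.log(0.055), np.log(0.29), np.log(2.8), np.log(0.013), np.log(0.050)),
    "CGM":   (np.log(0.085), np.log(0.31), np.log(0.80), np.log(0.014), np.log(0.044)),
    "CWM":   (np.log(0.040), np.log(0.23), np.log(0.15), np.log(0.014), np.log(0.040)),
}


@dataclass
class CohortConfig:
    """Study-design and data-generating settings for a synthetic cohort."""

    group_sizes: Dict[str, int] = field(
        default_factory=lambda: {"HV": 57, "NRM": 50, "AE": 53})
    regions: tuple = PROJECTION_REGIONS + ("RN",)
    include_reference: bool = True           # add CWM (SRTM reference)
    include_cerebellar_grey: bool = False    # add CGM (exploratory region)
    cwm_contamination: bool = True           # small specific binding in CWM
    schedule: FrameSchedule = field(default_factory=FrameSchedule.default)

    # hierarchy on log kinetic parameters (K1, VND, BPND, k4, vB)
    subject_sd: tuple = (0.12, 0.18, 0.22, 0.08, 0.15)
    # region x individual interaction on the log parameters: small relative
    # to measurement-driven estimation error, as in the emulated study's
    # simulation structure where most per-TAC error is recoverable noise
    tac_sd: tuple = (0.02, 0.025, 0.03, 0.015, 0.04)
    subject_corr: Optional[np.ndarray] = None  # default set in __post_init__

    # group effects on log BPND per region; None -> default raphe-dominant
    group_effects: Optional[Dict[str, Dict[str, float]]] = None
    rn_effect: float = 0.15       # NRM log-BP effect in the raphe
    projection_effect: float = 0.075  # NRM log-BP effect elsewhere (half)

    # plasma-free fraction model
    fp_mode: str = "group_offsets"   # "null" | "group_offsets" | "drift"
    fp_base: float = 0.07
    fp_group_offsets: Dict[str, float] = field(
        default_factory=lambda: {"HV": np.log(0.08 / 0.07),
                                 "NRM": np.log(0.06 / 0.07), "AE": 0.0})
    fp_drift_amplitude: float = 0.4
    fp_noise_sd: float = 0.2

    # TAC noise: frame SD = noise_base * region multiplier * mean(TAC) / w
    noise_base: float = 0.05
    region_noise: Dict[str, float] = field(
        default_factory=lambda: {"RN": 3.0, "CWM": 1.5, "CGM": 1.2})

    # per-region overrides of the mean log parameters, e.g.
    # {"CWM": {"VND": log(0.23)}}; parameter names K1/VND/BPND/k4/vB
    region_mean_overrides: Optional[Dict[str, Dict[str, float]]] = None

    # demographics
    age_mean: float = 38.0
    age_sd: float = 13.0
    female_fraction: Dict[str, float] = field(
        default_factory=lambda: {"HV": 32 / 57, "NRM": 34 / 50, "AE": 30 / 53})
    date_span_years: float = 10.0

    def __post_init__(self):
        if self.subject_corr is None:
            self.subject_corr = default_subject_corr()
        self.subject_corr = np.asarray(self.subject_corr, dtype=float)
        self.validate()

    def validate(self):
        if any(n < 0 for n in self.group_sizes.values()) or \
                sum(self.group_sizes.values()) <= 0:
            raise ValueError("group sizes must be nonnegative, at least one > 0")
        if self.fp_mode not in ("null", "group_offsets", "drift"):
            raise ValueError(f"unknown fp_mode {self.fp_mode!r}")
        C = self.subject_corr
        if C.shape != (5, 5) or not np.allclose(C, C.T):
            raise ValueError("subject_corr must be a symmetric 5x5 matrix")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise ValueError("subject_corr must be positive-definite")
        if any(sd <= 0 for sd in self.subject_sd):
            raise ValueError("subject SDs must be positive")
        unknown = set(self.regions) - set(_REGION_MEANS)
        if unknown:
            raise ValueError(f"regions without default parameters: {unknown}")

    @property
    def all_regions(self) -> tuple:
        extra = ()
        if self.include_cerebellar_grey:
            extra = extra + ("CGM",)
        if self.include_reference:
            extra = extra + ("CWM",)
        return tuple(self.regions) + extra

    def effects_table(self) -> Dict[str, Dict[str, float]]:
        """Injected log-BP group effects per group and region (HV = 0)."""
        if self.group_effects is not None:
            return self.group_effects
        eff = {"NRM": {}, "AE": {}}
        for r in self.all_regions:
            if r == "RN":
                eff["NRM"][r] = self.rn_effect
            elif r in ("CGM", "CWM"):
                eff["NRM"][r] = 0.0
            else:
                eff["NRM"][r] = self.projection_effect
            eff["AE"][r] = 0.0
        return eff


def default_subject_corr() -> np.ndarray:
    """Plausible individual-level correlations among log kinetic parameters."""
    C = np.array([
        # K1    VND   BP    k4    vB
        [1.00, 0.60, 0.25, 0.10, 0.20],
        [0.60, 1.00, 0.40, 0.15, 0.10],
        [0.25, 0.40, 1.00, -0.20, 0.05],
        [0.10, 0.15, -0.20, 1.00, 0.00],
        [0.20, 0.10, 0.05, 0.00, 1.00],
    ])
    return C


# ---------------------------------------------------------------------------
# arterial input
# ---------------------------------------------------------------------------

def _aif_grid() -> np.ndarray:
    return np.unique(np.concatenate([
        np.arange(0.0, 3.0, 0.005),
        np.arange(3.0, 20.0, 0.05),
        np.arange(20.0, 110.0, 0.25), [110.0]]))


def simulate_aif(dose: float, rng=None, fP: float = 0.07,
                 jitter: bool = True) -> ArterialInput:
    """Feng-type whole-plasma curve times a Hill-type parent fraction.

    Linear rise from zero to a dose-proportional peak at ~0.75 min followed
    by a tri-exponential decay; parent fraction decreases monotonically from
    1 following a Hill function (fast metabolism, ~5% parent at 110 min).
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    if jitter:
        amp = 5.0 * dose * float(np.exp(rng.normal(0.0, 0.15)))
        t_peak = float(np.clip(0.75 * np.exp(rng.normal(0.0, 0.1)), 0.4, 1.5))
        lams = np.array([3.5, 0.35, 0.012]) * np.exp(rng.normal(0, 0.1, 3))
        t50 = float(22.0 * np.exp(rng.normal(0.0, 0.1)))
    else:
        amp, t_peak, lams, t50 = 5.0 * dose, 0.75, np.array([3.5, 0.35, 0.012]), 22.0
    fracs = np.array([0.75, 0.18, 0.07])
    t = np.union1d(_aif_grid(), [t_peak])
    wp = np.where(
        t <= t_peak, amp * t / t_peak,
        amp * (fracs[None, :] * np.exp(-lams[None, :] *
                                       (t[:, None] - t_peak))).sum(axis=1))
    pf = 1.0 / (1.0 + (t / t50) ** 1.8)
    return ArterialInput(t, wp * pf, wp, fP=fP)


def simulate_fp(group: str, date_frac: float, config: CohortConfig,
                rng=None) -> float:
    """Plasma-free fraction: base x exp(group offset + drift + noise).

    In ``drift`` mode the group offsets are zero and a smooth cosine decline
    over the sampling period stands in for assay drift; group differences
    then arise only through inhomogeneous sampling of groups over time.
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    off = 0.0
    drift = 0.0
    if config.fp_mode == "group_offsets":
        off = config.fp_group_offsets.get(group, 0.0)
    elif config.fp_mode == "drift":
        drift = 0.5 * config.fp_drift_amplitude * np.cos(np.pi * date_frac)
    noise = rng.normal(0.0, config.fp_noise_sd) if config.fp_noise_sd > 0 else 0.0
    return float(np.clip(config.fp_base * np.exp(off + drift + noise),
                         0.01, 0.3))


def _date_frac(group: str, config: CohortConfig, rng) -> float:
    """Scan date as a fraction of the sampling period.

    Under the drift confound, healthy volunteers are mostly measured early
    and not-recently-medicated patients late.
    """
    if config.fp_mode == "drift":
        a, b = {"HV": (2.0, 5.0), "AE": (4.0, 4.0), "NRM": (5.0, 2.0)}[group]
        return float(rng.beta(a, b))
    return float(rng.uniform())


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    """A complete simulated study with ground truth."""

    config: CohortConfig
    seed: int
    schedule: FrameSchedule
    participants: pd.DataFrame
    aifs: Dict[str, ArterialInput]
    tacs: Dict[str, Dict[str, TimeActivityCurve]]
    true_params: pd.DataFrame   # subject, region, log K1/VND/BPND/k4/vB
    truth: dict                 # injected-effect ledger

    @property
    def subject_ids(self):
        return list(self.participants["subject_id"])

    @property
    def regions(self):
        return list(self.config.all_regions)

    def true_log_outcome(self, measure: str = "bpnd") -> pd.DataFrame:
        """True log binding potential per subject x region."""
        df = self.true_params.copy()
        if measure == "bpnd":
            df["value"] = df["log_BPND"]
        elif measure == "bpp":
            df["value"] = df["log_BPND"] + df["log_VND"]
        elif measure == "bpf":
            fp = self.participants.set_index("subject_id")["fP"]
            df["value"] = (df["log_BPND"] + df["log_VND"]
                           - np.log(fp.loc[df["subject_id"]].to_numpy()))
        else:
            raise ValueError(f"unknown measure {measure!r}")
        return df[["subject_id", "region", "value"]]


def draw_subject_deviations(config: CohortConfig, n: int, rng) -> np.ndarray:
    """Correlated individual-level deviations of the five log parameters."""
    D = np.diag(config.subject_sd)
    cov = D @ config.subject_corr @ D
    L = np.linalg.cholesky(cov)
    return rng.standard_normal((n, 5)) @ L.T


def simulate_cohort(config: Optional[CohortConfig] = None,
                    seed: int = 0, noise: bool = True) -> SyntheticStudy:
    """Generate a full synthetic study (participants, AIFs, TACs, truth)."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)
    regions = config.all_regions
    effects = config.effects_table()

    rows = []
    for group in ("HV", "NRM", "AE"):
        n = config.group_sizes.get(group, 0)
        for k in range(n):
            sid = f"{group.lower()}{k + 1:03d}"
            age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                                18.0, 70.0))
            sex = "F" if rng.uniform() < config.female_fraction[group] else "M"
            dfrac = _date_frac(group, config, rng)
            fp = simulate_fp(group, dfrac, config, rng)
            dose = float(np.clip(rng.lognormal(np.log(7.0), 0.35), 1.0, 20.0))
            rows.append((sid, group, age, sex, dfrac, fp, dose))
    participants = pd.DataFrame(rows, columns=[
        "subject_id", "group", "age", "sex", "scan_date_frac", "fP",
        "injected_dose"])

    region_means = np.array([_REGION_MEANS[r] for r in regions])
    if not config.cwm_contamination and "CWM" in regions:
        region_means[regions.index("CWM"), 2] = np.log(0.02)
    if config.region_mean_overrides:
        for r, over in config.region_mean_overrides.items():
            for pname, val in over.items():
                region_means[regions.index(r),
                             PARAM_NAMES.index(pname)] = val

    aifs = {}
    tacs = {}
    truth_rows = []
    n_subj = len(participants)
    subj_dev = draw_subject_deviations(config, n_subj, rng)
    for i, prow in participants.iterrows():
        sid, group = prow["subject_id"], prow["group"]
        aif = simulate_aif(prow["injected_dose"], rng=rng, fP=prow["fP"])
        aifs[sid] = aif
        tacs[sid] = {}
        for j, region in enumerate(regions):
            theta = region_means[j] + subj_dev[i]
            theta = theta + rng.normal(0.0, np.asarray(config.tac_sd))
            theta[2] += effects.get(group, {}).get(region, 0.0)
            K1, VND, BPND, k4, vB = np.exp(theta)
            params = TwoTCMParams(K1=K1, k2=K1 / VND, k3=BPND * k4, k4=k4,
                                  vB=min(vB, 0.3))
            model = solve_2tcm(params, aif, config.schedule)
            activity = model.activity
            if noise and config.noise_base > 0:
                w = compute_weights(config.schedule, model)
                mult = config.region_noise.get(region, 1.0)
                sd = config.noise_base * mult * activity.mean() / w
                activity = activity + rng.normal(0.0, 1.0, sd.shape) * sd
            tacs[sid][region] = TimeActivityCurve(
                sid, region, config.schedule, activity)
            truth_rows.append((sid, region, *theta))
    true_params = pd.DataFrame(truth_rows, columns=[
        "subject_id", "region"] + [f"log_{p}" for p in PARAM_NAMES])

    truth = {
        "seed": seed,
        "group_effects_logBP": effects,
        "fp_mode": config.fp_mode,
        "fp_group_offsets": (dict(config.fp_group_offsets)
                             if config.fp_mode == "group_offsets" else
                             {g: 0.0 for g in config.group_sizes}),
        "fp_drift_amplitude": (config.fp_drift_amplitude
                               if config.fp_mode == "drift" else 0.0),
        "noise_base": config.noise_base if noise else 0.0,
    }
    return SyntheticStudy(config=config, seed=seed, schedule=config.schedule,
                          participants=participants, aifs=aifs, tacs=tacs,
                          true_params=true_params, truth=truth)
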