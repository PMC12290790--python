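"""Compartmental forward models and outcome-measure algebra for dynamic PET.

Implements the two-tissue compartment model (2TCM) driven by an arterial
input function, the simplified reference tissue model (SRTM), the standard
binding outcome measures (BP_ND, BP_P, BP_F, V_T, V_ND), radioactive-decay
handling, and the frame weighting scheme used for weighted nonlinear least
squares (square root of frame duration times the decay-uncorrected mean
frame activity).

Conventions
-----------
* Times in minutes, activities in kBq/mL, K1 in mL/cm^3/min, rate constants
  in 1/min.  Stored time-activity curves are decay-corrected to injection.
* Frame predictions are *time averages* of the continuous model solution
  over each frame (20-s early frames make midpoint evaluation inaccurate).
* The blood-volume term always uses the unscaled whole-plasma curve (the
  whole-plasma proxy for whole blood), even when the input is scaled by the
  plasma-free fraction fP for BP_F-parameterized fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._conv import conv_frame_integrals, curve_frame_integrals

__all__ = [
    "C11_HALF_LIFE_MIN",
    "FrameSchedule",
    "TimeActivityCurve",
    "BloodData",
    "ArterialInput",
    "TwoTCMParams",
    "SRTMParams",
    "OutcomeSet",
    "solve_2tcm",
    "solve_srtm",
    "outcomes_from_rates",
    "decay_uncorrect",
    "compute_weights",
]

#: Half-life of carbon-11 in minutes.
C11_HALF_LIFE_MIN = 20.364


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Contiguous, non-overlapping PET frame timing (minutes)."""

    start: np.ndarray
    duration: np.ndarray

    def __post_init__(self):
        start = np.asarray(self.start, dtype=float)
        dur = np.asarray(self.duration, dtype=float)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "duration", dur)
        if start.ndim != 1 or start.shape != dur.shape:
            raise ValueError("start and duration must be 1-D and equal length")
        if np.any(dur <= 0):
            raise ValueError("frame durations must be positive")
        if not np.allclose(start[1:], (start + dur)[:-1], rtol=0, atol=1e-9):
            raise ValueError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return self.start.shape[0]

    @property
    def end(self) -> np.ndarray:
        return self.start + self.duration

    @property
    def mid(self) -> np.ndarray:
        return self.start + 0.5 * self.duration

    @property
    def total_minutes(self) -> float:
        return float(self.end[-1])

    @classmethod
    def from_seconds(cls, durations_sec) -> "FrameSchedule":
        d = np.asarray(durations_sec, dtype=np.int64)
        ends = np.cumsum(d)
        starts = ends - d
        return cls(starts / 60.0, d / 60.0)

    @classmethod
    def default(cls) -> "FrameSchedule":
        """The 20-frame, 110-minute schedule: 3x20 s, 3x1, 3x2, 2x5, 9x10 min."""
        sec = [20] * 3 + [60] * 3 + [120] * 3 + [300] * 2 + [600] * 9
        return cls.from_seconds(sec)


@dataclass
class TimeActivityCurve:
    """Frame-wise decay-corrected radioactivity for one subject x region."""

    subject_id: str
    region_id: str
    schedule: FrameSchedule
    activity: np.ndarray  # kBq/mL per frame
    weights: Optional[np.ndarray] = None

    def __post_init__(self):
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.shape != (self.schedule.n_frames,):
            raise ValueError("activity length must equal frame count")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.activity.shape or np.any(self.weights < 0):
                raise ValueError("weights must be nonnegative, one per frame")


@dataclass
class BloodData:
    """Raw arterial blood table: whole-plasma activity and parent fraction."""

    sample_times: np.ndarray
    whole_plasma: np.ndarray
    parent_fraction: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.sample_times, dtype=float)
        wp = np.asarray(self.whole_plasma, dtype=float)
        pf = np.asarray(self.parent_fraction, dtype=float)
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValueError(f"sample times must be strictly increasing (row {bad})")
        if np.any(wp < 0):
            raise ValueError("whole-plasma activity must be nonnegative")
        if np.any((pf < 0) | (pf > 1)):
            raise ValueError("parent fraction must lie in [0, 1]")
        self.sample_times, self.whole_plasma, self.parent_fraction = t, wp, pf

    @property
    def metabolite_corrected_plasma(self) -> np.ndarray:
        return self.whole_plasma * self.parent_fraction


def _interp_curve(t, times, values):
    out = np.interp(t, times, values, left=0.0)
    return out


@dataclass
class ArterialInput:
    """Continuous-time evaluable input curves on a dense knot grid.

    ``cp_parent`` is the metabolite-corrected plasma activity; the
    whole-plasma curve stands in for whole blood in the vascular term.
    Both are piecewise linear on ``times`` (zero before injection onset);
    evaluation beyond the last knot extrapolates the last value.
    """

    times: np.ndarray
    cp_parent_values: np.ndarray
    wholeplasma_values: np.ndarray
    fP: float = 1.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.cp_parent_values = np.asarray(self.cp_parent_values, dtype=float)
        self.wholeplasma_values = np.asarray(self.wholeplasma_values, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("input knot times must be strictly increasing")
        if np.any(self.cp_parent_values < 0) or np.any(self.wholeplasma_values < 0):
            raise ValueError("input curves must be nonnegative")
        if not (0 < self.fP <= 1):
            raise ValueError("fP must lie in (0, 1]")

    def cp_parent(self, t):
        return _interp_curve(t, self.times, self.cp_parent_values)

    def c_wholeplasma(self, t):
        return _interp_curve(t, self.times, self.wholeplasma_values)

    def check_covers(self, schedule: FrameSchedule):
        if self.times[-1] < schedule.total_minutes - 1e-9:
            warnings.warn(
                "input curve ends before the scan window; extrapolating the "
                "last sample as a constant", stacklevel=3)

    @classmethod
    def from_blood_data(cls, blood: BloodData, fP: float = 1.0,
                        grid_dt: float = 0.05) -> "ArterialInput":
        """Build an input from a sampled blood table.

        Whole plasma is interpolated linearly before its peak and
        log-linearly after it; parent fraction linearly.  The result is
        resampled onto a grid refined to ``grid_dt`` so downstream frame
        integrals resolve the peak.
        """
        t = blood.sample_times
        if t[0] > 0:
            t = np.concatenate([[0.0], t])
            wp = np.concatenate([[0.0], blood.whole_plasma])
            pf = np.concatenate([[blood.parent_fraction[0]], blood.parent_fraction])
        else:
            wp, pf = blood.whole_plasma, blood.parent_fraction
        grid = np.union1d(t, np.arange(0.0, t[-1] + grid_dt / 2, grid_dt))
        ipk = int(np.argmax(wp))
        wp_grid = np.empty_like(grid)
        pre = grid <= t[ipk]
        wp_grid[pre] = np.interp(grid[pre], t, wp)
        # log-linear interpolation of the decay tail
        tiny = max(wp.max(), 1.0) * 1e-12
        wp_grid[~pre] = np.exp(
            np.interp(grid[~pre], t[ipk:], np.log(wp[ipk:] + tiny))) - tiny
        wp_grid = np.clip(wp_grid, 0.0, None)
        pf_grid = np.clip(np.interp(grid, t, pf), 0.0, 1.0)
        return cls(grid, wp_grid * pf_grid, wp_grid, fP)


@dataclass(frozen=True)
class TwoTCMParams:
    """2TCM rate constants: K1 [mL/cm^3/min], k2..k4 [1/min], vB fraction."""

    K1: float
    k2: float
    k3: float
    k4: float
    vB: float = 0.0

    def __post_init__(self):
        if self.K1 < 0 or self.k3 < 0:
            raise ValueError("K1 and k3 must be nonnegative")
        if self.k2 <= 0 or self.k4 <= 0:
            raise ValueError("k2 and k4 must be positive")
        if not (0 <= self.vB < 1):
            raise ValueError("vB must lie in [0, 1)")


@dataclass(frozen=True)
class SRTMParams:
    """SRTM parameters: R1 (rel. delivery), k2prime [1/min], BPND."""

    R1: float
    k2prime: float
    BPND: float

    def __post_init__(self):
        if self.R1 <= 0 or self.k2prime <= 0:
            raise ValueError("R1 and k2prime must be positive")
        if self.BPND <= -1:
            raise ValueError("BPND must exceed -1")

    @property
    def k2(self) -> float:
        return self.R1 * self.k2prime

    @property
    def k2a(self) -> float:
        return self.k2 / (1.0 + self.BPND)


@dataclass(frozen=True)
class OutcomeSet:
    """Binding outcome measures derived from 2TCM rate constants."""

    BPND: float
    VND: float
    BPP: float
    VT: float
    BPF: Optional[float] = None


# ---------------------------------------------------------------------------
# model grids
# ---------------------------------------------------------------------------

def build_model_grid(schedule: FrameSchedule, curve_times: np.ndarray):
    """Knot grid (input knots + frame boundaries) and segment->frame map."""
    end = schedule.total_minutes
    bounds = np.concatenate([schedule.start, [end]])
    inner = curve_times[(curve_times > 0) & (curve_times < end)]
    knots = np.union1d(np.union1d(inner, bounds), [0.0])
    # drop near-duplicate knots from float unions
    keep = np.concatenate([[True], np.diff(knots) > 1e-12])
    knots = knots[keep]
    mids = 0.5 * (knots[:-1] + knots[1:])
    seg_frame = np.searchsorted(schedule.end, mids, side="right")
    seg_frame = np.clip(seg_frame, 0, schedule.n_frames - 1)
    return knots, seg_frame


def _two_tcm_alphas_phis(K1, k2, k3, k4):
    """Macro rates and amplitudes of the bi-exponential 2TCM impulse response."""
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    if np.any(disc < 0):
        raise ValueError("negative 2TCM discriminant (k2+k3+k4)^2 - 4 k2 k4")
    r = np.sqrt(disc)
    r = np.maximum(r, 1e-12 * np.maximum(s, 1e-30))  # guard repeated roots
    a1 = 0.5 * (s - r)
    a2 = 0.5 * (s + r)
    phi1 = K1 * (k3 + k4 - a1) / (a2 - a1)
    phi2 = K1 * (a2 - k3 - k4) / (a2 - a1)
    return a1, a2, phi1, phi2


# ---------------------------------------------------------------------------
# forward models
# ---------------------------------------------------------------------------

def solve_2tcm(params: TwoTCMParams, input: ArterialInput,
               schedule: FrameSchedule, scale_input_by_fp: bool = False
               ) -> TimeActivityCurve:
    """Frame-averaged 2TCM model curve.

    ``C(t) = (1 - vB) C_tissue(t) + vB C_wholeplasma(t)`` with ``C_tissue``
    the analytic bi-exponential convolution solution driven by the
    metabolite-corrected plasma curve (times fP when ``scale_input_by_fp``);
    the vascular term always uses unscaled whole plasma.
    """
    input.check_covers(schedule)
    knots, seg_frame = build_model_grid(schedule, input.times)
    cp = input.cp_parent(knots)[None, :]
    if scale_input_by_fp:
        cp = cp * input.fP
    wp = input.c_wholeplasma(knots)[None, :]
    a1, a2, p1, p2 = _two_tcm_alphas_phis(params.K1, params.k2, params.k3,
                                          params.k4)
    alphas = np.array([[a1, a2]])
    phis = np.array([[p1, p2]])
    tissue = conv_frame_integrals(knots, cp, np.zeros(1, dtype=int), alphas,
                                  phis, seg_frame, schedule.n_frames)[0]
    wp_int = curve_frame_integrals(knots, wp, seg_frame, schedule.n_frames)[0]
    activity = ((1.0 - params.vB) * tissue + params.vB * wp_int) / schedule.duration
    return TimeActivityCurve("model", "model", schedule, activity)


def solve_srtm(params: SRTMParams, ref_times: np.ndarray,
               ref_values: np.ndarray, schedule: FrameSchedule
               ) -> TimeActivityCurve:
    """Frame-averaged SRTM model curve.

    ``C(t) = R1 Cr(t) + (k2 - R1 k2a) [Cr (*) exp(-k2a t)](t)`` with
    ``k2 = R1 k2prime`` and ``k2a = k2 / (1 + BPND)``.  The reference curve
    is piecewise linear on (``ref_times``, ``ref_values``).
    """
    k2a = params.k2a
    if k2a <= 0:
        raise ValueError("k2a must be positive")
    knots, seg_frame = build_model_grid(schedule, np.asarray(ref_times, float))
    cr = _interp_curve(knots, np.asarray(ref_times, float),
                       np.asarray(ref_values, float))[None, :]
    conv = conv_frame_integrals(knots, cr, np.zeros(1, dtype=int),
                                np.array([[k2a]]),
                                np.array([[params.k2 - params.R1 * k2a]]),
                                seg_frame, schedule.n_frames)[0]
    cr_int = curve_frame_integrals(knots, cr, seg_frame, schedule.n_frames)[0]
    activity = (params.R1 * cr_int + conv) / schedule.duration
    return TimeActivityCurve("model", "model", schedule, activity)


def ref_curve_from_tac(tac: TimeActivityCurve):
    """Piecewise-linear continuous reference curve through frame midpoints."""
    times = np.concatenate([[0.0], tac.schedule.mid])
    values = np.concatenate([[0.0], tac.activity])
    return times, values


# ---------------------------------------------------------------------------
# outcomes, decay, weights
# ---------------------------------------------------------------------------

def outcomes_from_rates(params: TwoTCMParams,
                        fP: Optional[float] = None) -> OutcomeSet:
    """BP_ND = k3/k4, V_ND = K1/k2, BP_P = BP_ND V_ND, V_T = V_ND + BP_P,
    BP_F = BP_P / fP (only when fP is supplied)."""
    if fP is not None and fP <= 0:
        raise ValueError("fP must be positive when supplied")
    bpnd = params.k3 / params.k4
    vnd = params.K1 / params.k2
    bpp = bpnd * vnd
    vt = vnd * (1.0 + bpnd)
    bpf = bpp / fP if fP is not None else None
    return OutcomeSet(BPND=bpnd, VND=vnd, BPP=bpp, VT=vt, BPF=bpf)


def decay_uncorrect(tac: TimeActivityCurve,
                    half_life: float = C11_HALF_LIFE_MIN) -> np.ndarray:
    """Remove the decay correction using frame mid-times."""
    if half_life <= 0:
        raise ValueError("half_life must be positive")
    lam = np.log(2.0) / half_life
    return tac.activity * np.exp(-lam * tac.schedule.mid)


def compute_weights(schedule: FrameSchedule, tac: TimeActivityCurve,
                    half_life: float = C11_HALF_LIFE_MIN) -> np.ndarray:
    """Frame weights: sqrt(duration x decay-uncorrected activity), mean-1.

    Negative frame activities are floored at zero before the square root.
    An all-zero TAC yields uniform weights with a warning.
    """
    uncorr = np.clip(decay_uncorrect(tac, half_life), 0.0, None)
    w = np.sqrt(schedule.duration * uncorr)
    if not np.any(w > 0):
        warnings.warn("all-zero TAC: falling back to uniform weights",
                      stacklevel=2)
        return np.ones_like(w)
    return w / w.mean()
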