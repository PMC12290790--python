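"""Exact exponential-convolution kernels for compartmental forward models.

The tissue response of both the 2TCM and SRTM is a sum of terms of the form
``phi * (exp(-alpha t) (*) u)(t)`` where ``u`` is the (metabolite-corrected
plasma or reference-tissue) input curve.  Inputs are represented as
piecewise-linear curves on a knot grid; for such inputs the convolution and
its running time-integral have closed forms on every segment, so frame
averages are computed exactly (no quadrature error beyond the piecewise-linear
representation of the input itself).

Per segment of width ``h`` with input ``u(x) = u0 + b x`` and rate ``a``::

    y(x)      = y0 e^{-a x} + u0 J0(x) + b J1(x)
    J0(x)     = (1 - e^{-a x}) / a
    J1(x)     = x/a - (1 - e^{-a x}) / a^2
    int y dx  = y0 q0 + u0 J1(h) + b iJ1,   q0 = J0(h),
    iJ1       = (h^2/2 - J1(h)) / a

Series expansions are used when ``a h`` is tiny to avoid cancellation.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "conv_frame_integrals",
    "curve_frame_integrals",
    "HAVE_NUMBA",
]


def _conv_frames_py(knot_t, u_all, subj_idx, alphas, phis, seg_frame, n_frames):
    T, C = alphas.shape
    N = knot_t.shape[0]
    out = np.zeros((T, n_frames))
    y = np.zeros((T, C))
    u0 = u_all[subj_idx, 0]
    for i in range(N - 1):
        h = knot_t[i + 1] - knot_t[i]
        u1 = u_all[subj_idx, i + 1]
        b = (u1 - u0) / h
        ah = alphas * h
        small = ah <= 1e-4
        with np.errstate(over="ignore"):
            E = np.exp(-ah)
        q0 = np.where(small,
                      h * (1.0 - ah / 2.0 + ah * ah / 6.0 - ah ** 3 / 24.0),
                      -np.expm1(-ah) / alphas)
        J1 = np.where(small,
                      h * h * (0.5 - ah / 6.0 + ah * ah / 24.0 - ah ** 3 / 120.0),
                      (h - q0) / alphas)
        iJ1 = np.where(small,
                       h ** 3 * (1.0 / 6.0 - ah / 24.0 + ah * ah / 120.0),
                       (0.5 * h * h - J1) / alphas)
        seg = y * q0 + u0[:, None] * J1 + b[:, None] * iJ1
        out[:, seg_frame[i]] += (phis * seg).sum(axis=1)
        y = y * E + u0[:, None] * q0 + b[:, None] * J1
        u0 = u1
    return out


def _conv_frames_impl(knot_t, u_all, subj_idx, alphas, phis, seg_frame, n_frames):
    T, C = alphas.shape
    N = knot_t.shape[0]
    out = np.zeros((T, n_frames))
    for t in range(T):
        s = subj_idx[t]
        for c in range(C):
            a = alphas[t, c]
            ph = phis[t, c]
            if ph == 0.0:
                continue
            y = 0.0
            for i in range(N - 1):
                h = knot_t[i + 1] - knot_t[i]
                u0 = u_all[s, i]
                u1 = u_all[s, i + 1]
                b = (u1 - u0) / h
                ah = a * h
                if ah > 1e-4:
                    E = math.exp(-ah)
                    q0 = (1.0 - E) / a
                    J1 = (h - q0) / a
                    iJ1 = (0.5 * h * h - J1) / a
                else:
                    E = math.exp(-ah)
                    q0 = h * (1.0 - ah / 2.0 + ah * ah / 6.0 - ah * ah * ah / 24.0)
                    J1 = h * h * (0.5 - ah / 6.0 + ah * ah / 24.0 - ah * ah * ah / 120.0)
                    iJ1 = h * h * h * (1.0 / 6.0 - ah / 24.0 + ah * ah / 120.0)
                seg = y * q0 + u0 * J1 + b * iJ1
                out[t, seg_frame[i]] += ph * seg
                y = y * E + u0 * q0 + b * J1
    return out


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _conv_frames_nb = njit(cache=False, fastmath=False)(_conv_frames_impl)
    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _conv_frames_nb = None
    HAVE_NUMBA = False


def conv_frame_integrals(knot_t, u_all, subj_idx, alphas, phis, seg_frame, n_frames):
    """Frame integrals of ``sum_c phi_c (exp(-alpha_c t) (*) u_subj)`` per TAC.

    Parameters
    ----------
    knot_t : (N,) knot times, must include every frame boundary.
    u_all : (S, N) input curve values per subject (piecewise linear).
    subj_idx : (T,) int subject row of each TAC.
    alphas, phis : (T, C) decay rates (>0) and amplitudes.
    seg_frame : (N-1,) int frame index of each knot segment.
    n_frames : number of frames.

    Returns
    -------
    (T, n_frames) array of frame *integrals* (divide by durations to average).
    """
    knot_t = np.ascontiguousarray(knot_t, dtype=np.float64)
    u_all = np.ascontiguousarray(u_all, dtype=np.float64)
    subj_idx = np.ascontiguousarray(subj_idx, dtype=np.int64)
    alphas = np.ascontiguousarray(alphas, dtype=np.float64)
    phis = np.ascontiguousarray(phis, dtype=np.float64)
    seg_frame = np.ascontiguousarray(seg_frame, dtype=np.int64)
    if HAVE_NUMBA:
        return _conv_frames_nb(knot_t, u_all, subj_idx, alphas, phis,
                               seg_frame, n_frames)
    return _conv_frames_py(knot_t, u_all, subj_idx, alphas, phis,
                           seg_frame, n_frames)


def curve_frame_integrals(knot_t, u_all, seg_frame, n_frames):
    """Exact frame integrals of piecewise-linear curves (trapezoid is exact).

    ``u_all`` has shape (S, N); returns (S, n_frames).
    """
    h = np.diff(knot_t)
    seg_int = 0.5 * h * (u_all[:, :-1] + u_all[:, 1:])
    out = np.zeros((u_all.shape[0], n_frames))
    np.add.at(out.T, seg_frame, seg_int.T)
    return out
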