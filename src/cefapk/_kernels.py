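"""Numba-compiled concentration kernels.

Flat-layout duplicates of the closed-form infusion solutions in ``pkmodel``:
one row per (virtual) subject, columns are observation times.  These exist
purely for speed inside the likelihood engine; ``pkmodel`` remains the
readable reference implementation and the two are cross-checked in the test
suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["profile_2cpt_flat", "profile_1cpt_flat"]


@njit(cache=True, fastmath=True)
def profile_2cpt_flat(t, cl, vc, q, vp, dose_start, dose_amt, dose_dur):
    """Two-compartment superposed-infusion concentrations, (N, J) layout."""
    N, J = t.shape
    D = dose_start.shape[1]
    out = np.zeros((N, J))
    for i in range(N):
        # clamp against underflow of exp(eta)-scaled parameters during
        # line-search exploration; the likelihood floor handles the rest
        cl_i = min(max(cl[i], 1e-12), 1e12)
        vc_i = min(max(vc[i], 1e-12), 1e12)
        q_i = min(max(q[i], 1e-12), 1e12)
        vp_i = min(max(vp[i], 1e-12), 1e12)
        k10 = cl_i / vc_i
        k12 = q_i / vc_i
        k21 = q_i / vp_i
        s = k10 + k12 + k21
        prod = k10 * k21
        disc2 = s * s - 4.0 * prod
        if disc2 < 0.0:
            disc2 = 0.0
        alpha = 0.5 * (s + np.sqrt(disc2))
        beta = prod / alpha
        if alpha - beta <= 1e-9 * alpha:
            alpha = alpha * (1.0 + 1e-9)
            beta = prod / alpha
        if beta < 1e-30:
            beta = 1e-30
        denom = vc_i * (alpha - beta)
        coef_a = (alpha - k21) / denom / alpha
        coef_b = (k21 - beta) / denom / beta
        for d in range(D):
            amt = dose_amt[i, d]
            if amt == 0.0:
                continue
            dur = dose_dur[i, d]
            rate = amt / dur
            start = dose_start[i, d]
            for j in range(J):
                tau = t[i, j] - start
                if tau <= 0.0:
                    continue
                run = tau if tau < dur else dur
                decay = tau - dur if tau > dur else 0.0
                out[i, j] += rate * (
                    coef_a * -np.expm1(-alpha * run) * np.exp(-alpha * decay)
                    + coef_b * -np.expm1(-beta * run) * np.exp(-beta * decay)
                )
    return out


@njit(cache=True, fastmath=True)
def profile_1cpt_flat(t, cl, v, dose_start, dose_amt, dose_dur):
    """One-compartment superposed-infusion concentrations, (N, J) layout."""
    N, J = t.shape
    D = dose_start.shape[1]
    out = np.zeros((N, J))
    for i in range(N):
        cl_i = min(max(cl[i], 1e-12), 1e12)
        v_i = min(max(v[i], 1e-12), 1e12)
        k = cl_i / v_i
        for d in range(D):
            amt = dose_amt[i, d]
            if amt == 0.0:
                continue
            dur = dose_dur[i, d]
            rate = amt / dur
            start = dose_start[i, d]
            for j in range(J):
                tau = t[i, j] - start
                if tau <= 0.0:
                    continue
                run = tau if tau < dur else dur
                decay = tau - dur if tau > dur else 0.0
                out[i, j] += rate / (k * v_i) * -np.expm1(-k * run) * np.exp(-k * decay)
    return out
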