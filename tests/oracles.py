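"""Independent oracles used by the test suite.

These deliberately avoid the package's closed-form/linearized code paths:
concentrations come from a stiff ODE integration of the compartment system,
marginal likelihoods from adaptive Gauss–Hermite quadrature, and PTA switch
points from root finding on the typical-value profile.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq


def ode_profile_2cpt(cl, vc, q, vp, doses, times, rtol=1e-10, atol=1e-12):
    """Two-compartment infusion concentrations by numerical ODE integration.

    ``doses`` is a list of (start, amount, duration) tuples; returns central
    concentrations at ``times`` plus the final (central, peripheral,
    eliminated) amounts for mass-balance checks.
    """
    times = np.asarray(times, dtype=float)
    k10, k12, k21 = cl / vc, q / vc, q / vp

    def rate_in(t):
        r = 0.0
        for start, amount, dur in doses:
            if start <= t < start + dur:
                r += amount / dur
        return r

    def rhs(t, y):
        ac, ap, ae = y
        return [
            rate_in(t) - (k10 + k12) * ac + k21 * ap,
            k12 * ac - k21 * ap,
            k10 * ac,
        ]

    # integrate piecewise between dose discontinuities for accuracy
    breaks = sorted({0.0, *times.tolist()}
                    | {s for s, _, _ in doses}
                    | {s + d for s, _, d in doses})
    t_end = max(max(times, default=0.0), breaks[-1])
    breaks = [b for b in breaks if b <= t_end] + [t_end]
    y = np.zeros(3)
    sol_t, sol_c = [0.0], [0.0]
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        want = times[(times > a) & (times <= b)]
        t_eval = np.unique(np.concatenate([want, [b]]))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", rtol=rtol, atol=atol,
                        t_eval=t_eval, max_step=(b - a))
        y = sol.y[:, -1]
        sol_t.extend(sol.t.tolist())
        sol_c.extend((sol.y[0] / vc).tolist())
    sol_t = np.asarray(sol_t)
    sol_c = np.asarray(sol_c)
    conc = np.array([sol_c[np.argmin(np.abs(sol_t - t))] for t in times])
    return conc, y


def agq_neg2ll(engine, est, n_nodes=15):
    """Adaptive Gauss–Hermite -2 log marginal likelihood for a packed cohort.

    Centers the quadrature at the conditional mode with the exact mode
    curvature; exact as n_nodes grows for any number of random effects.
    """
    par = engine.param
    data = engine.data
    q = par.n_eta
    if q == 0:
        typ = engine.typical_params(est)
        omega = np.zeros(0)
        g = engine._g(est, typ, np.zeros((data.n_subjects, 0)), omega)
        return float((g + engine.n_i * np.log(2 * np.pi)).sum())
    omega = np.array([est[n] for n in par.omega_names])
    typ = engine.typical_params(est)
    eta_hat = engine.inner_solve(est, None, tol=1e-9, maxiter=300)
    H = engine._last_hessian  # (S, q, q): Hessian of joint -2 log density
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.array(list(itertools.product(range(n_nodes), repeat=q)))
    X = x[grids]
    W = w[grids].prod(axis=1)
    keep = W > W.max() * 1e-14
    X, W = X[keep], W[keep]
    Hh = (H + H.transpose(0, 2, 1)) / 4.0  # Hessian of -log joint
    evals, evecs = np.linalg.eigh(Hh)
    evals = np.maximum(evals, 1e-8)
    Lm = evecs * (1.0 / np.sqrt(evals))[:, None, :]
    etas = eta_hat[None, :, :] + np.sqrt(2.0) * np.einsum("kq,spq->ksp", X, Lm)
    f = engine.predict(typ, etas)
    v = engine.resid_var(est, f)
    r = np.where(engine.mask, data.y - f, 0.0)
    gdata = np.where(engine.mask, np.log(v) + r * r / v, 0.0).sum(axis=-1)
    gfull = gdata + (etas**2 / omega**2).sum(axis=-1)
    logjoint = (
        -0.5 * (gfull + engine.n_i[None, :] * np.log(2 * np.pi))
        - 0.5 * q * np.log(2 * np.pi)
        - np.log(omega).sum()
    )
    expo = logjoint + (X**2).sum(axis=1)[:, None]
    m = expo.max(axis=0)
    integ = (
        np.log((W[:, None] * np.exp(expo - m[None, :])).sum(axis=0))
        + m
        + 0.5 * q * np.log(2.0)
        - 0.5 * np.log(evals).sum(axis=1)
    )
    return float(-2.0 * integ.sum())


def trough_switch_clcr(pop, t, dose=1000.0, infusion_duration=0.25, mic=0.5,
                       lo=5.0, hi=120.0):
    """CLcr at which the typical-value (no-IIV) trough at time t equals the MIC.

    Root-found on the closed-form-free ODE profile so it is independent of
    the package's analytic solution.  Returns None when no crossing exists
    inside [lo, hi].
    """

    from cefapk.pkmodel import typical_cl

    def trough_minus_mic(clcr):
        cl = typical_cl(pop.theta1, pop.theta2, clcr, pop.clcr_ref)
        conc, _ = ode_profile_2cpt(
            cl, pop.theta3, pop.theta4, pop.theta5,
            [(0.0, dose, infusion_duration)], [t],
        )
        return conc[0] - mic

    f_lo, f_hi = trough_minus_mic(lo), trough_minus_mic(hi)
    if f_lo * f_hi > 0:
        return None
    return brentq(trough_minus_mic, lo, hi, xtol=1e-6)
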