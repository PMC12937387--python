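"""Model qualification: CWRES goodness-of-fit, prediction-corrected VPC and
nonparametric bootstrap.

CWRES follows the standard FOCE linearization: with J = df/deta evaluated at
the conditional mode eta-hat,

    r = y - [f(eta-hat) - J eta-hat],   V = J Omega J' + Sigma(eta-hat),
    CWRES = L^-1 r,  L lower Cholesky of V,

so that residuals from a correctly specified model are approximately
standard normal.  The pc-VPC applies the usual prediction correction
pcY_ij = Y_ij * median(PRED in bin) / PRED_ij to both observed and simulated
data before comparing percentiles.  The bootstrap resamples subjects (not
observations) with replacement and refits each replicate; a replicate counts
as successful when the optimizer converged with every parameter interior to
its plausibility bounds.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._engine import FOCEEngine, Parameterization, pack
from .estimate import FitResult, ModelStructure, _subjects, fit
from .pkmodel import SERUM, TISSUE

__all__ = ["VPCResult", "BootstrapResult", "cwres", "pcvpc", "bootstrap"]


def _engine_for(dataset, fit_result: FitResult, canonical_order: bool = False):
    subjects = _subjects(dataset)
    if canonical_order:
        # the Cholesky whitening below is sequence-sensitive; fix a canonical
        # within-subject order so results do not depend on input row order
        subjects = [
            type(s)(
                s.subject_id,
                s.covariates,
                list(s.doses),
                sorted(s.observations, key=lambda o: (o.time, o.channel)),
            )
            for s in subjects
        ]
    data = pack(subjects)
    structure = fit_result.structure
    refs = dict(structure.covariate_refs or {})
    refs.update(fit_result.covariate_refs)
    structure = ModelStructure(
        n_compartments=structure.n_compartments,
        residual_model=structure.residual_model,
        iiv=dict(structure.iiv),
        covariate_terms=structure.covariate_terms,
        covariate_refs=refs,
        tissue=structure.tissue,
    )
    param = Parameterization(structure, data)
    engine = FOCEEngine(data, structure, param)
    return data, engine


def cwres(dataset, fit_result: FitResult) -> pd.DataFrame:
    """Conditional weighted residuals, one row per (non-BLQ) observation.

    Returns a frame with columns ``id, time, channel, dv, pred, ipred,
    cwres``.  ``pred`` is the population prediction (eta = 0), ``ipred`` the
    prediction at the conditional mode.
    """
    if not fit_result.converged:
        warnings.warn("fit did not converge; CWRES may be unreliable", RuntimeWarning, stacklevel=2)
    data, engine = _engine_for(dataset, fit_result, canonical_order=True)
    est = fit_result.estimates
    eta = fit_result.eta_modes
    if eta is None or eta.shape[0] != data.n_subjects:
        eta = engine.inner_solve(est)
    f, Jac, v, r, V = engine.foce_pieces(est, eta)
    q = Jac.shape[-1]
    J_obs = V.shape[1]
    V = V + 1e-10 * np.eye(J_obs)[None, :, :]
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        warnings.warn("singular residual covariance; jittering diagonal", RuntimeWarning, stacklevel=2)
        L = np.linalg.cholesky(V + 1e-6 * np.eye(J_obs)[None, :, :])
    z = np.linalg.solve(L, r[..., None])[..., 0]
    typ = engine.typical_params(est)
    pred = engine.predict(typ, np.zeros((data.n_subjects, q)))
    rows = []
    for i in range(data.n_subjects):
        for j in range(J_obs):
            if not engine.mask[i, j]:
                continue
            rows.append(
                (
                    data.ids[i],
                    data.t[i, j],
                    TISSUE if data.tissue[i, j] else SERUM,
                    data.y[i, j],
                    pred[i, j],
                    f[i, j],
                    z[i, j],
                )
            )
    return pd.DataFrame(rows, columns=["id", "time", "channel", "dv", "pred", "ipred", "cwres"])


@dataclass
class VPCResult:
    """Prediction-corrected VPC summary for one observation channel."""

    channel: str
    bin_edges: np.ndarray  # (B+1,)
    bin_mid: np.ndarray  # (B,)
    observed: np.ndarray  # (B, 3) percentiles 2.5/50/97.5 of pc-observed
    ci_lower: np.ndarray  # (B, 3) lower 95% band of each simulated percentile
    ci_upper: np.ndarray  # (B, 3)
    n_replicates: int
    percentiles: tuple[float, ...] = (2.5, 50.0, 97.5)

    @property
    def coverage(self) -> float:
        """Fraction of (bin x percentile) cells with the observed value in the CI."""
        inside = (self.observed >= self.ci_lower) & (self.observed <= self.ci_upper)
        return float(inside.mean())


def pcvpc(
    dataset,
    fit_result: FitResult,
    n_rep: int = 1000,
    bins: int = 6,
    seed: int = 0,
    channel: str = SERUM,
) -> VPCResult:
    """Prediction-corrected visual predictive check.

    Simulates ``n_rep`` replicates of the dataset design from the fitted
    model, applies the prediction correction within time bins (quantile
    bins of the observed times) and compares observed percentiles with the
    95% confidence bands of the simulated percentiles.  Deterministic for a
    fixed seed.
    """
    data, engine = _engine_for(dataset, fit_result)
    est = fit_result.estimates
    q = engine.param.n_eta
    chan_mask = engine.mask & (data.tissue if channel == TISSUE else ~data.tissue)
    if not chan_mask.any():
        raise ValueError(f"no observations on channel {channel!r}")
    typ = engine.typical_params(est)
    pred = engine.predict(typ, np.zeros((data.n_subjects, q)))

    times = data.t[chan_mask]
    y_obs = data.y[chan_mask]
    pred_flat = pred[chan_mask]

    edges = np.quantile(times, np.linspace(0, 1, bins + 1))
    edges = np.unique(edges)
    if len(edges) < 2:
        edges = np.array([times.min(), times.max() + 1e-9])
    if len(edges) - 1 < bins:
        warnings.warn("empty or degenerate time bins merged", RuntimeWarning, stacklevel=2)
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    bin_idx = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    # duplicate-heavy designs (e.g. a fixed redosing time) can leave empty
    # bins after the quantile cut; merge them away by relabelling
    occupied = np.unique(bin_idx)
    if len(occupied) < len(edges) - 1:
        warnings.warn("empty time bins merged with neighbors", RuntimeWarning, stacklevel=2)
        remap = {b: k for k, b in enumerate(occupied)}
        bin_idx = np.array([remap[b] for b in bin_idx])
        edges = np.concatenate([[edges[0]], edges[occupied + 1]])
    n_bins = len(edges) - 1

    # prediction correction factor per observation: median PRED in bin / PRED
    corr = np.empty_like(pred_flat)
    for b in range(n_bins):
        sel = bin_idx == b
        corr[sel] = np.median(pred_flat[sel]) / pred_flat[sel]

    pcs = (2.5, 50.0, 97.5)

    def bin_percentiles(values: np.ndarray) -> np.ndarray:
        out = np.empty((n_bins, len(pcs)))
        for b in range(n_bins):
            sel = bin_idx == b
            out[b] = np.percentile(values[sel], pcs)
        return out

    observed = bin_percentiles(y_obs * corr)

    rng = np.random.default_rng(seed)
    omega = engine._omega_vec(est) if q else np.zeros(0)
    sim_stats = np.empty((n_rep, n_bins, len(pcs)))
    chunk = max(1, int(2e6 // max(1, data.y.size)))
    done = 0
    while done < n_rep:
        m = min(chunk, n_rep - done)
        eta = rng.standard_normal((m, data.n_subjects, q)) * omega[None, None, :]
        f = engine.predict(typ, eta)
        v = engine.resid_var(est, f)
        ysim = f + np.sqrt(v) * rng.standard_normal(f.shape)
        ysim_flat = ysim[:, chan_mask]
        for r_i in range(m):
            sim_stats[done + r_i] = bin_percentiles(ysim_flat[r_i] * corr)
        done += m
    ci_lower = np.percentile(sim_stats, 2.5, axis=0)
    ci_upper = np.percentile(sim_stats, 97.5, axis=0)
    mids = 0.5 * (edges[:-1] + edges[1:])
    return VPCResult(
        channel=channel,
        bin_edges=edges,
        bin_mid=mids,
        observed=observed,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        n_replicates=n_rep,
    )


@dataclass
class BootstrapResult:
    """Summary of a nonparametric (subject-resampling) bootstrap."""

    table: pd.DataFrame  # index parameter, columns median / q2.5 / q97.5
    estimates: pd.DataFrame  # successful replicate estimates, one row each
    n_success: int
    n_total: int

    def median(self, name: str) -> float:
        return float(self.table.loc[name, "median"])


def bootstrap(
    dataset,
    structure: ModelStructure | None = None,
    n_rep: int = 1000,
    seed: int = 0,
    original_fit: FitResult | None = None,
    options: dict | None = None,
    method: str = "laplace",
) -> BootstrapResult:
    """Nonparametric bootstrap of the population parameters.

    Subjects are resampled with replacement to the original cohort size and
    the model is refitted to each replicate, warm-started at the original
    estimates.  A replicate is successful when the refit converged with a
    positive-definite objective Hessian; medians and empirical 2.5/97.5
    percentiles are reported over successful replicates.  Aborts when more
    than half of the replicates fail.
    """
    subjects = _subjects(dataset)
    structure = structure or ModelStructure.final()
    if original_fit is None:
        original_fit = fit(dataset, structure, compute_se=False, method=method)
    if not original_fit.converged:
        raise RuntimeError("original fit did not converge; bootstrap not meaningful")
    replicate_opts = {
        "rounds": 1, "use_powell": False, "maxiter": 25, "jac": "2-point",
        "det_retry": False,
    }
    replicate_opts.update(options or {})

    rng = np.random.default_rng(seed)
    n = len(subjects)
    records = []
    n_success = 0
    for rep in range(n_rep):
        idx = rng.integers(0, n, n)
        resampled = []
        for new_id, i in enumerate(idx, start=1):
            s = copy.copy(subjects[i])
            s = type(s)(new_id, s.covariates, list(s.doses), list(s.observations))
            resampled.append(s)
        try:
            fr = fit(
                resampled,
                structure,
                init=dict(original_fit.estimates),
                options=replicate_opts,
                compute_se=False,
                method=method,
            )
        except Exception:  # noqa: BLE001 - replicate failure is data
            continue
        if fr.converged and not fr.at_bound:
            n_success += 1
            records.append(fr.estimates)
    if n_success < n_rep / 2:
        raise RuntimeError(
            f"bootstrap aborted: only {n_success}/{n_rep} replicates succeeded"
        )
    est_df = pd.DataFrame.from_records(records)
    table = pd.DataFrame(
        {
            "median": est_df.median(),
            "q2.5": est_df.quantile(0.025),
            "q97.5": est_df.quantile(0.975),
        }
    )
    return BootstrapResult(table=table, estimates=est_df, n_success=n_success, n_total=n_rep)
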