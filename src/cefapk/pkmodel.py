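"""Two-compartment infusion kinetics for unbound cefazolin with a tissue partition link.

The structural model is a linear two-compartment disposition model with
zero-order (constant-rate) intravenous infusion input, parameterized by the
unbound clearance ``CL``, central volume ``Vc``, intercompartmental clearance
``Q`` and peripheral volume ``Vp``.  Concentrations at the surgical site
(periprostatic adipose tissue) are linked to the unbound central-compartment
concentration through a partition coefficient ``F_PA`` under a
rapid-equilibrium assumption; tissue µg/g is treated as mg/L via a tissue
specific gravity of 1.0.

Renal function drives clearance through a power covariate model on
creatinine clearance (Cockcroft–Gault), normalized to a reference of
69 mL/min:

    CL (L/h) = theta1 * (CLcr / 69) ** theta2

Between-subject variability is log-normal (exponential random effects) on
CL, Vc, Vp and F_PA; residual variability is proportional.  Units are fixed
package-wide: mg, L, h, mg/L.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PopulationParameters",
    "SubjectCovariates",
    "DoseEvent",
    "Observation",
    "SubjectRecord",
    "IndividualParameters",
    "FINAL_MODEL",
    "cockcroft_gault",
    "typical_cl",
    "apply_iiv",
    "conc_unbound",
    "conc_tissue",
]

SERUM = "serum_unbound"
TISSUE = "tissue"

#: relative gap below which the hybrid rate constants are treated as degenerate
_DEGENERATE_TOL = 1e-9


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, between-subject SDs and residual SD of the model.

    ``theta1``..``theta6`` are the structural fixed effects (typical unbound
    clearance, CLcr exponent, Vc, Q, Vp, F_PA).  ``omega_*`` are the SDs of
    the log-scale random effects and ``sigma_prop`` the proportional residual
    SD; both are reported elsewhere as percentages (100 x SD).
    """

    theta1: float  # typical unbound clearance, L/h
    theta2: float  # CLcr exponent, dimensionless (sign unconstrained)
    theta3: float  # central volume Vc, L
    theta4: float  # intercompartmental clearance Q, L/h
    theta5: float  # peripheral volume Vp, L
    theta6: float  # tissue partition coefficient F_PA, dimensionless
    omega_cl: float = 0.0
    omega_vc: float = 0.0
    omega_vp: float = 0.0
    omega_fpa: float = 0.0
    sigma_prop: float = 1e-8
    clcr_ref: float = 69.0  # covariate normalization constant, mL/min

    def __post_init__(self) -> None:
        for name in ("theta1", "theta3", "theta4", "theta5", "theta6", "clcr_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("omega_cl", "omega_vc", "omega_vp", "omega_fpa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma_prop <= 0:
            raise ValueError("sigma_prop must be strictly positive")

    @property
    def omegas(self) -> np.ndarray:
        """Random-effect SDs in canonical order (CL, Vc, Vp, F_PA)."""
        return np.array([self.omega_cl, self.omega_vc, self.omega_vp, self.omega_fpa])

    def as_estimates(self) -> dict[str, float]:
        """Flatten into the named-estimate dict used by the fitting layer."""
        return {
            "cl": self.theta1,
            "beta_cl_clcr": self.theta2,
            "vc": self.theta3,
            "q": self.theta4,
            "vp": self.theta5,
            "fpa": self.theta6,
            "omega_cl": self.omega_cl,
            "omega_vc": self.omega_vc,
            "omega_vp": self.omega_vp,
            "omega_fpa": self.omega_fpa,
            "sigma_prop": self.sigma_prop,
        }

    def with_(self, **kwargs) -> "PopulationParameters":
        return replace(self, **kwargs)


#: Reference parameter set of the unbound-cefazolin RARP model (final
#: covariate model; omegas/sigma are SDs on the log/proportional scale).
FINAL_MODEL = PopulationParameters(
    theta1=25.8,
    theta2=0.735,
    theta3=44.3,
    theta4=44.0,
    theta5=52.2,
    theta6=0.638,
    omega_cl=0.283,
    omega_vc=0.529,
    omega_vp=0.463,
    omega_fpa=0.450,
    sigma_prop=0.216,
    clcr_ref=69.0,
)


def cockcroft_gault(age: float, weight: float, scr: float) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft–Gault formula (male).

    Parameters
    ----------
    age : years
    weight : kg
    scr : serum creatinine, mg/dL
    """
    if age <= 0 or weight <= 0 or scr <= 0:
        raise ValueError("age, weight and serum creatinine must be positive")
    if age >= 140:
        raise ValueError("age >= 140 years gives a non-positive creatinine clearance")
    return (140.0 - age) * weight / (72.0 * scr)


@dataclass(frozen=True)
class SubjectCovariates:
    """Baseline covariates of one subject.

    ``clcr`` is derived by Cockcroft–Gault when not supplied.  ``albumin``
    (g/L) and ``bilirubin`` (µmol/L) default to the study-population medians
    and only matter for covariate screening.
    """

    age: float  # years
    weight: float  # kg
    serum_creatinine: float  # mg/dL
    clcr: float | None = None  # mL/min
    albumin: float = 32.0  # g/L
    bilirubin: float = 17.1  # µmol/L

    def __post_init__(self) -> None:
        for name in ("age", "weight", "serum_creatinine", "albumin", "bilirubin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.clcr is None:
            object.__setattr__(
                self, "clcr", cockcroft_gault(self.age, self.weight, self.serum_creatinine)
            )
        elif self.clcr <= 0:
            raise ValueError("clcr must be strictly positive")


@dataclass(frozen=True)
class DoseEvent:
    """A zero-order intravenous infusion."""

    start_time: float  # h
    amount: float  # mg
    infusion_duration: float  # h

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ValueError("amount must be non-negative")
        if self.infusion_duration <= 0:
            raise ValueError("infusion_duration must be strictly positive")

    @property
    def rate(self) -> float:
        """Infusion rate, mg/h."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class Observation:
    """A timed concentration observation on one channel.

    ``channel`` is ``"serum_unbound"`` (unbound serum, mg/L) or ``"tissue"``
    (periprostatic adipose tissue, µg/g == mg/L at density 1.0).
    """

    time: float  # h since start of first infusion
    value: float  # mg/L
    channel: str = SERUM
    below_lloq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("observation time must be non-negative")
        if self.value < 0:
            raise ValueError("observed concentration must be non-negative")
        if self.channel not in (SERUM, TISSUE):
            raise ValueError(f"unknown channel {self.channel!r}")


@dataclass
class SubjectRecord:
    """One subject: covariates, dosing history and observations."""

    subject_id: int
    covariates: SubjectCovariates
    doses: list[DoseEvent]
    observations: list[Observation]

    def __post_init__(self) -> None:
        starts = [d.start_time for d in self.doses]
        if starts != sorted(starts):
            raise ValueError("dose events must be sorted by start_time")
        n_tissue = sum(1 for o in self.observations if o.channel == TISSUE)
        if n_tissue > 1:
            raise ValueError(
                f"subject {self.subject_id}: tissue observations at a single time only"
            )


@dataclass(frozen=True)
class IndividualParameters:
    """Subject-level disposition parameters after covariates and IIV."""

    cl: float  # L/h
    vc: float  # L
    q: float  # L/h
    vp: float  # L
    fpa: float  # dimensionless

    def __post_init__(self) -> None:
        for name in ("cl", "vc", "q", "vp", "fpa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def typical_cl(theta1: float, theta2: float, clcr: float, clcr_ref: float = 69.0) -> float:
    """Typical unbound clearance at a given creatinine clearance (power model)."""
    if clcr <= 0:
        raise ValueError("clcr must be strictly positive")
    return theta1 * (clcr / clcr_ref) ** theta2


def apply_iiv(pop: PopulationParameters, clcr: float, eta) -> IndividualParameters:
    """Individual parameters from population values, covariate and random effects.

    ``eta`` is the 4-vector of log-scale random effects in the order
    (CL, Vc, Vp, F_PA); Q carries no between-subject variability.
    """
    eta = np.asarray(eta, dtype=float)
    if eta.shape != (4,) or not np.all(np.isfinite(eta)):
        raise ValueError("eta must be a finite 4-vector (CL, Vc, Vp, F_PA)")
    return IndividualParameters(
        cl=typical_cl(pop.theta1, pop.theta2, clcr, pop.clcr_ref) * np.exp(eta[0]),
        vc=pop.theta3 * np.exp(eta[1]),
        q=pop.theta4,
        vp=pop.theta5 * np.exp(eta[2]),
        fpa=pop.theta6 * np.exp(eta[3]),
    )


# ---------------------------------------------------------------------------
# vectorized closed-form concentration kernels
# ---------------------------------------------------------------------------


def hybrid_rate_constants(cl, vc, q, vp):
    """Hybrid rate constants (alpha, beta) and k21 of the two-compartment model.

    alpha and beta are the roots of x^2 - (k10+k12+k21) x + k10*k21 = 0.
    beta is computed as (k10*k21)/alpha, which is numerically stable when the
    roots are well separated; a coincident-root configuration (measure zero in
    the parameter space) is perturbed by 1e-9 relative with a warning.
    """
    cl, vc, q, vp = (np.asarray(a, dtype=float) for a in (cl, vc, q, vp))
    k10 = cl / vc
    k12 = q / vc
    k21 = q / vp
    s = k10 + k12 + k21
    prod = k10 * k21
    disc = np.sqrt(np.maximum(s * s - 4.0 * prod, 0.0))
    alpha = 0.5 * (s + disc)
    beta = prod / alpha
    degenerate = (alpha - beta) <= _DEGENERATE_TOL * alpha
    if np.any(degenerate):
        warnings.warn(
            "degenerate hybrid rate constants (alpha == beta); "
            "perturbing alpha by 1e-9 relative",
            RuntimeWarning,
            stacklevel=2,
        )
        alpha = np.where(degenerate, alpha * (1.0 + 1e-9), alpha)
        beta = prod / alpha
    return alpha, beta, k21


def profile_2cpt(t, cl, vc, q, vp, dose_start, dose_amt, dose_dur):
    """Central-compartment concentration (mg/L) under superposed infusions.

    Broadcasting layout: ``t`` has shape (..., J); the disposition parameter
    arrays broadcast against (..., 1); the dose arrays have shape (..., D).
    The infusion interval is half-open, [start, start + duration).
    """
    t = np.asarray(t, dtype=float)
    params = [np.asarray(a, dtype=float)[..., None] for a in (cl, vc, q, vp)]
    alpha, beta, k21 = hybrid_rate_constants(*params)
    vc_b = params[1]
    denom = vc_b * (alpha - beta)
    coef_a = (alpha - k21) / denom / alpha
    coef_b = (k21 - beta) / denom / beta

    dose_start, dose_amt, dose_dur = (
        np.asarray(a, dtype=float) for a in (dose_start, dose_amt, dose_dur)
    )
    conc = np.zeros(np.broadcast_shapes(t.shape, alpha.shape), dtype=float)
    for d in range(dose_start.shape[-1]):
        start = dose_start[..., d : d + 1]
        dur = dose_dur[..., d : d + 1]
        rate = dose_amt[..., d : d + 1] / dur
        tau = t - start
        run = np.clip(tau, 0.0, dur)  # time infused so far
        decay = np.maximum(tau - dur, 0.0)  # time since end of infusion
        conc = conc + rate * (
            coef_a * -np.expm1(-alpha * run) * np.exp(-alpha * decay)
            + coef_b * -np.expm1(-beta * run) * np.exp(-beta * decay)
        )
    return conc


def profile_1cpt(t, cl, v, dose_start, dose_amt, dose_dur):
    """One-compartment analogue of :func:`profile_2cpt` (used for model comparison)."""
    t = np.asarray(t, dtype=float)
    cl = np.asarray(cl, dtype=float)[..., None]
    v = np.asarray(v, dtype=float)[..., None]
    k = cl / v
    dose_start, dose_amt, dose_dur = (
        np.asarray(a, dtype=float) for a in (dose_start, dose_amt, dose_dur)
    )
    conc = np.zeros(np.broadcast_shapes(t.shape, k.shape), dtype=float)
    for d in range(dose_start.shape[-1]):
        start = dose_start[..., d : d + 1]
        dur = dose_dur[..., d : d + 1]
        rate = dose_amt[..., d : d + 1] / dur
        tau = t - start
        run = np.clip(tau, 0.0, dur)
        decay = np.maximum(tau - dur, 0.0)
        conc = conc + rate / (k * v) * -np.expm1(-k * run) * np.exp(-k * decay)
    return conc


def _dose_arrays(doses: list[DoseEvent]):
    if not doses:
        return (np.zeros((1, 1)), np.zeros((1, 1)), np.ones((1, 1)))
    return (
        np.array([[d.start_time for d in doses]]),
        np.array([[d.amount for d in doses]]),
        np.array([[d.infusion_duration for d in doses]]),
    )


def conc_unbound(ind: IndividualParameters, doses: list[DoseEvent], t) -> float | np.ndarray:
    """Unbound central-compartment concentration (mg/L) at time(s) ``t``."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    starts, amts, durs = _dose_arrays(doses)
    out = profile_2cpt(
        t_arr[None, :], [ind.cl], [ind.vc], [ind.q], [ind.vp], starts, amts, durs
    )[0]
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def conc_tissue(c_unbound, fpa: float):
    """Periprostatic-tissue concentration from unbound serum concentration.

    Rapid-equilibrium partition: tissue = F_PA * unbound serum.
    """
    c = np.asarray(c_unbound, dtype=float)
    if np.any(c < 0):
        raise ValueError("unbound concentration must be non-negative")
    out = fpa * c
    return float(out) if np.ndim(c_unbound) == 0 else out
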