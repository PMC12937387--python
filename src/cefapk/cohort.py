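"""Synthetic cohort generator emulating the RARP cefazolin study design.

Reproduces the sampling design of the source cohort: 67 men undergoing
robotic-assisted radical prostatectomy, weight-based 1 g / 2 g cefazolin
10-min infusions with intraoperative redosing every 3 h, ~4 timed unbound
serum samples (incision, prostate removal, redosing, skin closure) plus
exactly one periprostatic adipose tissue sample at prostate removal,
log-normal between-subject variability and proportional residual error,
LLOQ 0.5 mg/L.  Covariates are drawn from log-normal distributions
calibrated to the cohort's median/IQR summaries; creatinine clearance is
derived by Cockcroft–Gault, never sampled independently.

Every stochastic operation takes an explicit integer seed; there is no
hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pkmodel import (
    SERUM,
    TISSUE,
    DoseEvent,
    Observation,
    PopulationParameters,
    SubjectCovariates,
    SubjectRecord,
    apply_iiv,
    conc_unbound,
)

__all__ = [
    "COVARIATE_QUARTILES",
    "StudyDesign",
    "SyntheticDataset",
    "sample_covariates",
    "build_dosing",
    "simulate_dataset",
]

#: cohort calibration targets: covariate -> (median, q25, q75)
COVARIATE_QUARTILES: dict[str, tuple[float, float, float]] = {
    "age": (69.0, 63.0, 73.0),  # years
    "weight": (67.2, 60.4, 74.2),  # kg
    "serum_creatinine": (0.92, 0.83, 1.06),  # mg/dL
    "albumin": (32.0, 30.0, 34.0),  # g/L
    "bilirubin": (17.1, 13.7, 23.1),  # µmol/L
}

#: standard-normal 75th percentile; IQR of a log-normal spans 2*0.6745 log-SDs
_Z75 = 0.6744897501960817


@dataclass(frozen=True)
class StudyDesign:
    """Dosing and sampling design constants of the emulated study."""

    n_subjects: int = 67
    weight_cutoff: float = 80.0  # kg; >= cutoff receives the high dose
    dose_low: float = 1000.0  # mg
    dose_high: float = 2000.0  # mg
    infusion_duration: float = 10.0 / 60.0  # h
    redose_interval: float = 3.0  # h
    surgery_duration_range: tuple[float, float] = (3.4, 4.8)  # h
    incision_window: tuple[float, float] = (0.25, 0.75)  # h after dose start
    removal_window: tuple[float, float] = (1.5, 3.0)  # h; prostate removal
    lloq: float = 0.5  # mg/L
    covariate_quartiles: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(COVARIATE_QUARTILES)
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.lloq <= 0:
            raise ValueError("lloq must be strictly positive")
        if self.surgery_duration_range[0] > self.surgery_duration_range[1]:
            raise ValueError("surgery_duration_range must be ordered")


@dataclass
class SyntheticDataset:
    """A simulated cohort together with its generating truth."""

    subjects: list[SubjectRecord]
    seed: int
    true_params: PopulationParameters
    true_etas: np.ndarray  # (n_subjects, 4): CL, Vc, Vp, F_PA
    design: StudyDesign

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)


def _lognormal_from_quartiles(median: float, q25: float, q75: float, rng, n: int):
    sigma = np.log(q75 / q25) / (2.0 * _Z75)
    return np.exp(np.log(median) + sigma * rng.standard_normal(n))


def sample_covariates(
    n: int, seed: int, quartiles: dict[str, tuple[float, float, float]] | None = None
) -> list[SubjectCovariates]:
    """Draw ``n`` covariate vectors calibrated to the cohort median/IQR.

    Each covariate is log-normal with median equal to the cohort median and
    log-SD ln(q75/q25) / (2 * 0.6745); covariates are sampled independently.
    CLcr is derived by Cockcroft–Gault from age, weight and serum creatinine.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    quartiles = quartiles or COVARIATE_QUARTILES
    rng = np.random.default_rng(seed)
    draws = {
        name: _lognormal_from_quartiles(*quartiles[name], rng, n)
        for name in ("age", "weight", "serum_creatinine", "albumin", "bilirubin")
    }
    return [
        SubjectCovariates(
            age=draws["age"][i],
            weight=draws["weight"][i],
            serum_creatinine=draws["serum_creatinine"][i],
            albumin=draws["albumin"][i],
            bilirubin=draws["bilirubin"][i],
        )
        for i in range(n)
    ]


def build_dosing(
    weight: float, surgery_duration: float, design: StudyDesign | None = None
) -> list[DoseEvent]:
    """Weight-based prophylaxis schedule: first dose at t=0, redoses every 3 h.

    Subjects under the 80 kg cutoff receive 1 g, others 2 g, as a 10-min
    infusion; an identical redose is given at each multiple of the redosing
    interval that falls strictly before the end of surgery.
    """
    if weight <= 0:
        raise ValueError("weight must be strictly positive")
    design = design or StudyDesign()
    amount = design.dose_high if weight >= design.weight_cutoff else design.dose_low
    doses = [DoseEvent(0.0, amount, design.infusion_duration)]
    t = design.redose_interval
    while t < surgery_duration:
        doses.append(DoseEvent(t, amount, design.infusion_duration))
        t += design.redose_interval
    return doses


def _noisy(value: float, sigma: float, rng) -> float:
    """Proportional residual error y = f*(1+eps); non-positive draws are redrawn."""
    if sigma == 0.0 or value == 0.0:
        return value
    for _ in range(1000):
        y = value * (1.0 + sigma * rng.standard_normal())
        if y > 0.0:
            return y
    raise RuntimeError("could not draw a positive observation")


def simulate_dataset(
    pop: PopulationParameters | None = None,
    design: StudyDesign | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate one cohort under the study design.

    Per subject: covariates from the calibrated log-normals; surgery duration
    uniform over the design range; doses from :func:`build_dosing`; serum
    samples at incision, prostate removal, redosing (surgeries >= 3 h) and
    skin closure; one tissue sample at prostate removal; random effects
    eta ~ N(0, diag(omega^2)); proportional residual error applied
    independently per observation on both channels; values below the LLOQ are
    retained but flagged ``below_lloq``.
    """
    from .pkmodel import FINAL_MODEL

    pop = pop or FINAL_MODEL
    design = design or StudyDesign()
    n = design.n_subjects
    rng = np.random.default_rng(seed)
    cov_seed = int(rng.integers(2**31))
    covariates = sample_covariates(n, cov_seed, design.covariate_quartiles)

    etas = rng.standard_normal((n, 4)) * pop.omegas[None, :]
    subjects: list[SubjectRecord] = []
    for i in range(n):
        cov = covariates[i]
        surgery = rng.uniform(*design.surgery_duration_range)
        doses = build_dosing(cov.weight, surgery, design)
        t_incision = rng.uniform(*design.incision_window)
        t_removal = rng.uniform(*design.removal_window)
        serum_times = [t_incision, t_removal]
        if surgery >= design.redose_interval:
            serum_times.append(design.redose_interval)
        serum_times.append(surgery)
        serum_times.sort()

        ind = apply_iiv(pop, cov.clcr, etas[i])
        obs: list[Observation] = []
        for t in serum_times:
            c = float(conc_unbound(ind, doses, float(t)))
            y = _noisy(c, pop.sigma_prop, rng)
            obs.append(Observation(float(t), y, SERUM, below_lloq=y < design.lloq))
        c_tis = ind.fpa * float(conc_unbound(ind, doses, float(t_removal)))
        y_tis = _noisy(c_tis, pop.sigma_prop, rng)
        obs.append(Observation(float(t_removal), y_tis, TISSUE, below_lloq=y_tis < design.lloq))
        obs.sort(key=lambda o: (o.time, o.channel))
        subjects.append(SubjectRecord(i + 1, cov, doses, obs))

    return SyntheticDataset(subjects, seed, pop, etas, design)
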