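# cefapk

Population pharmacokinetics of **unbound and periprostatic adipose tissue
cefazolin** for surgical antibiotic prophylaxis in robotic-assisted radical
prostatectomy (RARP).

Cefazolin is the standard prophylactic antibiotic for prostatectomy, dosed
1 g (2 g if ≥ 80 kg) with intra-operative redosing every 3 h. Because only
the unbound fraction is microbiologically active and the surgical site is
the fat surrounding the prostate, the question that matters clinically is:
*for how long after a dose do unbound serum and periprostatic-tissue
concentrations stay above the MIC of the likely pathogen (MSSA, MIC90
0.5 mg/L) — and how does that depend on renal function?*

`cefapk` implements the full analysis pipeline around that question:

- **Structural model** — two-compartment disposition with zero-order
  infusion input (closed-form superposition solution), parameterized by
  unbound clearance CL, central volume V_c, intercompartmental clearance Q
  and peripheral volume V_p. Tissue concentrations are linked by a
  rapid-equilibrium partition coefficient, C_tissue = F_PA · C_unbound
  (tissue µg/g ≡ mg/L at specific gravity 1.0).
- **Covariate model** — renal function drives clearance through a power
  model on Cockcroft–Gault creatinine clearance:

  CL (L/h) = θ₁ · (CLcr / 69)^θ₂,  with reference estimates
  θ₁ = 25.8 L/h, θ₂ = 0.735, V_c = 44.3 L, Q = 44.0 L/h, V_p = 52.2 L,
  F_PA = 0.638 (`cefapk.FINAL_MODEL`).
- **Mixed-effects estimation** — log-normal between-subject variability on
  CL, V_c, V_p and F_PA, proportional residual error, and an approximate
  marginal likelihood evaluated at per-subject conditional modes (Laplace
  by default; FOCE-with-interaction and adaptive Gauss–Hermite as options).
  AIC-based structural comparison and the classic stepwise covariate
  procedure (ΔOFV > 3.84 forward, < 6.63 backward).
- **Qualification** — conditional weighted residuals (CWRES),
  prediction-corrected visual predictive checks, nonparametric
  subject-resampling bootstrap.
- **Dosing simulation** — Monte Carlo probability of target attainment
  (PTA): fraction of virtual patients whose trough concentration still
  exceeds the MIC at candidate redosing times, across a CLcr grid.
- **Synthetic cohorts** — a generator that emulates the study design (67
  men, weight-based dosing, timed intra-operative sampling plus one tissue
  sample each, LLOQ 0.5 mg/L), so every stage is testable end to end.

## Worked example

```python
import numpy as np
from cefapk import FINAL_MODEL, DoseEvent, PTAConfig, apply_iiv, conc_unbound, simulate_pta
from cefapk.pkmodel import SERUM

typical = apply_iiv(FINAL_MODEL, clcr=69.0, eta=np.zeros(4))
doses = [DoseEvent(0.0, 1000.0, 1/6), DoseEvent(3.0, 1000.0, 1/6)]
print(round(conc_unbound(typical, doses, 3.0), 2))   # trough before redose

grid = simulate_pta(FINAL_MODEL, PTAConfig(seed=42))
serum = grid.probability[SERUM]
i5 = list(grid.times).index(5.0)
print(round(serum[grid.clcr <= 80, i5].min(), 3))
```

prints

```
3.72
0.988
```

The first number is the typical unbound trough (mg/L) at the 3 h redosing
time — 7.5× the MSSA MIC90, which is why the standard interval is safe for
typical renal function. The second is the *minimum* probability of target
attainment at 5 h across all CLcr ≤ 80 mL/min (1000 virtual patients per
grid point): mild renal impairment keeps >90% attainment out to 5 h, so the
3 h redose is conservative for that subgroup.

The `examples/` directory holds one narrative script per capability
(concentration profiles, simulate-and-refit, model qualification, PTA);
each prints what it computes and what the numbers mean. A thin CLI mirrors
the pipeline stages: `cefapk simulate | fit | select | bootstrap | vpc |
gof | pta`.

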