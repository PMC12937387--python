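# Methods

## Model

Unbound cefazolin disposition is a linear two-compartment model with
zero-order infusion input, written in clearance parameterization (CL, V_c,
Q, V_p; units mg, L, h, mg/L package-wide). Concentrations are evaluated
with the closed-form hybrid-constant solution: with k10 = CL/V_c,
k12 = Q/V_c, k21 = Q/V_p, the hybrid rates α, β are the roots of
x² − (k10+k12+k21)x + k10·k21 = 0; β is computed as (k10·k21)/α for
numerical stability, and a coincident-root configuration (measure zero) is
perturbed by 1e-9 relative with a warning. Multiple infusions superpose;
the infusion interval is half-open, [start, start + duration); t = 0 is the
start of the first infusion. A numba-compiled kernel duplicates this
closed form inside the likelihood engine and is cross-checked against both
the numpy reference and a stiff-ODE integration (tests demand < 0.1%
relative agreement at random parameter sets and schedules).

Periprostatic adipose tissue is modeled in rapid equilibrium with the
central compartment through a partition coefficient,
C_tissue = F_PA · C_unbound, with tissue µg/g treated as mg/L via a tissue
specific gravity of 1.0. No upper bound is placed on F_PA; log-normal
between-subject variability can push individual values above 1. Saturable
protein binding and carrier-mediated prostatic transport are out of scope:
beta-lactam penetration into adipose tissue is passive, and the one-sample-
per-subject tissue design cannot identify transfer rate constants anyway.

Renal function enters through a power covariate model on Cockcroft–Gault
creatinine clearance, CL = θ₁·(CLcr/69)^θ₂; 69 mL/min is the reference
(median) creatinine clearance of the study population. Between-subject
variability is exponential (log-normal) on CL, V_c, V_p and F_PA; the
variability on Q is fixed to zero in the final structure (estimating it is
supported, but with one distribution-phase sample per subject its variance
collapses toward zero and destabilizes the fit, which is why the final
model omits it). Residual error is proportional with a single SD shared by
the serum and tissue channels — an assumption, flagged as such, since the
data cannot separate two residual scales with 67 single tissue points.

Reference parameter set (`cefapk.FINAL_MODEL`): θ₁ = 25.8 L/h, θ₂ = 0.735,
V_c = 44.3 L, Q = 44.0 L/h, V_p = 52.2 L, F_PA = 0.638; ω_CL = 0.283,
ω_Vc = 0.529, ω_Vp = 0.463, ω_FPA = 0.450, σ_prop = 0.216. Here and in all
reports, ω and σ are SDs on the log/proportional scale; tabulated
percentages are 100·SD.

## Estimation

The marginal likelihood is approximated at per-subject conditional modes.
The inner problem (mode search) minimizes the joint −2 log density of each
subject's observations and random effects by a damped Newton iteration run
for the whole cohort at once, with gradient and full Hessian (including
cross terms) built from batched central finite differences; Gauss–Newton
curvature alone converges too slowly here because the proportional-error
"interaction" (residual variance depending on η through the prediction)
contributes materially to the curvature. Whenever a warm start is
supplied to a reference evaluation, the search is also run from the origin
and the deeper mode is kept per subject: with 4–5 observations and four
random effects the joint density can be multimodal, and committing to an
arbitrary basin would make the objective discontinuous in the population
parameters.

Three objective flavours share those modes:

- `laplace` (default): joint −2 log density at the mode plus ln|H/2| with
  the exact FD curvature H. Eigenvalues of H/2 are floored at 0.5/max(ω)²
  — the weakest curvature a genuine mode can have — which keeps ln|H|
  finite and continuous when a mode flattens without rewarding degeneracy.
- `foce`: the FOCE-with-interaction linearization
  (OFV_i = n_i ln 2π + ln|V| + r′V⁻¹r, V = JΩJ′ + Σ(η̂),
  r = y − f(η̂) + Jη̂). This is also the basis of CWRES.
- `agq`: adaptive Gauss–Hermite quadrature centered at the mode (3
  nodes/dimension by default) — the most accurate and the slowest.

Laplace was chosen as the fitting default after cross-checking all three
against high-order quadrature on study-sized cohorts: at this model's ω
magnitudes (0.28–0.53) the FOCE linearization misses by 1.5–2 OFV units
per 10 subjects — enough to displace optima along flat ridges — while
Laplace stays within a few tenths. The OFV includes the n·ln 2π constant;
software that omits it reports values lower by exactly that constant, which
cancels in every ΔOFV-based rule.

The outer problem runs on log-transformed parameters (positivity by
construction) inside plausibility boxes — clearances and volumes in
[0.5, 500], F_PA in [0.01, 10], ω ≤ 2, σ ≤ 1, power exponents in [−3, 3] —
chosen as wide physiological sanity limits for a renally cleared
cephalosporin, not as informative constraints. Optimization alternates
L-BFGS-B rounds (finite-difference gradients over warm-started
evaluations) with derivative-free Powell rounds, which are robust on the
flat CL/V_p ridges this sparse intra-operative design produces; every
round is accepted only if it improves a mode-seeded reference evaluation.
Fits start from a naive-pooled (no-IIV) stage unless initial estimates are
given. Convergence is declared when an optimizer terminates cleanly at or
within noise of the incumbent. Standard errors use the delta method on a
central FD Hessian with a deliberately coarse 2% step: the iterative mode
search leaves ~1e-3-level roughness in the objective, and finer steps
would amplify it past the curvature signal.

## Model building

Structural candidates (one- vs two-compartment, residual-error forms) are
ranked by AIC = OFV + 2k. The covariate procedure is the standard stepwise
screen: forward inclusion of the candidate with the largest OFV drop while
the drop exceeds 3.84 (χ², p < 0.05, 1 df; ties broken by fewer added
parameters, then covariate name), then backward elimination of any term
whose removal costs less than 6.63 (p < 0.01, 1 df), smallest first. The
default candidate set is power terms on CL for age, weight, bilirubin,
albumin, serum creatinine and CLcr; references for new terms are dataset
medians, while the shipped final structure pins CLcr's reference at
69 mL/min so estimates stay on the published scale.

## Synthetic cohorts

The generator reproduces the study conditions: 67 men; covariates drawn
from independent log-normals calibrated to the cohort's median/IQR
summaries (age 69 (63–73) y, weight 67.2 (60.4–74.2) kg, serum creatinine
0.92 (0.83–1.06) mg/dL, albumin 32 (30–34) g/L, bilirubin 17.1 (13.7–23.1)
µmol/L), with log-SD = ln(q75/q25)/(2·0.6745); CLcr derived by
Cockcroft–Gault, never sampled (accepting a ~4% systematic offset of its
median versus the summary table). Dosing is 1 g (< 80 kg) or 2 g (≥ 80 kg)
as a 10-min infusion at t = 0 with identical redoses every 3 h while
before the end of surgery; surgery duration is uniform on 3.4–4.8 h (the
typical operative range, implying nearly all subjects are redosed once).
Serum samples sit at incision (U(0.25, 0.75) h), prostate removal
(U(1.5, 3.0) h), the 3 h redosing time, and skin closure; one tissue
sample is taken at prostate removal — event-based sampling translated to
clock times consistent with induction-to-incision ≤ 1 h. That yields 4
serum samples/subject (268 per cohort, near the study's 295) plus 67
tissue samples. Proportional error is applied independently per
observation; non-positive draws are redrawn (negligible bias at σ = 0.216);
values below the 0.5 mg/L LLOQ are retained but flagged, and estimation
excludes them (M1) while reporting the count. Every stochastic operation
takes an explicit seed.

What the generator does not emulate: covariate correlations (none are
published), assay-specific error structure beyond the proportional model,
within-subject variability in redose timing, or dropout — so passing
recovery tests demonstrate the estimator works under the *assumed*
statistical model at the study's design and size, not robustness to
real-data violations of it.

A caution from our own simulation work: at this design (4–5 samples inside
a ≤ 5 h surgical window, distribution phase barely covered), single-cohort
maximum-likelihood estimates scatter widely along a CL/V_p trade-off ridge
— cross-checks with 15-node quadrature confirm the exact likelihood itself
prefers displaced optima on some cohorts. Averages over several simulated
cohorts are needed before estimates stabilize near the generating values,
and central-volume means can still sit 10–20% low. This mirrors the wide
bootstrap intervals of the original analysis and is a property of the
design, not of the optimizer.

## Qualification

CWRES uses the FOCE linearization at the conditional modes,
CWRES = L⁻¹(y − f(η̂) + Jη̂) with L the lower Cholesky factor of
JΩJ′ + Σ(η̂); observations are put in canonical time order first because
Cholesky whitening is sequence-sensitive. The pc-VPC applies the usual
prediction correction (observation × bin-median PRED / PRED) within six
quantile time bins (empty bins from the fixed 3 h redosing time are merged
with neighbors), and compares observed 2.5/50/97.5 percentiles with 95%
bands over simulated replicates; serum and tissue channels are checked
separately. The bootstrap resamples subjects with replacement to the
original cohort size and refits with a reduced optimizer budget
warm-started at the original estimates; a replicate succeeds if it
converges with every parameter interior to its bounds (a bound-pinned
replicate is the analogue of a failed covariance step — a finite-difference
positive-definiteness check proved noise-dominated at replicate budgets and
was abandoned). Because replicates are warm-started and budget-limited,
bootstrap medians are accurate but interval widths can understate those of
a full-refit bootstrap on this flat-ridged likelihood. GOF plots add LOESS
trend lines (span 0.75) as a visual aid only.

## PTA simulation

For each CLcr on a 5–120 mL/min grid (5 mL/min steps), 1000 virtual
patients per grid point receive a single 1 g dose over 15 min (the
simulation scenario; the estimation design uses the study's 10-min
infusions), random effects are drawn on CL, V_c, V_p and F_PA, and the
unbound and tissue concentrations are evaluated at 3, 5, 6, 9 and 12 h.
PTA is the fraction of patients above the 0.5 mg/L MSSA MIC90. Residual
(assay) error is excluded — the pharmacodynamic target concerns true
exposure — with an `include_residual` toggle for sensitivity checks. The
formal target is concentration > MIC for ≥ 90% of the dosing interval;
because concentration declines monotonically after this short infusion,
the end-of-interval trough is the binding check (the sub-MIC run-up during
a 15-min infusion occupies < 10% of every interval considered). Headline
claims are evaluated on the unbound-serum channel with the tissue channel
reported alongside. Monte Carlo SE at n = 1000 and p ≈ 0.9 is ≈ 0.0095.

## Problem sizes used in the shipped checks

Parameter recovery averages 8 simulated cohorts of 67 subjects; the
bootstrap check runs 200 replicates (the full analysis used 1000); the
pc-VPC uses 400 replicates; the null-covariate (type-I) screen uses a
handful of replicate datasets with the CLcr candidate only. These sizes
were chosen so the whole verification suite completes in tens of minutes
on one CPU while keeping Monte Carlo error well inside the tolerances the
checks assert.

## Known limitations

- The likelihood approximations (Laplace/FOCE) are approximations;
  bit-level agreement with any other mixed-effects implementation is not
  claimed, only statistical equivalence demonstrated through recovery and
  quadrature-oracle tests.
- Ω is diagonal; covariances between random effects are not estimable from
  this design and are not implemented.
- M3-style likelihood treatment of below-LLOQ data is not implemented
  (M1 exclusion only), and BLQ observations are rare under the reference
  parameters.
- The bootstrap success rule and the coarse-step SE Hessian are pragmatic
  responses to evaluation noise; both are documented above and in the
  result objects.
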