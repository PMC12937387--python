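"""Qualify a fitted model: CWRES, prediction-corrected VPC and bootstrap.

Fits a synthetic cohort, then (1) checks that conditional weighted
residuals are ~N(0,1), (2) runs a pc-VPC and reports how many observed
percentile cells fall inside the simulated 95% bands, and (3) runs a small
subject-resampling bootstrap for parameter uncertainty.  Plots are written
next to this script.  Takes a few minutes (dominated by the bootstrap).
"""

from cefapk import ModelStructure, bootstrap, cwres, fit, pcvpc, simulate_dataset
from cefapk.plots import gof_plots, vpc_plot

cohort = simulate_dataset(seed=7)
result = fit(cohort, ModelStructure.final(), compute_se=False)
print(f"fit converged: {result.converged}, OFV {result.ofv:.1f}")

table = cwres(cohort, result)
print(f"CWRES over {len(table)} observations: mean {table.cwres.mean():+.3f}, "
      f"variance {table.cwres.var():.3f}  (well-specified model: ~0 and ~1)")
gof_plots(table, path="gof_panels.png")

vpc = pcvpc(cohort, result, n_rep=400, seed=1)
print(f"pc-VPC: {100 * vpc.coverage:.0f}% of percentile cells inside the "
      f"simulated 95% bands ({vpc.n_replicates} replicates)")
vpc_plot(vpc, path="pcvpc.png")

boot = bootstrap(cohort, ModelStructure.final(), n_rep=50, seed=2, original_fit=result)
print(f"bootstrap: {boot.n_success}/{boot.n_total} replicates successful")
row = boot.table.loc["cl"]
print(f"unbound clearance: median {row['median']:.1f} "
      f"(95% CI {row['q2.5']:.1f}-{row['q97.5']:.1f}) L/h")
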