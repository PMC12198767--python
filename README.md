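# connres

Virtual-lesion resilience analysis of functional brain connectomes.

After a first stroke, functional brain networks reorganize, and one
hypothesis is that the reorganization makes them *more resilient* to
recurrent lesions. Because recurrent strokes cannot be observed on demand,
resilience is probed in silico: atlas regions overlapping real stroke
lesion masks are deleted from each subject's connectivity matrix, and the
network's integrative and modular character is compared before and after
the deletion. `connres` is a tested, reusable implementation of that whole
analysis for researchers in network neuroscience: preprocessing of region
time series into Pearson connectomes, lesion-mask-to-region mapping,
binary graph metrics over a proportional-threshold density sweep, the
virtual attack battery, a participation-coefficient hub analysis, and the
group-level statistics — plus a synthetic-cohort generator so the entire
pipeline runs and is testable without access-restricted clinical data.

## The statistic

Each weighted connectome is thresholded (w > 0), binarized at densities
δ ∈ {0.1, …, 1.0} (the δ·P strongest positive edges), and each graph
metric M — global efficiency E_glob, fixed-partition modularity Q, mean
clustering coefficient CC — is summarized by the area under its density
curve:

    AUC(M) = ∫₀¹ M(δ) dδ        (trapezoid; M(0) = 0 analytically)

A virtual attack deletes the regions of one lesion mask from the weighted
matrix; the matrix is re-thresholded and the AUCs recomputed. Resilience
of metric M is

    R(M)      = M_pre − M_post
    R_norm(M) = 1 − R(M) / mean(R_control(M))

so the control group averages exactly 0 and an attack that causes no
damage scores 1. Larger `R_norm` = more resilient. Nodal participation
coefficients PC_i = 1 − Σ_s (k_is/k_i)² identify hubs (the 10 highest-PC
nodes in controls); the analysis asks whether patients' hubs lose PC while
their lowest-PC nodes gain it, and whether that redistribution tracks
resilience.

## Worked example

```python
from connres import CohortSpec, build_cohort, run_attack_battery
from connres.hub_analysis import build_pc_table, rank_nodes_by_control_pc

spec = CohortSpec(n_patients=20, n_controls=10, n_nodes=60, n_modules=8,
                  lesion_count=30, hub_fraction=0.15, seed=7)
cohort = build_cohort(spec)          # subjects, connectomes, lesion library
battery = run_attack_battery(cohort)

out = battery.outcomes               # subject x timepoint x mask x metric
for group in ("control", "patient"):
    sub = out[(out.group == group)
              & (out.metric == "global_efficiency") & ~out.excluded]
    print(f"mean R_norm(E_glob) {group:8s} {sub.r_norm.mean():+.3f}  (n={len(sub)})")

pc = build_pc_table(cohort)
top, bottom = rank_nodes_by_control_pc(pc)
```

prints

```
mean R_norm(E_glob) control  -0.000  (n=300)
mean R_norm(E_glob) patient  +0.325  (n=1585)
```

The control mean is 0 by construction (the normalization divides by the
mean control damage). The patient mean of +0.33 says virtual lesions cost
patients about a third less global-efficiency AUC than they cost controls:
the synthetic patients' connectomes de-concentrate their inter-module
shortcuts away from hub gateways (`hub_redistribution_patient = 3`), so no
single clustered deletion can sever a module. The same run shows the hub
signature — control hubs average PC 0.743 against 0.617 in patients, while
the anti-hub nodes rise from 0.530 to 0.564 — and 95 of the 1 680
patient-attack pairs were skipped because the mask fell inside the
patient's own primary lesion.

Each stage is also exposed on the command line via `connres
simulate-cohort`, `build-connectome`, `map-lesions`, `graph-metrics`,
`run-attacks`, `hub-analysis` and `stats-report`; see `connres --help`.

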