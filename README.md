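# placebonet

Graph-theoretical analysis of cortical-thickness covariance for placebo-response
phenotyping in multiple sclerosis trials.

## The problem

In a sham-controlled MS trial, a subset of patients reports a transient
improvement in health-related quality of life — a placebo response — while
showing no objective clinical change. `placebonet` implements a reusable,
fully tested version of the analysis chain used to ask whether the *structure*
of the cortex differs between placebo responders and non-responders:

1. **Response scoring.** Each participant's MSQOL-54 Physical Health composite
   is tracked over seven visits (baseline + 48 weeks). The response measure is
   the trapezoidal area under the trajectory, `AUC = ∫ PH(t) dt`, adjusted for
   the baseline score by OLS (higher baselines leave less room to improve).
   Standardized residuals > 0 define *responders*; ≤ 0 *non-responders*.
2. **Covariance networks.** Mean cortical thickness (CT) in 78 AAL cortical
   regions is residualized per region for total brain volume, age, sex,
   age×sex (plus disease duration, site and lesion load in patients). Within
   each group the 78×78 inter-regional Pearson matrix `R_ij` is binarized by
   keeping the top fraction *s* of region pairs ("sparsity", 30 thresholds
   from 0.1 to 0.5), so every group graph has the same edge count
   `m = round(s·n(n−1)/2)`.
3. **Graph metrics.** On each binary graph: the clustering coefficient
   `C = (1/n) Σᵢ 2tᵢ/(kᵢ(kᵢ−1))`, the characteristic pathlength in its nodal
   inverse-distance form `Lᵢ = Σ_{j≠i} d_ij⁻¹/(n−1)` (well defined on
   disconnected graphs; a classic hop-count convention is also provided), and
   their normalized versions against the mean over 10 random networks with the
   same nodes and edges — yielding the small-world index
   `S = C_norm / L_norm`.
4. **Inference.** Group differences are tested against permutation nulls
   (1000 label shuffles over the fixed residual matrix, add-one two-sided p),
   with leave-one-out stability ribbons and Bonferroni α = 0.05/3 → 0.016
   across the three metric families. Region-level GLMs test the lesion-load ×
   group interaction on CT, with BH-FDR across the 78 regions.

A synthetic-cohort generator reproduces the statistical structure this
analysis assumes — group-specific correlation levels (median r ≈ 0.66 / 0.49
/ 0.41 for non-responders / responders / controls), a transient QoL gain in
responders only, and lesion-load-dependent thinning in non-responders only —
so the entire pipeline runs and is testable without any real MRI data.

## Worked example

```python
import numpy as np
from placebonet import (CohortSpec, CovarianceNetworkModel,
                        PlaceboResponseModel, simulate_study)

cohort, ct, qol = simulate_study(CohortSpec(seed=2))

scores = PlaceboResponseModel(qol).fit()
print(scores.summary())

model = CovarianceNetworkModel.from_raw(ct, cohort)
result = model.fit(grid=np.array([0.43]), n_perm=1000, seed=2,
                   compare=[("nonresponder", "responder")], loo=False)
print(result.summary())
```

prints

```
Placebo response scoring (AUC of MSQOL-54 PH, baseline-adjusted)
================================================================
subjects scored: 88   excluded (<2 visits): 0
baseline adjustment: slope=44.29 (SE 1.4, t=31.6, p=3.86e-49, 95% CI [41.51, 47.08])
 nonresponder: n=43  residual mean=-0.84  SD=0.56
    responder: n=45  residual mean=+0.80  SD=0.58

Cortical-thickness covariance network comparison
================================================================
reporting sparsity: 0.43   Bonferroni alpha: 0.016 (3 metric families)

group correlation matrices:
   nonresponder: n=45  median r=0.64  range [0.19, 0.94]
      responder: n=43  median r=0.55  range [0.12, 0.89]
        control: n=43  median r=0.30  range [-0.33, 0.72]

metrics at sparsity 0.43:
   nonresponder: C=0.741  L=0.701  S=1.763
      responder: C=0.695  L=0.710  S=1.632
        control: C=0.626  L=0.713  S=1.460

permutation tests (two-sided, add-one):
        clustering nonresponder vs responder: diff=+0.045  p=0.0340 (n_perm=1000)
        pathlength nonresponder vs responder: diff=-0.009  p=0.0869 (n_perm=1000)
        smallworld nonresponder vs responder: diff=+0.129  p=0.0400 (n_perm=1000)
```

Reading this: the scoring stage splits the 88 simulated patients into
responders (mean standardized residual +0.80) and non-responders (−0.84); the
non-responder group's CT is more regionally homogeneous (median r 0.64 vs
0.55); at the 43 % reporting sparsity its network is more clustered
(C 0.741 vs 0.695) with a higher small-world index (S 1.76 vs 1.63), and the
permutation test puts that clustering and small-world excess at p ≈ 0.03–0.04
for this particular draw. Exact numbers vary from cohort to cohort — each
simulated study is one random draw of 45 + 43 patients.

The same stages are available from the shell:

```bash
placebonet simulate --outdir sim --seed 2
placebonet score-response --qol sim/qol.csv --out scores.tsv
placebonet run-all --simulate --outdir out --seed 2   # full pipeline
```

## Layout

| module | contents |
| --- | --- |
| `placebonet.synthetic` | cohort / CT / QoL generators (`CohortSpec`, `CovarianceStructureSpec`, `QoLEffectSpec`) |
| `placebonet.response` | AUC scoring, baseline adjustment, `PlaceboResponseModel` |
| `placebonet.network` | residualization, correlation matrices, sparsity thresholding |
| `placebonet.metrics` | C, L, random ensembles, small-world index |
| `placebonet.inference` | permutation tests, LOO stability, `CovarianceNetworkModel` |
| `placebonet.glm` | region-level CT models, `RegionalThicknessGLM` |
| `placebonet.pipeline` / `placebonet.cli` | orchestration, YAML config, console script |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
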