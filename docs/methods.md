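# Methods

This note documents the models, conventions and design choices behind
`placebonet`, in the spirit of a statistical package's methods appendix.

## Placebo-response scoring

The response measure is the composite trapezoidal AUC of the MSQOL-54
Physical Health score over the visit schedule (baseline + six follow-ups,
points·weeks). The AUC is computed on raw scores and then adjusted for the
baseline score by OLS with intercept; the residuals are standardized by
their unbiased (n−1) SD. Participants with standardized residuals strictly
greater than 0 are responders; residuals ≤ 0 (including exactly 0) are
non-responders. Conventions the source analysis leaves open, decided here:

* **Missing visits** are dropped pairwise and the trapezoid taken over the
  remaining nodes; subjects with fewer than two usable visits are scored
  missing and excluded with a warning.
* **Pooling**: the adjustment regression is fitted over the pooled patient
  sample (sham and active arms combined), not within arms.
* A **change-score mode** (`change_scores=True`) computes the AUC of
  change-from-baseline instead of raw scores, as a sensitivity analysis.
* Degenerate inputs: zero baseline variance falls back to centered,
  standardized AUCs (warning); zero *residual* variance (AUC an exact linear
  function of baseline) is an error, because standardization is undefined.

## Covariate residualization

Regional CT (78 AAL cortical regions) is residualized per region by OLS.
Patients (both placebo groups pooled, group label deliberately excluded so
group differences in covariance are not absorbed) get total brain volume,
age, sex, age×sex, disease duration, site indicators and a disease-burden
term — lesion load by default, omissible, or baseline EDSS substituted.
Controls are fitted separately with the demographic covariates only. The
age×sex product uses centered age so the main effects remain interpretable.
A per-group residualization mode exists (`model_scope="per-group"`); pooled
is the default. Constant covariate columns are dropped with a warning; true
rank deficiency is an error naming the collinear columns.

## Networks and graph metrics

Within each group the regions×regions Pearson matrix is computed across
subjects. Binarization keeps the top `m = round(s·n(n−1)/2)` region pairs by
**signed** correlation (the structural-covariance convention; an `absolute`
flag ranks by |r| instead), with ties broken lexicographically by region
index, which makes edge sets nested across increasing sparsity. Rounding is
half-away-from-zero. The default grid is 30 linearly spaced sparsities from
0.1 to 0.5; results are reported at s = 0.43 (1291 of 3003 edges), where the
input matrices are stable.

Metrics on the binary graph:

* **Clustering coefficient** `C = (1/n) Σᵢ 2tᵢ/(kᵢ(kᵢ−1))` with `Cᵢ = 0`
  for degree < 2. Isolated nodes stay in the denominator of the mean (the
  1/n is over all nodes).
* **Characteristic pathlength**: the default "as-printed" form is nodal
  inverse distance, `Lᵢ = Σ_{j≠i} d_ij⁻¹/(n−1)` with unreachable pairs
  contributing 0 — an efficiency-like quantity that is well defined on the
  disconnected graphs arising at low sparsity (larger values mean *shorter*
  paths). The "classic" convention (mean finite hop count over reachable
  ordered pairs) is computed alongside; comparisons must use one convention
  consistently.
* **Normalization**: `C_norm = C/C_rand`, `L_norm = L/L_rand`, with
  `C_rand`, `L_rand` simple means over an ensemble of 10 random networks
  with the same number of nodes and edges. The default ensemble is uniform
  G(n, m) (matching the "same nodes and edges" description); a
  degree-preserving double-edge-swap ensemble (`model="rewire"`, 10·m swap
  attempts) is provided because that is the convention of the usual brain
  connectivity toolboxes. Ensemble means carry standard errors so
  normalization noise is visible. **Small-world index** `S = C_norm/L_norm`.

Distances are exact BFS hop counts (computed by boolean matrix
multiplication level sets); triangle counts come from the adjacency matrix
product. Both are cross-checked in the test suite against exhaustive
enumeration on all graphs with up to six nodes and against networkx.

## Inference

Permutation tests shuffle subject group labels over the *fixed* residual
matrix (the covariate adjustment is not refit per permutation; a refit
variant would be stricter but the permuted quantity here is the input
matrix). Each permutation rebuilds both correlation matrices, re-thresholds,
and recomputes the metric with a fresh deterministic random-ensemble subseed
(seeds are SHA-256 hashes of the master seed and the permutation index, so
runs are reproducible and below 2³¹). The two-sided p-value uses the add-one
convention `p = (1 + #{|null| ≥ |obs|})/(1 + n_perm)`, which cannot be 0. If
the metric is undefined on more than 5 % of permutations the test aborts
with a diagnostic. Leave-one-out curves recompute the metric with each
subject removed; ensemble seeds are deterministic in (subject id, sparsity).

Bonferroni control counts three metric families — clustering, pathlength,
small-world — because normalized and raw variants are redundant:
α = 0.05/3, printed as 0.016 under 3-decimal truncation.

## Regional lesion-load models

Region-level OLS replaces vertex-wise surface models: this is a **declared
substitute**, not a reproduction — there is no surface geometry here, so
random-field-theory vertex/cluster correction is replaced by
Benjamini–Hochberg FDR across the 78 regions at q = 0.05. Model variants:
group effect, dimensional response effect, lesion-load × group interaction,
and per-group lesion-load slopes. The follow-up per-group model is gated on
running the interaction model first (override flag available, logged).

The interaction model includes the lesion-load and group **main effects** by
default. The bare product-only parameterisation (available via
`include_main_effects=False`) cannot, with a responder-coded indicator,
express a lesion-load slope confined to the non-responder group at all — in
simulation it detects none of the injected effects — so the main-effects
form is the scientifically meaningful default.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated:

* **Cohort margins**: 45 non-responders / 43 responders / 43 controls; ages
  55.0 ± 7.4 / 53.0 ± 8.5 / 52.98 ± 8.93 years; female fractions 27/45,
  30/43, 30/43; disease durations 18.8 ± 9.6 / 16.7 ± 8.1 years; baseline
  MSQOL-54 PH 55.54 ± 21.57 / 56.96 ± 18.79 points; four recruitment sites
  assigned round-robin; lesion load log-normal (log-mean 8.5, log-SD 1.0,
  mm³); total brain volume 1.45 ± 0.12 ×10⁶ mm³.
* **Regional CT** follows a latent factor model
  `CT = μ_r + Σ_k Λ[g,k,r] f_k + covariate effects + slope_{g,r}·log LL + ε`,
  ε ~ N(0, 0.12² mm²). The default loading structure is one global factor
  with a mild linear profile across regions plus one wrap-around window
  factor per region (half-width 16), giving a banded correlation matrix
  whose thresholded graph is lattice-like. The whole loading matrix is
  scaled per group so the implied median off-diagonal correlation hits the
  targets 0.66 / 0.49 / 0.41. A pure single-factor structure (uniform
  loading, implied correlation λ²/(λ²+σ²)) and a non-overlapping block
  structure are selectable. The structured default matters: with a uniform
  single factor the population correlation matrix is exchangeable, the
  thresholded graph is pure ranking noise, and *no* group topology contrast
  exists at any correlation level — the banded structure is the minimal
  factor model in which "more homogeneous CT" translates into the more
  regular, more clustered, more small-world graphs the analysis is designed
  to detect.
* **Lesion-load coupling**: slope −0.06 mm per log-mm³ in non-responders
  only, applied to 12 named regions (right-lateralised sensorimotor,
  parietal association, precuneus, insula and two left-hemisphere regions).
  The coupling acts on log lesion load to avoid leverage from the heavy
  tail.
* **QoL trajectories**: seven visits at weeks 0–48 (the real trial's
  schedule is unpublished; this spacing is an assumption, flagged in the
  output sidecar). Responders receive a rise-then-decay gain peaking at 10
  points mid-trial and returning to baseline by week 48; non-responders are
  flat up to an optional linear drift; measurement noise 5 points. Scores
  are not clipped to the 0–100 instrument range so additive contracts stay
  exact.
* **Seeding**: one integer master seed; every stage derives independent
  generators by hashing (seed, stage, key), so any stage re-run in isolation
  reproduces its stream exactly, on any platform.

What the generator does *not* emulate: spatial geometry (regions have no
coordinates; the banded neighbourhood is an index ordering, not anatomy),
scanner/site effects on CT, non-Gaussian CT distributions, longitudinal CT
change, and any vertex-level structure. Passing tests therefore demonstrate
correctness and calibration of the *analysis machinery* under a plausible
covariance structure — not validity of the scientific conclusions on real
MRI data.

## Problem sizes used in validation

The test suite exercises the analysis at the trial's group sizes (45/43/43)
for direction-recovery and calibration checks: 200 replicates at 200
permutations for type-I calibration, 50 replicates at 300 permutations
(add-one resolution 1/301) for the small-world recovery check, and 200
replicates for the regional-FDR check; distributional checks on the
generator use n = 2000. The acceptance script runs one full study at the
default sizes with 1000 permutations.

## Known limitations

* At the trial's sample size the regional interaction model has limited
  power against the default coupling (the common CT factor acts as
  correlated noise), so single simulated cohorts often flag few or no
  regions; the effect is reliably recovered at larger n, and the
  false-positive side is calibrated at all n.
* Binarized graphs only; no weighted, directed or multilayer metrics, and
  no hub/efficiency analyses beyond the three reported families.
* The leave-one-out SD is a stability descriptor, not a standard error;
  inference rests on the permutation nulls.
* Group labels in the full pipeline come from the response scoring of noisy
  QoL data, so a simulated cohort's analysed groups differ from the
  generator's by the scoring misclassification (~10 % near the boundary);
  this is intentional — it mirrors how the real analysis defines its
  groups.
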