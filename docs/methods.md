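# Methods

This note documents the statistical machinery, its defaults, and the design
decisions taken where the problem left genuine choices.

## Activity-value screening

**TAV.** For a non-volatile compound with concentration C (mg/kg) and taste
threshold T (mg/kg), TAV = C/T. Classification is per compound across the
sample groups: *key* requires TAV > 1 in **every** group, *modifier*
requires 0.1 ≤ TAV ≤ 1 in **at least one** group. The asymmetry is
deliberate: a compound that crosses 1 in a single sample but sits below it
elsewhere behaves as a modifier overall (arginine is the canonical case),
while a compound that dips below 0.1 once still modifies taste where it is
present (methionine). Both cut-offs are configurable; the defaults are the
conventional ones. Compounds without a published threshold (cysteine,
tyrosine, all five nucleotides) are carried through as
`excluded_no_threshold` — never silently dropped — so reports can state
exactly what was not scored. Arginine's taste threshold is not published;
the packaged value of 500 mg/kg is back-calculated from its published
contents and activity values and marked as reconstructed in the data file.

**ROAV.** Volatiles are scored per sample against the compound with the
largest ratio of relative content to odor threshold: ROAV_i =
(C%_i/C%_ref)·(T_ref/T_i)·100, so the reference scores exactly 100 and all
scores fall in (0, 100] when the reference is the per-sample argmax. The
reference is selected per sample (deterministic: ties break to the
lexicographically first name); in the packaged tables the octanal monomer
wins in all five samples, so this coincides with a fixed reference. A fixed
reference id can be forced via `compute_roav(..., reference=...)`.
Monomer and dimer signals of one compound share the compound's threshold
but are scored separately (their contents differ); *screening* merges the
forms by default — a compound is key if any form in any sample reaches
ROAV ≥ 1 (inclusive), a modifier if its merged maximum lies in [0.1, 1).
Per-form screening is available (`merge_forms=False`) because the two
conventions genuinely disagree for compounds whose forms straddle the cut.

**Known data inconsistencies.** The packaged score table reproduces the
published ROAVs within rounding-propagated tolerance except for (a) the
butanal rows, where the published dimer scores are reproducible only from
the monomer contents (swapped labels in one of the two source tables; the
package reproduces both tables as printed and repairs neither), and (b)
three isolated cells, including a group-C heptanone content that also
contradicts its own class subtotal. The tests pin these exceptions
explicitly instead of loosening the tolerance globally.

## Semi-quantification and bookkeeping

Peak tables are normalized per sample (and per replicate): each value is
divided by the within-sample total and scaled to percent, so sample totals
are 100 within 1e-9 and the operation is idempotent. The unidentified-peak
remainder is carried as an explicit pseudo-analyte (`Others`) so closure
checks hold on the packaged tables. Compound counting merges monomer/dimer
forms by case-insensitive name stem (trailing `-M`/`-D` is the only form
marker; stereo-prefixes like `(Z)-` are preserved). Chemical-class
aggregation maps unmapped analytes to `other` and is conservative: class
totals sum to the per-sample totals.

## Synthetic replicates

The generator emulates the one structure published tables guarantee: per
(analyte, form, group) cell, `n_replicates` independent draws from
Normal(mean, SD) truncated at zero. Defaults: `n_replicates = 3` (the
analytical-triplicate practice behind mean ± SD reporting), truncated
Gaussian noise (a lognormal alternative is left as an extension point
of the noise-model enum). Relative-content tables are re-normalized per
replicate to sum to 100%, mirroring semi-quantification; for the
configured means to be recovered the template must therefore describe the
full composition (include `Others`). What the generator does **not**
emulate: inter-replicate correlation, batch effects, censoring at detection
limits, or any instrument drift — passing tests on synthetic data
demonstrate the statistical machinery, not robustness to those real-data
features.

**Discrimination injection.** `inject_discrimination(table, ids, shift)`
raises the j-th listed analyte by `shift` pooled within-group SDs in every
group at or beyond breakpoint `1 + (j mod (G−1))` — a monotone step whose
position cycles through the group gaps. Distinct breakpoints make a listed
set span the between-group contrast space (each compound switches at a
different cooking stage), which is what gives recovery experiments an
identifiable ground truth: if all injected compounds shared one pattern,
they would jointly explain a single class contrast and the model's
remaining predictive components would amplify noise variables instead.

**E-nose simulation.** Sensor arrays are simulated from a (sensor × group)
mean-response profile with truncated-Gaussian noise (relative SD 5% by
default) and five parallel repeats per sample. The default 10-sensor
profile has S2/S3/S6 (carbon compounds, hydrogen, aldehydes/ketones)
responding above the rest in every group and the total response peaking in
the 120-min group — the qualitative pattern such arrays show on this soup.

## PCA and OPLS-DA

**PCA** is the exact SVD of the centered (optionally scaled) matrix;
explained-variance fractions come from the squared singular values. The
iterative NIPALS extraction, which some tools use, converges to the same
components; the test suite checks agreement against an independent
implementation.

**OPLS-DA.** Group labels are dummy-coded (one column per class; the
centered dummy matrix has rank G−1). Variables are mean-centered and
unit-variance scaled by default (Pareto and center-only available). Up to
`n_orthogonal` Y-orthogonal components are stripped first: each is built
from the dominant predictive loading minus its projection onto the basis of
X'Y, so orthogonal scores carry exactly zero class information (checked to
1e-8). A PLS2 with one predictive component per dummy column is then fitted
on the filtered matrix, stopping early once the Y residual is exhausted
(the redundant G-th component would fit pure noise). Each latent direction
is the dominant left singular vector of the deflated cross-covariance —
the fixed point of the classical NIPALS inner iteration, computed exactly
so components carry no power-iteration convergence error. With
`n_orthogonal=0` the model is a plain PLS-DA and agrees with an independent
NIPALS implementation to 1e-8. `n_orthogonal="auto"` picks 0–3 by maximal
Q².

**Model statistics.** R²X counts predictive plus orthogonal components;
R²Y is the training fit of the centered dummy matrix. Q² uses stratified
k-fold cross-validation (folds deterministic from the seed; default 7,
capped at the smallest per-class replicate count in the pipeline). Two
accounting schemes are implemented:

* `cumulative` (default): the component-wise scheme of the standard
  chemometrics software — the workset is scaled once, and each predictive
  component is cross-validated against the Y-residual left by the previous
  full-data components; Q² = 1 − Π(PRESS_a/SS_{a−1}). The per-component
  ratios telescope against the training residuals, so Q² ≤ R²Y.
* `global`: the whole pipeline (scaling, orthogonal filter, all components)
  is refit per fold and total PRESS is compared to total SS. This is the
  more conservative estimate; on small group-mean-scale datasets (15
  observations, ~17 variables) it is dominated by regression variance and
  plateaus well below the cumulative value even for cleanly separable data.

The cumulative default reproduces the Q² magnitude (~0.93) that the
commercial tool reports on data of this size and structure; the global
scheme is kept for sensitivity analysis.

**VIP.** Over predictive components, VIP_j = √(p·Σ_a SSY_a w²_ja / Σ_a
SSY_a) with unit-norm weights, so mean VIP² = 1 identically and VIP > 1
flags above-average contributors. VIP is a *training-fit* importance: on
severely under-determined designs (observations < variables) noise
variables can exceed 1 by chance, which is why the recovery experiments in
the test suite use a powered design (8 replicates per group, giving 40
observations for 17 variables) rather than triplicates.

**Permutation test.** Class labels are permuted (default 200 times), the
model is refit per permutation, and the permuted R²Y/Q² distributions are
summarized together with the intercepts of their least-squares regressions
on the absolute label correlation (the conventional validation plot, the
unpermuted model included at correlation 1). Fewer than 20 permutations
triggers a warning (unstable intercepts). For structured data the original
Q² should exceed the permuted 95th percentile; for pure noise the median
permuted Q² is non-positive.

## Correlations and clustering

Pearson r with two-sided p from the t-distribution (n−2 df), flagged at
0.05/0.01. Defaults operate on the five group means (n = 5) because only
means are published; a replicate-level matrix can be passed instead.
Zero-variance variables are reported as `excluded`. No multiple-testing
correction by default (matching raw-p star conventions);
Benjamini–Hochberg is available. Conventions: population SD (÷n) for
row z-scoring, sample SD (÷(n−1)) inside r — both covered by tests.
One published association (GMP vs the hexanal monomer, stated negative) is
irreproducible from the published means, which force r = +0.80; the test
suite asserts the stated direction and is expected to fail there,
documenting the inconsistency.

Hierarchical clustering is deterministic agglomerative linkage
(euclidean/correlation metric; average/ward/complete linkage) with the
standard left-to-right leaf traversal; layouts export merge heights, leaf
order and newick text.

## Pipeline

`run_pipeline` chains the stages on the packaged tables (or user CSVs),
simulating replicate-level volatile data around the group means for the
multivariate stage (restricted to the ROAV ≥ 1 compounds, forms kept
apart). The JSON manifest records the package version, seed, every cut-off,
the effective CV fold count, per-stage status, every excluded analyte with
its reason, and the data provenance
(`simulated-replicates-around-group-means`), so a synthetic-replicate
result can never be mistaken for a published-replicate one. A stage failure
leaves earlier outputs in place and marks the stage `FAILED` in the
manifest. The whole bundle is byte-deterministic in (config, seed).

## Problem sizes

All shipped analyses run at the study's natural scale: 5 groups × 3
replicates × ≤ 51 analytes for simulation and modeling; 50-run recovery
experiments at 5 groups × 8 replicates × 17 variables; 200 permutations
per validation test. The recovery replicate counts are an experiment-design
choice (observations must exceed variables for VIP order statistics to
stabilize), as discussed above.

## Known limitations

* Thresholds are taken as published (odor thresholds in water, mg/kg); no
  matrix correction, and dimer thresholds equal monomer thresholds because
  the source database lists them that way.
* Nucleotide taste thresholds are not published; nucleotide TAVs are only
  computed if a user supplies a threshold database.
* Umami synergy between nucleotides and amino acids is noted in the field
  but not modeled.
* The correlation defaults (n = 5 group means) give wide p-value
  uncertainty; significance stars at n = 5 are descriptive, not
  confirmatory.
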