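# Methods

## Model and procedure

The package treats a two-condition replicated expression matrix (genes ×
replicate arrays, calibrated/log-scale intensities) as a multivariate
object: genes are observations, arrays are variables. All downstream
geometry lives in the space of the first K principal components of a
**correlation PCA** — columns centred and scaled to unit (population)
variance — so that each array's coordinates are its correlations with the
retained components and lie inside the unit circle. The correlation
convention makes arrays comparable regardless of their intensity scale and
is what makes the "mean of replicate vectors" a meaningful summary.

A biological condition is represented by a **direction**: the arithmetic
mean of the correlation-circle vectors of its replicates. This proxy is
only meaningful when the replicates of a condition are mutually coherent
and the two conditions are not collinear; `check_direction_coherence`
quantifies both (mean within-condition cosine, between-direction cosine)
and warns — it never blocks, because the decision belongs to the analyst.

The **closeness measure** of gene *g* to direction *d* is the signed ratio
of the orthogonal-projection norm to the gene-vector norm,
sign⟨g,d⟩·‖proj_d(g)‖/‖g‖, i.e. the signed cosine of their angle: ±1 iff
*g* = αd (collinear, strong relationship; the sign distinguishes the two
sides of the origin, which carry the same meaning for a correlation-based
geometry), 0 iff orthogonal. Assignment takes, per gene, the direction with
the largest |C_d| when it exceeds a threshold; exact ties are left
unassigned. Since a cosine is blind to the distance from the origin —
where noise genes concentrate — the genes whose score norms fall strictly
below the empirical 25 % quantile (linear interpolation) are first fixed to
C_d = 0. With ties at the cutoff nothing extra is removed; this makes the
degenerate all-equal-norms case a no-op rather than an arbitrary cull.

The **DAPC** component is deliberately minimal: k-means on the gene scores
(25 random restarts, best within-cluster sum of squares, seeded) proposes k
groups, a linear discriminant analysis trained on those groups re-assigns
every gene to its highest-posterior group, and with k = 3 the cluster whose
centroid has the smallest norm is read as "no differential expression"
while the other two take the condition whose direction matches their
centroid best in |cosine| (sign-blind, because a condition's genes occupy
both rays of its direction line). If both clusters prefer the same
condition, the stronger match wins and the other takes the remaining label,
with a warning — a pathological geometry should degrade gracefully, not
crash a sweep. The DA step reuses the PCs already retained; there is no
second reduction inside DAPC.

Four strategies combine these pieces (DAPC alone; C_d alone; DAPC run on
only the genes whose |C_d| clears the threshold; and the intersection
consensus). In the thresholded-subset variant the inner k defaults to 2:
thresholding has already removed the centre mass that would form a null
cluster. The subset reuses the full-data PC coordinates — re-fitting the
PCA on the subset would move the directions the threshold was defined
against.

## Accuracy measure

Classifications are scored against simulation truth with the empirical
false-discovery proportion FDR = Fp/(Fp+Tp) computed over the genes
assigned to either condition; genes placed in the "no differential
expression" group do not enter the ratio, and FDR = 0 when no gene is
assigned. Fp counts condition-labeled genes whose truth is the other
condition *or* no-change. This is a descriptive accuracy measure of a
finished classification, not an inferential multiple-testing control; the
package intentionally provides no per-gene p-values.

The threshold sweep evaluates a strategy on the grid 0.970, 0.974, …,
0.998 plus 0.999 and keeps, per simulation replicate, the **largest**
threshold attaining the minimal FDR (when several thresholds tie, the
strictest one calls fewer genes for the same error rate). Replicate
summaries report mean, sd and the 2.5/50/97.5 percentiles of both the FDR
at the best threshold and the best thresholds themselves, the latter on
the 1−C_d scale. A replicate where a method cannot run at any grid point
(e.g. too few genes pass for the subset DAPC) is dropped with a warning;
more than 20 % such failures aborts the study rather than reporting a
biased mean.

## Synthetic data

Both generators start from a base matrix of i.i.d. gene rows drawn from a
multivariate normal with mean 0 and a correlation matrix equal to identity
plus small symmetric jitter (default magnitude 0.05, projected back to a
valid correlation matrix), which sets the noise floor. An optional
within-condition noise correlation (`base_rho_within`, default 0) can
emulate batch-shared noise; the calibrated scenarios do not use it.
Defaults: n1 = n2 = 250 differential genes per condition, n0 = 500
background genes, p1 = p2 = 8 replicates — a realistic two-condition chip
design at a size where every study in the test suite runs in seconds.

**Sim1 (gene-structure confusion).** Each differential block (rows of one
group × columns of its condition) receives, per gene, `block_sd ·
(sqrt(rho)·a·1 + sqrt(1−rho)·ε)` with a positive per-gene amplitude
a ~ Normal(1, 0.3) truncated at 0 and i.i.d. ε. `rho` is the coherent
fraction of the block effect: at high `rho` the group moves as one body
along its condition and is visible as a separate cloud on the first two
PCs; at low `rho` the block effect is just extra noise and the groups melt
into the background. The scenario axis lowers both knobs:
(rho, block_sd) = F (0.95, 8), N (0.8, 5), U (0.5, 3), B (0.35, 2).

**Sim2 (condition-replicate confusion).** Each differential gene draws a
positive effect size from Normal(6, 2) truncated at 0 and a personal leak
fraction λ_g from Normal(leak, 0.35) truncated to [0, 1]; the effect is
added to the gene's own condition columns and λ_g·effect to the other
condition's columns. Genes therefore form a fan of condition-specificity
between the two condition axes; raising the scenario `leak` (F 0.15,
N 0.35, U 0.5, B 0.65) pushes the fan toward the common axis, so the two
conditions' replicate vectors become progressively correlated. Truncated
normals are sampled by inverse CDF so a run is bit-reproducible from its
seed.

The per-gene leak is what separates the failure modes of the strategies:
genes near the bisector are interleaved across the two conditions and
contaminate distance-based clusters (so DAPC's error grows smoothly with
the leak), but they almost never clear a |C_d| wedge of 0.97+, so the
direction-based call stays clean until the directions themselves collapse.

**Calibration.** The generative form is fixed by the model above; the
scenario constants are repository calibrations, chosen once so that the
F→B sweep moves the first-two-PC picture from cleanly separated to fully
confounded, every strategy's mean FDR is non-decreasing along F→N→U→B, the
strategy ordering matches the intended use (C_d beats DAPC under replicate
confusion; the combined strategy beats C_d alone under gene confusion),
and the worst-case regimes land at mean FDR ≈ 0.26 for the combined
strategy at threshold 0.998 (Sim1 B) and ≈ 0.09 for C_d at 0.987 (Sim2 B).
They are constants in `cdclassify.simulate`, not estimates.

**What the simulators do not emulate:** per-gene baseline intensities
(columns are standardized anyway), dye/batch artifacts, missing values,
heavy-tailed noise, more than two conditions, and any correlation between
a gene's effect size and its noise. Passing tests on this synthetic
substrate show the geometry and the strategy trade-offs behave as
designed; they do not certify error rates on real arrays, where the
coherence diagnostics must be consulted first.

## Numerical choices

* PCA via SVD of the standardized matrix; eigenvalues use the population
  (1/n) convention so the full spectrum sums exactly to the number of
  variables. Axis signs are fixed so the first condition's mean variable
  coordinate is non-negative on every retained axis — output is identical
  across runs and BLAS backends.
* K = 2 components by default (the factorial-map plane all diagnostics and
  calibrations refer to); configurable upward.
* Quantiles and percentiles use linear interpolation; "below the cutoff"
  is strict.
* A zero-norm gene scores C_d = 0 (a point at the origin has no
  direction); a zero-norm direction is an error, since it means the
  condition has no geometric representation.
* k-means: 25 restarts, seeded; degenerate clusterings (an emptied
  cluster, before or after the DA re-assignment) raise a dedicated error
  suggesting a smaller k.
* Replicate seeds for simulation studies are spawned from one base seed
  via `numpy` `SeedSequence`, and every stochastic component (generator,
  k-means) is threaded from them.

## Known limitations

* Exactly two conditions. The geometry generalizes to more directions,
  but assignment, mapping and evaluation here are written for the
  two-condition case.
* The cluster→condition mapping rule (smallest-norm centroid = null,
  |cosine| matching for the rest) is a pragmatic invention; other rules
  are defensible and could change DAPC's scores on pathological data.
* The closeness measure is scale-free by construction, so "strongly
  expressed far from the origin" enters only through the norm filter; the
  measure itself cannot rank two genes at the same angle by distance.
* FDR here is an empirical proportion on simulated truth; nothing in the
  package estimates error rates for real data without ground truth.
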