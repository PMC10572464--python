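# Methods

## Scope

`tfconn` implements a complete statistical pipeline for ROI-to-ROI
resting-state functional connectivity group studies: synthetic cohort
generation, connectivity estimation with outlier-scan scrubbing, edgewise
group contrasts, threshold-free cluster enhancement (TFCE) with permutation
inference, the network-based statistic (NBS), and downstream
cluster-of-interest (COI) analyses. Imaging preprocessing (realignment,
slice timing, segmentation/normalization, smoothing, denoising) is out of
scope; the package starts from per-ROI BOLD time series in delimited text.

## Atlas

The packaged default parcellation groups 32 ROIs into 8 large-scale
resting-state networks — default mode (4), sensorimotor (3), visual (4),
salience (7), dorsal attention (4), frontoparietal (4), language (4),
cerebellar (2) — with labels on the `Network.ROIName (L|R)` grammar. A
bookkeeping definition additionally lists the 132 anatomical parcels
(Harvard-Oxford cortical/subcortical plus AAL cerebellum naming) that
complete the 164-region parcellation those network ROIs are drawn from; the
anatomical labels are carried for provenance only and never enter statistics.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study conditions
under which every downstream guarantee is verified.

**Signal model.** Each group has an exact population ROI-correlation target
C: within-network pairs at `loading²` (default loading λ = 0.6, so r = 0.36),
zero across networks. In the affected group (default AD) each planted edge
(a, b, Δz) is moved from its baseline r₀ to tanh(atanh(r₀) − Δz), i.e. its
population Fisher-z is reduced by exactly Δz. Subjects are sampled by
driving the Cholesky factor of C with independent unit-variance stationary
AR(1) innovations (default φ = 0.3 on a T = 200, TR = 3 s grid — plausible
rs-fMRI values; the acquisition length and TR are configurable because real
protocols vary). For the baseline block structure this sampling is
distributionally identical to the natural latent-factor formulation (one
shared Gaussian signal per network with loading λ plus unique noise), while
also realizing arbitrary planted targets exactly. A pairwise
"attenuate-the-shared-signal" construction was considered and rejected:
per-ROI variance budgets make it infeasible for any connected cluster of
realistic size at Δz = 0.4 (each edge would need combined pair-loadings
exceeding the unique variance available at its endpoints). Targets are
checked for positive definiteness; an infeasible scenario raises a
configuration error rather than silently altering the effect. Columns are
standardized to zero mean and unit sample SD.

**Default planted effect.** The default scenario plants Δz = 0.4 on a
connected 10-edge cluster: the complete within-default-mode edge set (6),
the complete within-sensorimotor set (3), and one PCC–sensorimotor bridge.
Within-network blocks are used because group differences in this design are
*contiguous* in a hierarchically sorted connectivity matrix — the situation
matrix-image TFCE is built for — and because default-mode/sensorimotor
hypoconnectivity is the canonical presentation of AD-related disruption. A
sparse cross-network tree, by contrast, cannot be contiguous in any sorted
matrix image and is detectable but not recoverable as a single cluster.
Group sizes default to HC 31 / MCI 31 / AD 33 (n = 95); MCI is generated at
baseline, so HC-vs-MCI contrasts are true nulls.

**Clinical scores.** CDR = intercept(group) + slope · (subject's empirical
mean z over the planted edges) + Gaussian noise, with slope −1 and noise SD
0.15; per-group intercepts (0.39 / 0.84 / 0.92) offset the slope term so
group means land near 0.04 / 0.5 / 0.95 — the severity ladder of the cohort
being emulated. Scores are continuous by default (clean correlation
recovery); an optional `realistic_cdr` mode clips to [0, 3] and rounds to
the clinical half-point scale. An MMSE-like score is generated per group
(28.9 ± 1.65 / 27.5 ± 2.02 / 20.87 ± 3.6) but not analyzed. Note the
realistic noise SD makes the within-group CDR–connectivity correlation weak
(|ρ| ≈ 0.2 at the default conditions): with n ≈ 33 per group, single-study
estimates of it scatter widely — which is itself an instructive property of
the design.

**Nuisance traces.** Framewise displacement (baseline |N(0.2, 0.05²)| mm,
capped below 0.9) and a global-signal trace (standard normal baseline). A
configurable fraction of timepoints (default 0.02) is spiked above both
scrubbing thresholds — exactly `round(fraction · T)` spikes, FD ≈ 1.5 mm and
global signal at ±30 baseline-SD units. Because the scrubbing rule measures
deviation in SDs of the *whole* trace, a large spike fraction inflates the
trace SD until spikes no longer clear the 5-SD rule; the defaults keep them
clearly above it.

**What is not emulated.** No hemodynamic response, physiological noise
spectra, scanner drift, motion-correlated artifacts in the BOLD itself, or
volumetric data. Passing tests therefore demonstrate statistical
correctness of the pipeline under a Gaussian AR(1) block-correlation world,
not robustness to real acquisition artifacts.

## Connectivity

Scrubbing censors (removes) timepoints whose global signal deviates more
than 5 SD from the trace mean or whose FD exceeds 0.9 mm, before
correlation; interpolation or spike-regression alternatives are deliberately
not implemented. Fewer than 10 surviving timepoints is an error. Pearson
correlation is computed on mean-centered columns; zero-variance columns
raise an error naming the ROI. Fisher z = atanh(r) with the diagonal stored
as 0; a saturated off-diagonal |r| = 1 (possible with duplicated synthetic
signals) is clipped to 1 − 1e-7 with a warning naming the pair, keeping
pipelines running with an audit trail.

## Edgewise group statistics

Two-sample contrasts use the classical pooled-variance t (positive t means
first group larger), df = n₁ + n₂ − 2; Welch's t is available behind a flag.
Three-group comparisons use the one-way fixed-effects F, df = (2, n − 3).
Edges with zero pooled variance get statistic 0 with a warning. No
covariates (age, sex) are modeled. Statistics live on the strict upper
triangle and are mirrored for storage; the diagonal never enters.

## TFCE

TFCE(i,j) = ∫ e(h)^E h^H dh from h₀ (default 0) to the edge's height, with
the published default exponents E = 0.5, H = 2, discretized by a midpoint
rule over `n_steps` = 100 levels spanning h₀ to the tail maximum. Both
tails are enhanced separately (negative-tail scores carry negative sign).
Two neighborhoods define e(h):

* `matrix_image_4` (default): the stat matrix is re-ordered by the
  dendrogram leaf order of average-linkage clustering on distance
  1 − |mean z| (deterministic; computed once per contrast because the mean
  over the contrast's subjects is invariant under label permutation) and
  thresholded as a 2-D image with 4-connectivity; the two mirror-image
  halves are processed as one image.
* `edge_graph`: suprathreshold edges are adjacent iff they share an ROI
  (ROI sorting is irrelevant); extent is the number of edges in the
  component.

The production path is an incremental union-find kernel (numba-compiled,
with an equivalent pure-numpy fallback) that processes levels top-down in
O(levels × entries); it is validated against an independent flood-fill
oracle to 1e-10 relative error. The midpoint discretization reproduces the
closed-form single-edge limit v^(H+1)/(H+1) to well under 2% at 100 steps;
doubling the level count moves the peak score by < 1%, though individual
low-score edges adjacent to a component-merge height can shift by a few
percent — inference uses peaks and masses, which are stable.

## Permutation inference

Group labels are completely re-randomized among the contrast's subjects
(identity assignment excluded), default 1000 iterations. Each permutation
records the maximum |TFCE| (peak) and the maximum cluster mass. P-values
use the add-one estimator, so p ≥ 1/(n_perm + 1) and never 0.

**Cluster formation.** Observed clusters are connected components (per the
chosen neighborhood) of edges whose |TFCE| exceeds the 95th percentile of
the pooled null edgewise |TFCE| distribution; the same threshold defines
null cluster masses, with each unordered edge counted once. This rule is a
documented design choice — the enhancement itself is threshold-free, but
reporting discrete clusters with masses requires *some* deterministic
component-forming rule; components of all nonzero-TFCE edges are available
behind `cluster_rule="nonzero"`. Mass is the sum of |t| over a cluster's
edges (`mass_kind="stat"`); TFCE-mass is available behind a flag. Both
cluster-level uncorrected p (mass null) and peak-level FWE p (peak null) are
reported for every cluster, with displays defaulting to the uncorrected
value for small-sample studies.

## NBS

The comparator thresholds |t| at a hard value (default 3.0) per tail, forms
shared-ROI components, and tests component size against the permutation
null of maximum component size. Returned clusters reuse the shared Cluster
container: the size-based FWE p is stored in `peak_p_fwe`, a mass-based
permutation p in `p_uncorrected`, and the component's max |t| in
`peak_tfce`.

## Cluster-of-interest analysis

Per subject, a COI is summarized by the arithmetic mean z over its edges.
Across HC/MCI/AD the means are tested with a one-way ANOVA and pairwise
pooled-variance t-tests reported unadjusted (a Bonferroni column is emitted
alongside for rigor). Within each patient group, Pearson's R between mean z
and CDR is computed with the two-sided p from the t-transform on n − 2 df.
The reporting screen — p < 0.05 *and* |R| > 0.35 (R² > 0.1225) — is a pure
function of (R, p); non-passing correlations are returned with the flag
down rather than suppressed, so the screen's behavior is auditable. At
n = 33 the |R| > 0.35 cut is nearly equivalent to p < 0.05, so the screen's
null false-positive rate is ≈ 5%.

## Pipeline, formats, determinism

All artifacts are delimited text (time series, matrices, subject tables,
nuisance traces, edge-list reports) or JSON (scenarios, stat-map sidecars,
full results); every writer has a reader and write∘read∘write is
idempotent. One configured seed drives everything: stage seeds are spawned
from a single `SeedSequence` in a fixed order (scenario, then one per TFCE
contrast, then one per NBS contrast), so identical configurations yield
byte-identical result files; timestamps appear only in the run log.
Provenance (config hash, seed, stage seeds, package version) is written
once per run. Stage failures raise errors naming the stage; the CLI maps
them to a nonzero exit status.

## Problem sizes used in the test suite

Unit tests run on 2–10 ROI toys with hand-computed expectations. The
statistical guarantees use: oracle equivalence on 200 random 8-ROI maps per
neighborhood; FWE calibration on 100 null datasets (32 ROIs, 20/group,
T = 200) at 500 permutations, with the dataset-level rejection count
checked against the exact binomial 99% region for a 5% rate; power on 50
replicates of the default planted scenario at 30/group and 500
permutations, requiring a significant cluster with Jaccard ≥ 0.3 against
the planted edges in ≥ 80% of replicates; and correlation recovery at
n = 33 over 200–500 replicates. These sizes give stable Monte-Carlo
assertions while keeping the default suite fast.

## Known limitations

* No covariate adjustment in the second-level model (by design; the GLM
  here is the two-sample/three-group contrast).
* Matrix-image TFCE is sensitive to the leaf order within equicorrelated
  network blocks; effects that are sparse across networks fragment into
  multiple small clusters (the `edge_graph` neighborhood is the principled
  alternative for such effects).
* The permutation scheme assumes exchangeability of subjects under the
  null within the contrast; no covariate-aware permutation schemes are
  provided.
* Scrubbing uses plain mean/SD of the supplied global-signal trace; heavily
  contaminated traces shrink the rule's sensitivity (see the nuisance
  generator notes above).
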