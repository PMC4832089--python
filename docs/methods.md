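# Methods

This note records the models, conventions and numerical choices behind
`connparc`, and what the phantom validation does and does not establish.

## Phantom generative model

Each of K parcels k has a latent series u_k; its network target has
v_k = c·u_k + sqrt(1−c²)·w_k with u_k, w_k independent unit-variance
AR(1) processes (coefficient 0.3 by default, mimicking the temporal
autocorrelation of band-limited BOLD). A voxel in parcel k records
u_k + σ·ε, a network voxel v_k + σ·ε, with ε white Gaussian noise of
standard deviation `noise_sd` = σ. The latent coupling c is
`signal_corr`; the *realized* voxel-to-voxel correlation is therefore
c/(1+σ²) — `signal_corr` is the noise-free coupling, and all correlation
calibration checks are run at σ = 0. Background grey-matter voxels carry
independent unit-variance noise; white-matter and CSF blocks share their
own tissue latents so that principal-component extraction has real
structure to find. A baseline of 1000 units is added inside the brain so
that percent-signal-change normalisation (DVARS) is meaningful.

Motion spikes are modelled as *sustained* steps: at each spike frame the
head moves 1 mm (translation) and stays, and the global intensity steps
by 2 % of baseline. Steps rather than single-frame blips make FD and
DVARS each flag exactly the spike frame, which is what the
scrubbing-recovery tests assert. Alternating spike signs prevent
unbounded drift.

Cohorts draw ages uniformly (default 7–32 years; only the covariate
mechanics need emulating, not a specific demographic histogram), IQ from
a clipped normal (108 ± 12), and cycle subjects through the scanning
centres within each group so exchangeability blocks stay balanced. A
Group × Age effect is planted by modulating the designated pair's latent
coupling on the Fisher-z scale: z_pair = atanh(c) + β_g·(log age −
log-midpoint), with β_A − β_B = `interaction_slope` (z-units per
log-year), split symmetrically between groups.

## Preprocessing conventions

* FD follows the Power convention: sum of absolute backward differences
  of the six rigid-body parameters, rotations converted to arc length on
  a 50 mm sphere; FD[0] = 0.
* DVARS is the RMS over voxels of the backward difference, as percent of
  the grand within-mask temporal mean; DVARS[0] = 0. The percent
  normalisation makes the 0.5 % threshold scanner-independent.
* Censoring removes volumes with FD > 0.5 mm **or** DVARS > 0.5 %
  (strict inequalities), flagged volumes only (no forward/backward
  augmentation). Censoring everything is an error; a single surviving
  volume only warns, because the ≥2-volume requirement belongs to the
  downstream fits.
* The 24-parameter motion expansion time-shifts by one volume with the
  first row zero-filled.
* Tissue PCs are computed on column-demeaned retained volumes via SVD;
  rank-deficient data return fewer components with a warning.
* Band-pass is an order-2 zero-phase (forward–backward) Butterworth,
  0.009–0.2 Hz; the temporal mean is removed.
* Spatial smoothing (isotropic Gaussian, FWHM in mm, space only) is
  provided but off by default: the phantoms have no spatial
  autocorrelation to recover, and smoothing before parcellation blurs
  the very boundaries being estimated.
* Default stage order is scrub → regress → band-pass with confounds
  censored identically to the data; the alternative
  scrub → band-pass → regress order (confounds filtered the same way) is
  a constructor option, and every run logs which order ran. Censored
  volumes are excluded, not interpolated.

## Connectivity and parcellation

Correlations are computed over retained volumes only; zero-variance
voxels are excluded from the indices (logged), and |r| is clipped to
1 − 1e−7 before atanh so self-correlations stay finite. The group
matrix is the voxelwise mean of subject z-matrices transformed back to
r (fixed effects).

Fingerprint distance is 1 − Pearson correlation between matrix rows
(configurable to Euclidean); average linkage throughout. Cut levels are
uniformly spaced over (0, h_max], h_max the root merge height: the scan
therefore runs from the all-singletons end to the single-cluster root.
(An interval strictly between the smallest and largest merge heights
cannot represent both K = 2 and K = 1 on a two-voxel tree, so the span
was widened to include both ends of the hierarchy.)

For model selection, each level's *group* labeling is scored on each
subject's own fingerprint distances (mean silhouette; singleton clusters
contribute 0), and a one-sample t across subjects is computed per level.
Because adjacent levels frequently share a labeling, the t profile is
piecewise constant; local maxima are therefore evaluated over *runs* of
identical labelings — a run is a maximum when its t strictly exceeds
both neighbouring runs'. A globally flat or undefined profile yields no
maxima and a warning. All local maxima are reported; the estimator picks
the one with the highest t, but nothing auto-selects a "more plausible"
solution on anatomical grounds — that judgement is left to the user.

Subject solutions re-cluster the subject's own matrix and cut to the
group K (the group labeling is *scored* on individual data during model
selection, but individuals are *re-clustered* for back-projection).

## Matching and atlas

Group and subject clusters enter one average-linkage dendrogram under
distance 1 − Dice (within-set pairs pinned at distance 1); every
distinct merge height is scanned and the cut maximising the number of
two-element {group, subject} clusters wins, ties resolved toward the
lowest height. No minimum-Dice cutoff is enforced (an optional filter
exists, default off). Only matched subject clusters contribute to the
probability maps (unmatched clusters have no group identity to sum
into). The 25 % threshold is applied before winner-take-all; exact
probability ties are recorded in an explicit tie mask and broken toward
the lowest cluster index, so the partition is deterministic.

Note on tied Dice values: when several pairwise distances coincide, the
agglomeration order is ambiguous and two equally-valid dendrograms can
produce different (equally sized) matchings. The oracle tests therefore
use continuous-valued matrices; with real data exact Dice ties across
pairs are measure-zero rare but the ambiguity is inherited from
hierarchical clustering itself.

## Group GLM

Design columns: intercept, reference-coded centre dummies, mean FD, IQ,
natural-log age, group (±1), group × log-age, and optionally grey-matter
density with group × GM — the GM columns are voxel-dependent, i.e. the
design changes at every voxel. Continuous covariates are mean-centred
before interactions are formed so main effects stay interpretable.
All-zero columns (e.g. GM after centring a constant) are dropped with a
warning, which makes the constant-GM model reduce exactly to the GM-free
model; any remaining rank deficiency is an error naming the columns.

Inference is Freedman–Lane: the nuisance-only model is fit per voxel,
its residuals are permuted (subjects shuffled within scanning-centre
blocks, since between-centre exchange is not justified), the full model
is refit, and the maximum |t| over voxels per permutation forms the
voxelwise FWE null; p = (1 + #{null ≥ observed}) / (1 + n_perm), so the
attainable floor is 1/(n_perm+1). For cluster-level inference the
permuted t maps are converted to z, thresholded at |z| > 3.1, and the
maximum face-connected (6-connectivity; 18/26 available) component
extent per permutation forms the null. Cluster correction is
permutation-based throughout; Gaussian-random-field theory is
deliberately not used. The default n_perm is 10,000 for production use;
the validation studies use 500, which bounds the Monte-Carlo error of a
0.05-level test at about ±0.01.

The seed-type comparison (probability-map vs 4/8 mm sphere seeds) is a
split-plot ANOVA computed by explicit sums of squares: seed type is the
within-subject factor, group the between factor; with no group factor it
reduces to the one-way repeated-measures F. The implementation is
cross-checked in the tests against statsmodels (within-only) and
pingouin (mixed). Cohen's d uses the (n−1)-weighted pooled SD.

The sphere-grid decomposition places non-overlapping spheres greedily
from the probability peak outward (candidate centres ordered by
descending probability, lexicographic voxel order breaking ties, so
placement is deterministic), then reports per-sphere subject strengths,
group d, mean probability, and the per-group Pearson correlation between
strength and probability.

## Validation studies and their scope

The studies in `connparc.studies` (run by `scripts/acceptance.py`) use a
12×12×6 grid of 3 mm voxels, K = 6 planted parcels of 8 voxels each,
200 volumes at TR 2 s, latent coupling 0.7 and unit voxel noise — small
enough that the full suite runs in about three minutes on one CPU, while
keeping per-subject correlation sampling error (SD ≈ 0.08 in z at 200
volumes) comparable to real recordings.

* **Type-I calibration** uses 50 null cohorts of 10 subjects per group
  and 500 permutations; the empirical FWE rate at α = 0.05 has binomial
  SE ≈ 0.03.
* **Interaction power** uses the spec'd 50 subjects per group and an
  effect of 0.5 z-units per log-year. That value comes from an analytic
  budget: with seed-averaged maps the planted z-slope is attenuated by
  roughly 0.44 (noise dilution × tanh saturation), the per-subject z
  noise is ≈ 0.08, giving a group×age t of ≈ 6 at n = 50/group against
  a max-statistic threshold of ≈ 4.5 — comfortably detectable, as a
  developmental interaction worth reporting should be.
* **Slope recovery** checks the generator's calibration itself: a 0.02
  z/log-year difference is recovered by per-group OLS. At that small an
  effect the sampling error of the correlation estimate dominates, so
  the study uses two-parcel phantoms with 2000 white-latent volumes and
  no voxel noise, which brings the 20-cohort mean's SE to ≈ 0.002.

What passing these studies shows: the implementation recovers planted
block structure, its permutation inference is calibrated, and its
matching/atlas bookkeeping is exact. What it does not show: robustness
to spatial autocorrelation and smoothing (phantom voxels are spatially
independent), registration error, physiological noise, hemodynamic
variability, or non-block connectivity topographies — real-data
performance must be judged separately.

## Known limitations

* Band-pass filtering on censored series concatenates retained volumes;
  with heavy censoring this distorts the frequency axis (interpolation
  is not implemented).
* `fcluster(..., 'maxclust')` can return fewer than K clusters on
  degenerate trees with tied heights.
* The cohort filter treats sex/coverage/segmentation QC as
  manifest-level flags supplied by the user; no image-based QC is
  computed.
* Probability maps are voxel-based; no surface geometry.
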