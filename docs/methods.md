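# Methods

This note records the models, conventions and numerical choices behind
`speckletex`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The speckle phantom

**Model.** A phantom stack is fully developed speckle: Poisson-placed point
scatterers (density ρ per voxel) carry independent circular complex Gaussian
phasors; the phasor field is convolved with an effective coherence kernel
and magnitude-detected. The kernel's per-axis width combines the optical
PSF and the scatterer extent in quadrature,

σ_eff = sqrt(σ_psf² + (0.6 r)²),

with r the scatterer radius in voxels. With many scatterers per resolution
cell (ρ·V_cell ≈ 8 at the defaults) the field's real and imaginary parts are
near-Gaussian, so the amplitude is Rayleigh-distributed — the test suite
checks a Kolmogorov–Smirnov statistic below 0.05 against a moment-matched
Rayleigh at 10⁴ sampled voxels.

**Degeneration.** The parameter d ∈ [0, 1] emulates the fragmentation of
filamentous organelles into small rounded structures: scatterer radius
shrinks linearly to 0.55 r₀ and density grows linearly to 3 ρ₀ as d → 1.
Both movements shrink the speckle grain, so the median size of binarized
bright particles falls monotonically with d (the granulometry oracle used in
tests). The mapping is the simplest monotone texture-drift mechanism; its
endpoints are configuration, not claims about any particular biology.

**Nuisance structure.** On top of the speckle the generator adds: a bright
coverslip plane at a fractional depth (default 0.2 of the axial extent) with
a Gaussian axial profile of σ = 1.5 voxels, tiltable along y and x; a
fixed-row sinusoid (line-scan artifact) of configurable amplitude and
frequency; Gaussian background noise; quantization to a configurable bit
depth (default 8). Same spec + same seed reproduces a stack bit for bit.

**What the phantom does *not* emulate:** depth-dependent signal decay,
confocal gating, refraction, motion, polarization effects, or any physical
OCT forward model. Passing tests on phantoms therefore demonstrates that the
*analysis chain* behaves as specified under controlled texture drift — not
that any particular accuracy will be attained on real recordings.

## Preprocessing

Order is fixed: specular-reflection clean-up → FFT line-artifact notch →
coverslip detection → tilt removal.

* **Reflections**: voxels saturated over ≥ 5 consecutive axial positions are
  replaced by a 3³ median.
* **Line artifacts**: per en-face slice, 2D FFT; bins on the spectral axes
  whose magnitude exceeds median + 6·MAD of their radial band (off-axis bins
  of the same annulus, 16 annuli) are attenuated to the band median,
  preserving phase. Detection operates on the *median* spectrum across
  slices, so only patterns present in essentially every slice qualify —
  structure confined to a few slices (e.g. resampling boundaries) cannot
  trigger a notch. A guard disc of normalized radius 0.15 around DC is never
  notched: genuine low-frequency sample structure lives there.
* **Coverslip**: "high-frequency component" is operationalized as the
  squared axial intensity difference. The interface depth is located
  coarsely on the laterally averaged profile, then per lateral column as the
  background-subtracted energy centroid within ±8 voxels of the coarse depth
  (subvoxel, symmetric in the ridge flanks); a least-squares plane through
  the column depths gives the tilt. Columns below 5% of peak energy are
  excluded; an all-zero stack raises "no coverslip found".
* **Tilt removal**: each lateral column is resampled axially by the fitted
  plane offset (linear interpolation, zero fill, dimensions and bit depth
  unchanged). A per-column shear equals a rigid rotation to first order in
  the tilt and aligns the plane exactly; rotations above 30° are refused.
  Corrections under a quarter voxel of maximal displacement are skipped —
  resampling would only blur. Running the full pipeline twice changes the
  stack by < 1 quantization level RMS (tested).
* **Crop**: the report suggests a crop box starting 3 voxels below the
  fitted plane; the pipeline applies it before ROI masking so thresholding
  sees tissue, not glass.

## ROI masking and equalization

Automatic mode: Otsu threshold (or an explicit value) → largest 26-connected
component → morphological closing with a discrete ball (default radius 5) →
hole filling → erosion (default radius 2) → largest remaining component. The
result is a single hole-free "globule". Manual-seed mode refines each
user-supplied box with the same procedure restricted to the box; masks may
overlap and are not deduplicated.

In-ROI histogram equalization is **exact** (rank-based): in-ROI voxels are
stably sorted and their ranks mapped uniformly onto the quantization range.
Unlike CDF-lookup equalization this splits histogram spikes, so the
equalized histogram is flat to one voxel per level; ties are broken by scan
order, a constant ROI maps to a single level, re-application is a no-op, and
out-of-ROI voxels are untouched.

## The 65-feature registry

Ordered groups: `local_stats[12]`, `moments[2]`, `cooccurrence[12]`,
`granulometry[21]`, `wavelet[18]` (sizes asserted at import).

* **Local statistics.** Three per-voxel maps over 3D neighborhoods: local
  entropy (5³ window, local histogram over 32 gray bins — a 125-sample
  window cannot support 256 bins, and 32 bins cut cost ~8×), local range
  (3³) and local standard deviation (3³). Normalization follows the
  gray-scale-resolution rule: entropy-type values are divided by the bit
  depth b, range by 2ᵇ − 1, standard deviation by 2ᵇ/2 (the maximal
  two-point σ maps to ~1). For each map, the mean, median, entropy (of the
  map-value histogram over 2ᵇ bins, normalized by b) and standard deviation
  of in-ROI values.
* **Moments.** Skewness and non-excess kurtosis of the in-ROI intensities
  (a Gaussian scores 3). Zero variance returns (0, 0) with a warning.
* **Co-occurrence.** Intensities quantized to 8 levels; for each axis (x, y,
  z) a co-occurrence matrix at offset 5 voxels, counting only pairs with
  both endpoints in-ROI, symmetrized, normalized to sum 1. Statistics:
  contrast Σp(i,j)(i−j)², correlation, energy Σp², homogeneity
  Σp/(1+|i−j|). The correlation of a single-level (degenerate) matrix is
  defined as 1.
* **Granulometry.** In-ROI voxels binarized by Otsu on the in-ROI histogram;
  *dark* (below-threshold) voxels labeled by 26-connectivity; particle sizes
  histogrammed into 12 geometric bins with edges 2⁰ … 2¹² voxels (oversize
  particles clip into the last bin); pairwise coarsening gives the 6- and
  3-bin histograms; all 21 counts normalized by total particle count, zeros
  when no particles. Granulometry runs on the equalized ROI (it follows
  equalization in the pipeline order).
* **Wavelets.** Per en-face slice, a 3-level *undecimated* (stationary)
  separable 2D wavelet transform with the symmetric biorthogonal `bior2.2`
  wavelet; same-size subbands make in-ROI masking exact, and the symmetric
  filters make the x/y feature pairs swap exactly under 90° rotation
  (tested). Detail bands: detail-along-x, detail-along-y, and the diagonal
  band as the 45° direction (it mixes +45° and −45°; a complex dual-tree
  transform would separate them, at the cost of a nonstandard dependency).
  Per direction × scale (3 finest): mean and standard deviation of in-ROI
  coefficient magnitudes pooled over slices.

Whether the source analyses computed local maps in 2D or 3D is not
recoverable; 3D neighborhoods are used since the features describe a 3D ROI.

## Class models and classification

Each class is a full-covariance Gaussian mixture fitted by EM
(scikit-learn; 5 restarts, ridge ε = 10⁻⁶·trace/dim on covariance
diagonals). The component count is selected from a candidate list by
AIC = 2p − 2 ln L with p the **full** free-parameter count
p = k(d + d(d+1)/2) + (k−1); a `penalty="subpopulations"` switch implements
the deliberately undercounting variant that penalizes by k alone. The k = 1
case is computed in closed form (sample mean and covariance maximize the
likelihood exactly), which the tests verify against the EM path.

Distance from a point to a class is the minimum over that class's
components of the Mahalanobis distance under the component covariance;
assignment is to the argmin class with lexicographic tie-breaking. The
between-cluster distance symmetrizes the two one-sided distances by their
arithmetic mean, (D₁ + D₂)/2, isolated in one function
(`cross_cluster_distance`) so the mean/max/min choice can be revisited in
one place.

Cross-validation leaves out one *subset* (imaging session) at a time;
feature standardization uses training-fold statistics only; folds whose
training set lacks a class are skipped with a warning.

## Feature reduction

Greedy forward search; at each step the feature minimizing
leave-one-subset-out classification error (single-Gaussian class models in
the inner loop, for speed and stability at small n) is added, ties going to
the lower registry index. The feature-set size k is chosen by

BIC(k) = −2[m ln p̂ + (n−m) ln(1−p̂)] + k ln n,

with n validation decisions, m errors, p̂ = m/n clamped to
[1/(2n), 1 − 1/(2n)] (the log-likelihood diverges at 0 and 1). BIC's n is
the number of validation decisions; a `n_mode="features"` switch implements
the literal alternative of using k itself, kept for comparison because the
two readings disagree and the conventional one is statistically defensible.
Nested over outer folds, the per-fold selected sets are combined by set
union, ordered by earliest selection step — deliberately inclusive, the
right bias when training data are scarce.

## Sammon projection and the Texture Index

The Sammon stress E = (ΣD_ij)⁻¹ Σ (D_ij − d_ij)²/D_ij is minimized by
gradient descent with step halving (growth 1.3× after success, 30 halvings
max per iteration, max 500 iterations, relative tolerance 10⁻⁹, ε-floor
10⁻¹² on zero distances), initialized from classical MDS (double-centered
eigendecomposition). Descent-by-construction: the recorded stress history
never increases. MVP/SVP axes are the principal axes of the pooled embedded
cloud — pooled, not per class, since the index compares class centers along
one shared direction.

Input distances come from `pairwise_class_distances`: within-class pairs use
a class covariance metric, cross-class pairs the symmetrized two-sided
distance. Two metrics are available: `per_class` (each class whitened by its
own sample covariance — faithful to the classifier but ill-conditioned when
class sizes are small relative to dimension) and `pooled` (pooled
within-class scatter shared by all classes). The timecourse pipeline uses
`pooled`: with ~10 images per timepoint in a 65-feature space, per-class
covariances are rank-deficient and make the embedding geometry unstable,
whereas the pooled metric (rank ≈ Σ(nᵢ−1)) keeps the Texture Index stable
and monotone under monotone texture drift.

TI(t) = mean MVP coordinate of timepoint t minus that of the reference
(earliest) timepoint, sign-oriented so the final timepoint is nonnegative.
Confidence half-widths are Z·s/√N with Z = 1.96 at 95% (sample standard
deviation, N−1); per-timepoint significance is Welch's two-sample t on
per-image MVP coordinates against the reference.

## Experiment designs and problem sizes

The three `run_experiment` designs mirror the emulated study layouts:
`two_class_24h` (control vs degeneration 1, default 20 stacks per class in 4
imaging-session subsets), `timecourse_cells` (6 timepoints, default 10
stacks each, 5 subsets), `timecourse_explant` (same schedule on 128×64×64
stacks). The default timecourse schedule is saturating,
d(t) = (1 − e^(−t/15 min)) normalized to reach 1 at 60 min — front-loaded
the way early apoptotic texture change is front-loaded in time.

Default stacks are 64³ voxels (the explant ROI size of the emulated
protocol is 128×64×64): large enough for stable texture statistics, small
enough that the full suite runs on one CPU in minutes. The acceptance
script uses 20 stacks per class for the two-class analog and 5 timecourse
replicates; the test suite runs 10 replicates. Visual image-quality control
is replaced by an automated gate on in-ROI mean intensity and speckle
contrast (`qc_gate`), a divergence from any manual protocol.

## Known limitations

* The phantom's texture drift is one specific, clean mechanism; real
  degeneration may move texture along directions the 65 features weight
  differently. Accuracies on phantoms do not transfer to real data.
* The diagonal wavelet band mixes ±45°.
* The Eq-style BIC/AIC forms follow the conventional statistical readings
  where the source descriptions are ambiguous; the literal alternatives are
  available behind configuration switches.
* Tilt correction is a shear, exact for plane alignment but only
  first-order equivalent to a rigid rotation; at the 30° guard limit the
  difference is ~5% volumetric distortion.
* With 65 features and tens of images per class, class covariances are
  ridge-dominated in the full feature space; classification accuracy there
  leans on large class separation, which is why the reduction stage exists.
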