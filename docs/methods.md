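# Methods

## Data model and conventions

All rasters are row-major with the origin at the top-left pixel; windows
are half-open and 0-based.  The central object is the 3×3 Hermitian,
positive-semidefinite coherency matrix T₃ of the Pauli scattering vector
k = (S_HH+S_VV, S_HH−S_VV, 2S_HV)/√2, in linear power units, with an
attached look count L.  Monostatic reciprocity (S_HV = S_VH) is assumed
throughout.  On disk, band values are 32-bit float (the convention of
PolSAR products); in memory everything is double precision.  Validation
rejects non-Hermitian or non-PSD input (relative tolerance 1e-9) rather
than repairing it; only the six independent elements are ever stored.

## Scene simulator

A scene is a partition of the grid into labeled patches (rectangular tiles
or seeded Voronoi cells).  Every class carries a prescribed coherency
matrix: total power (Span) times a convex mixture of unit-trace mechanism
templates — surface diag(1,0,0), double-bounce diag(0,1,0), volume
diag(2,1,1)/4, helix ½[[0,0,0],[0,1,i],[0,−i,1]] — where the volume term
may instead use the Neumann particle-cloud covariance T_v(δ, τ) (two
linear branches split at τ = ½, normalized by 1/(1+|δ|²)).  The mapping
from orientation concentration κ to randomness is τ = I₀(κ)e^(−κ),
computed with the scaled Bessel function for numerical stability.

Speckle follows the multilook complex Wishart model: each pixel's T₃ is
the average of L outer products x x^H with x zero-mean circular complex
Gaussian with the class covariance.  This is the standard distributional
model for multilooked PolSAR; the simulator makes no claim about
radiometric calibration, incidence-angle or topographic effects, tides,
or spatial texture within a patch (pixels are i.i.d. given the class).
Passing tests on these scenes therefore validate the *algorithms*, not
the radiometry of any real sensor.

The default seven-class preset assigns each wetland class a mechanism
mixture and power consistent with its scattering narrative: water and
beach surface-dominated with water much darker; the marsh species
volume-dominated with differing orientation randomness (τ = 0.45 for
*Suaeda*, 0.75 for *Spartina*, 0.95 for rice) and power; road
double-bounce dominated; irrigable land a broad mix.  Powers
(0.12–8.0 relative linear units) were chosen once so that the class
signatures are well separated in Pauli-dB space — the regime the
end-to-end rehearsal is specified for — and are configurable for studies
of harder contrasts.  All random generation is explicitly seeded and the
seed is recorded in the raster metadata.

## Preprocessing

Multilooking averages Pauli outer products over non-overlapping
azimuth × range windows (trailing partial windows dropped; output look
count is the window area).  The refined Lee filter uses eight
edge-aligned directional half-windows; per pixel, the direction with the
lowest local Span variance is selected and the minimum-mean-square weight
b = max(0, var − μ²σ_v²)/((1+σ_v²)·var), σ_v² = 1/L, scales the deviation
of every T₃ element from its directional mean.  A boxcar filter is
provided as a linear baseline.  Filters replicate edges, are
translation-equivariant in the interior, and project the output back to
the PSD cone when floating-point noise produces a slightly negative
eigenvalue (the projection count is logged).  Exact numerical parity with
any particular legacy implementation of the refined Lee filter is a
non-goal; the contracts are the statistical ones tested.

## Feature stack

Sixteen features per pixel, vectorized over the raster; pixels with zero
trace are masked (NaN fill) rather than zero-filled.

* **H/A/α** — eigen-decomposition of T₃; entropy uses base-3 logarithms
  (so H ∈ [0,1]) with 0·log 0 := 0; A := 0 when λ₂+λ₃ vanishes; alpha
  angles αᵢ = arccos|v_i1| in degrees, averaged with the
  pseudo-probabilities pᵢ = λᵢ/Σλ.
* **RVI** = 4λ₃/Σλ ∈ [0, 4/3].
* **SERD/DERD** — the co-polar eigenvalues λ′₁ ≥ λ′₂ are computed as the
  eigenvalues of the 2×2 co-pol covariance
  [[⟨|S_HH|²⟩, ⟨S_HH S_VV*⟩], [·, ⟨|S_VV|²⟩]] recovered from T₃ under
  reflection symmetry, and λ′₃ = 2⟨|S_HV|²⟩ = T₃₃.  The single-bounce
  eigenvalue is whichever of λ′₁, λ′₂ has co-pol eigenvector alpha ≤ 45°;
  SERD = (λ_s−λ′₃)/(λ_s+λ′₃) and DERD likewise for λ_d, with 0/0 → 0
  (logged).  This 2×2-eigenvalue formulation is used because the
  "difference-without-square" variant sometimes printed in the literature
  is dimensionally inconsistent; both readings coincide for the corrected
  formula.
* **Yamaguchi four-component** (2005 variant, no rotation compensation):
  helix power p_h = 2|Im T₂₃| capped by the cross-pol power; the volume
  template is chosen among three branches by the co-pol ratio
  10·log₁₀(⟨|S_VV|²⟩/⟨|S_HH|²⟩) at ±2 dB; p_v from the cross-pol channel;
  surface/double from the residual co-pol system with the Freeman-style
  dominant-mechanism split (sign of Re C).  Negative intermediate powers
  are clamped and the remainder redistributed so that
  p_s+p_d+p_v+p_h = tr T₃ holds exactly (to 1e-9 relative it is an
  asserted invariant, in exact arithmetic an identity of the
  implementation).
* **SE** = ln(π³e³ det T₃) with det floored at 1e-30·tr³ so singular
  matrices give a finite value (floor events logged).
* **Neumann** — |δ| = sqrt((T₂₂+T₃₃)/T₁₁) (the square-root reading of the
  anisotropy magnitude; the plain-ratio variant is available behind
  `sqrt_delta=False` for sensitivity checks), phase arg T₁₂,
  τ = 1 − |T₁₂|/(|δ|·T₁₁) clamped to [0,1], and mean orientation ψ from
  the circular-polarization estimator ¼·atan2(2 Re T₂₃, T₂₂−T₃₃), an
  estimator choice since no closed form is prescribed for ψ.

Whether the "α" feature means the mean or the dominant alpha angle is an
open convention; the probability-weighted mean is implemented because it
is the quantity the H/α plane uses.

## Segmentation

Bottom-up pairwise region merging in the multiresolution
(Baatz–Schäpe-style) formulation: fusion cost
f = (1−w_shape)·Δh_color + w_shape·Δh_shape, with Δh_color the
area-weighted increase of the per-band standard deviation summed over
bands and Δh_shape mixing compactness (perimeter/√area) and smoothness
(perimeter/bounding-box perimeter) by w_compact.  A merge is admissible
while f < scale²; the globally cheapest admissible pair is merged next,
which makes every executed merge mutually best-fitting, with ties broken
on the lower region id; determinism, not bit-parity with any proprietary
implementation, is the contract.  Input bands are standardized to zero
mean and unit variance so the scale parameter is comparable across
scenes.  Regions are 4-connected and final ids are canonicalized in
raster-scan order from 1.  Defaults: scale 28, shape weight 0.3,
compactness weight 0.5.

Object features are the unweighted per-segment means of the unmasked
feature pixels (mean rather than any robust statistic — the simplest
defensible choice); an optional majority-vote truth label breaks ties
toward the lower class index (logged).

In the end-to-end workflow the segmenter is fed the dB-scaled Pauli image
(10·log₁₀ of the band powers): Pauli composites are conventionally
displayed and segmented on a logarithmic scale, which makes multiplicative
speckle additive with class-independent variance and keeps dark classes
(water, road) from being washed out by bright ones during band
standardization.

## Importance ranking and subset selection

Forests are bagged decision-tree ensembles (800 trees by default; only
the tree count is treated as a tuned parameter — split and depth settings
are the library defaults) with per-tree in-bag/out-of-bag indices
retained.  MDA(f) is the plain mean over trees of the OOB
misclassification-rate increase after permuting feature f within the
tree's OOB subset; trees with empty OOB sets are excluded from the mean
(logged).  A weighted-mean variant (weights = OOB sizes) exists behind a
flag, since "weighted average" and the plain-mean formula are both found
in descriptions of the estimator; the plain mean is the default because
it is what the defining formula states.  Per-class importance restricts
both error terms to the OOB samples of one class.  For oracle testing,
explicit permutations can be injected per (tree, feature).

Sequential backward selection ranks features once from the full model and
removes the lowest-ranked remaining feature per step (re-ranking after
each removal is available behind a flag); each subset is scored by
stratified 10-fold cross-validated accuracy of freshly trained forests,
and the selected subset maximizes that accuracy with ties going to the
smaller subset.  The error measure everywhere is the misclassification
rate.  `cv_trees` decouples the forest size used inside the subset search
from the final model size, since the search trains folds × subsets
forests.

## Evaluation

Stratified 1:5 train/test splitting over objects (at least one training
object per class).  Confusion matrices put predicted classes on rows and
reference classes on columns, so user's accuracy lies on row totals and
producer's accuracy on column totals; OA = 100·tr/N and Cohen's
κ = (p_o−p_e)/(1−p_e) with p_e = Σ row_k·col_k/N².  Zero row/column
totals leave the corresponding UA/PA undefined (NaN), never zero.  The
SVM comparison arm standardizes features and uses an RBF kernel with
fixed, recorded hyperparameters (C = 10, gamma = "scale"); it exists as a
baseline, and no claim is made that it matches any particular published
SVM configuration.

Six published seven-class confusion matrices are bundled as fixed inputs;
the package recomputes OA, kappa, UA and PA from their raw counts.  Three
printed per-class cells disagree with their own printed row/column totals
by ≈0.1 percentage points (road UA in two tables, one *Suaeda* PA); the
recomputed values are taken as the arithmetic truth and the discrepancy
is noted in the acceptance tests.

## End-to-end rehearsal and problem sizes

The workflow rehearsal simulates a 256×256 seven-class scene at L = 16
(32-pixel tiles), extracts features, segments at the default parameters,
and splits objects 1:5.  At this scene size segmentation yields roughly
40–55 objects — far too few to train on object units — so labeled sample
points (40 pixels per training object, seeded) are drawn from the
training objects for forest fitting, MDA ranking and the cross-validated
subset search, mirroring how training points are collected inside
ground-truth polygons; test objects are then classified from their mean
feature vectors.  Accuracy is reported object-based (each test object
counts once against its majority truth label), with the pixel-level
accuracy of the painted map against the raw truth raster reported
alongside.  The subset search uses 200-tree forests inside
cross-validation while final classifiers use 800 trees.

The selection-recovery study uses a synthetic object table: four classes
at the corners of a 3-simplex in three informative dimensions
(separation 3, unit noise), 60 samples per class, plus seven independent
standard-normal noise features, across 20 seeds with 150-tree ranking
forests and 25-tree CV forests.

## Known limitations

* The simulator's classes are internally homogeneous; real scenes have
  within-class texture, mixed pixels and topographic modulation, so
  real-data accuracies will be lower than the rehearsal's.
* The segmenter is O(E log E) in Python and intended for scenes up to a
  few hundred thousand pixels, not full satellite frames.
* SERD/DERD switch conditions in the literature are printed ambiguously;
  the implemented rule (single-bounce eigenvalue by α ≤ 45°) follows the
  original definition of the quantities, and borderline eigenvectors at
  exactly 45° resolve toward the first eigenvalue.
* Ingestion of native GF-3 level-1 products, geocoding and radiometric
  calibration are out of scope; rasters enter as T3 directories or
  multiband TIFF.
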