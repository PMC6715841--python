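# Methods

## The measurement model

A CRIF acquisition interleaves, per z-plane, one reflection-confocal
scan and six confocal microspectroscopy scans (laser lines 405, 458,
488, 514, 543, 633 nm, acquired longest-to-shortest; the order is kept
as metadata only). Emission from 416 to 691 nm is dispersed into 32
contiguous 8-nm bins, so a cell's signature is a 6 × 32 matrix of mean
intensities — the *hyperspectrum*. Voxel pitches are 0.264 × 0.264 ×
0.674 µm (reflection) and 0.264 × 0.264 × 0.871 µm (spectral);
`SpectralConfig` carries both, but the simulator renders the two
modalities on one shared grid at the reflection pitch so a 3D label map
transfers voxelwise onto the spectral stack. Modelling the true
mismatched z-grids would require resampling the mask with an
interpolation policy that the rest of the pipeline never needs; the
shared grid keeps extraction exact and testable, and the spectral
z-step remains available as acquisition metadata.

## Segmentation

Cells scatter less light than the coverslip, so reflection imaging
shows them dark on a bright background and their outlines as intensity
gradients. The pipeline is Sobel gradient magnitude → threshold (Otsu
on the gradient image by default; a fixed value is available for
reproducibility) → morphological closing (radius 1 px) → hole filling →
erosion by the closing footprint → size filter (min 20 px in 2D, 50
voxels in 3D) → connected-component labeling (8-/26-connectivity). The
post-fill erosion exists because the thresholded gradient ring
straddles the true edge: filling the ring yields a region dilated by
roughly the ring half-width, and eroding by the closing radius
recenters the contour (on synthetic disks and spheres this brings
detected areas/volumes within ~20–30 % of the analytic value; without
it the 3D volume error exceeds 100 %). Touching cells are deliberately
not split — no watershed — matching a contour-based routine in which
unrecognized or merged cells are an accepted, *measured* failure mode:
`segmentation_recall` reports the fraction of true cells matched by a
greedy one-to-one centroid assignment within a pixel tolerance
(default 3 px).

The 2D path operates on the maximum-intensity projection of the
reflection z-stack and suits monolayers of small cells; the 3D path
applies the same operators volumetrically for larger cells or 3D
populations. All numeric parameters live in `SegmentationParams`;
none of them is prescribed by the source workflow, which names only a
2D intensity-gradient method.

## Hyperspectrum extraction and features

Each labeled region masks the spectral data; the cell's matrix entry
(r, c) is the mean intensity over member pixels. In 2D mode the
spectral stack is first averaged (not max-projected) over z — the mean
keeps extraction linear, at the cost of diluting the cell signal by the
z fill fraction when a thin monolayer is imaged with many planes
(single-plane scenes, the simulator's 2D default, are undiluted). The
background spectrum is the mean over the complement of the cell
regions dilated by 2 px (guarding against PSF halos), and is
subtracted entrywise with clipping at 0 so relative fluorescence stays
non-negative; a provenance flag blocks double subtraction.

Feature vectors are built as: optional normalization (`max1` divides by
the matrix maximum — the default, making signatures amplitude-
invariant; `sum1` and `none` available) → optional 3 × 3 four-neighbor
Laplacian (center −4, replicate padding, so constants map to exactly
zero) → row-major excitation-major flattening to 192 dimensions.
Whether the Laplacian feeds the SVM, the CNN, or both is genuinely
open; here the SVM defaults to Laplacian features and the CNN to raw
matrices, and both are recorded per-model and switchable.

## Synthetic scenes

The simulator emulates the imaging setup, not the physics. Cell
classes carry parametric signatures: per excitation row, a sum of
Gaussian emission components (amplitude, peak nm, width nm) evaluated
at the 32 bin centers. The four built-in classes peak near flavin-like
(~520–530 nm) and pigment-like long-wavelength emission with amplitudes
of ~30–60 detector units, an order of magnitude above the default
background (a broad 2-unit component at 510 nm on every row). Shapes
are spheres (budding yeast, radius ~2 µm), spherocylindrical rods
(bacteria, 2.5 × 1 µm) and ellipsoids (fission yeast); placement is
uniform rejection sampling with a minimum center-to-center gap.
Rendering adds the signature inside each cell, blurs with an isotropic
Gaussian PSF (default σ = 0.132 µm ≈ 0.5 px), then applies Poisson
noise on a photon-scaled signal (default 10 photons/unit) followed by
Gaussian read noise (default SD 0.5) and clips at zero; the reflection
channel is a constant background (100) attenuated inside cells
(× 0.6). The ground-truth label map is exact (no blur, no noise).
Within-population variability for sampled catalogs is entrywise
multiplicative lognormal noise with mean 1 and CV 0.1 by default — a
"minor variability" regime chosen once as realistic; no quantitative
figure exists to calibrate it against.

What the simulator does **not** model: photobleaching, spectral
bleed-through between excitation sequences, refractive-index-based
reflection physics, vectorial PSFs, intra-cell signature gradients, or
correlated noise. Passing tests therefore demonstrate the correctness
and internal consistency of the analysis chain, and qualitative
reproduction of the published behaviors (cluster formation, learning-
curve saturation, stage-robust species classification) — not
performance on real microscopes, where class separations are smaller
and backgrounds structured.

## Classification protocol

The SVM is scikit-learn's `SVC` (RBF kernel, C = 1, variance-scaled
gamma; no kernel or hyperparameters are prescribed upstream, and a
linear kernel is a config switch). The CNN is a 4-layer network — two
3 × 3 convolutions (8 then 16 filters, stride 1, replicate padding,
ReLU, no pooling since the input is only 6 × 32) and two linear layers
(64 units, then K outputs) — implemented in numpy with Adam
(lr 10⁻³) so training is bit-reproducible from a seed on any machine.
The schedule is 100 epochs × 100 minibatch cycles (batch 10, drawn with
replacement so sets smaller than 1000 samples still follow it);
analytic gradients are verified against finite differences in the test
suite. Scaled-down profiles (20 epochs) are used where many models are
trained repeatedly; problem sizes for those runs are stated in the
tests and acceptance script.

Evaluation draws `n_train` and 50 test cells *per class*, disjoint,
without replacement (per-class counts are the natural reading given
that the published per-stage test pools differ in size). Learning
curves report mean ± SD over R independently seeded
split/train/evaluate cycles (R = 100 by default; smaller R where noted).
Confusion matrices use rows = predicted / columns = true; per-class
accuracy is the diagonal over the column sum, displayed with exact
integer half-up rounding to 2 decimals (floating-point `round` would
turn 62/80 = 0.775 into 0.77). The mixed-stage protocol pools all
stages of each species for training and reports the two-class accuracy
separately per held-out stage. Class order is lexicographic throughout;
argmax ties break toward the lower index.

## Embeddings

PCA and t-SNE run on the same feature vectors the classifiers use.
PCA signs are fixed (largest-magnitude loading positive) and t-SNE uses
PCA initialization, perplexity 30 and a caller-supplied seed, with
inputs sorted by cell id, so both are reproducible; cluster separation
is quantified by the mean Euclidean silhouette.

## Numerical and degenerate-input policy

Stacks are float64 in memory and float32 on disk (multi-page TIFF; a
JSON manifest names the six per-excitation files). Catalog CSVs store
full-precision floats and round-trip exactly. A constant image yields
zero regions (not an error); NaNs are an error. Normalizing an all-zero
hyperspectrum, estimating background with no non-cell pixels left,
single-class training, and evaluating on an empty test set all raise.
An overcrowded placement request fails after a bounded number of
rejection-sampling retries.

## Known limitations

Under-segmentation of touching cells is by design unrecoverable
downstream (merged cells yield mixed spectra). The 2D z-mean dilutes
signal for multi-plane monolayers. The background model is spatially
constant; structured backgrounds (agar texture, debris) would bias the
complement mean. Signature drift across growth stages is a
deterministic parametric emulation, not fitted to measured dynamics.
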