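# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `massreg`.

## Coordinate and image conventions

All images use 0-based (row, col) indexing with the origin at the top-left
and rows increasing downward. The registration currency of the whole
package is the 64×64 contour image with values in [0, 1]; binary masks use
exactly {0, 1}. Deformation fields store one (d_row, d_col) displacement
per pixel, in pixels; sampling positions outside the frame read zero,
consistent with the zero-padded preprocessing. Pixel spacing defaults to
0.05 mm (the 50 µm DESI raster) and only enters the FRE metric.

## Preprocessing

**Histology → fixed mask.** The stain is separated from the white slide on
the HSV saturation channel with Otsu's threshold (both the channel and the
threshold are overridable — the choice of colour space and threshold rule
is an open design point, and saturation-plus-Otsu is the standard
parameter-free default for stained-tissue/background separation). The mask
is zero-padded to a square symmetrically, preserving the aspect ratio, then
resized with nearest-neighbour interpolation so it stays binary.

**DESI cube → moving contour.** Lock-mass calibration shifts each pixel
spectrum so that the strongest peak within ±0.5 Da of the reference mass
(default 556.2771, the deprotonated leucine-enkephalin standard) lands
exactly on the reference; intensities are re-binned onto the common m/z
axis by linear interpolation, and spectra with no peak in the window pass
through unchanged. Spectra are then divided by their total ion current
(zero spectra pass through), projected per-pixel onto 3 principal
components, and the component with the largest Otsu between-class variance
is kept — an automatic substitute for the per-sample manual component
choice the original workflow used, overridable via
`PreprocessParams.pca_component_choice`. Orientation is normalised so the
minority (tissue) class is bright, the image is shifted/scaled so its
maximum is 1, and the same pad-and-resize step (bilinear this time)
produces the moving image. Intensities within 10⁻⁶ of the background level
are snapped to exact zero: downstream Dice binarises at "intensity > 0",
and PCA round-off would otherwise promote the entire background to tissue.

A constant cube has no variance direction and raises a degenerate-PCA
error rather than returning an arbitrary contour.

## Synthetic data

The generator defines the study conditions; its defaults are not tuning
knobs.

**Virtual cores.** A biopsy core is drawn as a quadratic Bézier spine of
random length (60–90 % of the canvas), orientation and curvature, thickened
to a random width (8–15 % of the canvas) with round caps. By construction
the core is one 8-connected component and keeps a clear 1-px border.

**Augmentation.** Each input (image or matched pair) yields exactly 10
variants: rotations of 0/45/90/180/270°, each with and without mirroring,
applied identically to both images of a pair. Lattice-preserving transforms
(90° family, mirroring) are exact; 45° rotations use bilinear resampling
with a 0.5 threshold for binary inputs, performed on an enlarged canvas and
re-fitted so foreground is never clipped (shapes wider than the frame after
rotation are rescaled down with a 1-px margin rather than cropped). For the
core shapes the generator emits, foreground pixel count is preserved within
±2 %.

**Misalignment labels.** Rigid perturbations are rotations of 0 or 3–10°
and integer per-axis translations up to 12 px. The similarity label is
linear in each axis: s_rot = (10 − r)/8 for r ≥ 3 (1 at r = 0), s_trans =
1 − t/10 with t the per-axis maximum (Chebyshev) magnitude, both clipped to
[0, 1] — so 3° ↦ 0.875, 10° ↦ 0, 2 px ↦ 0.8, 10–12 px ↦ 0, identity ↦ 1.
When rotation and translation are combined the label is the minimum of the
two sub-scores: the scheme defines each scale separately, and the worse
component dominates perceived misalignment. Misalignments are sampled
uniformly: one of {rotation only, translation only, both} and then integer
values over the ranges, with r = 0 reserved for aligned pairs.

**Noise.** Three families emulate DESI background structure on the moving
image: i.i.d. Gaussian (σ = 0.1), a 2-D sinusoid of random orientation and
phase (amplitude 0.2, frequency uniform in 2–8 cycles/frame) and
multi-octave gradient-lattice (Perlin) noise (amplitude 0.3, 2–4 octaves).
No amplitudes are stated for the original acquisition, so these were chosen
once as visually plausible DESI-like contamination and left fixed. Noise is
applied to the whole frame and only to the *moving* image of a pair, so a
"registered" noisy pair is a clean mask against a noisy duplicate — this is
what makes the pair multi-modal-looking and forces the similarity network
to ignore background rather than memorise it.

**Datasets.** From a 25-mask training fold: `sim1` is one misaligned pair
per augmented mask (250 pairs); `sim2` adds aligned duplicates and aligned
virtual-core pairs from 10 procedural cores (250 + 250 + 100 = 600);
`sim3` is noisy aligned duplicates plus noisy misaligned pairs
(250 + 250 = 500). Other fold sizes scale proportionally with a warning.
All randomness flows from explicit seeded generators; equal seeds give
bit-identical datasets.

What the generator does **not** emulate: chemically realistic spectra
(peak shapes, isotopes, matrix effects), stain-specific histology texture,
and genuinely non-rigid tissue deformation. Passing tests therefore
demonstrate that the machinery learns and scores *rigid* contour
misalignment under synthetic noise, not performance on real acquisitions.

## Registration network

A fully convolutional encoder–decoder with skip connections maps the
2-channel (fixed, moving) stack to a 2-channel deformation field. Encoder:
stride-2 3×3 convolutions with LeakyReLU(0.2), filters 16/32/32/32.
Decoder: 3×3 convolutions with nearest-neighbour ×2 upsampling and skip
concatenations (filters 32/32/32/32 across scales, then 16/16 at full
resolution). The flow head is a zero-initialised 3×3 convolution, so the
untrained model predicts the identity transform exactly. Default
configuration: 90 994 parameters.

The loss is MSE between fixed and warped-moving plus λ × the mean over
pixels of the squared forward-difference gradient of the field (summed over
the two displacement components); λ = 0.01 by default. The original
description names "MSE and l2" losses without defining the l2 term or its
weight; the gradient-smoothness reading is the standard regulariser of the
unsupervised-registration framework the model follows. Adam at 1e-4 (also
unstated upstream; the framework's customary default). Curriculum: stage 1
("exp1") trains 20 epochs at batch 11 on sim1; stage 2 ("exp2") trains 30
more epochs at batch 11 on real multi-modal pairs, carrying the stage-1
weights. Because no real data ships with the package, stage 2 must be given
pairs explicitly — `simulate.make_multimodal_standin` builds sim3-style
noisy pairs as the documented stand-in, and calling exp2 with no data
raises rather than silently substituting.

The affine variant predicts a 2×3 output→input transform about the image
centre from a small localisation CNN whose head is identity-initialised;
it is trained with 1 − NCC loss under plain SGD (rate 0.01, no momentum —
upstream states only the loss and optimiser family) on the same curriculum.

The bilinear sampler used in training is float32 (with analytically derived
gradients for both image and grid, finite-difference-checked); the public
`warp`/`affine_warp` functions use a float64 sampler so that the zero-field
and identity-theta warps are exact identities, not approximations.

## Similarity network

Twin weight-sharing branches: four 3×3 convolution blocks (filters
32/64/64/128, ReLU, 2×2 max-pool) and a dense sigmoid embedding of width
1024 — the classic one-shot verification architecture scaled to 64×64
inputs, since no layer sizes are stated upstream. The head takes the
element-wise |e₁ − e₂| into one sigmoid unit, making the score symmetric
under input swap by construction and confined to (0, 1).

Training uses binary cross-entropy with binary targets (registered = 1,
misaligned = 0); the graded misalignment labels are kept in the manifests
and drive only the sensitivity analysis. Each stage splits its dataset
70/30 (deterministic per seed); an epoch draws one batch of 32 from the
training split — at full scale (2000 epochs) this presents 64 000 pairs,
roughly a hundred passes over a stage dataset, and it keeps desk-scale runs
(200 epochs) proportional. Every 200 epochs the validation split is probed
with 20-way one-shot trials (50 per probe by default): the true registered
partner of a fixed image must outscore 19 distractor moving images; ties
break uniformly at random, so a constant scorer sits at the 1/20 chance
level. Anchors are drawn from registered pairs whenever the validation
split contains any. The curriculum is exp3 (sim2) → exp4 (sim3) → exp5
(manually registered real pairs, or the simulated stand-in, labelled 1
against unregistered originals labelled 0), with weights carried across
stages and the exp5 stand-in required explicitly, as for exp2.

## Metrics

Dice binarises both images at intensity > 0 and returns
2|A∩B|/(|A|+|B|); two empty masks return 1 (vacuous agreement, logged) —
the degenerate case is undefined upstream. FRE is the RMS Euclidean
distance over corresponding fiducials (3 by default) times the pixel
spacing in mm; fiducials are taken as input, never auto-detected. The
sensitivity sweep transforms each held-out mask over rotation 3–12° and
x/y translation 0–10 px, pairs it with its original, scores it, and
averages across masks (8 by default, any count accepted) into a tidy
(axis, magnitude, mean_score) table.

## Numerical choices and degenerate inputs

* float32 everywhere inside the autodiff core; float64 in preprocessing,
  metrics and the public warp API.
* Optimisers: Adam (β = 0.9/0.999, ε = 1e-8) and plain SGD; He
  initialisation for convolutions, Glorot for dense layers, all from seeded
  generators keyed by (seed, module salt) so the two networks and every
  stochastic stage are independently reproducible; training is
  bit-reproducible for a fixed seed on a given BLAS.
* BCE predictions are clipped to [1e-7, 1 − 1e-7] before the logarithm.
* NCC adds 1e-8 inside the square root; an all-constant image therefore
  correlates near zero rather than dividing by zero.
* Empty masks: histology thresholding that selects nothing returns an
  all-zero mask with a warning; lock-mass calibration leaves peakless
  spectra unshifted; TIC normalisation passes zero spectra through.
* One-shot validation requires at least k candidate pairs and errors
  otherwise.

## Scaled-down schedules

The demo pipeline and the test suite run reduced schedules chosen so the
complete workflow finishes in minutes on a single CPU while still
exhibiting the qualitative training behaviour: registration stage 1 at 5
epochs (loss decreasing, held-out Dice above the unregistered baseline)
and similarity stage 3 at 200 epochs (one-shot accuracy far above chance,
similarity score decreasing monotonically with misalignment magnitude).
The full-length schedules (20/30 registration epochs, 2000 similarity
epochs per stage) sit behind configuration defaults and the CLI's
`--paper-scale` flag.

## Limitations

* The real acquisitions the design targets are not distributed, so every
  quantitative statement in this repository is about synthetic data; the
  multi-modal stages train on a simulated stand-in and say nothing about
  vendor-specific spectral artefacts.
* The deformation model is unconstrained displacement with a smoothness
  penalty — it is not diffeomorphic and can fold.
* The similarity score is a learned proxy, not calibrated to FRE in mm or
  to any clinical grading.
* Registration and evaluation are 2-D only.
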