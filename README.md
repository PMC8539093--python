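# massreg

Deformable registration and automatic quality scoring for DESI
mass-spectrometry / histology image pairs.

## The problem

Desorption electrospray ionization (DESI) mass-spectrometry imaging records
a full mass spectrum at every ~50 µm pixel of a tissue section, and the same
slide is subsequently H&E-stained and scanned. Building pixel-level training
databases that pair metabolomic signatures with pathology labels requires the
two images to be spatially registered — but staining deforms the tissue, DESI
acquisition adds background noise, and manually registering every sample does
not scale. `massreg` addresses this for elongated specimens such as prostate
needle-biopsy cores with a two-part deep-learning pipeline:

1. **Registration.** Both modalities are reduced to 64×64 tissue-contour
   images (histology → binary mask via saturation thresholding; DESI cube →
   grayscale contour via TIC normalisation and per-pixel PCA). An
   unsupervised encoder–decoder network with skip connections maps the
   (fixed, moving) pair to a dense deformation field φ, and a differentiable
   bilinear warping layer resamples the moving image *m* at *p* + φ(*p*).
   Training minimises

   L(f, m, φ) = MSE(f, m∘φ) + λ · mean‖∇φ‖²,  λ = 0.01 by default,

   with no ground-truth transforms. An affine variant (localisation CNN → 6
   transform parameters → affine sampling grid, NCC loss, SGD) is included
   for comparison.

2. **Evaluation.** A Siamese network — twin weight-sharing convolutional
   encoders whose embedding difference |e₁ − e₂| feeds a single sigmoid unit
   — scores registration quality in [0, 1], reported as a percentage.
   Training uses binary cross-entropy with binary targets (registered = 1,
   unregistered = 0) and is monitored by 20-way one-shot validation trials.

Both networks are trained in curricula of increasing difficulty: rigid
misalignments on clean simulated pairs first, then noisy multi-modal pairs.
Because real paired acquisitions are scarce, the package ships the complete
data-synthesis machinery: 10-fold augmentation (rotations 0/45/90/180/270°,
each mirrored and unmirrored), graded rigid misalignments with linear
similarity labels (3° → 0.875, 10° → 0; 2 px → 0.8, 10 px → 0; identity →
1), procedurally drawn virtual biopsy cores, and Gaussian/periodic/Perlin
noise. Quality metrics are the Dice overlap DS = 2|A∩B|/(|A|+|B|) (binarised
at intensity > 0), fiducial registration error in mm, and a rotation /
translation sensitivity sweep of the similarity score.

The networks run on a compact numpy reverse-mode autodiff core
(`massreg.nn`) whose operator gradients are verified against finite
differences in the test suite; no GPU or deep-learning framework is needed.

## Worked example

```python
import numpy as np
from massreg import (RegTrainConfig, EvalTrainConfig, RegistrationNet, SiameseNet,
                     train_registration, train_siamese, register, predict_similarity,
                     make_misaligned_pair, MisalignmentSpec, build_dataset, dice)
from massreg.fixtures import make_demo_fold
from massreg.simulate import _random_misalignment

train_masks, test_masks = make_demo_fold(25, 8, seed=0)

for r, t in [(3, (0, 0)), (0, (0, 2)), (0, (0, 0)), (10, (0, 0))]:
    pair = make_misaligned_pair(train_masks[0], MisalignmentSpec(r, t))
    print(f"rotation {r:>2} deg, translation {t}: label = {pair.label}")

sim1 = build_dataset("sim1", train_masks, np.random.default_rng((0, 1)))
reg_cfg = RegTrainConfig(epochs_exp1=5, seed=0)
reg, loss_hist = train_registration(RegistrationNet(reg_cfg), sim1, reg_cfg, "exp1")
print("registration loss per epoch:", [round(h, 4) for h in loss_hist])

rng = np.random.default_rng((0, 5))
before, after = [], []
for mask in test_masks:
    pair = make_misaligned_pair(mask, _random_misalignment(rng))
    moved, field = register(reg, pair.fixed, pair.moving)
    before.append(dice(pair.fixed, pair.moving)); after.append(dice(pair.fixed, moved))
print(f"held-out mean dice: {np.mean(before):.3f} unregistered -> {np.mean(after):.3f} registered")

sim2 = build_dataset("sim2", train_masks, np.random.default_rng((0, 2)))
eval_cfg = EvalTrainConfig(epochs_per_stage=200, seed=0)
sia, hist = train_siamese(SiameseNet(eval_cfg), "exp3", sim2, eval_cfg)
print("one-shot accuracy (epoch, acc):", hist["one_shot"])
mask = test_masks[0]
good = predict_similarity(sia, mask, mask)
bad = predict_similarity(sia, mask, make_misaligned_pair(mask, MisalignmentSpec(10, (0, 0))).moving)
print(f"similarity: aligned pair {100*good:.1f}%, 10-degree rotated pair {100*bad:.1f}%")
```

This prints (about six minutes on one CPU):

```
rotation  3 deg, translation (0, 0): label = 0.875
rotation  0 deg, translation (0, 2): label = 0.8
rotation  0 deg, translation (0, 0): label = 1.0
rotation 10 deg, translation (0, 0): label = 0.0
registration loss per epoch: [0.0966, 0.0934, 0.0917, 0.0899, 0.0837]
held-out mean dice: 0.593 unregistered -> 0.628 registered
one-shot accuracy (epoch, acc): [(200, 1.0)]
similarity: aligned pair 50.5%, 10-degree rotated pair 1.9%
```

Reading the numbers: the graded labels follow the linear misalignment score;
five epochs of unsupervised training already shrink the reconstruction loss
and lift held-out contour overlap above the unregistered baseline; the
similarity network separates the true registered partner from 19 distractors
perfectly (chance is 0.05) and gives a 10°-rotated pair a near-zero score
while the aligned duplicate scores 26× higher.

## Command line

Every stage is also a subcommand of the `massreg` entry point —
`fixtures`, `preprocess`, `simulate`, `train-reg`, `train-eval`,
`register`, `score`, `evaluate`, `sweep` — and `massreg demo --out DIR`
runs the whole scaled-down workflow (synthetic fixtures → preprocessing →
simulated datasets → both training curricula → held-out registration,
scoring and a dice/sweep report) in one call. `--paper-scale` switches to
the full-length training schedules.

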