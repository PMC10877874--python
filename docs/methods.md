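# Methods

`ovadx` implements two loosely coupled method families — a tumor-slice
segmentation network and a laboratory-panel diagnostic classifier — plus
the synthetic data needed to exercise both end to end. This note records
the models, their assumptions, the defaults and why, and what the
synthetic experiments do and do not demonstrate.

## Segmentation half

### Model

A fully-convolutional network with *edge-output* side branches. A
residual backbone is truncated before its stride-32 stage (feature maps
that coarse blur too much after upsampling); at the ends of the stride-4,
stride-8 and stride-16 stages, side branches take the feature map,
reduce it to a fixed channel width (default 128) with a 1×1 convolution,
and upsample it to the input resolution with a transposed convolution of
kernel 2f, stride f, padding f/2, initialized to bilinear interpolation
(learned thereafter — the standard stable choice for deconvolution
layers). The three full-resolution maps are concatenated and fused by
two convolutions (3×3 to `head_channels[0]`, then 1×1 to a single
channel); a sigmoid gives per-pixel tumor probability, thresholded at
0.5 by default to produce a mask. The final head's bias is initialized
to −2 so training starts near "all background": with tumor pixels the
rare class, a neutral start floods early updates with false-positive
gradient, which intermittently collapses soft-Dice training at small
budgets; the negative prior logit removes that failure mode for all
three losses.

Two backbones share this tap structure:

- `resnet50`: the standard bottleneck layout. Its 16 residual blocks are
  numbered 1–16 in forward order; the last three (the stride-32 stage)
  are removed along with global pooling and the fully-connected head,
  leaving 13 blocks with taps at blocks 3, 7 and 13. Pre-trained weights
  are an optional hook (grayscale inputs are replicated to three
  channels when enabled); nothing in the package requires them.
- `reduced`: a shallow basic-block backbone (default channels 8/16/32,
  one block per stage, strides 2/2/2) with taps at the end of each
  stage. This is the configuration every training test uses: it reaches
  high Dice scores on phantoms in seconds-to-minutes on one CPU.

The engine underneath is a small numpy layer library (im2col
convolutions, transposed convolutions, max-pooling, residual blocks,
Adam) with hand-derived backpropagation, verified against central finite
differences in the test suite. Parameters are float32 by default (memory
traffic dominates CPU convolution cost; casting parameters to float64
switches the whole computation to float64, which the gradient-check
tests do). Runs are bitwise reproducible under a fixed seed on a given
platform; no global random state is used anywhere.

Losses are attached to the fused head only by default; a
`deep_supervision` flag adds per-branch 1×1 side heads whose losses are
summed with the fused loss, as in the wider edge-output literature.
Whether side supervision helps is left as an experiment, not a default.

### Losses

For a gold mask Y with positive set Y+ and negative set Y−, and
predicted probabilities p_j:

- **CBCE** (class-balanced cross-entropy):
  `L = −β Σ_{j∈Y+} log p_j − (1−β) Σ_{j∈Y−} log(1−p_j)` with
  `β = |Y−|/|Y|`. The weight equalizes the total gradient mass
  contributed by each class, countering the extreme tumor/background
  imbalance of large ROIs.
- **CE**: the same sum with β fixed at 1 (unweighted).
- **Dice loss**: `1 − (2 Σ p·g + s)/(Σ p + Σ g + s)` with smoothing
  s = 1 (soft/probability intersection; the smoothing keeps the loss
  defined for empty masks).

Losses are summed over pixels in their definitions; training uses the
pixel-averaged form so one learning rate works across ROI sizes.
Probabilities are clipped to [1e−7, 1−1e−7] before logs; the clipping
constant is part of the contract so oracle tests can reproduce values
exactly. For training, the cross-entropy gradients are taken with
respect to pre-sigmoid logits analytically (numerically stable); the
Dice gradient is chained through p(1−p).

### Evaluation

Four metrics per case: DSC = 2TP/(2TP+FP+FN), sensitivity TP/(TP+FN),
specificity TN/(TN+FP), and the symmetric Hausdorff distance between
boundary point sets (4-connectivity boundaries; image-edge positives
count as boundary; pixel spacing 1 unless supplied). Dataset summaries
report mean ± sd (sample sd, n−1). Degenerate policies, chosen to keep
pipelines running and stated once: both-masks-empty DSC is 1 with a
warning; sensitivity/specificity raise when undefined; a completely
empty *predicted* mask is scored in summaries with DSC = Se = 0 and HD
set to the image diagonal (the largest distance the frame allows),
since the strict Hausdorff is undefined on empty sets.

### Synthetic phantoms

Each phantom is a smooth Gaussian-random-field background (base level
0.35, texture sd 0.02, correlation length 6 px) with one tumor of a
requested shape raised by `tumor_intensity_contrast` (default 0.5),
plus optional i.i.d. Gaussian noise, clipped to nonnegative
intensities. Shapes cover three difficulty regimes: a plain rotated
**ellipse**; a **ring** (ellipse minus a concentric half-scale ellipse
— the mask provably has a hole); and a **fuzzy** tumor whose intensity
follows a Gaussian-smoothed ramp while the gold mask is the ramp
thresholded at 0.5, so the boundary is genuinely ambiguous in the
image. Tumor semi-axes default to [n/8, n/5] of the image side; an
absolute `tumor_radius` range decouples tumor size from frame size,
which the ROI-size experiments need. The texture amplitude is kept an
order of magnitude below the default contrast so that the realized
tumor/background mean offset stays within ±0.05 of the requested
contrast.

What phantoms do **not** emulate: MRI physics (bias fields, coil
inhomogeneity, partial-volume effects), anatomy, multi-focal disease,
or inter-slice 3D structure. Passing phantom tests therefore shows the
architecture, losses, metrics and training loop are implemented
correctly and can learn; it says nothing about clinical segmentation
accuracy, and the published clinical-data figures are not reproduction
targets here.

### Experiments and desk-scale sizes

`train_model` normalizes each slice to [0,1] (min–max; constant slices
map to zeros with a warning), crops a tumor-centroid-centered square ROI
(clamped inside the frame rather than padded, so intensities are always
real), five-fold augments the training split ({original, rot90, rot180,
vertical flip, horizontal flip} — the four augmenting transforms that
yield exactly 5×), and runs seeded mini-batch Adam.

The loss × ROI-size grid trains one network per (loss, size) cell on
ROIs cropped from the *same* source phantoms and scores a held-out
split, reproducing the qualitative finding that performance degrades as
ROI size grows (larger ROIs mean heavier class imbalance). Default desk
scale, chosen after a pilot timing run so the whole grid fits in a few
CPU-minutes: 18 phantoms of 320×320 px with tumor semi-axes 10–16 px,
contrast 0.6, noise 0.05; 12 training / 6 held-out slices per cell; no
augmentation; reduced backbone; Adam lr 5e−3, batch 4, 8 epochs; sizes
96/192/320. At this budget all three losses learn well at ROI 96 and
degrade at 320, the cross-entropy most visibly — exactly the imbalance
mechanism the class-balanced loss exists to counter. The easier
demonstration task (held-out DSC ≥ 0.85) uses 40 phantoms of 64×64 px,
contrast 0.6, noise 0.05, five-fold augmentation and 8 epochs.

## Diagnostic half

### Cohort model

A case/control cohort with 185 cases and control subgroups of 138
(other malignant), 339 (benign) and 92 (healthy) by default, mirroring
the study population sizes; all counts configurable. Each of the 25
panel indicators (tumor markers, blood-cell parameters, sex hormones,
biochemistry, lipids) is

```
value = subgroup baseline + case effect + Σ_f loading_f · factor_f + noise
```

with three standard-normal latent factors per subject — tumor-marker/
hormone, glucose-lipid, inflammation — loading 0.8 on each indicator's
home factor, noise sd 0.6 (unit total variance). The case effect is
`effect_size` (default 1.0 sd) times a per-indicator sign, negative for
exactly {E2, P, AGR, PA, TC} (the indicators that run *lower* in the
cancer group) and positive otherwise. Control subgroups get a modest
tumor-marker shift (other-malignant +0.4, benign +0.2) so they are not
interchangeable. Demographics (age uniform within subgroup-specific
printed ranges, 16–83 for cases; menopausal status mostly determined by
age > 50 with 10% noise; pregnancies Poisson(2)) are drawn independently
of the indicators. Cases also carry a uniformly random FIGO stage
(I–IV), deliberately independent of everything else, so that
stage-restricted evaluation has tags to work with and the expected
result is stage-invariant performance.

This is the simplest model with the three-factor structure the PCA step
is meant to find; it does not attempt realistic marginal distributions
(real tumor markers are heavily right-skewed), realistic inter-indicator
correlations beyond three factors, or any dependence of indicators on
demographics. AUCs obtained on these cohorts validate the pipeline
mechanics, not clinical performance.

### Pipeline

1. **Stratified split**: per subgroup, a seeded shuffle sends
   floor(2/3·n) rows to training, the rest to test. With the default
   cohort this yields the 123/62 case split; the floor rule gives
   379/190 controls.
2. **z-score**: training-column mean/sd (sample sd); test rows are
   transformed with training statistics. Constant columns map to zeros
   with a warning.
3. **PCA**: eigendecomposition of the correlation matrix (z-scored
   input makes covariance = correlation; eigenvalues sum to 25). The
   top 3 components are retained. Sign convention: each component's
   largest-magnitude loading is positive, making loadings reproducible
   run to run.
4. **Features**: the 3 PC scores plus the 3 z-scored demographics
   (demographics bypass the PCA; configurable off).
5. **GA-BP classifier**: one hidden layer, logistic activations at
   hidden and output layers (hence scores in [0,1]). A real-valued GA
   chromosome encodes a hidden-size gene plus weight/threshold blocks
   sized for the maximum hidden size, with only the first h units
   active. Tournament selection, arithmetic (blend) crossover at rate
   0.8, Gaussian mutation at rate 0.05, elitism 2, population 40, 100
   generations, hidden size 2–20; fitness is validation cross-entropy
   on an internal seeded split (25%). Elitism makes the best-fitness
   trace non-worsening by construction. An optional back-propagation
   fine-tune (full-batch gradient descent on cross-entropy) polishes
   the GA solution; GA global search plus gradient refinement is the
   usual division of labor.
6. **Evaluation**: ROC on the held-out third. AUC is the scaled
   Mann–Whitney U with ties worth ½ (identical to trapezoidal area).
   The reported operating point maximizes the Youden index
   Se + Sp − 1; ties break to the lowest threshold. Model-vs-CA125 is
   a paired DeLong test (fast structural-components covariance,
   two-sided normal p). Partition-restricted ROC lets untagged
   subjects join every partition, so "early cases vs all controls" and
   "cases vs one control subgroup" are both expressible.

### Numerical choices and degenerate inputs

- BP activations clip their argument to ±500 before exp (overflow
  guard; saturated outputs are exactly 0/1 there anyway).
- GA chromosome decoding clips the hidden-size gene into the configured
  range; mutation keeps it in range.
- DeLong with zero variance: z is 0 when the AUCs are equal (p = 1) and
  ±∞ otherwise (p = 0).
- The GA's internal validation split falls back to evaluating on all
  rows if a class is missing from either side (only possible on very
  small inputs).

## Known limitations

- The full ResNet50-layout backbone is buildable and runs forward at
  its native sizes, but CPU training at that scale is out of scope;
  all training claims rest on the reduced backbone.
- No batch normalization: at the reduced scale it is unnecessary, and
  omitting it keeps backpropagation exactly checkable; very deep
  configurations would likely need it to train well.
- The grid experiment's per-cell budget is deliberately small; its
  purpose is the *ordering* of cell scores, and absolute grid DSCs
  should not be read as converged performance.
- Synthetic cohorts have no missing values, no measurement-unit
  heterogeneity and no label noise; real laboratory panels have all
  three.
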