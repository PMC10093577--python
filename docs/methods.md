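# Methods

## The model

DISubNet is a lightweight convolutional classifier for grayscale thermal
images of pigs under four treatments — isolation after feeding (IAF),
isolation before feeding (IBF), paired after feeding (PAF), paired before
feeding (PBF).  Its two building blocks are:

* **Depthwise-separable convolution**: a per-channel 3×3 spatial (depthwise)
  convolution followed by a 1×1 cross-channel (pointwise) convolution, with a
  ReLU after each.  The factorization replaces the K²·C_in·C_out weights of a
  standard convolution with K²·C_in + C_in·C_out — for 3×3 kernels a saving
  that holds for every C_in, C_out ≥ 2.
* **Inception module**: four parallel branches over the same input — 1×1
  convolution, 3×3 convolution, 3×3 dilated convolution (rate 2), and an
  identity skip — concatenated along channels.  The dilated branch enlarges
  the receptive field without pooling; the skip passes the input through
  unchanged.

Two arrangements are built:

* **DISubNetV1** — two parallel subnetworks of depthwise-separable blocks
  process the same input; their outputs are concatenated and fed to a single
  inception module, then the classifier head.
* **DISubNetV2** — each subnetwork opens with its own inception module on the
  raw input; the two module outputs are concatenated and processed by one
  shared depthwise-separable stack, then the head.

The classifier head in both versions is a 1×1 projection (pointwise
convolution adds non-linear depth at minimal parameter cost), average
pooling to a 7×7 grid, one hidden dense layer with ReLU, and a 4-way softmax.

## Width calibration

Published descriptions of this model family typically omit per-layer channel
widths, printing only total parameter counts.  All widths in
`disubnet.architectures` are therefore frozen calibration constants, solved
(by exact integer search over the analytic counting formulas) so each
build reproduces its printed total **exactly**:

| model            | calibrated structure                                        | total      |
|------------------|-------------------------------------------------------------|------------|
| LeNet5 (modified)| conv 20/50 (5×5), dense 500                                 | 19,628,074 |
| AlexNet (4-conv) | 96/256/384/256, dense 4096/4096                             | 23,392,580 |
| VGG-16           | standard 13-conv stack, dense 512                           | 17,075,396 |
| Xception-like    | entry 32/64, blocks 128/256/728, 7 middle blocks, exit 1024, pointwise 1784/2320, GAP | 20,991,980 |
| CNN-LeakyReLU    | 3×3 convs (16,40,64,80,88,112) + batch-norm, dense 320      | 7,255,332  |
| CNN-Inception    | same trunk + inception stages (40,72,64), dense 112         | 7,419,812  |
| DISubNetV1       | subnets (16,48); inception (32,32,32); proj 120; dense 766  | 4,591,574  |
| DISubNetV2       | inceptions (32,32,32); stack (16,48); proj 192; dense 486   | 4,591,574  |

Notably, the AlexNet variant calibrates *uniquely* to the canonical
ImageNet-era widths, and VGG-16 to the standard conv stack with a single
512-unit hidden layer — evidence the calibration recovers the original
configurations rather than arbitrary solutions.  The two DISubNet versions
share the subnetwork and inception configuration; only the head constants
differ, absorbing the different fan-ins of the two topologies so the totals
coincide.  Equality of the two totals is a property of the calibrated
defaults, not of arbitrary shared configurations: the two topologies place
the inception module at different fan-in, so their totals as functions of a
shared configuration cannot agree identically.

## Parameter accounting

`layer_graph.count_parameters` is analytic: conv K_h·K_w·C_in·F (+F bias),
depthwise K_h·K_w·C_in (+C_in), pointwise C_in·F (+F), dense n_in·F (+F),
batch-norm 2C trainable (scale/shift) plus 2C non-trainable (moving
statistics); pooling, activations, dropout, flatten, concat and elementwise
add contribute nothing.  Reported totals are the grand total including
moving statistics; the trainable-only total is also exposed since printed
"number of parameters" figures are ambiguous between the two (they differ
only for the batch-normalized baselines).  Shape conventions: channels-last
(H, W, C), row-major flatten, "same" padding `ceil(in/stride)`, "valid"
padding `floor((in − dilation·(k−1) − 1)/stride) + 1`, and a kernel that does
not fit its input under valid padding is a hard error.

## Synthetic thermal scenes

The FLIR-camera study data are available only on request, so
`synthetic_thermal` generates stand-in scenes: 112×112 grayscale in [0, 1],
a background at 0.2 intensity with a mild vertical gradient (0.0005/row), one
(IAF/IBF) or two (PAF/PBF) elliptical warm bodies at 0.6 base intensity with
Gaussian-smoothed rims (σ = 2 px), +0.15 body intensity for after-feeding
classes, and additive pixel noise (σ = 0.05).  Semi-axes are drawn from
(11–13) × (7.5–9) px; the ranges are deliberately narrow so that no single
body's thresholded area can reach the area of two, making the class structure
separable by a two-threshold rule (foreground pixel count → single vs.
paired; body-core mean intensity → before vs. after feeding).  That rule
scores ≥ 99 % on default scenes, which bounds the difficulty of the CNN task
from above: passing tests show the pipeline can learn an easy, well-posed
surrogate, not that it would reach the published accuracy on real thermal
footage.  Real FLIR frames differ in ways the generator does not emulate —
pose articulation, partial occlusion, radiometric calibration drift,
background clutter, and correlated sensor noise.

Dataset planning apportions classes and the 60/20/20 train/validation/test
split by the largest-remainder rule, stratified per class; at the study's
62,800 images this yields exactly 37,680 training and 25,120 non-training
images (the published "test" count equals the combined 40 % pool; the
manifest keeps the three-way split and reports both conventions).  Scene
rendering is lazy and keyed by (manifest seed, row index), so manifests and
images are byte-identical across runs.  Images are written as 8-bit grayscale
PNG under class-named directories with a `manifest.csv`.

## Training backend

No deep-learning framework is part of the package's dependency set; training
runs on a numpy backend (`disubnet.backend`) that materializes a layer graph
into real weight arrays and implements exact analytic backprop for every
layer kind (convolutions via strided sliding-window views and einsum), plus
Adam with the canonical moments (β₁ = 0.9, β₂ = 0.999, ε = 1e-7).  Before
training, the backend's allocated parameter totals are checked against the
analytic engine node by node; a mismatch is a hard error.  This dual route —
counting formulas vs. allocated tensors, inferred shapes vs. observed
activation shapes — is the package's core self-check and is exercised on
randomized graphs in the test suite, alongside finite-difference gradient
checks on a kink-free graph.

Loss is categorical cross-entropy −Σ yᵢ log sᵢ with probabilities clipped to
[1e-12, 1]; ReLU is max(x, 0); LeakyReLU is max(0.1·x, x) with the slope
fixed at 0.1.  The reference protocol is Adam at batch size 32 for 100
epochs, learning rates 1e-2/1e-3/1e-4; desk-scale runs keep the protocol and
shrink widths (÷4), sample counts, and epochs.

**Input preprocessing.**  Images enter the network as 2x − 1, i.e. centered
to [−1, 1] (the same convention as the separable-convolution model family).
With strictly positive inputs every first-layer weight gradient has the same
sign pattern, which conditions early training badly on low-contrast thermal
scenes; centering removed a multi-epoch plateau in desk-scale runs.

**Pooling choice.**  The DISubNet builders use average pooling (subnetworks
and head); the baselines keep max pooling where their descriptions pin it.
Average pooling preserves the area and mean-intensity statistics that
actually discriminate the treatments, and suppresses the i.i.d. pixel noise
that max-pool chains amplify into position-specific features — on the
synthetic task a max-pooled head memorized noise (train ≫ validation) while
the average-pooled network generalized.  Pooling kind does not affect any
parameter count.

**Determinism.**  Initialization, shuffling, and dropout all derive from the
training seed; runs are bit-reproducible on one machine.  Across BLAS
implementations reductions may reorder, so cross-machine reproducibility is
statistical (accuracy within a couple of percent), not bit-level.

## Evaluation

Confusion matrices have rows = true class, columns = predicted, class order
(IAF, IBF, PAF, PBF).  Precision, recall and F1 are computed per class from
TP/FP/FN and aggregated under an explicit scheme: micro (pooled counts),
macro (unweighted mean), weighted (support-weighted).  For single-label
multiclass data, micro-averaged precision = recall = accuracy identically —
which is why published comparison tables in this setting often print four
equal values per row; micro is therefore the default, and all three schemes
are computed.  Classes with zero support or zero predictions score 0 with a
warning.  Argmax ties break toward the lowest class index.  Percentages are
printed to four decimals to match the published table convention.

## Desk-scale problem sizes

The test suite trains the width-reduced (÷4) DISubNetV1 on 2,000 synthetic
scenes for 10 epochs (reaching ≥ 95 % test accuracy from a fixed seed), and
runs shorter 3-epoch trainings on a 400-scene fixture for protocol
invariants.  Full-size, full-length training (62,800 images × 100 epochs)
mirrors the original GPU experiment and is available through the CLI
(`disubnet experiment run`) but is not part of the test suite.

## Known limitations

* The synthetic scenes are calibration constants, not a fitted model of FLIR
  imagery; accuracy numbers on them say nothing quantitative about real pigs.
* The numpy backend targets clarity and desk scale; it has no GPU path and
  trains ~10³ images/minute on the scaled model.
* AlexNet/VGG/Xception-like internal widths are reconstructions constrained
  by the printed totals and the textual descriptions; other width settings
  could print the same totals.
* Batch-norm moving statistics use momentum 0.99 and are only as good as the
  (short) training runs that update them.
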