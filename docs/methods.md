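# Methods

`dsunet` implements a lightweight encoder/decoder classifier for
two-class (benign vs malignant) breast-lesion images from two imaging
modalities — mammography (MGI) and ultrasound (USI) — together with the
preprocessing, evaluation, and GAN-side machinery around it, and a
synthetic data generator that makes the whole pipeline testable without
any clinical image collection.

## Preprocessing

Images of arbitrary size are bilinearly resized to a common square size
(default 256 x 256).  The resize uses the corner-aligned convention
(output sample `i` reads input coordinate `i*(n_in-1)/(n_out-1)`); rows of
the interpolation operator sum to one, so constant images are preserved
exactly.

Intensity normalization is a Box-Cox power transform,

    y = (x^lam - 1) / lam   (lam != 0),    y = log x   (lam = 0),

with `lam = 0.5` by default (configurable).  Box-Cox requires x > 0 while
8-bit pixels include 0, so each intensity v in [0, 255] is first mapped to
x = (v + 1)/256 in (0, 1]; after the transform each image is min-max
rescaled to [0, 1].  Both the shift and the rescale are strictly monotone,
so pixel rank order is never altered; per-image (rather than per-dataset)
rescaling removes source-level intensity offsets, which matters when
images are pooled from heterogeneous archives.  The transform is
evaluated as `expm1(lam * log x)/lam`, which stays accurate (and strictly
monotone) down to arbitrarily small nonzero `lam`.  A constant image maps
to all zeros.  Processed images are stored as float32 `.npy` arrays, and
the whole step is a pure function of input bytes and parameters: reruns
are bit-identical.

## Architecture

The classifier is a nine-layer U-shaped network built entirely from
depthwise-separable convolution (DSConv) blocks: a per-channel 3x3
depthwise convolution (stride 1, padding 1, no bias), a 1x1 pointwise
convolution, batch normalization (eps 1e-5, running-stat momentum 0.1),
and ReLU.  Convolutions carry no bias because BN immediately follows.

* Encoder: four DSConv blocks with channel schedule C0, 2C0, 4C0, 8C0,
  each followed by 2x2 average pooling (stride 2).
* Bottleneck: one DSConv block expanding 8C0 to 16C0.
* Decoder: four levels, each a 2x bilinear upsample, concatenation with
  the matching encoder map (skip connection), and a DSConv block reducing
  channels: 16C0+8C0 -> 8C0, 8C0+4C0 -> 4C0, 4C0+2C0 -> 2C0,
  2C0+C0 -> C0.
* Head: global average pooling over the final C0-channel map, then a
  fully connected layer to 2 logits with softmax semantics.

C0 defaults to 16 and is configurable; the decoder's halving-toward-C0
schedule is a design choice (several consistent schedules exist; this one
keeps encoder and decoder symmetric).  The depthwise kernel is fixed at
3x3.  The head produces two logits rather than a single sigmoid neuron,
matching the two-class cross-entropy training loss.  Global pooling makes
the network size-agnostic; the four pooling stages require input sides
divisible by 16.

A DSConv block has `Cin*9 + Cin*Cout + 2*Cout` trainable parameters
versus `Cin*Cout*9` for a standard 3x3 convolution; its multiply count is
a fraction `1/Cout + 1/9` of the standard convolution's, which is the
source of the architecture's low computational cost.

The network, backpropagation, and the Adam optimizer are implemented in
NumPy (`dsunet/_nn.py`), sized for desk-scale experiments on a single
CPU.  2x bilinear upsampling is expressed as a pair of 1-D interpolation
matrices applied to rows and columns; its adjoint (transposed matrices)
gives the exact backward pass.  All backward passes are verified against
finite differences in the test suite.

## Training protocol

Training follows a stratified k-fold cross-validation protocol: the fixed
train/test split (default 80:20) is made first; the k folds (default 5)
partition only the training split, stratified by class x modality.  Each
fold trains a fresh model with Adam (default learning rate 1e-5, the
published setting for 50-epoch runs on ~10k images) and categorical
cross-entropy — the loss is a package choice consistent with the two-class
softmax head.  One record of train/validation loss and accuracy is logged
per epoch; the weights at the best validation accuracy are checkpointed;
every fold's best model is evaluated on the same fixed test split, and
fold reports are aggregated by arithmetic means.  No weight decay,
learning-rate schedule, or early stopping is applied.  All randomness
(weight init, fold shuffling, batch order) derives from one seed;
histories are bit-for-bit reproducible.

Validation curves come from the fold's held-out portion; the fixed test
split is used only for the final per-fold evaluation.

## Metrics

Per-class precision, recall, and F1 are computed one-vs-rest from the 2x2
confusion matrix and reported in percent; accuracy is the diagonal
fraction.  Weighted averages weight classes by support; macro averages do
not; the two coincide exactly on balanced test sets.  Cross-validation
summaries are the arithmetic means of per-class metrics across folds,
with an overall row equal to the mean of the two per-class averages;
displayed values are rounded to 3 decimals (improvement deltas between
two experiments to 2 decimals) while unrounded values are kept in the
JSON.  When a denominator vanishes the metric is reported as 0 with a
warning.

## GAN-side computations

AdaIN standardizes a feature channel to zero mean/unit variance and
restyles it with a scale and bias; a small `sigma_eps` stabilizes
constant channels.  The discriminator losses are the logistic forms
`E[-log sigma(D(x_real))]` and `E[-log(1 - sigma(D(x_fake)))]`, evaluated
with numerically stable softplus identities and log arguments clamped at
1e-12.  Feature matching is the squared Euclidean distance between mean
feature vectors (mean-feature matching, not per-layer).  The gradient
penalty is `E[(||grad_x D(x_hat)|| - 1)^2]` on uniform interpolates
between real and fake samples (one interpolate per batch element).

FID is the Frechet distance between Gaussians fitted to image
embeddings: `||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2})`.
The matrix square root is computed by eigendecomposition of the
symmetrized product `sqrt(S_r) S_g sqrt(S_r)`; eigenvalues below a
relative tolerance of 1e-10 are clamped to zero and the result is clamped
at 0.  The embedding is pluggable: raw pixels (default) or the trained
classifier encoder (bottleneck global-average-pool features).  No
pretrained reference network is involved, so these FID values live on the
embedding's own scale and are not comparable to Inception-based FID
numbers.

The mini-GAN is a deliberately small convolutional generator
(dense -> 4x4 map -> repeated upsample + DSConv -> sigmoid) and
discriminator (DSConv + ReLU + average pool stack -> GAP features ->
dense logit) for images up to 64x64.  The discriminator objective is
`L_real + L_fake + lambda_GP * GP`; the generator minimizes the
non-saturating adversarial loss plus `lambda_FM * L_FM` against the
discriminator's GAP features.  Default weights `lambda_GP = 1`,
`lambda_FM = 0.1` keep the auxiliary terms subordinate to the adversarial
term.  The gradient penalty's parameter gradients require differentiating
through the input-gradient computation; because the discriminator's only
nonlinearity is ReLU (no BN), whose activation masks are piecewise
constant, treating the masks as fixed during a second adjoint pass yields
the exact penalty gradient almost everywhere.  This second pass is
verified against finite differences in the tests.

## Synthetic data generator

The generator emulates the *shape* of a balanced two-modality lesion
dataset; it does not attempt photorealism, microcalcifications, or
clinical grading.  The class signal is morphological — the canonical
benign/malignant contrast in breast imaging: benign lesions are smooth
ellipses; malignant lesions add `count >= 5` radial cosine lobes
(spicules) of positive amplitude to the elliptical boundary.  Per-image
geometry is randomized within class ranges (semi-axes 0.13-0.20 and
0.08-0.14 of the image side; 6-11 spicules with amplitude 0.30-0.45 of
the minor axis; uniform rotation and phase).  By construction a threshold
on boundary irregularity (isoperimetric ratio) alone separates the
classes, so a classifier failing to learn indicates a training defect,
not an unlearnable task.

Rendering: MGI images place the lesion (+120 intensity, edges softened
by a 1-pixel Gaussian blur) on a fixed smooth low-frequency background
(ramp plus gentle sinusoids, 90-150) with additive Gaussian noise
(sigma 8); with the noise scale at 0 the image is a deterministic
function of the mask.  USI images use a dark background (45) with a
bright lesion (+120) multiplied by unit-mean gamma speckle of shape 9 —
a multi-look smoothed-speckle model chosen so that the mass clipped at
255 is negligible and mean lesion intensity is preserved.  Grayscale is
replicated to 3 RGB planes for storage, since the classifier consumes
3-channel input.  Every image derives its RNG stream from
(seed, cell, index), so identical seeds give identical bytes.

What passing tests on this generator do and do not show: they demonstrate
that the architecture can extract a shape-based class signal under
modality-specific noise, that the pipeline's bookkeeping (splits, folds,
checkpoints, metrics) is correct, and that training is reproducible.
They say nothing about performance on clinical mammograms or ultrasounds,
whose variability (acquisition protocols, tissue texture, lesion
heterogeneity) the generator does not model.

## Desk-scale experiment sizes

The learning-sanity experiment uses 500 images per class (250 per class
per modality) at 64 x 64 with C0 = 8, an 80:20 split, and trains one
fold of the 5-fold protocol for 10 epochs.  Because the published
learning rate (1e-5) is calibrated to ~32,000 Adam steps (50 epochs on
10,400 images), the desk-scale run uses 1e-3 over its ~400 steps — the
equivalent step-size budget — while `TrainConfig` keeps the published
default.  The mini-GAN reference run trains 500 steps on 120 synthetic
ultrasound images at 32 x 32.

## Known limitations

* The NumPy engine targets clarity and desk scale, not throughput; there
  is no GPU path and no mixed precision.
* Pixel/encoder FID values are not comparable across embeddings or to
  Inception-based FID.
* The generator's two-class morphology is far cleaner than clinical
  data; accuracy numbers on it are sanity checks, not performance claims.
* Batch-norm statistics are per-fold; transferring a checkpoint to data
  with a different intensity distribution requires re-estimation.
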