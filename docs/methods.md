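# Methods

`feedback-rsa` implements a model–brain comparison workflow for studying
feedforward and feedback visual processing: a convolutional adversarial
autoencoder (AAE) is trained on category images, representational
dissimilarity matrices (RDMs) are computed for each of its layers, and
those RDMs are compared — via Spearman representational similarity
analysis (RSA) with cluster-permutation and bootstrap inference — against
temporally resolved (MEG-like) and spatially resolved (fMRI-ROI-like)
neural data. Real recordings are out of scope; a synthetic-data module
generates stimuli and neural data with *planted* representational
geometry, so every downstream stage is validated by parameter recovery.

## The model

The generator is a 13-layer autoencoder. The encoder has five
convolutional blocks E1–E5 (each: batch normalization → 3×3 stride-1
convolution → leaky-ReLU, slope 0.2 → 2×2 max-pooling) and a fully
connected layer E6; a linear projection LV produces the latent code. The
decoder mirrors it: fully connected D1, then five deconvolutional blocks
D2–D6 (batch normalization → convolution → leaky-ReLU → 2×2
nearest-neighbour upsampling), with D6 mapping to image channels through
a final tanh. Counting E1–E6, LV and D1–D6 gives the 13 parameterized
layers. Input images are scaled to [−1, 1]; the image side must be
divisible by 2⁵.

Training alternates two updates per minibatch:

* **Reconstruction** — pixel mean squared error ‖x − f(x)‖² through the
  full generator (Adam). Reported reconstruction *performance* uses mean
  absolute error (MAE); MSE is the optimization criterion, MAE the
  reporting metric, and both are exposed by `reconstruction_loss`.
* **Adversarial regularization** — a small fully connected discriminator
  (three layers by default; the width and depth are configurable)
  receives the latent vector concatenated with a one-hot category label.
  It is trained to separate (encoder latent, true label) from (standard
  normal draw, random one-hot label); the encoder is then updated to
  cross the boundary. At equilibrium the aggregate latent posterior
  matches the N(0, I) prior. The "random one-hot" for prior-side samples
  is a uniform category draw.

Unstated engineering choices, fixed as package defaults: Adam with
generator lr 1e-3, discriminator 3e-3, encoder-regularization 2e-3, all
decayed linearly to 5% over training (the decay settles the adversarial
game near its equilibrium; without it the latent moments oscillate);
batch 32–64; leaky slope 0.2; prior N(0, I). The full-scale 224×224
configuration with channel widths (16, 32, 64, 128, 256) and a 128-d
latent is a config point; the tested desk scale (`desk_scale_config`)
uses 32×32 images, widths (8, 12, 16, 24, 32) and a 16-d latent, which
trains to its loss plateau in ~2–3 minutes on one CPU. Ablations:
`make_plain_autoencoder` (no discriminator, reconstruction loss only) and
`make_untrained_model` (seeded random weights, never updated).

## RDM construction

* **Model layers**: activations per stimulus are flattened per block
  (evaluation mode — batch-norm running statistics, no stochastic ops)
  and converted to 1 − Pearson correlation distances.
* **fMRI-like patterns**: 1 − Pearson over condition × voxel rows.
* **MEG-like epochs**: per trial and sensor, the baseline mean
  (−200..0 ms) is subtracted and a zero-phase 4th-order Butterworth
  low-pass at 30 Hz is applied. At each time point, each condition's
  trials are randomly partitioned into 8 bins and subaveraged; a linear
  SVM (C = 1) is trained per condition pair with leave-one-pseudo-trial-
  pair-out cross-validation, and the mean accuracy, averaged over
  random-partition repeats (default 3), is the pairwise dissimilarity.
  The decoding RDM's diagonal is stored as zero and flagged by
  `dissimilarity_kind`; only strict lower triangles enter any statistic.

The SVM is solved by a vectorized dual coordinate-descent routine (the
liblinear L1-dual update, bias as an augmented feature) that handles all
pair × fold × repeat problems of a time point in one batch; a
`backend="sklearn"` option fits `sklearn.svm.SVC(kernel="linear")` per
fold instead, and the two agree to solver tolerance.

## RSA, ceilings, inference

Model–brain comparison is Spearman rank correlation over strict lower
triangles. MEG comparisons give a subject × layer × time correlation
series; fMRI ROI comparisons a subject × layer profile. The noise
ceiling follows the standard leave-one-out construction under Spearman:
the upper bound correlates each subject with the all-subject mean RDM,
the lower bound with the mean of the remaining subjects. Note the upper
bound is *not* null-centred: with no shared geometry at all it converges
to 1/√n_subjects because each subject is part of its own reference. ROI
profiles may be divided by a ceiling bound (default: the conservative
lower bound); MEG series are left raw.

Inference is nonparametric throughout:

* **Cluster-size permutation test** — one-sample t across subjects at
  each time point; contiguous runs above the cluster-definition
  threshold (default P < 0.01, one-sided positive) form clusters scored
  by size; the null distribution of the maximum cluster size comes from
  random subject sign flips (default 1000); clusters are significant at
  the cluster threshold (default P < 0.05). The two thresholds are both
  configurable because conventions differ between uses.
* **Bootstrap peak latencies** — subjects are resampled with replacement
  (default 1000 replicates); each replicate's average trace is searched
  for local maxima above a prominence threshold (default 10% of the
  trace range; raise it for traces with a single true peak) within a
  window (default 0–1000 ms); the selected peak's latency is recorded,
  and replicates without a qualifying peak are dropped and counted.
  Pairwise layer-latency differences are tested two-sided from the
  paired bootstrap distribution, Bonferroni-corrected across pairs.
* **Hierarchy correlations** — Spearman of layer rank vs latency with a
  permutation p-value (exhaustive up to 7 layers).
* **Layer comparisons** — paired two-sided t-tests (or sign-flip
  permutation) per layer with Benjamini–Hochberg FDR correction;
  all-zero differences give p = 1 by convention.

## Synthetic data: what it emulates and what it does not

**Stimuli.** Four procedural families — mirror-symmetric blob
arrangements ("faces"), curved closed contours ("animates"), rectilinear
compositions ("objects") and full-field horizon/texture layouts
("scenes") — with wide within-family parameter variation, a ±0.2
(normalized units) global translation jitter, weak fixed colour tints
and 0.05 pixel noise. The wide within-category variation and the
translation jitter emulate, at desk scale, the heterogeneity of natural
photographs: they load the *shallow* representation with
category-unrelated variance that pooling and compression progressively
discard, so category structure comes to dominate deep but not shallow
layer geometry. Within-category pixel correlation still exceeds
between-category correlation. A second generator,
`generate_probe_images`, draws octave-band noise images with no shared
structural dimension; these are the right *condition set* for
experiments that must tell individual layer geometries apart, because on
the category set the desk-scale model's adjacent-layer RDMs are nearly
collinear (r ≥ 0.96) and no analysis could identify six collinear
geometries.

**Planted geometry.** A `PlantedGeometry` is a target RDM, a latency, a
Gaussian temporal kernel (width parameter = 2 standard deviations,
default 50 ms) and an amplitude. Patterns are built by eigenfactoring
the implied correlation matrix R = 1 − RDM (negative eigenvalues
truncated) and projecting the factors onto random orthonormal, zero-mean
sensor/voxel basis vectors. Because the basis rows are orthonormal and
sum-free, the Pearson correlation of two embedded rows equals R exactly
whenever R is positive semidefinite — the noiseless pattern RDM *is* the
target. This spectral construction was chosen over plain classical MDS
of the distance matrix precisely for that exactness. Deep-layer RDMs
with tiny absolute dissimilarities embed as near-identical patterns that
no classifier can decode, so recovery experiments plant
`rescale_rdm`-normalized copies (a strictly increasing affine map of the
off-diagonal onto [0.4, 1.4]); rank-based recovery statistics are
unchanged by construction.

**Recordings.** MEG-like epochs default to the acquisition conventions
of the emulated study: 306 sensors, −200..1000 ms at 1 kHz (1200
samples), 25 trials per condition, with white per-trial sensor noise
(a correlated-noise option is deliberately left out; real MEG noise is
spatially and temporally correlated, which would lower effective SNR).
fMRI-like patterns are the shared embedding plus independent white
subject noise at the t-map level — no hemodynamics, no voxel
correlation structure. Consequences: passing recovery tests show the
*pipeline* is unbiased and calibrated on data whose generative model is
known; they do not show robustness to structured neural noise,
inter-subject spatial misalignment, or eye-movement/artifact confounds
of real recordings.

## Recovery experiments and their design

* **Two-geometry latency recovery**: two independent random-pattern RDMs
  (uncorrelated triangles) planted at 150 and 400 ms (kernel width
  30 ms, amplitude 0.08 vs noise 1.0, 4 subjects, 24 trials, 64
  sensors, 5 ms decoding stride). The amplitude is deliberately small:
  stronger signals saturate pairwise decoding at 1.0, which flattens the
  RDM near the peak and biases the correlation maximum toward the
  flanks. Under these conditions both maxima land within ±10 ms.
* **Hierarchy recovery**: the trained model's E1–E6 RDMs on 16 probe
  images, range-rescaled, planted at 100–400 ms in 60 ms steps
  (6 subjects, otherwise as above, 10 ms stride); the Spearman
  correlation between recovered argmax latencies and layer rank is
  ≥ 0.97 across tested noise realizations.
* **ROI profile recovery**: an EVC-like ROI generated from the stimulus
  pixel RDM and an IT-like ROI from a categorical block RDM (8 subjects,
  150 voxels, subject noise 0.5). The encoder-depth profile of the
  trained model decreases against the EVC-like ROI and increases against
  the IT-like ROI. This direction pair depends on training strength:
  training much longer or with much more data re-introduces per-image
  detail into deep layers and flattens the categorical gradient, so the
  reference model is trained to its loss plateau (350 epochs on 96
  images) and not beyond.
* **Training sanity**: held-out MAE of the trained model vs the MAE of
  untrained (random-weights) models. A single random initialization is a
  noisy baseline — random convolution chains leak low-frequency image
  structure to the output to a degree that varies by seed — so the
  baseline is the mean over three initializations. Latent moments are
  evaluated on the *training* set, the distribution whose aggregate
  posterior the adversarial game actually shapes.
* **Calibration**: decoding sits at 0.5 on signal-free conditions and
  1.0 on noiseless separable ones; the cluster test's false-positive
  rate over 200 null simulations stays within its nominal level plus
  two Monte-Carlo standard deviations; bootstrap peak CIs cover planted
  latencies with point estimates within ±10 ms.

## Numerical choices and degenerate inputs

Spearman of a constant vector (e.g. a fully saturated decoding RDM) is
undefined and returned as 0 (no rank information). `correlation_rdm`
refuses zero-variance condition rows by name. Cluster tests with all-zero
data produce no clusters (the t statistic is NaN-safe). Bootstrap
replicates without a qualifying peak are dropped and counted rather than
imputed. The permutation null for the cluster test exploits the
sign-flip invariance of per-time sums of squares, so each permutation
costs one matrix product. The neural-network layer framework is written
in numpy with explicit backward passes, verified against finite
differences; training is single-threaded-deterministic given the config
seed. MDS is metric SMACOF (seeded); figures render with a fixed
backend.

## Known limitations

Desk-scale training (32×32, 16-d latent, 96 images) reconstructs to an
MAE floor of ~0.15 set by architecture capacity, not data volume — the
trained/untrained contrast (~0.5×) is far smaller than a full-scale run
would give. Decoder and LV hierarchies are not exercised by recovery
tests (the decoder mirrors the encoder's construction; its RDMs are
equally near-collinear at desk scale). The cluster test assumes
exchangeable subjects under sign flips; the bootstrap treats subjects as
the only resampling unit. None of the paper-scale quantities (MAE of a
1.98M-image model, 15-subject peak-latency hierarchies) are desk-scale
targets.
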