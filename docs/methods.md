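# Methods

`singlehit` implements the single-hit classification stage of an X-ray
single-particle-imaging (SPI) analysis pipeline, together with the analytics
used to judge the quality of a selection.  This note records the models, the
parameters that matter, and the design choices made where more than one
reasonable option existed.

## The classification problem

In an SPI experiment, individual bioparticles (here modelled on a ~70 nm
quasi-spherical virus) are injected into a pulsed X-ray free-electron-laser
beam and each pulse produces one detector frame.  After upstream hit finding,
the surviving frames divide into *single hits* — scattering from exactly one
particle, the only frames usable for 3D reconstruction — and *non-single
hits*: multi-particle shots, aggregates, debris and weak residual frames.
Singles are rare (roughly 1 in 200 frames) and their identification is the
bottleneck the classifier removes.

## Classifier

The model is a pre-activation residual network.  A 3×3 stem convolution with
`base_filters` channels is followed by eight pre-activation residual blocks
(BN → leaky ReLU → 3×3 conv → BN → leaky ReLU → 3×3 conv, identity shortcut,
1×1 strided projection where shape changes).  Downsampling is by strided
convolution inside a block, and the channel count doubles at every
downsampling up to `max_filters`.  For the full-scale 192×96 detector patch
the default plan is five stride-2 steps on the long axis and four on the
short axis — one block uses an anisotropic (2, 1) stride — leaving a 6×6
feature map (channels 16→32→64→128→256) that is globally average-pooled and
mapped by a linear layer to two class scores.  This is the only stride
arrangement that reconciles "double the filters at each downsampling, cap at
256" with a 6×6 final map from a 192×96 input.  The leaky-ReLU slope defaults
to 0.01; the exact placement of downsampling among the blocks and the slope
are configurable because they are not uniquely determined by the
architecture's published description.

Training uses Adam on a per-class-weighted softmax cross-entropy with
minibatches drawn with replacement at a controlled class-presentation rate.
Two operating points are provided:

| setting            | MaxF1 (default) | moreSH (high recall) |
|--------------------|-----------------|----------------------|
| p(single in batch) | 0.02            | 0.05                 |
| loss weights (non-single, single) | (0.5, 0.5) | (0.1, 0.9)  |

The full-scale recipe is: batch 64, initial learning rate 1e-4, 1000 epochs
of 50 iterations (50 000 total), polynomial learning-rate decay
`lr0·(1 − t/T)^0.9`.  On-the-fly augmentation (rotation, scaling, elastic
deformation, gamma, Gaussian noise and blur, mirroring, shift, cutout)
compensates for the tiny positive class; gamma acts on the patch rescaled to
[0, 1] so it cannot blow up standardized values.  Model selection is
stratified 5-fold cross-validation; the five fold models predict jointly at
inference by averaging softmax outputs over the members and the four mirror
variants of the input (20 predictions per frame), thresholded strictly at
0.5 — an exact tie is conservatively non-single.

Frames are cropped to a fixed window of the live detector panel (the window
nearest the beam centre by default), masked pixels are zero-filled, and
intensities are standardized by the training set's mean and standard
deviation.  Optionally (`log_scale`) the counts pass through `log1p` before
standardization; diffraction intensity spans several orders of magnitude and
the compression makes low-intensity fringe structure visible to the network
at scale parity with the bright centre.  The statistics (and the transform
flag) are persisted with the ensemble so inference preprocesses identically.
The constants μ = 0.342, σ = 2.336 from the experimental training set are
retained as defaults for real-data runs.

### The network engine

No GPU framework is used: `_nn.py` is a compact NHWC numpy engine
(convolution, batch normalization, leaky ReLU, global average pooling,
linear head, weighted cross-entropy, Adam) with hand-written backward passes.
The convolution and normalization inner loops are numba-compiled when numba
is available, with an im2col/BLAS fallback otherwise.  Correctness is pinned
by float64 central-difference gradient tests and a numba-vs-numpy agreement
test; training is bit-deterministic for fixed seeds on a fixed BLAS.

## Synthetic data generator

The simulator reproduces the statistical structure of the experiment so that
every downstream stage is testable without the (optional) experimental
accessions:

* **Geometry** — far-field two-panel detector, one panel dead, 0.130 m
  distance, 75 µm pixels, λ = 0.729 nm (1.7 keV); q = (4π/λ)sin θ with
  2θ = arctan(r/D).
* **Single hits** — uniform-sphere diffraction
  I(q) = I₀·[3(sin qR − qR cos qR)/(qR)³]², radius drawn uniformly from
  27.5–42 nm (diameter 55–84 nm) with a 20% contaminant fraction outside that
  band so size filtering has real work to do.
* **Non-single hits** — coherent sums of 2–4 spheres with random in-plane
  displacement vectors of 100–600 nm (squared modulus of the summed
  amplitudes produces interference speckle crossing the fringes), or, for a
  configurable fraction (default 0.3), weak/empty frames that survived
  upstream hit finding.
* **Noise** — per-pixel Poisson counting, log-normal shot-to-shot fluence
  jitter (σ = 0.5), and a flat background (default 0.05 photons/pixel).
  Scattering power scales with particle volume squared, i.e. R⁶ in intensity.
* **Class balance** — 1 single per 200 frames when drawing streams; labelled
  data sets take explicit class counts (the reference split is 100 singles /
  19 900 non-singles).

The default forward intensity, 20 photons/pixel at q → 0 for a band-centre
particle at nominal fluence, describes a bright hit with clearly visible
fringes.  What the generator does **not** model: icosahedral/atomistic
structure factors, detector gain and dark-current maps, structured (jet)
background, saturation, and the unknown composition of the real non-single
population (exposed as configuration instead).  Passing tests on synthetic
data therefore demonstrate that the pipeline's machinery is correct and that
the recipe behaves as published under controlled conditions — not that any
particular real-data F1 value would be reproduced.

## Selection analytics

* **Precision/recall/F1** — P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R);
  degenerate denominators give 0.
* **IoU (α)** — 100·|A∩B| / |A∪B| between selection id sets, with an
  all-pairs comparison matrix (counts + percentages) and a multi-set variant
  100·|∩ᵢAᵢ|/|∪ᵢAᵢ|.  Percentages are displayed with nearest-integer
  rounding; full precision is kept internally.
* **PSD** — the azimuthal average of frame intensity in q bins (default 200
  linear bins over the live-panel q range), averaged over all frames of a
  selection, with per-bin valid-pixel occupancy.
* **PSD contrast** — extrema are detected on log10 of the max-normalized
  curve after a Savitzky–Golay smooth (window 7 bins, polyorder 2) with a
  prominence threshold of 2% of the curve's range; the i-th maximum is paired
  with the first minimum following it, and C is the mean paired difference
  over the first N = 3 pairs.  The log/linear scale is a switch: published
  PSD figures are logarithmic and order-unity contrast values are consistent
  with log-scale differences, but no extremum-detection procedure is
  published, so contrast values are comparable within one procedure only and
  are treated as an ordering, not an absolute.
* **Sizing** — per-frame, from the frame's own PSD: default a least-squares
  fit of the sphere intensity with free radius, scale and flat background
  (radius grid-searched at 0.5 nm then refined), falling back to the
  asymptotic fringe relation diameter = 2π/Δq from the mean spacing of
  successive minima.  Frames without a usable estimate are flagged
  size-undetermined and dropped by the filter rather than failing the run.
* **Size filter** — keep diameters in [55, 84] nm, bounds inclusive.
* **Background** — mean PSD intensity over a high-q window where particle
  signal is negligible; flat subtraction clamps at zero.

## Scaled study sizes

CPU-scale runs use a miniature version of the study: a 64×64 half-dead
detector at the experiment's q-sampling (so multi-particle speckle spans
2–13 pixels exactly as it would on the real detector), 32×32 crops, a
base-8/max-64 filter network with four stride-2 blocks (final 2×2 map),
batch 32, initial learning rate 1e-3, 1500–2000 iterations per fold,
`log1p` preprocessing, and patch-proportional augmentation.  The shorter schedule
needs the larger initial rate: with the full-scale 1e-4 each positive
example influences too few updates to generalize before the budget ends.
Training sets are 100 singles / 3900 non-singles (the reference class-count
recipe at reduced frame count).  The full-scale defaults in `ModelConfig` /
`TrainConfig` remain the published recipe throughout.

At these short schedules neither full-scale operating point is F1-optimal:
the 2%/equal-weights settings leave the network under-confident at the 0.5
threshold (the output stays anchored near the presentation prior), while
5%/0.1-0.9 over-predicts.  `TrainConfig.scaled_f1` — 3% minority
presentation, 0.3/0.7 loss weights, and a short augmentation cool-down (the
final 15% of iterations run without augmentation so confidence on clean
inputs recovers) — was selected by validation-split F1 over candidate
settings, the same selection-by-cross-validation methodology that defines
the full-scale F1-optimal configuration.  The cool-down fraction is 0 in the
full-scale recipe.

## Known limitations

* The scaled network and schedule are not the published full-scale ones;
  absolute synthetic scores do not transfer to real data.
* At the scaled 32×32 crop, aggregates with small inter-particle
  displacements (~100–150 nm) produce only ~2–3 interference periods inside
  the field of view and are close to indistinguishable from single hits;
  they dominate the false positives of every configuration tried (ensemble
  members agree on them, so test-time averaging cannot remove them) and cap
  the scaled held-out F1 near 0.78 even though ranking quality is high
  (AUC ≈ 0.99).  The full-scale 192×96 crop resolves 8–25 periods for the
  same aggregates, so this ceiling is an artifact of the reduced geometry,
  not of the method.
* PSD contrast values depend on the extremum-detection procedure (see above).
* The sphere model makes sizing exact by construction on synthetic data;
  real particles deviate from sphericity and real size estimates inherit
  model error.
* Monodisperse aggregates leave the azimuthally averaged fringe positions
  intact (their interference cross terms share the single-particle zeros);
  contrast degradation from non-singles requires size heterogeneity, which
  the generator's defaults provide.
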