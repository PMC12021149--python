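# Methods

`strawseg` is a self-contained sim-to-real pipeline for strawberry ripeness
segmentation: a procedural generator of plant scenes with pixel-perfect
tri-class masks, a SwinUNet segmenter, a joint supervised + domain-confusion
objective, and per-class Dice evaluation. This note records the models, the
defaults and why they are what they are, the numerical choices, and what the
desk-scale experiments do and do not demonstrate.

## Procedural scenes

A scene is a flat list of 2-D primitives — wall, stem polylines, trifoliate
leaf clusters (three rotated ellipse lobes), fruit ellipses with a calyx cap,
five-petal flowers — each with an analytic coverage test in world
coordinates, a coloring rule, a semantic class, and a scalar depth key.
Rendering is a painter's algorithm over the depth-sorted list; the mask is
rasterized from the same transformed geometry, so a pixel's label is exactly
the class of the topmost covering primitive. Consequences:

- Occluded fruit regions are *not* labeled (visibility-based masks, as a
  compositing pipeline would produce them).
- Stems, leaves, flowers, calyces and the wall all map to background (0);
  ripe fruit is 128, unripe 255.
- Re-rasterizing any subset of primitives and recomposing by depth
  reproduces the emitted mask exactly — this "alignment oracle" is tested.

Plant randomization is driven by `RandomizationRanges`, constrained
intervals for stem count/curvature noise, leaves per stem, leaf scale/hue
(HSV degrees, light-to-dark green)/curl, fruit count (at least 2) and scale,
continuous ripeness stage in [0, 1], flower probability, camera track
position and roll, and a multiplicative brightness. Defaults emulate a small
indoor grow-wall plant (2-4 stems, 2-5 leaves per stem, 2-6 fruits); fruit
pixels come to roughly 3% of a frame, so the class imbalance that motivates
weighted losses is present in the synthetic data.

A fruit's ripeness stage colors it along a linear green-to-red gradient with
per-fruit jitter and is thresholded at 0.5 (stage >= 0.5 is ripe; the
midpoint with an explicit tie rule, since only the continuum is physically
meaningful). The stage sampler retries (bounded, 20 attempts) until both
classes are present on the plant, and dataset generation additionally
retries the camera/occlusion draw until both classes are *visible*, so every
emitted image contains ripe and unripe pixels. A stage interval narrowed to
one side of the threshold therefore fails generation with a clear error.

The camera track is a one-parameter family of viewport similarity
transforms: track position translates the view laterally (up to ±15% of the
frame), the angle rotates it about the frame center. Image size defaults to
224×224 (any size divisible by 32 is accepted — the patch embedding and
three 2× merges need 4·2³ = 32 to divide both sides); the desk preset uses
64×64.

Randomness: one root seed; per-sample child seeds are spawned with numpy's
`SeedSequence` (documented splitting rule), and all texture noise within a
render derives from the sample seed. Identical (config, seed) gives
bit-identical PNGs across runs.

### Domain shift

`DomainShiftParams` is a desk-scale stand-in for a real target domain
(photographs of real plants): HSV hue rotation and desaturation, a busier
background (low-frequency colored field blended into mask==0 pixels, or
speckle), Gaussian blur and sensor noise, and vignetting. Masks are returned
bit-identical; each step is skipped exactly at its identity parameter, so
the all-zero setting is a no-op. What this emulates: global color statistics,
texture clutter and optics. What it does not: perspective-dependent lighting,
specular highlights, real leaf morphology, physically damaged fruit —
passing desk-scale tests therefore bounds optimism about real imagery.

## Segmenter

SwinUNet: 4×4 patch embedding, encoder stages of Swin blocks (window
multi-head self-attention alternating with shifted-window attention,
relative position bias, LayerNorm, MLP with ReLU — GELU by flag), patch
merging between stages, a bottleneck, and a mirrored decoder with patch
expanding, one skip connection per resolution (concat + linear reduction),
a final 4× patch expansion and a linear 3-class head. Shifted windows use
cyclic shifts with additive −1e9 masking across wrapped borders; a window
not dividing the stage resolution is a configuration error unless it covers
the whole map, in which case attention degenerates to global attention over
the map.

The full-scale preset follows the common Swin-T layout (embed 96, depths
(2,2,6,2), heads (3,6,12,24), window 7 at 224²). The desk preset — embed 24,
depths (2,2), heads (3,6), window 4 at 64² — has ~108k parameters and trains
on a CPU in minutes. Encoder weights can be loaded from a checkpoint;
default is random init (trunc-normal 0.02), as no pretrained source is
assumed.

The network is implemented as pure numpy functions over a nested parameter
dict and differentiated with HIPS `autograd`; training therefore needs no
GPU framework, at the cost of speed — which the desk presets are sized for.

Domain-adaptation features are the global-average-pooled bottleneck tokens
(width `embed_dim · 2^(stages−1)`), the deepest, most abstract
representation shared by both decoder and domain alignment.

## Objective

    L = (1 − α) · CE_w  +  α · Dice  +  λ_t · MMD²

- **Weighted cross-entropy** normalizes by the realized weight mass
  (Σ w_t·nll / Σ w_t), so equal weights reduce to the plain mean and the
  uniform-logit value is exactly ln 3. Default class weights
  (0.5, 1.0, 1.0) keep the rare fruit classes dominant.
- **Soft Dice** pools pixel sums over the batch per class, ε = 1e-6;
  α = 0.5 mixes the two segmentation terms equally.
- **MMD²** is the biased V-statistic (diagonal included — stable for small
  batches, and what the in-test double-sum oracle computes):
  mean k(S,S) + mean k(T,T) − 2 mean k(S,T). Kernels: linear (reduces to
  the squared distance of domain means, the original Deep Domain Confusion
  statistic) and RBF summed over a bandwidth list, default the
  {0.5, 1, 2}× median pairwise distance heuristic, computed once from the
  initial features and frozen (the kernel is a fixed function during
  optimization, outside the gradient tape).

**Domain-weight schedule.** λ_t is held at 0 for the first half of training
and ramped linearly to its full value (default 0.25) over the next quarter.
This "fit first, then align" schedule exists because the alternative
demonstrably fails at desk scale: with λ > 0 from step 0 the encoder
minimizes MMD the cheap way — collapsing domain-discriminative (and
task-relevant) features before the segmentation signal has shaped them — and
training settles into all-background predictions. Delaying alignment until
the task features exist turns the MMD term into a genuine distribution
aligner. Ramped schedules for adaptation terms are standard practice in
domain-adversarial training; the variant here is the simplest one that
works. Both fractions are configurable (`domain_delay_frac`,
`domain_ramp_frac`).

## Training

AdamW (lr 3e-4, weight decay 0.01, β = (0.9, 0.999)) with cosine decay; the
optimizer, rate and schedule are conventional choices for Swin-style models
— none are dictated by the problem. Each step draws a labeled source batch
(shuffled without replacement per epoch) and an unlabeled target batch
(with replacement). Validation DSC runs every `eval_every` epochs; the
checkpoint with the best fruit-class mean is retained alongside the final
parameters. Checkpoints are a single `.npz` with a JSON config echo. All
randomness flows from `TrainConfig.seed`; two runs with the same config
produce identical loss histories bit for bit.

The dataset-size study trains one fresh model per size on prefixes of a
fixed generated pool and evaluates every row on the same held-out
domain-shifted set, mirroring independent-row scaling tables.

## Desk-scale problem sizes

All tests and the acceptance script run on the desk preset: 64×64 images,
the 108k-parameter model, 200 training images / 30 epochs for the
fixed-size run, and a {100, 1000}-image ladder at 6 epochs for the scaling
trend. These sizes are the package's CPU-friendly study conditions; they
preserve the structure of the full-scale experiment (10⁴ images, 400
epochs, 224² inputs — configurable but impractical without a GPU) while
keeping any single run in the minutes range. Observed desk-scale behavior:
held-out synthetic DSC around 0.99 background / 0.85-0.9 ripe / 0.75-0.8
unripe; unripe is consistently the hardest class (green fruit on green
foliage), the same ordering the full-scale setting reports.

## Numerical choices and degenerate inputs

- DSC of a class absent from both prediction and truth is 1.0 (agreed
  absence); dataset scores micro-average pooled counts (order-invariant),
  macro by flag.
- Softmax and log-softmax are max-shifted; attention masking uses −1e9
  logits (exact zeros after softmax at float32).
- Mask PNGs are single-channel 8-bit; any value outside {0, 128, 255} is a
  format error listing the offenders. Nearest-neighbor resampling of masks
  cannot introduce new labels; letterboxing pads with background.
- Grayscale conversion (provided as a preprocessing utility, not in the
  inference path — the model consumes RGB for both domains) uses ITU-R 601
  weights, rounded half up.
- NaN/Inf in a forward pass surfaces as a numeric error naming the stage.

## Known limitations

- The rasterizer is deliberately stylized; it preserves the statistical
  structure the method needs (occlusion, class imbalance, appearance
  randomization) rather than photorealism.
- The synthetic domain shift cannot certify real-photograph performance.
- MMD with small batches is a noisy distribution distance; the V-statistic
  bias is of order 1/n.
- Window padding for non-divisible resolutions is not implemented; sizes
  divisible by 32 with the default windows avoid it entirely.
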