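# Methods

`bandfuse` classifies *multiband patterns* — samples made of C
co-registered single-band 2-D rasters, such as the 13 spectral bands of
a Sentinel-2 tile, the 10 bands of an urban climate-zone patch, or the
16 illumination angles of a reflected-light microscopy stack of a
foraminifera shell.  Its central idea is an ensemble whose members each
see the bands differently: every member is a neural network trained on
its own three-channel or K-channel re-encoding of the band stack, and
the members' class-probability vectors are added (the sum rule), the
argmax of the sum giving the prediction.

## Normalization

Raw band values are non-negative reals on sensor-specific scales.  Two
procedures map them to uint8:

* **per_band_max_tenth** — let `rec[b]` be the maximum value of band *b*
  over the *training* patterns.  A value *v* maps to the 8-bit cast of
  `v / ((rec[b]/10) / 255)`, so anything at or above one tenth of the
  training maximum becomes 255.  This is deliberate outlier handling:
  multispectral sensors produce occasional readings an order of
  magnitude above scene level, and scaling by the raw maximum would
  crush the useful dynamic range into a few gray levels.
* **fixed_scale** — when all bands share a known physical ceiling *m*
  (e.g. 2.8), *v* maps to the 8-bit cast of `v / (m/255)`.

The 8-bit cast rounds half away from zero and saturates at 0 and 255
(`bandfuse.normalize.cast_uint8`), matching the saturating-cast
semantics of the numeric environment the procedure originates from.
Arithmetic is double precision with a single cast at the end.
Statistics are fitted per training fold, serialized to JSON, and never
updated by test data.  Normalization precedes augmentation, so the
augmentation operates on 8-bit images; the reverse order is also
defensible but was not adopted.

## Channel recipes

A recipe is an ordered list of source-band positions:

* **grayset** — band *i* replicated into all three color planes,
  giving C deterministic views per pattern whose scores are averaged at
  evaluation time (one network, C views);
* **random** — three i.i.d. uniform draws over all bands;
* **random_one_rgb** — as random, but one slot (its position itself
  uniform over the three positions) is drawn uniformly from the declared
  red/green/blue bands, which tend to be the strongest predictors;
* **bagged** / **bagged_first_rgb** — K i.i.d. draws with replacement
  (optionally pinning the first channel to an RGB band) for networks
  with multichannel input.

All draws are with replacement and unconstrained — degenerate views
such as an all-red triplet are allowed on purpose.  The ensemble's
strength comes from member diversity, not per-member optimality.
Recipes are drawn once per member before training and frozen; they
serialize to JSON with their seed and replay exactly.

## Architectures

All networks are built on `bandfuse.nn`, a compact tape-based
NumPy automatic-differentiation engine written for this package
(reverse-mode autograd; im2col convolutions; 3-D convolution;
max/adaptive-average pooling; batch/layer normalization; multi-head
attention; SGD with momentum, Adam, step decay).  Pure NumPy makes runs
bit-reproducible on a fixed machine and keeps the dependency surface to
the scientific stack.

* **Classic RGB backbones** — ResNet50 (bottleneck stages 3-4-6-3),
  DenseNet201 (growth 32, blocks 6-12-48-32, half-compression
  transitions), MobileNetV2 (inverted residuals, expansion 6, ReLU6).
  They follow the published architectures, require exactly three input
  channels, and end in global average pooling plus a task-sized linear
  head; every layer is trainable.  Weights initialize from He/Glorot
  draws; previously trained checkpoints can be loaded through
  `load_state_dict`.
* **Cres** — a stem convolution (64 filters, 3×3) with 2×2 max pooling,
  then three macroblocks (128, 256, 512 filters).  Each macroblock is a
  four-branch inception transform (1×1; 1×1→3×3; 1×1→5×5; 3×3
  max-pool→1×1, each branch carrying filters/4) inside a residual
  connection whose 1×1 convolution aligns shapes.  Every convolution
  except the residual 1×1 is followed by batch normalization; ReLU
  everywhere, including after the residual addition (a design choice —
  the alternative of a linear addition is equally defensible).  A 64×64
  input leaves the last macroblock as 512×4×4; the head is
  8192→1024→256→classes.  Input sizes must be divisible by 16.
* **Catt** — bands on the depth axis of 3-D convolutions with a
  singleton feature axis prepended.  Three Conv3D(3×3×3)→BatchNorm3D→
  Tanh blocks (32, 64, 128 channels); 1×2×2 max pooling after the first
  two blocks halves height and width while preserving spectral depth;
  adaptive average pooling then fixes the map at 1×8×8 regardless of
  input size.  The 64 spatial positions become tokens (channel vectors
  as features), linearly projected to d_model=256, summed with
  sinusoidal positional encodings, and refined by six post-norm
  Transformer encoder layers (8 heads, FFN width 512, softmax(QKᵀ/√d_k)V
  attention, max(0, XW₁+b₁)W₂+b₂ feed-forward, residual connections and
  layer normalization).  Token mean-pooling feeds the linear head.
  Tokenization, d_model, head count, FFN width and the pooling head are
  this package's choices where the design was open; they are exposed in
  `CattSpec` so experiments can pin them.
* **TinyCNN** — two conv/BN/ReLU/pool stages (8 and 16 filters), global
  average pooling, linear head; under 50k parameters.  It is the
  desk-scale stand-in that lets end-to-end ensemble behavior be
  exercised on a CPU in seconds per member.

## Training

Presets (`bandfuse.training.PRESETS`):

| preset | optimizer | lr | batch | epochs | schedule | augment |
|---|---|---|---|---|---|---|
| pretrained | SGD (momentum 0.9) | 1e-3 | 30 | 20 | — | yes |
| pretrained_large | SGD (momentum 0.9) | 1e-3 | 30 | 10 | — | no |
| custom | Adam | 1e-3 | 30 | 20 | ×0.5 every 5 | yes |
| tiny | Adam | 1e-2 | 30 | 10 | ×0.5 every 5 | yes |

Momentum 0.9 is the conventional default for SGD fine-tuning.  The
`pretrained_large` preset reflects the very-large-dataset regime where
augmentation is unnecessary and the schedule is halved.  Loss is
cross-entropy throughout; a NaN loss aborts with a diagnostic.

Augmentation is materialized offline, ×4: original, top–bottom
reflection, left–right reflection, and an anisotropic scaling whose two
factors are drawn from U(1, 2) per axis (bilinear magnification followed
by center-cropping back to the original size, so batch shapes never
change; all bands of a pattern transform identically).  The U(1, 2)
magnify-and-crop choice sidesteps the padding question that
shrinking factors would raise.

After the optimization loop the batch-normalization running statistics
are recalibrated: one cumulative-average pass over shuffled training
batches under the final weights.  Short, high-learning-rate runs
otherwise leave the exponential running estimates lagging the
activations the trained weights actually produce, which depresses
eval-mode accuracy; shuffling matters because class-ordered batches
would push the between-class spread out of the variance estimates.

Inputs reach the network as recipe views scaled to [0, 1] (uint8/255),
resized bilinearly if the network's configured input size differs from
the data.  Scoring runs in eval mode without augmentation; a grayset
member emits one score row per band view, tagged with the pattern id,
and the view rows are averaged before fusion.

## Fusion and metrics

Members' raw score rows are softmaxed (max-subtracted for stability)
before summation so all members contribute on the probability scale;
the fused score is Σᵢ wᵢ·vᵢ with positive weights, and an integer weight
w replicates summing that member w times — useful when a small family
of expensive networks should count as much as a larger family.
Predictions are the per-pattern argmax (NumPy's first-index tie-break).

Metrics come from per-class one-vs-rest confusion counts: precision
TP/(TP+FP), recall TP/(TP+FN), F1 = 2TP/(2TP+FP+FN), overall accuracy
(TP+TN)/(TP+TN+FP+FN); classes are summarized by macro (unweighted)
averaging.  Micro or weighted averaging are defensible alternatives;
macro was chosen because it treats rare classes on equal terms, which
matches how per-class results are usually tabulated in this area.  A
zero denominator yields 0 with a warning — deterministic and
conservative.

Protocols: stratified seeded four-fold cross-validation (mean over
folds) or a stratified fixed split (e.g. 80/20).  Normalization and
augmentation are fitted/applied strictly within each training fold.

## Synthetic fixtures

The generator (`bandfuse.synthetic`) produces datasets whose
separability is known by construction, so test thresholds are honest
rather than tuned:

* **Spectral regime** — class *c* has per-band mean `signature[c, b]`;
  patterns are the signature broadcast over space plus i.i.d. Gaussian
  noise clipped at 0 (clipping, not wrapping, preserves non-negativity),
  optionally textured with Gaussian blobs.  Rare outlier pixels (~10×
  scene level) emulate the heavy-tailed sensor readings that the
  max/10 normalization rule exists for — without them that rule would
  saturate everything and the fixture would be unusable evidence.
  Band informativeness can be heterogeneous (a few strong bands among
  many weak), which mirrors the empirical pattern that visible-band
  channels outpredict the others in satellite collections and is what
  makes random channel-subset members genuinely diverse.
* **Multiview regime** — emulates multi-illumination microscopy: each
  class owns a fixed spatial reflectance prototype (a class-seeded blob
  texture at a class-specific brightness level — a cartoon of shell
  morphology), each pattern adds small per-pattern texture jitter, and
  every channel is that base modulated by a per-channel linear shading
  ramp of distinct orientation, one per illumination angle.  The
  16-view, 7-class default includes one 3× larger "rest" class to
  exercise imbalance.

`expected_separability` returns a nearest-centroid accuracy estimate
for the flat-field regime from the pairwise-Gaussian union bound
Φ(−d/2σ) on band means (σ = noise_sd/√(H·W)), clipped at the
random-guess floor — tight when errors are rare, conservative
otherwise, and cross-checked against a Monte-Carlo oracle in the tests.

What the fixtures do *not* model: spatial texture that carries class
information, band-to-band correlated noise, atmospheric effects,
georeferencing artifacts, or anything resembling real foraminifera or
satellite imagery.  Passing tests therefore certify the pipeline's
mechanics and its ensemble behavior under controlled diversity, not
benchmark-level performance on real data — the full-scale runs with
fine-tuned pretrained backbones live outside this package's test
envelope.

## Problem sizes

Desk-scale experiments use 13-band 10-class 32×32 fixtures of 120–200
patterns and the tiny CNN (10 epochs), chosen so a full ensemble-size
sweep (5 seeds × 10 members) and the complete test suite run on a
single CPU in minutes.  The ensemble-size sweep fixes noise_sd = 25
with three strong bands of 13, a regime where single members span
roughly 40–90% accuracy and fusion visibly stabilizes them — the same
qualitative shape as ensemble-size curves on real multiband benchmarks,
with the steep gains concentrated in the first handful of members.

## Known limitations

* The NumPy engine is single-threaded per op (BLAS-backed matmuls
  aside) and sized for desk-scale work; full-resolution fine-tuning of
  the classic backbones is out of its intended envelope.
* ImageNet-pretrained weights are not bundled; backbones start from
  random initialization unless a checkpoint is supplied, so their
  desk-scale accuracy says nothing about their fine-tuned potential.
* Catt requires input height/width that are multiples of 4 and at
  least 32 so the pooled map reaches 8×8; Cres requires divisibility
  by 16.
* Bit-reproducibility holds per machine/BLAS build; exact values can
  differ across platforms.
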