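# Methods

This note records the models, parameter choices and numerical
conventions behind `chronorsa`, and what its synthetic benchmarks do
and do not demonstrate.

## Segmentation architectures

All three networks share one fully convolutional encoder–decoder plan:

- encoder channels 16 / 32 / 64 (three 2×2 average-pooling stages),
  bottleneck 128;
- two 3×3 convolutions per level, **bias-free**, each followed by batch
  normalization (trainable scale and shift) and an ELU;
- decoder upsampling by 3×3 stride-2 transposed convolutions
  (implemented as zero-stuffing + same convolution), skip connections
  merged by **summation**, not concatenation;
- a final 3×3 convolution to two channels and a softmax over
  {background, root}; the probability map is the root channel.

This plan has exactly **488,212** trainable parameters for the plain
(UNet) variant, matching the reference budget for this architecture
family. The ResUNet replaces each two-convolution block with a
residual block whose shortcut is a 1×1 bias-free projection plus batch
norm (applied at every block, including same-width decoder blocks),
adding 16,848 parameters (505,060 total). The deeply supervised
variant (DSResUNet) concatenates the ResUNet's softmax output with the
input image and refines it through two further convolutions
(3 → 580 → 2 channels, batch-normalized), adding 27,264 parameters
(532,324 total); both stages are exposed so the training loss is the
sum of two cross-entropy terms.

The reference budgets for the residual variants are 505,046 and
532,336 — 14 parameters away in each direction. An exhaustive search
over standard structural variants (kernel sizes, bias conventions,
normalization, shortcut placement, head shapes, free channel widths)
shows that no conventional design reaches those two values jointly
from any plan that reaches 488,212; the counts achieved here are the
closest principled designs, and the width of the refinement head (580)
was chosen so that its parameter budget matches the reference
increment (~27 k, i.e. ≈5% model growth). The discrepancy is 3 × 10⁻⁵
in relative terms and has no effect on behaviour.

`ArchitectureConfig` exposes the knobs (base width, depth, block type,
deep supervision, head width); the parameter count of a built model is
a pure function of the config, and depths that would shrink the
declared minimum input below 1 px at the bottleneck are rejected.

## The numpy network engine

No deep-learning framework is used: `chronorsa.nn` is a small
reverse-mode autodiff engine over float32 NCHW arrays providing
exactly the operations the plan needs (same-convolution via im2col,
zero-stuffed transposed convolution, 2×2 average pooling, ELU, batch
norm with running statistics, summation/concatenation, channel
softmax, softmax cross-entropy) plus Adam with L2 weight decay. Every
operation's gradient is pinned by finite-difference checks in the test
suite. Inference pads inputs by reflection to a multiple of the
pooling footprint and crops back, so output shape always equals input
shape regardless of size.

## Training protocol

Defaults follow the standard protocol for this family: cross-entropy
loss (two summed terms when deep supervision is active), Adam at
learning rate 1e-4 with weight decay 1e-8, 256×256 patches in batches
of 8, patches centered on a root pixel with probability 0.5 (roots
occupy a tiny image fraction, so unbiased sampling would starve the
loss), and online augmentation: horizontal flip (applied to image and
mask), Gaussian noise, random gamma and blur (image only).

Training the full-size networks to plate-imagery accuracy needs GPUs
and an annotated corpus, which is out of scope here. The repository's
**toy benchmark** instead trains a narrow DSResUNet (base width 8,
depth 2, head width 16 — same topology, ~33 k parameters) for 200
steps on 20 synthetic image/mask pairs with 96×96 patches, batch 8,
learning rate 3e-3. On one CPU this takes ~2–3 minutes and reaches a
held-out Dice above 0.9; the suite asserts > 0.8. Training is
deterministic for a fixed seed on a fixed machine; bit-level
reproducibility across BLAS builds is not promised, only statistical
reproducibility of the benchmark.

## CRF refinement

The dense CRF assumes contiguous pixels of similar intensity share a
label. Unary terms are −log of the (background, root) probabilities;
the pairwise term is a Potts compatibility (weight 3) over a bilateral
appearance kernel with spatial std θ_α = 5 px and intensity std
θ_β = 3 grey levels. Mean-field inference runs 5 iterations (a common
default; the update is usually converged after 3–4). Message passing
under the Gaussian kernel is approximated on a bilateral grid sampled
at one standard deviation per axis (splat → unit-σ Gaussian blur →
nearest-bin slice), the standard fast approximation for fully
connected CRFs. Degenerate probability maps (all 0 or all 1) are
returned unchanged.

## Temporal consistency and mask extraction

The trailing average aᵗ = sᵗ + α aᵗ⁻¹ with α = 0.9 (first frame:
a¹ = s¹) acts as an occlusion memory: a persistently segmented pixel
follows the closed form a_k = 10 (1 − 0.9ᵏ), saturating at
1/(1−α) = 10, while a single-frame artifact never exceeds 1 + α. The
extraction threshold is 1.0: a persistent pixel crosses it on its
second frame, a one-frame droplet reflection never does, and a pixel
occluded for one frame retains a = 0.9 · a_prev ≫ 1. (Numerically,
the gap to the limit at frame 150 is 10 · 0.9¹⁵⁰ ≈ 1.4 × 10⁻⁶; the
series first comes within 10⁻⁶ at frame 153.) Per-plant masks are
cut from the accumulated map by ROI crop → threshold → 3×3 closing
then opening (bridges 1-px gaps, removes isolated pixels; 3×3 matches
the thinnest expected root stroke) → largest 8-connected component
(4-connectivity would fragment thin diagonal roots). An empty result
is an explicit "no plant detected" signal (`None`), which the pipeline
flags per frame; with threshold 1.0 this is expected on the first
frame of every run.

## Graph reconstruction and labelling

Masks are thinned with a topology-preserving skeletonization. The
skeleton's 8-neighbour adjacency is traversed depth-first from the
seed — the topmost skeleton pixel, or the pixel nearest a caller
hint — visiting neighbours in a fixed clockwise order starting from
"down", which makes traversal and bifurcation tie-breaks
deterministic. The DFS tree is condensed to a graph whose nodes are
the seed, bifurcations and tips; edges carry the traversed pixel path
and its arc length (1 px per axis step, √2 per diagonal, scaled by
mm/px). Leaf twigs shorter than 3 px hanging off a junction are
pruned: thinning a 3-px-wide stroke leaves 1–2 px side twigs at
junctions and blunt ends, while a genuine young lateral is longer than
the stroke width as soon as it is visible at all.

Labelling: in the first frame the seed-to-deepest-tip path (by arc
length) is the MR. In later frames the MR tip is the node nearest the
previous MR tip — searched among leaves first, so the MR tip stays a
tip, with junction nodes as fallback when the tip has merged into
another root — and the seed→MR-tip path is the MR even when a lateral
has grown longer. Previous LR tips are matched to their nearest
current node (gate 20 px, far above per-frame growth at 15-min
cadence), so a lateral that collides with the MR or another lateral
keeps its tip identity; unmatched tips start new laterals. Every edge
is assigned to exactly one root (tip-to-MR walks claim unclaimed
edges), so MR + Σ LR equals the total skeleton arc length identically.
If the previous MR tip has no node within the gate, the frame is
flagged as a tracking failure and the fallback rule is used.

Two quantitative caveats of this measurement model:

- **Chain-code length bias.** The {1, √2} step metric overestimates
  straight lines at orientations away from 0°/45°: +3.2% at 50° from
  vertical, +5.7% at 55°, up to +8% at 22.5°. Ground-truth recovery
  within 5% therefore holds for roots within roughly ±50° of vertical
  or diagonal — the gravitropically realistic range — not for
  arbitrary orientations.
- **Emergence detection.** A lateral becomes separable from the MR
  skeleton only once it protrudes beyond the stroke; at the synthetic
  benchmark's resolution this is the frame of emergence provided the
  lateral is born with its spec'd initial visible length (see below).

Simplification collapses unlabelled degree-2 nodes, concatenating
paths and summing lengths, and never merges across root-class
boundaries. RSML export writes one document per time step (or one
consolidated multi-scene file), with polylines in mm, per-root length
properties, and laterals nested inside the MR element; a structural
XML schema for the dialect ships with the package and is enforced in
the tests.

## The synthetic generator

The generator emulates what the measurement chain actually faces in
near-infrared plate imagery: a bright thin root on a darker
background (default levels 180/50), additive Gaussian sensor noise
(σ = 6 grey levels), per-frame illumination (gamma) jitter
(0.9–1.1), and transient circular droplet occluders that erase root
pixels in isolated frames only — droplets only ever remove signal,
so they specifically exercise the temporal memory. Geometry: the MR
grows straight down from the seed at a configurable (possibly
sinusoidal) speed; each lateral emerges at a configurable time,
attached 1 mm above the MR tip's position at that moment (laterals
emerge from the mature zone, never the elongation zone), with an
initial visible length of 0.6 mm — "emergence" is defined as the
moment the primordium is visible at image scale, which is also what a
segmentation-based observer can ever detect — and grows straight at
its angle from vertical. Ground truth (polylines, lengths, counts) is
exact by construction; rendering is seeded and bit-reproducible.

What the generator does **not** emulate: root curvature and
gravitropic bending, waving/skewing, root-hair halo, width variation
along the root, crossings between neighbouring plants, agar texture,
condensation films, or lighting drift. Passing the synthetic suite
therefore demonstrates the correctness of the measurement chain
(segmentation → refinement → graph → traits) under controlled
conditions, not field-readiness for arbitrary real imagery; on real
plates the published protocol (training on annotated images from the
actual imaging setup) remains necessary.

Growth-speed fixtures are generated directly as
speed(t) = trend + a₂₄ sin(2πt/24) + a₁₂ sin(2πt/12) + noise, the
form the spectral analyses assume.

## Phenotypes and spectra

Traits per frame: MR length, Σ LR length, TR = MR + Σ LR (asserted,
not assumed), LR count, LR density = count/MR (mm⁻¹), MR fraction =
MR/TR, convex-hull area of the root pixel centers (mm², degenerate
inputs → 0), Σ LR / hull area (mm/mm²). Ratios with zero denominators
are missing values, never exceptions.

The crossing time t\* is the first time Σ LR reaches MR, refined by
linear interpolation between the bracketing samples; later
re-crossings are ignored. The difference curve d(τ) = MR − Σ LR is
aligned at t\* over ±24 h on the native 15-min grid (193 samples);
windows truncated by the record are flagged. Its local derivative is
the central difference over one step (exact for linear curves,
one-sided and flagged at a boundary); its trend is the least-squares
slope over the full window.

Growth speed is the first difference over the sampling interval at
interval midpoints, with an optional centered moving average (default
1 h) to tame pixel-quantization noise; the 1 h window attenuates a
24 h component by < 0.3%. Spectral preprocessing is a high-pass
(subtraction of a centered 24 h moving average) followed by
normalization to unit variance; the moving average uses **periodic**
padding at the record edges, consistent with the DFT's periodicity
assumption and exact for integer-cycle records (reflect padding
measurably leaks into the 1/12 bin). Energies are |X_k|²/n with
one-sided doubling, so total energy equals the sum of squared samples
(Parseval); a sinusoid's amplitude is recoverable as
√(2E/n) × the normalization scale, which the suite verifies to within
10% at 10% noise. The windowed energy series uses a 7-day window (672
samples at 15-min cadence — exactly 7 circadian and 14 ultradian
cycles, so both targets are leakage-free DFT bins; this motivates
keeping the window fixed), slid one sample at a time, each window
preprocessed independently. Records shorter than one window abort
with a message. Trait reporting supports a configurable start offset
(days) for discarding pre-germination frames; synthetic runs default
to 0.

## Pipeline

`run_pipeline` processes frames sequentially (probability map → CRF →
accumulate), then plants one at a time within their ROIs (mask →
skeleton → graph → labels → traits → RSML). Per-frame failures are
logged and flagged in the manifest, never fatal. A state checkpoint
(accumulator, per-plant previous graphs, trait rows) is saved after
every frame, so re-invoking on a partially complete output directory
resumes at the first missing frame and produces outputs identical to
an uninterrupted run. The manifest records the package version, the
full configuration, per-stage counts and all flags, and suffices to
reproduce a run. With a fixed seed and fixed model weights, reruns
are bit-identical (CSV and RSML compared byte-for-byte in the suite).
"fast" resolves to the deeply supervised ResUNet, "accurate" to the
ensemble of all three architectures.

## Problem sizes

The test suite and the acceptance script run everything at CPU scale
by choice: toy networks (base 8, depth 2) instead of full-size ones
for training benchmarks; 192²–420×320 px plates; sequences of 41–241
frames at full 15-min cadence for tracking and occlusion tests. The
full-size architectures are built and counted exactly but only ever
run in inference-shape tests.

## Known limitations

- The two residual architectures' parameter counts are 14 away from
  the reference budgets (see above); the exact reference layer plan is
  not recoverable from the printed totals alone.
- Arc lengths inherit the chain-code bias described above.
- The labeller keeps both tips when two laterals fuse for several
  frames (identity via matching) but does not attempt to re-split
  their shared skeleton; the shared edges are assigned to one of them
  deterministically, and such frames are detectable by the per-frame
  flags rather than silently resolved.
- CRF message passing is a bilateral-grid approximation; for images
  with very fine intensity structure the grid resolution (one std per
  axis) is the accuracy limit.
- Training determinism is per-machine; cross-platform bit equality of
  trained weights is not guaranteed.
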