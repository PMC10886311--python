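# Methods

## Preprocessing chain

Raw 16-bit stacks pass through a fixed normalization before any frame is
used for training or evaluation:

1. **3D median filter**, per-axis radius 1 (a 3×3×3 window), reflection
   padding at borders. A radius is used rather than a window size because a
   1×1×1 window would be the identity and could not serve its despeckling
   purpose.
2. **Full-scale contrast stretch (FSCS)** over the *whole stack*: the clip
   bounds are the `s/2` and `1 − s/2` intensity quantiles (saturated
   fraction `s`, default 0.3 %, split evenly between tails; quantiles use
   linear interpolation between order statistics). `[low, high]` maps
   linearly onto the full bit range, so output always attains 0 and
   `2^depth − 1` on non-constant input. A constant stack maps to all zeros
   with a warning instead of raising, so batch runs survive empty frames.
3. **16→8-bit conversion**, `round(i · 255 / 65535)`.
4. **Frame separation** into (z-index, frame) pairs.

## Semi-synthetic degradation

Training pairs are manufactured from high-resolution frames alone: noise is
injected *first*, then the frame is downscaled fourfold (512×512 → 128×128
at acquisition scale). Downscaling defaults to area (box) averaging, which
conserves mean intensity exactly; bilinear subsampling is available.

Noise models operate on frames scaled to [0, 1]:

| model | parameters | convention |
|---|---|---|
| none | — | reference degradation |
| poisson | gain g (default 50) | draw ∼ Poisson(g·p)/g; g = expected photons at full scale. No gain is inherent to the formulation, so it is exposed as a parameter. |
| gaussian | μ = 0, σ = 0.1 | on the [0, 1] scale |
| additive_gaussian | μ = 0, σ = 5, c = 0.001 | μ, σ on the 8-bit [0, 255] scale; variance σ² + c·I with the signal-proportional term on the [0, 1] scale |

The two Gaussian modes reflect two parameter conventions of common
analysis environments; both are exposed explicitly. Outputs are clipped to
[0, 1] (saturating sensor). The `gaussian` σ is recoverable from residuals
on a constant frame to within a few percent (tested), which is the
calibration check that the injected noise is what the configuration says.

Multi-frame samples stack five axially consecutive LR frames; the HR
target is the middle (third) frame. A stack of n frames yields n − 4
windows, and windows never span stack boundaries. Window construction is
index-based: physical axial separation is whatever the stack was acquired
with, and is not interpreted by the sampler.

## The network

A compact residual U-Net with a subpixel super-resolution decoder:

- **Stem**: 3×3 convolution to `base_channels` (default 32).
- **Encoder**: `encoder_depth` stages (default 4), each a stride-2
  convolution (side halves, channels double up to 4× base) followed by a
  residual block (conv–relu–conv + identity, relu after the sum).
- **Decoder**: mirrored stages; each upsamples ×2 with a learnable
  subpixel layer (conv to 4× channels, pixel shuffle), concatenates the
  encoder skip at that scale, and fuses with a 3×3 convolution.
- **Super-resolution tail**: log2(scale) further subpixel ×2 stages
  (scale = 4 by default), then a linear 3×3 head to one channel.
- **Checkerboard suppression**: every subpixel layer is followed by a
  normalized zero-order-hold (box) blur of width equal to that stage's
  factor, applied with reflection padding. The kernel sums to one, so
  constant feature maps are preserved exactly.
- **Global residual skip**: the network predicts a *correction* to the
  bilinear upsample of the (centre) input frame, and the head is
  zero-initialized so the untrained model starts exactly at the bilinear
  baseline. This makes a few CPU epochs productive: optimization refines a
  sensible starting point instead of first rediscovering interpolation.

The implementation is pure numpy (im2col convolutions with hand-written
backward passes) in float64; gradients are verified against central finite
differences in the test suite. A classifier-pretrained encoder can be
emulated by warm-starting encoder weights from a previous checkpoint
(`init=<path>`); random initialization is the default.

**Training**: MSE loss, Adam (β = 0.9/0.999), learning rate 9×10⁻⁴ for
single-frame and 1×10⁻⁴ for multi-frame models, batch size 8, an internal
15 % validation split when no explicit validation set is given. The
best-validation-loss weights are kept; the recorded best-so-far validation
loss is monotone non-increasing by construction. With a fixed seed and
thread count, runs are reproducible to floating-point tolerance.

**Inference**: frames are normalized to [0, 1], predicted per frame (or
per 5-frame window; edge windows reflect their indices so output frame
count equals input), clipped to [0, 1] and rescaled to the stack's bit
range. Bilinear upscaling uses the half-pixel-centre convention (no corner
alignment), stated explicitly so its closed-form test values are
well-defined.

## Metrics

- **PSNR** `10·log10(R²/MSE)`; R defaults to the bit-range maximum, not
  the observed maximum. Identical frames give +inf, which propagates and
  is excluded from medians with a warning.
- **SSIM** with the conventional Gaussian-weighted 11-pixel window
  (σ = 1.5), `C1 = (0.01R)²`, `C2 = (0.03R)²`, averaged over positions
  where the full window fits. The denominator uses the variance form
  `σx² + σy² + C2` of the standard definition.
- **CNR** `(Ī_fg − Ī_bg)/σ_bg` with the population (ddof = 0) background
  standard deviation; invariant under affine intensity rescaling.
- **Paired Wilcoxon signed-rank**, two-sided: zeros dropped, mid-ranks for
  ties, exact null distribution for n ≤ 25 (without ties), normal
  approximation with continuity correction otherwise.
- **Bonferroni**: α/m (0.05/3 = 0.0167 for the three-way upscaling-method
  comparison).

## Segmentation and strand statistics

Segmentation is plain intensity thresholding, scored against the
ground-truth mask by weighted accuracy `0.1·sensitivity +
0.9·specificity` — vascular foreground is only ~5–10 % of the volume, so
balanced accuracy would underweight background errors enormously. The
threshold sweep uses 256 evenly spaced levels across the intensity range
and reports the peak (lowest threshold on ties). LR-derived images are
upscaled before segmentation, so all masks compare on the HR voxel grid.

Strand morphology is summarized per strand: path length; length-weighted
mean radius; z-direction (length-weighted mean of |Δz|/‖Δ‖, 1 for a strand
along the optical axis); inverse tortuosity (endpoint chord / path length,
1 iff straight). These definitions are this package's stated conventions
for quantities that vectorization tools report in slightly differing
forms. Distributions are compared via empirical CDFs: squared Pearson
correlation evaluated on the union of both samples' values (two roughly
linear CDFs can correlate strongly even when the distributions differ —
the documented blind spot that motivates also running the two-sample
Kolmogorov–Smirnov test on the raw samples).

## Phantom generator

The phantom emulates a labelled vascular volume: smooth random-walk
centerlines (step 2 µm, direction perturbed by a tortuosity amplitude of
0.15 and renormalized) with per-point radii (base radius uniform in
2–4 µm, ±10 % smooth modulation), rasterized as capsules (voxel center
within the linearly interpolated local radius). Strands are added until
the foreground fraction reaches its target (default 7.5 %, within the
5–10 % range typical of cortical vasculature); an exact strand count can
be requested instead. The clean image paints foreground 0.6 over
background 0.2 and applies an anisotropic Gaussian PSF (0.5/0.5/2.0 µm in
x/y/z) mimicking the elongated two-photon focal volume; these optics
values are conventions of the generator, not measurements. Background
noise is a single seeded standard-normal field whose scale is solved by
bisection so that the *final quantized, clipped* stack measures the target
CNR (default 0.94) — the round trip is accurate to ±0.02 by construction
and tested over 20 seeds.

What the phantom does not model: branching topology, hemodynamics, depth-
dependent attenuation, motion artifacts, and detector-specific noise
correlations. Passing tests on phantoms therefore demonstrates that the
pipeline's machinery is correct and that the method ordering (learned
model ≥ bilinear) holds under controlled conditions — not that any
particular accuracy value transfers to acquired data.

## Desk-scale experiments and problem sizes

`vascusr.experiments` fixes the sizes used by the worked example, the
acceptance script and the end-to-end tests: 4 phantom volumes × 50 frames
of 128×128 (one volume held out entirely), additive-Gaussian degradation
to 32×32, and a compact single-frame model (encoder depth 2, 16 base
channels) trained 5 epochs — about three minutes on one CPU core. The
high-resolution targets are the phantom's *clean* PSF-blurred images,
playing the role of high-quality frame-averaged acquisitions. Training
against CNR-0.94 images as targets would make PSNR noise-floor-dominated
(the optimal predictor reproduces the target noise visible in the input)
and uninformative about restoration quality.

The segmentation experiment uses one fresh phantom volume three ways: the
high-quality image is degraded with the training degradation
(additive-Gaussian + fourfold downscale) and upscaled with the trained
model and with bilinear interpolation, while the noisy CNR-0.94 image —
the simulated typical acquisition — is segmented directly as the
original-image baseline. The observed ordering (model > bilinear >
original) reflects that upscaled images are partly interpolated and hence
less noisy than a directly acquired image.

## Numerical and degenerate-input choices

- Quantile computation: linear interpolation (numpy default).
- FSCS on constant input: all-zero output + warning (not an error).
- Median filter borders: reflection.
- Threshold-sweep ties: lowest threshold wins.
- Per-stage seeds: `sha256(master_seed:stage_name) mod 2³¹`, so any stage
  can be rerun alone, reproducibly.
- Reported reproducibility tolerance for pipeline reruns: 1e-6 relative on
  loss histories and metric tables.

## Known limitations

- The encoder is a compact residual stack, not a full classification
  backbone; no claim of architectural equivalence with large pretrained
  encoders is made, only the structural elements (residual encoder, skip
  connections, subpixel decoder, post-shuffle blur).
- Vector extraction (converting images to strand graphs) is out of scope;
  strand tables come from the phantom generator or from external
  vectorization tools.
- Tile stitching, registration and flat-field correction are assumed done
  upstream.
- float64 CPU training is practical for the compact configurations here;
  full-scale training (tens of thousands of 512×512 pairs) would need a
  GPU framework.
- When the low-resolution input derives from a CNR-0.94 noisy image (far
  noisier than the training inputs), the compact 5-epoch model's peak
  weighted segmentation accuracy stays slightly below bilinear's (~0.934
  vs ~0.940, and more epochs do not close the gap); recovering a learned
  advantage in that regime appears to need substantially larger models
  and training sets than desk scale allows.
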