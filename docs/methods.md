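# Methods

This note records the scientific and numerical choices behind the package:
the synthesis model, the Hessian analysis, the translation model and its
losses, the identification and evaluation procedures, and what the reduced
CPU-scale experiments do and do not demonstrate.

## Coordinate and intensity conventions

Volumes are numpy arrays in (z, y, x) axis order, 0-based voxel indices,
intensities normalized to [0, 1]. Blobs are *dark* objects on a bright
background; whenever peak-like curvature is needed the analysis runs on the
inverted image `J − f` (J all-ones), whose Hessian is exactly `−H(f)`.
NIfTI is the canonical on-disk format (arrays transposed so the same volume
loads identically from NIfTI and multi-page TIFF).

## Blob synthesis

A blob is `F(x,y,z) = A·exp(−(ax² + by² + cz² + dxy + eyz + fxz))` with the
six coefficients parameterized by spherical angles θ, φ and scales σx, σy,
σz. The diagonal coefficients mix the inverse squared scales through
squared sines/cosines; the cross terms carry sin 2θ and sin 2φ factors.
Under this parameterization the quadratic-form matrix has eigenvalues
exactly {1/σx², 1/σy², 1/σz²} — every accepted draw is a rotated Gaussian
ellipsoid. A positive-definiteness guard (eigenvalue check, redraw on
failure) protects against degenerate parameter combinations regardless of
parameterization details.

Choices where the protocol is open, fixed once:

- **Angles** uniform in [0, 2π) (full orientation coverage); sub-ranges are
  a config option.
- **Compositing** of overlapping blobs by voxelwise maximum (keeps the
  field in [0, A] and each blob's profile intact near its core); sum-then-
  clip is available via `compositing="sum"`.
- **Polarity**: the composed bright field is inverted, `image = 1 − field`.
- **Amplitude** A = 1 on the normalized scale.
- **Ground-truth mask**: voxels where a blob's own Gaussian reaches
  `A·e⁻¹` — the ellipsoid with semi-axes σ — plus the voxel nearest the
  center. The extra voxel matters only for sub-voxel blobs (σ ≈ 0.5)
  centered between grid points, which otherwise would have an empty mask;
  it keeps the invariant "every recorded blob has ≥ 1 mask voxel".
- **Placement** uniform with a 1-voxel margin; overlaps allowed. At the
  study density (500–800 blobs in 64×64×32) many blobs touch a neighbour
  under 26-connectivity, so mask components under-count blobs — centers,
  not mask components, are the counting ground truth.
- **Noise**: `σ²_noise = var(image)/10^(SNR/10)`, SNR ~ U[0.01, 1] dB by
  default — noise power within a fraction of a percent of signal power.
  Noisy volumes are clipped to [0, 1]; calibration tests measure the
  pre-clip residual. Degenerate (constant) images are rejected since their
  SNR is undefined.

Everything is a pure function of (config, seed); datasets store per-image
seeds in a JSON manifest so any volume can be regenerated bit-identically.

## Hessian analysis

Second derivatives use compact central differences ([1, −2, 1] same-axis,
successive [½, 0, −½] for mixed partials) with replicate edge handling; the
1-voxel border is flagged invalid and never enters masks. The stencil is
exact on quadratic volumes, which the tests exploit.

"Hessian < 0" is interpreted as negative definiteness, decided by
Sylvester's criterion on leading principal minors (m1 < 0, m2 > 0, m3 < 0) —
O(1) per voxel and vectorized; an eigenvalue oracle cross-checks it on 10⁴
random symmetric matrices in the test suite.

Per-voxel blobness on a negative-definite Hessian H is
`3·|det H|^(2/3) / pm(H)` with pm the sum of the three 2×2 principal
minors. Writing eigenvalues −λᵢ (λᵢ > 0), the score is the geometric-to-
arithmetic-mean ratio of the pairwise products λᵢλⱼ, hence in (0, 1] with
equality iff λ₁ = λ₂ = λ₃ (AM–GM). Per blob, scores are averaged over the
blob's negative-definite voxels (`mode="mean"`, the default); a
centroid-voxel mode is available. Blobs with no negative-definite voxel get
NaN and are excluded from aggregates. Voxels with pm ≤ 0 cannot occur
inside the negative-definite set and are excluded by construction.

Measured on clean phantoms at the study protocol, ground-truth blobs score
high (voxel-mean ≈ 0.87): blobs in the modeled σ range are near-isotropic
at their cores. The score separates structure from elongated clutter
rather than ranking well-formed blobs.

## Translation model

Generator: 7×7×7 conv stem → 2 stride-2 downsampling convs → 6 residual
blocks → 2 fractional-strided upsampling stages (zero-stuffing + conv) →
7×7×7 head with tanh; instance normalization (no affine) and ReLU
throughout; replicate padding. The encoder half (stem, downs, first three
residual blocks) provides features for the contrastive and distribution
losses. Discriminator: 3D PatchGAN (three stride-2 4×4×4 stages + one
stride-1 stage + 1-channel head, leaky-ReLU 0.2, sigmoid patch scores).
Inputs are resized ×2 per axis (64×64×32 → 128×128×64) on an aligned dyadic
grid — every second upsampled voxel coincides with an input voxel, so the
inverse resize is exact subsampling — and min-max normalized.

All networks run on `blobcut.nn`, a small reverse-mode autodiff engine over
float32 numpy arrays (convolution as per-kernel-offset matmuls, which keeps
memory at O(output) instead of im2col's O(output × kernel volume)).
Gradients of every primitive are finite-difference checked in the tests.

Losses and their numerical treatment:

- **Adversarial**: standard non-saturating BCE objectives for both players
  (the bounded, saturation-free convention); the textbook objective value
  `E[log D(real)] + E[1 − log D(fake)]` is logged as a diagnostic.
  Sigmoid outputs are ε-clamped before logs.
- **PatchNCE**: per tapped encoder layer, 256 shared spatial locations are
  sampled; query (re-encoded translation) and key (input) features pass
  through a two-layer MLP, are L2-normalized, and enter an InfoNCE
  cross-entropy with temperature 0.07; layers are averaged so uniform
  similarities give exactly log(S). Applied to the source volume and, as an
  identity term, to the target volume.
- **Convexity consistency**: the hard value — mean |HI(J−G(Iₙ)) −
  HI(J−Iₙ)| over the region mask — is piecewise constant, so optimization
  uses a smooth surrogate: sigmoids of the Sylvester minors with sharpness
  k, k², k³ (matching their curvature units), multiplied into a soft
  indicator; the hard value is what gets logged. The region mask defaults
  to all-ones: restricting it to the input's convex voxels (the other
  natural reading) leaves new spurious convexity unpenalized and, measured
  at smoke scale, lets the translated volumes *gain* convex voxels,
  contradicting the constraint the loss exists to enforce
  (`conv_region_mask="input_convex"` restores the restricted variant).
- **KL distribution consistency**: the translated volume is binarized
  (< 0.5), its 26-components counted, a phantom with that blob count is
  synthesized on the fly, both volumes are encoded, each encoder channel's
  activations are softmax-normalized over space, and KL(translated ∥
  synthetic) is averaged over channels (differentiable through both
  encoder passes). Zero components falls back to a configured minimum; the
  count is capped at the study maximum of 800 to bound synthesis cost.
- **Total**: GAN + λ_In·NCE_in + λ_Ic·NCE_ic + λ_conv·L_convex +
  λ_KLD·L_KLD, all λ = 1 by default (they are exposed as tuning
  parameters without published values).

Optimization: Adam, lr 2·10⁻⁴ (constant, no decay), betas (0.5, 0.999),
batch size 1, default 25 epochs. A single master seed fans out to weight
init, data order, location sampling and phantom synthesis; training,
checkpointing (npz weights + optimizer state, JSON sidecar with config,
seed, history, RNG state and a weights hash) and resumption are exactly
reproducible. Non-finite losses abort with a diagnostic.

## Identification

`detect` composes: inverted-image convexity mask of the input → translation
→ dark-object mask (threshold 0.5, configurable) → Hadamard intersection →
26-connected components with centroids, voxel counts and per-blob blobness
(computed from the input volume's inverted Hessian). Components smaller
than 2 voxels are dropped as residual noise (configurable to 1; the choice
is recorded in the detection's parameter block). The intersection is the
load-bearing step: on overlapping-blob fixtures the dark mask merges blobs
the convexity mask keeps apart, and on noisy volumes the convexity mask
over-segments while the dark mask vetoes bright-noise curvature.

## Evaluation

True positives use the min-construction: TP = min(#GT centers whose nearest
detection lies within d, #detections whose nearest GT center lies within
d), with d defaulting to the ground-truth average blob diameter, taken as
2 × the mean of all per-axis σ (the e⁻¹ ellipsoid's semi-axes are the σ).
A greedy nearest-first one-to-one matching (distance-sorted, ties broken by
candidate then GT index — permutation invariant) is returned for per-blob
auditing; on sparse instances it coincides with the min-construction,
though adversarial configurations can separate them, which is why the
reported TP is the formula value. Precision = TP/n, recall = TP/m, F their
harmonic mean (0 when degenerate, flagged); Dice and IoU on voxel masks
(both-empty = 1, flagged); DER = |m − n|/m. Per-image reports aggregate as
mean ± std.

## Reduced-scale experiments: what they show

The published training regime (1000 volumes × ~23 epochs, GPU) is far
outside a CPU test budget. The suite instead runs a smoke experiment: 8
training + 4 validation volumes of 32×32×16 with 5–10 blobs each, study
noise (0.01–1 dB), 2 epochs, narrow networks (8 base channels). At this
scale the experiment demonstrates: the full loop runs end to end with
finite losses; the total training loss decreases; checkpoints resume
exactly; and the joint-mask identification with the identity translation
beats the Hessian-only baseline by a wide margin on the same noisy
validation volumes (asserted in the suite).

What it cannot show: 2 epochs × 8 volumes is 16 optimizer steps at the
fixed lr 2·10⁻⁴ — each parameter moves by at most roughly one
initialization standard deviation, so the generator cannot yet realize an
input-preserving denoising map, and detection through the barely-trained
translator underperforms the identity translation. Conclusions about
translation quality require training budgets of the published order; the
smoke run validates mechanics and the identification mechanism, not learned
denoising.

## Known limitations

- Blobs are strictly Gaussian ellipsoids; irregular shapes, heterogeneous
  backgrounds and illumination fields are not modeled, so metrics on these
  phantoms bound, rather than estimate, real-data performance.
- The mean ground-truth blobness of the synthetic protocol measures ≈ 0.87
  under this implementation's conventions (voxel-mean aggregation, compact
  central differences, no DoG); the score's absolute level is sensitive to
  unpublishable details of masking and aggregation, so cross-study
  comparisons of blobness levels should be made under one fixed convention.
- Whole-volume inference requires volume dimensions divisible by the patch
  shape; no implicit padding is performed.
- The autodiff engine is single-threaded numpy; it is sized for the smoke
  and desk-scale experiments, not for the published training regime.
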