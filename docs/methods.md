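# Methods

`bonesup` studies one question: if the bony anatomy in a kV radiograph is
suppressed by an unpaired image-to-image translation network, does markerless
template matching localize a lung tumor more reliably? Because real treatment
imagery cannot ship with a software package, the whole experiment runs on a
synthetic, fully-controlled twin of that setting: a digital thorax phantom
population in paired with-bone / without-bone form, radiograph-like parallel
projections of it, a CycleGAN trained on the unpaired tiles, and a tracking
experiment on noise-degraded "treatment-like" images.

## Phantom model

A phantom is a 3-D linear-attenuation map (1/cm) assembled from analytic
shapes on an isotropic voxel grid (default 128³ at 0.03 cm; the headline
experiments use 96³ so that the nine projection tiles are exactly 32×32):

* body — ellipsoid of soft tissue (0.20/cm);
* lungs — two ellipsoids of low attenuation (0.05/cm), placed symmetrically
  inside the body and slightly anterior of center, with band-limited
  vessel-like parenchymal texture (default amplitude 0.04/cm, correlation
  length ≈1.2 mm, identical in both volumes of a pair) — without it the
  lungs are featureless and a tumor template has no distinctive context to
  match against;
* tumor — sphere (0.25/cm) fully contained in one lung;
* spine — posterior cylinder of bone (0.50/cm) with periodic vertebral
  bulges; posterior placement matters: the oblique views then sweep the
  spine shadow toward the mediastinum rather than across the tracked lung,
  emulating a tracking-eligible patient geometry in which the tumor is
  visible in the imaging view;
* ribs — per-side partial elliptical tori hugging the inside of the body
  wall, sloping caudally toward the sternum; rib arcs do cross the tumor in
  projection, which is the disturbance under study.

The attenuation ordering bone > tumor ≥ soft > lung ≥ 0 is enforced as an
invariant. The defaults give bone/soft-tissue contrast similar to a chest
radiograph and are configurable. Population variation (inter-subject
differences in body habitus, rib count/spacing, tumor size and position)
is drawn from uniform ranges that scale with the grid extent
(`default_population`), so the same relative anatomy is produced at any
resolution. The tumor center is sampled inside the lung ellipsoid shrunken
by the tumor radius, so tumor-in-lung containment holds by construction.

"Turning bone off" replaces every bone voxel with soft-tissue attenuation
rather than zero, so the bone-free volume remains an anatomically plausible
soft-tissue thorax; everything outside the bone mask is bit-identical across
the pair. This exact pairing is what makes suppression measurable: the
bone-free projection is a pixel-level ground truth.

Deliberately not modelled: respiratory/cardiac motion, organ deformation,
scatter, beam hardening, detector blur, and the cone-beam geometry of a real
treatment imager.

## Projection

Projections are parallel-beam ray sums of attenuation (Σ μ·Δl, Δl the voxel
size in cm) along the posteroanterior axis after rotating the volume about
the cranio-caudal axis by 40/45/50°; rotation uses trilinear resampling and
angle 0° takes an exact axis-aligned summation path, which makes bone-ray
membership exactly computable for tests. Raw line integrals (not
Beer–Lambert intensities) are used throughout, because only the relative
shadow structure matters to the networks and metrics.

Each paired raw projection is windowed to 8 bits with the *same* window —
the with-bone image's min/max — so the bone-free image of a pair lives on
the same gray scale and suppression remains measurable (rounding is
half-up). Images are then split 3×3 at floor(n/3) boundaries (the last
row/column of tiles absorbs the remainder: 512 → 170/170/172); concatenating
tiles reproduces the parent bit-exactly. Tiles are the training images; at
inference a full image is suppressed tile-wise and reassembled.

Train/test splitting is at the phantom level, never the tile level, so no
subject appears on both sides.

## Translation network

The suppressor is a CycleGAN: generators G_XY (bone → bone-free) and G_YX,
discriminators D_X and D_Y, least-squares adversarial objectives
(real → 1, fake → 0), an L1 cycle-consistency term weighted by
λ_cycle = 10, and an optional identity term (λ_identity, default 0). Each
generator's body is a 7×7 conv stem, two stride-2 downsampling convs, n
residual blocks (default 2 at desk scale), two nearest-neighbor-upsample +
conv stages, and a 7×7 output conv squashed by tanh; instance
normalization and ReLU throughout. By default the generator is *residual*:
its output is clip(x + body(x), −1, 1) with the body's output conv
zero-initialized, so the generator starts as the exact identity and
training only learns the bone-signal deviation. This choice is decisive at
desk scale: a pure encoder-decoder must re-synthesize every pixel through
the bottleneck and, within a 3000-update budget, generalizes poorly to
unseen anatomy (block artifacts on held-out phantoms severe enough that
suppressed images tracked *worse* than unsuppressed ones), whereas the
residual form leaves non-bone content untouched by construction. The
non-residual form remains available via configuration. Discriminators are
PatchGAN stacks of three stride-2 convs (LeakyReLU 0.2, instance norm
after the first) and a final 1-channel conv, scoring overlapping patches
rather than whole images. Optimization is Adam with learning rate 0.0002,
β₁ = 0.5, β₂ = 0.999 for generators and discriminators alike; both are
updated once per iteration; discriminators are fed from a 50-image replay
buffer of past fakes (50% swap rule). Training runs a fixed epoch budget
with an optional cap on generator updates and per-epoch checkpoints.
Because no objective stopping rule exists for adversarial training,
suppression MSSIM is probed on pairs drawn from the *training* split every
500 updates and the best-scoring generator parameters are restored at the
end; the held-out phantoms play no part in selection.

The network stack (convolution, instance norm, Adam, backprop) is
implemented directly in numpy, NCHW float32, single-threaded. This is a
deliberate design: the models at desk scale are small enough that a CPU
implementation trains in minutes, carries no framework dependency, and is
bit-reproducible — the entire training history is a pure function of the
config seed. Forward passes are functional (they return an activation tape)
so one network can appear several times in the cycle objective graph.
Weight init is N(0, 0.02); batch size defaults to 1 as in the reference
CycleGAN recipe (instance norm makes batch statistics irrelevant).

Images enter the generators mapped from [0, 255] to [−1, 1] and outputs are
mapped back with half-up rounding; the round trip through an identity
generator is exact to ±1 gray level.

## Similarity metrics

SSIM of two co-located blocks uses Gaussian-weighted moments
(11×11 window, σ 1.5 — the standard of the original SSIM reference),
C1 = (0.01·255)² = 6.5025, C2 = (0.03·255)² = 58.5225. MSSIM is the dense
mean over all window positions with symmetric boundary padding; a
double-loop brute-force oracle and scikit-image cross-check pin the
implementation in the tests. PSNR is 10·log₁₀(255²/MSE); identical images
raise a distinct infinite-PSNR condition rather than returning a number,
and reports store it as null with a flag. Whether metrics are computed on
whole images or per tile is configurable; held-out evaluation scores the
32×32 test tiles, matching the unit the network is trained on.

## Tracking experiment

Treatment-like images are with-bone projections degraded by Poisson quantum
noise (default scale: 1.75 photons per gray level) plus additive Gaussian
electronic noise (default sd 4.5 gray levels), clipped back to 8 bits. No
noise model for live kV images is published, so the defaults were fixed by
a calibration rule stated in advance: choose the level at which template
matching on the *unsuppressed* with-bone images succeeds at the rate the
study design implies for its baseline condition (roughly three-quarters of
images identified), so the suppressed condition is measured at the same
operating point as the real system, neither in a trivially clean nor in an
inoperable noise regime. The template is cut from the *clean bone-free*
projection around the projected tumor mask plus a 20% margin, mimicking a
planning-DRR-derived tumor tracking volume; its center is the ground-truth
tumor position. Only cases in which a rib arc casts at least 0.5 mm of
bone path across the projected tumor box are kept — the stratum in which
rib suppression can matter at all.

ZNCC is the standard zero-mean normalized cross-correlation; windows with
zero variance score 0 by definition (a documented fallback that keeps the
heatmap total). Matching scans the entire image, ties at the peak break
toward the smallest row then column, and the matched center is the peak
offset plus half the template size. "Identified correctly" means the
matched center lies within half the template's larger side of the true
center (inclusive); the criterion is the single most consequential free
choice in the evaluation — no published definition exists — and it is
prominently configurable. Per condition (with-bone vs suppressed) the
report gives the detection percentage and mean ± sd of peak ZNCC over
identified images only; the two ZNCC groups are compared with a two-sided
Welch t-test at α = 0.05 (Welch rather than pooled-variance because group
variances have no reason to be equal).

## Desk-scale headline configuration

The headline experiment (`bonesup.experiments.run_headline`, also what
`scripts/acceptance.py` runs) uses: 40 phantoms at 96³/0.03 cm, angles
40/45/50°, phantom-level test fraction 0.1 (→ 108 held-out tile pairs),
32×32 tiles, base_channels 16, 2 residual blocks, batch size 1, 3000
generator updates, and 201 treatment-like tracking images from phantoms
disjoint from the training population. These sizes are the package's chosen
desk-scale twin of the full study design (56 subjects, 512² slices,
GPU-scale training); the full-scale settings remain reachable through
configuration. All stage seeds derive from one base seed. The twin's
unsuppressed condition identifies about three-quarters of images with mean
peak ZNCC ≈ 0.90; suppression raises the detection rate by roughly ten
points at a significant Welch-test level, the same direction and a larger
detection gain than the full-scale study reports, while suppressed-image
similarity to ground truth sits slightly above the study's reported level
(a scaled-down synthetic scene is cleaner than real patient anatomy).

## Numerical and design notes

* Projection rotation clips negative interpolation residues at 0; order-1
  (trilinear) resampling cannot overshoot, so this is a no-op guard.
* The ZNCC heatmap is computed with exact direct window sums
  (`sliding_window_view` + einsum), not FFT correlation, so it agrees with
  the brute-force double loop to ~1e-15 — at these image sizes exactness is
  cheaper than asymptotics.
* tile_3x3 of non-multiples of 3 gives the last row/column the remainder;
  the dataset layer only ever tiles multiples of 3, but the rule is fixed
  for external images.
* Degenerate inputs: zero-width gray windows, sub-window images, templates
  not smaller than the image, empty dataset splits, and zero-variance
  t-test groups all raise typed errors rather than returning NaNs.
* Checkpoints store config echo + parameter arrays; loading reconstructs
  the architecture from the echo, so a checkpoint is self-describing.

## What passing the synthetic experiments does and does not show

The phantom population exercises the *mechanism* — bone shadows corrupt
template matching, and learned suppression restores it — under controlled
anatomy where the bone-free ground truth is exact. It does not establish
clinical performance: real patient radiographs differ in anatomy complexity,
scatter and detector physics, tumor texture, and the absence of any paired
ground truth. The synthetic tracking percentages should be read as an
upper-bound demonstration of the pipeline's internal consistency, not as a
patient-level detection rate.
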