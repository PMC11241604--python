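# Methods

`lungscreen` implements a complete screening chain for lung-carcinoma
candidates in 2-D chest CT-like images: denoise, extract the lung fields,
segment them into four parts from optimizer-selected seed points, extract
engineered features, select the class-informative ones with a chi-square
test, classify Normal/Abnormal with a small residual network, and grade
abnormal findings as low or high risk. A synthetic chest-phantom generator
provides ground truth for every stage, so the whole chain is testable
without any external imaging data.

## Phantom generator

Each phantom is rendered on an `H x W` float raster (default 160 x 160) from
a fixed intensity palette: background 0.05, lung parenchyma 0.25, thorax
0.45, vessels 0.65, ribs 0.75, nodules 0.90. The ordering
background < lung < vessels ≈ ribs < nodules is a modeling assumption the
feature operators rely on (lesions are the brightest compact structures, as
in contrast-normalised CT slices).

Geometry: an elliptical thorax with two elliptical lung fields (semi-axes
0.36 H x 0.16 W, centers at 0.28 W and 0.72 W); `n_ribs` (default 4)
downward-bowing parabolic bands of ~5 px thickness; `n_vessels` (default 6)
thin spokes radiating from each hilum. Two geometric constraints are
deliberate: rib bands are clipped out of the medial 35 % of each lung field,
and vessel spokes stop at rib bands and before the pleura. Both keep the
parenchyma 8-connected, which is what lets a single region-growing flood
cover a lung field — real parenchyma is connected in 3-D for the same
reason, but a 2-D slice of real anatomy need not be, and this is a known
simplification of the phantom.

Nodules are rendered disks (radius >= 2 px) whose centers must lie inside a
lung field; `random_spec` samples centers from the structure named by the
placement tag (rib pixels for `on_rib`, vessel pixels for `on_vessel`, clear
parenchyma for `free`) and radii uniformly in [3, 10] px. Ground-truth
labels: Abnormal iff any nodule exists; risk is high iff any nodule is
on-rib or has radius >= `high_risk_radius` (default 8 px), else low.

Default corruption is additive Gaussian noise with sigma 0.03 — a mild,
realistic level for reconstructed CT at display normalisation; the noise
study uses sigma 0.05. Poisson noise (photon counts at a configurable scale)
is available for count-limited acquisition models. Augmentation ops
(rotate/scale/flip/translate) are shape-preserving; bilinear interpolation
for images, nearest for masks.

What the phantom does **not** emulate: 3-D anatomy and partial-volume
effects, Hounsfield calibration, textured parenchyma, pleural/mediastinal
lesions, motion or beam-hardening artifacts. Passing tests demonstrate the
pipeline's internal consistency and its behaviour under the stated geometry
and noise models — not clinical performance.

## Denoising (I-ADF)

The improved anisotropic diffusion filter evolves the image by

    dI/dt = 6 [ 1/6 div((1-C) grad I) + 1/4 div((1-C_p) grad_p I)
              + 1/2 div((1-C_l) grad_l I) ]

with three gain coefficients computed from local *intra-class variance*
(unnormalised sums of squared deviations): C from an axis-aligned 5x5
window, C_p from a 25-sample stencil spanned by the structure-tensor
eigenvectors (e2, e3), C_l from a 7-sample stencil along e3. The diffusion
matrix eigenvalues are alpha1 = 1-C, alpha2 = alpha1 + 3/2 (1-C_p),
alpha3 = alpha2 + 3 (1-C_l), so alpha3 <= 5.5.

The gain functional form is a design point of this package: we use the
structure-confidence convention

    C(m, v) = 1 - exp(-v / (k^2 m^2 + eps)),

zero at zero variance and increasing toward 1 across strong edges, so the
diffusivities 1-C are large exactly where the neighbourhood is flat or
noise-dominated and vanish at structure — the behaviour that makes
anisotropic diffusion edge-preserving. (With the opposite monotonicity the
filter smooths edges and sharpens noise; we verified it degrades PSNR on
noisy phantoms.)

* `k` (default 1.5, dimensionless): positions the gain knee. A noise-only
  5x5 intra-class variance is ~24 sigma^2 (≈ 0.06 at sigma 0.05), which at
  parenchyma mean ~0.3 gives v/(k^2 m^2) ≈ 0.3 (weak structure evidence),
  while a 0.2-intensity step gives a ratio far above 1.
* `dt` (default 0.04): explicit-Euler step. Stability requires
  dt <= 1/(2 d max alpha3); with d=2 and the worst case alpha3 = 5.5 the
  bound is 1/22 ≈ 0.045. The bound is evaluated each iteration from the
  actual gain fields and violations raise an error naming it.
* `iterations` (default 10): enough to remove most pixel noise at the
  default dt without flattening vessels.

For 2-D images the structure tensor is computed in-plane: e1 is the
dominant-gradient direction, e2 its in-plane perpendicular; the notional
out-of-plane e3 contributes no in-plane offset, so the planar stencil
collapses onto 5 distinct samples along e2 (25-sample normalisation kept)
and the linear term is realised as smoothing along e2. Stacks are treated
as thin volumes and filtered slice by slice; a true 3-D path is out of
scope.

The update is discretised in conservative flux form (face fluxes differenced,
zero-flux boundary faces), so the global intensity sum is conserved to float
round-off each iteration — asserted in the tests — and a constant image is
an exact fixed point.

## Lung-field extraction and enhancement

After a percentile contrast stretch (defaults 1st -> 0, 99.9th -> 1; the
high anchor is deliberately above the rib/nodule tail so the brightness
ordering survives), Otsu's threshold separates the bright body from dark
air. Candidate lung fields are dark regions *enclosed* by the thorax
(border-touching air is discarded), closed with a 6-px disk to bridge rib
shadows; the two largest candidates are kept and replaced by their convex
hulls. Degenerate inputs (nothing above 0.5 % of the frame) raise
"no lung field found".

Edge enhancement is plain unsharp masking, E = Q + eta (Q - G_sigma Q), with
eta 0.5 and sigma 1.5 px. These deliberately conservative defaults bound the
overshoot halos around ribs; stronger settings carve the parenchyma into
disconnected cells and starve the region growing stage (measured during
development).

## Segmentation (B-RGS)

Seeds are selected by a coati optimization algorithm whose random numbers
are Bates(phi) draws — means of phi i.i.d. uniform(0,1) variables (default
phi 3; mean 1/2, variance 1/(12 phi)). Each iteration runs an iguana-hunt
phase (half the population moves toward the incumbent best with per-entry
Bates steps and a random multiplier theta in {1,2}; the other half reacts to
a freshly sampled "ground iguana", approaching it if better and retreating
otherwise) and a predator-escape phase (per-coati random steps whose scale
is bounds/iteration). Candidates are clamped to the bounds and accepted only
on strict improvement, so the best-so-far fitness is non-increasing by
construction. Defaults m=20 coatis, Tn=50 iterations.

One COA instance runs per lung-field quadrant (TL/TR/BL/BR of the lung-mask
bounding box). The default fitness of a candidate seed is
`(1 + var(region)) / |region|` where the region is grown from the candidate
inside the quadrant: the winning seed anchors the *largest* region
admissible under the growing criterion, with within-region homogeneity as
tie-break. (Raw within-region variance is degenerate here: residual noise is
near-uniform, so every homogeneous pocket scores alike and the optimizer
may anchor in tiny enhancement-halo cells.) The fitness is pluggable; an
end-to-end objective such as classifier accuracy can be substituted at much
higher cost.

Region growing itself is the classic flood: a pixel joins iff it is 4- or
8-adjacent to the region and |I(p) - I(seed)| < T, with
T = c * std(5x5 neighbourhood of the seed) + floor (defaults c=3,
floor=0.05). At T=0 the criterion degenerates to exact equality. Because
membership depends only on the seed value, the region equals the connected
component of the predicate mask containing the seed, which is how it is
computed. Each of the four parts is grown within its quadrant's bounding box
and intersected with the lung mask, so the parts are disjoint by
construction; a gray-value overlap resolver is provided for callers that
grow on the full frame (four floods in one connected parenchyma otherwise
coincide, making "four parts" vacuous).

## Features

21 named values per quadrant, 84 per image, always finite (every degenerate
branch maps to a documented default, never NaN):

* **Gradient block (7)** — 64-bin histogram of the Sobel gradient magnitude
  over the part's pixels: spacing between the two tallest local maxima
  (clamped to >= 1 bin; a single-mode histogram duplicates its mode), the
  probability mass within ±2 bins of each mode, skewness g1, excess-free
  kurtosis b2, the bimodality coefficient (g1^2+1)/b2 (0 when b2 = 0), and
  the mode-height ratio divided by the spacing.
* **Spectral flatness (1)** — geometric over arithmetic mean of the non-DC
  2-D Fourier magnitudes of the zero-mean masked crop; in [0, 1] by AM-GM,
  1 for noise-like content, 0 for constant crops.
* **Profile block (4)** — 16 equally spaced vertical columns through the
  gradient image (ribs are near-horizontal, so vertical profiles cross
  them), each Gaussian-smoothed (sigma 1): fraction of profiles whose
  largest peak exceeds mean + 2 std ("rib cross"), mean max/min peak ratio,
  mean min(diff)/max(diff) slope ratio, and mean |second difference|.
* **On-rib block (7)** — Canny edge chains (sigma 1) are split into rib
  candidates (length >= 15 px, |least-squares slope| <= 0.5) and vessel
  candidates (the rest). Reported: distance from the candidate-lesion
  centroid to the nearest rib chain, the median spacing of row-sorted rib
  centroids (capped at 1e4 with < 2 chains), the on-rib flag (distance <
  spacing), the nearest chain's length/slope/eccentricity, and the
  candidate blob's equivalent radius sqrt(area/pi).
* **On-vessel block (2)** — product of the two longest vessel-chain lengths
  over the sub-image area (0 with < 2 chains), and the inverse of the
  smallest chain-to-center distance, capped at 1/0.5 px.

The candidate lesion blob is found on the pre-enhancement lung region when
available (unsharp overshoot otherwise merges lesions with rib halos):
pixels at or above the 92nd brightness percentile of the part are opened
with a 2-px disk to detach blobs from thin bands, components with
second-moment eccentricity <= 0.95 (compact, lesion-like) are preferred,
and the brightest-peak one wins; its equivalent radius is compensated by
the opening radius. The percentile is set well below the lesion's own area
fraction so whole structures, not their noise tips, cross the threshold.

## Feature selection (BD-CST)

Features are median-binarised (strictly-above = high, ties low) and
cross-tabulated against the class label; the 2x2 Pearson statistic is
computed in the closed form e (WZ-YX)^2 / ((W+Y)(X+Z)(W+X)(Y+Z)), which the
tests verify equals sum (O-E)^2/E to 1e-9 on random tables. The
significance level is the binomial pmf value R = C(e, rho) g^rho (1-g)^(e-rho)
(defaults e=20, rho=1, g=0.05, R ≈ 0.377), used as the alpha of a
chi-square(1) test; `alpha_override` substitutes a conventional level.
Critical values come from a bisection on the regularised incomplete gamma,
identical across platforms. If no feature survives, the top 10 by score are
kept with a warning.

A caveat of median binarisation: a binary indicator that is majority-positive
has median 1 and maps entirely to "low", scoring 0. Guaranteed detection of
a label-identical feature therefore assumes the classes are not imbalanced
past the median — the regime of the balanced worked example.

## Classifier (PResNet) and risk screen

Feature-vector mode treats the selected features as a 1-channel 1-D signal:
conv stem (width 32, kernel 3, same padding) -> p-ReLU -> 3 residual blocks
[conv -> p-ReLU -> conv] + identity skip -> non-overlapping max pool
(stride kappa = 2) -> fully connected head -> 2 logits. The parametric
rectifier mu(x) = x for x > 0 else J x has one learnable slope per
activation site, initialised at 0.25. Everything is NumPy with explicit
backward passes (verified against central finite differences at 1e-4
relative tolerance), float64 parameters, seeded He initialisation, Adam
(lr 0.01, batch 32, 50 epochs), and softmax cross-entropy. Runs are
bit-reproducible for a fixed seed and checkpoints (npz) reload to identical
predictions. Transfer learning is an optional warm start from a checkpoint.
An image mode (2-D convolutions) is not implemented in this build; the
configuration rejects it explicitly.

Inputs are z-scored with training-split statistics (stored with the
checkpoint): the raw features span several orders of magnitude (distance
caps of 1e4 against flatness values of 1e-2), which unnormalised would
dominate the early optimisation.

Risk screening applies only to Abnormal predictions. The quadrant with the
largest candidate-blob radius is taken as the salient one (on-rib evidence
is meaningful only where a lesion candidate exists); the image is high risk
if that quadrant's on-rib flag is set or its blob radius reaches `tau_risk`
(default 8 px, the same scale as the generator's risk ground truth), else
low. Normal predictions carry risk "none". The screen inherits the
flag's permissiveness (any candidate within the inter-rib spacing of a rib
chain is flagged), so it is biased toward high risk — the conservative
direction for a screening tool, and a known limitation.

## Pipeline, seeds, and problem sizes

A single global seed derives all stage randomness through
`SeedSequence(seed, spawn_key=(stage, index))`, making every stage a pure
function of (inputs, config, seed); the tests assert byte-identical reruns.
The demo study uses 60 phantoms (half abnormal) at 160 x 160 with a
stratified 70/30 train/test split; these sizes keep the full study in the
low minutes on one CPU while leaving ~18 held-out images for the error
rates. At that training size the full-width network (32 channels, 3 blocks,
~18k parameters) overfits, so the pipeline's default classifier is
capacity-matched: 8 channels, one residual block, weight decay 1e-3 —
measurably better held-out accuracy across corpus seeds. The full-size
architecture remains the module default and a config switch away. Intermediates (enhanced frames, masks, features, predictions,
reports) are persisted as 16-bit PNG / CSV / JSON so each stage can be
re-run and inspected independently.

## Known limitations

* The phantom's contrast model makes lesions the brightest compact objects;
  the feature set would need re-tuning for ground-glass or cavitary lesions.
* Slice-wise denoising ignores inter-slice correlation in stacks.
* The risk screen is rule-based on two features; it does not learn.
* Held-out accuracy of the demo study varies a few points with the corpus
  seed at n=60; the reported rates carry the sampling noise of an 18-image
  test set.
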