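# Methods

## Quantification model

The study endpoint is infarct size (IS) as a percentage of the area at risk
(AAR), with the AAR itself reported as a percentage of the left ventricle
(LV).  Surface areas of infarct, non-infarcted AAR and remote myocardium
are measured on both cut faces of each transverse slice, the two faces are
averaged, and areas are converted to masses with the weighed slice mass:

    Ā_LV = Ā_inf + Ā_aarNI + Ā_rem,   m_c,s = m_s · Ā_c / Ā_LV

    IS  = 100 · Σ_s m_inf,s / Σ_s (m_inf,s + m_aarNI,s)
    AAR = 100 · Σ_s (m_inf,s + m_aarNI,s) / Σ_s m_LV,s

Assumptions: tissue density is homogeneous within a slice, so the weighed
mass distributes across the LV classes in proportion to mean face area;
right-ventricular and remaining pixels carry no LV mass.  The per-slice
mass weighting makes the estimate robust to varying slice thickness —
duplicating a slice's geometry while doubling its mass exactly doubles its
contribution.  When only one cut face exists (the outermost slice surfaces
are not cut faces) the face average degrades to that single face rather
than dropping the slice, which would discard its mass from the totals.
Areas enter only as ratios, so the result is invariant to uniform
rescaling of pixel areas (magnification invariance); this is tested
exactly.

Degenerate inputs: a slice whose faces contain no LV pixels raises a
degenerate-slice error; an experiment with zero total AAR mass raises an
undefined-IS error (IS is a ratio to AAR mass).

## Segmentation model

A dynamic U-Net maps a 3×S×S RGB input to five per-pixel class
probabilities (softmax).  "Dynamic" is honored literally: decoder block
widths are read off the encoder's feature shapes during a probe forward
pass at build time rather than hard-coded.  The network is implemented as
a compact CPU micro-framework (numpy, im2col convolutions, manual
backpropagation, BatchNorm, 2×2 max-pool, nearest-neighbor upsampling,
spatial dropout at the bottleneck); gradients are verified against finite
differences in the test suite.  No pretrained encoder weights are bundled;
requesting one raises an explicit error.

The composite training loss on probabilities p and one-hot target y is

    L = w_ce · CE_w + w_mae · mean|p − y| + w_dice · (1 − mean_c softDSC_c)

with component weights (1, 1, 1) by default and cross-entropy class
weights set to inverse pixel frequency on the training split (normalized
to mean 1, frequencies floored at 1e-4).  Soft Dice is computed on
probabilities pooled over the batch per class with an ε = 1e-7 stabilizer,
so a class absent from both prediction and target contributes 1 (no
penalty).  All three components are non-negative and vanish iff the
prediction is exactly the one-hot target.

Optimization is Adam (β = 0.9/0.999) with decoupled multiplicative weight
decay on convolution weights only; "0.5 %" decay corresponds to 0.005.
The best epoch is chosen by validation overall DSC, defined as the mean
per-class Dice over classes present in either mask, averaged over
validation images.  Exact argmax ties in prediction go to the lowest class
index.

Two execution profiles:

| parameter        | full profile | tiny profile |
|------------------|--------------|--------------|
| image size       | 384 px       | 96 px        |
| epochs           | ≥ 300        | 20           |
| batch size       | 26           | 8            |
| learning rate    | 1e-4         | 1e-3         |
| depth / width    | 4 / 16, two convs per block | 3 / 8, one conv per block |
| dropout, decay   | 0.50, 0.005  | same         |

The tiny profile is the package's scaled-down test profile: with a 15×
shorter schedule the learning rate is raised tenfold and the network
narrowed so that three-fold cross-validation on a 24-heart phantom cohort
completes in minutes on one CPU.  Fold counts: fivefold (80 %/20 %) is the
reference protocol and is what the split arithmetic tests exercise
(220 → 5 × 44); the tiny-profile recovery check uses k = 3 so each fold
still trains on 16 hearts.

Augmentation applies rotation (±15°), zoom (0.9–1.1) and shear (±4°) as a
single affine transform to image and mask jointly (mask nearest-neighbor,
so labels stay in the scheme), random erasing blanks the same rectangle in
both (image → black, mask → class 0, consistent with black padding mapping
to "remaining"), and brightness/contrast/saturation shifts plus Gaussian
blur touch the image only.

## Preprocessing

Background removal is deterministic chroma-distance thresholding: the
background color is the median of a 5 % border strip, pixels farther than
40 RGB-Euclidean units are foreground candidates, the mask is closed
(3×3, two iterations), reduced to its largest connected component and
hole-filled; background pixels become black, which the class scheme maps
to "remaining".  The threshold is a parameter; 40 clearly separates
stained tissue from typical photographic backgrounds while tolerating
moderate illumination gradients.  The operation is idempotent because the
fill color is itself background on a second pass.

Images are padded to square (centered, black fill) and resized; images
bilinearly, masks nearest-neighbor through the identical geometry so
image/mask alignment survives the chain.  Resize quality is assessed by
down-resampling to the target and back to native size, then scoring SSIM
(uniform 7-px window, K1 = 0.01, K2 = 0.03, 255 dynamic range; channel
mean for RGB) and PSNR (10·log₁₀(255²/MSE), +∞ sentinel for identical
images) per image, with cohort median and IQR.  The down-then-up protocol
is a design choice; comparing images of different sizes requires picking a
common grid and the native grid is the conservative one.

## Synthetic phantoms

Each heart: 5–7 slices (rat profile 5–6), slice thickness 10–20 mm (rat
≈ 2 mm), both faces of each slice parameterized, the outermost apical and
basal surfaces left unimaged (they are not cut faces), so n slices yield
2n − 2 images.  On a face the LV is a Fourier-perturbed annulus; the lumen
is "remaining"; the right ventricle a tapered crescent on the outer wall;
the AAR an angular sector of the annulus; the infarct a predominantly
subendocardial sub-region of the AAR with a wavy border.  AAR and infarct
pixel sets are selected by rank thresholding on smooth fields (angular
distance; normalized wall depth plus angular waves), so the rendered pixel
shares equal the requested continuous fractions to sub-pixel accuracy —
this is what makes the generator usable as a quantification oracle.

Cohort statistics mirror the emulated study: AAR fraction uniform on
0.09–0.38 of the LV; infarct fraction uniform on 0–0.73 of the AAR for
untreated hearts, on the lower 35 % of that range for "protected" hearts
(default protected share 0.415 ≈ 162/390); slice-level jitter around
heart-level values, clipped to the configured ranges.  Slice masses follow
mass = 1.05 mg/mm³ × thickness × mean face (LV+RV) cross-section, with
the pixel→mm scale set by species (110 mm field for pig, 22 mm for rat);
the generator must invent a mass model because real slices are weighed.
Coloration uses TTC-like class colors (brick-red remote, light-red viable
AAR, off-white infarct, red-brown RV) with per-face color jitter (SD 6),
per-pixel noise (SD 4), a random linear illumination gradient (up to
±12 %) and Gaussian blur (σ 0.3–0.9).  The rat profile optionally
compresses class contrast to emulate a harder distribution shift.

Exact truth is computed by evaluating the quantification formula on the
continuous face fractions and analytic face areas of the imaged faces —
the same algebra as the pixel path, minus rasterization — and the
two-slice hand example (masses 10 g/20 g, fractions 0.1:0.1:0.8 and
0:0.2:0.8 → IS = 16.67 %) pins the shared formula in the tests.

What the phantoms do not emulate: real anatomy (papillary muscles,
trabeculae), staining artifacts and diffuse infarct borders, specular
highlights, film/scan warping, and annotation subjectivity.  Passing tests
therefore demonstrate that the pipeline machinery is correct and that the
network can learn this class of images; they do not certify performance on
real slices.

## Evaluation metrics

Per class: DSC = 2|P∩G|/(|P|+|G|); ACC = one-vs-rest pixel accuracy
including true negatives (the reading under which small classes can score
ACC ≈ 0.99 above their DSC); boundary F1 with boundary pixels defined as
class pixels 4-adjacent to another class (image border counts as another
class) and a Euclidean match tolerance, default 2 px at 384 resolution and
configurable; AP = area under the pixel-ranking precision–recall curve
with pixels pooled over the whole evaluation set before ranking (per-image
averaging would change the values; pooling is the documented choice).
Empty-vs-empty conventions: DSC and bF1 are 1 when the class is absent
from both masks — correct absence, e.g. infarct-free slices — and 0 when
absent from exactly one.  Overall row: mean per-class DSC, ground-truth
pixel-share weighted ACC, mean per-class bF1, unweighted mAP over classes
present.  Every metric is held to 1e-9 agreement with independently coded
brute-force oracles in the tests.

Agreement statistics: Pearson r with least-squares regression; Bland–
Altman bias ± 1.96·SD (sample SD, n−1); ANCOVA against the identity line
realized as an extra-sum-of-squares F-test of the fixed model y = x (0
parameters) versus the fitted line (2 parameters), F = ((SSE_id −
SSE_fit)/2)/(SSE_fit/(n−2)), with p = 1 as the fail-to-reject sentinel for
a perfect identity fit; KS normality against a normal with estimated
parameters (Lilliefors caveat: anti-conservative p).  Significance is read
at p < 0.05.

## Problem sizes used by the test suite

Metric oracles run on 200 random ≤ 16×16 mask pairs; quantification
recovery on a 50-heart cohort at 256 px (max |error| ≤ 1 % of AAR);
parameter recovery on a 24-heart cohort at 96 px with three-fold
cross-validation of the tiny profile (out-of-fold IS vs annotation IS:
r ≥ 0.9, |bias| ≤ 3 % AAR); the end-to-end determinism check on a 5-heart,
64-px, 2-epoch micro run.  These sizes are the package's own scaled-down
study conditions; the full profile is documented but not exercised by the
suite.

## Known limitations

* The CPU implementation is intentionally small; the full 384-px profile
  is supported but slow, and no GPU path exists.
* No pretrained encoder is available, so very small real datasets would
  train from scratch.
* Background removal assumes a roughly uniform background distinct in
  chroma from tissue.
* ANCOVA is a joint slope/intercept F-test against the fixed identity
  line; other formulations (sequential covariate tests) would give
  different F values on the same data.
* The KS normality p-value uses estimated parameters and is therefore
  anti-conservative for small n.
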