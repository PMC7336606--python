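# Methods

## Phantom generator

The generator renders the minimal set of fundus-photograph properties that
the downstream pipeline exploits, with exact ground truth; it makes no
attempt at photorealism.

Intensity model (scalar field in [0,1], tinted to RGB with per-channel
gains (1.0, 0.55, 0.22)): background 0.02; retinal base 0.45 modulated by a
linear illumination ramp (default slope 0.05 across one boundary radius);
vessels — seeded random walks radiating from the disc — clamped to 0.25;
bright exudate-like blobs as Gaussian bumps peaking at 0.75; dark
microaneurysm-like dots at 0.12; optic disc a plateau at 0.95 with a
Gaussian skirt, strictly the brightest structure. Additive Gaussian pixel
noise (default sd 0.01) is clipped at the disc brightness so the
brightest-region assumption survives noise. Default geometry: 220×220 px,
boundary radius 97 px centred, disc radius 11 px offset (44, −10) px from
centre.

Lesions appear for grades 1–4; their count is drawn from the configured
range (default 2–8) with the lower bound rising with grade, and their
positions are rejection-sampled inside 0.92·R of the boundary subject to a
minimum distance from the disc centre of `lesion_eccentricity_min`·R
(default 0.4). The eccentricity default encodes the clinical observation
that DR lesions concentrate away from the optic nerve head, which is the
mechanism the FOV experiment probes. The binary label is grade > 0; grade 0
phantoms have no lesions by construction.

Determinism: each phantom is a pure function of (config, grade, seed);
cohorts derive per-image seeds from a `SeedSequence` spawn of the cohort
seed.

What the phantoms do *not* emulate: real retinal texture, macula,
illumination artefacts of specific devices, image blur and compression,
grader noise in labels. Tests passing on phantoms therefore validate the
pipeline's *mechanisms* (geometry recovery, masking arithmetic, the
lesion-visibility effect), not clinical-grade DR detection.

## Boundary and disc detection

Boundary: Canny edges (σ = 2) on the green channel — the highest-contrast
channel in fundus photography — followed by a circular Hough transform over
radii [0.25, 0.6]·min(H, W), coarse step 2 px refined to 1 px around the
best candidate. Ties break by larger accumulator score, then larger radius.
A normalised accumulator floor of 0.25 guards against degenerate fits
(an all-black image raises `BoundaryNotFound`).

Optic disc: the grayscale image is Gaussian-smoothed (σ = 2) so pixel noise
cannot fragment the bright plateau; pixels strictly above the 99th
intensity percentile inside the boundary are kept, cleaned by opening and
closing with a disk structuring element of radius 3·R/300 px, and the
largest connected component's centroid is returned. Guards: minimum area
20 px² and maximum area 20% of the boundary disc (a uniform retina or a
non-compact bright region raises `DiscNotFound`). The strict inequality
makes a constant-intensity region select nothing. The percentile and kernel
are deliberate design choices; only the brightest-region principle is
fixed.

Masking: mask radius is exactly `fov_fraction × boundary_radius`; the
raster uses nearest-pixel rounding with membership distance < r + 0.5 from
the mask centre, the crop is the (2r+1)² square bounding box, zero-padded
where it overhangs the frame. Preprocessing crops landscape images
symmetrically left/right (odd margins lose the extra pixel on the
right; portrait images crop top/bottom, extra pixel at the bottom) and
resizes bilinearly with anti-aliasing to 227×227×3; an input already at
target size is returned unchanged, making the operation idempotent. The
FOV mask is applied before preprocessing.

## Curation

Grades 1–2 are dropped and 3–4 merged (binarization), the larger pool is
down-sampled uniformly at random to the smaller one, and the balanced pool
is split stratified with per-class test count ⌈class/10⌉. This is the
unique simple reading of a "1/9" test:train ratio consistent with both a
686 + 686 balanced pool and a 1234/138 split (⌈68.6⌉ = 69 per class). The
curation seed is an explicit, recorded input.

## Classifier

The classifier keeps the transfer-learning structure — frozen feature
extractor, trainable two-class fully-connected + softmax head — with the
head fitted by minibatch SGD: batch 2, learning rate 1e-5, momentum 0.9,
zero-initialised weights, run until the epoch-mean cross-entropy plateaus
(relative tolerance 1e-5, patience 3) with a hard cap of 40 epochs. All of
these are `TrainingConfig` fields.

The default desk-scale backend (`dog-head`) uses an analytic frozen stage
instead of pretrained CNN weights: difference-of-Gaussians band-pass maps
at scale pairs (1,2), (2,4), (4,8) px, rectified into on-centre (bright
blob) and off-centre (dark dot/vessel) channels, plus a low-pass intensity
map — the classic early-vision decomposition, matched to the structures
that distinguish DR from healthy retinas. Each map is pooled globally
(mean, max, 99th percentile) over the *retina content region*: pixels above
a 0.05 grayscale floor, eroded 20 px to exclude the image-boundary or
FOV-mask rim response, with the brightest region (grayscale > 0.5, dilated
15 px — the optic disc) excluded, as lesion-oriented fundus analysis
conventionally does. Global pooling over the disc-free content region makes
the 21 features tolerant to the recentring, rescaling and circular masking
that FOV simulation applies; features are standardised with a 1e-3 floor on
the scale so near-constant training features cannot blow up under domain
shift. A grid-pooled variant was rejected during design because its
features encode absolute position and break under disc-centred cropping.

Training on full-field images and testing on device crops is a genuine
domain shift; the feature design reduces it but cannot remove it. With no
deep-learning framework among the dependencies, a pretrained-CNN backend is
out of scope, but the backend registry accepts one without interface
changes; the evaluation layer never inspects backend internals.

## Evaluation

Accuracy reports draw `n_repeats` (default 20) stratified sub-samples of
`subsample_fraction` (default 0.8) per class and report mean and population
std of overall and per-class accuracy under the argmax decision rule. On a
balanced sample the overall accuracy equals the mean of the two class
accuracies by construction.

The ROC sweeps all distinct scores (ties grouped) with ±∞ sentinels,
positive class "No DR" by default (a flag inverts it). AUC is the
trapezoidal integral, identical to Mann–Whitney pair counting with half
credit for ties. The EER interpolates linearly along the sweep polyline to
the crossing FPR = FNR; the reported threshold interpolates on the same
segment, clamped to the nearest finite endpoint when the crossing touches a
sentinel. Against a brute-force evenly-spaced threshold sweep the
interpolated EER agrees to within half an empirical ROC step, i.e. to 1e-3
once class sizes exceed ~1000.

## The end-to-end experiment

`pipeline.run_fov_experiment` generates 400 phantoms by default (200
grade 0, 100 grade 3, 100 grade 4), curates and splits them (360 train / 40
test), trains the default backend on preprocessed full-field training
images, then fits boundary and disc once per held-out image and evaluates
the classifier at FOV fractions {0.32, 0.40, 0.45, 0.94, 1.0}. Held-out
images failing detection would be dropped from all fractions alike (none do
on phantoms). The problem size keeps the full experiment under a minute on
one CPU while leaving ~40 test images per fraction — enough to resolve the
large-vs-small FOV contrast, though not fine differences between the three
small-FOV devices.

Expected behaviour, and what the tests assert: overall accuracy is
non-decreasing in FOV fraction (within one pooled std between adjacent
fractions), and the DR-class accuracy gap between the largest and smallest
FOV is positive. At FOV 0.32–0.45 the disc-centred mask excludes nearly all
lesions (minimum lesion eccentricity 0.4·R), so DR sensitivity collapses to
~0 while No DR specificity stays high — the small-FOV failure mode — and
the transition to high accuracy happens between 0.45 and 0.94. Real
devices additionally differ in optics, illumination and noise, which this
experiment deliberately holds fixed to isolate the FOV effect.

## Known limitations

- Phantom realism is limited to the properties listed above; absolute
  accuracy numbers on phantoms say nothing about clinical performance.
- The desk-scale backend is linear in 21 hand-designed features; it cannot
  learn lesion types the features do not respond to.
- The boundary fitter assumes a single dominant circular boundary with
  radius in [0.25, 0.6]·min(H, W).
- EER interpolation is only as fine as the empirical ROC; with few test
  items it is quantised accordingly.
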