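# Methods

## Problem setting

Dynamic FLT PET records, for every voxel, a time-activity curve (TAC): the
tracer concentration (kBq/mL) across an ordered set of acquisition frames.
FLT accumulates in proliferating tissue, so lung tumours stand out — but so
do bone marrow (similar irreversible kinetics) and liver (higher uptake,
reversible kinetics from FLT-glucuronide metabolism).  `fltseg` implements
two segmentation routes for the metabolically active tumour volume and the
statistics used to compare their test-retest (TRT) repeatability.

## Kinetic filtering (KF)

Each voxel TAC `p` is compared with a set of *kinetic classes* — per-tissue
mean dose-normalised TACs `mu` with per-frame standard deviations `sigma` —
by the Mahalanobis distance

    D_M(p, class) = sqrt( sum_t ((p_t - mu_t) / sigma_t)^2 )

and assigned to the nearest class.  Classes are derived from a cohort of
scans: per scan and tissue, a VOI-mean TAC divided by the injected dose
(MBq); across scans, the per-frame mean and sample SD (n−1 denominator).
Because the classes are dose-normalised, the scan under analysis is divided
by its own injected dose before classification.

When class and scan schedules differ, TACs are resampled by linear
interpolation of (frame mid-time, value) pairs, clamped outside the source
range.  Mid-time point evaluation is the standard TAC convention; it makes
the 95-min and 60-min protocols interoperable deterministically.

Ties in the argmin resolve to the earlier class in the set's fixed order.
A frame in scope whose effective SD is zero is an error (a degenerate class
would silently dominate or vanish from the distance), never skipped.

### Variants KF1–KF9

The original algorithm (KF1) classifies on all frames and relabels
vertebrae-assigned voxels as tumour, because marrow and tumour kinetics are
not reliably separable.  The shipped presets add the adaptations that make
the classifier portable across acquisition protocols:

| preset | classes | adaptation |
|---|---|---|
| KF1 | hammersmith | original algorithm |
| KF2 | hammersmith | 3-point temporal smoothing of voxel TACs |
| KF3 | hammersmith | scan resampled onto the class schedule (not vice versa) |
| KF4 | hammersmith | liver relabelled tumour; classify 9–60 min p.i. |
| KF5 | hammersmith | liver relabelled tumour; classify 20–60 min p.i. |
| KF6 | hammersmith | liver class omitted |
| KF7 | hammersmith | liver and vertebrae classes omitted |
| KF8 | vumc | original algorithm with locally derived classes |
| KF9 | vumc | liver/vertebrae relabelled tumour inside lesion masks; smoothing; 15–60 min |

KF4/KF5 apply the liver relabelling globally (relabelling the class is
equivalent to relabelling every voxel assigned to it); KF9 applies it only
inside the lesion masks, where liver and vertebrae are anatomically
impossible.  Time windows keep frames whose mid-times fall inside the
interval; smoothing averages each frame with its neighbours (edge frames
with their single neighbour).  Uniform SD scaling (the `sigma_scale`
setting, 0.5/1.0/2.0) rescales all distances equally and provably cannot
change any label — it is exposed because per-class scaling could, and the
invariance itself is a useful integrity check.

Per lesion, the segmentation is the tumour-labelled voxels inside a *lesion
mask* (tumour plus a small rim, drawn by an observer; here produced by the
phantom).  A lesion counts as detected when at least `min_detect_voxels`
(default 1) tumour voxels fall inside its mask; the threshold is
configurable because "reliably segmented" has no universal definition, and
the label composition inside the mask is reported so users can apply
stricter rules.  The VOI is deliberately not restricted to one connected
component; component counts are available in the A50% diagnostics and the
label image for users who want to filter.

## A50% segmentation

The background-adapted 50% isocontour operates on the duration-weighted
mean of the last three frames (45–60 min p.i. for the built-in protocols):

1. locate the hottest voxel within 20 mm (configurable) of a user seed;
2. grow the connected region above 70% of that maximum;
3. measure local background as the mean of a one-voxel-thick shell of
   voxels 15 mm outside that contour (Euclidean distance in mm, so
   anisotropic grids are handled; shell thickness is one mean voxel pitch);
4. threshold at `0.5 × (max + background)` and grow the connected region
   above it from the max voxel.

Both levels are relative, so the segmentation is invariant to global
intensity rescaling; in particular a sum image and a mean image of the same
frames give identical contours (the mean is used because it is also the
correct SUV input).  Threshold comparisons are inclusive (`>=`).  Default
connectivity is 26 (vertex-adjacent), avoiding spurious splits of thin
bridges at PET resolution; 6 is available.  No contrast (threshold not
above background, e.g. a flat image, or a 70% contour that fills the whole
grid) marks the lesion undetected; a VOI escaping a caller-supplied
bounding region is flagged as a leak and likewise counted undetected, but
the mask is returned unclipped for inspection.

## Volume, SUV, TRT statistics

Volume is voxel count × voxel volume (cm³).  SUV uses the body-weight
convention, `SUV = C[kBq/mL] × weight[kg] / dose[MBq]` (tissue density
1 g/mL); decay correction is assumed already applied in the reconstruction,
as is standard.  Both SUVmean and SUVmax over the VOI are reported, and SUV
is evaluated on the same late-uptake mean image the A50% method segments.

TRT variability of a measurement is `|test − retest| / mean × 100` (%),
symmetric, scale invariant and bounded by 200; it is NaN when both
measurements are zero.  Method comparisons restrict to lesions detected by
every method on both scans (detection tallies are reported separately) and
emit both the median and the mean of the per-lesion variabilities, which
can differ materially in small skewed samples.

## The digital phantom

The phantom emulates a thorax FLT study: lung background with two spherical
tumours, a liver sphere, a heart sphere, a vertebral column box and a
chest-wall soft-tissue slab, on a 40×40×20 grid of 4-mm voxels (160×160×80
mm) by default.  Tissue kinetics are simple analytic families chosen to
satisfy the qualitative constraints of FLT physiology rather than to
reproduce any particular scanner's amplitudes:

| tissue | family | amplitude (kBq/mL) | parameters |
|---|---|---|---|
| lung | flat | 0.4 | — |
| soft tissue | flat | 1.2 | — |
| heart | gamma-variate bolus + plateau | 3.5 | peak 0.75 min |
| liver | bi-exponential (reversible) | 9.0 | k_in 0.8/min, k_out 0.02/min |
| vertebrae | saturating rise (irreversible) | 7.0 | k 0.25/min |
| tumour | saturating rise (irreversible) | 6.0 | k 0.35/min |

Amplitudes are free parameters ordered as in real FLT biodistribution
(liver highest, lung lowest).  Frame values are point evaluations at frame
mid-times, consistent with how every downstream operation consumes TACs.

Noise is zero-mean Gaussian, independent per voxel and frame, with SD
`noise_level × sqrt(amplitude) / sqrt(duration_min)` — the count-statistics
scaling of reconstructed PET, which makes the short early frames of a
dynamic protocol much noisier than the late 5-min frames.  The default
`noise_level` 0.5 gives late-frame SDs around 10% of tumour uptake.  The
phantom does not simulate reconstruction (no FBP streaks, the failure mode
that makes KF unusable on analytically reconstructed images), no partial
volume/point-spread blur, no motion, and spatially independent noise —
passing tests show algorithmic correctness under controlled conditions, not
clinical performance.  Test/retest pairs share geometry and true kinetics
and differ only in the noise realisation; real repeat scans additionally
differ in positioning and physiology, so phantom TRT numbers are a floor,
not an estimate.

Lesion masks are the true lesions dilated by 2 voxels ("tumour plus a rim"
of the sort an observer would draw); the rim width is configurable, with
rim 0 giving the true lesion exactly.  Overlapping placed geometries are an
error — each voxel has exactly one truth label.

`true_class_set` builds classes matched to the phantom's true kinetics
(mean = true TAC / dose; SD = 10% of the class mean, floored at 10% of its
time average so no frame is degenerate).  With these classes and zero
noise, classification recovers the truth labels exactly — the phantom's
central calibration property.

## Verification sizes and determinism

All checks run on synthetic data generated at run time: 20×20×10×39
phantoms for oracle-equivalence and invariance checks (4 000 voxels is
ample for voxel-wise label comparison), the 40×40×20 default phantom for
noiseless recovery and TRT runs, and three noise levels × 6 seeds for the
noise-degradation trend.  Every random quantity flows from an explicit seed
(`numpy.random.default_rng`), so reruns are bit-identical; the brute-force
oracles in the tests (per-voxel distance loops, BFS flood fill, shell
enumeration) are written independently of the vectorised implementations
they check.

## Known limitations

* Classification is purely per-voxel; no spatial regularisation.
* Kinetic classes must be protocol- and site-appropriate: with mismatched
  classes the classifier degrades sharply, which is the method's documented
  weakness and the reason the variant presets exist.
* The Mahalanobis weighting uses cohort SDs, not voxel-noise SDs, so very
  noisy early frames can dominate the distance; the windowed presets
  (KF4/KF5/KF9) are the remedy.
* A50% assumes the lesion is surrounded by representative background at
  15 mm; hot neighbouring structures inside the shell bias the background
  upward (no exclusion is applied beyond the initial contour interior).
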