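# Methods

This note documents the models, numerical choices and limitations of
the meiostorm analysis pipeline and its synthetic-data generator.

## Coordinate and rendering conventions

All modules share one coordinate frame: nanometers, origin at the
image top-left, y increasing downward. Density images are rendered on
a 5-nm pixel grid; each localization contributes an isotropic 2-D
Gaussian of **unit mass** with σ equal to its localization precision
(default) or a fixed bandwidth, so image values are localizations per
nm² and the segmentation thresholds (0.05 loc/nm² for axis proteins,
0.15 loc/nm² for recombinases) are absolute densities. Gaussians are
truncated at 5σ; the resulting mass loss is below 0.01% and is covered
by the 1% mass-conservation tolerance asserted in the tests.

Two rendering engines produce the same field: an *exact* engine that
evaluates each truncated Gaussian at its sub-pixel center (used for
per-ROI segmentation and all closed-form tests), and a *binned* engine
for whole-nucleus images (> 20,000 localizations) that histograms
localizations into precision bins no coarser than 1/8 of the precision
spread and applies separable Gaussian convolution per bin in float32.
Binning snaps positions to pixel centers (≤ 2.5 nm) and quantizes σ by
≤ ~1 nm; both effects are negligible at the 10-nm blur and
particle-size scales where the binned engine is used.

## ROI detection

The 11-step selection uses published parameter values throughout: axis
blur σ = 10 nm; axis particle filter ≥ 50,000 nm² with circularity
4π·A/P² in [0, 0.89] (beads excluded); axis dilation 125 nm;
recombinase minimum areas 12,500 nm² (RAD51) and 7,500 nm² (DMC1);
recombinase dilation 15 nm; 750-nm ROI diameter; one single-linkage
merging round at 400 nm. Numerical choices where the procedure leaves
room:

* **Huang threshold** — implemented as Huang–Wang fuzzy-entropy
  minimization on a 256-bin histogram, objects above threshold.
  Qualitative agreement with the reference implementation is tested on
  bimodal fixtures; bit-parity with any particular GUI implementation
  is not promised. Thresholding operates on the blurred rendered
  density image.
* **Find maxima** — regional maxima of the mask-restricted merged
  recombinase density above a noise tolerance equal to the recombinase
  KDE threshold (0.15 loc/nm², configurable), with a 50-nm minimum
  peak separation to suppress plateau duplicates; the 400-nm merging
  round absorbs the rest.
* **Merging** — single-linkage with transitive chains formed within
  one round, each cluster replaced by its unweighted centroid.
  Consequence: in a D2R1 site whose far focus produces its own maximum
  ~300 nm away, the merged ROI center lands between the two maxima, so
  a minority of ROI centers sit ~100–150 nm from the density-weighted
  site center. Detection accuracy is therefore summarized by the
  *median* center error (≈ 5 nm on the default generator) together
  with recall at the ROI radius.
* **Dilation** — Euclidean-disc dilation computed via the distance
  transform (exact disc, radius rounded to the nearest pixel).
* **Connectivity** — 8-connected everywhere; perimeter from the
  scikit-image boundary estimator.

Manual curation (step 11) is declarative: removal/addition/recentering
lists applied by `apply_manual_edits`, with the touched fraction
logged. On synthetic data the fiducial beads — which are bright in
every channel and therefore double-positive — are removed this way,
exactly as bead ROIs are removed by hand in practice.

## Nanofocus segmentation and configurations

Within each ROI circle all localizations are used. Per channel, the
exact-engine density on the 5-nm grid is thresholded at 0.15 loc/nm²;
8-connected components ≥ 1,250 nm² (50 px) become nanofoci. Area is
pixel count × 25 nm²; eccentricity is √(1 − λ₂/λ₁) from the binary
region's second central moments (0 = disc, → 1 = line); the center of
mass is the unweighted mean of pixel centers; each localization is
assigned to the component containing its position (localizations in no
component are counted separately). ROIs keep their DxRy label from the
per-channel counts; QC drops ROIs whose largest nanofocus is ≤ 12,500
nm² (500 px) and, by default, single-protein ROIs (D0Ry/DxR0) — the
latter re-enterable for background-sensitivity analyses. Close/far
ties (exactly equidistant centers) resolve to the lower nanofocus
index with a warning. Overlapping ROI circles are analyzed
independently; a localization inside two circles contributes to both.

For an isolated Gaussian cluster the expected threshold-crossing area
is A = 2πS²·ln(N/(2πS²t)) with S² = s² + ⟨σ²⟩ (cluster spread plus
mean squared precision). This closed form is the independent oracle
for the area-recovery tests (median measured/predicted within 10%).
One consequence worth noting: a cluster of a few hundred localizations
with ~15 nm spread crosses the 0.15 threshold only over a few hundred
nm², i.e. *below* the 50-pixel floor — crossing the floor requires
either more localizations or a larger physical spread.

## Geometry

The consensus rotation is a rigid transform (translation + rotation,
no reflection or scaling): anchor center of mass to the origin, goal
center onto the positive vertical half-axis. Distance preservation is
asserted to 1e-9 relative. Consensus accumulation sums per-channel
fixed-bandwidth KDE images on a common grid and reports one far-center
dot per ROI (localization-count independent) beside the pooled
far-localization density.

Distance to the axes is the exact point-to-polyline (segment-wise)
minimum over all fragments of the nucleus, computed with shapely;
distances > 500 nm are flagged excluded. Inside/outside relative to a
synapsed lateral pair uses the unit vectors from the center of mass to
the nearest point on each lateral: inside iff u₁·u₂ ≤ 0 (a point on a
lateral counts as inside). The D2R1 angle is the acute angle (folded
into [0°, 90°]) between total-least-squares lines through the three
nanofocus centers and through the axis coordinates within a 1.5-µm
window of the ROI (window size configurable; orthogonal fits are used
because ordinary regression depends on axis orientation).

## Axis profiles and coiling

Perpendicular intensity profiles place sample lines every 25 nm along
a drawn centerline, with perpendicular directions from the local
central-difference tangent, 5-nm sampling steps and bilinear
interpolation; lines are averaged point-wise. The randomized control
redraws the observed number of localizations uniformly inside the
signal-region mask with precisions uniform in the observed range,
renders and profiles each of 50 patterns identically, and averages.
The mask must be the *filled* boundary of the signal region: a mask
that itself consists of two sub-ribbons would trivially preserve the
double-axis structure the control is meant to destroy. Peak counting
uses prominence ≥ 20% of the profile range.

Coil spacing is axis length / (twist count + 1) per axis; the
per-nucleus value is the unweighted mean over that nucleus's axes
(average-of-ratios; pooling lengths first would weight long axes more,
and one value per nucleus is the reported unit). Twist counts are
manual inputs; the generator supplies its ground-truth crossing counts.

## Nearest-neighbor analysis

Each nanofocus contributes its directed nearest same-channel neighbor
distance within the nucleus (mutual pairs count twice); channels are
analyzed separately. Histograms use half-open 100-nm bins to 3.5 µm
with a "rest" class beyond, normalized per nucleus and averaged with
one vote per nucleus. Subset sizes are floor(fraction × n) with a
minimum of 1 (conservative, reproducible); sampling is without
replacement with an explicit seed. The axis-projected variant measures
|Δarc| between projected coordinates within a fragment, excluding
fragments whose nanofoci all derive from a single ROI and
leptotene(-like) nuclei (axis fragments too short). For synapsed
regions the projection line is the midline of the paired laterals
(equal arc-fraction midpoint construction).

## Group comparisons

`compare_groups` runs two-sided tests at a declared unit of analysis
(nucleus, ROI or nanofocus), recorded in the output: Student's t,
Wilcoxon rank-sum (unpaired), Wilcoxon signed-rank (paired) and
Fisher's exact test. The bare name "wilcoxon" aliases to the unpaired
rank-sum because genotype comparisons are unpaired designs; the
signed-rank variant remains available for genuinely paired data. No
multiple-testing correction is applied; raw p-values are reported with
the test name.

## The synthetic-data generator

`synthdata` emulates the *statistical structure* the analysis assumes,
not microscope physics (no PSF, camera noise or blinking kinetics —
localizations are generated post-fitting):

* **Axes** — smooth random curves (heading random-walk, σ = 0.05
  rad/150-nm step) in a 25-µm field; 12 axes of 7–11 µm. Synapsed
  axes are a centerline plus two laterals offset ±100·sin(πs/c) nm
  along the normal, crossing every coil period c (2.1 µm wild type,
  1.0 µm knockout); synapsed lengths snap to whole periods, so the
  ground-truth spacing is exactly c — an idealization that makes the
  coil-recovery test exact rather than boundary-dependent.
* **Sites** — placed along centerlines with N(900, 150) nm arc
  spacing; sites that would fall within 750 nm of a site on another
  axis are dropped (such overlapping regions are not analyzable on
  real spreads either). A configuration is drawn per site from the
  observed mixture {D1R1 0.69, D2R1 0.15, D1R2 0.06, other 0.10},
  with "other" realized as D2R2.
* **Site geometry** — RAD51 rides the axis (normal offset N(0, 20)
  nm); DMC1 sits ~N(45, 8) nm from it; far foci lie ~N(300, 40) nm
  from the close focus, collinear beyond the single focus with ~12°
  jitter (a dumbbell), D1R2 with 2.5× the angular spread. This
  encodes: intra-site ~300 nm and inter-site ~900 nm preferred
  distances, the far-smaller-than-close area asymmetry (far cluster
  σ 20 vs 45 nm), and RAD51 nearer the axis than DMC1. The last
  property is recovered on *unsynapsed* axes; on synapsed pairs the
  distance is taken to the nearest lateral, and the centerline is the
  locally farthest point from both laterals, so the ordering inverts
  there by construction.
* **Localization counts** — negative binomial (over-dispersed) with
  role-specific means: ~8,000 per close/single nanofocus, ~1,800 per
  far nanofocus, dispersion 50; precisions uniform in 10–25 nm. The
  means are set so that nanofoci relate to the fixed thresholds the
  way real foci do: by the closed form above, a close focus needs
  several thousand localizations to exceed the 12,500 nm²
  ROI-inclusion area at 0.15 loc/nm², and a far focus ~1,000 to clear
  the 1,250 nm² floor. Smaller counts would make the published
  thresholds unsatisfiable by construction.
* **Background and beads** — uniform background (20 loc/µm², far too
  sparse to cross any threshold) and 4 fiducial beads (25,000
  localizations per channel, σ 70 nm) that are bright in every
  channel: they are excluded from the axis mask by the circularity
  filter but, being double-positive, yield ROIs that must be removed
  by the manual-edit step, as in real curation.
* **Knockout preset** — 40% site retention, 15% smaller focus areas,
  1.0-µm coil period, knockout stage vocabulary.

What passing tests on this generator do **not** show: robustness to
drift-correction residuals, fluorophore-specific blinking statistics,
antibody labeling density variation, overlapping chromatin
backgrounds, or axis-tracing (manual-drawing) error — the generator's
axes are known exactly, so axis-distance medians are tens of nm where
real data (with drawing error and biological offsets) report ~90–110
nm. Ordering and structural properties, not absolute medians, are the
meaningful recoveries.

## Problem sizes

The default test suite simulates compact nuclei (3 axes, 12-µm field,
~20–30 sites) with full-scale focus photophysics, so every fixed
threshold operates in its realistic regime while the suite stays under
a minute. The acceptance script uses 12 full-size wild-type nuclei
(~1,000 ROIs) for segmentation-level quantities, 4 of them for
whole-nucleus ROI detection, and 6 knockout nuclei at ground-truth
level; these sizes give binomial standard errors of ~1.5% on the
configuration fractions and stable medians while completing in a few
minutes on one CPU.

## Known limitations

* Blink grouping is greedy in frame order (earliest open group wins);
  pathological interleavings of two nearby emitters can split
  differently than a global optimizer would.
* The binned rendering engine snaps positions to the pixel grid;
  sub-pixel quantities (centers of mass) are always computed from
  masks or the exact engine.
* Fiji bit-parity (Huang, Find Maxima, perimeter) is not promised —
  parameters and polarity match, implementations differ in rounding.
* 2-D only: no 3-D segmentation, rotation or helical SC modeling.
* Chromosome identity (X/Y/PAR) is consumed as an input label; no
  morphology-based assignment is attempted.
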