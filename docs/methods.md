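# Methods

This note records the models, conventions and design choices behind
`octaquant`, in the order the pipeline runs.

## Input model

An en-face image is a square raster of flow signal over a 6×6 mm macular
field, held internally as floats in [0, 1]. The default grid is 500 px
(12 µm/px), the native scan-grid class of swept-source devices for this
field size; at that pitch the vessel-diameter index lands in the tens of
micrometres, the magnitude range reported for the SCP. Each image carries a
device signal-strength index (SSI, 0–10); the quality filter drops scans
below 8, the conventional cutoff.

## Dual binarization

The chain is: 3×3 median despeckle → white top-hat (disc radius 12 px) →
duplicate → { Hessian tubeness + Huang global threshold } ∪ { local median
threshold } → removal of connected components under 20 px.

* **Despeckle.** OCTA texture is dominated by multiplicative speckle; a 3×3
  median is the usual first step of ImageJ-based OCTA quantification and is
  required for the local-median branch to stay quiet on vessel-free areas.
* **Top-hat (radius 12 px).** Roughly 3× the widest expected vessel, so
  vessels pass while illumination gradients and large-scale background are
  removed; constant backgrounds map to exactly zero.
* **Hessian branch.** The tubeness score at scale σ is the magnitude of the
  most negative eigenvalue of the σ²-normalized Hessian (Gaussian
  derivatives, replicate-edge boundary), clipped at zero; bright ridges of
  width ≈ 2σ respond maximally on their centreline. The default σ = 1.2 px
  is about half the expected capillary caliber; larger scales respond to
  the *bends* of tortuous capillaries and bridge them, which both inflates
  perfusion density and straightens the skeleton. The global threshold is
  the Huang–Wang minimum-fuzziness level on a 256-bin histogram (membership
  u = 1/(1+|g−µ_class|/C), Shannon entropy summed over the histogram; the
  exhaustive scan over all levels *is* the implementation, so the test
  oracle is a plain-loop re-derivation). Two deliberate conventions:
  the histogram fed to Huang is that of the **signed** eigenvalue map — on
  the clipped map the zero spike representing empty background dominates
  the entropy and drags the threshold into the faint bend halo — and the
  resulting threshold is floored at an absolute tubeness of 0.02
  (normalized units). The floor only matters for images with no tubular
  structure at all, where any histogram split is spurious; on vessel-bearing
  images the Huang level (0.06–0.10) sits above it.
* **Median branch.** Foreground iff pixel > median of its (2r+1)² window
  (r = 15, edge-replicated) + offset 0.06. A strictly zero offset marks
  ~half of any noise field (half of the samples exceed their local median),
  so the offset is set just above the despeckled noise floor; on clean
  images vessels exceed the local median by the full vessel contrast and
  the offset costs nothing.
* **Combination.** Pixel-wise union, maximizing continuity: the median
  branch recovers capillary support almost exactly, the Hessian branch adds
  large-vessel cores and bridges low-contrast stretches. Components under
  20 px are then discarded as speckle; optional small-hole filling is
  available but off by default.

## Skeleton analysis

Thinning is topology-preserving (connected components conserved). Branch
decomposition follows the Analyze-Skeleton convention: skeleton pixels with
≥3 eight-neighbours are junction pixels, merged into junction clusters
(raw neighbour counts fragment junctions); pixels with exactly one
neighbour are endpoints; branches are maximal node-free paths, with arc
length step-summed (1 orthogonal, √2 diagonal) and chord the Euclidean
distance between the terminal node pixels. Node-free loops are labelled
cycles.

For branch statistics the skeleton is first **spur-pruned**: end twigs
shorter than 12 px are deleted and the skeleton re-thinned (up to three
passes). Thinning a slightly rough mask sprouts such twigs, and every twig
converts one through-going centreline into two branches whose chords then
cut below the tortuosity scale; pruning removes the artefact without
touching the mask. PD, VLD and VDI use the *unpruned* skeleton, so the
identity PD/VLD = VDI/pitch holds to machine precision by construction.

Tortuosity eligibility: non-cycle branches with arc ≥ 3 px; region
assignment by branch midpoint, so a branch straddling the annulus boundary
is counted once. VT ≥ 1 holds per branch by the triangle inequality.
Metrics undefined on their input (no skeleton in region, no eligible
branch) return NaN rather than raising.

One measured limitation: standard thinning uses directional sub-iterations
and is not exactly equivariant under 90° rotation; PD is exactly invariant,
VLD shifts by ≲1 % and VT by ≲3–5 % under a quarter turn.

## Region geometry

Masks are built in physical units with pixel-centre membership and
half-open rings [inner, outer): parafovea = [FAZ/2, 1.25 mm), perifovea =
[1.25, 2.75 mm). The two regions are disjoint and tile the FAZ-excluded
macular annulus exactly. The FAZ is excluded as a fixed disc (default
0.6 mm) rather than segmented — deterministic, with a mask-file override
for hand-drawn FAZ outlines. The foveal centre is located as the centroid
of the near-maximal plateau of the distance transform of the non-vessel
area within a central 1.5 mm window — the largest inscribed avascular disc,
which is the FAZ bounded by its terminal capillary ring; a flat image falls
back to the geometric centre. On default phantoms the detector lands within
4 px of the true centre.

## Synthetic phantoms

Purpose: exact, pre-noise ground truth for every measured quantity. The
default layout emulates the centripetal organisation of the SCP:
near-parallel radial trunks from the field boundary toward the centre, each
forking one inward daughter, plus a terminal ring of short arcs bounding an
avascular centre (0.3 mm radius kept vessel-free). Centrelines are straight
radii with a small spline meander plus a tanh-flattened sinusoid
(wavelength 33 px) whose amplitude is solved numerically (Brent) so each
path's arc/chord ratio hits the tortuosity target (default 1.4, the level
reported for iERM eyes). The flattened waveform matters: a plain sine
concentrates all curvature at its crests, below the radius a ≥3 px tube can
express after thinning, which silently destroys tortuosity ground truth.

Rendering strokes each centreline at a caliber drawn from N(2.5, 0.5²) px
(truncated ≥ 1) via a distance transform; truth is captured before noise:
fill fraction and centreline fraction by pixel count (8-connected Bresenham
chains, the same chain convention thinning produces), mean caliber as
area/centreline pixels, tortuosity as Σ analytic arc / Σ chord per path.
Noise is multiplicative gamma speckle (shape 9) then additive Gaussian
(SD 0.02), applied after truth capture. Identical spec + seed is
bit-identical.

The default field is deliberately sparser (fill ≈ 0.11) than a real SCP
(≈ 0.25–0.40): at realistic density the strands of *any* generator merge
under rendering, and merged geometry has no well-defined per-vessel truth —
ground-truth recovery and anatomical density are in direct tension, and
this generator's job is truth. Consequences: phantom VLD (≈ 3–4 %) sits
below clinical values, and passing recovery tests demonstrates measurement
fidelity on resolvable vasculature, not performance on densely packed
capillary meshes. The parameter-recovery suite (`recovery_spec`) uses
noiseless phantoms with calibers truncated at 3 px — thinning cannot
localize the centreline of a much narrower wiggling tube — and achieves,
over 20 seeds, worst-case relative errors of about 4 % (PD), 12 % (VLD),
17 % (VDI) and 5 % (VT). Under default speckle, PD and VT remain accurate
while VLD degrades (noise breaks skeleton continuity); noisy recovery is
not asserted.

## Cohort simulation

Per-eye values are drawn from the published group summaries (mean ± SD per
group × region × metric × visit): the four SCP metrics at baseline for both
groups, and three-visit central-macular-thickness / visual-acuity courses
for the surgical group. Cross-visit dependence uses a Gaussian copula with
equicorrelation ρ = 0.5 (no within-eye correlation is published; this is a
free knob). Two-grader mode draws paired readings at correlation 0.995 with
no bias, emulating the reported interobserver concordance of 0.99. The
control tortuosity location of 0.7 is kept exactly as published even though
an arc/chord ratio below 1 cannot arise from the measurement definition;
in simulation it acts purely as a location parameter separating groups, and
the package flags the inconsistency here rather than "correcting" the value.

## Statistics

scipy.stats provides the distributional machinery (Shapiro–Wilk,
Mann–Whitney with exact enumeration for n₁+n₂ ≤ 12 without ties and
tie-corrected normal approximation otherwise, Pearson χ² without Yates
correction by default, Friedman, Wilcoxon signed-rank with zeros dropped).
"Wilcoxon U test" between time points is read as the signed-rank test —
the comparisons are within-eye and therefore paired. Bonferroni multiplies
by the number of pairwise time-point contrasts (3 for baseline/1 mo/6 mo)
and caps at 1. Lin's CCC uses population (1/n) moments,
ccc = 2·cov/(varx + vary + (meanx−meany)²), with the confidence interval
from Lin's asymptotic variance of the Fisher-z transform. Both the omnibus
Friedman p and the adjusted pairwise contrasts are reported and labelled,
since published analyses quote sometimes one, sometimes the other.

## Pipeline and reproducibility

Batch processing isolates failures per image (logged, batch continues),
mirroring manual QC. Every run writes a manifest (config hash, seed,
package versions) sufficient to reproduce any table cell. The study
replica simulates both cohorts (n = 24 per group), runs between-group
tests at baseline, the longitudinal battery within the surgical group,
interobserver concordance, metric-vs-thickness rank correlations, and the
demographics χ² from the published gender counts.

Problem sizes used by the test suite and the acceptance script: 500 px
phantoms (20 for recovery, seeds 1–20 equivalent), 100 cohort simulations
for the group-comparison medians, 2000 replicates for the null calibration
of the between-group test (empirical type-I error ≈ 5 %).

## Known limitations

* No projection-artifact removal and no deep-plexus/choriocapillaris
  analysis; the chain targets the SCP only.
* No automatic FAZ segmentation; the FAZ is a fixed-diameter disc or a
  user-supplied mask.
* Phantom density is below clinical SCP density (see above); absolute VLD
  levels of phantoms are not comparable to published cohort values.
* The thinning-based skeleton is only approximately rotation-equivariant.
* How repeated scans per eye were reduced to one measurement is not
  published; the simulator exposes replicates but takes no stance.
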