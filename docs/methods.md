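# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `lungmorph`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Morphometric model

For a cubic reference region of volume V_ref (an RVE or a moving mask)
containing alveolar surface area A_alv and airspace volume V_airspace:

    rho = A_alv / V_airspace        surface-to-volume ratio, mm^-1
    eta = A_alv / V_ref             alveolar surface density, mm^-1
    phi = V_airspace / V_ref        porosity, dimensionless

whence rho = eta / phi.  The package treats this identity as structural:
the rho map is *defined* as eta/phi voxel-wise (with an epsilon guard,
default 0.01, below which the voxel carries a NaN sentinel), and RVE
records populate eta as rho*phi, so the identity holds exactly wherever all
three are reported.

Porosity convention: phi = 1 means all air, phi = 0 all tissue.  Written
descriptions of voxel-porosity maps sometimes invert this ("0 = airspace");
this package follows the defining ratio (airspace over total), and all maps,
tables and figures use that convention consistently.

Units: lengths in μm internally; eta and rho are reported in mm^-1
(multiply the μm^-1 value by 1000), matching how such values are usually
tabulated (tens of mm^-1 for rodent parenchyma).

## 2. Synthetic alveolar-foam phantoms

The generator emulates fixed, air-inflated rodent parenchyma at 4 μm
isotropic resolution: quasi-spherical alveolar cavities, 30–55 μm diameter,
separated by septal walls of ~7 μm.  Design goals, in order: (i) exact
ground truth, (ii) reproducibility, (iii) morphological plausibility.

**Geometry.**  Cavities are non-overlapping spheres with a hard minimum
inter-sphere gap (`wall_gap_um`, default 7 μm).  Candidate centres sit on an
FCC lattice with nearest-neighbour distance `2*(mean + 0.5*sd) + gap`,
jittered by ±1 μm; sites are visited in a seeded random order, each sphere's
radius is drawn from a truncated normal (default mean 20 μm, sd 1 μm,
bounds 15–27.5 μm) and capped by per-neighbour feasibility so no gap ever
falls below `wall_gap_um`.  The within-foam radius sd is deliberately small:
the several-μm diameter sds reported for real lungs describe variation
*between* sampling volumes, not the spread inside one acinus-scale patch.

**Porosity control is thinning, never rescaling.**  A sphere is placed only
while the slab containing its centre is below its porosity budget (exact
voxel counts drive the stop rule), so the drawn radius distribution is
preserved and every truth invariant (radii within bounds, gaps >= wall)
holds exactly.  Budgeting is per slab even for uniform foams: it pins the
slab-scale cavity density, which otherwise fluctuates enough (a few
percent) to leak into regional statistics as spurious between-ROI variance.

**The porosity ceiling.**  Non-overlapping spheres with finite walls cannot
be arbitrarily porous: even a perfect FCC packing gives
phi_max = 0.74 * (r / (r + gap/2))^3, about 0.44 for 40 μm cavities and
0.52 for 55 μm ones; the realized generator reaches ~0.40 and ~0.46
respectively (measured, including jitter and thinning losses).  Real
alveoli evade this bound by being space-filling polyhedra, which is why
measured lung porosities of 0.5–0.65 coexist with 7 μm septa.  Targets
above the ceiling *saturate*: generation stops when no further sphere fits,
a `SaturationWarning` reports the achieved porosity, and the truth records
it.  All downstream validation is stated relative to the *counted* truth,
so saturating phantoms remain fully usable.  The default target (0.35) sits
below the ceiling so default phantoms are exactly on target.

**Ground truth.**  A voxel is air iff its centre lies inside a cavity, so
air counts (global and per slab) are exact integers.  The continuum surface
area is the sum of analytic sphere areas, with spherical-cap corrections
for cavities clipped by the box faces (exact for single-face clips; rare
edge/corner clips are slightly under-corrected).

**Porosity profiles.**  `generate_profile_foam` applies per-slab targets
(default 10 slabs) along a labelled axis.  The bundled `saf_like_profile`
(0.30 at both ends rising to 0.45 at the centre) emulates the concave
ventral–dorsal porosity signature of ethanol-fixation subpleural collapse
at a porosity scale the sphere foam can realize exactly.

**Artifacts.**  `apply_ct_appearance` renders two class means (defaults
50/200), a Gaussian point-spread (default sigma 4 μm) and i.i.d. Gaussian
noise (default sigma 15), seeded.  `apply_subpleural_collapse` dilates
tissue inside a boundary shell only — a direct model of micro-atelectasis;
it provably never increases porosity.

**What the phantoms do not emulate:** alveolar ducts and bronchioles
(cavities are isolated; real airspace is connected), polyhedral cavity
shapes, wall-thickness variation, CT physics (beam hardening, rings,
anisotropic PSF).  Passing tests therefore demonstrate correctness of the
*computations* under a known geometry, not robustness to every property of
real scans.

## 3. Preparation and segmentation

Median (radius 1 voxel) then Wiener (window 3) filtering for noise; contrast
enhancement as input + white-top-hat − black-bottom-hat (radius 2 voxels)
with optional histogram equalization rescaled to the input range.  All
filters are 3D.  Otsu thresholding uses a 256-bin histogram over the
observed range, making the threshold invariant under affine intensity maps
up to bin quantization; a `polarity` flag ("tissue-bright"/"tissue-dark")
maps the bright class onto the tissue = 1 convention.  The analysis domain
is the morphological closing (default radius 30 μm) of the largest
connected tissue component, hole-filled — this is what excludes exterior
air from maps and ROIs.

## 4. RVE morphometry

RVEs are cubes of ~500 μm, realized as the nearest odd voxel count (125 at
4 μm).  Selection is seeded rejection sampling: `n_per_zone` cubes per
apical/mid/basal third (cube centre within the zone), fully inside the
domain, pairwise non-overlapping, and rejected if the largest connected
airspace component exceeds `exclusion_fraction` of the cube (a proxy for
bronchi and vessels).  Greedy zone order can wedge tight domains, so the
whole selection restarts with a fresh sub-seed (bounded), and early tries
prefer axial positions that leave room for later zones.  Note the geometry:
zone-constrained 500 μm cubes need an apical–basal extent of roughly three
cube edges.

**Sphere fits.**  Seeds are local maxima of the airspace Euclidean distance
transform (minimum separation = expected wall thickness, 7 μm; threshold
2 voxels).  Each seed's watershed cell collects its boundary point cloud —
the *midpoints of air/tissue voxel faces*, which straddle the true
interface symmetrically and make the algebraic least-squares fit unbiased
to well under half a voxel (measured: ~0.07 voxels at r = 15 voxels).
Retention filters: radius >= 2 voxels, RMS residual <= 0.5*radius, and
radius <= 2x the seed's inscribed-sphere radius — the last guards against
algebraic fits to nearly planar point clouds, which otherwise produce
enormous spheres with deceptively small relative residuals.

**Wall thickness.**  For each sphere, its nearest neighbour at centre
distance d gives t = d − r_i − r_j; pairs with t <= 0 or t > `max_gap_um`
(default 20 μm, excluding cross-duct pairings) are dropped and the mean of
the deduplicated admissible pairs is returned (NaN if none).

**Cavity surface and volume.**  The union of fitted spheres (intersected
with the airspace) initializes a region-based morphological active contour
(Chan–Vese, fixed 50-iteration budget, smoothing 1) on the binary image;
the refined region gives V_airspace, and its Gaussian-smoothed (sigma 1
voxel) 0.5-iso-surface, triangulated by marching cubes, gives A_alv.
Cavities escaping the cube are clipped at the face; triangles on the
padded boundary band are excluded from A_alv and the clipped area is
logged.  On a digitized 60 μm-radius sphere this recovers V within ~1%,
A within ~0.1%, rho within ~1%.

**Record definition.**  Per-RVE records report phi as the exact air-voxel
fraction (the global-porosity definition), rho from the cavity
measurement, and eta = rho*phi.  A cavity-based phi would understate
porosity because boundary-clipped cavities yield no retained seed.

## 5. Moving-mask maps

Kernels are cubes; the nominal size in μm is rounded to the nearest odd
voxel edge (140 → 35 voxels exactly; 105 → 27 (108 μm); 70 → 17 (68 μm);
35 → 9 (36 μm); 17.5 → 5 (20 μm); deviations are logged).  Window sums use
separable prefix sums with int64 accumulation, so the porosity map equals
brute-force per-voxel window counting *bit for bit* — this is asserted, not
assumed.  Voxels whose kernel exits the domain carry NaN (no partial-window
renormalization: the statistics of partial windows are not defined by the
moving-mask construction).

The surface source field triangulates the 0.5 iso-surface of the
1-voxel-Gaussian-smoothed air indicator with marching cubes and accumulates
each triangle's area into the voxel containing its centroid; the iso-surface
itself localizes the tissue–air boundary, so no separate edge-detection
pass is needed.  Σ field equals the total interface area; eta is the
kernel-summed field over the kernel volume.  On a digitized sphere the
total agrees with the analytic area to ~0.2% and with an independent
normal-weighted face-count oracle to <3%.  One convention caveat: for an
interface spanning the whole box the marching-cubes domain is (n−1)
spacings per side, so a "plane area" differs from the face-count value by
(1−1/n)²; interior surfaces are convention-free.  Translation invariance
of the total area is digitization-limited: ~0.8% under sub-voxel shifts of
a 15-voxel sphere (the independent oracle shows the same on the same
masks), ~0.25% at 25 voxels.

**Mask-size sensitivity.**  For each size the supported map values are
summarized by a Gaussian KDE (Silverman bandwidth, computed by fine
histogram + Gaussian smoothing on a fixed grid — exact up to grid
resolution and sample-size independent), and successive-size curves are
compared by L1 distance.  On a ~40 μm-cavity foam the 105-vs-140 μm
distance is far below the 17.5-vs-35 μm one, reproducing the qualitative
finding that masks >= 70 μm give converged distributions while smaller
masks oscillate.

## 6. Regional analysis and statistics

ROIs are contiguous equal-volume slabs of advancing planes along the
ventral–dorsal axis (taken from metadata, never inferred from the image),
default 10.  Planes are assigned greedily against cumulative k/n quantiles;
every region's volume is within one plane's voxels of the ideal equal
share.  (No contiguous plane partition can bound the max–min spread by one
plane in general — boundary roundings compound — so the per-region bound is
the honest guarantee, and it is what the tests assert.)

Regional values are means of the supported map voxels per ROI (± sample
sd, n−1 denominator everywhere).  Group comparisons: two-sided
Mann–Whitney U, exact null distribution when both sides have n < 8 without
ties (verified against exhaustive enumeration of all label arrangements),
tie-corrected normal approximation otherwise; Bonferroni correction
defaults to the number of group pairs.  Normality: D'Agostino–Pearson K²
with a hard validity floor of n >= 20 (smaller samples raise an error
rather than silently passing).  Per-lung regional variability: one-way
fixed-effects ANOVA with groups = ROIs and samples = per-section regional
means (three apical–basal sections), mirroring the per-subject
section-variability analysis; degenerate inputs (zero within-group variance
with unequal means) raise instead of returning an infinite F.

On phantoms this pipeline flags the concave SAF-like profile in ≥99/100
seeded runs and flags the uniform phantom in ~0/100 (both recomputed by
`scripts/acceptance.py`).

## 7. Problem sizes and defaults

Validation runs use phantoms from 256³ μm (64³ voxels) to 600×1600×600 μm
(9M voxels), sizes at which every stage's behaviour is already asymptotic
(window counts are exact at any size; surface and fit errors are set by
voxel/feature ratios, not box size).  Key defaults: spacing 4 μm; cavity
diameter 40 μm (sd 2); wall gap 7 μm; target porosity 0.35; kernel sizes
140/105/70/35/17.5 μm; RVE edge 500 μm, 3 per zone, exclusion fraction
0.3; 10 ROIs; alpha 0.05; rho-map epsilon 0.01.

## 8. Known limitations

* The sphere-foam ceiling means porosities above ~0.46 cannot be realized
  with exact spherical truth; such targets saturate (with a warning) and
  validation is truth-relative.
* Isolated spherical cavities lack the connected duct tree of real
  parenchyma, so the bronchus-exclusion rule is exercised with synthetic
  cylinders, not realistic airways.
* Active-contour cavity measurement only sees cavities whose sphere seed
  survived the retention filters; rho is therefore a seeded-cavity
  statistic (phi, reported from exact counts, is not affected).
* Anisotropic voxels, DICOM input, and vendor reconstruction corrections
  (ring, beam hardening) are out of scope.
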