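# Methods

`lungdose` quantifies where pulmonary-delivered nanoparticles (NPs) end up
in a mouse lung imaged as a 3D light-sheet fluorescence microscopy (LSFM)
stack, and ships a synthetic-lung generator that makes every stage of the
pipeline testable against exact ground truth.  This note records the models,
the defaults and why they were chosen, and what the synthetic validation
does and does not demonstrate.

## Regional dose model

Given an NP fluorescence stack, a binary airway mask and a binary lung
mask, all voxel sums are restricted to above-threshold voxels inside the
lung.  The bronchial compartment is the airway mask (optionally dilated by
an explicit, logged number of voxels; default 0 — boundary voxels follow
the mask verbatim); the acinar compartment is the rest of the lung.  The
primary readouts are

* dose fractions `f_B = S_B / (S_B + S_A)`, `f_A = 1 − f_B`, and the
  bronchial-to-acinar ratio `B/A = S_B / S_A`, where `S` is summed
  fluorescence (a.u.);  a binary voxel-count mode exists for volume-style
  accounting;
* apparent NP-positive volumes: above-threshold voxel count × voxel volume
  (µm³) per compartment;
* absolute doses `dose_X = f_X · total` when a total lung dose (µg, from
  external dosimetry) is supplied — the package never converts
  fluorescence to µg on its own;
* the agglomeration state: apparent NP-positive volume per µg
  (µm³ µg⁻¹), the inverse packing density of the deposited material.
  Finely dispersed particles occupy at least one resolution-limited blob
  each, so equal doses read larger apparent volumes when dispersed and
  smaller ones when packed into few dense clumps;
* the central-to-peripheral (C/P) ratio on a maximum-intensity projection
  (MIP): the central region is the set of projected-lung pixels whose
  distance to the lung boundary is at least a cut `d*`, with `d*` chosen
  over the observed distance values so the central area is as close as
  possible to half the lung area (ties resolved toward the larger cut).
  The scan over sorted distance values makes the choice exact; there is no
  bisection residual.

### Thresholding

The NP/autofluorescence separation threshold defaults to an Otsu split of
the in-lung intensities computed on `log1p`-transformed values and mapped
back.  Fluorescence histograms are heavily right-skewed (a dominant dark
background plus a long bright tail); linear-domain Otsu then places the cut
among the bright values and can wipe out an entire compartment, while the
log-domain split lands between background and signal.  Two heuristic
diagnostics are reported and *warn* (never block): the mean positive
intensity should be at least twice the threshold, and the maximum intensity
5–50× the threshold.  A user-supplied threshold always overrides the
suggestion and is recorded as such.

## Synthetic lung phantom

The generator is a pure function of a `PhantomSpec` and its seed.  Each
sub-stage (tree growth, deposition, autofluorescence, observed-channel
composition) draws from an independent child stream of the seed, so adding
options to one stage never shifts the draws of another.

**Airway tree.**  Monopodial (rodent-like): every non-terminal branch ends
in one junction spawning a near-straight continuation daughter and one
lateral daughter at ~`branch_angle_deg` (default 40°, jitter SD 5°,
clipped ±10°); both daughters are one generation deeper (Weibel
numbering).  Lengths and diameters follow exact geometric schedules
`root·length_ratio^g` and `root·diameter_ratio^g`, so closed-form checks
are available at every generation.  Daughter directions are chosen from 25
seeded candidates scored by clearance against already-placed branches,
with a mild outward pull and a steep penalty for crowding existing tips;
trees whose terminal tips approach within `min_tip_separation_um` (45 µm)
are regrown from a jittered seed.  A `lateral_branching_depth` knob limits
how many lateral take-offs occur along any root-to-tip path (the default,
effectively unlimited, gives a full binary tree of 32 tips at 5
generations).

**Domain and acini.**  The lung is the set of voxels within
`acinus_radius_um` (140 µm) of the airway, Gaussian-smoothed into an
organ-like hull; containment of the airway is guaranteed by construction.
(An inscribed ellipsoid cannot hold a 5-generation tree inside a 128³
grid, so the tube-following hull replaced it.)  Every parenchymal voxel
joins the acinus of its nearest terminal-branch tip (a Voronoi
tessellation, so the acinar labels partition the parenchyma exactly);
within each acinus the proximal region (PAR) is the `par_cut_frac`
(default 0.5) nearest-to-tip volume quantile, the distal region (DAR) the
rest.  The equal-volume split makes `par_bias` interpretable as a dose
share over equal volumes: 0.7 means a 2.3× concentration contrast, a
moderate proximal gradient rather than a point hotspot.

**Deposition.**  `n_np_events` point events are placed.  A
`bronchial_fraction_target` share lands on airway-lumen voxels — weighted
toward low generations by `exp(−gen_decay·g)` for the instillation routes
and toward the lumen interior (blob centers ≥1.5 render-σ from the wall
where the caliber allows; instilled liquid pools in the lumen).  The rest
is distributed across acini with weight ∝ volume·exp(−λ·d̂), where d̂ is
the tip's distance to the lung centroid over the mean lung semi-axis; λ=0
is volume-proportional (uniform).  Within an acinus a `par_bias` share
lands in PAR.  The UNIFORM route instead samples voxels uniformly over the
whole lung (airway hits count as bronchial).  All truth sums
(bronchial/acinar/PAR/DAR/per-acinus) are event bookkeeping computed
before rendering, hence exact regardless of blob overlap or thresholding.

**Rendering.**  An agglomerate of Gaussian-equivalent radius `a` renders
as a Gaussian blob of width `sqrt(a² + psf²)` (psf 10 µm): below the
optical resolution every dot is imaged at least psf-sized.  The
fluorescence mass per event is `packing_density·(2π)^{3/2}·a³`, i.e.
proportional to physical NP mass at constant packing — this is what makes
the agglomeration-state readout discriminate dispersed aerosol from packed
instillate.  Each event's kernel (truncated at 3σ) is renormalized by its
local lung coverage so the rendered in-lung mass equals the event mass
exactly; without this, blobs at the pleural border bleed fluorescence into
the void and even ideal uniform deposition reads C/P ≈ 1.1–1.2 from rim
depletion.

**Channels.**  The autofluorescence (AF) channel is a base tissue level
(150 a.u.) inside the lung, a brighter shell on airway walls (gain 1.8; the
lumen itself is dark), a smooth multiplicative texture field (SD 0.15) and
additive Gaussian noise (SD 8).  The "observed" NP channel adds 5% AF
bleed-through and sensor noise (SD 5) to the rendered NP channel.

**Route presets.**  Bulk-liquid instillation (INLA, ITLI) deposits a large
bronchial share as few large central agglomerates; aerosol delivery (VAAD,
NOAI) spreads many fine dots nearly homogeneously, VAAD with a proximal
acinar bias:

| preset  | bronchial share | λ   | agglomerate radius | events | PAR bias |
|---------|-----------------|-----|--------------------|--------|----------|
| INLA    | 0.32            | 3.0 | 25 µm              | 1 500  | volume-prop. |
| ITLI    | 0.19            | 1.5 | 18 µm              | 3 000  | volume-prop. |
| VAAD    | 0.11            | 0   | 10 µm              | 30 000 | 0.7 |
| NOAI    | 0.08            | 0   | 5 µm               | 60 000 | 0.5 |
| UNIFORM | (volume-prop.)  | 0   | 12 µm              | 500 000| volume-prop. |

The bronchial-share centers are plausible means for these four routes, not
reproduction claims.  Event counts follow the physical picture (few large
clumps vs many fine dots); the UNIFORM preset uses a high enough density
that the rendered field is statistically homogeneous — the MIP of a sparse
blob field is depth-biased, so a preset whose defining property is
uniformity must saturate the projection.

The default deposition grid is 128³ at 12 µm isotropic voxels (a 1.54 mm
cube) — a scaled-down mouse lung with a 5-generation tree, chosen so a
full phantom builds in about two seconds and whole validation campaigns
(tens of phantoms) stay cheap.

## Artifact augmentation

The LSFM-specific transforms model the dataset's acquisition artifacts:
per-slice illumination scaling, a smooth radial dark-center attenuation
(cos² bump, exact `1−a` at the center column), local blur / contrast /
brightness / sharpness inside a cosine-feathered random box (voxels beyond
the feather are bit-identical to the input), and blank boxes at an exact
fill value.  The standard set (mirror, in-plane 90° rotations, Gaussian
noise/blur, brightness/contrast, gamma, low-resolution simulation) runs as
an ordered pipeline with per-op firing probabilities from one seeded
stream; sub-seeds are drawn even for skipped ops so firing of later ops
never shifts.  Arbitrary-angle rotation is deliberately excluded by
default for anisotropic stacks.  Patch-based inference support consists of
foreground-guaranteed two-patch sampling (uniform over origins covering a
uniformly chosen foreground voxel) and sliding-window aggregation with
half-patch stride, inward-shifted edge tiles and separable Gaussian center
weights (σ = patch/8); with an identity patch function the aggregation
reproduces the input voxelwise for any geometry, which pins the
normalization.

## Segmentation metrics

Volumetric Dice and centerline Dice (clDice) with Lee 3D thinning as the
default (pluggable) skeletonizer.  Empty-mask conventions are pinned: both
empty → 1.0, exactly one empty → 0.0, an empty skeleton of a nonempty mask
contributes 0 to its ratio.  Set evaluation reports the unweighted
per-image mean.  clDice is exactly mirror-invariant on tubular masks; on
blobby random masks the thinning algorithm itself is only approximately
mirror-equivariant (observed deviations ≲0.04), which is a property of the
thinning, not of the metric arithmetic.

## Morphometry

`extract_tree` thins the mask (largest component, with a warning, if it is
fragmented), builds the 26-connected skeleton graph, and restores tree
topology: 2-edge-connected clusters that are small relative to the local
inscribed radius (triangle chords and thinning "collars" around thick
junctions) are contracted to their widest voxel, while larger cyclic cores
— genuinely fused branches — are resolved by a minimum spanning tree.
Terminal twigs are pruned when they look like thinning artifacts: endpoint
inscribed radius under 1.4 voxels (a surface ridge) or length under half
the local tube radius plus one voxel (an in-tube stub).  Genuine terminal
branches end in a cap whose inscribed radius matches the branch caliber
even after thinning has eroded most of their length, which separates them
from both spur classes; at a junction whose distal side is entirely prune
candidates (a forked cap) the longest twig is kept — the tube genuinely
ends there.  The root defaults to the endpoint with the largest inscribed
radius (the trachea is the widest airway) and can be overridden.

Diameters are twice the mean distance-transform value along the
centerline, sampled as the local 3³ ridge maximum (the thinned skeleton
zigzags off the medial axis by up to a voxel) and excluding one local
radius at each end (carina bulges).  No half-voxel correction is applied:
the nearest background center of a digitized radius-R tube sits at
distance ≈R from the axis.  Branching angles compare direction windows
fitted after skipping one parent radius of arc on each side of the
junction, because the thinned daughter centerline first crosses from the
parent's axis to its own and the immediate post-junction direction
overstates the angle.  Generation numbering is Weibel-style (increment at
every junction), which matches how the monopodial generator counts and is
flagged in the output.

### The morphometry benchmark configuration

Exact tree recovery is validated on a dedicated phantom configuration
(`morphometry_benchmark_spec`): 192³ at 8 µm, slower taper
(`length_ratio` 0.85, `diameter_ratio` 0.78), 50° laterals,
`lateral_branching_depth` 2 (16 tips) and a hard voxelization-clearance
check on non-adjacent branches.  These choices make every terminal branch
well resolved by the mask — tips ~6 voxels across, siblings separating
well before their caps — which is the regime in which exact generation and
tip counts are a meaningful claim about the extractor rather than about
mask resolution.  On the coarser deposition presets, sibling terminal
branches fuse over much of their length and no skeleton method can recover
them separately; extraction still returns a usable (under-counted) tree,
and this limitation is inherent to the mask, not the graph analysis.

## What the phantom validation shows — and what it does not

Passing tests demonstrate that the quantification is self-consistent and
recovers known ground truth under the generator's assumptions: Gaussian
blob rendering, a monopodial capsule tree, piecewise-constant AF with
stationary noise, and exactly co-registered masks.  Real LSFM lungs add
effects the phantom does not model: depth- and wavelength-dependent
attenuation, stripe artifacts, imperfect clearing, segmentation errors in
the airway mask, alveolar micro-architecture, and partial-volume mixing at
the airway wall.  Recovery errors measured here (~0.005 on the bronchial
fraction) are therefore a floor, not an estimate of accuracy on real data.
The route presets reproduce the *qualitative* ordering of deposition
metrics across delivery techniques; their magnitudes are design centers,
not measurements.

## Numerical and edge-case choices

* Thresholding is strict `>` so a threshold equal to the background
  plateau excludes it (`>=` available by flag).
* Masks are stored as uint8 {0,1}; nonzero values are coerced to 1 with a
  warning (0/255 dialects).  Mismatched shapes or spacings between
  co-registered volumes are an error, never silently resampled.
* Axis order is (z, y, x) everywhere; spacing is µm and travels with every
  volume.
* `dose_fractions` raises on zero total signal and on a zero acinar signal
  (B/A undefined); `profile_lung` raises a dedicated `NoSignalError` when
  nothing is above threshold inside the lung; C/P raises when the
  peripheral sum is zero.
* Phantom geometry that fails its internal checks (tip separation, acinar
  collapse, clearance when enforced) is regrown from a jittered sub-seed
  up to 8 times before erroring.
* All randomness flows through `numpy` `SeedSequence` children of a single
  user-visible seed; every CLI run records its resolved seed, config and
  input digests in a manifest.
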