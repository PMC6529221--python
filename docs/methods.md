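# Methods

This note documents the models, conventions and numerical choices behind
`lhoverlap`, and what the synthetic-data generators do and do not emulate.

## Coordinate and grid conventions

Volumes are 3D arrays indexed `[x, y, z]` with 0-based voxel indices; world
position (µm) = `origin + index · spacing`. The default grid is 64 × 64 × 32
voxels at 0.56 × 0.56 × 1.0 µm — the 20× template voxel size on a spatially
scaled-down field of view, chosen so that full pipelines run in seconds
while keeping the anisotropy of real stacks. All masks being compared must
share shape, spacing (to 1e-6 relative) and template identifier
(`space_id`); no registration or bridging between template spaces is
performed — inputs are assumed pre-registered. Overlap denominators use
voxel counts, not physical volume: on a shared grid the two differ only by
a constant factor, so percentages are identical.

NRRD (raw or gzip, Fortran index order, spacing in `space directions`) is
the canonical on-disk format because it carries spacing natively; mask
annotations travel in NRRD key-value fields mirrored in a JSON sidecar.
Multi-page TIFF is supported with ImageJ spacing metadata; a TIFF without
spacing metadata requires spacing from the caller or config — it is never
guessed.

## Mask pipeline

Stages run in the order overlay → contrast enhancement → Gaussian blur →
Otsu threshold.

* **Overlay** is voxelwise max by default (robust to replicate-count
  differences); sum is available.
* **Contrast enhancement** is a percentile clip at the
  `saturation_fraction/2` lower/upper quantiles followed by a linear
  rescale to [0, 1]. The saturation fraction is not pinned down by the
  interactive tool the recipe originated in; the default 0.0035 is that
  tool's common interactive default, and the value used is recorded in
  every mask's provenance JSON. A constant image cannot be rescaled and
  returns all-zeros with a warning.
* **Blur** σ is in voxel units, isotropic in index space (σ = 1 matches a
  pixel-sigma convention); `gaussian_smooth_um` gives a µm-specified,
  anisotropic-in-voxels alternative.
* **Otsu** runs on 256 bins of the rescaled image; the mask is the strict
  upper class (`data > threshold`); ties in the between-class variance
  resolve to the lower threshold. Constant images raise rather than
  silently emitting an empty mask. Note that when the histogram has an
  empty gap between modes, every split inside the gap is an exact
  mathematical tie; the chosen threshold within such a gap is arbitrary to
  float rounding and (data permitting) leaves the mask unchanged.

The pipeline is deterministic and preserves grid and spacing at every
stage. One caveat on the "no-degradation" intuition for clean input: the
blur can pull isolated high-curvature corner voxels of a digitised tube
just below the threshold, so the mask tracks the ground truth as a sandwich
(interior preserved, excursions bounded by the blur support, coverage
> 99%) rather than as a strict superset.

## Overlap analysis

P1 = 100·|A∩B|/|A| requires |A| > 0; empty masks are an error, never a
silent zero. The mean combine rule is symmetric; max/min are carried on
every result. In self-vs-self matrices the numeric diagonal keeps its true
value (100); the −1 display sentinel exists only at render time.
Interaction classification uses strict `> 15` (in percent); row summary
fractions exclude the diagonal when rows and columns are the same family.
Clustering operates on the raw score rows/columns (no standardisation) with
Euclidean distance and complete linkage; exact leaf order is a rendering
choice of the heatmap package and treated as non-normative — merge heights
and cluster co-membership are the tested contract. The axon–dendrite
relationship is OLS of vectorised off-diagonal axonal scores on dendritic
scores; a constant predictor yields R² = 0 with a warning flag.

Which compartment enters which comparison (axon vs dendrite vs membrane for
local neurons) is configuration, not hard-coded, since it varies by
analysis.

## Modality maps

The voxelwise mean of one exemplar mask per cell type, restricted to a
region mask. Exemplar choice is an explicit list, never implicit. The
ventral/dorsal occupancy statistic — mass fraction of the map in each half
of a region split by a plane through the region centroid along a named
axis — is this package's own quantification of "restricted ventral zone"
and should not be quoted as a literature value.

## Quadrant assay

Sectors: Q1 = [0°, 90°), …, Q4 = [270°, 360°); Q2+Q3 (left half-disk) and
Q1+Q4 (right) are the two illuminable pairs. Boundary rays tie-break to the
lower-indexed adjacent quadrant; the centre point is Q1 by convention.
PI is computed per frame (optional time binning is available; the original
analyses do not state a binning, and per-frame is the least processed
choice). During ON epochs the labels are normalised so the illuminated pair
maps to Q2/Q3 (positive PI = attraction) — both epochs then contribute with
consistent sign even though the assay alternates the lit pair; the raw
fixed-label series is available with `normalize_on=False`. Frames with no
tracked flies yield NaN flagged by `n_flies = 0`.

Delta metrics: pre-window is the 5 s immediately before onset; stim window
the first 5 s of the (by default first) ON epoch; delta = (stim − pre)/pre.
The normalising denominator is the pre-stimulation mean — the source recipe
says only "normalised to the mean metric", so this choice is flagged in the
output schema. Flies leaving the lit pair during the stim window are
excluded with a machine-readable reason, as are flies with zero
pre-stimulation metric (delta undefined). Turning uses headings from
centroid displacement; displacements under 0.5 px contribute zero turning
to avoid angle-noise blow-up. Missing frames are linearly interpolated up
to 3 consecutive frames, beyond which the fly is dropped from gated
windows. Locomotion is reported in tracker pixels/s with 1 px ≈ 0.12 mm.
Flybowl analysis takes the strongest (third) 5 s whole-field window by
default and keeps per-fly values — each fly is one experimental unit.

## Tethered flight

Yaw = L − R, thrust = L + R wingbeat amplitude. Per trial the mean of the
100 ms before LED onset is subtracted; for |yaw| the absolute value is
taken *after* that subtraction (the plotting convention for turning
magnitude). Stim and no-stim trials are averaged separately within fly
(across the six blocks), responses are stim − no-stim per fly, and group
traces average flies with equal weight — whether the original averaging
pooled trials or flies is not stated, and equal per-fly weight is the
choice least sensitive to unequal trial exclusion. Trials whose wingbeat
frequency drops below a configurable floor are excluded whole (flight
stop). Per-timepoint comparisons use the two-sided Wilcoxon rank-sum test,
uncorrected at p < 0.05, exact null for groups of ≤ 10 flies, normal
approximation with continuity correction above; a decimation flag trades
time resolution for runtime.

## Screening statistics

Levene check defaults to the Brown–Forsythe (median-centred) variant with
mean-centring as an option, since the original R call's centring is
unstated; two all-constant groups return statistic 0 by convention rather
than 0/0. Dunn's z uses pooled mid-ranks with the tie correction
Σ(t³−t)/(12(N−1)); p-values are two-sided (the screen detects attraction
and aversion alike). The screen's dual criterion — FDR controlled at 10%,
significance declared at BH-adjusted p < 0.05 — is implemented as one BH
adjustment with both thresholds as parameters, reported side by side.

## Synthetic data: what it emulates, and what it does not

* **Arbor stacks**: a random branched walk voxelised as a tube (default
  radius 2 µm, at least two voxels thick along every axis so the σ = 1 blur
  cannot erode it below threshold), painted at two intensity levels with
  additive Gaussian noise. Replicate-to-replicate variation is a rigid
  Gaussian translation (default SD one in-plane voxel, a free choice — the
  residual registration error of real data is not characterised) — no
  non-rigid deformation, no PSF, no channel bleed-through, no
  intensity-dependent noise. Passing recovery tests therefore demonstrates
  correctness of the pipeline's arithmetic and robustness to additive noise
  and small rigid misregistration, not to optical artefacts.
* **Overlap stack pairs**: two equal boxes sharing a designed slab, so the
  ground-truth directional overlap is exact by construction (box length 30
  voxels makes the shifts for fractions 0.1/0.3/0.5/0.8 integral).
  Replicates differ by noise only; jitter would displace the designed
  intersection.
* **Arena trajectories**: fly membership of the illuminated half-disk
  follows an explicit two-state Markov chain (enter rate a, leave rate b →
  stationary lit-occupancy a/(a+b)), with reflecting random-walk steps
  inside the current half-disk. This is the minimal model whose occupancy
  is analytically checkable; it does not emulate wall-following, social
  interactions, airflow or odour responses. Default trial structure: 30 s
  dark / 30 s one lit pair / 30 s dark / 30 s the other pair at 30 Hz,
  20 flies, 10 cm arena. Flybowl: 30 s acclimatisation plus three 5 s
  whole-field epochs (3.59 / 11.88 / 25.2 µW/mm²); speed scales linearly
  with intensity through a gain parameter.
* **Flight sessions**: 6 blocks per fly of randomly interleaved
  (3 visual × 2 stim) 10 s trials at 1 kHz, onset 5 s, 500 ms stim. Designed
  effects are embedded antisymmetrically for yaw (±e/2 on the two wings),
  symmetrically for thrust, directly for frequency; the step holds during
  stimulation and decays exponentially afterwards (default τ = 1 s). Noise
  is white Gaussian per sample (default SD 0.08 amplitude units, 10× that
  for frequency) plus per-fly baseline offsets that the baseline
  subtraction removes; real wingbeat data has temporally correlated,
  state-dependent variability that this does not reproduce.

Every generator is a pure function of its design dataclass; a single
session seed spawns independent per-object substreams, and generated
objects carry their generating parameters so recovery tests never re-derive
ground truth from file names.

## Problem sizes in the test and acceptance runs

Pipelines run on 64 × 64 × 32 grids; overlap-recovery checks use 20 seeds
per designed fraction; the oracle-equivalence checks use 50 mask pairs and
100 images; the global-null screen simulation uses 30 screens of 50 lines
(n = 10 each); flight checks use 6 flies per group at the full 1 kHz
resolution. These sizes were chosen so the complete suite verifies every
contract in well under a minute per module while keeping Monte-Carlo
standard errors small enough for 3-SE bounds to be meaningful.

## Known limitations

* No video tracking, wingbeat signal processing, image registration,
  manual segmentation or skeletonisation: inputs begin at registered
  volumes, tracked coordinates and extracted wingbeat parameters.
* Overlap is proximity, not connectivity; nothing here validates synapses.
* The published summary fractions for real mask datasets depend on that
  data and are not reproduced by synthetic runs.
* "Movement upwind" is not among the delta metrics: the per-quadrant wind
  direction in the arena arms is not defined anywhere the package could
  draw on, and a metric against an unknown reference would be
  uninterpretable. Forward locomotion, turning and distance-from-centre
  cover the stated deltas.
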