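# Methods

## Scope and data model

`breastphantom` turns a breast MRI volume into a numerical phantom: an
integer label grid (background / skin / fat / K fibroglandular clusters /
optional tumour), a single-pole Debye parameter set per cluster, and
descriptive attributes (health, density class, density %, cluster count,
voxel size). Volumes are indexed `(row, column, slice)`, 0-based, with
the slice axis the axial stack; all modules share this convention.
Intensities are kept as stored (rescale slope/intercept applied when the
DICOM metadata carries them) because the property mapping uses relative,
not absolute, intensities.

## Synthetic acquisition generator

The generator emulates the statistical structure of a fat-suppressed 3 T
breast scan, not its MR physics (no Bloch simulation, no coil
sensitivity). Defaults reproduce the emulated protocol geometry: a
256 × 256 matrix, 240 slices, 0.9375 × 0.9375 × 1.1 mm voxels. Anatomy is
a half-ellipsoid resting on the chest-wall face of the grid (default
semi-axes 90 × 80 × 90 mm, a breast of ≈ 1.4 L on a full field of view);
skin is a geometric shell (default 1.5 mm, defined by spacing-aware
Euclidean distance to the exterior) so the ground truth is unambiguous.
Fibroglandular structures are a thresholded correlated noise field
(white noise smoothed at a 6 mm texture scale), which produces connected,
heterogeneous, slice-spanning structures. The threshold is the quantile
of the field over the interior that delivers the target fibroglandular
fraction — the same fixed point a bisection would find, reached exactly
in one step — and the achieved fraction must land within ±0.02 of the
target or the call fails as infeasible. Because a lower threshold can
only add voxels, the achieved fraction is monotone in the target at a
fixed seed.

Class intensities are Gaussian: fat 60 ± 8, fibroglandular 200 ± 20, skin
120 ± 10, background |N(0, 5)| (arbitrary scanner units; the published
protocol gives no intensity statistics, so only the fat-suppressed
ordering — fibroglandular brightest — is enforced). Optional Gibbs
ringing truncates each slice's 2D spectrum to the central fraction of
frequencies per axis and takes the inverse-transform magnitude. All
randomness flows from one integer seed; identical parameters give
bit-identical volumes.

What the generator does *not* emulate — bias fields, partial-volume
blur at tissue interfaces, motion, vasculature, pectoral muscle —
means that passing the density-recovery checks shows the pipeline's
stages compose correctly and recover a known truth under realistic
contrast and noise, not that segmentation accuracy on patient scans
equals the synthetic figures.

## Pipeline stages and numerical choices

**Denoising.** PCA treats slices as observations and in-plane pixels as
variables (the unfolding that expresses inter-slice structure); the
volume is centred, decomposed by SVD, and reconstructed from the leading
components covering a variance fraction (default 0.99) or an explicit
count. Negative reconstructed intensities are clamped to zero. A
variance fraction of exactly 1 short-circuits to the identity.

**Masking.** The background threshold is mean + k·SD (default k = 3) of
the corner-margin voxels (margin width 5 % per dimension) — where the
background is sampled is an open design choice, and the grid corners are
the location least likely to contain breast. A diagnostic warning fires when
more than 20 % of all voxels fall below threshold + SD; on a field of
view that is mostly air this is routine and informational, but on a
volume whose corners contain object it flags the known failure mode
(threshold above object intensities). Surface detection fills each ray
between the first and last run of at least r = 3 consecutive
above-threshold voxels (r rejects isolated noise); the mask is the
intersection of the three directional fills, cleaned to the largest
connected component (two components for bilateral scans). Reading the
stage-one description as a per-ray fill (rather than explicit surface
meshes intersected afterwards) is this package's interpretation.

**Segmentation.** Skin is geometric (distance-to-exterior shell,
configurable thickness) rather than intensity-derived, because skin
intensity overlaps other tissues. Fat/fibroglandular separation and
fibroglandular sub-clustering are 1-D k-means on intensity, run on the
unique intensity values weighted by multiplicity (exact for scalar data
and independent of voxel count), k-means++ seeded with 10 restarts under
a fixed seed. Cluster labels are renumbered by ascending mean intensity;
fat is always a single cluster. A single-valued interior degenerates to
all-fat with a warning; requesting more clusters than distinct
intensities is an error.

**Dielectrics.** The Debye convention is ε* = ε′ − jε″ with ε″ ≥ 0.
Cluster curves are combined in parameter space — each of ε∞, Δε, τ, σs
mixed convexly by the intensity weight — because a pointwise-in-frequency
mixture of two Debye curves is not in general single-pole, while the
parameter mixture is, matching the one-Debye-set-per-cluster property
files. Contrast levels scale ε∞, Δε and σs (τ untouched), which scales
the whole complex curve uniformly: exactly 0.85 (med) and 0.75 (low) of
the high curve at every frequency, σs included. Scaling the conductivity
with the curve is the literal reading of scaling the property curve; a
configuration that exempts σs would be a one-line change in
`apply_property_level`. The shipped reference table carries
representative literature-style Debye values for skin, fat, the
fibroglandular lower/upper bounds and tumour, marked as editable
defaults; every quantitative check in the test suite uses ratios,
limits or orderings, never these absolute numbers.

**Classification.** Density = 100 × FGT / (fat + FGT). Skin is excluded
from the denominator by default (configurable), since the density of
interest is that of the soft interior tissue the segmentation separates.
Class boundaries sit exactly at 25/50/75 % with boundary values going to
the upper class ("less than 25 %" read strictly).

**Tumour.** The default inclusion is a 10 mm sphere voxelized by
centre-inclusion on its own grid, resampled to the host grid if spacings
differ. Embedding overwrites fat/fibroglandular voxels only — skin is
never replaced, for anatomical plausibility — requires the centre inside
the breast, and rejects placements where more than 10 % of the tumour
would land on skin or background (including the part clipped by the
grid).

**Export.** RAW files are one unsigned byte per voxel, row index fastest,
with a mandatory JSON sidecar (dimensions, spacing, axis order, legend)
making them self-describing. The HDF5 layout stores one occupancy
dataset per element under `modelData`, the four Debye parameters per
element under `modelProps`, and breastHealth/breastClass/density/
modelName/nClusters/voxelSize as root attributes. XML property files
have a `modelProps` root and four Debye child tags per tissue node,
serialized at 17 significant digits (lossless for doubles). STL meshes
are binary, in millimetres, the 0.5-level marching-cubes isosurface of
the zero-padded cluster mask with outward normals. The NPZ container is
the neutral single-file voxel representation (label grid, spacing,
legend, properties, attributes). RAW, XML and STL writes are
byte-reproducible; HDF5 and NPZ are verified as lossless roundtrips.

## Problem sizes in tests

The unit and property tests use coarse phantoms (48 × 48 × 32 at
2 × 2 × 2.5 mm) and a small native-resolution phantom (128 × 128 × 96 at
0.9375 × 0.9375 × 1.1 mm, ≈ 50 mm semi-axes); the acquisition-geometry
check generates the full default 256 × 256 × 240 series once and reads it
back through the DICOM reader. The density-recovery check runs the whole
pipeline on native-resolution phantoms at target fractions 0.10, 0.30,
0.60 and 0.85 and requires agreement within ±3 percentage points —
the desk-scale analogue of validating computed density against the
radiologist-reported class. Tumour-volume checks voxelize at 0.25 mm,
where the sphere volume is within 3 % of πd³/6.

## Known limitations

- No chest-wall/pectoral delineation, vasculature or nipple modelling;
  the mask is the thresholded breast surface only.
- Intensity-only clustering: no spatial regularization (a
  `cluster_features` hook is reserved for intensity+space features).
- Single-pole Debye only; no Cole–Cole or multi-pole dispersion, no
  temperature dependence.
- The resampler (`resample_volume`) is provided but the default pipeline
  applies none: the published models use a finer grid than the scans and
  the producing resampling rule is unstated, so regridding is left to
  the user.
- Multi-frame/enhanced DICOM and vendor-specific reconstruction are out
  of scope; the reader consumes plain single-frame slice series.
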