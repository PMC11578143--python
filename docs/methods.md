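# Methods

This note documents the models and procedures implemented in `choroid3d`,
the parameters that matter, the numerical choices, and what the synthetic
validation does and does not establish.

## Geometry and coordinates

A volume is `(n_bscans, n_ascans, n_depth)` with spacing `(dy, dx, dz)` in
µm/voxel; axis 0 is the slow scan direction (superior–inferior en face),
axis 1 the fast direction, axis 2 depth. The nominal wide-field geometry is a
12 × 12 mm field sampled 1024 × 1024 with a 6 mm depth range over 1536 voxels
(dy = dx ≈ 11.72 µm, dz ≈ 3.906 µm). dz is a sampling pitch, not the optical
axial resolution (a PSF figure), and is what converts voxel heights to µm.
8-bit exports carry no physical metadata, so spacing must always come from
the caller or a sidecar file.

The choroid slab is the half-open interval `[z_i, z_o)` between the inner
(RPE–choriocapillaris) and outer (chorioscleral) surfaces. Half-openness
makes per-column thickness in voxels exactly `z_o − z_i` and makes the slab
voxel count an exact integer identity — the denominator of CVI and the mask
inverse of the surface extraction both rely on it.

## Boundary handling

Boundaries arrive as height-map CSVs/TIFFs or as a slab mask volume
(surfaces = first/one-past-last true voxel per column); a classical fallback
segmenter is included only so the pipeline runs end to end without an
external model: per A-scan it takes the brightest axial band as the RPE
complex, the strongest negative gradient just below it as the inner boundary,
and the strongest negative gradient in a window around a prior thickness
(default 300 µm) as the outer boundary. Columns without a detectable band are
marked invalid and excluded from every later denominator — never filled.

Volumetric smoothing is a per-surface 2D moving median (default window 5
columns, edge-truncated, invalid columns excluded). The median was chosen
over the mean because segmentation errors present as isolated spikes; a
median removes them without displacing smooth anatomy. Being a monotone
operator applied identically to both surfaces, it cannot create crossings
from a valid input; the invariant is still re-checked and clamped with a
logged count.

Manual correction is file-based: export the height maps, edit, re-load.

## Luminal binarization

Vessel lumens are hyporeflective, so within the slab a pixel is luminal when
its normalized intensity (raw/255) falls below the local threshold

    t = m · (1 + p·exp(−q·m) + k·(s/r − 1))

with `m`, `s` the mean and standard deviation of in-ROI pixels of the window
and defaults window = 16 px, k = 0.25, p = 2, q = 10, r = 0.5 (the standard
constants of the method; none are printed in the clinical workflow this
mirrors, so all are exposed in the config). The exponential term raises the
threshold in dark regions, which is what distinguishes this rule from
Niblack/Sauvola at low local contrast. Two window policies: `tiled` (one
threshold per 16 × 16 tile of the B-scan, the default) and `sliding`
(per-pixel centered window, oracle-testable). Note the two policies agree
exactly only where a sliding window coincides with a tile (tile centers, or
globally uniform images); near tile borders tiling produces block seams,
which is why `sliding` exists.

Window statistics are restricted to slab (ROI) pixels so the bright retina
above the inner boundary cannot bias thresholds; windows with no ROI pixel
classify nothing. Sliding-mode statistics are computed from integer integral
images of the raw 8-bit values, so the sums are exact and the per-pixel
result matches a direct recomputation bit for bit.

A per-B-scan 3 × 3 median despeckle (`prefilter_median`, 1 disables) runs
before thresholding. Rationale: uncorrelated multiplicative speckle at
σ = 0.2 drives ~18% of stromal pixels below the local threshold — above the
3D percolation threshold for 26-connectivity, so the noise would merge with
vessels and corrupt centerline-based diameters. The median filter reduces the
stromal false-positive rate to ~0.4% (isolated voxels, removed by the size
filter) while preserving vessel edges; on noiseless data it changes at most a
thin rim of boundary voxels. The filter is applied to ROI-masked data, so
intensities outside the slab can never influence the result.

Cleanup order is fixed and logged: 3D closing (ball radius 1) → removal of
26-connected components smaller than the voxel count of a 100 µm × 100 µm
cylinder at the current spacing (anything smaller cannot be a measurable
Haller vessel) → optic-disc masking (disc columns are also excluded from all
sector denominators). 26-connectivity is used throughout because vessels run
obliquely through anisotropic voxels.

## Sector grid

The fovea-centered grid has a central circle of 4 mm diameter (membership is
`physical distance ≤ 2000 µm`, boundary inclusive) and four quadrants split
by the 45° diagonals — the ophthalmic convention; the quadrant borders are
not otherwise standardized for this grid, and diagonals keep the sectors
rotationally comparable. Distances are physical, so anisotropic en-face
sampling is handled. Columns exactly on a diagonal are assigned
deterministically to the counter-clockwise sector of the boundary ray
(NE → superior, NW → left, SW → inferior, SE → right); each sector gains
exactly one ray, so quadrant areas stay balanced and the rule is
rotation-equivariant (property-tested).

Orientation is declared, never guessed from image content: row 0 is superior
by default (`superior_side`), and the nasal side follows laterality under the
conventional fundus view (OD → nasal on the right of the image, OS → left),
overridable with `nasal_side`. The fovea coordinate is primarily a manual
input; the automatic locator (darkest region of a smoothed, centrally
weighted en-face) is plumbing for unattended runs and carries a confidence
flag.

## Vessel metrology

Connected components of the luminal mask are the unit of measurement; a
component is assigned to the sector containing the largest share of its
en-face footprint.

The centerline of a component is computed from the anisotropic Euclidean
distance transform (EDT, in µm): two geodesic sweeps find the component's
farthest voxel pair, then the minimal-cost path between them with per-voxel
cost `(max EDT − EDT + ε)` follows the EDT ridge — a medial-axis substitute
that is robust for tubular shapes of any voxel parity. (A thinning-based
skeleton was rejected: the installed 3D thinning implementation returns empty
skeletons for even-width objects.)

Measurement sites sit at the 25/50/75% positions of the centerline arc
length; fixed quantiles make the grader protocol deterministic and spread the
sites along the vessel. A site diameter is `2 × EDT` at the site voxel — the
full lumen width through the centerline, with no sub-voxel fitting, so the
expected discretization error is about one voxel diagonal. A vessel's
representative diameter is the mean of its three sites.

Selection per sector: vessels with representative diameter strictly greater
than 100 µm (the Haller floor), ordered by diameter, ties broken by voxel
count then id; the top three are measured. "Largest" means largest diameter,
not largest voxel count, because diameter is the measured and filtered
quantity. Fewer than three qualifiers are measured as-is and flagged
`insufficient_vessels`.

IVD is edge-to-edge: for each site, the minimum distance (µm) from the
vessel's surface near the site (surface voxels within one site radius of the
local centerline stretch) to the surface of the nearest *other component* in
the sector. "Non-collateral vessel" is operationalized as "different
26-connected component" — component identity is the only vessel identity
available after binarization; branch-level reasoning is out of scope and this
choice is deliberately prominent. A sector with a single vessel reports IVD
as missing with a `no_neighbor` flag, never as zero. Because surfaces are
voxel centers, measured gaps carry an expected positive bias of up to about
one voxel.

The mean-of-nine convention applies to both MChVD and IVD (three sites ×
three vessels). An alternative reading — nine repeats on the largest vessel
only — exists for IVD; three-sites-by-three-vessels was chosen for symmetry
with the diameter protocol.

## Metrics and reliability

CVI per sector is the exact voxel-count ratio over non-excluded columns; the
`average` row is the whole-field ratio (equivalently, the voxel-count-weighted
mean of sector CVIs), not the unweighted mean of the five sectors — users
comparing against per-sector means should note the difference. ChT averages
the per-column thickness the same way. Missing sites are excluded from means,
never imputed as zero. Empty denominators yield NaN plus a flag.

The ICC is the single-measurement, absolute-agreement, two-way random-effects
coefficient from the standard mean-squares decomposition,

    ICC = (MSR − MSE) / (MSR + (k−1)·MSE + k·(MSC − MSE)/n),

with the McGraw–Wong F-based 95% interval, banded at <0.5 poor, 0.5–0.75
moderate, 0.75–0.9 good, ≥0.9 excellent. Zero total variance leaves it
undefined. The implementation is cross-checked in the tests against both a
hand-coded ANOVA oracle and an independent library implementation.

## Phantom generator

The phantom emulates what the pipeline consumes: a slab of configurable
thickness (defaults: inner depth 100 µm, thickness in the 150–520 µm range
used per test) painted stroma 170, with embedded cylindrical lumens painted
40, a 3-voxel RPE band (250) above, sclera (40) below, vitreous 20; optional
multiplicative speckle `I' = clip(I·max(0, 1+σ·ε))` (unit mean, seeded) and
optional shadowed A-scans. Lumen 40 was chosen so a homogeneous lumen
interior stays below its own local threshold: with s = 0 the rule classifies
a uniform region luminal iff `p·e^(−q·m) > k`, i.e. normalized intensity
below ln(p/k)/q = ln(8)/10 ≈ 0.208 (intensity ≈ 53). Contrast is a free
parameter of the generator, not a claim about any particular device's export.

Vessels are capsules (point-to-polyline distance ≤ D/2), so ground-truth
diameters, nearest-neighbor edge gaps (exact segment–segment distances minus
radii) and the luminal fraction are known exactly; a vessel whose rasterized
tube leaves the slab is rejected at validation time rather than clipped, so
the recorded diameters stay exact. Generation is a pure function of
(spec, seed).

Default test geometry is a 256 × 256 × 192 grid at (12, 12, 4) µm — the
aspect of a wide-field scan at reduced sampling, chosen so the full
validation battery runs in seconds while keeping ≥8 voxels across the
smallest (100 µm) vessel in depth.

What the phantom does *not* emulate: retinal layers above the RPE band,
motion/blink artifacts, spatially correlated speckle, curved or branching
vasculature, intensity inhomogeneity across the field. Passing recovery
tests therefore demonstrates correctness of the measurement machinery under
controlled conditions, not clinical segmentation accuracy on device data —
boundary segmentation quality on real scans is supplied by the upstream
model, which is a pluggable input here.

## Numerical choices and degenerate inputs

- Thresholding uses exact integer box sums; the EDT and all distances use
  physical µm with anisotropic sampling; never voxel units.
- Components whose centerline has fewer than 3 voxels collapse their sites to
  the available voxels and carry a `short_skeleton` flag; single-voxel
  components take their radius directly from the EDT.
- All tie-breaks (selection order, diagonal columns, path endpoints) are
  fixed, so identical inputs reproduce identical tables; pipeline reruns with
  the same config and seed are byte-identical.
- The expected discretization tolerance quoted throughout is one voxel
  diagonal (≈17.4 µm at test spacing); diameter estimates carry a small
  negative bias (centerline voxels sit up to half a voxel off-axis) and IVD a
  small positive bias, both within that tolerance on the validation phantoms.

## Known limitations

- No branch-point analysis: touching vessels merge into one component, which
  perturbs both selection and IVD ("non-collateral" = separate component).
- The >100 µm floor uses the estimated diameter; vessels designed within a
  voxel of 100 µm may fall on either side of it.
- No axial-length or angular-unit correction; all outputs are in device µm.
- Group-level clinical statistics (mixed models, normality tests) are out of
  scope; the metrics table is analysis-ready for external stats software.
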