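# Methods

`cytoseg` implements a template-free route from ultra-high-resolution
diffusion-weighted MR volumes of a fixed brain to a 3D segmentation of
cortical cytoarchitectonic domains, together with a synthetic phantom
framework that makes every stage testable against known ground truth.
This note records the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## The cortical reference frame

The cortex is treated as a curved ribbon bounded by the GM/WM interface
and the pial surface.  Every gray-matter voxel is assigned a normalized
depth and a radial unit vector (pointing from white matter toward the
pial surface); the plane orthogonal to the radial vector approximates the
local tangent plane of the cortical laminae.

Two depth parameterizations are provided.

**Equidistant.**  `depth = d_wm / (d_wm + d_pial)` from voxel-size-aware
Euclidean distance transforms to the WM core and to the background, each
reduced by half a voxel pitch so that zero falls near the tissue
interface rather than on the first voxel center.

**Equivolumetric (default).**  Anatomical layers conserve their *volume*
fraction, not their thickness fraction, as the ribbon bends, so on curved
cortex equidistant depth misplaces laminar boundaries.  The equivolume
depth of a voxel is defined as the fraction of its local column's volume
that lies between the WM surface and the voxel.  Columns are traced per
voxel by integrating the radial direction field in both directions with a
fixed step of 0.25 voxel.  Along a column, the relative cross-sectional
area A evolves by the frustum relation `d ln A / ds = div(n)`, where `n`
is the unit radial field — the divergence of a unit normal field equals
the sum of the principal curvatures of its level surfaces — and the depth
is the ratio of the area-weighted arclength integrals below and above the
voxel.  For a spherical shell with radii `a < b` this construction is
exact and reproduces `depth(r) = (r^3 - a^3)/(b^3 - a^3)`; on a flat slab
`div(n) = 0` and it degenerates to the equidistant ratio.  Both limits
are enforced by tests.

Three numerical details matter at 1-voxel scale:

* the direction and divergence fields are computed from the smoothed
  signed mid-surface field `(S_wm - S_out)/2`, where `S_x` is the
  difference of distance transforms to region x and its complement
  (a signed distance), because this field has no plateaus on either side
  of either boundary;
* column endpoints are located where the Gaussian-smoothed (sigma = 1.5
  voxels) signed distance fields cross a curvature-corrected level
  `±sigma^2 div/2` — smoothing a signed distance shifts its zero level by
  `-sigma^2 H` at a surface with mean-curvature sum `H`, and the
  correction cancels that bias to O(sigma^2).  Plain interpolated-mask
  stopping criteria pin to lattice values for boundary-adjacent voxels
  and systematically inflate short column segments;
* the final partial integration step is interpolated inside the crossing
  interval.

Voxels whose trace stalls (vanishing direction field) are excluded from
the defined mask and counted in the log.  Layer labels bin depth into
half-open intervals `[(k-1)/n, k/n)` with depth 1.0 assigned to layer n.

A practical voxelization limit, established with an exact-depth oracle:
binning a discrete spherical shell into six equivolume layers has
intrinsic count lumpiness that can exceed 5% on thin shells (e.g. an
8..12-voxel shell reaches 12% with *perfect* depth).  Geometry tests
therefore use shells thick enough (21.5..30.5 voxels) that the oracle's
own lumpiness is ~1.5%, leaving the tolerance to measure algorithmic
error.

The radial field is the normalized, voxel-size-aware gradient of the
depth volume; outside GM the depth volume carries the smooth extended
equidistant field (0 in WM, 1 in background) so finite differences behave
at the ribbon borders.

## Surface-oriented anisotropic denoising

Each diffusion-weighted volume is denoised independently by a spatially
varying Gaussian kernel oriented by the local radial direction r:

    w(x) ∝ exp(-1/2 [ (x·r)^2 / sr^2 + (|x|^2 - (x·r)^2) / st^2 ])

with sr = 0.1 mm radial and st = 1.0 mm tangential by default, evaluated
at voxel-center offsets over a 5×5×5 support and normalized to unit sum.
The kernel is rotationally symmetric about r, so no tangent basis is
required.  On a 0.2 mm grid the tangential footprint is 5 × 0.2 = 1.0 mm,
the maximum in-plane blurring.  Kernels are renormalized over in-grid
voxels at image borders; voxels without a defined frame pass through
unchanged.  By default neighbors outside the cortical mask contribute
(the weighted sum is over the full support); `mask_restrict` zeroes
extra-cortical weights and renormalizes, for users who prefer a
cortex-confined average.  Evaluating the continuous Gaussian at voxel
centers (rather than integrating over voxel volumes) keeps the filter
exactly conservative after normalization.

Two filter facts are verified quantitatively: filtered iid noise variance
drops by the kernel's sum of squared weights, and a depth-layered signal
is preserved (< 2% per-layer change) while a filter with the two sigmas
swapped destroys it (> 20%), which discriminates the radial/tangential
roles.

## Scalar microstructural maps

The diffusion tensor is fitted per voxel by log-linear least squares with
one reweighting pass (weights equal to squared predicted signals), which
is exact on noise-free monoexponential data; eigenvalues are clamped to
at least 1e-7 mm^2/s.  From the eigenvalues lam1 >= lam2 >= lam3:

* FA, MD = mean(lam), AD = lam1, RD = (lam2+lam3)/2;
* zero-displacement probabilities in the Gaussian propagator limit at
  diffusion time tau = Delta - delta/3 (0.026 s for the default 6/28 ms
  pulse timings):
  RTPP = (4 pi tau lam1)^(-1/2), RTAP = (4 pi tau)^(-1) (lam2 lam3)^(-1/2),
  RTOP = RTAP·RTPP;
* propagator anisotropy PA = sqrt(1 - cos^2 theta) with
  cos theta = 2^(3/2) (|D||D_iso|)^(1/4) / |D + D_iso|^(1/2),
  D_iso = MD·I — the normalized overlap of the voxel's Gaussian
  propagator with its closest isotropic counterpart (the diffusion time
  cancels).  The closed form is validated in tests against direct grid
  integration of the Gaussian overlap integral.  No sigmoidal rescaling
  is applied to PA: any monotone rescaling is absorbed by the z-scoring
  used for clustering.

The full polynomial-basis propagator expansion is intentionally not
fitted.  Non-Gaussianity (NG) is identically zero for a Gaussian
propagator, so NG always enters the pipeline as a supplied map (from an
external propagator fit on real data, or simulated directly by the
phantom).  This keeps every quantity computed here analytically
verifiable while preserving the downstream contracts (feature vectors,
clustering, matching).

## Voxelwise clustering

Cortical voxels of one hemisphere are clustered on their scalar feature
vectors only — by construction the model never sees voxel coordinates,
so the segmentation is spatially agnostic.  Default features are PA, NG,
RTAP, RTPP, z-scored per hemisphere (each hemisphere is clustered
independently, so its own standardization is the natural normalization).
The model is a full-covariance Gaussian mixture fitted by EM: k-means++
initialization, 5 restarts keeping the best likelihood, covariance ridge
1e-6, convergence when the per-sample mean log-likelihood improves by
less than 1e-7, at most 500 iterations.  The component count defaults to
14 and can be selected by BIC (= -2 log L + p ln n with
p = (k-1) + k d + k d(d+1)/2) over a default search range 8..20 that
brackets the default.

Two canonicalizations make the fit exactly reproducible.  First, EM runs
on a lexicographically sorted copy of the rows and labels are then
predicted per input row: EM is mathematically order-independent, but
seeded initialization and floating-point summation are not, and at
~5·10^4 voxels a permuted input can otherwise land on a microscopically
different optimum.  Likelihood and BIC are evaluated on the sorted array,
so every reported quantity is exactly invariant under voxel-order
permutation.  Second, components are reordered lexicographically by mean
vector and labels renumbered 1..k, so label ids are a function of the
fitted mixture rather than of the initialization path.

## Morphological refinement

The mixture assigns one label to every voxel with a similar signature
regardless of position, so a cluster typically covers many disjoint
anatomical domains.  Refinement (per hemisphere):

1. **Split** — every 26-connected component of every cluster becomes its
   own label, with a provenance table back to the source cluster.
2. **Merge** — iteratively, the smallest component below the size
   threshold (default 100 voxels ≈ 0.8 nL at 0.2 mm, the smallest
   cytoarchitectonic region expected) is merged into the adjacent label
   with the largest face-to-face shared boundary; sizes and adjacency are
   recomputed after each merge, and ties break toward the lower label id.
   Components with no labeled neighbor are kept and logged.

Components exactly at the threshold are retained (>= keeps, < merges).
26-connectivity for components avoids spurious splits of thin curved
laminae; 6-face counting approximates shared surface area.  Merging
smallest-first with recomputation removes any dependence on arbitrary
label order.  The fraction of labeled voxels sitting in sub-threshold
components after the split is reported as the noise share at that
threshold; it is non-decreasing in the threshold by construction.  The
whole step conserves the set of labeled voxel locations exactly and is
idempotent up to label renaming.

## Label harmonization across hemispheres

Cluster labels are arbitrary, so left and right segmentations are aligned
through a symmetric reference parcellation: composite (area × layer)
labels, encoded `area_id·100 + layer`, with six equivolumetric layers per
area.  Each hemisphere's refined labels are cross-tabulated against the
composite atlas (voxel-overlap contingency matrix, background excluded),
and because the atlas rows are identical across hemispheres the product

    M = C_left^T · C_right

is a left-by-right affinity accumulating overlap through common atlas
cells.  Matching proceeds in rounds: an optimal one-to-one assignment on
M by the Hungarian algorithm (zero-overlap pairs discarded), then the
remaining labels in decreasing size order each attach greedily to their
largest-overlap partner, many-to-one allowed — with hundreds of
data-driven domains against dozens of atlas cells, many-to-one tails are
expected.  Right-hemisphere ids are rewritten onto the left's ids; labels
with no atlas-mediated overlap receive fresh ids beyond the left range.
Only ids change; every domain's voxel set is untouched.  On mirrored
phantoms with randomly permuted right-hemisphere labels the procedure
recovers the inverse permutation exactly (100% post-harmonization voxel
agreement), provided each label's overlap profile is non-degenerate.

## The synthetic phantom

The phantom emulates the study conditions at desk scale: a two-hemisphere
cortical ribbon with known areas, laminar classes, per-class diffusion
signatures, and noise.

* **Geometry.**  One hemisphere is built in a voxel box (slab, spherical
  shell — the default — or sinusoidal ribbon); the full grid is the box,
  a one-voxel mid-sagittal gap (so no connected component can span
  hemispheres), and the mirror image.  The default shell (inner radius
  20, outer 27 voxels in a 60-voxel box) gives ~49,000 GM voxels per
  hemisphere.
* **Classes.**  Areas partition the tangential extent (azimuthal wedges
  on the shell, strips on the slab); laminar classes partition depth with
  equivolumetric spacing.  Each (area, layer) cell maps to one of 14
  classes; with 5 areas × 3 layers = 15 cells, one signature is shared by
  two non-adjacent areas, so refinement must split it.
* **Signatures.**  Each class carries an axially symmetric tensor
  (lam1 stratified over 0.5–1.8e-3 mm^2/s, anisotropy ratio over
  0.15–0.85, principal axis radial or tangential alternating by class)
  plus an NG level (0.05–0.5).  Ground-truth parameter maps come from the
  same closed forms used by the analysis modules, so feature units are
  realistic (RTAP in mm^-2, RTPP in mm^-1, PA/NG dimensionless).
* **Mirror symmetry.**  The right hemisphere is the exact mirror of the
  left — tensors conjugated by the flip, class labels renamed by a random
  permutation — which is what makes harmonization testable.
* **Noise.**  Two independent mechanisms.  (1) Simulated DWIs follow the
  monoexponential forward model S = S0 exp(-b g^T D g) with Rician noise
  (magnitude of a complex Gaussian perturbation, sigma = S0/SNR, default
  SNR 20 at b≈0, applied over the whole grid so background shows the
  Rician floor).  (2) Observed feature maps add Gaussian feature noise
  whose per-feature sd is *derived* from the requested class separation:
  signatures are scaled by their across-class sd, and the isotropic noise
  sd in that space is set so the closest signature pair sits at exactly
  `class_separation` Mahalanobis units (default 4).  This ties "default
  noise level" to a single interpretable parameter instead of a free
  dial.

What the phantom does not emulate: realistic gyral/sulcal folding from
meshes, partial-volume mixing at tissue interfaces, non-Gaussian
(kurtosis) signal decay, spatially correlated noise, or scanner
artifacts.  Passing tests therefore demonstrate the correctness and
self-consistency of the pipeline's operations under the stated model, not
segmentation accuracy on real tissue.

## Problem sizes and determinism

Default experiment sizes were chosen so the full suite runs comfortably
on a single CPU: ~49k GM voxels per hemisphere for clustering experiments
(the BIC sweep over k = 8..20 with 5 restarts is the dominant cost),
~13k-voxel shells for most geometry tests and a ~77k-voxel shell for the
layer-volume check, and a compact slab with a 3-shell/18-volume scheme for
the end-to-end pipeline test.  Every stochastic stage takes an explicit
seed; a pipeline run expands one global seed into per-stage seeds by fixed
offsets, so stages re-run in isolation reproduce their in-pipeline
behavior, and two runs with the same seed produce voxelwise-identical
label volumes.

## Known limitations

* The equivolume trace assumes columns follow the radial field of the
  mid-surface signed distance; on geometries with strongly varying ribbon
  thickness the mid-surface normal and the depth-ratio normal diverge
  slightly.
* The Gaussian-limit propagator scalars deliberately omit restricted-
  diffusion effects; on real multi-shell data RTOP/RTAP/RTPP from a full
  propagator fit differ from the tensor-limit values, and NG must be
  supplied externally.
* Dice scores use one-to-one overlap matching; heavily over-segmented
  predictions are penalized even when their union matches a truth label.
* The merge step's shared-boundary count uses face adjacency only;
  diagonal-only contacts never attract a merge.
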