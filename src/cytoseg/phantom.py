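"""Synthetic two-hemisphere cortical-ribbon phantoms with known ground truth.

The phantom stands in for a real ultra-high-resolution ex vivo dataset: a
folded or shell-shaped gray-matter ribbon sits on a white-matter core, is
split into two mirror-image hemispheres by a mid-sagittal one-voxel gap,
and is partitioned tangentially into areas and radially into laminar
classes.  Every (area, layer) cell maps to one of ``n_classes``
cytoarchitectonic classes; each class carries an axially symmetric
diffusion-tensor signature (principal axis radial or tangential to the
ribbon) plus a non-Gaussianity (NG) level.  From the tensor field the
phantom derives noiseless ground-truth parameter maps with the same
closed forms used by the analysis modules, simulates diffusion-weighted
volumes under a monoexponential forward model with Rician noise, and can
emit "observed" feature maps with additive Gaussian feature noise whose
scale is tied to the requested class separation.

The right hemisphere is an exact mirror image of the left with its class
labels renamed by a random permutation, which is what makes the
hemisphere-harmonization stage testable against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion_params import TensorField, compute_parameter_maps
from .io_core import DWIVolumeSet, GradientScheme, VolumeGrid, get_logger, write_volume

__all__ = ["PhantomSpec", "PhantomTruth", "default_spec", "make_phantom",
           "simulate_dwis", "sample_observed_params", "FEATURE_NAMES"]

#: The cluster feature set; class separation and feature noise are defined on it.
FEATURE_NAMES = ("PA", "NG", "RTAP", "RTPP")

GEOMETRIES = ("slab", "spherical-shell", "sinusoidal-ribbon")


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a synthetic two-hemisphere phantom.

    ``hemisphere_shape`` is the (nx, ny, nz) voxel box of one hemisphere;
    the full grid is (2*nx+1, ny, nz) with a one-voxel mid-sagittal gap so
    no connected component can span hemispheres.  Geometry parameters are
    in voxels.  ``class_separation`` is the minimum pairwise Mahalanobis
    distance between class signatures in the cluster feature space; the
    additive feature-noise standard deviation is derived from it (see
    :func:`make_phantom`).
    """

    geometry: str = "spherical-shell"
    hemisphere_shape: tuple[int, int, int] = (60, 60, 60)
    inner_radius: float = 20.0      # shell geometries, voxels
    outer_radius: float = 27.0
    gm_thickness: float = 10.0      # slab/ribbon geometries, voxels
    wm_thickness: float = 4.0
    ribbon_amplitude: float = 4.0   # sinusoidal-ribbon fold amplitude, voxels
    ribbon_period: float = 30.0     # fold period, voxels
    n_areas: int = 5
    n_layer_classes: int = 3
    n_classes: int = 14             # distinct classes per hemisphere
    class_separation: float = 4.0   # Mahalanobis, in feature-noise units
    snr: float = 20.0               # Rician SNR at b ~ 0
    voxel_size: float = 0.2         # mm
    tau_s: float = 0.026            # diffusion time for propagator scalars, s
    identity_permutation: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.n_areas < 1 or self.n_layer_classes < 1:
            raise ValueError("n_areas and n_layer_classes must be >= 1")
        if self.n_classes < 1 or self.n_classes > self.n_areas * self.n_layer_classes:
            raise ValueError("need 1 <= n_classes <= n_areas * n_layer_classes")
        if self.class_separation <= 0:
            raise ValueError("class_separation must be > 0")
        if not (self.snr > 0):
            raise ValueError("snr must be > 0")
        thickness = (self.outer_radius - self.inner_radius
                     if self.geometry == "spherical-shell" else self.gm_thickness)
        if thickness < self.n_layer_classes:
            raise ValueError(
                f"GM thickness {thickness} voxels cannot hold "
                f"{self.n_layer_classes} layer classes (>= 1 voxel per layer)"
            )


def default_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """The default study phantom: a spherical-shell ribbon with ~49,000 GM
    voxels per hemisphere and 14 cytoarchitectonic classes (5 areas x 3
    laminar classes with one signature shared between two areas)."""
    return PhantomSpec(seed=seed, **overrides)


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    spec: PhantomSpec
    grid: VolumeGrid
    gm_mask: np.ndarray
    wm_mask: np.ndarray
    hemisphere_labels: np.ndarray      # 0 background, 1 left, 2 right
    area_labels: np.ndarray            # 1..n_areas within GM
    layer_class_labels: np.ndarray     # 1..n_layer_classes within GM
    class_labels: np.ndarray           # 1..n_classes (right side permuted)
    tensor_field: np.ndarray           # (..., 3, 3) mm^2/s, GM+WM
    s0: np.ndarray
    true_params: dict[str, np.ndarray]
    permutation: np.ndarray            # permutation[i-1] = right-hemisphere id of left class i
    class_table: pd.DataFrame
    noise_sigma: dict[str, float]      # feature-noise sd per feature (raw units)

    @property
    def left_mask(self) -> np.ndarray:
        return self.hemisphere_labels == 1

    @property
    def right_mask(self) -> np.ndarray:
        return self.hemisphere_labels == 2

    def write(self, out_dir) -> dict[str, Path]:
        """Write truth volumes as NIfTI plus the class-signature manifest."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        vols = {
            "gm_mask": self.gm_mask.astype(np.uint8),
            "wm_mask": self.wm_mask.astype(np.uint8),
            "hemisphere_labels": self.hemisphere_labels.astype(np.int16),
            "area_labels": self.area_labels.astype(np.int16),
            "layer_class_labels": self.layer_class_labels.astype(np.int16),
            "class_labels": self.class_labels.astype(np.int16),
        }
        for name, vol in vols.items():
            paths[name] = write_volume(out_dir / f"{name}.nii.gz", vol, self.grid)
        for name, vol in self.true_params.items():
            paths[f"true_{name}"] = write_volume(
                out_dir / f"true_{name}.nii.gz", vol.astype(np.float32), self.grid
            )
        manifest = self.class_table.copy()
        manifest["right_hemisphere_id"] = self.permutation
        manifest.to_csv(out_dir / "class_manifest.tsv", sep="\t", index=False)
        paths["class_manifest"] = out_dir / "class_manifest.tsv"
        return paths


# ---------------------------------------------------------------------------
# geometry builders (one hemisphere box, local coordinates)
# ---------------------------------------------------------------------------


def _stratified(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """One uniform draw per equal-width bin, bins shuffled: a cheap latin
    hypercube in 1D that guarantees spread across [lo, hi]."""
    edges = np.linspace(lo, hi, n + 1)
    vals = edges[:-1] + rng.random(n) * (edges[1:] - edges[:-1])
    rng.shuffle(vals)
    return vals


def _hemisphere_geometry(spec: PhantomSpec):
    """Masks, area/layer labels and radial/tangential frames for one box.

    Returns gm, wm, area (1..A), layer (1..L), radial (...,3), tangential
    (...,3) on the ``hemisphere_shape`` box.  Analytic depth in [0, 1)
    drives the laminar partition: equivolumetric (cube-root) spacing for
    the spherical shell, linear for the flat geometries.
    """
    nx, ny, nz = spec.hemisphere_shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    A, L = spec.n_areas, spec.n_layer_classes

    if spec.geometry == "spherical-shell":
        a, b = spec.inner_radius, spec.outer_radius
        need = b + 2
        if min(nx, ny, nz) < 2 * need:
            raise ValueError("hemisphere box too small for the requested shell")
        c = (np.array([nx, ny, nz]) - 1) / 2.0
        dx, dy, dz = ii - c[0], jj - c[1], kk - c[2]
        r = np.sqrt(dx**2 + dy**2 + dz**2)
        wm = r < a
        gm = (r >= a) & (r < b)
        depth = np.clip((r**3 - a**3) / (b**3 - a**3), 0.0, 1.0 - 1e-9)
        phi = np.arctan2(dz, dy)
        area = (np.floor((phi + np.pi) / (2 * np.pi) * A).astype(int) % A) + 1
        with np.errstate(invalid="ignore", divide="ignore"):
            radial = np.stack([dx, dy, dz], axis=-1) / np.maximum(r, 1e-9)[..., None]
    else:
        wt, T = spec.wm_thickness, spec.gm_thickness
        if spec.geometry == "slab":
            zlow = np.full((nx, ny, nz), wt)
            radial = np.zeros((nx, ny, nz, 3))
            radial[..., 2] = 1.0
        else:  # sinusoidal-ribbon
            k = 2 * np.pi / spec.ribbon_period
            zlow = wt + spec.ribbon_amplitude * (1 + np.sin(k * jj)) / 1.0
            # surface normal of z = zlow(y): grad(z - zlow) = (0, -A k cos, 1)
            ny_comp = -spec.ribbon_amplitude * k * np.cos(k * jj)
            radial = np.stack(
                [np.zeros_like(ny_comp), ny_comp, np.ones_like(ny_comp)], axis=-1
            )
            radial /= np.linalg.norm(radial, axis=-1, keepdims=True)
        if np.max(zlow) + T + 1 > nz:
            raise ValueError("hemisphere box too thin for the requested ribbon")
        wm = kk < zlow
        gm = (kk >= zlow) & (kk < zlow + T)
        depth = np.clip((kk - zlow + 0.5) / T, 0.0, 1.0 - 1e-9)
        area = (np.floor(jj / ny * A).astype(int) % A) + 1

    layer = np.floor(depth * L).astype(int) + 1
    area[~gm] = 0
    layer[~gm] = 0

    # a tangential unit vector: radial x ex, with a fallback near poles
    ex = np.zeros_like(radial)
    ex[..., 0] = 1.0
    tang = np.cross(radial, ex)
    norm = np.linalg.norm(tang, axis=-1)
    degenerate = norm < 1e-6
    if degenerate.any():
        ey = np.zeros(3)
        ey[1] = 1.0
        tang[degenerate] = np.cross(radial[degenerate], ey)
        norm = np.linalg.norm(tang, axis=-1)
    tang /= np.maximum(norm, 1e-12)[..., None]
    return gm, wm, area, layer, radial, tang


def _class_map(spec: PhantomSpec) -> np.ndarray:
    """(A, L) table of class ids 1..n_classes; surplus cells reuse early
    classes, giving spatially disjoint components that share a signature."""
    A, L = spec.n_areas, spec.n_layer_classes
    cells = np.arange(A * L)
    return (cells % spec.n_classes + 1).reshape(A, L)


def _class_signatures(spec: PhantomSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Per-class tensor eigenvalues, orientation mode, NG level, and the
    resulting feature-space means."""
    n = spec.n_classes
    lam1 = _stratified(rng, n, 0.5e-3, 1.8e-3)
    ratio = _stratified(rng, n, 0.15, 0.85)
    lam_perp = lam1 * ratio
    ng = _stratified(rng, n, 0.05, 0.50)
    orientation = np.where(np.arange(n) % 2 == 0, "radial", "tangential")

    c = 4.0 * np.pi * spec.tau_s
    rtpp = (c * lam1) ** -0.5
    rtap = 1.0 / (c * lam_perp)
    md = (lam1 + 2 * lam_perp) / 3.0
    det_d = lam1 * lam_perp**2
    det_sum = (lam1 + md) * (lam_perp + md) ** 2
    cos = 2.0**1.5 * (det_d * md**3) ** 0.25 / np.sqrt(det_sum)
    pa = np.sqrt(np.clip(1 - cos**2, 0, 1))
    return pd.DataFrame(
        {
            "class_id": np.arange(1, n + 1),
            "lambda1": lam1,
            "lambda_perp": lam_perp,
            "orientation": orientation,
            "PA": pa,
            "NG": ng,
            "RTAP": rtap,
            "RTPP": rtpp,
        }
    )


def _feature_noise_sigma(table: pd.DataFrame, separation: float) -> dict[str, float]:
    """Feature-noise sd per feature such that the minimum pairwise
    Mahalanobis distance between class signatures equals ``separation``.

    Signatures are scaled by their across-class sd, the closest pair is
    found in that normalized space, and the isotropic noise sd is set to
    (closest distance) / separation, then mapped back to raw units.
    """
    M = table[list(FEATURE_NAMES)].to_numpy(float)
    scale = M.std(axis=0)
    scale[scale <= 0] = 1.0
    Z = M / scale
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    d_min = float(np.sqrt(d2.min()))
    sigma_norm = d_min / separation
    return {f: float(sigma_norm * s) for f, s in zip(FEATURE_NAMES, scale)}


# ---------------------------------------------------------------------------
# phantom assembly
# ---------------------------------------------------------------------------


def make_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Generate a mirrored two-hemisphere phantom with full ground truth.

    Deterministic for a given ``spec.seed``.  The right hemisphere is the
    mid-sagittal mirror image of the left (tensors conjugated by the flip)
    with class labels renamed by a random permutation.
    """
    log = get_logger("phantom")
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.hemisphere_shape
    gm_l, wm_l, area_l, layer_l, radial_l, tang_l = _hemisphere_geometry(spec)

    cmap = _class_map(spec)
    class_l = np.zeros_like(area_l)
    in_gm = gm_l
    class_l[in_gm] = cmap[area_l[in_gm] - 1, layer_l[in_gm] - 1]

    table = _class_signatures(spec, rng)
    noise_sigma = _feature_noise_sigma(table, spec.class_separation)

    # per-voxel tensors: axially symmetric, principal axis radial or tangential
    tensor_l = np.zeros((nx, ny, nz, 3, 3))
    ng_l = np.zeros((nx, ny, nz))
    for row in table.itertuples():
        sel = class_l == row.class_id
        axis = radial_l[sel] if row.orientation == "radial" else tang_l[sel]
        iso = row.lambda_perp * np.eye(3)
        tensor_l[sel] = iso + (row.lambda1 - row.lambda_perp) * np.einsum(
            "vi,vj->vij", axis, axis
        )
        ng_l[sel] = row.NG
    # white matter: anisotropic along x (arbitrary but fixed)
    wm_axis = np.array([1.0, 0.0, 0.0])
    wm_lam1, wm_perp, wm_ng = 1.4e-3, 0.35e-3, 0.15
    tensor_l[wm_l] = wm_perp * np.eye(3) + (wm_lam1 - wm_perp) * np.outer(wm_axis, wm_axis)
    ng_l[wm_l] = wm_ng

    # assemble the full grid: left box | 1-voxel gap | mirrored right box
    full_shape = (2 * nx + 1, ny, nz)
    grid = VolumeGrid.isotropic(full_shape, spec.voxel_size)

    def _mirror_scalar(vol):
        out = np.zeros(full_shape, dtype=vol.dtype)
        out[:nx] = vol
        out[nx + 1:] = vol[::-1]
        return out

    gm = _mirror_scalar(gm_l)
    wm = _mirror_scalar(wm_l)
    area = _mirror_scalar(area_l)
    layer = _mirror_scalar(layer_l)
    ng = _mirror_scalar(ng_l)

    hemi = np.zeros(full_shape, dtype=np.int16)
    hemi[:nx][gm_l | wm_l] = 1
    hemi[nx + 1:][(gm_l | wm_l)[::-1]] = 2

    if spec.identity_permutation:
        perm = np.arange(1, spec.n_classes + 1)
    else:
        perm = rng.permutation(spec.n_classes) + 1
    class_full = np.zeros(full_shape, dtype=np.int16)
    class_full[:nx] = class_l
    right_cls = class_l[::-1].copy()
    nonzero = right_cls > 0
    right_cls[nonzero] = perm[right_cls[nonzero] - 1]
    class_full[nx + 1:] = right_cls

    tensors = np.zeros(full_shape + (3, 3))
    tensors[:nx] = tensor_l
    flipped = tensor_l[::-1].copy()
    # conjugate by F = diag(-1, 1, 1): negate the x-row/column off-diagonals
    for i in (1, 2):
        flipped[..., 0, i] *= -1.0
        flipped[..., i, 0] *= -1.0
    tensors[nx + 1:] = flipped

    s0 = (gm | wm).astype(float)
    tissue = gm | wm
    tf = TensorField(tensors=tensors, s0=s0, fit_mask=tissue)
    true_params = compute_parameter_maps(tf, spec.tau_s)
    true_params["NG"] = ng

    n_gm_left = int(gm_l.sum())
    log.info(
        "phantom: %s, %d GM voxels/hemisphere, %d classes, min separation %.2f",
        spec.geometry, n_gm_left, spec.n_classes, spec.class_separation,
    )
    return PhantomTruth(
        spec=spec,
        grid=grid,
        gm_mask=gm,
        wm_mask=wm,
        hemisphere_labels=hemi,
        area_labels=area.astype(np.int16),
        layer_class_labels=layer.astype(np.int16),
        class_labels=class_full,
        tensor_field=tensors,
        s0=s0,
        true_params=true_params,
        permutation=perm,
        class_table=table,
        noise_sigma=noise_sigma,
    )


def simulate_dwis(
    truth: PhantomTruth,
    scheme: GradientScheme,
    snr: float | None = None,
    seed: int = 0,
) -> DWIVolumeSet:
    """Monoexponential tensor forward model with Rician noise.

    Signal S(b, g) = S0 exp(-b g^T D g) per voxel; noise is the magnitude
    of (S + n1, n2) with n1, n2 ~ N(0, sigma), sigma = S0_scale / snr
    applied over the whole grid (so background voxels carry a Rician noise
    floor).  ``snr=None`` or ``inf`` disables noise.  Deterministic given
    ``seed``.
    """
    rng = np.random.default_rng(seed)
    tissue = truth.gm_mask | truth.wm_mask
    D = truth.tensor_field[tissue]
    s0 = truth.s0[tissue]
    n = len(scheme)
    data = np.zeros(truth.grid.shape + (n,), dtype=np.float32)
    for v in range(n):
        g = scheme.directions[v]
        adc = np.einsum("vij,i,j->v", D, g, g, optimize=True)
        data[..., v][tissue] = s0 * np.exp(-scheme.b_values[v] * adc)
    if snr is not None and np.isfinite(snr):
        sigma = float(truth.s0.max()) / snr
        noise = rng.normal(0.0, sigma, size=data.shape + (2,)).astype(np.float32)
        data = np.sqrt((data + noise[..., 0]) ** 2 + noise[..., 1] ** 2)
    return DWIVolumeSet(data=data, scheme=scheme, grid=truth.grid)


def sample_observed_params(
    truth: PhantomTruth, seed: int = 0, noise_scale: float = 1.0
) -> dict[str, np.ndarray]:
    """Noisy copies of the cluster feature maps (PA, NG, RTAP, RTPP).

    Adds zero-mean Gaussian noise with per-feature sd ``noise_scale *
    truth.noise_sigma[f]`` inside GM.  At ``noise_scale=1`` (default) the
    class signatures are separated by exactly ``spec.class_separation``
    Mahalanobis units, the condition the clustering stage is specified
    against.  Maps outside the feature set are returned noiseless.
    """
    rng = np.random.default_rng(seed)
    out = {}
    gm = truth.gm_mask
    for name, vol in truth.true_params.items():
        if name in FEATURE_NAMES:
            noisy = vol.copy()
            noisy[gm] = noisy[gm] + rng.normal(
                0.0, noise_scale * truth.noise_sigma[name], size=int(gm.sum())
            )
            out[name] = noisy
        else:
            out[name] = vol.copy()
    return out
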