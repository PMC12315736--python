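"""Spatially varying anisotropic Gaussian denoising oriented by the CRF.

Each cortical voxel is replaced by a Gaussian-weighted sum of its
``support^3`` neighborhood.  The kernel is rotationally symmetric about
the local radial direction r: a narrow standard deviation ``sigma_radial``
(default 0.1 mm) across the cortical laminae and a wide
``sigma_tangential`` (default 1.0 mm) within the plane tangent to the
cortical surface, so noise is averaged along layers without blurring the
laminar profile.  With the default 5-voxel support on a 0.2 mm grid the
tangential footprint is 5 x 0.2 = 1.0 mm, the maximum in-plane blurring.

The kernel is evaluated by sampling the continuous Gaussian at voxel-center
offsets and normalizing to unit sum, so constant signals are preserved
exactly.  Voxels without a defined frame are passed through unchanged; at
image borders the in-grid weights are renormalized.  By default neighbors
outside the cortical mask do contribute (set ``mask_restrict`` to confine
the weighted sum to GM).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crf import CorticalFrameField
from .io_core import DWIVolumeSet, VolumeGrid, get_logger

__all__ = [
    "FilterParams",
    "build_kernel",
    "apply_crf_filter",
    "filter_dwi_set",
    "tangential_support_width_mm",
]


@dataclass(frozen=True)
class FilterParams:
    """Anisotropic kernel geometry (mm) and voxel support."""

    sigma_radial: float = 0.1
    sigma_tangential: float = 1.0
    support: int = 5
    mask_restrict: bool = False

    def __post_init__(self) -> None:
        if self.sigma_radial <= 0 or self.sigma_tangential <= 0:
            raise ValueError("filter sigmas must be > 0")
        if self.support < 1 or self.support % 2 == 0:
            raise ValueError("support must be odd and >= 1")


def tangential_support_width_mm(params: FilterParams, grid: VolumeGrid) -> float:
    """Full tangential footprint of the kernel: support x voxel pitch (mm)."""
    return params.support * float(max(grid.voxel_size))


def _offsets_mm(params: FilterParams, voxel_size) -> np.ndarray:
    r = params.support // 2
    ax = [np.arange(-r, r + 1) * v for v in voxel_size]
    ox, oy, oz = np.meshgrid(*ax, indexing="ij")
    return np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)  # (support^3, 3)


def _offset_weights(offsets_mm: np.ndarray, radial: np.ndarray,
                    params: FilterParams) -> np.ndarray:
    """Unnormalized Gaussian weights, shape (n_voxels, support^3).

    w(x) = exp(-1/2 [ (x.r)^2/sr^2 + (|x|^2-(x.r)^2)/st^2 ]) — rotationally
    symmetric about r, so no tangent basis is needed.
    """
    proj = radial @ offsets_mm.T                      # (n, m)
    sq = np.einsum("mi,mi->m", offsets_mm, offsets_mm)  # (m,)
    rad2 = proj**2
    tan2 = np.maximum(sq[None, :] - rad2, 0.0)
    return np.exp(
        -0.5 * (rad2 / params.sigma_radial**2 + tan2 / params.sigma_tangential**2)
    )


def build_kernel(radial, params: FilterParams, voxel_size) -> np.ndarray:
    """The ``support^3`` weight stencil for one radial direction.

    Weights are sampled at voxel-center offsets (mm) and normalized to sum
    exactly to 1.
    """
    radial = np.asarray(radial, dtype=float)
    nrm = np.linalg.norm(radial)
    if nrm < 1e-12:
        raise ValueError("radial direction must be non-zero")
    radial = radial / nrm
    voxel_size = (voxel_size,) * 3 if np.isscalar(voxel_size) else tuple(voxel_size)
    offs = _offsets_mm(params, voxel_size)
    w = _offset_weights(offs, radial[None, :], params)[0]
    w = w.reshape((params.support,) * 3)
    return w / w.sum()


def apply_crf_filter(
    volume: np.ndarray,
    frame: CorticalFrameField,
    params: FilterParams | None = None,
    gm_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Filter one 3D volume with the spatially varying oriented kernel.

    Voxels where the frame is defined are replaced by the kernel-weighted
    neighborhood sum; all other voxels pass through unchanged.  Weights
    falling outside the grid (or outside ``gm_mask`` when
    ``params.mask_restrict``) are dropped and the rest renormalized to 1.
    """
    params = params or FilterParams()
    volume = np.asarray(volume, dtype=float)
    if volume.shape != frame.defined_mask.shape:
        raise ValueError(
            f"volume shape {volume.shape} does not match frame {frame.defined_mask.shape}"
        )
    if params.mask_restrict and gm_mask is None:
        raise ValueError("mask_restrict requires a gm_mask")
    wv, neigh = _prepare_stencil(frame, params, gm_mask)
    out = volume.copy()
    flat = volume.ravel()
    num = np.einsum("vm,vm->v", wv.astype(np.float64), flat[neigh])
    den = wv.sum(axis=1, dtype=np.float64)
    sel = frame.defined_mask
    out[sel] = num / den
    return out


def _prepare_stencil(frame, params, gm_mask):
    """Per-defined-voxel kernel weights and flat neighbor indices.

    Returns ``(wv, neigh)``: weights with invalid (out-of-grid or, with
    ``mask_restrict``, extra-cortical) neighbors zeroed, shape (n, m)
    float32, and the clipped flat neighbor indices, shape (n, m) int32.
    Built one offset at a time to keep memory linear in the mask size.
    """
    shape = frame.defined_mask.shape
    idx = np.column_stack(np.nonzero(frame.defined_mask))  # (n, 3)
    radial = frame.radial[frame.defined_mask]
    offs_mm = _offsets_mm(params, frame.grid.voxel_size)
    weights = _offset_weights(offs_mm, radial, params).astype(np.float32)  # (n, m)

    r = params.support // 2
    ax = np.arange(-r, r + 1)
    ox, oy, oz = np.meshgrid(ax, ax, ax, indexing="ij")
    offs_vox = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)

    n, m = weights.shape
    neigh = np.empty((n, m), dtype=np.int64)
    gm_flat = gm_mask.ravel() if params.mask_restrict else None
    dims = np.array(shape)
    for k in range(m):
        pos = idx + offs_vox[k]          # (n, 3)
        inside = np.all((pos >= 0) & (pos < dims), axis=1)
        pos[~inside] = 0
        flat = np.ravel_multi_index((pos[:, 0], pos[:, 1], pos[:, 2]), shape)
        ok = inside
        if gm_flat is not None:
            ok = ok & gm_flat[flat]
        weights[~ok, k] = 0.0
        neigh[:, k] = flat
    return weights, neigh


def filter_dwi_set(
    dwis: DWIVolumeSet,
    frame: CorticalFrameField,
    params: FilterParams | None = None,
    gm_mask: np.ndarray | None = None,
) -> DWIVolumeSet:
    """Apply the CRF filter to each diffusion-weighted volume independently.

    The stencil (weights and neighbor indices) depends only on the frame,
    so it is computed once and reused across the 4th dimension; the result
    is identical to looping :func:`apply_crf_filter` over each 3D volume.
    The gradient scheme is unchanged.
    """
    params = params or FilterParams()
    log = get_logger("filter")
    if tuple(dwis.data.shape[:3]) != frame.defined_mask.shape:
        raise ValueError("DWI grid does not match frame grid")
    if params.mask_restrict and gm_mask is None:
        raise ValueError("mask_restrict requires a gm_mask")
    wv, neigh = _prepare_stencil(frame, params, gm_mask)
    wv64 = wv.astype(np.float64)
    den = wv.sum(axis=1, dtype=np.float64)
    sel = frame.defined_mask
    out = np.array(dwis.data, dtype=np.float32, copy=True)
    n = dwis.n_volumes
    log.info("CRF-filtering %d volumes over %d cortical voxels", n, int(sel.sum()))
    for v in range(n):
        flat = dwis.data[..., v].astype(np.float64).ravel()
        vals = np.einsum("vm,vm->v", wv64, flat[neigh]) / den
        out[..., v][sel] = vals
    return DWIVolumeSet(data=out, scheme=dwis.scheme, grid=dwis.grid)
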