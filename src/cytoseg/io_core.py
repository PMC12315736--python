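"""On-disk artifacts, acquisition bookkeeping, and run configuration.

Every volume handled by the pipeline is a NIfTI-1 image tied to a
:class:`VolumeGrid` (shape, voxel size, voxel-to-world affine).  Diffusion
acquisition metadata travels as a :class:`GradientScheme` read from
FSL-style ``.bval``/``.bvec`` tables.  All stage parameters live in a
:class:`RunConfig` whose defaults reproduce the reference processing
protocol (0.1/1.0 mm filter sigmas, 5-voxel kernel support, 100-voxel
morphology threshold, six equivolumetric layers, PA/NG/RTAP/RTPP features,
14 mixture components).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "B0_THRESHOLD",
    "VolumeGrid",
    "GradientScheme",
    "DWIVolumeSet",
    "RunConfig",
    "read_volume",
    "write_volume",
    "read_gradient_scheme",
    "write_gradient_scheme",
    "make_multishell_scheme",
    "fibonacci_directions",
    "read_label_names",
    "write_label_names",
    "get_logger",
]

#: Volumes with b <= this value (s/mm^2) are treated as non-diffusion-weighted.
#: The reference acquisition has no b=0 volumes (its lowest shell is b=100),
#: so all of its volumes count as weighted.
B0_THRESHOLD = 50.0


def get_logger(stage: str) -> logging.Logger:
    """Return the package logger for a pipeline stage."""
    return logging.getLogger(f"cytoseg.{stage}")


# ---------------------------------------------------------------------------
# grids and volumes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VolumeGrid:
    """Voxel lattice geometry: shape, voxel size (mm) and RAS affine.

    Voxel indices are 0-based; world coordinates are mm in RAS.  All kernel
    geometry downstream is computed in mm and converted through
    ``voxel_size``.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        vox = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {self.shape}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel sizes must be > 0, got {self.voxel_size}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vox)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, shape, voxel_size: float) -> "VolumeGrid":
        """Grid with isotropic voxels and a diagonal RAS affine."""
        aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
        return cls(tuple(shape), (voxel_size,) * 3, aff)

    @classmethod
    def from_image(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        shape = tuple(int(s) for s in img.shape[:3])
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(shape, vox, np.asarray(img.affine, dtype=float))

    def matches(self, other: "VolumeGrid", tol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=tol)
            and np.allclose(self.affine, other.affine, atol=tol)
        )


def read_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a 3D or 4D NIfTI volume.

    Integer-typed images (label volumes, masks) are returned with their
    integer dtype so label values round-trip exactly; floating images are
    returned as float64.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the payload is not NIfTI or is not 3- or 4-dimensional; the
        message names the offending dimensionality.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises ImageFileError subclasses
        raise ValueError(f"not a readable NIfTI file: {path} ({exc})") from exc
    ndim = len(img.shape)
    if ndim < 3 or ndim > 4:
        raise ValueError(
            f"{path}: expected a 3D or 4D image, got {ndim}D with shape {tuple(img.shape)}"
        )
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(data.dtype, np.integer):
        data = np.asarray(data)
    else:
        data = np.asarray(data, dtype=np.float64)
    return data, VolumeGrid.from_image(img)


def write_volume(path, data: np.ndarray, grid: VolumeGrid) -> Path:
    """Write a 3D/4D array as NIfTI on ``grid``; integer dtypes are kept."""
    path = Path(path)
    data = np.asarray(data)
    if data.ndim not in (3, 4):
        raise ValueError(f"can only write 3D or 4D volumes, got {data.ndim}D")
    if tuple(data.shape[:3]) != grid.shape:
        raise ValueError(f"data shape {data.shape[:3]} does not match grid {grid.shape}")
    if np.issubdtype(data.dtype, np.integer):
        out = data.astype(np.int32) if data.dtype.itemsize > 4 else data
    elif data.dtype == bool:
        out = data.astype(np.uint8)
    else:
        out = data
    img = nib.Nifti1Image(out, grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size) + ((1.0,) if data.ndim == 4 else ()))
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# diffusion acquisition scheme
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume diffusion weighting and encoding directions.

    Parameters
    ----------
    b_values : (n,) array, s/mm^2
    directions : (n, 3) array of unit vectors (b0 volumes may carry zeros)
    delta_small : gradient pulse duration delta, ms
    delta_big : pulse separation Delta, ms
    """

    b_values: np.ndarray
    directions: np.ndarray
    delta_small: float = 6.0
    delta_big: float = 28.0

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float).ravel()
        g = np.asarray(self.directions, dtype=float)
        if g.shape != (b.size, 3):
            raise ValueError(f"directions shape {g.shape} does not match {b.size} b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be >= 0")
        if self.delta_big <= self.delta_small / 3.0:
            raise ValueError("require Delta > delta/3 so the diffusion time is positive")
        weighted = b > B0_THRESHOLD
        norms = np.linalg.norm(g[weighted], axis=1)
        if weighted.any() and np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("weighted directions must have unit norm (tol 1e-6)")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "directions", g)

    def __len__(self) -> int:
        return int(self.b_values.size)

    @property
    def is_b0(self) -> np.ndarray:
        """Boolean flags for non-diffusion-weighted volumes (b <= 50 s/mm^2)."""
        return self.b_values <= B0_THRESHOLD

    @property
    def diffusion_time_ms(self) -> float:
        """Effective diffusion time tau = Delta - delta/3 in ms."""
        return self.delta_big - self.delta_small / 3.0

    @property
    def tau_s(self) -> float:
        """Effective diffusion time in seconds (for propagator scalars)."""
        return self.diffusion_time_ms / 1000.0

    def shell_table(self) -> pd.DataFrame:
        """Unique b-value shells with per-shell direction counts."""
        shells, counts = np.unique(np.round(self.b_values, 1), return_counts=True)
        return pd.DataFrame({"b_value": shells, "n_directions": counts})


@dataclass
class DWIVolumeSet:
    """A 4D diffusion-weighted stack with its scheme and grid."""

    data: np.ndarray
    scheme: GradientScheme
    grid: VolumeGrid

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D")
        if self.data.shape[3] != len(self.scheme):
            raise ValueError(
                f"{self.data.shape[3]} volumes but scheme lists {len(self.scheme)}"
            )
        if tuple(self.data.shape[:3]) != self.grid.shape:
            raise ValueError("DWI data does not match grid shape")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def read_gradient_scheme(bval_path, bvec_path, delta_small: float = 6.0,
                         delta_big: float = 28.0) -> GradientScheme:
    """Parse FSL-style ``.bval``/``.bvec`` text tables.

    bvecs may be written 3 rows x n columns (FSL convention) or n x 3.
    Weighted directions that are not unit-norm are normalized with a
    logged warning; zero directions on weighted volumes are an error.
    """
    log = get_logger("io")
    bval_path, bvec_path = Path(bval_path), Path(bvec_path)
    for p in (bval_path, bvec_path):
        if not p.exists():
            raise FileNotFoundError(f"gradient table not found: {p}")
    try:
        b = np.loadtxt(str(bval_path), dtype=float).ravel()
        g = np.loadtxt(str(bvec_path), dtype=float)
    except ValueError as exc:
        raise ValueError(f"non-numeric token in gradient tables: {exc}") from exc
    g = np.atleast_2d(g)
    if g.shape[0] == 3 and g.shape[1] != 3:
        g = g.T
    elif g.shape == (3, 3):
        # ambiguous 3x3: FSL writes 3 rows of n entries, so rows are axes
        g = g.T
    if g.shape[0] != b.size:
        raise ValueError(
            f"bval/bvec length mismatch: {b.size} b-values vs {g.shape[0]} directions"
        )
    weighted = b > B0_THRESHOLD
    norms = np.linalg.norm(g, axis=1)
    if np.any(weighted & (norms < 1e-12)):
        raise ValueError("zero direction on a diffusion-weighted volume")
    fix = weighted & (np.abs(norms - 1.0) > 1e-6)
    if fix.any():
        log.warning("normalizing %d non-unit gradient directions", int(fix.sum()))
        g = g.copy()
        g[fix] /= norms[fix, None]
    return GradientScheme(b, g, delta_small=delta_small, delta_big=delta_big)


def write_gradient_scheme(scheme: GradientScheme, bval_path, bvec_path) -> None:
    np.savetxt(str(bval_path), scheme.b_values[None, :], fmt="%.1f")
    np.savetxt(str(bvec_path), scheme.directions.T, fmt="%.8f")


def fibonacci_directions(n: int, offset: float = 0.0) -> np.ndarray:
    """``n`` roughly uniform unit vectors from a Fibonacci spiral on the sphere."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n) + 0.5
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = golden * i + offset
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_multishell_scheme(
    shell_bvalues=(100.0, 1000.0, 2500.0, 4500.0, 7000.0, 10000.0),
    shell_counts=(3, 9, 15, 21, 28, 36),
    delta_small: float = 6.0,
    delta_big: float = 28.0,
) -> GradientScheme:
    """Replicate the multi-shell sampling bookkeeping of the reference protocol.

    Defaults give six shells at b = 100...10000 s/mm^2 with 3/9/15/21/28/36
    directions (112 volumes total), uniformly spread on each shell, and
    pulse timings delta = 6 ms, Delta = 28 ms.
    """
    if len(shell_bvalues) != len(shell_counts):
        raise ValueError("one direction count per shell required")
    bs, gs = [], []
    for k, (b, n) in enumerate(zip(shell_bvalues, shell_counts)):
        bs.append(np.full(int(n), float(b)))
        gs.append(fibonacci_directions(int(n), offset=0.7 * k))
    return GradientScheme(
        np.concatenate(bs), np.vstack(gs), delta_small=delta_small, delta_big=delta_big
    )


def read_label_names(path) -> pd.DataFrame:
    """Read a tab-separated (label_id, name) table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["label_id", "name"])
    df["label_id"] = df["label_id"].astype(int)
    return df


def write_label_names(df: pd.DataFrame, path) -> None:
    df[["label_id", "name"]].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """All stage parameters with protocol defaults, YAML round-trippable."""

    # CRF anisotropic filter
    sigma_radial: float = 0.1          # mm, radial to the cortical surface
    sigma_tangential: float = 1.0      # mm, tangent plane
    support: int = 5                   # odd kernel width in voxels per axis
    mask_restrict: bool = False
    # depth / layering
    depth_mode: str = "equivolume"
    n_layers: int = 6
    # clustering
    features: tuple[str, ...] = ("PA", "NG", "RTAP", "RTPP")
    n_clusters: int = 14
    k_range: tuple[int, int] | None = None   # e.g. (8, 20) to select k by BIC
    gmm_n_init: int = 5
    # morphology
    size_threshold: int = 100          # voxels
    component_connectivity: int = 26
    # misc
    b0_threshold: float = B0_THRESHOLD
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.support < 1 or self.support % 2 == 0:
            raise ValueError("kernel support must be odd and >= 1")
        if self.sigma_radial <= 0 or self.sigma_tangential <= 0:
            raise ValueError("filter sigmas must be > 0")
        if self.size_threshold < 1:
            raise ValueError("size_threshold must be >= 1")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        self.features = tuple(self.features)
        if self.k_range is not None:
            self.k_range = tuple(int(k) for k in self.k_range)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"] = list(self.features)
        if self.k_range is not None:
            d["k_range"] = list(self.k_range)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls(**d)
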