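"""Scalar microstructural parameter maps from diffusion-weighted data.

Two families of maps are produced:

* classical diffusion-tensor scalars (FA, MD, AD, RD) from a log-linear
  weighted least-squares tensor fit;
* zero-displacement probabilities (RTOP, RTAP, RTPP) and propagator
  anisotropy (PA) evaluated in the Gaussian (pure tensor) limit of the
  propagator, where they have closed forms in the tensor eigenvalues and
  the effective diffusion time tau = Delta - delta/3.

The full Gauss-Hermite propagator expansion is deliberately not fitted
here: non-Gaussianity (NG) is identically zero for tensor diffusion, so NG
always enters the pipeline as a supplied or simulated map, never as a
quantity estimated from the DWIs by this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import DWIVolumeSet, get_logger

__all__ = [
    "TensorField",
    "fit_dti",
    "dti_scalars",
    "gaussian_zero_displacement",
    "gaussian_pa",
    "compute_parameter_maps",
    "PARAMETER_UNITS",
]

#: Units of every map name this module can produce.
PARAMETER_UNITS = {
    "FA": "dimensionless",
    "MD": "mm^2/s",
    "AD": "mm^2/s",
    "RD": "mm^2/s",
    "PA": "dimensionless",
    "NG": "dimensionless",
    "RTOP": "mm^-3",
    "RTAP": "mm^-2",
    "RTPP": "mm^-1",
}

#: Floor for tensor eigenvalues (mm^2/s); keeps the closed forms finite.
EIGENVALUE_FLOOR = 1e-7


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors on a grid.

    Attributes
    ----------
    tensors : (nx, ny, nz, 3, 3) array, mm^2/s
    s0 : (nx, ny, nz) non-weighted signal estimate
    fit_mask : boolean volume of voxels with a valid fit
    """

    tensors: np.ndarray
    s0: np.ndarray
    fit_mask: np.ndarray

    _eigvals: np.ndarray | None = None

    def eigenvalues(self) -> np.ndarray:
        """Sorted eigenvalues lam1 >= lam2 >= lam3, clamped positive.

        Shape (nx, ny, nz, 3); cached after the first call.
        """
        if self._eigvals is None:
            ev = np.linalg.eigvalsh(self.tensors[self.fit_mask])  # ascending
            ev = np.maximum(ev[..., ::-1], EIGENVALUE_FLOOR)
            out = np.zeros(self.fit_mask.shape + (3,), dtype=float)
            out[self.fit_mask] = ev
            self._eigvals = out
        return self._eigvals


def _design_matrix(scheme) -> np.ndarray:
    """(n, 7) design for ln S = X @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
    b = scheme.b_values
    g = scheme.directions
    return np.column_stack(
        [
            np.ones_like(b),
            -b * g[:, 0] ** 2,
            -b * g[:, 1] ** 2,
            -b * g[:, 2] ** 2,
            -2.0 * b * g[:, 0] * g[:, 1],
            -2.0 * b * g[:, 0] * g[:, 2],
            -2.0 * b * g[:, 1] * g[:, 2],
        ]
    )


def fit_dti(dwis: DWIVolumeSet, mask: np.ndarray) -> TensorField:
    """Log-linear weighted least-squares tensor fit.

    An ordinary least-squares pass on ln(S) is followed by one reweighting
    pass with weights equal to the squared predicted signals, the standard
    correction for the log transform's noise heteroscedasticity.  Voxels
    with non-positive signal everywhere are excluded from ``fit_mask``.

    Requires at least 7 volumes spanning 6 non-coplanar directions.
    """
    log = get_logger("params")
    scheme = dwis.scheme
    if len(scheme) < 7:
        raise ValueError("tensor fit needs at least 7 volumes")
    X = _design_matrix(scheme)
    if np.linalg.matrix_rank(X) < 7:
        raise ValueError("gradient scheme does not span 6 independent tensor components")

    mask = np.asarray(mask, dtype=bool)
    Y = dwis.data[mask].astype(float)  # (nv, n)
    ok = np.all(Y > 0, axis=1)
    n_bad = int((~ok).sum())
    if n_bad:
        log.info("excluding %d voxels with non-positive signal from the tensor fit", n_bad)
    Yok = np.log(Y[ok])

    # OLS (shared design): beta = (X^T X)^-1 X^T y
    beta = np.linalg.lstsq(X, Yok.T, rcond=None)[0].T  # (nv_ok, 7)
    # one WLS pass with w = predicted^2
    w = np.exp(2.0 * (beta @ X.T))  # (nv_ok, n)
    XtWX = np.einsum("ni,vn,nj->vij", X, w, X, optimize=True)
    XtWy = np.einsum("ni,vn,vn->vi", X, w, Yok, optimize=True)
    beta = np.linalg.solve(XtWX, XtWy[..., None])[..., 0]

    tensors = np.zeros(mask.shape + (3, 3), dtype=float)
    s0 = np.zeros(mask.shape, dtype=float)
    fit_mask = np.zeros(mask.shape, dtype=bool)
    ii, jj, kk = np.nonzero(mask)
    ii, jj, kk = ii[ok], jj[ok], kk[ok]
    D = np.empty((beta.shape[0], 3, 3), dtype=float)
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]
    tensors[ii, jj, kk] = D
    s0[ii, jj, kk] = np.exp(beta[:, 0])
    fit_mask[ii, jj, kk] = True
    return TensorField(tensors=tensors, s0=s0, fit_mask=fit_mask)


def dti_scalars(tensors: TensorField) -> dict[str, np.ndarray]:
    """FA, MD, AD, RD from the tensor eigenvalues.

    MD = (lam1+lam2+lam3)/3, AD = lam1, RD = (lam2+lam3)/2,
    FA = sqrt(3/2) * ||lam - MD|| / ||lam||.
    """
    ev = tensors.eigenvalues()
    m = tensors.fit_mask
    lam = ev[m]
    md = lam.mean(axis=1)
    num = np.sqrt(((lam - md[:, None]) ** 2).sum(axis=1))
    den = np.sqrt((lam**2).sum(axis=1))
    fa = np.sqrt(1.5) * np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    out = {}
    for name, vals in (
        ("FA", np.clip(fa, 0.0, 1.0)),
        ("MD", md),
        ("AD", lam[:, 0]),
        ("RD", lam[:, 1:].mean(axis=1)),
    ):
        vol = np.zeros(m.shape, dtype=float)
        vol[m] = vals
        out[name] = vol
    return out


def gaussian_zero_displacement(tensors: TensorField, tau: float) -> dict[str, np.ndarray]:
    """RTOP, RTAP, RTPP of the Gaussian propagator at diffusion time ``tau`` (s).

    RTPP = (4 pi tau lam1)^(-1/2)            [mm^-1]
    RTAP = (4 pi tau)^(-1) (lam2 lam3)^(-1/2) [mm^-2]
    RTOP = (4 pi tau)^(-3/2) (lam1 lam2 lam3)^(-1/2) [mm^-3]

    so RTOP = RTAP * RTPP identically.
    """
    if tau <= 0:
        raise ValueError("diffusion time tau must be > 0")
    ev = tensors.eigenvalues()
    m = tensors.fit_mask
    lam = ev[m]
    c = 4.0 * np.pi * tau
    rtpp = (c * lam[:, 0]) ** -0.5
    rtap = (1.0 / c) * (lam[:, 1] * lam[:, 2]) ** -0.5
    rtop = c ** -1.5 * np.prod(lam, axis=1) ** -0.5
    out = {}
    for name, vals in (("RTOP", rtop), ("RTAP", rtap), ("RTPP", rtpp)):
        vol = np.zeros(m.shape, dtype=float)
        vol[m] = vals
        out[name] = vol
    return out


def gaussian_pa(tensors: TensorField) -> dict[str, np.ndarray]:
    """Propagator anisotropy in the Gaussian limit.

    The angular similarity between the voxel propagator and its closest
    isotropic counterpart (same mean diffusivity) is the normalized overlap
    of two zero-mean Gaussians, which reduces to

        cos(theta) = 2^(3/2) (|D| |D_iso|)^(1/4) / |D + D_iso|^(1/2)

    with D_iso = MD * I, and PA = sqrt(1 - cos^2 theta).  The diffusion
    time cancels, so PA is a pure eigenvalue shape measure in [0, 1].  No
    sigmoidal rescaling is applied; any monotone rescaling is irrelevant to
    clustering in normalized feature space.
    """
    ev = tensors.eigenvalues()
    m = tensors.fit_mask
    lam = ev[m]
    md = lam.mean(axis=1)
    det_d = np.prod(lam, axis=1)
    det_iso = md**3
    det_sum = np.prod(lam + md[:, None], axis=1)
    cos = 2.0**1.5 * (det_d * det_iso) ** 0.25 / np.sqrt(det_sum)
    pa = np.sqrt(np.clip(1.0 - cos**2, 0.0, 1.0))
    vol = np.zeros(m.shape, dtype=float)
    vol[m] = pa
    return {"PA": vol}


def compute_parameter_maps(
    tensors: TensorField,
    tau: float,
    names=("FA", "MD", "AD", "RD", "PA", "RTOP", "RTAP", "RTPP"),
) -> dict[str, np.ndarray]:
    """All requested tensor-derived scalar maps on the fit grid.

    NG cannot be derived from a tensor field (it is identically zero in the
    Gaussian limit) and is rejected here; supply it as an external map.
    """
    names = tuple(names)
    if "NG" in names:
        raise ValueError("NG is not derivable from a tensor field; supply it as a map")
    maps: dict[str, np.ndarray] = {}
    if {"FA", "MD", "AD", "RD"} & set(names):
        maps.update(dti_scalars(tensors))
    if {"RTOP", "RTAP", "RTPP"} & set(names):
        maps.update(gaussian_zero_displacement(tensors, tau))
    if "PA" in names:
        maps.update(gaussian_pa(tensors))
    return {k: maps[k] for k in names}
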