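"""Tensor fitting and the Gaussian-limit propagator scalars."""

import numpy as np
import pytest

from cytoseg.diffusion_params import (TensorField, compute_parameter_maps,
                                      dti_scalars, fit_dti, gaussian_pa,
                                      gaussian_zero_displacement)
from cytoseg.io_core import (DWIVolumeSet, GradientScheme, VolumeGrid,
                             make_multishell_scheme)


def _field_from_eigvals(lams, rotations=None):
    """A (n,1,1) tensor field with the given eigenvalue triples."""
    lams = np.atleast_2d(lams)
    n = lams.shape[0]
    tensors = np.zeros((n, 1, 1, 3, 3))
    for i, lam in enumerate(lams):
        D = np.diag(lam)
        if rotations is not None:
            R = rotations[i]
            D = R @ D @ R.T
        tensors[i, 0, 0] = D
    mask = np.ones((n, 1, 1), dtype=bool)
    return TensorField(tensors=tensors, s0=np.ones((n, 1, 1)), fit_mask=mask)


def _random_rotations(n, seed):
    from scipy.spatial.transform import Rotation

    return Rotation.random(n, rng=np.random.default_rng(seed)).as_matrix()


def _simulate(D, scheme, shape=(2, 2, 2)):
    data = np.empty(shape + (len(scheme),))
    adc = np.einsum("ni,ij,nj->n", scheme.directions, D, scheme.directions)
    data[...] = np.exp(-scheme.b_values * adc)
    grid = VolumeGrid.isotropic(shape, 0.2)
    return DWIVolumeSet(data=data, scheme=scheme, grid=grid)


class TestFitDti:
    def test_noiseless_recovery(self):
        """Log-linear WLS is exact on noise-free monoexponential data."""
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        scheme = make_multishell_scheme((100.0, 1000.0), (3, 9))
        dwis = _simulate(D, scheme)
        fit = fit_dti(dwis, np.ones((2, 2, 2), bool))
        np.testing.assert_allclose(fit.tensors[0, 0, 0], D, rtol=1e-6,
                                   atol=1e-12)

    def test_isotropic_fa_zero(self):
        D = np.eye(3) * 1e-3
        scheme = make_multishell_scheme((100.0, 1000.0), (3, 9))
        fit = fit_dti(_simulate(D, scheme), np.ones((2, 2, 2), bool))
        fa = dti_scalars(fit)["FA"]
        assert np.abs(fa).max() < 1e-6

    def test_high_b_shells_no_overflow(self):
        """The full protocol reaches b = 10,000 s/mm^2; the fit must stay
        finite and accurate."""
        D = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        scheme = make_multishell_scheme()
        fit = fit_dti(_simulate(D, scheme), np.ones((2, 2, 2), bool))
        assert np.isfinite(fit.tensors).all()
        np.testing.assert_allclose(fit.tensors[0, 0, 0], D, rtol=1e-6,
                                   atol=1e-12)

    def test_insufficient_volumes_rejected(self):
        scheme = GradientScheme(np.full(6, 1000.0),
                                np.tile([1.0, 0, 0], (6, 1)))
        dwis = _simulate(np.eye(3) * 1e-3, scheme)
        with pytest.raises(ValueError):
            fit_dti(dwis, np.ones((2, 2, 2), bool))

    def test_zero_signal_voxels_excluded(self):
        scheme = make_multishell_scheme((100.0, 1000.0), (3, 9))
        dwis = _simulate(np.eye(3) * 1e-3, scheme)
        dwis.data[0, 0, 0] = 0.0
        fit = fit_dti(dwis, np.ones((2, 2, 2), bool))
        assert not fit.fit_mask[0, 0, 0]
        assert fit.fit_mask.sum() == 7


class TestDtiScalars:
    def test_prolate_tensor_values(self):
        """lam = (1.7, 0.3, 0.3)e-3: MD = 0.7667e-3, FA = 0.8084."""
        tf = _field_from_eigvals([[1.7e-3, 0.3e-3, 0.3e-3]])
        s = dti_scalars(tf)
        assert s["MD"][0, 0, 0] == pytest.approx(0.76667e-3, rel=1e-4)
        assert s["AD"][0, 0, 0] == pytest.approx(1.7e-3)
        assert s["RD"][0, 0, 0] == pytest.approx(0.3e-3)
        lam = np.array([1.7, 0.3, 0.3]) * 1e-3
        md = lam.mean()
        fa_ref = np.sqrt(1.5 * ((lam - md) ** 2).sum() / (lam**2).sum())
        assert fa_ref == pytest.approx(0.7990, abs=5e-4)
        assert s["FA"][0, 0, 0] == pytest.approx(fa_ref, rel=1e-10)

    def test_rotation_invariance(self):
        lam = [1.4e-3, 0.6e-3, 0.2e-3]
        rots = _random_rotations(20, seed=5)
        tf = _field_from_eigvals([lam] * 20, rotations=rots)
        for name, vol in dti_scalars(tf).items():
            vals = vol[tf.fit_mask]
            assert np.abs(vals - vals[0]).max() < 1e-10 * max(1.0, vals[0])


class TestZeroDisplacement:
    def test_isotropic_rtop_closed_form(self):
        """D = 1e-3 mm^2/s at tau = 26 ms: RTOP = (4 pi tau D)^(-3/2)."""
        tf = _field_from_eigvals([[1e-3, 1e-3, 1e-3]])
        maps = gaussian_zero_displacement(tf, tau=0.026)
        expected = (4 * np.pi * 0.026 * 1e-3) ** -1.5
        assert expected == pytest.approx(1.69e5, rel=0.01)
        assert maps["RTOP"][0, 0, 0] == pytest.approx(expected, rel=1e-12)

    def test_rtop_is_rtap_times_rtpp(self):
        rng = np.random.default_rng(2)
        lams = np.sort(rng.uniform(0.1e-3, 2e-3, (50, 3)))[:, ::-1]
        tf = _field_from_eigvals(lams, rotations=_random_rotations(50, 3))
        maps = gaussian_zero_displacement(tf, tau=0.026)
        m = tf.fit_mask
        np.testing.assert_allclose(
            maps["RTOP"][m], (maps["RTAP"] * maps["RTPP"])[m], rtol=1e-10
        )

    def test_invalid_tau(self):
        tf = _field_from_eigvals([[1e-3, 1e-3, 1e-3]])
        with pytest.raises(ValueError):
            gaussian_zero_displacement(tf, tau=0.0)


def _pa_numeric_oracle(lam, n=120, extent=6.0):
    """Propagator anisotropy from grid integration of Gaussian overlaps.

    cos(theta) = <p, p_iso> / (|p| |p_iso|) with p = N(0, 2 tau D); the
    diffusion time cancels, so tau = 0.5 and unit-scale eigenvalues are
    used for numerical convenience.
    """
    lam = np.asarray(lam, float)
    lam = lam / lam.mean()  # scale invariant
    iso = np.full(3, 1.0)
    ax = [np.linspace(-extent * np.sqrt(l), extent * np.sqrt(l), n) for l in
          np.maximum(lam, iso)]
    X = np.meshgrid(*ax, indexing="ij")

    def gauss(cov_diag):
        q = sum(x**2 / c for x, c in zip(X, cov_diag))
        norm = (2 * np.pi) ** 1.5 * np.sqrt(np.prod(cov_diag))
        return np.exp(-0.5 * q) / norm

    p = gauss(lam)
    p_iso = gauss(iso)
    dv = np.prod([a[1] - a[0] for a in ax])
    inner = (p * p_iso).sum() * dv
    cos = inner / np.sqrt((p**2).sum() * dv * (p_iso**2).sum() * dv)
    return float(np.sqrt(max(0.0, 1 - cos**2)))


class TestPropagatorAnisotropy:
    def test_isotropic_pa_zero(self):
        tf = _field_from_eigvals([[1e-3, 1e-3, 1e-3]])
        assert gaussian_pa(tf)["PA"][0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_prolate_pa_against_numeric_overlap(self):
        """lam = (1.7, 0.2, 0.2)e-3 gives PA ~ 0.610; the closed form must
        agree with direct grid integration of the Gaussian overlap."""
        lam = [1.7e-3, 0.2e-3, 0.2e-3]
        tf = _field_from_eigvals([lam])
        pa = gaussian_pa(tf)["PA"][0, 0, 0]
        assert pa == pytest.approx(0.610, abs=5e-3)
        assert pa == pytest.approx(_pa_numeric_oracle(lam), abs=2e-3)

    def test_pa_monotone_in_anisotropy_ratio(self):
        """At fixed MD, PA strictly increases with lam1/lam3 for axially
        symmetric tensors."""
        ratios = np.linspace(1.0, 12.0, 12)
        pas = []
        for rho in ratios:
            lam1 = 3.0e-3 * rho / (rho + 2.0)
            lam_perp = 3.0e-3 / (rho + 2.0)
            tf = _field_from_eigvals([[lam1, lam_perp, lam_perp]])
            pas.append(gaussian_pa(tf)["PA"][0, 0, 0])
        assert all(b > a - 1e-12 for a, b in zip(pas, pas[1:]))
        assert pas[-1] > pas[0]

    def test_rotation_invariance(self):
        lam = [1.5e-3, 0.5e-3, 0.25e-3]
        tf = _field_from_eigvals([lam] * 10,
                                 rotations=_random_rotations(10, 11))
        vals = gaussian_pa(tf)["PA"][tf.fit_mask]
        assert np.abs(vals - vals[0]).max() < 1e-10


class TestComputeParameterMaps:
    def test_ng_rejected(self):
        tf = _field_from_eigvals([[1e-3, 1e-3, 1e-3]])
        with pytest.raises(ValueError, match="NG"):
            compute_parameter_maps(tf, 0.026, names=("FA", "NG"))

    def test_requested_names_returned_in_order(self):
        tf = _field_from_eigvals([[1e-3, 0.5e-3, 0.25e-3]])
        maps = compute_parameter_maps(tf, 0.026, names=("PA", "FA", "RTPP"))
        assert list(maps) == ["PA", "FA", "RTPP"]
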