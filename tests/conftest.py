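"""Shared fixtures: phantoms and geometric masks used across test modules."""

import numpy as np
import pytest

from cytoseg.crf import compute_frame
from cytoseg.io_core import VolumeGrid
from cytoseg.phantom import PhantomSpec, default_spec, make_phantom, sample_observed_params


@pytest.fixture(scope="session")
def default_truth():
    """The standard two-hemisphere study phantom (14 classes, seed 42)."""
    return make_phantom(default_spec(seed=42))


@pytest.fixture(scope="session")
def default_observed(default_truth):
    """Feature maps with the default class-separation-scaled noise."""
    return sample_observed_params(default_truth, seed=43)


@pytest.fixture(scope="session")
def default_frame(default_truth):
    """Equivolume CRF for the default phantom."""
    return compute_frame(
        default_truth.gm_mask, default_truth.wm_mask, default_truth.grid,
        mode="equivolume",
    )


@pytest.fixture(scope="session")
def default_left_features(default_truth, default_observed):
    """Standardized PA/NG/RTAP/RTPP features of the left hemisphere."""
    from cytoseg.clustering import build_feature_matrix

    return build_feature_matrix(
        default_observed, default_truth.gm_mask, default_truth.left_mask
    )


@pytest.fixture(scope="session")
def default_left_gmm(default_left_features):
    """The 14-component mixture fit of the default left hemisphere."""
    from cytoseg.clustering import fit_gmm

    return fit_gmm(default_left_features, 14, seed=44)


@pytest.fixture(scope="session")
def slab_truth():
    """A compact slab phantom for morphology and filter tests."""
    spec = PhantomSpec(
        geometry="slab", hemisphere_shape=(30, 30, 18),
        gm_thickness=10.0, wm_thickness=3.0,
        n_areas=3, n_layer_classes=2, n_classes=5,
        seed=7,
    )
    return make_phantom(spec)


def spherical_shell(n, a, b, voxel=1.0):
    """Grid, radius volume, WM ball and GM shell masks."""
    grid = VolumeGrid.isotropic((n, n, n), voxel)
    c = (n - 1) / 2.0
    ii, jj, kk = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    r = np.sqrt((ii - c) ** 2 + (jj - c) ** 2 + (kk - c) ** 2)
    return grid, r, r < a, (r >= a) & (r < b)


def slab_masks(shape, wm_thickness, gm_thickness, voxel=1.0):
    """Grid and masks for a flat slab: WM below, GM above, background on top."""
    grid = VolumeGrid.isotropic(shape, voxel)
    kk = np.arange(shape[2])[None, None, :] * np.ones(shape)
    wm = kk < wm_thickness
    gm = (kk >= wm_thickness) & (kk < wm_thickness + gm_thickness)
    return grid, wm, gm
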