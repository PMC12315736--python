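"""Voxelwise Gaussian-mixture clustering of normalized scalar features.

Cortical voxels of one hemisphere are clustered purely on their scalar
microstructural parameter values — by construction the model never sees
voxel coordinates, so the segmentation is spatially agnostic and invariant
to any permutation of voxel order.  Features (default PA, NG, RTAP, RTPP)
are z-scored per hemisphere, fitted with a full-covariance Gaussian
mixture by EM (k-means++ initialization, 5 restarts), and the component
count can be selected by the Bayesian Information Criterion.

After fitting, components are reordered lexicographically by their mean
vectors so that label ids are a deterministic function of the fitted
mixture rather than of the initialization path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io_core import VolumeGrid, get_logger

__all__ = ["FeatureMatrix", "GmmResult", "build_feature_matrix", "fit_gmm",
           "select_k_bic", "labels_to_volume"]


@dataclass
class FeatureMatrix:
    """Z-scored voxel-by-feature table for one hemisphere.

    ``values[i]`` are the standardized features of the voxel at
    ``voxel_index[i]``; each column has mean 0 and sd 1 over the included
    voxels.  ``column_means`` / ``column_sds`` retain the raw-unit
    statistics used for the standardization.
    """

    values: np.ndarray          # (n_voxels, n_features)
    voxel_index: np.ndarray     # (n_voxels, 3) int
    feature_names: tuple[str, ...]
    hemisphere: str
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def n_voxels(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class GmmResult:
    """A fitted Gaussian mixture with hard labels in 1..k."""

    k: int
    means: np.ndarray           # (k, d), standardized units
    covariances: np.ndarray     # (k, d, d)
    weights: np.ndarray         # (k,)
    labels: np.ndarray          # (n,) in 1..k
    log_likelihood: float
    bic: float
    converged: bool


def build_feature_matrix(
    params: dict[str, np.ndarray],
    gm_mask: np.ndarray,
    hemisphere_mask: np.ndarray,
    feature_names=("PA", "NG", "RTAP", "RTPP"),
    hemisphere: str = "left",
) -> FeatureMatrix:
    """Extract and z-score features over GM voxels of one hemisphere.

    Voxels with any non-finite feature are excluded (count logged); a
    feature with zero variance over the included voxels is rejected.
    """
    log = get_logger("cluster")
    feature_names = tuple(feature_names)
    for name in feature_names:
        if name not in params:
            raise KeyError(f"requested feature map {name!r} is missing")
    mask = np.asarray(gm_mask, bool) & np.asarray(hemisphere_mask, bool)
    idx = np.column_stack(np.nonzero(mask))
    raw = np.column_stack([params[name][mask] for name in feature_names])
    finite = np.all(np.isfinite(raw), axis=1)
    n_dropped = int((~finite).sum())
    if n_dropped:
        log.info("excluding %d voxels with non-finite features", n_dropped)
        raw, idx = raw[finite], idx[finite]
    if raw.shape[0] == 0:
        raise ValueError("no usable voxels in the requested hemisphere mask")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    zero_var = sds <= 0
    if zero_var.any():
        bad = [feature_names[i] for i in np.nonzero(zero_var)[0]]
        raise ValueError(f"zero-variance feature(s): {', '.join(bad)}")
    values = (raw - means) / sds
    return FeatureMatrix(
        values=values,
        voxel_index=idx,
        feature_names=feature_names,
        hemisphere=hemisphere,
        column_means=means,
        column_sds=sds,
    )


def _canonical_order(gm: GaussianMixture) -> np.ndarray:
    """Component order sorted lexicographically by mean vector."""
    return np.lexsort(gm.means_.T[::-1])


def fit_gmm(features: FeatureMatrix, k: int, seed: int = 0) -> GmmResult:
    """Full-covariance EM fit with ``k`` components.

    k-means++ initialization with 5 restarts keeping the best likelihood,
    diagonal covariance regularization 1e-6, convergence when the change
    in mean log-likelihood falls below 1e-7 (at most 500 iterations).
    Hard labels are maximum-posterior assignments, renumbered through the
    canonical (lexicographic mean) component order.

    The EM fit is run on a canonically *sorted* copy of the rows and the
    labels are then predicted per input row.  EM itself is mathematically
    order-independent, but seeded initialization and floating-point
    summation are not; fitting in a canonical order makes the result —
    parameters, likelihood, BIC and labels — exactly invariant under any
    permutation of the voxel order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = features.values
    if X.shape[0] <= 10 * k * X.shape[1]:
        raise ValueError(
            f"too few voxels ({X.shape[0]}) for k={k} with {X.shape[1]} features"
        )
    Xs = X[np.lexsort(X.T)]
    gm = GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=5,
        init_params="k-means++",
        reg_covar=1e-6,
        tol=1e-7,
        max_iter=500,
        random_state=int(seed),
    )
    gm.fit(Xs)
    raw_labels = gm.predict(X)
    order = _canonical_order(gm)
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    return GmmResult(
        k=k,
        means=gm.means_[order],
        covariances=gm.covariances_[order],
        weights=gm.weights_[order],
        labels=relabel[raw_labels],
        log_likelihood=float(gm.score(Xs) * Xs.shape[0]),
        bic=float(gm.bic(Xs)),
        converged=bool(gm.converged_),
    )


def select_k_bic(
    features: FeatureMatrix, k_range, seed: int = 0
) -> tuple[int, pd.DataFrame, dict[int, GmmResult]]:
    """Fit the mixture for each k and pick the BIC minimum.

    BIC = -2 log L + p ln n with p = (k-1) + k d + k d (d+1) / 2 free
    parameters (mixing weights, means, full covariances).  Returns the
    selected k, the full BIC table for inspection, and the fitted results.
    """
    k_values = sorted(set(int(k) for k in k_range))
    if not k_values:
        raise ValueError("k_range must be non-empty")
    log = get_logger("cluster")
    rows = []
    results: dict[int, GmmResult] = {}
    for k in k_values:
        res = fit_gmm(features, k, seed=seed)
        results[k] = res
        rows.append({"k": k, "bic": res.bic, "log_likelihood": res.log_likelihood,
                     "converged": res.converged})
        log.info("k=%d BIC=%.1f", k, res.bic)
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["bic"].idxmin(), "k"])
    return best_k, table, results


def labels_to_volume(
    result: GmmResult, features: FeatureMatrix, grid: VolumeGrid
) -> np.ndarray:
    """Scatter hard labels back onto the 3D grid (background 0)."""
    vol = np.zeros(grid.shape, dtype=np.int32)
    idx = features.voxel_index
    if idx.max(axis=0).tolist() >= list(grid.shape) or idx.min() < 0:
        raise IndexError("voxel index outside the target grid")
    vol[idx[:, 0], idx[:, 1], idx[:, 2]] = result.labels
    return vol
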