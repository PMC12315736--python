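"""Label harmonization via contingency matrices and optimal assignment.

Cluster labels are arbitrary, so segmentations of the two hemispheres
cannot be compared directly.  The harmonization route goes through a
symmetric reference parcellation: each hemisphere's refined labels are
cross-tabulated against a composite (area x equivolumetric-layer) atlas,
and because the atlas labels are identical across hemispheres, the product
M = C_left^T . C_right is a left-by-right affinity matrix whose entries
accumulate overlap through common atlas cells.  A first Kuhn-Munkres
(Hungarian) round finds the optimal one-to-one matching on M; remaining
labels are then attached greedily, largest first, allowing many-to-one
(there are typically far more data-driven domains than atlas cells).
Relabeling only renames ids — the geometry of every domain is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .crf import equivolume_layers
from .io_core import get_logger

__all__ = ["ContingencyMatrix", "LabelAssignment", "make_layer_atlas",
           "cross_tabulate", "hemisphere_correspondence", "kuhn_munkres_match",
           "harmonize_hemispheres"]


@dataclass
class ContingencyMatrix:
    """Voxel-overlap counts between two label volumes.

    ``counts[i, j]`` is the number of voxels carrying ``row_labels[i]`` in
    segmentation A and ``col_labels[j]`` in segmentation B; background and
    voxels unlabeled in either segmentation are excluded.
    """

    counts: np.ndarray
    row_labels: np.ndarray
    col_labels: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


@dataclass
class LabelAssignment:
    """Row-to-column label matches with overlaps and assignment round."""

    pairs: pd.DataFrame          # columns: row_label, col_label, overlap, round
    unmatched: list

    def mapping(self) -> dict:
        return dict(zip(self.pairs["row_label"], self.pairs["col_label"]))


def make_layer_atlas(
    area_labels: np.ndarray,
    depth: np.ndarray,
    gm_mask: np.ndarray,
    n_layers: int = 6,
) -> np.ndarray:
    """Composite (area, layer) reference labels: ``area_id * 100 + layer``.

    Every GM voxel of a labeled area receives exactly one composite label;
    layers come from equivolumetric depth binning (default six layers).
    The encoding caps layers at 99.
    """
    if n_layers > 99:
        raise ValueError("layer encoding supports at most 99 layers")
    area_labels = np.asarray(area_labels)
    if area_labels.max() * 100 + n_layers >= np.iinfo(np.int32).max:
        raise ValueError("area ids collide with the composite encoding range")
    layers = equivolume_layers(depth, gm_mask, n_layers)
    out = np.zeros(area_labels.shape, dtype=np.int32)
    sel = (area_labels > 0) & (layers > 0)
    out[sel] = area_labels[sel] * 100 + layers[sel]
    return out


def cross_tabulate(
    seg_a: np.ndarray, seg_b: np.ndarray, mask: np.ndarray | None = None
) -> ContingencyMatrix:
    """Two-dimensional label histogram of two segmentations on one grid."""
    seg_a, seg_b = np.asarray(seg_a), np.asarray(seg_b)
    if seg_a.shape != seg_b.shape:
        raise ValueError(f"grid mismatch: {seg_a.shape} vs {seg_b.shape}")
    sel = (seg_a > 0) & (seg_b > 0)
    if mask is not None:
        sel &= np.asarray(mask, bool)
    a, b = seg_a[sel], seg_b[sel]
    row_labels, a_idx = np.unique(a, return_inverse=True)
    col_labels, b_idx = np.unique(b, return_inverse=True)
    counts = np.zeros((row_labels.size, col_labels.size), dtype=np.int64)
    np.add.at(counts, (a_idx, b_idx), 1)
    return ContingencyMatrix(counts=counts, row_labels=row_labels,
                             col_labels=col_labels)


def hemisphere_correspondence(
    c_left: ContingencyMatrix, c_right: ContingencyMatrix
) -> ContingencyMatrix:
    """Left-by-right affinity matrix M = C_left^T . C_right.

    Both contingency matrices must share the identical ordered atlas-label
    list on their rows; otherwise the set difference is reported.
    """
    if (c_left.row_labels.size != c_right.row_labels.size
            or not np.array_equal(c_left.row_labels, c_right.row_labels)):
        only_l = set(c_left.row_labels) - set(c_right.row_labels)
        only_r = set(c_right.row_labels) - set(c_left.row_labels)
        raise ValueError(
            "atlas label lists differ between hemispheres: "
            f"left-only {sorted(only_l)}, right-only {sorted(only_r)}"
        )
    m = c_left.counts.T @ c_right.counts
    return ContingencyMatrix(counts=m, row_labels=c_left.col_labels,
                             col_labels=c_right.col_labels)


def kuhn_munkres_match(
    affinity: np.ndarray,
    row_labels=None,
    col_labels=None,
    row_sizes=None,
) -> LabelAssignment:
    """Match row labels to column labels by maximum total overlap.

    Round 1 solves the rectangular optimal one-to-one assignment
    (Hungarian algorithm, maximizing); zero-affinity pairs in the optimum
    are discarded.  Rows left over are processed in decreasing
    ``row_sizes`` order (row sums by default) and each is attached to its
    largest-overlap column, many-to-one allowed.  Rows whose affinity is
    all zero stay unmatched.
    """
    affinity = np.asarray(affinity)
    if affinity.ndim != 2 or affinity.size == 0:
        raise ValueError("affinity matrix must be 2D and non-empty")
    if (affinity < 0).any():
        raise ValueError("affinity must be non-negative")
    n_rows, n_cols = affinity.shape
    row_labels = np.arange(1, n_rows + 1) if row_labels is None else np.asarray(row_labels)
    col_labels = np.arange(1, n_cols + 1) if col_labels is None else np.asarray(col_labels)
    row_sizes = affinity.sum(axis=1) if row_sizes is None else np.asarray(row_sizes)

    rows = []
    ri, ci = linear_sum_assignment(affinity, maximize=True)
    matched_rows = set()
    for r, c in zip(ri, ci):
        if affinity[r, c] > 0:
            rows.append({"row_label": row_labels[r], "col_label": col_labels[c],
                         "overlap": int(affinity[r, c]), "round": 1})
            matched_rows.add(r)
    leftover = [r for r in range(n_rows) if r not in matched_rows]
    leftover.sort(key=lambda r: -row_sizes[r])
    unmatched = []
    for r in leftover:
        if affinity[r].max() <= 0:
            unmatched.append(row_labels[r])
            continue
        c = int(np.argmax(affinity[r]))
        rows.append({"row_label": row_labels[r], "col_label": col_labels[c],
                     "overlap": int(affinity[r, c]), "round": 2})
    pairs = pd.DataFrame(rows, columns=["row_label", "col_label", "overlap", "round"])
    return LabelAssignment(pairs=pairs, unmatched=unmatched)


def harmonize_hemispheres(
    left_labels: np.ndarray,
    right_labels: np.ndarray,
    layer_atlas: np.ndarray,
    mask_left: np.ndarray,
    mask_right: np.ndarray,
) -> tuple[np.ndarray, LabelAssignment, ContingencyMatrix]:
    """Rename right-hemisphere labels onto the left hemisphere's ids.

    Builds the per-hemisphere atlas contingency matrices, forms
    M = C_L^T C_R, matches right labels (rows of M^T) to left labels, and
    rewrites the right-hemisphere volume accordingly.  Right labels that
    find no atlas-mediated overlap keep fresh ids beyond the left range.
    Label geometry is untouched — only ids change.
    """
    log = get_logger("match")
    c_left = cross_tabulate(layer_atlas, left_labels, mask_left)
    c_right = cross_tabulate(layer_atlas, right_labels, mask_right)
    m = hemisphere_correspondence(c_left, c_right)

    right_sizes_all = {int(l): int(c) for l, c in
                       zip(*np.unique(right_labels[right_labels > 0],
                                      return_counts=True))}
    sizes = np.array([right_sizes_all.get(int(l), 0) for l in m.col_labels])
    assignment = kuhn_munkres_match(
        m.counts.T, row_labels=m.col_labels, col_labels=m.row_labels,
        row_sizes=sizes,
    )

    mapping = assignment.mapping()  # right label -> left label
    out = np.asarray(right_labels).copy()
    next_free = int(max(np.max(left_labels), 0)) + 1
    for right_id in np.unique(right_labels):
        if right_id == 0:
            continue
        if right_id in mapping:
            new_id = int(mapping[right_id])
        else:
            new_id = next_free
            next_free += 1
            log.info("right label %d had no atlas overlap; assigned fresh id %d",
                     right_id, new_id)
        out[right_labels == right_id] = new_id
    return out, assignment, m
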