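"""Segmentation quality against ground truth: Dice, ARI, boundary distance.

Label ids of an unsupervised segmentation are arbitrary, so Dice scores
are computed after matching predicted to true labels by maximum overlap
(Hungarian assignment on the contingency matrix).  The adjusted Rand
index compares the raw partitions and needs no matching.  Boundary
distance is the symmetric mean surface distance between the 6-neighbor
label-interface voxel sets, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from sklearn.metrics import adjusted_rand_score

from .io_core import VolumeGrid
from .matching import cross_tabulate, kuhn_munkres_match

__all__ = ["SegmentationScore", "score_against_truth", "boundary_voxels",
           "boundary_distance_mm"]

_FACE_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


@dataclass
class SegmentationScore:
    dice_per_label: dict
    mean_dice: float
    ari: float
    boundary_distance: float   # mm


def boundary_voxels(labels: np.ndarray) -> np.ndarray:
    """Voxels whose 6-neighborhood contains a *different non-zero* label.

    Interfaces with background do not count, so a single uniform label has
    an empty boundary set.  The set is invariant under label renaming.
    """
    labels = np.asarray(labels)
    out = np.zeros(labels.shape, dtype=bool)
    for off in _FACE_OFFSETS:
        shifted = np.full_like(labels, 0)
        src = tuple(
            slice(max(-o, 0), labels.shape[d] - max(o, 0)) for d, o in enumerate(off)
        )
        dst = tuple(
            slice(max(o, 0), labels.shape[d] - max(-o, 0)) for d, o in enumerate(off)
        )
        shifted[dst] = labels[src]
        out |= (labels != 0) & (shifted != 0) & (labels != shifted)
    return out


def boundary_distance_mm(
    labels_a: np.ndarray, labels_b: np.ndarray, grid: VolumeGrid
) -> float:
    """Symmetric mean surface distance between two boundary voxel sets.

    Zero iff the sets coincide; symmetric in its arguments.  Returns NaN
    when either segmentation has no internal boundary.
    """
    ba = boundary_voxels(labels_a)
    bb = boundary_voxels(labels_b)
    if not ba.any() or not bb.any():
        return float("nan")
    vox = grid.voxel_size
    d_to_b = ndi.distance_transform_edt(~bb, sampling=vox)
    d_to_a = ndi.distance_transform_edt(~ba, sampling=vox)
    return float(0.5 * (d_to_b[ba].mean() + d_to_a[bb].mean()))


def score_against_truth(
    pred: np.ndarray, truth: np.ndarray, grid: VolumeGrid
) -> SegmentationScore:
    """Dice (after label matching), ARI, and boundary distance vs truth.

    ARI is evaluated over voxels labeled in the truth (unpredicted voxels
    count as one extra predicted class).  Dice per truth label uses the
    overlap-optimal one-to-one matching; unmatched truth labels score 0.
    """
    pred, truth = np.asarray(pred), np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"grid mismatch: {pred.shape} vs {truth.shape}")
    sel = truth > 0
    ari = float(adjusted_rand_score(truth[sel], pred[sel]))

    dice: dict = {}
    if ((pred > 0) & sel).any():
        ct = cross_tabulate(truth, pred)
        assignment = kuhn_munkres_match(
            ct.counts, row_labels=ct.row_labels, col_labels=ct.col_labels
        )
        round1 = assignment.pairs[assignment.pairs["round"] == 1]
        truth_sizes = {int(l): int(c) for l, c in
                       zip(*np.unique(truth[sel], return_counts=True))}
        pred_sizes = {int(l): int(c) for l, c in
                      zip(*np.unique(pred[pred > 0], return_counts=True))}
        matched = {}
        for rec in round1.itertuples():
            t, p, ov = int(rec.row_label), int(rec.col_label), int(rec.overlap)
            matched[t] = 2.0 * ov / (truth_sizes[t] + pred_sizes[p])
        dice = {t: matched.get(t, 0.0) for t in truth_sizes}
    mean_dice = float(np.mean(list(dice.values()))) if dice else 0.0
    bd = boundary_distance_mm(pred, truth, grid)
    return SegmentationScore(
        dice_per_label=dice, mean_dice=mean_dice, ari=ari, boundary_distance=bd
    )
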