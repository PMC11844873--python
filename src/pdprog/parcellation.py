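"""Atlas handling: merging label images, nearest-neighbour label resampling,
regional mean extraction, and centroid-based region naming.

The study design merges a cortical parcellation with cerebellar and striatal
parts (e.g. 100 + 28 + 7 = 135 ROIs) into one custom atlas, resamples it to
the feature-map grid, and averages each map within every label.  Region names
for reporting are assigned by locating each ROI's world-space centroid in a
reference atlas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import Image3D, LabelAtlas, check_same_grid

__all__ = [
    "RegionalFeatures",
    "merge_atlases",
    "resample_labels",
    "extract_regional_means",
    "name_regions_by_centroid",
]

logger = logging.getLogger(__name__)


@dataclass
class RegionalFeatures:
    """Label-ordered regional means for one participant and feature type."""

    values: pd.Series  # index = label ids, values = regional means (NaN if empty)
    feature_type: str = "reho"
    participant: str | None = None
    empty_labels: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.feature_type not in ("reho", "falff", "alff"):
            raise ValueError(f"unknown feature_type {self.feature_type!r}")

    def as_named(self, atlas: LabelAtlas, prefix: str | None = None) -> pd.Series:
        """Series keyed by '<feature_type>_<region name>'."""
        prefix = prefix or self.feature_type
        return pd.Series(
            self.values.to_numpy(),
            index=[f"{prefix}_{atlas.labels[int(lab)]}" for lab in self.values.index],
        )


def merge_atlases(
    parts: list[LabelAtlas], overlap_policy: str = "later_overwrites"
) -> LabelAtlas:
    """Merge label images in order, offsetting each part's labels by the
    cumulative label count of the preceding parts.

    Overlapping voxels are resolved by ``overlap_policy``: the default lets a
    later part overwrite earlier ones (the overlap volume is logged);
    ``first_wins`` keeps the earlier assignment.
    """
    if not parts:
        raise ValueError("need at least one atlas part")
    if overlap_policy not in ("later_overwrites", "first_wins"):
        raise ValueError(f"unknown overlap_policy {overlap_policy!r}")
    ref = parts[0]
    for p in parts[1:]:
        check_same_grid(ref, p, "atlas parts (resample first)")

    out = np.zeros(ref.shape, dtype=np.int32)
    labels: dict[int, str] = {}
    offset = 0
    total_overlap = 0
    for part in parts:
        part_ids = part.label_ids
        remap = {old: offset + i + 1 for i, old in enumerate(part_ids)}
        shifted = np.zeros_like(out)
        for old, new in remap.items():
            shifted[part.data == old] = new
        overlap = (out > 0) & (shifted > 0)
        total_overlap += int(overlap.sum())
        if overlap_policy == "later_overwrites":
            out = np.where(shifted > 0, shifted, out)
        else:
            out = np.where(out > 0, out, shifted)
        for old, new in remap.items():
            labels[new] = part.labels[old]
        offset += len(part_ids)
    if total_overlap:
        logger.info("merge_atlases: %d overlapping voxels resolved by %s", total_overlap, overlap_policy)
    merged = LabelAtlas(out, ref.affine, labels)
    merged.overlap_voxels = total_overlap  # audit trail
    return merged


def _world_coords(shape: tuple[int, int, int], affine: np.ndarray) -> np.ndarray:
    """World (mm) coordinates of every voxel centre; shape (*grid, 3)."""
    ijk = np.stack(np.indices(shape), axis=-1).astype(float)
    return ijk @ affine[:3, :3].T + affine[:3, 3]


def resample_labels(
    atlas: LabelAtlas, target_shape: tuple[int, int, int], target_affine: np.ndarray
) -> LabelAtlas:
    """Nearest-neighbour resampling of a label image onto a target grid.

    Each target voxel takes the label of the nearest source voxel centre
    (world coordinates through both affines); exact half-distance ties
    resolve to the higher source index.  Target voxels whose nearest source
    index falls outside the source grid become background; no new labels are
    created.
    """
    target_affine = np.asarray(target_affine, dtype=float)
    if abs(np.linalg.det(target_affine[:3, :3])) < 1e-12:
        raise ValueError("degenerate target affine")
    world = _world_coords(tuple(target_shape), target_affine)  # (*tgt, 3)
    inv = np.linalg.inv(atlas.affine)
    src_idx = world @ inv[:3, :3].T + inv[:3, 3]
    nearest = np.floor(src_idx + 0.5).astype(int)
    inside = np.ones(tuple(target_shape), dtype=bool)
    for axis in range(3):
        inside &= (nearest[..., axis] >= 0) & (nearest[..., axis] < atlas.shape[axis])
    out = np.zeros(tuple(target_shape), dtype=np.int32)
    nz = np.nonzero(inside)
    out[nz] = atlas.data[nearest[..., 0][nz], nearest[..., 1][nz], nearest[..., 2][nz]]
    present = set(int(v) for v in np.unique(out)) - {0}
    return LabelAtlas(out, target_affine, {k: atlas.labels[k] for k in sorted(present)})


def extract_regional_means(
    map3d: Image3D,
    atlas: LabelAtlas,
    feature_type: str = "reho",
    participant: str | None = None,
) -> RegionalFeatures:
    """Mean of the map within each atlas label.

    Labels without any voxel on this grid are flagged and reported as NaN
    (missing), to be handled by the modelling layer's imputation policy.
    """
    check_same_grid(map3d, atlas, "map/atlas (resample_labels first)")
    ids = atlas.label_ids
    counts = ndimage.sum_labels(np.ones(atlas.shape), labels=atlas.data, index=ids)
    sums = ndimage.sum_labels(map3d.data, labels=atlas.data, index=ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)
    empty = [int(lab) for lab, c in zip(ids, counts) if c == 0]
    return RegionalFeatures(
        pd.Series(means, index=ids), feature_type=feature_type,
        participant=participant, empty_labels=empty,
    )


def name_regions_by_centroid(atlas: LabelAtlas, reference: LabelAtlas) -> dict[int, str]:
    """Name each atlas label by its world-space centroid in a reference atlas.

    If a label's centroid falls inside a nonzero reference label, that name is
    used; otherwise the name of the nearest nonzero reference voxel (Euclidean
    distance in mm) is taken, with exact ties going to the lower reference
    label.
    """
    ref_nonzero = np.nonzero(reference.data > 0)
    if len(ref_nonzero[0]) == 0:
        raise ValueError("reference atlas has no labelled voxels")
    ref_world = (
        np.stack(ref_nonzero, axis=1).astype(float) @ reference.affine[:3, :3].T
        + reference.affine[:3, 3]
    )
    ref_labels = reference.data[ref_nonzero]
    inv_ref = np.linalg.inv(reference.affine)

    names: dict[int, str] = {}
    for lab in atlas.label_ids:
        voxels = np.stack(np.nonzero(atlas.data == lab), axis=1).astype(float)
        if voxels.size == 0:
            continue
        centroid_ijk = voxels.mean(axis=0)
        centroid_world = centroid_ijk @ atlas.affine[:3, :3].T + atlas.affine[:3, 3]
        # direct hit: reference voxel containing the centroid
        ref_ijk = np.rint(centroid_world @ inv_ref[:3, :3].T + inv_ref[:3, 3]).astype(int)
        if all(0 <= ref_ijk[a] < reference.shape[a] for a in range(3)):
            hit = int(reference.data[tuple(ref_ijk)])
            if hit > 0:
                names[lab] = reference.labels[hit]
                continue
        dist = np.linalg.norm(ref_world - centroid_world, axis=1)
        order = np.lexsort((ref_labels, dist))  # nearest, then lower label on ties
        names[lab] = reference.labels[int(ref_labels[order[0]])]
    return names
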