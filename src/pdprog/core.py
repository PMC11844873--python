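"""Core in-memory containers for volumetric data.

Thin, validated wrappers around numpy arrays plus the NIfTI affine, used by
every stage of the pipeline.  I/O goes through nibabel; label atlases carry a
sidecar label table (TSV with columns ``label``, ``name``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["Image3D", "Image4D", "BrainMask", "LabelAtlas"]


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class Image3D:
    """A 3D scalar map (e.g. a ReHo or fALFF map) in voxel space."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got shape {self.data.shape}")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @classmethod
    def from_nifti(cls, path: str | Path) -> "Image3D":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj, dtype=float), img.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float64), self.affine), str(path))


@dataclass
class Image4D:
    """A 4D fMRI volume: X x Y x Z x T array, affine, repetition time (s)."""

    data: np.ndarray
    affine: np.ndarray
    repetition_time: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        self.affine = _check_affine(self.affine)
        if not self.repetition_time > 0:
            raise ValueError("repetition_time must be positive")

    @property
    def shape(self) -> tuple[int, int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]  # type: ignore[return-value]

    @classmethod
    def from_nifti(cls, path: str | Path, repetition_time: float | None = None) -> "Image4D":
        """Load a 4D NIfTI; TR defaults to the header's time-axis spacing."""
        img = nib.load(str(path))
        if repetition_time is None:
            zooms = img.header.get_zooms()
            if len(zooms) < 4 or zooms[3] <= 0:
                raise ValueError("NIfTI header carries no time-axis spacing; pass repetition_time")
            repetition_time = float(zooms[3])
        return cls(np.asarray(img.dataobj, dtype=float), img.affine, repetition_time)

    def to_nifti(self, path: str | Path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.float64), self.affine)
        zooms = list(img.header.get_zooms())
        zooms[3] = self.repetition_time
        img.header.set_zooms(zooms)
        nib.save(img, str(path))


@dataclass
class BrainMask:
    """Binary brain mask with at least one in-mask voxel."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) != 0
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D mask, got shape {self.data.shape}")
        if not self.data.any():
            raise ValueError("mask is empty")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def from_nifti(cls, path: str | Path) -> "BrainMask":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj) != 0, img.affine)

    def to_nifti(self, path: str | Path) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.uint8), self.affine), str(path))


@dataclass
class LabelAtlas:
    """Integer ROI map (0 = background) with a label -> name table."""

    data: np.ndarray
    affine: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label map, got shape {self.data.shape}")
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("label map must hold integers")
            self.data = rounded.astype(np.int32)
        if (self.data < 0).any():
            raise ValueError("labels must be non-negative")
        self.affine = _check_affine(self.affine)
        present = set(int(v) for v in np.unique(self.data)) - {0}
        if not self.labels:
            self.labels = {lab: f"region_{lab}" for lab in sorted(present)}
        missing = present - set(self.labels)
        if missing:
            raise ValueError(f"voxel labels missing from label table: {sorted(missing)}")
        self.labels = {int(k): str(v) for k, v in sorted(self.labels.items())}

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.labels)

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def mask(self) -> BrainMask:
        """Brain mask covering all labelled voxels."""
        return BrainMask(self.data > 0, self.affine)

    @classmethod
    def from_nifti(cls, path: str | Path, label_table: str | Path | None = None) -> "LabelAtlas":
        img = nib.load(str(path))
        labels: dict[int, str] = {}
        if label_table is not None:
            table = pd.read_csv(label_table, sep="\t")
            labels = dict(zip(table["label"].astype(int), table["name"].astype(str)))
        return cls(np.asarray(img.dataobj).astype(np.int32), img.affine, labels)

    def to_nifti(self, path: str | Path, label_table: str | Path | None = None) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))
        if label_table is not None:
            pd.DataFrame(
                {"label": self.label_ids, "name": [self.labels[k] for k in self.label_ids]}
            ).to_csv(label_table, sep="\t", index=False)


def check_same_grid(a, b, what: str = "inputs") -> None:
    """Raise if two volumetric objects disagree on grid shape or affine."""
    sa = a.shape[:3] if hasattr(a, "shape") else None
    sb = b.shape[:3] if hasattr(b, "shape") else None
    if sa != sb:
        raise ValueError(f"{what}: grid shapes differ ({sa} vs {sb})")
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError(f"{what}: affines differ")
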