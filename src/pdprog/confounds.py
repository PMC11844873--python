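"""Motion quality control and one-step nuisance regression.

Framewise displacement (FD) summarises head motion per volume as the sum of
absolute volume-to-volume changes of the six rigid-body parameters, with
rotations converted to arc displacement on a 50 mm sphere.  Nuisance signals
(motion parameters, tissue mean timeseries, component regressors) are
concatenated into a single design matrix and regressed out of every voxel
timeseries in one ordinary-least-squares step; no volume censoring is
performed, FD is reporting-only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import BrainMask, Image4D, check_same_grid

__all__ = [
    "MotionParams",
    "ConfoundMatrix",
    "FDSeries",
    "framewise_displacement",
    "mean_mask_timeseries",
    "regress_confounds",
]

FD_FLAG_THRESHOLD_MM = 0.55  # lenient mean-FD screening threshold


@dataclass
class MotionParams:
    """T x 6 rigid-body motion trace.

    ``convention`` declares column order: 3 translations (mm) then 3 rotations
    (radians), or the reverse.
    """

    trace: np.ndarray
    convention: str = "translations_first"

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.trace.ndim != 2 or self.trace.shape[1] != 6:
            raise ValueError(f"trace must be T x 6, got {self.trace.shape}")
        if self.trace.shape[0] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.convention not in ("translations_first", "rotations_first"):
            raise ValueError(f"unknown convention {self.convention!r}")

    @property
    def translations(self) -> np.ndarray:
        return self.trace[:, :3] if self.convention == "translations_first" else self.trace[:, 3:]

    @property
    def rotations(self) -> np.ndarray:
        return self.trace[:, 3:] if self.convention == "translations_first" else self.trace[:, :3]

    @classmethod
    def from_text(cls, path: str | Path, convention: str = "translations_first") -> "MotionParams":
        return cls(np.loadtxt(path), convention)

    def to_text(self, path: str | Path) -> None:
        np.savetxt(path, self.trace, fmt="%.10g")


@dataclass
class FDSeries:
    """Framewise displacement: T-1 non-negative values in mm plus summaries."""

    values: np.ndarray
    rotation_radius: float = 50.0
    rotation_scale: str = "radius"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if (self.values < 0).any():
            raise ValueError("FD values must be non-negative")

    @property
    def mean(self) -> float:
        return float(self.values.mean()) if self.values.size else 0.0

    @property
    def high_motion(self) -> bool:
        return self.mean > FD_FLAG_THRESHOLD_MM


def framewise_displacement(
    motion: MotionParams, radius: float = 50.0, rotation_scale: str = "radius"
) -> FDSeries:
    """FD_t = sum |delta translation| + scale * sum |delta rotation|.

    ``rotation_scale='radius'`` uses the standard arc-length approximation
    (displacement = radius * angle); ``'two_pi_radius'`` multiplies by
    2*pi*radius instead, a circumference-based variant found in some reports.
    """
    if not np.isfinite(motion.trace).all():
        raise ValueError("motion parameters contain non-finite values")
    if rotation_scale == "radius":
        scale = radius
    elif rotation_scale == "two_pi_radius":
        scale = 2.0 * np.pi * radius
    else:
        raise ValueError(f"unknown rotation_scale {rotation_scale!r}")
    d_trans = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    d_rot = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
    return FDSeries(d_trans + scale * d_rot, rotation_radius=radius, rotation_scale=rotation_scale)


def mean_mask_timeseries(img: Image4D, tissue_mask: BrainMask) -> np.ndarray:
    """Arithmetic mean over in-mask voxels at each timepoint."""
    check_same_grid(img, tissue_mask, "image/tissue mask")
    return img.data[tissue_mask.data].mean(axis=0)


@dataclass
class ConfoundMatrix:
    """Named T x C matrix of nuisance regressors."""

    columns: pd.DataFrame
    includes_intercept: bool = False

    def __post_init__(self) -> None:
        if not isinstance(self.columns, pd.DataFrame):
            self.columns = pd.DataFrame(np.asarray(self.columns, dtype=float))
            self.columns.columns = [f"confound_{i}" for i in range(self.columns.shape[1])]
        values = self.columns.to_numpy(dtype=float)
        if values.shape[1] >= values.shape[0]:
            raise ValueError("need fewer confound columns than timepoints")
        zero = (values == 0).all(axis=0)
        if zero.any():
            names = list(self.columns.columns[zero])
            raise ValueError(f"constant-zero confound column(s): {names}")

    @property
    def n_timepoints(self) -> int:
        return self.columns.shape[0]

    @property
    def names(self) -> list[str]:
        return list(self.columns.columns)

    def values(self) -> np.ndarray:
        return self.columns.to_numpy(dtype=float)

    @classmethod
    def concatenate(cls, named: dict[str, np.ndarray]) -> "ConfoundMatrix":
        """Build a single matrix from named blocks (1D series or 2D blocks)."""
        frames = {}
        for name, block in named.items():
            arr = np.asarray(block, dtype=float)
            if arr.ndim == 1:
                frames[name] = arr
            else:
                for j in range(arr.shape[1]):
                    frames[f"{name}_{j}"] = arr[:, j]
        return cls(pd.DataFrame(frames))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConfoundMatrix":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.columns.to_csv(path, sep="\t", index=False)


def regress_confounds(
    img: Image4D, confounds: ConfoundMatrix, mask: BrainMask | None = None
) -> Image4D:
    """Residualise every voxel timeseries on [intercept | confounds] jointly.

    A single OLS fit removes all confounds at once; an intercept is always
    included, so residuals are mean-zero.  A rank-deficient design is reported
    (listing the colliding columns) and handled via pseudoinverse.
    """
    if confounds.n_timepoints != img.n_timepoints:
        raise ValueError(
            f"confounds have {confounds.n_timepoints} timepoints, image has {img.n_timepoints}"
        )
    c = confounds.values()
    if not np.isfinite(c).all():
        raise ValueError("confound columns contain non-finite values")
    t = img.n_timepoints
    design = np.column_stack([np.ones(t), c])
    if design.shape[1] >= t:
        raise ValueError("design has as many columns as timepoints; regression degenerate")

    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        colliding = _colliding_columns(confounds)
        warnings.warn(
            f"rank-deficient confound design (rank {rank} < {design.shape[1]}); "
            f"near-collinear columns: {colliding}; proceeding via pseudoinverse",
            stacklevel=2,
        )

    if mask is None:
        flat = img.data.reshape(-1, t).T  # (T, V)
        beta = np.linalg.pinv(design) @ flat
        resid = flat - design @ beta
        out = resid.T.reshape(img.shape)
    else:
        check_same_grid(img, mask, "image/mask")
        flat = img.data[mask.data].T  # (T, V)
        beta = np.linalg.pinv(design) @ flat
        resid = flat - design @ beta
        out = np.zeros(img.shape)
        out[mask.data] = resid.T
    return Image4D(out, img.affine, img.repetition_time)


def _colliding_columns(confounds: ConfoundMatrix) -> list[tuple[str, str]]:
    values = confounds.values()
    names = confounds.names
    centred = values - values.mean(axis=0)
    norms = np.linalg.norm(centred, axis=0)
    norms[norms == 0] = 1.0
    corr = (centred / norms).T @ (centred / norms)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 1 - 1e-8:
                pairs.append((names[i], names[j]))
    return pairs


def qc_report(
    fd_by_participant: dict[str, FDSeries], path: str | Path | None = None
) -> dict:
    """Summarise FD per participant; optionally write a JSON QC report."""
    report = {
        "fd_threshold_mm": FD_FLAG_THRESHOLD_MM,
        "participants": {
            pid: {
                "mean_fd_mm": fd.mean,
                "max_fd_mm": float(fd.values.max()) if fd.values.size else 0.0,
                "high_motion": fd.high_motion,
            }
            for pid, fd in fd_by_participant.items()
        },
    }
    means = [fd.mean for fd in fd_by_participant.values()]
    report["mean_fd_across_participants_mm"] = float(np.mean(means)) if means else 0.0
    report["n_flagged"] = sum(fd.high_motion for fd in fd_by_participant.values())
    if path is not None:
        Path(path).write_text(json.dumps(report, indent=2))
    return report
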