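"""Voxelwise resting-state fMRI features: ReHo, ALFF, fALFF, and z-scored maps.

Regional homogeneity (ReHo) is Kendall's coefficient of concordance W between
a voxel's timeseries and those of its neighbours (up to 27-voxel neighbourhood
including the centre).  ALFF is the standard deviation of the linearly
detrended, band-passed (0.01-0.1 Hz by default) signal; fALFF divides ALFF by
the standard deviation of the unfiltered signal, making it (with an ideal
filter) the square root of the in-band power fraction.  Maps are z-scored at
the participant level within the brain mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal
from scipy.stats import rankdata

from .core import BrainMask, Image3D, Image4D, check_same_grid

__all__ = [
    "ReHoParams",
    "SpectralParams",
    "kendall_w",
    "compute_reho",
    "compute_alff_falff",
    "zscore_map",
]

DEFAULT_BAND = (0.01, 0.1)


@dataclass
class ReHoParams:
    """Neighbourhood and tie handling for ReHo.

    neighborhood_size counts the centre voxel plus face (7), face+edge (19) or
    face+edge+corner (27) neighbours.  Edge voxels use the in-mask subset of
    the neighbourhood; voxels with fewer than ``min_neighbors`` in-mask
    neighbours (centre excluded) are set to 0.
    """

    neighborhood_size: int = 27
    min_neighbors: int = 2
    tie_policy: str = "midrank_no_correction"

    def __post_init__(self) -> None:
        if self.neighborhood_size not in (7, 19, 27):
            raise ValueError("neighborhood_size must be one of 7, 19, 27")
        if self.min_neighbors < 2:
            raise ValueError("min_neighbors must be >= 2")
        if self.tie_policy not in ("midrank_no_correction", "midrank_tie_correction"):
            raise ValueError(f"unknown tie_policy {self.tie_policy!r}")


@dataclass
class SpectralParams:
    """Band and filter choices for ALFF/fALFF."""

    band: tuple[float, float] = DEFAULT_BAND
    detrend: str = "linear"
    filter: str = "fft_ideal"
    falff_denominator: str = "detrended_unfiltered"
    eps: float = 1e-12

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not (0 <= lo < hi):
            raise ValueError(f"invalid band {self.band}")
        if self.detrend != "linear":
            raise ValueError("only linear detrending is supported")
        if self.filter not in ("fft_ideal", "butterworth"):
            raise ValueError(f"unknown filter {self.filter!r}")
        if self.falff_denominator not in ("detrended_unfiltered", "raw"):
            raise ValueError(f"unknown falff_denominator {self.falff_denominator!r}")


def _neighborhood_offsets(size: int) -> np.ndarray:
    offs = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
    ]
    if size == 7:
        offs = [o for o in offs if sum(abs(c) for c in o) <= 1]
    elif size == 19:
        offs = [o for o in offs if sum(abs(c) for c in o) <= 2]
    return np.array(offs, dtype=int)


def _tie_term(series: np.ndarray) -> float:
    """Sum over tie groups of (t^3 - t) for one series."""
    _, counts = np.unique(series, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float((t**3 - t).sum())


def kendall_w(block: np.ndarray, tie_policy: str = "midrank_no_correction") -> float:
    """Kendall's coefficient of concordance of a K x n timeseries block.

    Each of the K series is rank-transformed over its n timepoints (midranks
    for ties); W = 12 S / (K^2 (n^3 - n) - K * tie_term), where S is the sum of
    squared deviations of the per-timepoint rank sums from their mean.  The
    tie term is included only under ``midrank_tie_correction``.  An
    all-constant block has no defined W; 0 is returned with a warning.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2:
        raise ValueError("block must be 2D (K series x n timepoints)")
    k, n = block.shape
    if k < 2 or n < 2:
        raise ValueError("need K >= 2 series and n >= 2 timepoints")
    ranks = rankdata(block, axis=1)
    rank_sums = ranks.sum(axis=0)
    s = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    denom = k**2 * (n**3 - n)
    if tie_policy == "midrank_tie_correction":
        denom -= k * sum(_tie_term(row) for row in block)
    elif tie_policy != "midrank_no_correction":
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if denom <= 0:
        warnings.warn("all-constant block: Kendall's W undefined, returning 0", stacklevel=2)
        return 0.0
    return float(np.clip(12.0 * s / denom, 0.0, 1.0))


def _shift3d(arr: np.ndarray, off: tuple[int, int, int]) -> np.ndarray:
    """Shift a 3D/4D array by integer voxel offsets, zero-filling the border."""
    out = np.zeros_like(arr)
    src = []
    dst = []
    for axis, o in enumerate(off):
        size = arr.shape[axis]
        if o >= 0:
            src.append(slice(0, size - o))
            dst.append(slice(o, size))
        else:
            src.append(slice(-o, size))
            dst.append(slice(0, size + o))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def compute_reho(img: Image4D, mask: BrainMask, params: ReHoParams | None = None) -> Image3D:
    """Voxelwise ReHo map: Kendall's W over each in-mask voxel and its in-mask
    neighbours.

    Out-of-mask voxels and voxels with fewer than ``params.min_neighbors``
    in-mask neighbours are set to 0.  Vectorised over voxels: per-timepoint
    rank sums are accumulated by shifting the rank volume over the
    neighbourhood offsets.
    """
    params = params or ReHoParams()
    check_same_grid(img, mask, "image/mask")
    n = img.n_timepoints
    if n < 4:
        raise ValueError("ReHo needs at least 4 timepoints for non-degenerate ranks")

    inmask = mask.data
    flat = img.data[inmask]  # (V, T)
    ranks4d = np.zeros(img.shape, dtype=float)
    ranks4d[inmask] = rankdata(flat, axis=1)

    offsets = _neighborhood_offsets(params.neighborhood_size)
    maskf = inmask.astype(float)
    rank_sum = np.zeros(img.shape, dtype=float)
    k_count = np.zeros(img.shape[:3], dtype=float)
    for off in offsets:
        rank_sum += _shift3d(ranks4d, tuple(off))
        k_count += _shift3d(maskf, tuple(off))

    # S = sum_t R_t^2 - (sum_t R_t)^2 / n, per voxel
    s = (rank_sum**2).sum(axis=3) - rank_sum.sum(axis=3) ** 2 / n
    denom = k_count**2 * (n**3 - n)
    if params.tie_policy == "midrank_tie_correction":
        ties3d = np.zeros(img.shape[:3], dtype=float)
        ties3d[inmask] = [_tie_term(row) for row in flat]
        tie_sum = np.zeros_like(ties3d)
        for off in offsets:
            tie_sum += _shift3d(ties3d, tuple(off))
        denom = denom - k_count * tie_sum

    valid = inmask & (k_count - 1 >= params.min_neighbors) & (denom > 0)
    out = np.zeros(img.shape[:3], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        w = 12.0 * s / denom
    out[valid] = np.clip(w[valid], 0.0, 1.0)
    return Image3D(out, img.affine)


def _band_limits(params: SpectralParams, repetition_time: float) -> tuple[float, float]:
    lo, hi = params.band
    nyquist = 1.0 / (2.0 * repetition_time)
    if hi > nyquist + 1e-12:
        raise ValueError(f"band upper edge {hi} Hz exceeds Nyquist {nyquist:.4g} Hz")
    return lo, hi


def compute_alff_falff(
    img: Image4D, mask: BrainMask, params: SpectralParams | None = None
) -> tuple[Image3D, Image3D]:
    """ALFF and fALFF maps.

    Per in-mask voxel: linear detrend, band-pass to ``params.band``; ALFF is
    the standard deviation of the filtered series, fALFF divides by the
    standard deviation of the unfiltered series (detrended by default).
    Voxels whose denominator is below ``params.eps`` get fALFF = 0 (flagged
    with a warning).
    """
    params = params or SpectralParams()
    check_same_grid(img, mask, "image/mask")
    n = img.n_timepoints
    if n < 16:
        raise ValueError("ALFF/fALFF needs at least 16 timepoints")
    lo, hi = _band_limits(params, img.repetition_time)

    inmask = mask.data
    raw = img.data[inmask]  # (V, T)
    detrended = sp_signal.detrend(raw, axis=1, type="linear")

    if params.filter == "fft_ideal":
        freqs = np.fft.rfftfreq(n, d=img.repetition_time)
        keep = (freqs >= lo - 1e-12) & (freqs <= hi + 1e-12)
        if not keep.any():
            raise ValueError(
                "no FFT bin falls inside the band: timeseries too short for "
                f"band {params.band} at repetition_time {img.repetition_time}"
            )
        spectrum = np.fft.rfft(detrended, axis=1)
        spectrum[:, ~keep] = 0.0
        filtered = np.fft.irfft(spectrum, n=n, axis=1)
    else:  # butterworth, order 2, zero-phase
        fs = 1.0 / img.repetition_time
        wn_lo = max(lo, 1e-6)
        sos = sp_signal.butter(2, [wn_lo, hi], btype="bandpass", fs=fs, output="sos")
        filtered = sp_signal.sosfiltfilt(sos, detrended, axis=1)

    alff_v = filtered.std(axis=1)
    denom_series = detrended if params.falff_denominator == "detrended_unfiltered" else raw
    denom = denom_series.std(axis=1)
    bad = denom < params.eps
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} in-mask voxel(s) have (near-)constant signal; fALFF set to 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        falff_v = np.where(bad, 0.0, alff_v / np.where(bad, 1.0, denom))

    alff = np.zeros(img.shape[:3])
    falff = np.zeros(img.shape[:3])
    alff[inmask] = alff_v
    falff[inmask] = falff_v
    return Image3D(alff, img.affine), Image3D(falff, img.affine)


def zscore_map(map3d: Image3D, mask: BrainMask) -> Image3D:
    """Participant-level z-scoring within the mask (population-SD convention).

    Out-of-mask voxels are set to 0.  A constant in-mask map has no z-score
    and raises ``ValueError``.
    """
    check_same_grid(map3d, mask, "map/mask")
    values = map3d.data[mask.data]
    if values.size < 2:
        raise ValueError("need at least 2 in-mask voxels to z-score")
    mu = values.mean()
    sd = values.std()  # population (1/N) convention
    if sd < 1e-15:
        raise ValueError("constant in-mask map: z-score undefined")
    out = np.zeros(map3d.shape)
    out[mask.data] = (values - mu) / sd
    return Image3D(out, map3d.affine)
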