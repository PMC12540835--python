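"""Kinetochore fluorescence quantification from sum projections.

Workflow: sum-project the z-stack of the channel of interest, define a small
region per kinetochore on the reference (CENP-A) channel, integrate the
signal, subtract the per-pixel cytoplasmic background scaled by the region
area, and divide by the number of z-planes in the projection.  Ratios to the
CENP-A reference remove expression/gain differences between kinetochores;
within-cell normalization to the aligned-group mean removes cell-to-cell
staining differences.

Pixel coordinates are 0-based with origin at the top-left; x indexes columns
and y rows.  Stacks are ordered (z, channel, y, x).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from skimage.measure import label as cc_label

from .errors import NormalizationError


@dataclass
class ImageStack:
    """Multi-channel z-stack with physical calibration.

    ``voxels`` is ordered (z, channel, y, x); intensities are non-negative
    arbitrary units.  ``pixel_size_xy`` and ``z_step`` are in um.
    """

    voxels: np.ndarray
    pixel_size_xy: float
    z_step: float
    channels: Sequence[str]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be 4D (z, channel, y, x)")
        if self.voxels.shape[0] < 1:
            raise ValueError("need at least one z-slice")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.voxels.shape[1] != len(self.channels):
            raise ValueError("channel axis does not match channel names")
        if not np.all(np.isfinite(self.voxels)) or np.any(self.voxels < 0):
            raise ValueError("voxel intensities must be finite and non-negative")

    def channel_index(self, name: str) -> int:
        try:
            return list(self.channels).index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass
class SpotRegion:
    """Connected pixel region around one kinetochore in the projection plane."""

    mask: np.ndarray
    seed: tuple[int, int]  # (x, y) pixels
    area: int


@dataclass
class IntensityRecord:
    """Background-subtracted, per-z-plane-normalised intensity of one spot."""

    object_id: str
    raw_integrated: float
    background_per_pixel: float
    area: int
    n_z: int
    mean_intensity: float
    negative_flag: bool
    ref_ratio: Optional[float] = None
    group_norm: Optional[float] = None
    d_pole_norm: Optional[float] = None


def write_stack_tiff(stack: ImageStack, path) -> None:
    """Write a stack as a multi-page TIFF, pages ordered (z, channel, y, x)."""
    import tifffile

    tifffile.imwrite(
        path,
        stack.voxels.astype(np.float32),
        metadata={
            "axes": "ZCYX",
            "channels": list(stack.channels),
            "pixel_size_xy_um": stack.pixel_size_xy,
            "z_step_um": stack.z_step,
        },
    )


def read_stack_tiff(
    path, channels: Sequence[str], pixel_size_xy: float, z_step: float
) -> ImageStack:
    """Read a multi-page TIFF with (z, channel, y, x) page order into a stack.

    The channel names and physical calibration come from configuration; a 3D
    file (z, y, x) is accepted as a single declared channel.
    """
    import tifffile

    vox = np.asarray(tifffile.imread(path), dtype=float)
    if vox.ndim == 3:
        vox = vox[:, None]
    if vox.ndim != 4:
        raise ValueError(f"expected a (z, channel, y, x) stack, got shape {vox.shape}")
    return ImageStack(
        voxels=vox, pixel_size_xy=pixel_size_xy, z_step=z_step,
        channels=list(channels),
    )


def sum_projection(stack: ImageStack, channel: str) -> tuple[np.ndarray, int]:
    """Pixel-wise sum of all z-planes of one channel; returns (image, n_z)."""
    c = stack.channel_index(channel)
    return stack.voxels[:, c].sum(axis=0), stack.voxels.shape[0]


def disk_mask(shape: tuple[int, int], center_xy: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean disk of the given pixel radius on an image of the given shape."""
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - center_xy[0]) ** 2 + (yy - center_xy[1]) ** 2 <= radius**2


def define_spot_region(
    ref_projection: np.ndarray,
    seed: tuple[int, int],
    r_max: int = 6,
) -> SpotRegion:
    """Deterministic spot region from a seed on the reference projection.

    The region is the connected component, containing the seed, of pixels at
    or above half of (local peak - local floor) inside a disk of radius
    ``r_max`` around the seed; peak is taken within 2 px of the seed and floor
    as the window minimum.  If thresholding yields fewer than 3 px the region
    falls back to a 2-px disk around the seed.
    """
    img = np.asarray(ref_projection, dtype=float)
    x0, y0 = int(seed[0]), int(seed[1])
    if not (0 <= y0 < img.shape[0] and 0 <= x0 < img.shape[1]):
        raise ValueError(f"seed {seed} outside image of shape {img.shape}")
    window = disk_mask(img.shape, (x0, y0), r_max)
    near = disk_mask(img.shape, (x0, y0), 2)
    peak = img[near].max()
    floor = img[window].min()
    if peak - floor > 0:
        mask = window & (img >= floor + 0.5 * (peak - floor))
        labels = cc_label(mask, connectivity=2)
        mask = labels == labels[y0, x0] if labels[y0, x0] > 0 else np.zeros_like(mask)
    else:
        mask = np.zeros_like(window)  # flat window: no peak to segment
    if mask.sum() < 3:
        mask = disk_mask(img.shape, (x0, y0), 2)
    return SpotRegion(mask=mask, seed=(x0, y0), area=int(mask.sum()))


def annulus_background_region(
    shape: tuple[int, int],
    seed: tuple[int, int],
    inner: float = 8.0,
    outer: float = 12.0,
    exclude: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Cytoplasmic background annulus around a seed, minus any excluded spots."""
    ann = disk_mask(shape, seed, outer) & ~disk_mask(shape, seed, inner)
    if exclude is not None:
        ann &= ~exclude
    return ann


def measure_kinetochore_intensity(
    projection: np.ndarray,
    region: SpotRegion,
    background_region: np.ndarray,
    n_z: int,
    object_id: str = "",
) -> IntensityRecord:
    """Integrated region intensity, background-corrected and divided by n_z.

    mean_intensity = (sum over region - mean(background) * area) / n_z.
    Negative corrected values are retained and flagged, not clipped, so that
    group means stay unbiased.
    """
    img = np.asarray(projection, dtype=float)
    if region.area < 1 or not region.mask.any():
        raise ValueError("empty spot region")
    if not np.asarray(background_region).any():
        raise ValueError("empty background region")
    if (region.mask & background_region).any():
        raise ValueError("spot and background regions overlap")
    if n_z < 1:
        raise ValueError("n_z must be >= 1")
    raw = float(img[region.mask].sum())
    bg = float(img[background_region].mean())
    corrected = raw - bg * region.area
    return IntensityRecord(
        object_id=object_id,
        raw_integrated=raw,
        background_per_pixel=bg,
        area=region.area,
        n_z=int(n_z),
        mean_intensity=corrected / n_z,
        negative_flag=corrected < 0,
    )


def normalize_to_reference(target: IntensityRecord, reference: IntensityRecord) -> float:
    """Ratio of a target-channel record to its CENP-A-like reference record."""
    if reference.mean_intensity <= 0:
        raise NormalizationError(
            f"non-positive reference intensity for {target.object_id!r}"
        )
    return target.mean_intensity / reference.mean_intensity


def normalize_within_cell_to_aligned(
    records: pd.DataFrame,
    cell_col: str = "cell_id",
    ratio_col: str = "ref_ratio",
    d_pole_col: str = "d_pole",
    aligned_col: str = "aligned",
) -> pd.DataFrame:
    """Within-cell normalization to the aligned-group mean.

    Adds ``group_norm`` (ref_ratio / mean ref_ratio of the cell's aligned
    records) and ``d_pole_norm`` (pole distance / aligned-group mean pole
    distance).  Cells with an empty aligned group or a non-positive aligned
    mean ratio raise :class:`NormalizationError`.
    """
    out = records.copy()
    out["group_norm"] = np.nan
    out["d_pole_norm"] = np.nan
    for cell, grp in records.groupby(cell_col):
        aligned = grp.loc[grp[aligned_col].astype(bool)]
        if aligned.empty:
            raise NormalizationError(f"cell {cell!r}: empty aligned group")
        mean_ratio = aligned[ratio_col].mean()
        if not mean_ratio > 0:
            raise NormalizationError(
                f"cell {cell!r}: non-positive aligned mean ratio"
            )
        out.loc[grp.index, "group_norm"] = grp[ratio_col] / mean_ratio
        mean_d = aligned[d_pole_col].mean()
        if mean_d > 0:
            out.loc[grp.index, "d_pole_norm"] = grp[d_pole_col] / mean_d
    return out


def binned_profile(
    x: np.ndarray, y: np.ndarray, n_bins: int
) -> pd.DataFrame:
    """Mean +/- s.d. of y in equal-width bins of x over [min(x), max(x)].

    Returns a frame with bin centers, per-bin mean, s.d. and count; empty
    bins carry NaN statistics.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < n_bins:
        raise ValueError("need len(x) == len(y) >= n_bins")
    if x.max() == x.min():
        raise ValueError("degenerate x-range")
    edges = np.linspace(x.min(), x.max(), n_bins + 1)
    mean, _, _ = sps.binned_statistic(x, y, statistic="mean", bins=edges)
    sd, _, _ = sps.binned_statistic(x, y, statistic="std", bins=edges)
    n, _, _ = sps.binned_statistic(x, y, statistic="count", bins=edges)
    return pd.DataFrame(
        {
            "bin_center": 0.5 * (edges[:-1] + edges[1:]),
            "mean": mean,
            "sd": np.where(n > 0, sd, np.nan),
            "n": n.astype(int),
        }
    )


def mad2_loss(
    t: np.ndarray,
    intensity: np.ndarray,
    t0: float,
    t1: float,
    fractional: bool = True,
) -> float:
    """Checkpoint-signal loss between two times, default fractional.

    Fractional loss is (I(t0) - I(t1)) / I(t0); the absolute alternative
    returns I(t0) - I(t1).  The nearest samples to each endpoint are used.
    An intensity increase yields a negative loss.
    """
    t = np.asarray(t, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    i0 = int(np.argmin(np.abs(t - t0)))
    i1 = int(np.argmin(np.abs(t - t1)))
    I0, I1 = float(intensity[i0]), float(intensity[i1])
    if fractional:
        if I0 <= 0:
            raise ValueError("non-positive intensity at window start")
        return (I0 - I1) / I0
    return I0 - I1
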