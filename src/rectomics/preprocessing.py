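"""ROI intensity re-segmentation and fixed-bin-count discretization.

Texture matrices operate on grey *levels*, not raw intensities.  The ROI is
first restricted to the [P1, P99] intensity band (outlier re-segmentation),
then intensities inside the refined ROI are mapped to a fixed number of bins
(64 by default) between the ROI minimum and maximum.  Both steps run
independently per modality; no denoising filter and no global intensity
normalization are applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imaging import ImageVolume, SegmentationMask

__all__ = [
    "ResegmentationConfig",
    "DiscretizationConfig",
    "DiscretizedROI",
    "resegment",
    "discretize",
    "slice_decompose",
]

log = logging.getLogger(__name__)

#: sentinel level for out-of-ROI pixels in discretized grids
BACKGROUND = 0


@dataclass(frozen=True)
class ResegmentationConfig:
    """Percentile band (in percent) retained inside the ROI."""

    low_percentile: float = 1.0
    high_percentile: float = 99.0

    def __post_init__(self) -> None:
        if not 0 <= self.low_percentile < self.high_percentile <= 100:
            raise ValueError("need 0 <= low < high <= 100")


@dataclass(frozen=True)
class DiscretizationConfig:
    bin_count: int = 64

    def __post_init__(self) -> None:
        if self.bin_count < 2:
            raise ValueError("bin_count must be >= 2")


@dataclass
class DiscretizedROI:
    """Integer level grid (1..bin_count in-ROI, 0 outside) plus slice index list."""

    levels: np.ndarray  # 3D int grid, BACKGROUND outside ROI
    bin_count: int
    slice_indices: list[int]
    source_modality: str = "t2w"

    def roi_levels(self) -> np.ndarray:
        return self.levels[self.levels != BACKGROUND]


def resegment(
    volume: ImageVolume,
    mask: SegmentationMask,
    cfg: ResegmentationConfig = ResegmentationConfig(),
) -> SegmentationMask:
    """Restrict the mask to voxels with intensity in the ROI's [P_low, P_high].

    Percentiles use linear interpolation between order statistics and the
    interval is closed at both ends, so a constant ROI is returned unchanged.
    """
    if mask.n_foreground == 0:
        raise ValueError("cannot re-segment an empty mask")
    values = volume.voxels[mask.voxels]
    lo, hi = np.percentile(values, [cfg.low_percentile, cfg.high_percentile])
    keep = mask.voxels & (volume.voxels >= lo) & (volume.voxels <= hi)
    if not keep.any():
        raise ValueError("re-segmented mask is empty (degenerate ROI intensities)")
    return SegmentationMask(voxels=keep, spacing=mask.spacing, provenance=mask.provenance)


def discretize(
    volume: ImageVolume,
    mask: SegmentationMask,
    cfg: DiscretizationConfig = DiscretizationConfig(),
    modality: str = "t2w",
) -> DiscretizedROI:
    """Fixed-bin-count discretization of in-ROI intensities.

    level(x) = 1 + floor(N (x - min) / (max - min)), with x = max clamped to
    level N; min and max are taken over the (re-segmented) ROI of this volume.
    A constant ROI maps entirely to level 1.
    """
    if mask.n_foreground == 0:
        raise ValueError("cannot discretize an empty mask")
    values = volume.voxels[mask.voxels]
    vmin, vmax = float(values.min()), float(values.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    if vmax == vmin:
        levels[mask.voxels] = 1
    else:
        scaled = 1 + np.floor(cfg.bin_count * (values - vmin) / (vmax - vmin))
        levels[mask.voxels] = np.minimum(scaled, cfg.bin_count).astype(np.int32)
    slice_indices = [int(s) for s in np.flatnonzero(levels.any(axis=(1, 2)))]
    return DiscretizedROI(
        levels=levels, bin_count=cfg.bin_count, slice_indices=slice_indices,
        source_modality=modality,
    )


def slice_decompose(droi: DiscretizedROI, min_slice_pixels: int = 2) -> list[np.ndarray]:
    """Split the discretized ROI into per-slice 2D level grids.

    Slices with fewer than ``min_slice_pixels`` in-ROI pixels are dropped
    (texture matrices need at least one neighbouring pair).
    """
    slices = []
    for s in droi.slice_indices:
        grid = droi.levels[s]
        n = int((grid != BACKGROUND).sum())
        if n >= min_slice_pixels:
            slices.append(grid)
        else:
            log.info("dropping slice %d with %d < %d ROI pixels", s, n, min_slice_pixels)
    if not slices:
        raise ValueError("all slices dropped: ROI too small for per-slice texture analysis")
    return slices
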