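"""2D texture matrices over discretized ROI slices.

All builders take a 2D integer grid where in-ROI pixels carry levels
``1..n_levels`` and background pixels are 0.  Neighbourhoods are strictly
in-plane (2.5D extraction) at Chebyshev distance 1; background pixels never
contribute: runs, zones and dependences are confined to the ROI, and
out-of-ROI neighbours are ignored rather than treated as level 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "DIRECTIONS",
    "NeighbourhoodConfig",
    "TextureMatrix",
    "glcm_matrix",
    "glrlm_matrix",
    "glszm_matrix",
    "ngtdm_matrix",
    "gldm_matrix",
    "build_texture_matrix",
]

#: in-plane direction offsets (drow, dcol) at angles 0, 45, 90, 135 degrees
DIRECTIONS: dict[int, tuple[int, int]] = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_EIGHT_NEIGHBOURS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass(frozen=True)
class NeighbourhoodConfig:
    """Distance-1 neighbourhood conventions for the five matrix families."""

    distance: int = 1
    angles: tuple[int, ...] = (0, 45, 90, 135)
    gldm_alpha: int = 0

    def __post_init__(self) -> None:
        if self.distance < 1:
            raise ValueError("distance must be >= 1")


@dataclass
class TextureMatrix:
    family: str
    values: np.ndarray  # counts; for NGTDM: stacked (n_i, s_i) rows
    direction: int | None = None
    n_roi_pixels: int = 0

    def normalized(self) -> np.ndarray:
        total = self.values.sum()
        return self.values / total if total > 0 else self.values.astype(float)


def _paired(grid: np.ndarray, offset: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Levels of all (pixel, neighbour) pairs at the given offset, ROI-interior only."""
    dr, dc = offset
    rows, cols = grid.shape
    r0, r1 = max(0, -dr), rows - max(0, dr)
    c0, c1 = max(0, -dc), cols - max(0, dc)
    a = grid[r0:r1, c0:c1]
    b = grid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a > 0) & (b > 0)
    return a[valid], b[valid]


def glcm_matrix(grid: np.ndarray, n_levels: int, angle: int = 0, distance: int = 1) -> TextureMatrix:
    """Symmetric grey-level co-occurrence counts at one in-plane angle."""
    dr, dc = DIRECTIONS[angle]
    a, b = _paired(grid, (dr * distance, dc * distance))
    counts = np.zeros((n_levels, n_levels))
    np.add.at(counts, (a - 1, b - 1), 1.0)
    counts = counts + counts.T  # symmetrize by adding the transpose
    return TextureMatrix("glcm", counts, direction=angle, n_roi_pixels=int((grid > 0).sum()))


def _lines(grid: np.ndarray, angle: int):
    """1D scan lines of the grid along a direction (order within a line is irrelevant)."""
    rows, cols = grid.shape
    if angle == 0:
        yield from (grid[r] for r in range(rows))
    elif angle == 90:
        yield from (grid[:, c] for c in range(cols))
    elif angle == 135:  # constant r - c: main diagonals
        yield from (np.diagonal(grid, offset=k) for k in range(-(rows - 1), cols))
    elif angle == 45:  # constant r + c: anti-diagonals
        flipped = np.fliplr(grid)
        yield from (np.diagonal(flipped, offset=k) for k in range(-(rows - 1), cols))
    else:
        raise ValueError(f"unsupported angle {angle}")


def glrlm_matrix(grid: np.ndarray, n_levels: int, angle: int = 0) -> TextureMatrix:
    """Run-length counts per (level, run length) along one direction.

    Background pixels break runs; the matrix has one column per possible run
    length up to the longer grid side.
    """
    max_len = max(grid.shape)
    counts = np.zeros((n_levels, max_len))
    for line in _lines(grid, angle):
        line = np.asarray(line)
        if line.size == 0:
            continue
        change = np.flatnonzero(np.diff(line) != 0)
        starts = np.r_[0, change + 1]
        ends = np.r_[change, line.size - 1]
        levels = line[starts]
        lengths = ends - starts + 1
        keep = levels > 0
        np.add.at(counts, (levels[keep] - 1, lengths[keep] - 1), 1.0)
    return TextureMatrix("glrlm", counts, direction=angle, n_roi_pixels=int((grid > 0).sum()))


def glszm_matrix(grid: np.ndarray, n_levels: int) -> TextureMatrix:
    """Zone counts per (level, zone size); zones are 8-connected constant-level regions."""
    structure = np.ones((3, 3), dtype=int)
    n_pixels = int((grid > 0).sum())
    max_zone = max(n_pixels, 1)
    counts = np.zeros((n_levels, max_zone))
    for level in np.unique(grid[grid > 0]):
        labelled, n_zones = ndimage.label(grid == level, structure=structure)
        if n_zones == 0:
            continue
        sizes = np.bincount(labelled.ravel())[1:]
        np.add.at(counts, (np.full(n_zones, level - 1), sizes - 1), 1.0)
    return TextureMatrix("glszm", counts, n_roi_pixels=n_pixels)


def ngtdm_matrix(grid: np.ndarray, n_levels: int) -> TextureMatrix:
    """Neighbourhood grey-tone difference table.

    Row 0 holds n_i (number of valid ROI pixels at level i), row 1 holds
    s_i (summed absolute difference between level i pixels and the mean of
    their in-ROI 8-neighbours).  Pixels without any in-ROI neighbour are
    excluded from n_i.
    """
    roi = grid > 0
    vals = grid.astype(float) * roi
    kernel = np.ones((3, 3))
    kernel[1, 1] = 0
    nb_sum = ndimage.correlate(vals, kernel, mode="constant", cval=0.0)
    nb_cnt = ndimage.correlate(roi.astype(float), kernel, mode="constant", cval=0.0)
    valid = roi & (nb_cnt > 0)
    diffs = np.zeros_like(vals)
    diffs[valid] = np.abs(grid[valid] - nb_sum[valid] / nb_cnt[valid])
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    np.add.at(n_i, grid[valid] - 1, 1.0)
    np.add.at(s_i, grid[valid] - 1, diffs[valid])
    return TextureMatrix("ngtdm", np.stack([n_i, s_i]), n_roi_pixels=int(roi.sum()))


def gldm_matrix(grid: np.ndarray, n_levels: int, alpha: int = 0) -> TextureMatrix:
    """Dependence counts per (level, dependence size).

    Dependence size is 1 + the number of in-ROI 8-neighbours whose level
    differs from the centre by at most ``alpha`` (the centre counts itself),
    so sizes span 1..9 and size-weighted denominators are never zero.
    """
    roi = grid > 0
    rows, cols = grid.shape
    dep = np.zeros(grid.shape, dtype=int)
    for dr, dc in _EIGHT_NEIGHBOURS:
        r0, r1 = max(0, -dr), rows - max(0, dr)
        c0, c1 = max(0, -dc), cols - max(0, dc)
        a = grid[r0:r1, c0:c1]
        b = grid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        hit = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[r0:r1, c0:c1] += hit
    counts = np.zeros((n_levels, 9))
    np.add.at(counts, (grid[roi] - 1, dep[roi]), 1.0)  # column j <-> size j+1
    return TextureMatrix("gldm", counts, n_roi_pixels=int(roi.sum()))


def build_texture_matrix(
    family: str,
    slice2d: np.ndarray,
    cfg: NeighbourhoodConfig = NeighbourhoodConfig(),
    direction: int | None = None,
) -> TextureMatrix:
    """Dispatch to the family-specific builder (directional families need ``direction``)."""
    n_roi = int((slice2d > 0).sum())
    if n_roi < 2:
        raise ValueError(f"too few ROI pixels ({n_roi}) for texture analysis")
    n_levels = int(slice2d.max())
    if family == "glcm":
        return glcm_matrix(slice2d, n_levels, angle=_need_dir(direction), distance=cfg.distance)
    if family == "glrlm":
        return glrlm_matrix(slice2d, n_levels, angle=_need_dir(direction))
    if family == "glszm":
        return glszm_matrix(slice2d, n_levels)
    if family == "ngtdm":
        return ngtdm_matrix(slice2d, n_levels)
    if family == "gldm":
        return gldm_matrix(slice2d, n_levels, alpha=cfg.gldm_alpha)
    raise ValueError(f"unknown texture family {family!r}")


def _need_dir(direction: int | None) -> int:
    if direction is None:
        raise ValueError("directional family requires a direction angle")
    return direction
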