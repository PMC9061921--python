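"""Volume and mask handling for the radiomics pipeline.

Volumes are stored axis-ordered ``(slice, row, col)`` with the axial slice
axis first, matching the per-slice (2.5D) texture extraction.  Spacing is
``(dx, dy, dz)`` in mm where ``dx``/``dy`` are the in-plane pixel sizes and
``dz`` the slice thickness.  NIfTI affines are used only for spacing; volumes
are treated as axis-aligned (no oblique reorientation).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "DiceResult",
    "StudyCase",
    "DSC_EXCLUSION_THRESHOLD",
    "read_volume",
    "write_volume",
    "read_mask",
    "resample_to_grid",
    "dice",
    "roi_volume_mm3",
    "label_from_trg",
    "load_cohort",
]

#: Automatic segmentations overlapping the manual reference below this Dice
#: value are treated as segmentation failures and excluded from training.
DSC_EXCLUSION_THRESHOLD = 0.20

RESPONDER = "responder"
NONRESPONDER = "nonresponder"


@dataclass
class ImageVolume:
    """A 3D scalar grid with voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (n_slices, n_rows, n_cols)
        Intensities. Arbitrary units for T2w; ADC maps carry
        10^-3 mm^2/s-scaled diffusion values.
    spacing : tuple of float
        ``(dx, dy, dz)`` in mm, all positive.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"not a 3D volume: payload has {self.voxels.ndim} dims")
        if self.voxels.shape[0] < 1:
            raise ValueError("volume must contain at least one slice")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite voxels")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing}: components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass
class SegmentationMask:
    """Binary ROI aligned to a reference :class:`ImageVolume` grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    provenance: str = "manual"  # manual | automatic

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError("mask must be 3D")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary {0, 1}")
        self.voxels = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


@dataclass(frozen=True)
class DiceResult:
    """Dice similarity coefficient with the DSC < 0.20 exclusion flag."""

    value: float
    excluded: bool


@dataclass
class StudyCase:
    """One patient: T2w + ADC volumes, one or two masks, outcome metadata."""

    id: str
    centre: str
    t2w: ImageVolume
    adc: ImageVolume
    masks: dict[str, SegmentationMask]
    trg: int
    split: str  # construction-train | construction-test | validation
    label: str = field(default="")

    def __post_init__(self) -> None:
        if self.centre not in ("A", "B", "C"):
            raise ValueError(f"unknown centre {self.centre!r}")
        expected = label_from_trg(self.trg)
        if not self.label:
            self.label = expected
        elif self.label != expected:
            raise ValueError(
                f"case {self.id}: label {self.label!r} inconsistent with TRG {self.trg}"
            )
        for prov, mask in self.masks.items():
            if mask.shape != self.t2w.shape:
                raise ValueError(f"case {self.id}: {prov} mask not aligned to T2w grid")
        if self.adc.shape != self.t2w.shape:
            raise ValueError(f"case {self.id}: ADC not resampled onto the T2w grid")

    @property
    def is_responder(self) -> bool:
        return self.label == RESPONDER


def read_volume(path: str | os.PathLike) -> ImageVolume:
    """Read a 3D NIfTI-1 volume.

    The on-disk (x, y, z) array is transposed to the internal
    (slice, row, col) order; spacing is taken from the header zooms.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: not a 3D volume (payload has {data.ndim} dims)")
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite voxels")
    dx, dy, dz = (float(z) for z in img.header.get_zooms()[:3])
    return ImageVolume(voxels=np.transpose(data, (2, 1, 0)), spacing=(dx, dy, dz))


def write_volume(vol: ImageVolume, path: str | os.PathLike) -> None:
    """Write an :class:`ImageVolume` (or mask grid) as NIfTI-1."""
    data = np.transpose(np.asarray(vol.voxels), (2, 1, 0))
    if data.dtype == bool:
        data = data.astype(np.uint8)
    affine = np.diag(list(vol.spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path: str | os.PathLike, reference: ImageVolume, provenance: str) -> SegmentationMask:
    """Read a binary mask and check alignment with its reference volume."""
    vol = read_volume(path)
    if vol.shape != reference.shape:
        raise ValueError(f"{path}: mask grid {vol.shape} does not match reference {reference.shape}")
    return SegmentationMask(voxels=vol.voxels > 0.5, spacing=reference.spacing, provenance=provenance)


def resample_to_grid(moving: ImageVolume, reference: ImageVolume, mode: str = "linear") -> ImageVolume:
    """Resample ``moving`` onto the grid of ``reference``.

    Both volumes are assumed axis-aligned with a shared origin at the centre
    of voxel (0, 0, 0).  Linear interpolation for intensities, nearest for
    masks; voxels outside the moving field of view are filled with 0.
    """
    if mode not in ("linear", "nearest"):
        raise ValueError(f"unknown resampling mode {mode!r}")
    # with a shared origin at voxel (0,0,0) the world-space overlap always
    # contains that voxel, so the empty-overlap failure mode cannot arise here
    if moving.shape == reference.shape and np.allclose(moving.spacing, reference.spacing):
        return ImageVolume(voxels=moving.voxels.copy(), spacing=reference.spacing)

    # world coordinate of reference voxel centres, expressed in moving voxel
    # indices: world = index * step (per axis), so idx_mov = idx_ref * step_ref/step_mov
    steps_ref = (reference.spacing[2], reference.spacing[1], reference.spacing[0])
    steps_mov = (moving.spacing[2], moving.spacing[1], moving.spacing[0])
    grids = np.meshgrid(
        *[np.arange(n) * sr / sm for n, sr, sm in zip(reference.shape, steps_ref, steps_mov)],
        indexing="ij",
    )
    order = 1 if mode == "linear" else 0
    out = ndimage.map_coordinates(
        moving.voxels.astype(float), np.stack(grids), order=order, mode="constant", cval=0.0
    )
    return ImageVolume(voxels=out, spacing=reference.spacing)


def dice(a: SegmentationMask, b: SegmentationMask) -> DiceResult:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|).

    Both masks empty is defined as perfect agreement (1.0).  The ``excluded``
    flag marks DSC below :data:`DSC_EXCLUSION_THRESHOLD`.
    """
    if a.shape != b.shape:
        raise ValueError(f"mask shape mismatch: {a.shape} vs {b.shape}")
    na, nb = a.n_foreground, b.n_foreground
    if na == 0 and nb == 0:
        value = 1.0
    else:
        inter = int(np.logical_and(a.voxels, b.voxels).sum())
        value = 2.0 * inter / (na + nb)
    return DiceResult(value=value, excluded=value < DSC_EXCLUSION_THRESHOLD)


def roi_volume_mm3(mask: SegmentationMask, spacing: tuple[float, float, float] | None = None) -> float:
    """ROI volume in mm^3: foreground voxel count times voxel volume."""
    if mask.n_foreground == 0:
        raise ValueError("empty mask has no ROI volume")
    dx, dy, dz = spacing if spacing is not None else mask.spacing
    return mask.n_foreground * dx * dy * dz


def label_from_trg(trg: int) -> str:
    """Map Mandard tumour regression grade to the binary response label.

    TRG 1-2 -> responder, TRG 3-5 -> nonresponder.
    """
    trg = int(trg)
    if not 1 <= trg <= 5:
        raise ValueError(f"TRG must be in 1..5, got {trg}")
    return RESPONDER if trg <= 2 else NONRESPONDER


def load_cohort(clinical_csv: str | os.PathLike) -> list[StudyCase]:
    """Assemble study cases from a clinical table.

    The CSV must provide columns ``id, centre, trg, split, t2w_path,
    adc_path, mask_manual_path`` and optionally ``mask_automatic_path``.
    Relative paths are resolved against the CSV location.  The ADC volume is
    resampled (linear) onto the T2w grid at ingestion.
    """
    import pandas as pd

    table = pd.read_csv(clinical_csv, dtype={"id": str})
    required = {"id", "centre", "trg", "split", "t2w_path", "adc_path", "mask_manual_path"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    base = os.path.dirname(os.path.abspath(clinical_csv))

    def _resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    cases = []
    for row in table.itertuples(index=False):
        t2w = read_volume(_resolve(row.t2w_path))
        adc = resample_to_grid(read_volume(_resolve(row.adc_path)), t2w, mode="linear")
        masks = {"manual": read_mask(_resolve(row.mask_manual_path), t2w, "manual")}
        auto_path = getattr(row, "mask_automatic_path", None)
        if isinstance(auto_path, str) and auto_path:
            masks["automatic"] = read_mask(_resolve(auto_path), t2w, "automatic")
        cases.append(
            StudyCase(
                id=str(row.id), centre=str(row.centre), t2w=t2w, adc=adc,
                masks=masks, trg=int(row.trg), split=str(row.split),
            )
        )
    return cases
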