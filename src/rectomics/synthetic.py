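"""Synthetic multicentre cohorts and tabular feature sets.

The cohort generator emulates the statistical structure the analysis
assumes, not MRI physics: ellipsoidal tumours on a background volume, a T2w
texture whose spatial correlation length differs between responders and
nonresponders (a contrast GLCM/GLRLM-type features provably respond to,
surviving the affine-invariant discretization), an ADC map with a
class-dependent tumour mean, three centres with their distinct voxel
spacings, and a paired "automatic" mask produced by seeded perturbation of
the manual one at a controllable Dice overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imaging import ImageVolume, SegmentationMask, StudyCase, resample_to_grid

__all__ = [
    "ClassTexture",
    "CohortSpec",
    "TabularSpec",
    "CENTRE_SPACING_T2W",
    "CENTRE_SPACING_ADC",
    "generate_cohort",
    "generate_study_cohort",
    "perturb_mask",
    "generate_feature_table",
    "write_cohort",
]

#: per-centre (dx, dy, dz) in mm of the T2w acquisition
CENTRE_SPACING_T2W = {"A": (0.43, 0.43, 4.0), "B": (0.47, 0.47, 3.5), "C": (0.8, 0.8, 3.0)}
#: per-centre in-plane pixel size of the native diffusion acquisition
CENTRE_SPACING_ADC = {"A": (0.86, 0.86, 4.0), "B": (1.88, 1.88, 3.5), "C": (2.8, 2.8, 3.0)}

#: TRG sampling weights within class (marginals of the study population)
TRG_WEIGHTS_RESPONDER = {1: 16 / 42, 2: 26 / 42}
TRG_WEIGHTS_NONRESPONDER = {3: 26 / 53, 4: 27 / 53, 5: 0.0}


@dataclass(frozen=True)
class ClassTexture:
    """Class-conditional appearance parameters.

    corr_length — in-plane correlation length of the T2w tumour texture, in
    pixels (texture granularity rides on the reconstruction grid, so texture
    features stay comparable across centres with different pixel sizes);
    contrast — standard deviation of that texture field (arbitrary units);
    adc_mean — tumour ADC in 10^-3 mm^2/s.
    """

    corr_length: float
    contrast: float
    adc_mean: float


@dataclass(frozen=True)
class CohortSpec:
    """Study conditions of one synthetic cohort block."""

    n_responders: int
    n_nonresponders: int
    centres: tuple[str, ...] = ("A", "B")
    tumour_radius_mm: tuple[float, float] = (6.0, 10.0)
    responder_texture: ClassTexture = ClassTexture(2.2, 60.0, 0.92)
    nonresponder_texture: ClassTexture = ClassTexture(1.1, 60.0, 1.16)
    corr_length_log_sd: float = 0.35  # case-level lognormal jitter of the correlation length
    adc_case_sd: float = 0.13  # case-level jitter of the tumour ADC mean
    adc_voxel_sd: float = 0.15
    # fraction of each class drawn as borderline tumours whose appearance is
    # pulled toward the between-class midpoint (atypical responders /
    # near-regressing nonresponders keep every cohort from being separable)
    ambiguous_fraction: float = 0.15
    ambiguity_pull: float = 0.7
    mask_dsc_mean: float = 0.8
    mask_dsc_spread: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responders < 1 or self.n_nonresponders < 1:
            raise ValueError("need at least one case per class")
        if not 0 < self.mask_dsc_mean <= 1:
            raise ValueError("target DSC must be in (0, 1]")


def _t_jitter(rng: np.random.Generator, sd: float) -> float:
    """Unit-variance Student-t(3) noise scaled to sd: most cases sit close to
    their class mean but occasional atypical tumours cross over, as real
    cohorts show."""
    return sd * float(rng.standard_t(3)) / np.sqrt(3.0)


def _smooth_field(shape, sigma_vox, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian random field with the given smoothing scale (voxels)."""
    raw = rng.standard_normal(shape)
    smoothed = ndimage.gaussian_filter(raw, sigma=sigma_vox)
    sd = smoothed.std()
    return smoothed / sd if sd > 0 else smoothed


def _ellipsoid(shape, spacing, radii_mm, centre_mm) -> np.ndarray:
    """Boolean ellipsoid on a (slice, row, col) grid; spacing is (dx, dy, dz)."""
    dx, dy, dz = spacing
    z = np.arange(shape[0]) * dz
    y = np.arange(shape[1]) * dy
    x = np.arange(shape[2]) * dx
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    rz, ry, rx = radii_mm
    cz, cy, cx = centre_mm
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _effective_texture(spec: CohortSpec, is_responder: bool, ambiguous: bool) -> ClassTexture:
    own = spec.responder_texture if is_responder else spec.nonresponder_texture
    if not ambiguous:
        return own
    other = spec.nonresponder_texture if is_responder else spec.responder_texture
    pull = spec.ambiguity_pull
    mid_adc = 0.5 * (own.adc_mean + other.adc_mean)
    mid_corr = np.sqrt(own.corr_length * other.corr_length)
    return ClassTexture(
        corr_length=float(np.exp((1 - pull) * np.log(own.corr_length) + pull * np.log(mid_corr))),
        contrast=own.contrast,
        adc_mean=(1 - pull) * own.adc_mean + pull * mid_adc,
    )


def _make_case(
    case_id: str,
    centre: str,
    is_responder: bool,
    split: str,
    spec: CohortSpec,
    rng: np.random.Generator,
    ambiguous: bool = False,
) -> StudyCase:
    tex = _effective_texture(spec, is_responder, ambiguous)
    dx, dy, dz = CENTRE_SPACING_T2W[centre]

    r_lo, r_hi = spec.tumour_radius_mm
    rx = rng.uniform(r_lo, r_hi)
    ry = rx * rng.uniform(0.8, 1.2)
    rz = rng.uniform(0.7, 0.9) * rx
    n_xy_mm = 2 * max(rx, ry) + 8.0
    n_rows = int(np.ceil(n_xy_mm / dy))
    n_cols = int(np.ceil(n_xy_mm / dx))
    n_slices = int(np.ceil((2 * rz + 2.5 * dz) / dz))
    shape = (n_slices, n_rows, n_cols)
    centre_mm = ((n_slices - 1) / 2 * dz, (n_rows - 1) / 2 * dy, (n_cols - 1) / 2 * dx)

    mask_vox = _ellipsoid(shape, (dx, dy, dz), (rz, ry, rx), centre_mm)

    # T2w: smooth background + tumour texture whose correlation length is the
    # class signal (in-plane; slices are thick and treated independently);
    # heavy-tailed case-level jitter makes the classes overlap realistically
    corr = tex.corr_length * float(np.exp(_t_jitter(rng, spec.corr_length_log_sd)))
    sigma_vox = (0.5, corr, corr)
    # the background emulates neighbouring tissue: signal level and texture
    # scale sit between the two tumour classes, so an imperfect (automatic)
    # mask leaks plausible tissue that dilutes, rather than biases, the signal
    mid_corr = np.sqrt(spec.responder_texture.corr_length * spec.nonresponder_texture.corr_length)
    background = 290.0 + 40.0 * _smooth_field(shape, (0.5, mid_corr, mid_corr), rng)
    texture = tex.contrast * _smooth_field(shape, sigma_vox, rng)
    t2w_vox = background + 8.0 * rng.standard_normal(shape)
    t2w_vox[mask_vox] = 320.0 + texture[mask_vox] + 8.0 * rng.standard_normal(int(mask_vox.sum()))
    t2w = ImageVolume(voxels=t2w_vox, spacing=(dx, dy, dz))

    # ADC on its native, coarser grid; resampled onto the T2w grid at ingestion
    adc_dx, adc_dy, adc_dz = CENTRE_SPACING_ADC[centre]
    adc_shape = (
        n_slices,
        int(np.ceil(n_rows * dy / adc_dy)) + 1,
        int(np.ceil(n_cols * dx / adc_dx)) + 1,
    )
    adc_mask = _ellipsoid(adc_shape, (adc_dx, adc_dy, adc_dz), (rz, ry, rx), centre_mm)
    case_mean = tex.adc_mean + _t_jitter(rng, spec.adc_case_sd)
    adc_bg = 0.5 * (spec.responder_texture.adc_mean + spec.nonresponder_texture.adc_mean)
    adc_vox = adc_bg + 0.1 * _smooth_field(adc_shape, (0.5, 1.5, 1.5), rng)
    adc_vox[adc_mask] = case_mean + spec.adc_voxel_sd * _smooth_field(
        adc_shape, (0.5, 1.0, 1.0), rng
    )[adc_mask]
    adc_native = ImageVolume(voxels=adc_vox, spacing=(adc_dx, adc_dy, adc_dz))
    adc = resample_to_grid(adc_native, t2w, mode="linear")

    manual = SegmentationMask(voxels=mask_vox, spacing=(dx, dy, dz), provenance="manual")
    target = float(np.clip(
        rng.normal(spec.mask_dsc_mean, spec.mask_dsc_spread), 0.05, 1.0
    ))
    automatic = perturb_mask(manual, target, seed=int(rng.integers(2**31 - 1)))

    if is_responder:
        trg = int(rng.choice(list(TRG_WEIGHTS_RESPONDER), p=list(TRG_WEIGHTS_RESPONDER.values())))
    else:
        trg = int(rng.choice(list(TRG_WEIGHTS_NONRESPONDER),
                             p=list(TRG_WEIGHTS_NONRESPONDER.values())))
    return StudyCase(
        id=case_id, centre=centre, t2w=t2w, adc=adc,
        masks={"manual": manual, "automatic": automatic}, trg=trg, split=split,
    )


def generate_cohort(spec: CohortSpec) -> list[StudyCase]:
    """Generate one cohort block, bit-reproducible given (spec, seed).

    Centre C cases are tagged ``validation``; centre A/B cases are split
    70/30 into ``construction-train`` / ``construction-test``, stratified by
    label.  Centres cycle over the requested tuple.
    """
    rng = np.random.default_rng(spec.rng_seed)
    labels = [True] * spec.n_responders + [False] * spec.n_nonresponders
    centres = [spec.centres[i % len(spec.centres)] for i in range(len(labels))]

    # stratified 70/30 construction-train/test assignment for centres A/B
    split_of: dict[int, str] = {}
    for is_resp in (True, False):
        members = [i for i, (lab, c) in enumerate(zip(labels, centres)) if lab == is_resp]
        constr = [i for i in members if centres[i] != "C"]
        n_train = int(round(0.7 * len(constr)))
        order = rng.permutation(len(constr))
        for rank, j in enumerate(order):
            split_of[constr[j]] = "construction-train" if rank < n_train else "construction-test"
        for i in members:
            if centres[i] == "C":
                split_of[i] = "validation"

    # a fixed number of borderline tumours per class
    ambiguous_idx: set[int] = set()
    for is_resp in (True, False):
        members = np.array([i for i, lab in enumerate(labels) if lab == is_resp])
        k = int(np.ceil(spec.ambiguous_fraction * len(members))) if spec.ambiguous_fraction else 0
        if k:
            ambiguous_idx.update(rng.choice(members, size=min(k, len(members)), replace=False))

    prefix = "2" if spec.centres == ("C",) else ""
    cases = []
    for i, (is_resp, centre) in enumerate(zip(labels, centres)):
        case_id = f"{prefix}{i + 1:03d}"
        cases.append(
            _make_case(case_id, centre, is_resp, split_of[i], spec, rng,
                       ambiguous=i in ambiguous_idx)
        )
    return cases


def generate_study_cohort(
    n_construction: tuple[int, int],
    n_validation: tuple[int, int],
    seed: int = 0,
    **spec_overrides,
) -> list[StudyCase]:
    """Construction (centres A+B) plus external validation (centre C) blocks."""
    constr = CohortSpec(
        n_responders=n_construction[0], n_nonresponders=n_construction[1],
        centres=("A", "B"), rng_seed=seed, **spec_overrides,
    )
    val = CohortSpec(
        n_responders=n_validation[0], n_nonresponders=n_validation[1],
        centres=("C",), rng_seed=seed + 1, **spec_overrides,
    )
    return generate_cohort(constr) + generate_cohort(val)


def _shift_mask(mask: np.ndarray, shift: tuple[int, int, int]) -> np.ndarray:
    out = np.zeros_like(mask)
    src = [slice(max(0, -s), mask.shape[i] - max(0, s)) for i, s in enumerate(shift)]
    dst = [slice(max(0, s), mask.shape[i] - max(0, -s)) for i, s in enumerate(shift)]
    out[tuple(dst)] = mask[tuple(src)]
    return out


def perturb_mask(
    mask: SegmentationMask,
    target_dsc: float,
    seed: int = 0,
    tol: float = 0.05,
    max_steps: int = 2000,
) -> SegmentationMask:
    """A seeded "automatic" mask at a controlled Dice overlap with the input.

    An in-plane translation along a random direction brackets the target,
    then random boundary voxels are added (lowering DSC) or boundary voxels
    outside the reference are removed (raising it) until the overlap is
    within ``target_dsc ± tol``.  ``target_dsc = 1`` returns the mask itself.
    """
    if not 0 < target_dsc <= 1:
        raise ValueError("target DSC must be in (0, 1]")
    a = mask.voxels

    def dsc_of(b: np.ndarray) -> float:
        s = int(a.sum() + b.sum())
        return 2.0 * int((a & b).sum()) / s if s else 1.0

    if target_dsc == 1.0:
        return SegmentationMask(voxels=a.copy(), spacing=mask.spacing, provenance="automatic")

    rng = np.random.default_rng(seed)
    theta = rng.uniform(0, 2 * np.pi)
    direction = np.array([0.0, np.sin(theta), np.cos(theta)])

    # coarse bracket: translate until DSC falls below the target
    best = a.copy()
    for s in range(1, max(a.shape) + 1):
        shift = tuple(int(round(s * d)) for d in direction)
        candidate = _shift_mask(a, shift)
        if dsc_of(candidate) < target_dsc:
            break
        best = candidate
    b = best  # DSC(b) >= target

    struct = np.zeros((3, 3, 3), dtype=bool)
    struct[1] = True  # in-plane 8-connectivity for boundary moves
    batch = max(1, int(a.sum()) // 100)
    for _ in range(max_steps):
        d = dsc_of(b)
        if abs(d - target_dsc) <= tol:
            mask_b = SegmentationMask(voxels=b, spacing=mask.spacing, provenance="automatic")
            return mask_b
        if d > target_dsc:  # grow outside the reference to dilute the overlap
            candidates = ndimage.binary_dilation(b, structure=struct) & ~b & ~a
            if not candidates.any():
                candidates = ndimage.binary_dilation(b, structure=struct) & ~b
        else:  # shrink the non-overlapping boundary to recover overlap
            boundary = b & ~ndimage.binary_erosion(b, structure=struct)
            candidates = boundary & ~a
            if not candidates.any():
                break
        idx = np.flatnonzero(candidates.ravel())
        take = rng.choice(idx, size=min(batch, len(idx)), replace=False)
        flat = b.ravel().copy()
        flat[take] = d > target_dsc  # grow when overlap is too high, else shrink
        b = flat.reshape(b.shape)
    raise RuntimeError(f"could not reach target DSC {target_dsc} within {max_steps} steps")


@dataclass(frozen=True)
class TabularSpec:
    """Synthetic feature-table conditions with known informative structure."""

    n_cases: int = 67
    n_features: int = 157
    n_informative: int = 10
    effect_size: float = 0.8  # standardized class shift of informative features
    redundancy_r: float = 0.9  # correlation of each informative duplicate
    class_balance: float = 0.5
    # label-independent features come in equicorrelated blocks, mirroring the
    # heavy redundancy of real radiomics catalogues ("independent" for i.i.d.)
    noise_structure: str = "blocks"
    noise_block_size: int = 10
    noise_block_r: float = 0.9
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if 2 * self.n_informative > self.n_features:
            raise ValueError("informative block (originals + duplicates) exceeds n_features")
        if not abs(self.redundancy_r) < 1:
            raise ValueError("|redundancy_r| must be < 1")


def generate_feature_table(spec: TabularSpec) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Gaussian feature table: informative block, correlated copies, noise.

    Returns (features, labels, truth) where truth lists the informative,
    duplicate and noise column names.  Informative features are shifted by
    ``effect_size`` standard deviations in the responder class; each has one
    duplicate at correlation ``redundancy_r`` (itself carrying the attenuated
    shift r*d); remaining columns are independent standard normal noise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, p, k = spec.n_cases, spec.n_features, spec.n_informative
    n_pos = int(round(spec.class_balance * n))
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    rng.shuffle(y)

    informative = rng.standard_normal((n, k)) + spec.effect_size * y[:, None]
    r = spec.redundancy_r
    duplicates = r * informative + np.sqrt(1 - r * r) * rng.standard_normal((n, k))
    n_noise = p - 2 * k
    if spec.noise_structure == "independent":
        noise = rng.standard_normal((n, n_noise))
    elif spec.noise_structure == "blocks":
        rb = spec.noise_block_r
        cols = []
        while len(cols) < n_noise:
            shared = rng.standard_normal(n)
            for _ in range(min(spec.noise_block_size, n_noise - len(cols))):
                cols.append(np.sqrt(rb) * shared + np.sqrt(1 - rb) * rng.standard_normal(n))
        noise = np.column_stack(cols)
    else:
        raise ValueError(f"unknown noise structure {spec.noise_structure!r}")

    inf_names = [f"informative_{i:02d}" for i in range(k)]
    dup_names = [f"duplicate_{i:02d}" for i in range(k)]
    noise_names = [f"noise_{i:03d}" for i in range(p - 2 * k)]
    table = pd.DataFrame(
        np.hstack([informative, duplicates, noise]),
        columns=inf_names + dup_names + noise_names,
    )
    truth = {"informative": inf_names, "duplicates": dup_names, "noise": noise_names}
    return table, y, truth


def write_cohort(cases: list[StudyCase], out_dir) -> str:
    """Write cohort volumes/masks as NIfTI plus the clinical CSV; returns the CSV path."""
    import os

    from .imaging import write_volume

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for case in cases:
        paths = {
            "t2w_path": f"{case.id}_t2w.nii.gz",
            "adc_path": f"{case.id}_adc.nii.gz",
            "mask_manual_path": f"{case.id}_mask_manual.nii.gz",
        }
        write_volume(case.t2w, os.path.join(out_dir, paths["t2w_path"]))
        write_volume(case.adc, os.path.join(out_dir, paths["adc_path"]))
        man = case.masks["manual"]
        write_volume(ImageVolume(man.voxels.astype(np.uint8), man.spacing),
                     os.path.join(out_dir, paths["mask_manual_path"]))
        if "automatic" in case.masks:
            auto = case.masks["automatic"]
            paths["mask_automatic_path"] = f"{case.id}_mask_automatic.nii.gz"
            write_volume(ImageVolume(auto.voxels.astype(np.uint8), auto.spacing),
                         os.path.join(out_dir, paths["mask_automatic_path"]))
        rows.append({"id": case.id, "centre": case.centre, "trg": case.trg,
                     "split": case.split, **paths})
    csv_path = os.path.join(out_dir, "clinical.csv")
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path
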