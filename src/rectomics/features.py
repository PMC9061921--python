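"""Texture and first-order feature computation with 2.5D aggregation.

Feature definitions follow the reference (IBSI-style) formulas for each
matrix family.  Features are computed per axial slice — and per in-plane
direction for the co-occurrence and run-length families — then averaged:
directions within a slice first, slices second.  Degenerate matrices (single
grey level, single run, ...) take documented limit conventions and never
produce NaN.

Logs are base 2; 0·log(0) terms are dropped.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np

from .catalogue import FAMILY_FEATURES, feature_name
from .imaging import StudyCase, roi_volume_mm3
from .matrices import (
    NeighbourhoodConfig,
    TextureMatrix,
    glcm_matrix,
    glrlm_matrix,
    glszm_matrix,
    gldm_matrix,
    ngtdm_matrix,
)
from .preprocessing import (
    DiscretizationConfig,
    ResegmentationConfig,
    discretize,
    resegment,
    slice_decompose,
)

__all__ = [
    "compute_family_features",
    "aggregate_25d",
    "adc_first_order",
    "extract_case_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "ngtdm_features",
    "gldm_features",
]


def _xlog2(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features(matrix: TextureMatrix) -> dict[str, float]:
    """The 25 co-occurrence features (24 reference features plus sum variance)."""
    counts = matrix.values
    total = counts.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    p = counts / total
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    px = p.sum(axis=1)  # == py by symmetry
    n_present = int((px > 0).sum())
    mu = float(i @ px)
    sigma2 = float(((i - mu) ** 2) @ px)
    sigma = np.sqrt(sigma2)

    ii, jj = np.meshgrid(i, i, indexing="ij")
    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(ng, dtype=float)  # |i-j| = 0..ng-1
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).astype(int), p)
    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).astype(int) - 2, p)

    autocorr = float((ii * jj * p).sum())
    diff_avg = float(k_diff @ p_diff)
    sum_avg = float(k_sum @ p_sum)
    hxy = -float(_xlog2(p).sum())
    hx = -float(_xlog2(px).sum())
    pxpy = np.outer(px, px)
    mask = (p > 0) & (pxpy > 0)
    hxy1 = -float((p[mask] * np.log2(pxpy[mask])).sum())
    hxy2 = -float(_xlog2(pxpy).sum())

    if sigma > 0:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = 0.0  # flat ROI convention

    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0  # HX == HY by symmetry
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    # maximal correlation coefficient works on the level-cropped matrix
    present = px > 0
    if n_present > 1:
        psub = p[np.ix_(present, present)]
        pxs = psub.sum(axis=1)
        q = (psub / pxs[:, None]) @ (psub / pxs[None, :]).T
        eig = np.sort(np.real(np.linalg.eigvals(q)))
        mcc = float(np.sqrt(max(0.0, eig[-2])))
    else:
        mcc = 1.0

    ngd = float(n_present)
    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": float((((ii + jj) - 2 * mu) ** 4 * p).sum()),
        "ClusterShade": float((((ii + jj) - 2 * mu) ** 3 * p).sum()),
        "ClusterTendency": float((((ii + jj) - 2 * mu) ** 2 * p).sum()),
        "Contrast": float(((ii - jj) ** 2 * p).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": -float(_xlog2(p_diff).sum()),
        "DifferenceVariance": float(((k_diff - diff_avg) ** 2) @ p_diff),
        "Id": float((p_diff / (1.0 + k_diff)).sum()),
        "Idm": float((p_diff / (1.0 + k_diff**2)).sum()),
        "Idmn": float((p_diff / (1.0 + (k_diff / ngd) ** 2)).sum()),
        "Idn": float((p_diff / (1.0 + k_diff / ngd)).sum()),
        "Imc1": float(imc1),
        "Imc2": imc2,
        "InverseVariance": float((p_diff[1:] / k_diff[1:] ** 2).sum()) if ng > 1 else 0.0,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": hxy,
        "MCC": mcc,
        "MaximumProbability": float(p.max()),
        "SumAverage": sum_avg,
        "SumEntropy": -float(_xlog2(p_sum).sum()),
        "SumSquares": sigma2,
        "SumVariance": float(((k_sum - sum_avg) ** 2) @ p_sum),
    }


def _size_weighted_features(
    counts: np.ndarray, n_pixels: int, names: Mapping[str, str]
) -> dict[str, float]:
    """Shared arithmetic for the run-length / size-zone / dependence families.

    ``counts`` is (levels x sizes); ``names`` maps the 16 generic roles to the
    family's feature names.
    """
    total = counts.sum()
    if total == 0:
        raise ValueError("empty texture matrix")
    p = counts / total
    ng, ns = counts.shape
    iv = np.arange(1, ng + 1, dtype=float)
    jv = np.arange(1, ns + 1, dtype=float)
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(iv @ pi)
    mu_j = float(jv @ pj)
    out = {
        names["small"]: float(pj @ (1.0 / jv**2)),
        names["large"]: float(pj @ jv**2),
        names["gln"]: float((counts.sum(axis=1) ** 2).sum() / total),
        names["glnn"]: float((pi**2).sum()),
        names["sn"]: float((counts.sum(axis=0) ** 2).sum() / total),
        names["snn"]: float((pj**2).sum()),
        names["percentage"]: float(total / n_pixels),
        names["glv"]: float(((iv - mu_i) ** 2) @ pi),
        names["sv"]: float(((jv - mu_j) ** 2) @ pj),
        names["entropy"]: -float(_xlog2(p).sum()),
        names["lowgl"]: float(pi @ (1.0 / iv**2)),
        names["highgl"]: float(pi @ iv**2),
        names["small_low"]: float((p / np.outer(iv**2, jv**2)).sum()),
        names["small_high"]: float((p * np.outer(iv**2, 1.0 / jv**2)).sum()),
        names["large_low"]: float((p * np.outer(1.0 / iv**2, jv**2)).sum()),
        names["large_high"]: float((p * np.outer(iv**2, jv**2)).sum()),
    }
    return out


_GLRLM_NAMES = {
    "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "RunLengthNonUniformity", "snn": "RunLengthNonUniformityNormalized",
    "percentage": "RunPercentage", "glv": "GrayLevelVariance", "sv": "RunVariance",
    "entropy": "RunEntropy", "lowgl": "LowGrayLevelRunEmphasis",
    "highgl": "HighGrayLevelRunEmphasis",
    "small_low": "ShortRunLowGrayLevelEmphasis", "small_high": "ShortRunHighGrayLevelEmphasis",
    "large_low": "LongRunLowGrayLevelEmphasis", "large_high": "LongRunHighGrayLevelEmphasis",
}

_GLSZM_NAMES = {
    "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
    "gln": "GrayLevelNonUniformity", "glnn": "GrayLevelNonUniformityNormalized",
    "sn": "SizeZoneNonUniformity", "snn": "SizeZoneNonUniformityNormalized",
    "percentage": "ZonePercentage", "glv": "GrayLevelVariance", "sv": "ZoneVariance",
    "entropy": "ZoneEntropy", "lowgl": "LowGrayLevelZoneEmphasis",
    "highgl": "HighGrayLevelZoneEmphasis",
    "small_low": "SmallAreaLowGrayLevelEmphasis", "small_high": "SmallAreaHighGrayLevelEmphasis",
    "large_low": "LargeAreaLowGrayLevelEmphasis", "large_high": "LargeAreaHighGrayLevelEmphasis",
}


def glrlm_features(matrix: TextureMatrix) -> dict[str, float]:
    """The 16 run-length features (run percentage uses the slice ROI pixel count)."""
    return _size_weighted_features(matrix.values, matrix.n_roi_pixels, _GLRLM_NAMES)


def glszm_features(matrix: TextureMatrix) -> dict[str, float]:
    return _size_weighted_features(matrix.values, matrix.n_roi_pixels, _GLSZM_NAMES)


def gldm_features(matrix: TextureMatrix) -> dict[str, float]:
    """The 14 dependence features (the dependence family has no percentage,
    no normalized grey-level non-uniformity and no plain entropy analogue on
    the grey-level margin)."""
    generic = _size_weighted_features(
        matrix.values, matrix.n_roi_pixels, {
            "small": "SmallDependenceEmphasis", "large": "LargeDependenceEmphasis",
            "gln": "GrayLevelNonUniformity", "glnn": "_drop_glnn",
            "sn": "DependenceNonUniformity", "snn": "DependenceNonUniformityNormalized",
            "percentage": "_drop_percentage", "glv": "GrayLevelVariance",
            "sv": "DependenceVariance", "entropy": "DependenceEntropy",
            "lowgl": "LowGrayLevelEmphasis", "highgl": "HighGrayLevelEmphasis",
            "small_low": "SmallDependenceLowGrayLevelEmphasis",
            "small_high": "SmallDependenceHighGrayLevelEmphasis",
            "large_low": "LargeDependenceLowGrayLevelEmphasis",
            "large_high": "LargeDependenceHighGrayLevelEmphasis",
        },
    )
    generic.pop("_drop_glnn")
    generic.pop("_drop_percentage")
    return generic


def ngtdm_features(matrix: TextureMatrix) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength."""
    n_i, s_i = matrix.values
    nvp = n_i.sum()
    if nvp == 0:
        raise ValueError("NGTDM has no valid pixels")
    p_i = n_i / nvp
    ng = len(n_i)
    levels = np.arange(1, ng + 1, dtype=float)
    nz = p_i > 0
    ngp = int(nz.sum())

    coarse_denom = float(p_i @ s_i)
    coarseness = 1.0 / coarse_denom if coarse_denom > 0 else 1e6  # flat-ROI cap

    if ngp > 1:
        li, lj = np.meshgrid(levels[nz], levels[nz], indexing="ij")
        pi2 = np.outer(p_i[nz], p_i[nz])
        contrast = float((pi2 * (li - lj) ** 2).sum()) / (ngp * (ngp - 1)) * float(s_i.sum()) / nvp
        ipi = levels[nz] * p_i[nz]
        busy_denom = float(np.abs(ipi[:, None] - ipi[None, :]).sum())
        busyness = coarse_denom / busy_denom if busy_denom > 0 else 0.0
        ps = p_i[nz] * s_i[nz]
        complexity = float(
            (np.abs(li - lj) * (ps[:, None] + ps[None, :])
             / (p_i[nz][:, None] + p_i[nz][None, :])).sum()
        ) / nvp
        s_sum = float(s_i.sum())
        strength = (
            float(((p_i[nz][:, None] + p_i[nz][None, :]) * (li - lj) ** 2).sum()) / s_sum
            if s_sum > 0 else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Coarseness": coarseness,
        "Contrast": contrast,
        "Busyness": busyness,
        "Complexity": complexity,
        "Strength": strength,
    }


_FAMILY_FUNCS = {
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}

DIRECTIONAL_FAMILIES = ("glcm", "glrlm")


def compute_family_features(family: str, matrix: TextureMatrix) -> dict[str, float]:
    """Named feature values for one texture matrix."""
    if family not in _FAMILY_FUNCS:
        raise ValueError(f"unknown texture family {family!r}")
    values = _FAMILY_FUNCS[family](matrix)
    expected = FAMILY_FEATURES[family]
    assert set(values) == set(expected), f"{family} features do not match the catalogue"
    if not all(np.isfinite(v) for v in values.values()):
        bad = [k for k, v in values.items() if not np.isfinite(v)]
        raise ValueError(f"non-finite {family} features: {bad}")
    return values


def aggregate_25d(
    per_slice: Sequence[Mapping[str, float] | Sequence[Mapping[str, float]]],
) -> dict[str, float]:
    """2.5D aggregation: average directions within each slice, then slices.

    Each element of ``per_slice`` is either one feature dict (non-directional
    family) or a sequence of per-direction dicts for that slice.
    """
    if not per_slice:
        raise ValueError("need at least one retained slice")
    slice_means = []
    for entry in per_slice:
        if isinstance(entry, Mapping):
            slice_means.append(dict(entry))
        else:
            keys = entry[0].keys()
            slice_means.append({k: float(np.mean([d[k] for d in entry])) for k in keys})
    keys = slice_means[0].keys()
    return {k: float(np.mean([d[k] for d in slice_means])) for k in keys}


def adc_first_order(values: np.ndarray) -> dict[str, float]:
    """First-order statistics of raw (re-segmented, unnormalized) ADC values.

    Standard deviation uses the n-1 denominator; skewness is m3/m2^1.5 and
    kurtosis m4/m2^2, both moment estimators without small-sample correction.
    A degenerate (constant) sample returns 0 for both by convention.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 ADC values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    m2 = float(((values - mean) ** 2).mean())
    # a numerically constant sample is degenerate even if rounding leaves dust
    if sd <= 1e-12 * (1.0 + abs(mean)):
        sd = 0.0
        m2 = 0.0
    if m2 > 0:
        m3 = float(((values - mean) ** 3).mean())
        m4 = float(((values - mean) ** 4).mean())
        skew = m3 / m2**1.5
        kurt = m4 / m2**2
    else:
        skew = kurt = 0.0
    return {"Mean": mean, "StandardDeviation": sd, "Skewness": skew, "Kurtosis": kurt}


def _modality_texture_features(
    slices: list[np.ndarray], modality: str, nbh: NeighbourhoodConfig
) -> dict[str, float]:
    """76 texture features for one modality from its per-slice level grids.

    Degenerate geometry handling: a direction whose co-occurrence matrix is
    empty on a slice (e.g. two isolated apex pixels) is skipped in that
    slice's direction average, and a slice that supports no valid matrix for
    a family (no pixel pairs, no valid neighbourhoods) is skipped in that
    family's slice average.  A family with no usable slice at all is an error.
    """
    out: dict[str, float] = {}
    n_levels_of = [int(s.max()) for s in slices]

    per_slice_dir: dict[str, list] = {f: [] for f in _FAMILY_FUNCS}
    for grid, ng in zip(slices, n_levels_of):
        glcm_dirs = [
            m for a in nbh.angles
            if (m := glcm_matrix(grid, ng, angle=a, distance=nbh.distance)).values.sum() > 0
        ]
        if glcm_dirs:
            per_slice_dir["glcm"].append([glcm_features(m) for m in glcm_dirs])
        per_slice_dir["glrlm"].append(
            [glrlm_features(glrlm_matrix(grid, ng, angle=a)) for a in nbh.angles]
        )
        per_slice_dir["glszm"].append(glszm_features(glszm_matrix(grid, ng)))
        ngtdm = ngtdm_matrix(grid, ng)
        if ngtdm.values[0].sum() > 0:
            per_slice_dir["ngtdm"].append(ngtdm_features(ngtdm))
        per_slice_dir["gldm"].append(gldm_features(gldm_matrix(grid, ng, alpha=nbh.gldm_alpha)))

    for family, entries in per_slice_dir.items():
        if not entries:
            raise ValueError(f"no slice supports {family} features")
        agg = aggregate_25d(entries)
        for fname, val in agg.items():
            out[feature_name(modality, family, fname)] = val
    return out


def extract_case_features(
    case: StudyCase,
    provenance: str = "manual",
    reseg: ResegmentationConfig = ResegmentationConfig(),
    disc: DiscretizationConfig = DiscretizationConfig(),
    nbh: NeighbourhoodConfig = NeighbourhoodConfig(),
    min_slice_pixels: int = 2,
) -> dict[str, float]:
    """The full 157-feature vector for one case and mask provenance.

    T2w textures come from the discretized T2w ROI, ADC textures from the
    discretized ADC ROI; each modality is re-segmented independently under
    the same drawn mask.  ROI volume uses the original (morphological) mask.
    """
    if provenance not in case.masks:
        raise KeyError(f"case {case.id}: no {provenance!r} mask")
    mask = case.masks[provenance]
    try:
        out: dict[str, float] = {
            feature_name("t2w", "shape", "roi_volume"): roi_volume_mm3(mask, case.t2w.spacing)
        }
        for modality, volume in (("t2w", case.t2w), ("adc", case.adc)):
            refined = resegment(volume, mask, reseg)
            droi = discretize(volume, refined, disc, modality=modality)
            slices = slice_decompose(droi, min_slice_pixels)
            out.update(_modality_texture_features(slices, modality, nbh))
            if modality == "adc":
                stats = adc_first_order(volume.voxels[refined.voxels])
                for sname, val in stats.items():
                    out[feature_name("adc", "firstorder", sname)] = val
    except ValueError as exc:
        raise ValueError(f"case {case.id} ({provenance}): {exc}") from exc
    return out
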