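"""The 157-feature catalogue: the single source of truth for feature names.

Per modality the five matrix families contribute 25 (co-occurrence, the 24
reference features plus sum variance), 16 (run length), 16 (size zone),
5 (grey-tone difference) and 14 (dependence) features = 76 texture features;
T2w additionally carries the ROI volume and ADC four first-order statistics,
for 77 T2w-derived + 80 ADC-derived = 157 names in total.
"""

from __future__ import annotations

import json
import os

__all__ = [
    "FAMILY_FEATURES",
    "FIRSTORDER_FEATURES",
    "MODALITIES",
    "feature_name",
    "build_catalogue",
    "catalogue_names",
    "export_catalogue",
]

GLCM_FEATURES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "Id", "Idm", "Idmn", "Idn",
    "Imc1", "Imc2", "InverseVariance", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "SumVariance",
]

GLRLM_FEATURES = [
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
]

GLSZM_FEATURES = [
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
]

NGTDM_FEATURES = ["Coarseness", "Contrast", "Busyness", "Complexity", "Strength"]

GLDM_FEATURES = [
    "SmallDependenceEmphasis", "LargeDependenceEmphasis", "GrayLevelNonUniformity",
    "DependenceNonUniformity", "DependenceNonUniformityNormalized",
    "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
    "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LargeDependenceHighGrayLevelEmphasis",
]

FAMILY_FEATURES: dict[str, list[str]] = {
    "glcm": GLCM_FEATURES,
    "glrlm": GLRLM_FEATURES,
    "glszm": GLSZM_FEATURES,
    "ngtdm": NGTDM_FEATURES,
    "gldm": GLDM_FEATURES,
}

FIRSTORDER_FEATURES = ["Mean", "StandardDeviation", "Skewness", "Kurtosis"]

MODALITIES = ("t2w", "adc")


def feature_name(modality: str, family: str, feature: str) -> str:
    return f"{modality}.{family}.{feature}"


def build_catalogue() -> list[dict[str, str]]:
    """Ordered catalogue entries with (name, modality, family, feature)."""
    entries = [
        {"name": feature_name("t2w", "shape", "roi_volume"),
         "modality": "t2w", "family": "shape", "feature": "roi_volume"}
    ]
    for stat in FIRSTORDER_FEATURES:
        entries.append(
            {"name": feature_name("adc", "firstorder", stat),
             "modality": "adc", "family": "firstorder", "feature": stat}
        )
    for modality in MODALITIES:
        for family, feats in FAMILY_FEATURES.items():
            for feat in feats:
                entries.append(
                    {"name": feature_name(modality, family, feat),
                     "modality": modality, "family": family, "feature": feat}
                )
    names = [e["name"] for e in entries]
    assert len(names) == len(set(names)) == 157
    return entries


def catalogue_names(modality: str | None = None) -> list[str]:
    entries = build_catalogue()
    if modality is not None:
        entries = [e for e in entries if e["modality"] == modality]
    return [e["name"] for e in entries]


def export_catalogue(path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(build_catalogue(), fh, indent=2)
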