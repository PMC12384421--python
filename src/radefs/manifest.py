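"""Radiomics feature manifest: the canonical 120-feature naming scheme.

Features are named ``<family>_<FeatureName>`` so that tables produced by the
built-in extractor and synthetic tables generated by :mod:`radefs.simulate`
share one schema.  The default manifest covers eight families: first-order
intensity statistics, 3D and 2D shape descriptors, and five gray-level texture
matrix families (GLCM, GLRLM, GLSZM, GLDM, NGTDM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

FAMILIES = (
    "firstorder",
    "shape3d",
    "shape2d",
    "glcm",
    "glrlm",
    "glszm",
    "gldm",
    "ngtdm",
)

_FIRSTORDER = [
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
    "Variance", "Uniformity",
]  # 19

_SHAPE3D = [
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "Compactness1", "SphericalDisproportion",
    "Maximum3DDiameter", "Maximum2DDiameterSlice", "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow", "MajorAxisLength", "MinorAxisLength",
    "LeastAxisLength", "Elongation", "Flatness",
]  # 16

_SHAPE2D = [
    "MeshSurface", "PixelSurface", "Perimeter", "PerimeterSurfaceRatio",
    "Sphericity", "SphericalDisproportion", "MaximumDiameter",
    "MajorAxisLength", "MinorAxisLength", "Elongation",
]  # 10

_GLCM = [
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
]  # 24

_GLRLM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
]  # 16

_GLSZM = [
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
]  # 16

_GLDM = [
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
]  # 14

_NGTDM = ["Busyness", "Coarseness", "Complexity", "Contrast", "Strength"]  # 5

_DEFAULT_FAMILY_FEATURES: dict[str, list[str]] = {
    "firstorder": _FIRSTORDER,
    "shape3d": _SHAPE3D,
    "shape2d": _SHAPE2D,
    "glcm": _GLCM,
    "glrlm": _GLRLM,
    "glszm": _GLSZM,
    "gldm": _GLDM,
    "ngtdm": _NGTDM,
}


@dataclass(frozen=True)
class FeatureManifest:
    """Ordered feature names plus a name -> family map.

    Invariants (checked on construction): names are unique and every name has
    exactly one family tag drawn from :data:`FAMILIES`.
    """

    names: tuple[str, ...]
    family: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("manifest names must be unique")
        missing = [n for n in self.names if n not in self.family]
        if missing:
            raise ValueError(f"names without a family tag: {missing[:5]}")
        bad = {f for f in self.family.values() if f not in FAMILIES}
        if bad:
            raise ValueError(f"unknown feature families: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in set(self.names)

    def names_in_family(self, family: str) -> list[str]:
        return [n for n in self.names if self.family[n] == family]

    def subset(self, names: list[str]) -> "FeatureManifest":
        unknown = [n for n in names if n not in self.family]
        if unknown:
            raise KeyError(f"names not in manifest: {unknown[:5]}")
        return FeatureManifest(tuple(names), {n: self.family[n] for n in names})


def default_manifest() -> FeatureManifest:
    """The canonical 120-feature manifest (all families, default classes)."""
    names: list[str] = []
    family: dict[str, str] = {}
    for fam in FAMILIES:
        for feat in _DEFAULT_FAMILY_FEATURES[fam]:
            name = f"{fam}_{feat}"
            names.append(name)
            family[name] = fam
    return FeatureManifest(tuple(names), family)
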