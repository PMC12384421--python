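"""Feature extraction from CT volume + segmentation mask pairs.

The extractor computes the full default manifest (120 features across eight
families) from a 3D image and a label mask.  Inputs may be numpy arrays,
``SimpleITK.Image`` objects, or file paths — NRRD files and DICOM series
directories are read through SimpleITK.

Mask semantics: any nonzero voxel belongs to the region of interest; for
multi-label masks pass ``label=`` explicitly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk

from . import _texture
from ._shape import shape2d_features, shape3d_features
from .manifest import FeatureManifest, default_manifest

_EPS = np.finfo(float).eps


class GeometryError(ValueError):
    """Image and mask do not share dimensions/spacing."""


class EmptyROIError(ValueError):
    """Mask contains no labeled voxel."""


def load_volume(source) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load (array, spacing) from an array, SimpleITK image, NRRD file or
    DICOM series directory.  Arrays are returned in (z, y, x) axis order with
    spacing in the same order."""
    if isinstance(source, np.ndarray):
        return np.asarray(source), (1.0, 1.0, 1.0)
    if isinstance(source, sitk.Image):
        img = source
    else:
        path = Path(source)
        if path.is_dir():  # DICOM series
            reader = sitk.ImageSeriesReader()
            files = reader.GetGDCMSeriesFileNames(str(path))
            if not files:
                raise FileNotFoundError(f"no DICOM series found in {path}")
            reader.SetFileNames(files)
            img = reader.Execute()
        else:
            img = sitk.ReadImage(str(path))
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    sp = img.GetSpacing()  # (x, y, z)
    return arr, (sp[2], sp[1], sp[0])


def firstorder_features(
    image: np.ndarray,
    mask: np.ndarray,
    spacing: tuple[float, float, float],
    n_bins: int = 16,
) -> dict[str, float]:
    x = image[mask].astype(float)
    voxel_volume = float(np.prod(spacing))
    hist = np.bincount(_texture.quantize(image, mask, n_bins)[mask] - 1,
                       minlength=n_bins).astype(float)
    p = hist / hist.sum()
    q25, q75 = np.percentile(x, [25, 75])
    p10, p90 = np.percentile(x, [10, 90])
    robust = x[(x >= p10) & (x <= p90)]
    energy = float((x**2).sum())
    return {
        "Energy": energy,
        "TotalEnergy": energy * voxel_volume,
        "Entropy": -float((p * np.log2(p + _EPS)).sum()),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(x.mean()),
        "Median": float(np.median(x)),
        "InterquartileRange": float(q75 - q25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - x.mean()).mean()),
        "RobustMeanAbsoluteDeviation": (
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0
        ),
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "StandardDeviation": float(x.std()),
        "Skewness": _skew(x),
        "Kurtosis": _kurt(x),
        "Variance": float(x.var()),
        "Uniformity": float((p**2).sum()),
    }


def _skew(x: np.ndarray) -> float:
    s = x.std()
    return float(((x - x.mean()) ** 3).mean() / s**3) if s > _EPS else 0.0


def _kurt(x: np.ndarray) -> float:
    s = x.std()
    return float(((x - x.mean()) ** 4).mean() / s**4) if s > _EPS else 0.0


def extract_features(
    image,
    mask,
    manifest: FeatureManifest | None = None,
    label: int | None = None,
    n_bins: int = 16,
) -> dict[str, float]:
    """Compute the manifest's features for one image/mask pair.

    Returns a dict keyed by manifest names, in manifest order.  Raises
    :class:`GeometryError` on shape/spacing mismatch and
    :class:`EmptyROIError` when the mask selects no voxel.
    """
    manifest = manifest or default_manifest()
    img_arr, img_sp = load_volume(image)
    msk_arr, msk_sp = load_volume(mask)
    if img_arr.shape != msk_arr.shape:
        raise GeometryError(
            f"image shape {img_arr.shape} != mask shape {msk_arr.shape}"
        )
    if not isinstance(image, np.ndarray) and not isinstance(mask, np.ndarray):
        if not np.allclose(img_sp, msk_sp, rtol=1e-4):
            raise GeometryError(f"image spacing {img_sp} != mask spacing {msk_sp}")
    spacing = img_sp
    if label is None:
        roi = msk_arr != 0
    else:
        roi = msk_arr == label
    if not roi.any():
        raise EmptyROIError("mask selects no voxels")
    img_arr = img_arr.astype(float)

    q = _texture.quantize(img_arr, roi, n_bins)
    by_family = {
        "firstorder": firstorder_features(img_arr, roi, spacing, n_bins),
        "shape3d": shape3d_features(roi, spacing),
        "shape2d": shape2d_features(roi, spacing),
        "glcm": _texture.glcm_features(_texture.glcm_matrix(q, roi, n_bins)),
        "glrlm": _texture.glrlm_features(q, roi, n_bins),
        "glszm": _texture.glszm_features(q, roi, n_bins),
        "gldm": _texture.gldm_features(q, roi, n_bins),
        "ngtdm": _texture.ngtdm_features(q, roi, n_bins),
    }
    out: dict[str, float] = {}
    missing = []
    for name in manifest.names:
        fam = manifest.family[name]
        feat = name[len(fam) + 1 :]
        if fam not in by_family or feat not in by_family[fam]:
            missing.append(name)
        else:
            out[name] = by_family[fam][feat]
    if missing:
        raise KeyError(f"extractor does not produce features: {missing[:5]}")
    return out
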