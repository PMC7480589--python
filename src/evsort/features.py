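"""Classical per-channel image features (the CP-RF baseline's inputs).

A compact, documented feature schema standing in for a full CellProfiler
pipeline: per channel it covers the same families a CP measurement run would
produce — intensity statistics, morphology of the thresholded object,
Haralick texture at distance 1, a small granularity spectrum, and spot-like
descriptors. 26 features per channel, 52 per cell, each tagged with its
source channel so channel-wise importance analysis stays possible.

All values are deterministic functions of the pixel data alone and are
defined (finite) on degenerate inputs such as constant images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import feature as skfeature
from skimage import filters as skfilters
from skimage import measure as skmeasure
from skimage import morphology as skmorph

from .io import CellImage

__all__ = [
    "ClassicFeatureConfig",
    "feature_names",
    "feature_channels",
    "extract_classic_features",
    "extract_classic_features_batch",
]

_CHANNEL_TAGS = ("bf", "fl")
_QUANTILES = (0.10, 0.25, 0.75, 0.90)
_GRANULARITY_RADII = (1, 2, 4)
_HARALICK_PROPS = ("contrast", "dissimilarity", "homogeneity", "ASM",
                   "energy", "correlation")


@dataclass
class ClassicFeatureConfig:
    texture_levels: int = 32           # grey levels for the co-occurrence matrix
    peak_min_distance: int = 2
    peak_sd_factor: float = 3.0        # local-max threshold: median + k * sd


def _per_channel_names() -> list[str]:
    names = ["mean", "median", "sd", "mass", "min", "max"]
    names += [f"q{int(q * 100)}" for q in _QUANTILES]
    names += ["area", "perimeter", "eccentricity", "solidity"]
    names += [f"haralick_{p}" for p in _HARALICK_PROPS]
    names += [f"granularity_r{r}" for r in _GRANULARITY_RADII]
    names += ["n_local_maxima", "max_mean_ratio", "max_minus_median"]
    return names


def feature_names(config: ClassicFeatureConfig | None = None) -> list[str]:
    """Full ordered schema: channel-tagged feature names."""
    return [f"{tag}_{n}" for tag in _CHANNEL_TAGS for n in _per_channel_names()]


def feature_channels(config: ClassicFeatureConfig | None = None) -> np.ndarray:
    """Source channel of each feature ('brightfield' / 'fluorescence')."""
    per = len(_per_channel_names())
    return np.array(["brightfield"] * per + ["fluorescence"] * per)


def _morphology(img: np.ndarray) -> list[float]:
    """Area/perimeter/eccentricity/solidity of the Otsu-thresholded object.

    The object is the largest connected component above (fluorescence-style,
    bright-object) Otsu; degenerate images with no contrast yield zeros.
    """
    vals = img.ravel()
    if vals.max() == vals.min():
        return [0.0, 0.0, 0.0, 0.0]
    thr = skfilters.threshold_otsu(img)
    mask = img > thr
    if not mask.any():
        return [0.0, 0.0, 0.0, 0.0]
    lab, n = ndi.label(mask)
    sizes = ndi.sum(mask, lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    solidity = props.solidity if props.area > 0 else 0.0
    return [float(props.area), float(props.perimeter),
            float(props.eccentricity), float(solidity)]


def _haralick(img: np.ndarray, levels: int) -> list[float]:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        # constant image: all mass on one grey level -> zero contrast and
        # dissimilarity, full homogeneity/ASM/energy; correlation undefined,
        # defined here as 0
        return [0.0, 0.0, 1.0, 1.0, 1.0, 0.0]
    q = np.clip(((img - lo) / (hi - lo) * levels).astype(np.int64),
                0, levels - 1).astype(np.uint8)
    glcm = skfeature.graycomatrix(
        q, distances=[1], angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels, symmetric=True, normed=True)
    out = []
    for prop in _HARALICK_PROPS:
        v = skfeature.graycoprops(glcm, prop)
        out.append(float(np.mean(v)))
    return out


def _granularity(img: np.ndarray) -> list[float]:
    """Fraction of total intensity removed by opening at increasing radii."""
    total = float(img.sum())
    if total <= 0:
        return [0.0] * len(_GRANULARITY_RADII)
    out = []
    for r in _GRANULARITY_RADII:
        opened = ndi.grey_opening(img, footprint=skmorph.disk(r))
        out.append(float(1.0 - opened.sum() / total))
    return out


def _spot_like(img: np.ndarray, cfg: ClassicFeatureConfig) -> list[float]:
    med, sd = float(np.median(img)), float(img.std())
    thr = med + cfg.peak_sd_factor * sd
    if sd == 0:
        n_peaks = 0.0
    else:
        peaks = skfeature.peak_local_max(
            img, min_distance=cfg.peak_min_distance, threshold_abs=thr)
        n_peaks = float(len(peaks))
    mean = float(img.mean())
    ratio = float(img.max()) / mean if mean > 0 else 1.0
    return [n_peaks, ratio, float(img.max()) - med]


def _channel_features(img: np.ndarray, cfg: ClassicFeatureConfig) -> list[float]:
    v = img.ravel().astype(np.float64)
    feats = [v.mean(), float(np.median(v)), v.std(), v.sum(),
             float(v.min()), float(v.max())]
    feats += [float(np.quantile(v, q)) for q in _QUANTILES]
    img64 = img.astype(np.float64)
    feats += _morphology(img64)
    feats += _haralick(img64, cfg.texture_levels)
    feats += _granularity(img64)
    feats += _spot_like(img64, cfg)
    return feats


def extract_classic_features(image: CellImage | np.ndarray,
                             config: ClassicFeatureConfig | None = None,
                             ) -> np.ndarray:
    """One cell -> the 52-value classical feature vector (schema order)."""
    config = config or ClassicFeatureConfig()
    pixels = image.pixels if isinstance(image, CellImage) else np.asarray(image)
    feats = _channel_features(pixels[0], config) + _channel_features(
        pixels[1], config)
    out = np.asarray(feats, dtype=np.float64)
    out[~np.isfinite(out)] = 0.0
    return out


def extract_classic_features_batch(images, config=None,
                                   as_frame: bool = False):
    """Feature matrix for a cohort; rows follow the input order.

    ``images`` may be an (n, 2, 32, 32) array or a list of CellImages.
    With ``as_frame`` a DataFrame with the schema's column names is returned.
    """
    config = config or ClassicFeatureConfig()
    if hasattr(images, "load_pixel_array"):
        images = images.load_pixel_array()
    mat = np.stack([
        extract_classic_features(img, config) for img in images])
    if as_frame:
        return pd.DataFrame(mat, columns=feature_names(config))
    return mat
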