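"""Geometric and visual wound descriptors.

Two descriptor groups feed the supervised comparison:

* ``geometry`` — wound size and shape, border regularity, and the
  depth-profile descriptors: the computational counterpart of the clinical
  notion of edge morphology.
* ``visual`` — chromatic statistics of the bed / inner band / outer band and
  texture of the rectified band: the global appearance cues a clinician may
  implicitly use beyond strict edge geometry.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from scipy.stats import circmean, circstd
from skimage import color as skcolor
from skimage import measure, morphology
from skimage.feature import graycomatrix, graycoprops

from .mask_ops import Contour
from .rectify import RectifiedBand

logger = logging.getLogger("periwound")

#: value written for features whose region was empty (logged when used)
SENTINEL = 0.0


class FeatureError(ValueError):
    """Degenerate geometry; descriptors undefined."""


@dataclasses.dataclass(frozen=True)
class FeatureVector:
    """Named finite descriptors with a group tag per name."""

    values: dict[str, float]
    groups: dict[str, str]  # name -> "geometry" | "visual"

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise FeatureError(f"non-finite feature {name!r} = {v}")
        if set(self.values) != set(self.groups):
            raise FeatureError("group tags must cover exactly the feature names")

    def select(self, group: str) -> dict[str, float]:
        return {k: v for k, v in self.values.items() if self.groups[k] == group}


def _shoelace_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def geometric_features(
    mask: np.ndarray,
    contour: Contour,
    band: RectifiedBand,
    profile_feats: dict[str, float],
) -> FeatureVector:
    """Size/shape/border-regularity descriptors plus the profile descriptors."""
    mask = np.asarray(mask, bool)
    pts = contour.points
    if len(pts) < 3 or contour.length <= 0:
        raise FeatureError("degenerate contour")
    perimeter = contour.length
    poly_area = _shoelace_area(pts)
    if poly_area <= 0:
        raise FeatureError("degenerate (zero-area) contour polygon")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    hull = ConvexHull(pts)  # 2-D: .area is the hull perimeter
    centroid = pts.mean(axis=0)
    radial = np.linalg.norm(pts - centroid, axis=1)
    feats: dict[str, float] = {
        "area": float(mask.sum()),
        "perimeter": float(perimeter),
        "circularity": float(4.0 * np.pi * poly_area / perimeter**2),
        "solidity": float(props.solidity),
        "eccentricity": float(props.eccentricity),
        "border_irregularity": float(perimeter / hull.area),
        "radial_cv": float(radial.std() / radial.mean()),
    }
    feats.update(profile_feats)
    return FeatureVector(values=feats, groups={k: "geometry" for k in feats})


def _region_color_stats(image: np.ndarray, region: np.ndarray, prefix: str) -> dict:
    out: dict[str, float] = {}
    names_rgb = ("r", "g", "b")
    if not region.any():
        logger.warning("empty region %s: colour features set to sentinel", prefix)
        for ch in names_rgb + ("hue", "sat", "val"):
            out[f"{prefix}_{ch}_mean"] = SENTINEL
            out[f"{prefix}_{ch}_sd"] = SENTINEL
        out[f"{prefix}_redness"] = SENTINEL
        return out
    px = image[region].astype(float)  # (n, 3)
    for i, ch in enumerate(names_rgb):
        out[f"{prefix}_{ch}_mean"] = float(px[:, i].mean())
        out[f"{prefix}_{ch}_sd"] = float(px[:, i].std())
    hsv = skcolor.rgb2hsv(px[None, :, :] / 255.0)[0]
    hue = hsv[:, 0] * 2.0 * np.pi
    out[f"{prefix}_hue_mean"] = float(circmean(hue) / (2.0 * np.pi))
    out[f"{prefix}_hue_sd"] = float(circstd(hue) / (2.0 * np.pi))
    for i, ch in enumerate(("sat", "val"), start=1):
        out[f"{prefix}_{ch}_mean"] = float(hsv[:, i].mean())
        out[f"{prefix}_{ch}_sd"] = float(hsv[:, i].std())
    denom = np.maximum(px.sum(axis=1), 1e-9)
    out[f"{prefix}_redness"] = float((px[:, 0] / denom).mean())
    return out


def band_texture(band: RectifiedBand, levels: int = 32) -> dict[str, float]:
    """Gray-level co-occurrence and gradient statistics of the rectified band.

    The co-occurrence offset is 1 px along the band (the arc-length axis), so
    texture is measured parallel to the wound border.
    """
    vals = np.asarray(band.values, dtype=float)
    if vals.ndim == 3:
        vals = skcolor.rgb2gray(vals / 255.0) * 255.0
    # invalid samples replaced by their column median so GLCM stays defined
    if not band.valid.all():
        med = np.nanmedian(np.where(band.valid, vals, np.nan), axis=0)
        med = np.where(np.isfinite(med), med, np.nanmedian(vals))
        vals = np.where(band.valid, vals, med[None, :])
    lo, hi = float(vals.min()), float(vals.max())
    if hi - lo < 1e-12:
        q = np.zeros(vals.shape, dtype=np.uint8)
    else:
        q = np.clip(((vals - lo) / (hi - lo) * levels), 0, levels - 1).astype(np.uint8)
    glcm = graycomatrix(
        q, distances=[1], angles=[np.pi / 2], levels=levels, symmetric=True, normed=True
    )
    out = {
        f"glcm_{prop}": float(graycoprops(glcm, prop)[0, 0])
        for prop in ("contrast", "homogeneity", "energy", "correlation")
    }
    gy, gx = np.gradient(vals)
    gmag = np.hypot(gx, gy)
    out["gradient_mean"] = float(gmag.mean())
    hist, _ = np.histogram(gmag, bins=32)
    p = hist / max(hist.sum(), 1)
    p = p[p > 0]
    out["gradient_entropy"] = float(-(p * np.log2(p)).sum())
    return out


def visual_features(
    image: np.ndarray,
    mask: np.ndarray,
    band: RectifiedBand,
    d_in: int | None = None,
    d_out: int | None = None,
) -> FeatureVector:
    """Chromatic statistics of bed / inner band / outer band plus band texture."""
    image = np.asarray(image)
    mask = np.asarray(mask, bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask shapes differ")
    d_in = band.d_in if d_in is None else d_in
    d_out = band.d_out if d_out is None else d_out
    bed = ndi.binary_erosion(mask, structure=morphology.disk(d_in))
    inner = mask & ~bed
    outer = ndi.binary_dilation(mask, structure=morphology.disk(d_out)) & ~mask
    feats: dict[str, float] = {}
    for region, prefix in ((bed, "bed"), (inner, "inner"), (outer, "outer")):
        feats.update(_region_color_stats(image, region, prefix))
    feats.update(band_texture(band))
    return FeatureVector(values=feats, groups={k: "visual" for k in feats})


def combine(*vectors: FeatureVector) -> FeatureVector:
    values: dict[str, float] = {}
    groups: dict[str, str] = {}
    for vec in vectors:
        overlap = set(values) & set(vec.values)
        if overlap:
            raise FeatureError(f"duplicate feature names: {sorted(overlap)}")
        values.update(vec.values)
        groups.update(vec.groups)
    return FeatureVector(values=values, groups=groups)


def build_matrix(
    vectors: Iterable[tuple[str, FeatureVector]],
    image_ids: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Assemble (image_id, FeatureVector) pairs into an aligned matrix.

    Returns the n x p DataFrame (rows indexed by image_id, column order from
    the first vector) and the name -> group tag map.
    """
    rows, ids, groups = [], [], None
    columns = None
    for image_id, vec in vectors:
        if groups is None:
            groups = dict(vec.groups)
            columns = list(vec.values)
        elif set(vec.values) != set(columns):
            raise ValueError(f"feature names for {image_id!r} differ from the first row")
        rows.append([vec.values[c] for c in columns])
        ids.append(image_id)
    if not rows:
        raise ValueError("no feature vectors given")
    df = pd.DataFrame(rows, index=pd.Index(ids, name="image_id"), columns=columns)
    if image_ids is not None:
        missing = set(image_ids) ^ set(df.index)
        if missing:
            raise ValueError(f"feature/annotation image_id mismatch: {sorted(missing)}")
        df = df.loc[image_ids]
    return df, groups
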