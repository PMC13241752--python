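"""Mask cleanup, transition-band morphology, and ordered contour extraction.

The peri-wound transition band is the annulus obtained by dilating the wound
mask outward by ``d_out`` pixels and eroding it inward by ``d_in`` pixels;
everything between the two is the band within which edge morphology is
analysed.  The wound contour is extracted at the 0.5 iso-level of the mask
and resampled to uniform arc length, with an outward unit normal per point.

Coordinate convention: pixel centres sit at integer ``(row, col)``;
``(x, y) = (col, row)``; contour points are 0-based subpixel coordinates.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology

logger = logging.getLogger("periwound")


class EmptyMaskError(ValueError):
    """Mask has no foreground pixels."""


class BandError(ValueError):
    """Erosion annihilated the mask; the requested band cannot be built."""


class BorderContactError(ValueError):
    """Wound component touches the image frame; its contour is not closed."""


@dataclasses.dataclass(frozen=True)
class TransitionBand:
    """Annular band mask around the wound contour."""

    band: np.ndarray  # bool raster
    d_in: int
    d_out: int


@dataclasses.dataclass(frozen=True)
class Contour:
    """Closed wound contour at uniform arc-length spacing.

    ``points`` are ``(K, 2)`` subpixel ``(x, y)``; ``normals`` are unit
    outward normals per point; ``spacing`` is the (uniform) inter-point arc
    length in pixels.
    """

    points: np.ndarray
    normals: np.ndarray
    spacing: float

    @property
    def length(self) -> float:
        return self.spacing * len(self.points)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component; fill its holes.

    Ties on area are broken by the component whose lexicographically smallest
    ``(row, col)`` pixel comes first.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise EmptyMaskError("mask has no foreground pixels")
    labels = measure.label(mask, connectivity=2)
    areas = np.bincount(labels.ravel())
    areas[0] = 0
    best_area = areas.max()
    candidates = np.flatnonzero(areas == best_area)
    if len(candidates) > 1:
        # first max-area label encountered in row-major scan order wins
        order = []
        flat = labels.ravel()
        for lab in candidates:
            order.append((int(np.argmax(flat == lab)), lab))
        winner = min(order)[1]
    else:
        winner = candidates[0]
    out = labels == winner
    filled = ndi.binary_fill_holes(out)
    n_filled = int(filled.sum() - out.sum())
    if n_filled:
        logger.info("filled %d hole pixels inside the wound component", n_filled)
    return filled


def transition_band(mask: np.ndarray, d_in: int, d_out: int) -> TransitionBand:
    """band = dilate(mask, disk d_out) AND NOT erode(mask, disk d_in)."""
    mask = np.asarray(mask, bool)
    dilated = (
        ndi.binary_dilation(mask, structure=morphology.disk(d_out)) if d_out else mask
    )
    eroded = (
        ndi.binary_erosion(mask, structure=morphology.disk(d_in)) if d_in else mask
    )
    if d_in and mask.any() and not eroded.any():
        raise BandError(
            f"erosion by d_in={d_in} px annihilates the mask; use a smaller d_in"
        )
    return TransitionBand(band=dilated & ~eroded, d_in=d_in, d_out=d_out)


def _resample_closed(points: np.ndarray, k: int) -> np.ndarray:
    """Resample a closed polyline to ``k`` points at equal arc length."""
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    target = np.linspace(0.0, total, k, endpoint=False)
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


def _circular_smooth(points: np.ndarray, window: int = 5) -> np.ndarray:
    kernel = np.ones(window) / window
    out = np.empty_like(points)
    for j in range(points.shape[1]):
        padded = np.concatenate(
            [points[-(window // 2):, j], points[:, j], points[: window // 2, j]]
        )
        out[:, j] = np.convolve(padded, kernel, mode="valid")
    return out


def extract_contour(mask: np.ndarray, k: int = 360) -> Contour:
    """Subpixel closed contour at the 0.5 iso-level, ``k`` equal-arc points.

    Normals come from 5-point-smoothed central-difference tangents rotated by
    90 degrees, with the sign fixed to point outward (toward decreasing mask
    occupancy).
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 16:
        raise EmptyMaskError("component area must be >= 16 px")
    edge_touch = (
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
    if edge_touch:
        raise BorderContactError("wound component touches the image border")
    contours = measure.find_contours(mask.astype(float), 0.5)
    rc = max(contours, key=len)  # (row, col) vertices, closed loop
    points = rc[:-1, ::-1].copy()  # drop duplicate endpoint; to (x, y)
    # 5-point smoothing removes marching-squares staircase jitter (which
    # would otherwise inflate arc length by ~3% on smooth shapes)
    points = _circular_smooth(points, window=5)
    points = _resample_closed(points, k)

    smoothed = _circular_smooth(points, window=5)
    tangent = np.roll(smoothed, -1, axis=0) - np.roll(smoothed, 1, axis=0)
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normals = np.column_stack([tangent[:, 1], -tangent[:, 0]])

    # orient outward by majority vote of mask occupancy 2 px along the normal
    probe = points + 2.0 * normals
    rows = np.clip(np.round(probe[:, 1]).astype(int), 0, mask.shape[0] - 1)
    cols = np.clip(np.round(probe[:, 0]).astype(int), 0, mask.shape[1] - 1)
    if mask[rows, cols].mean() > 0.5:
        normals = -normals

    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    return Contour(points=points, normals=normals, spacing=float(seg.mean()))
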