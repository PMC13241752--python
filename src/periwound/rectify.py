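"""Depth detrending and normal-wise resampling into the standardized band.

Monocular depth maps carry a global planar trend from the orientation of the
limb/skin surface relative to the camera.  A least-squares plane fitted over
the transition band (or the full frame) is subtracted before edge profiles
are measured, so that profile shape reflects wound morphology rather than
pose.  The annular band is then unwrapped into a rectangle indexed by contour
arc length (rows) and signed normal offset (columns, outside -> inside).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage as ndi

from .mask_ops import Contour


class PlaneFitError(ValueError):
    """Region degenerate (collinear / too few pixels) for a plane fit."""


@dataclasses.dataclass(frozen=True)
class PlaneFit:
    """Coefficients of z = a*x + b*y + c and the fit's RMS residual."""

    a: float
    b: float
    c: float
    rms: float
    region: str = ""

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        return self.a * xx + self.b * yy + self.c


@dataclasses.dataclass(frozen=True)
class RectifiedBand:
    """The peri-wound annulus unwrapped to a (K, W) rectangle.

    Row ``k`` follows contour point ``k``; column ``j`` holds the sample at
    signed normal offset ``delta = d_out - j`` (positive outside the wound,
    zero at the border, negative inside), so columns run outside -> inside.
    ``values`` is (K, W) for scalar rasters or (K, W, C) for multichannel;
    ``valid`` flags samples that fell inside the image frame.
    """

    values: np.ndarray
    valid: np.ndarray
    d_in: int
    d_out: int

    @property
    def width(self) -> int:
        return self.d_in + self.d_out + 1

    @property
    def border_column(self) -> int:
        return self.d_out

    @property
    def offsets(self) -> np.ndarray:
        """Signed normal offset per column, +d_out ... -d_in."""
        return self.d_out - np.arange(self.width)

    @property
    def valid_rows(self) -> np.ndarray:
        """Rows whose samples all fell inside the frame."""
        return self.valid.all(axis=1)


def detrend_depth(
    depth: np.ndarray, region: np.ndarray, label: str = ""
) -> tuple[np.ndarray, PlaneFit]:
    """Fit z = a*x + b*y + c over ``region`` pixels; subtract it everywhere."""
    depth = np.asarray(depth, dtype=float)
    region = np.asarray(region, bool)
    rows, cols = np.nonzero(region)
    if len(rows) < 3:
        raise PlaneFitError("plane fit needs >= 3 region pixels")
    design = np.column_stack([cols, rows, np.ones(len(rows))]).astype(float)
    if np.linalg.matrix_rank(design) < 3:
        raise PlaneFitError("region pixels are collinear; plane fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, depth[rows, cols], rcond=None)
    a, b, c = (float(v) for v in coef)
    fitted = design @ coef
    rms = float(np.sqrt(np.mean((depth[rows, cols] - fitted) ** 2)))
    plane = PlaneFit(a=a, b=b, c=c, rms=rms, region=label)
    residual = depth - plane.evaluate(depth.shape)
    return residual, plane


def rectify_band(
    raster: np.ndarray, contour: Contour, d_in: int, d_out: int
) -> RectifiedBand:
    """Bilinearly sample ``raster`` at ``p_k + delta * n_k`` for every contour
    point ``k`` and offset ``delta = d_out, ..., 0, ..., -d_in``."""
    raster = np.asarray(raster)
    deltas = d_out - np.arange(d_in + d_out + 1)  # +d_out ... -d_in
    # (K, W, 2) sample positions in (x, y)
    pos = contour.points[:, None, :] + deltas[None, :, None] * contour.normals[:, None, :]
    xs, ys = pos[..., 0], pos[..., 1]
    h, w = raster.shape[:2]
    valid = (xs >= 0) & (xs <= w - 1) & (ys >= 0) & (ys <= h - 1)
    coords = np.stack([ys.ravel(), xs.ravel()])
    if raster.ndim == 2:
        vals = ndi.map_coordinates(
            raster.astype(float), coords, order=1, mode="nearest"
        ).reshape(xs.shape)
    else:
        chans = [
            ndi.map_coordinates(
                raster[..., c].astype(float), coords, order=1, mode="nearest"
            ).reshape(xs.shape)
            for c in range(raster.shape[2])
        ]
        vals = np.stack(chans, axis=-1)
    return RectifiedBand(values=vals, valid=valid, d_in=d_in, d_out=d_out)
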