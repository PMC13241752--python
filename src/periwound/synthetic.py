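"""Parametric synthetic wound scenes and simulated raters.

Real chronic-wound photographs with expert annotations are not publicly
available, so every pipeline stage is exercised on generated scenes with a
known ground truth.  A scene is an (image, mask, depth) triplet built from:

* an irregular closed contour — a radial-Fourier perturbation of a circle,
  ``rho(theta) = r0 * (1 + sum_m a_m cos(m*theta + phi_m))``;
* an archetype-specific crater profile expressed as a function of the signed
  distance ``s`` to the contour (positive outside, negative inside), one
  archetype per merged clinical category:

  - ``indistinct``      shallow, wide, smooth descent
  - ``attached``        linear ramp across the border
  - ``not_attached``    abrupt logistic drop (undermined edge)
  - ``rolled_fibrotic`` raised rim just outside the border, then a drop
  - ``hyperkeratotic``  elevated callus plateau before the descent

* a global planar tilt ``g_x*x + g_y*y`` plus Gaussian noise in depth, to
  exercise detrending;
* a reddish wound bed, skin-toned periphery, and (for hyperkeratotic) a
  whitened ring, with per-archetype texture noise.

Simulated raters draw labels from per-rater confusion matrices; the exact
chance-corrected agreement implied by two such raters is available in closed
form (``expected_kappa``) as an oracle for the empirical statistics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.special import expit

from .io_config import MERGED_CATEGORIES, AnnotationTable

ARCHETYPES: tuple[str, ...] = MERGED_CATEGORIES  # one-to-one with merged labels


class GeometryError(ValueError):
    """Requested wound does not fit inside the frame."""


class KappaUndefinedError(ZeroDivisionError):
    """Expected agreement p_e = 1; Cohen's kappa is undefined."""


@dataclasses.dataclass(frozen=True)
class SceneParams:
    """Generator knobs; ``None`` crater fields take archetype defaults.

    Lengths are in pixels, depths in the (arbitrary) depth-map unit.
    """

    frame: int = 512
    r0: float = 90.0
    #: ((m, a_m, phi_m), ...); None -> small random irregularity from the seed
    perturb: tuple[tuple[int, float, float], ...] | None = None
    crater_depth: float | None = None  # D
    edge_width: float | None = None  # w_e
    rim_height: float | None = None  # h_r
    rim_offset: float = 4.0  # rim centre, px outside the border
    plateau_width: float = 14.0  # hyperkeratotic ring thickness
    tilt: tuple[float, float] = (0.02, 0.01)  # (g_x, g_y)
    noise_sigma: float = 0.15
    color_noise: float = 6.0
    margin: float = 25.0  # clearance to the frame edge
    crater_scale: float = 1.0  # multiplies archetype-default transition widths


#: archetype -> (crater_depth D, edge_width w_e, rim_height h_r)
ARCHETYPE_DEFAULTS: dict[str, tuple[float, float, float]] = {
    "indistinct": (2.5, 10.0, 0.0),
    "attached": (10.0, 10.0, 0.0),
    "not_attached": (12.0, 1.2, 0.0),
    "rolled_fibrotic": (10.0, 1.5, 5.0),
    "hyperkeratotic": (10.0, 2.0, 5.0),
}

#: archetype -> wound-bed RGB (periphery is skin-toned for all)
_BED_COLOR: dict[str, tuple[float, float, float]] = {
    "indistinct": (185.0, 95.0, 90.0),
    "attached": (155.0, 45.0, 50.0),
    "not_attached": (120.0, 25.0, 35.0),
    "rolled_fibrotic": (170.0, 70.0, 55.0),
    "hyperkeratotic": (150.0, 40.0, 45.0),
}
_SKIN_COLOR = np.array([205.0, 160.0, 135.0])
_RING_COLOR = np.array([232.0, 226.0, 210.0])

#: per-archetype texture (colour-noise multiplier)
_TEXTURE = {
    "indistinct": 0.8,
    "attached": 1.0,
    "not_attached": 1.2,
    "rolled_fibrotic": 1.5,
    "hyperkeratotic": 2.0,
}


@dataclasses.dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray  # (H, W) bool, single component
    depth: np.ndarray  # (H, W) float32
    truth: str  # merged-category archetype
    params: SceneParams
    seed: int


def _resolve(params: SceneParams, archetype: str) -> tuple[float, float, float]:
    d_def, w_def, h_def = ARCHETYPE_DEFAULTS[archetype]
    d = params.crater_depth if params.crater_depth is not None else d_def
    w = (
        params.edge_width
        if params.edge_width is not None
        else w_def * params.crater_scale
    )
    h = params.rim_height if params.rim_height is not None else h_def
    return d, w, h


def crater_function(archetype: str, params: SceneParams = SceneParams()):
    """Depth-vs-signed-distance function generating the given archetype.

    ``s`` is positive outside the wound, negative inside; the returned
    callable is vectorized over ``s``.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    depth, w_e, h_r = _resolve(params, archetype)
    sc = params.crater_scale
    rim_s, plateau = params.rim_offset, params.plateau_width

    if archetype == "indistinct":
        return lambda s: -depth * expit(-np.asarray(s, float) / w_e)
    if archetype == "attached":
        return lambda s: -depth * np.clip(
            (w_e / 2.0 - np.asarray(s, float)) / w_e, 0.0, 1.0
        )
    if archetype == "not_attached":
        return lambda s: -depth * expit(-np.asarray(s, float) / w_e)
    if archetype == "rolled_fibrotic":
        sigma_rim = 2.5 * sc
        return lambda s: h_r * np.exp(
            -((np.asarray(s, float) - rim_s) ** 2) / (2.0 * sigma_rim**2)
        ) - depth * expit(-np.asarray(s, float) / w_e)
    # hyperkeratotic: elevated plateau over [0, plateau] px outside, then drop
    return lambda s: h_r * (
        expit((np.asarray(s, float) + 2.0 * sc) / (1.5 * sc))
        - expit((np.asarray(s, float) - plateau) / (1.5 * sc))
    ) - depth * expit(-np.asarray(s, float) / w_e)


def scaled_scene_params(scale: float, **overrides) -> SceneParams:
    """Geometry-proportional down/up-scaling of the default 512 px scene.

    All pixel lengths (frame, radius, rim offset, plateau width, archetype
    transition widths) shrink together; depth amplitudes are unchanged.
    """
    base: dict = dict(
        frame=int(round(512 * scale)),
        r0=90.0 * scale,
        rim_offset=4.0 * scale,
        plateau_width=14.0 * scale,
        margin=25.0 * scale,
        crater_scale=scale,
    )
    base.update(overrides)
    return SceneParams(**base)


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed distance to the 0.5 iso-contour; negative inside the wound."""
    mask = np.asarray(mask, bool)
    return np.where(
        mask,
        -(ndi.distance_transform_edt(mask) - 0.5),
        ndi.distance_transform_edt(~mask) - 0.5,
    )


def generate_scene(
    archetype: str,
    params: SceneParams = SceneParams(),
    seed: int = 0,
    geometry_as: str | None = None,
    color_as: str | None = None,
) -> SyntheticScene:
    """Render one wound scene with a known archetype.

    ``geometry_as`` / ``color_as`` decouple the depth crater and the colour
    appearance from the nominal label, for experiments that need visual
    signal without geometric signal (or vice versa).
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}")
    geom = geometry_as or archetype
    col = color_as or archetype
    rng = np.random.default_rng(seed)

    if params.perturb is None:
        modes = (2, 3, 4, 5)
        perturb = tuple(
            (m, float(rng.uniform(0.01, 0.06) / np.sqrt(m)), float(rng.uniform(0, 2 * np.pi)))
            for m in modes
        )
    else:
        perturb = params.perturb
    amp_sum = sum(a for _, a, _ in perturb)
    if params.r0 * (1 + amp_sum) + params.margin >= params.frame / 2.0:
        raise GeometryError(
            f"wound radius {params.r0 * (1 + amp_sum):.0f}px + margin "
            f"{params.margin}px exceeds half frame {params.frame / 2.0}px"
        )

    n = params.frame
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    theta = np.arctan2(yy - cy, xx - cx)
    rho = params.r0 * (
        1.0
        + sum(a * np.cos(m * theta + phi) for m, a, phi in perturb)
    )
    r = np.hypot(xx - cx, yy - cy)
    mask = r <= rho

    # radial signed distance to the contour: exact for circles, a smooth
    # proxy of the normal distance for mildly perturbed contours
    s = r - rho
    params = dataclasses.replace(params, perturb=perturb)
    crater = crater_function(geom, params)
    gx, gy = params.tilt
    depth = gx * xx + gy * yy + crater(s)
    if params.noise_sigma > 0:
        depth = depth + rng.normal(0.0, params.noise_sigma, depth.shape)

    # colour composition: skin outside, archetype bed inside, optional ring
    inside_w = expit(-s / 2.0)[..., None]
    bed = np.array(_BED_COLOR[col])
    img = _SKIN_COLOR * (1.0 - inside_w) + bed * inside_w
    if col == "hyperkeratotic":
        sc = params.crater_scale
        ring_w = (
            expit((s + 2.0 * sc) / (1.5 * sc))
            - expit((s - params.plateau_width) / (1.5 * sc))
        )[..., None]
        img = img * (1.0 - ring_w) + _RING_COLOR * ring_w
    img = img + rng.normal(0.0, params.color_noise * _TEXTURE[col], img.shape)
    image = np.clip(img, 0, 255).astype(np.uint8)

    return SyntheticScene(
        image=image,
        mask=mask,
        depth=depth.astype(np.float32),
        truth=archetype,
        params=params,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Simulated raters


@dataclasses.dataclass(frozen=True)
class AnnotatorModel:
    """Per-rater confusion: row = true archetype, column = assigned category."""

    rater_id: str
    confusion: np.ndarray  # (5, 5), rows sum to 1

    def __post_init__(self) -> None:
        c = np.asarray(self.confusion, dtype=float)
        if c.shape != (len(ARCHETYPES), len(ARCHETYPES)):
            raise ValueError(f"confusion must be {len(ARCHETYPES)}x{len(ARCHETYPES)}")
        if (c < 0).any() or not np.allclose(c.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("confusion rows must be probability vectors")
        object.__setattr__(self, "confusion", c)


def identity_annotator(rater_id: str) -> AnnotatorModel:
    return AnnotatorModel(rater_id, np.eye(len(ARCHETYPES)))


def uniform_error_annotator(rater_id: str, error_rate: float) -> AnnotatorModel:
    """Identity mixed with a uniform response at the given error rate."""
    k = len(ARCHETYPES)
    conf = (1.0 - error_rate) * np.eye(k) + error_rate * np.full((k, k), 1.0 / k)
    return AnnotatorModel(rater_id, conf)


def default_annotator_panel() -> list[AnnotatorModel]:
    """Four raters whose closed-form pairwise kappa sits near 0.2.

    Emulates the low agreement observed between expert clinicians scoring
    wound edges from 2-D photographs.
    """
    rates = (0.50, 0.55, 0.55, 0.60)
    return [
        uniform_error_annotator(f"e{i + 1}", e) for i, e in enumerate(rates)
    ]


def simulate_annotations(
    truths: list[str],
    models: list[AnnotatorModel],
    seed: int = 0,
    image_ids: list[str] | None = None,
) -> AnnotationTable:
    """Draw each rater's label for each image from their confusion row."""
    rng = np.random.default_rng(seed)
    idx = {a: i for i, a in enumerate(ARCHETYPES)}
    cats = np.array(ARCHETYPES)
    data = {}
    for model in models:
        rows = np.array([model.confusion[idx[t]] for t in truths])
        u = rng.random(len(truths))
        choice = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)
        data[model.rater_id] = cats[choice]
    ids = image_ids or [f"img_{i:05d}" for i in range(len(truths))]
    return AnnotationTable(pd.DataFrame(data, index=pd.Index(ids, name="image_id")), merged=True)


def expected_kappa(
    model_a: AnnotatorModel,
    model_b: AnnotatorModel,
    truth_prior: np.ndarray | list[float],
) -> float:
    """Cohen's kappa implied by two confusion models under a truth prior.

    Computed from the exact joint label distribution: observed agreement
    ``p_o = sum_t pi_t sum_c A[t,c] B[t,c]``; chance agreement from the
    marginal label distributions ``pi @ A`` and ``pi @ B``.
    """
    pi = np.asarray(truth_prior, dtype=float)
    if not np.isclose(pi.sum(), 1.0):
        raise ValueError("truth prior must sum to 1")
    a, b = model_a.confusion, model_b.confusion
    p_o = float(np.sum(pi[:, None] * a * b))
    marg_a = pi @ a
    marg_b = pi @ b
    p_e = float(marg_a @ marg_b)
    if np.isclose(p_e, 1.0):
        raise KappaUndefinedError("p_e = 1: kappa undefined")
    return (p_o - p_e) / (1.0 - p_e)
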