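"""Per-image orchestration: mask -> band -> rectification -> profile -> features."""

from __future__ import annotations

import dataclasses

import numpy as np

from . import features as feat
from . import mask_ops, profiles, rectify
from .io_config import RunConfig


@dataclasses.dataclass(frozen=True)
class WoundAnalysis:
    """Everything the pipeline derives from one (image, mask, depth) triplet."""

    mask: np.ndarray
    contour: mask_ops.Contour
    band_mask: mask_ops.TransitionBand
    plane: rectify.PlaneFit
    rect_depth: rectify.RectifiedBand
    rect_rgb: rectify.RectifiedBand
    profile: profiles.EdgeProfile
    fit: profiles.TemplateFit
    features: feat.FeatureVector


def analyze_wound(
    image: np.ndarray,
    mask: np.ndarray,
    depth: np.ndarray,
    config: RunConfig = RunConfig(),
) -> WoundAnalysis:
    """Run the full standardization and descriptor pipeline on one wound."""
    clean = mask_ops.largest_component(mask)
    band_mask = mask_ops.transition_band(clean, config.d_in, config.d_out)
    contour = mask_ops.extract_contour(clean, config.contour_points)
    region = band_mask.band if config.detrend_region == "band" else np.ones_like(clean)
    residual, plane = rectify.detrend_depth(depth, region, label=config.detrend_region)
    rect_depth = rectify.rectify_band(residual, contour, config.d_in, config.d_out)
    rect_rgb = rectify.rectify_band(image, contour, config.d_in, config.d_out)
    profile = profiles.normalize_profile(profiles.aggregate_profile(rect_depth))
    fit = profiles.fit_templates(profile, w_abrupt=config.w_abrupt)
    pf = profiles.profile_features(fit, profile)
    geo = feat.geometric_features(clean, contour, rect_depth, pf)
    vis = feat.visual_features(image, clean, rect_rgb, config.d_in, config.d_out)
    return WoundAnalysis(
        mask=clean,
        contour=contour,
        band_mask=band_mask,
        plane=plane,
        rect_depth=rect_depth,
        rect_rgb=rect_rgb,
        profile=profile,
        fit=fit,
        features=feat.combine(geo, vis),
    )


def profile_vector(analysis: WoundAnalysis) -> np.ndarray:
    """Clustering feature vector: normalized profile values plus template
    parameters/residuals (the depth-derived edge-profile summary)."""
    fit = analysis.fit
    extras = [fit.rss[name] for name in profiles.TEMPLATE_NAMES]
    branch = "abrupt" if fit.rss["abrupt"] <= fit.rss["smooth"] else "smooth"
    p = fit.params[branch]
    extras.extend(p if np.all(np.isfinite(p)) else [0.0, 0.0, 0.0, 0.0])
    return np.concatenate([analysis.profile.values, np.asarray(extras, dtype=float)])
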