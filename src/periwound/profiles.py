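"""Edge-depth profiles and their trend-template classification.

A wound's edge profile is the 1-D depth trace along the contour normal, read
from outside the wound toward the bed.  Each profile is summarized by the
best-fitting member of a small family of trend templates:

* ``flat``    — constant ``c`` (1 parameter)
* ``linear``  — ``alpha + beta * delta`` (2 parameters)
* ``abrupt``  — logistic step ``A / (1 + exp(-(delta - delta0)/w)) + c`` with
  transition width ``w <= w_abrupt`` (4 parameters)
* ``smooth``  — the same logistic with ``w > w_abrupt``

where ``delta`` is the signed normal offset (positive outside).  The winner
minimizes BIC = n*ln(RSS/n) + p*ln(n), so the nested flat/linear forms can
beat the logistic when the extra parameters buy nothing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from .rectify import RectifiedBand

#: profiles whose robust amplitude falls below this are degenerate-flat
EPS_FLAT = 1e-6
#: RSS floor guarding BIC's log against an exactly-interpolating fit
_RSS_FLOOR = 1e-12

TEMPLATE_NAMES = ("flat", "linear", "abrupt", "smooth")


class CoverageError(ValueError):
    """Too few valid band rows to aggregate a profile."""


@dataclasses.dataclass(frozen=True)
class EdgeProfile:
    """Outside -> inside depth trace plus its normalization record."""

    values: np.ndarray  # (W,)
    offsets: np.ndarray  # (W,) signed normal offset, +d_out ... -d_in
    valid_rows: int = 0
    n_rows: int = 0
    normalized: bool = False
    norm_offset: float = 0.0
    norm_scale: float = 1.0
    degenerate_flat: bool = False

    @property
    def width(self) -> int:
        return len(self.values)


@dataclasses.dataclass(frozen=True)
class TemplateFit:
    """Per-template least-squares results and the BIC-selected winner."""

    rss: dict[str, float]
    params: dict[str, np.ndarray]
    bic: dict[str, float]
    selected: str
    w_abrupt: float

    @property
    def selected_params(self) -> np.ndarray:
        return self.params[self.selected]


def aggregate_profile(band: RectifiedBand) -> EdgeProfile:
    """Per-column median over valid rows: one profile per wound."""
    ok = band.valid_rows
    n_rows = len(ok)
    n_valid = int(ok.sum())
    if n_valid < 0.5 * n_rows:
        raise CoverageError(
            f"only {n_valid}/{n_rows} band rows fully inside the frame"
        )
    values = np.median(band.values[ok], axis=0)
    return EdgeProfile(
        values=values,
        offsets=band.offsets.astype(float),
        valid_rows=n_valid,
        n_rows=n_rows,
    )


def normalize_profile(profile: EdgeProfile) -> EdgeProfile:
    """Anchor the outer end at 0 and scale by the 90th-10th percentile range.

    Degenerate (near-constant) profiles are only offset-anchored and flagged,
    so noise is not blown up to unit amplitude.
    """
    v = np.asarray(profile.values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("profile contains non-finite values")
    offset = float(v[0])
    amplitude = float(np.percentile(v, 90) - np.percentile(v, 10))
    degenerate = amplitude < EPS_FLAT
    scale = 1.0 if degenerate else amplitude
    return dataclasses.replace(
        profile,
        values=(v - offset) / scale,
        normalized=True,
        norm_offset=offset,
        norm_scale=scale,
        degenerate_flat=degenerate,
    )


def _logistic(delta: np.ndarray, amp: float, delta0: float, w: float, c: float):
    return amp / (1.0 + np.exp(-(delta - delta0) / w)) + c


def _logistic_jac(delta: np.ndarray, amp: float, delta0: float, w: float, c: float):
    z = (delta - delta0) / w
    sig = 1.0 / (1.0 + np.exp(-z))
    dsig = sig * (1.0 - sig)
    return np.column_stack(
        [sig, -amp * dsig / w, -amp * dsig * z / w, np.ones_like(delta)]
    )


def _fit_logistic(
    delta: np.ndarray,
    v: np.ndarray,
    w_lo: float,
    w_hi: float,
) -> tuple[float, np.ndarray]:
    """Bounded logistic fit, multi-start over a delta0 grid x w in {1, 5, 15}."""
    d_lo, d_hi = float(delta.min()), float(delta.max())
    amp0 = float(v[0] - v[-1]) or 1.0
    grid_d0 = np.linspace(d_lo, d_hi, 5)
    steepest = delta[np.argmax(np.abs(np.gradient(v, delta)))]
    starts_d0 = np.append(grid_d0, steepest)
    starts_w = [w for w in (1.0, 5.0, 15.0) if w_lo <= w <= w_hi] or [
        0.5 * (w_lo + min(w_hi, 50.0))
    ]
    span = max(np.ptp(v), 1.0)
    lower = [-10.0 * span, d_lo, w_lo, v.min() - 10.0 * span]
    upper = [10.0 * span, d_hi, w_hi, v.max() + 10.0 * span]
    best_rss, best_p = np.inf, None
    for d0 in starts_d0:
        for w0 in starts_w:
            x0 = np.clip([amp0, d0, w0, float(v[-1])], lower, upper)
            try:
                res = least_squares(
                    lambda p: _logistic(delta, *p) - v,
                    x0,
                    jac=lambda p: _logistic_jac(delta, *p),
                    bounds=(lower, upper),
                    method="trf",
                    max_nfev=200,
                )
            except Exception:  # non-convergent start: try the next one
                continue
            rss = float(np.sum(res.fun**2))
            if rss < best_rss:
                best_rss, best_p = rss, res.x
    if best_p is None:
        return np.inf, np.full(4, np.nan)
    return best_rss, best_p


def _bic(rss: float, n: int, p: int) -> float:
    return n * np.log(max(rss, _RSS_FLOOR) / n) + p * np.log(n)


def fit_templates(profile: EdgeProfile, w_abrupt: float = 3.0) -> TemplateFit:
    """Fit all four trend templates to a normalized profile; select by BIC."""
    if not profile.normalized:
        raise ValueError("fit_templates expects a normalized profile")
    delta = np.asarray(profile.offsets, dtype=float)
    v = np.asarray(profile.values, dtype=float)
    n = len(v)

    rss: dict[str, float] = {}
    params: dict[str, np.ndarray] = {}

    c = float(v.mean())
    rss["flat"] = float(np.sum((v - c) ** 2))
    params["flat"] = np.array([c])

    beta, alpha = np.polyfit(delta, v, 1)
    lin = alpha + beta * delta
    rss["linear"] = float(np.sum((v - lin) ** 2))
    params["linear"] = np.array([alpha, beta])

    rss["abrupt"], params["abrupt"] = _fit_logistic(delta, v, 0.25, w_abrupt)
    rss["smooth"], params["smooth"] = _fit_logistic(delta, v, w_abrupt, 60.0)

    n_params = {"flat": 1, "linear": 2, "abrupt": 4, "smooth": 4}
    bic = {
        name: (_bic(rss[name], n, n_params[name]) if np.isfinite(rss[name]) else np.inf)
        for name in TEMPLATE_NAMES
    }
    selected = min(bic, key=bic.get)
    return TemplateFit(rss=rss, params=params, bic=bic, selected=selected, w_abrupt=w_abrupt)


def profile_features(fit: TemplateFit, profile: EdgeProfile) -> dict[str, float]:
    """Scalar descriptors of the fitted edge profile (geometry group)."""
    delta = np.asarray(profile.offsets, dtype=float)
    v = np.asarray(profile.values, dtype=float)
    feats: dict[str, float] = {}
    for name in TEMPLATE_NAMES:
        feats[f"template_{name}"] = 1.0 if fit.selected == name else 0.0
        r = fit.rss.get(name, np.inf)
        feats[f"rss_{name}"] = float(r) if np.isfinite(r) else float(np.sum(v**2))
    # logistic parameters from the better of the two logistic branches
    log_branch = "abrupt" if fit.rss["abrupt"] <= fit.rss["smooth"] else "smooth"
    amp, d0, w, _ = (
        fit.params[log_branch]
        if np.all(np.isfinite(fit.params[log_branch]))
        else (0.0, 0.0, fit.w_abrupt, 0.0)
    )
    feats["logistic_amplitude"] = float(amp)
    feats["logistic_center"] = float(d0)
    feats["logistic_width"] = float(w)

    grad = np.gradient(v, delta)
    imax = int(np.argmax(np.abs(grad)))
    feats["max_gradient"] = float(np.abs(grad[imax]))
    feats["gradient_location"] = float(delta[imax])

    inside = v[delta < 0]
    outside = v[delta > 0]
    feats["inside_minus_outside"] = float(inside.mean() - outside.mean())

    outer_baseline = float(v[: max(3, len(v) // 10)].mean())
    near_edge = v[(delta >= 0)]
    feats["rim_prominence"] = float(near_edge.max() - outer_baseline)
    return feats
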