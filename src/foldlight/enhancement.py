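"""Adaptive saturation-luminance shift enhancement.

Each pixel's three channels are shifted by the same amount,

    f'_k = clip(f_k + alpha * (S - V), 0, 1),   k = R, G, B,

where S and V come from the *original* image (a single pass).  Because
S - V is positive on tissue folds and negative on background/ordinary
tissue, folds are pushed toward white while everything else darkens —
folds that were colorimetrically buried in the tissue become solid
bright regions.  An equal shift on all channels leaves the hue of every
unclipped pixel unchanged.

Closed-form predictions of the induced change in luminance and
saturation are exposed separately (:func:`predicted_delta_v`,
:func:`predicted_delta_s`); away from clipping they match the measured
changes exactly and serve as analytic oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspace import compute_luminance, compute_saturation, decompose, validate_rgb

__all__ = [
    "EnhancementResult",
    "enhance",
    "predicted_delta_v",
    "predicted_delta_s",
    "unclipped_mask",
    "scale",
]


@dataclass(frozen=True)
class EnhancementResult:
    """Output of :func:`enhance`.

    Attributes
    ----------
    enhanced : ndarray
        The shifted, clipped H×W×3 image on the unit cube.
    alpha : float
        Enhancement coefficient used.
    dV : ndarray
        Actual luminance change ``V(enhanced) - V(original)`` per pixel,
        the detection feature.  On pixels where no channel clipped it
        equals ``alpha * (S - V)`` exactly.
    clip_fraction : float
        Fraction of channel values (over H*W*3) clipped to [0, 1].
    """

    enhanced: np.ndarray
    alpha: float
    dV: np.ndarray
    clip_fraction: float


def enhance(img, alpha: float) -> EnhancementResult:
    """Shift every channel of every pixel by ``alpha * (S - V)``.

    Parameters
    ----------
    img : array_like
        H×W×3 RGB image on [0, 1].
    alpha : float
        Nonnegative enhancement coefficient.  1.5 is the standard value
        for H&E-stained material; 1.2 suits lightly counterstained IHC.

    Raises
    ------
    ValueError
        If ``alpha`` is negative.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    f = validate_rgb(img)
    dec = decompose(f)
    raw = f + (alpha * dec.f_sv)[..., None]
    enhanced = np.clip(raw, 0.0, 1.0)
    clip_fraction = float(np.mean((raw < 0.0) | (raw > 1.0))) if raw.size else 0.0
    dv = compute_luminance(enhanced) - dec.V
    return EnhancementResult(
        enhanced=enhanced, alpha=float(alpha), dV=dv, clip_fraction=clip_fraction
    )


def predicted_delta_v(img, alpha: float) -> np.ndarray:
    """Closed-form luminance change ``alpha * (S - V)``, ignoring clipping."""
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    dec = decompose(img)
    return alpha * dec.f_sv


def predicted_delta_s(img, alpha: float) -> np.ndarray:
    """Closed-form saturation change induced by the shift, ignoring clipping.

    With ``d = alpha*(S-V)``, ``T = R+G+B`` and ``m`` the minimum channel,

        dS = 3*(2*f_m - f_a - f_b) * d / (T * (T + 3*d))
           = 3*(3*min(R,G,B) - T) * d / (T * (T + 3*d)),

    the two forms coinciding because ties among minimum channels give
    equal values (tie-break order R, G, B is therefore value-neutral).
    The channel term is never positive, so the *sign of d alone* decides
    whether saturation rises or falls: d > 0 desaturates, d < 0
    saturates — the mirror image of the luminance change.

    Pixels where ``T = 0`` or ``T + 3*d <= 0`` (the shifted color leaves
    the region where the formula is defined) are returned as NaN, except
    achromatic pixels: an equal shift keeps R = G = B on the gray line,
    so their saturation change is identically zero for every alpha.
    """
    if alpha < 0:
        raise ValueError(f"alpha must be nonnegative, got {alpha}")
    f = validate_rgb(img)
    dec = decompose(f)
    total = f.sum(axis=2)
    d = alpha * dec.f_sv
    numer = 3.0 * (3.0 * f.min(axis=2) - total) * d
    denom = total * (total + 3.0 * d)
    out = np.full(total.shape, np.nan)
    ok = (total > 0.0) & (total + 3.0 * d > 0.0)
    out[ok] = numer[ok] / denom[ok]
    out[(total > 0.0) & (f.max(axis=2) == f.min(axis=2))] = 0.0
    return out


def unclipped_mask(img, alpha: float) -> np.ndarray:
    """H×W bool plane, True where no channel of the pixel needs clipping.

    On these pixels the analytic predictions hold exactly and the
    minimum-channel identity is preserved by the equal shift.
    """
    f = validate_rgb(img)
    dec = decompose(f)
    raw = f + (alpha * dec.f_sv)[..., None]
    return np.all((raw >= 0.0) & (raw <= 1.0), axis=2)


def scale(img, gamma: float) -> np.ndarray:
    """Multiply every channel by ``gamma`` and clip to [0, 1].

    Scaling changes luminance (V scales linearly until clipping) while
    shifting changes saturation; scaling is kept as a minor utility and
    plays no role in fold detection.
    """
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    f = validate_rgb(img)
    return np.clip(gamma * f, 0.0, 1.0)
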