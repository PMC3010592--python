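"""Saturation-luminance decomposition of RGB images.

The enhancement method rests on an HSI-style decomposition of each pixel:

* saturation ``S = 1 - 3*min(R,G,B)/(R+G+B)`` — distance of the color
  vector from the gray line of the RGB cube, in [0, 1];
* luminance  ``V = (R+G+B)/3`` — the channel mean, in [0, 1].

Stained tissue folds are thicker than the surrounding section, absorb
more dye, and therefore appear both darker (low V) and more strongly
saturated (high S) than ordinary tissue or the white slide background.
The per-pixel difference ``f_sv = S - V`` is consequently positive on
folds and negative elsewhere; it is the shifting factor the enhancement
adds (scaled) to every RGB channel.

All functions operate on H×W×3 float arrays with components in [0, 1]
(channel order R, G, B). Integer bit depths are normalized at the I/O
boundary (:mod:`foldlight.io_utils`), never here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SVDecomposition",
    "validate_rgb",
    "compute_saturation",
    "compute_luminance",
    "compute_hue",
    "decompose",
]


def validate_rgb(pixels) -> np.ndarray:
    """Coerce ``pixels`` to a float H×W×3 array on the unit cube.

    Raises
    ------
    ValueError
        If the array is not H×W×3 or any component falls outside [0, 1].
    """
    arr = np.asarray(pixels, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an H×W×3 RGB array, got shape {arr.shape}"
        )
    if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
        raise ValueError("RGB components must lie in [0, 1]")
    return arr


@dataclass(frozen=True)
class SVDecomposition:
    """Per-pixel saturation and luminance planes plus their difference.

    Attributes
    ----------
    S : ndarray
        Color saturation, H×W in [0, 1].
    V : ndarray
        Luminance (channel mean), H×W in [0, 1].
    f_sv : ndarray
        The shifting factor ``S - V``, H×W in [-1, 1].
    """

    S: np.ndarray
    V: np.ndarray
    f_sv: np.ndarray


def compute_saturation(img) -> np.ndarray:
    """HSI color saturation ``1 - 3*min(R,G,B)/(R+G+B)`` per pixel.

    Black pixels (R+G+B = 0) are assigned S = 0: black is achromatic,
    and a finite value keeps ``f_sv`` free of NaNs.
    """
    f = validate_rgb(img)
    total = f.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = 1.0 - 3.0 * f.min(axis=2) / total
    s[total == 0.0] = 0.0
    return s


def compute_luminance(img) -> np.ndarray:
    """Luminance ``(R+G+B)/3`` per pixel."""
    return validate_rgb(img).mean(axis=2)


def compute_hue(img) -> np.ndarray:
    """Standard HSI inverse-cosine hue in degrees, [0, 360).

    H = acos(beta) with beta = ((R-G)+(R-B)) / (2*sqrt((R-G)^2+(R-B)(G-B))),
    reflected to 360 - acos(beta) when B > G.  Achromatic pixels
    (R = G = B) have undefined hue and are assigned 0 by convention.

    The enhancement never modifies hue (the same shift is applied to all
    three channels), so this plane serves only to verify that invariance.
    """
    f = validate_rgb(img)
    r, g, b = f[..., 0], f[..., 1], f[..., 2]
    num = 0.5 * ((r - g) + (r - b))
    den = np.sqrt((r - g) ** 2 + (r - b) * (g - b))
    achromatic = den == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.clip(num / den, -1.0, 1.0)
    h = np.degrees(np.arccos(beta))
    h = np.where(b > g, 360.0 - h, h)
    h = np.where(h >= 360.0, 0.0, h)
    h[achromatic] = 0.0
    return h


def decompose(img) -> SVDecomposition:
    """Compute S, V and the shifting factor ``f_sv = S - V`` in one pass."""
    f = validate_rgb(img)
    s = compute_saturation(f)
    v = compute_luminance(f)
    return SVDecomposition(S=s, V=v, f_sv=s - v)
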