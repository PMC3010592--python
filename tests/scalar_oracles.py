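"""Independent per-pixel scalar implementations used as test oracles.

Deliberately written as plain Python loops over scalars, sharing no
code with the package's vectorized implementation.
"""

import math


def sat_scalar(r, g, b):
    total = r + g + b
    if total == 0:
        return 0.0
    return 1.0 - 3.0 * min(r, g, b) / total


def lum_scalar(r, g, b):
    return (r + g + b) / 3.0


def hue_scalar(r, g, b):
    den = math.sqrt((r - g) ** 2 + (r - b) * (g - b))
    if den == 0:
        return 0.0
    beta = max(-1.0, min(1.0, 0.5 * ((r - g) + (r - b)) / den))
    h = math.degrees(math.acos(beta))
    if b > g:
        h = 360.0 - h
    return 0.0 if h >= 360.0 else h


def enhance_scalar(r, g, b, alpha):
    shift = alpha * (sat_scalar(r, g, b) - lum_scalar(r, g, b))
    return tuple(min(1.0, max(0.0, c + shift)) for c in (r, g, b))


def iou_scalar(mask_a, mask_b):
    """Set-based intersection over union of two 2-D bool masks."""
    a = {(i, j) for i, row in enumerate(mask_a) for j, v in enumerate(row) if v}
    b = {(i, j) for i, row in enumerate(mask_b) for j, v in enumerate(row) if v}
    union = a | b
    if not union:
        return 1.0
    return len(a & b) / len(union)
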