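"""Synthetic pre-scan phantoms with ground-truth fold masks.

Real pre-scan images of stained slides are a near-white background, a
blob of eosin-pink tissue, dark strongly saturated fold ribbons where
the section doubled over, and (the detector's known confounder) dark
hematoxylin-stained nuclei speckled through the tissue.  The phantom
reproduces exactly the colorimetric structure the detector relies on —
the sign of S - V per region — with fully known ground truth:

* background and tissue colors are drawn with S < V,
* fold and nuclei colors with S > V,

so the ideal detector output is computable in advance and every other
module can be tested end-to-end without scanned slides.  Shapes (ribbon
polyline folds, a smoothed-noise tissue blob, single-pixel nuclei
speckle) are deliberately simple: the detector is purely per-pixel, so
geometry only serves to make the masks nontrivial.

Generation is deterministic: the same spec and seed reproduce the image
and masks bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

__all__ = ["PhantomSpec", "generate", "sample_fold_pixels", "color_sv_gap"]


def color_sv_gap(color) -> float:
    """S - V of a single RGB triple (the phantom's region sign check)."""
    r, g, b = (float(c) for c in color)
    total = r + g + b
    s = 0.0 if total == 0 else 1.0 - 3.0 * min(r, g, b) / total
    return s - total / 3.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic pre-scan image.

    Colors are per-region means with a per-channel Gaussian spread
    (truncated by re-clipping to [0, 1]).  The defaults emulate an
    H&E-stained section: near-white glass, eosin-pink tissue, dark
    purple folds, and darker hematoxylin nuclei.  Region means must
    satisfy the S - V sign structure (background/tissue negative,
    fold/nuclei positive); :func:`generate` rejects specs that do not.

    ``fold_geometry`` may list explicit ribbons as ``(points, width)``
    pairs — ``points`` an ordered (K, 2) array of (row, col) vertices —
    in which case ``n_folds`` is ignored; otherwise ``n_folds``
    random-walk ribbons of width ``fold_width`` are drawn inside the
    tissue blob.
    """

    height: int = 512
    width: int = 512
    background_color: tuple = (0.97, 0.97, 0.97)
    background_sd: float = 0.01
    tissue_color_mean: tuple = (0.91, 0.65, 0.76)
    tissue_color_sd: float = 0.02
    fold_color_mean: tuple = (0.45, 0.20, 0.40)
    fold_color_sd: float = 0.005
    nuclei_color_mean: tuple = (0.30, 0.15, 0.45)
    nuclei_color_sd: float = 0.02
    nuclei_density: float = 0.0
    n_folds: int = 3
    fold_width: int = 6
    fold_geometry: tuple | None = None
    seed: int = 0

    def with_(self, **changes) -> "PhantomSpec":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _validate_spec(spec: PhantomSpec) -> None:
    if spec.height <= 0 or spec.width <= 0:
        raise ValueError("phantom height and width must be positive")
    if not 0.0 <= spec.nuclei_density <= 1.0:
        raise ValueError("nuclei_density must lie in [0, 1]")
    if spec.fold_geometry is None and spec.n_folds < 1:
        raise ValueError("n_folds must be at least 1 when no geometry is given")
    checks = [
        ("background", spec.background_color, -1),
        ("tissue", spec.tissue_color_mean, -1),
        ("fold", spec.fold_color_mean, +1),
    ]
    if spec.nuclei_density > 0:
        checks.append(("nuclei", spec.nuclei_color_mean, +1))
    for name, color, sign in checks:
        gap = color_sv_gap(color)
        if sign * gap <= 0:
            want = "S > V" if sign > 0 else "S < V"
            raise ValueError(
                f"{name} color {tuple(color)} has S - V = {gap:.4f}; "
                f"the {name} region requires {want}"
            )


def _tissue_blob(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Irregular blob covering roughly the central 40% of the frame."""
    h, w = spec.height, spec.width
    rows = (np.arange(h) - (h - 1) / 2.0) / (0.42 * h)
    cols = (np.arange(w) - (w - 1) / 2.0) / (0.42 * w)
    radial = np.exp(-(rows[:, None] ** 2 + cols[None, :] ** 2))
    noise = ndimage.gaussian_filter(rng.standard_normal((h, w)),
                                    sigma=max(2.0, min(h, w) / 12.0))
    scale = np.abs(noise).max()
    if scale > 0:
        noise = noise / scale
    return (radial + 0.3 * noise) > 0.5


def _ribbon(points: np.ndarray, width: int, shape) -> np.ndarray:
    """Rasterize a polyline spine and thicken it to a ribbon."""
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(points, dtype=float)
    for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
        n = int(max(abs(r1 - r0), abs(c1 - c0))) + 1
        rr = np.clip(np.round(np.linspace(r0, r1, n)).astype(int), 0, shape[0] - 1)
        cc = np.clip(np.round(np.linspace(c0, c1, n)).astype(int), 0, shape[1] - 1)
        mask[rr, cc] = True
    radius = max(1, int(width) // 2)
    return ndimage.binary_dilation(mask, structure=disk(radius))


def _random_fold_ribbons(
    spec: PhantomSpec, tissue: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Random-walk ribbon spines seeded inside the tissue blob."""
    h, w = tissue.shape
    coords = np.argwhere(tissue)
    if coords.size == 0:
        raise ValueError("tissue blob is empty; enlarge the phantom")
    mask = np.zeros_like(tissue)
    n_steps = max(8, int(0.6 * min(h, w)))
    for _ in range(spec.n_folds):
        start = coords[rng.integers(len(coords))]
        angle = rng.uniform(0.0, 2.0 * np.pi)
        pos = start.astype(float)
        pts = [pos.copy()]
        for _ in range(n_steps):
            angle += rng.normal(0.0, 0.2)
            pos = pos + np.array([np.sin(angle), np.cos(angle)])
            pts.append(pos.copy())
        mask |= _ribbon(np.array(pts), spec.fold_width, tissue.shape)
    return mask & tissue


def _paint(
    img: np.ndarray,
    region: np.ndarray,
    mean,
    sd: float,
    rng: np.random.Generator,
) -> None:
    n = int(np.count_nonzero(region))
    colors = np.asarray(mean, dtype=float) + sd * rng.standard_normal((n, 3))
    img[region] = np.clip(colors, 0.0, 1.0)


def generate(spec: PhantomSpec):
    """Generate a phantom image with ground-truth fold and nuclei masks.

    Returns
    -------
    (img, fold_mask, nuclei_mask)
        ``img`` an H×W×3 float image on [0, 1]; the masks H×W bool.

    Raises
    ------
    ValueError
        If the spec's region colors violate the S - V sign structure
        (the offending region is named), or if the realized per-region
        mean S - V violates it after drawing.
    """
    _validate_spec(spec)
    rng = np.random.default_rng(spec.seed)

    tissue = _tissue_blob(spec, rng)
    if spec.fold_geometry is not None:
        fold = np.zeros_like(tissue)
        for points, width in spec.fold_geometry:
            fold |= _ribbon(np.asarray(points), width, tissue.shape)
        fold &= tissue
    else:
        fold = _random_fold_ribbons(spec, tissue, rng)
    if not fold.any():
        raise ValueError("fold geometry produced no pixels inside the tissue")

    plain_tissue = tissue & ~fold
    nuclei = np.zeros_like(tissue)
    if spec.nuclei_density > 0:
        nuclei = (rng.random(tissue.shape) < spec.nuclei_density) & plain_tissue
        plain_tissue &= ~nuclei
    background = ~tissue

    img = np.empty((spec.height, spec.width, 3))
    _paint(img, background, spec.background_color, spec.background_sd, rng)
    _paint(img, plain_tissue, spec.tissue_color_mean, spec.tissue_color_sd, rng)
    _paint(img, fold, spec.fold_color_mean, spec.fold_color_sd, rng)
    if nuclei.any():
        _paint(img, nuclei, spec.nuclei_color_mean, spec.nuclei_color_sd, rng)

    _check_realized(img, background, plain_tissue, fold, nuclei)
    return img, fold, nuclei


def _check_realized(img, background, tissue, fold, nuclei) -> None:
    from .colorspace import decompose

    fsv = decompose(img).f_sv
    for name, region, sign in (
        ("background", background, -1),
        ("tissue", tissue, -1),
        ("fold", fold, +1),
        ("nuclei", nuclei, +1),
    ):
        if not region.any():
            continue
        mean = float(fsv[region].mean())
        if sign * mean <= 0:
            raise ValueError(
                f"realized {name} region has mean S - V = {mean:.4f}, "
                f"violating its sign constraint; reduce the color spread"
            )


def sample_fold_pixels(
    img, fold_mask, n: int, seed: int, replace: bool = False
) -> np.ndarray:
    """Draw ``n`` fold pixel colors uniformly from the fold region.

    Sampling is without replacement unless ``replace`` is set, and is
    reproducible from ``seed``.  Returns an (n, 3) array of RGB triples
    suitable for :func:`foldlight.detection.sweep_alpha`.
    """
    from .colorspace import validate_rgb

    f = validate_rgb(img)
    mask = np.asarray(fold_mask, dtype=bool)
    coords = np.argwhere(mask)
    if coords.size == 0:
        raise ValueError("fold mask is empty; nothing to sample")
    if n <= 0:
        raise ValueError("n must be positive")
    if n > len(coords) and not replace:
        raise ValueError(
            f"requested {n} samples from {len(coords)} fold pixels; "
            f"pass replace=True to sample with replacement"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(coords), size=n, replace=replace)
    picked = coords[idx]
    return f[picked[:, 0], picked[:, 1]]
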