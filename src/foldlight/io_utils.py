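"""Image and mask readers/writers and run-output bundling.

All computation happens on float images on the unit cube; bit depth is
handled only here.  8-bit inputs are divided by 255 and 16-bit by
65535; alpha channels are stripped with a warning; grayscale inputs are
rejected (the method needs all three channels to form S and V).
Enhanced images are written back as 8-bit, masks as single-channel
8-bit PNG with 0 = non-fold and 255 = fold.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import __version__
from .colorspace import validate_rgb
from .evaluation import OverlapReport, overlap_reports_to_csv

logger = logging.getLogger("foldlight")

__all__ = [
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "save_outputs",
]


def load_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG into an H×W×3 float array on [0, 1].

    Raises
    ------
    ValueError
        Grayscale input (a 3-channel RGB image is required) or an
        unsupported channel count / dtype.
    OSError
        Unreadable or undecodable file.
    """
    arr = iio.imread(Path(path))
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise ValueError(
            f"{path}: grayscale input; a 3-channel RGB image is required"
        )
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"{path}: expected 3 or 4 channels, got shape {arr.shape}")
    if arr.shape[2] == 4:
        logger.warning("%s: alpha channel stripped", path)
        arr = arr[..., :3]
    if arr.dtype == np.uint8:
        out = arr / 255.0
    elif arr.dtype == np.uint16:
        out = arr / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        out = arr.astype(float)
    else:
        raise ValueError(f"{path}: unsupported pixel dtype {arr.dtype}")
    return validate_rgb(out)


def save_image(path, img) -> None:
    """Write a float RGB image as 8-bit, container chosen by extension."""
    f = validate_rgb(img)
    iio.imwrite(Path(path), np.round(f * 255.0).astype(np.uint8))


def save_mask(path, mask) -> None:
    """Write a bool mask as single-channel 8-bit PNG (0/255)."""
    m = np.asarray(mask, dtype=bool)
    iio.imwrite(Path(path), np.where(m, 255, 0).astype(np.uint8))


def load_mask(path) -> np.ndarray:
    """Read a mask image; any nonzero value counts as fold."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def save_outputs(result, mask, report, config, output_dir, stem="output",
                 image_ext=".png") -> dict:
    """Write the full result bundle of a run into ``output_dir``.

    Writes the enhanced image (``<stem>_enhanced<image_ext>``), the
    detected mask PNG, a metrics CSV and a JSON run manifest recording
    alpha, seed, clip fraction and the software version.  Returns a dict
    of the written paths.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["enhanced"] = out / f"{stem}_enhanced{image_ext}"
    save_image(paths["enhanced"], result.enhanced)
    paths["mask"] = out / f"{stem}_mask.png"
    save_mask(paths["mask"], mask)
    if report is not None:
        paths["metrics"] = out / f"{stem}_metrics.csv"
        overlap_reports_to_csv({stem: report}, paths["metrics"])

    manifest = {
        "alpha": result.alpha,
        "seed": config.seed,
        "clip_fraction": result.clip_fraction,
        "version": __version__,
    }
    paths["manifest"] = out / f"{stem}_manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    return paths
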