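"""Agreement metrics between fold masks and S-V histogram analysis.

The overlap ratio TP/(FN+TP+FP) — the intersection-over-union of the
detected and reference fold masks — is the headline agreement score.
The S-V histograms of fold vs non-fold pixels make the separation the
detector exploits directly visible: fold mass sits at positive S-V,
non-fold mass at negative S-V.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .colorspace import decompose

__all__ = [
    "OverlapReport",
    "SVHistogram",
    "overlap_ratio",
    "sv_histograms",
    "overlap_reports_to_csv",
    "histogram_to_csv",
]


@dataclass(frozen=True)
class OverlapReport:
    """Pixel confusion counts and the overlap ratio TP/(FN+TP+FP)."""

    tp: int
    fp: int
    fn: int
    tn: int
    overlap_ratio: float


def _as_mask(mask, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        raise ValueError(f"{name} must be a boolean mask, got dtype {arr.dtype}")
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {arr.shape}")
    return arr


def overlap_ratio(detected, reference) -> OverlapReport:
    """Overlap ratio TP/(FN+TP+FP) between detected and reference masks.

    TP counts pixels true in both masks, FP detected-only, FN
    reference-only.  When both masks are empty the ratio is defined as
    1.0 (perfect agreement on absence); a nonempty detection against an
    empty reference gives 0.

    Raises
    ------
    ValueError
        If the masks differ in shape or are not boolean.
    """
    det = _as_mask(detected, "detected")
    ref = _as_mask(reference, "reference")
    if det.shape != ref.shape:
        raise ValueError(
            f"mask shapes differ: detected {det.shape} vs reference {ref.shape}"
        )
    tp = int(np.count_nonzero(det & ref))
    fp = int(np.count_nonzero(det & ~ref))
    fn = int(np.count_nonzero(~det & ref))
    tn = int(np.count_nonzero(~det & ~ref))
    denom = tp + fp + fn
    ratio = 1.0 if denom == 0 else tp / denom
    return OverlapReport(tp=tp, fp=fp, fn=fn, tn=tn, overlap_ratio=ratio)


@dataclass(frozen=True)
class SVHistogram:
    """Normalized S-V histograms of fold and non-fold pixels.

    Each density sums to 1 over the bins when its pixel set is nonempty
    and is all-zero otherwise.
    """

    bin_edges: np.ndarray
    fold_density: np.ndarray
    nonfold_density: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def sv_histograms(img, reference, n_bins: int = 64) -> SVHistogram:
    """Histogram S - V separately over fold and non-fold pixels.

    Bins are uniform over [-1, 1].  An empty fold set yields an all-zero
    fold density with a warning rather than an error (an image may
    legitimately contain no folds).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    ref = _as_mask(reference, "reference")
    fsv = decompose(img).f_sv
    if fsv.shape != ref.shape:
        raise ValueError(
            f"mask shape {ref.shape} does not match image plane {fsv.shape}"
        )
    edges = np.linspace(-1.0, 1.0, n_bins + 1)

    def _density(values: np.ndarray) -> np.ndarray:
        counts, _ = np.histogram(values, bins=edges)
        total = counts.sum()
        return counts / total if total else np.zeros(n_bins)

    fold_vals = fsv[ref]
    if fold_vals.size == 0:
        warnings.warn("reference fold mask is empty; fold density is all-zero",
                      stacklevel=2)
    return SVHistogram(
        bin_edges=edges,
        fold_density=_density(fold_vals),
        nonfold_density=_density(fsv[~ref]),
    )


def overlap_reports_to_csv(reports, path) -> None:
    """Write one row per image: sample, tp, fp, fn, tn, overlap_ratio.

    ``reports`` maps sample labels to :class:`OverlapReport`.
    """
    rows = [
        {"sample": label, "tp": r.tp, "fp": r.fp, "fn": r.fn, "tn": r.tn,
         "overlap_ratio": r.overlap_ratio}
        for label, r in dict(reports).items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def histogram_to_csv(hist: SVHistogram, path) -> None:
    """Write bin_center, fold_density, nonfold_density columns."""
    pd.DataFrame(
        {
            "bin_center": hist.bin_centers,
            "fold_density": hist.fold_density,
            "nonfold_density": hist.nonfold_density,
        }
    ).to_csv(path, index=False)
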