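import numpy as np
import pytest

from foldlight import overlap_ratio, sv_histograms
from foldlight.evaluation import histogram_to_csv, overlap_reports_to_csv
from scalar_oracles import iou_scalar


def test_identical_masks_give_one(rng):
    m = rng.random((8, 8)) > 0.5
    assert m.any()
    assert overlap_ratio(m, m).overlap_ratio == 1.0


def test_disjoint_masks_give_zero():
    a = np.zeros((4, 4), bool)
    b = np.zeros((4, 4), bool)
    a[:2] = True
    b[2:] = True
    assert overlap_ratio(a, b).overlap_ratio == 0.0


def test_shifted_block_counts_by_hand():
    # 2x2 block vs the same block shifted one column: tp=2, fp=2, fn=2
    det = np.zeros((4, 4), bool)
    ref = np.zeros((4, 4), bool)
    det[1:3, 1:3] = True
    ref[1:3, 2:4] = True
    rep = overlap_ratio(det, ref)
    assert (rep.tp, rep.fp, rep.fn, rep.tn) == (2, 2, 2, 10)
    assert rep.overlap_ratio == pytest.approx(2 / 6)


def test_counts_partition_the_image(rng):
    det = rng.random((16, 16)) > 0.6
    ref = rng.random((16, 16)) > 0.6
    rep = overlap_ratio(det, ref)
    assert rep.tp + rep.fp + rep.fn + rep.tn == det.size


def test_empty_mask_conventions():
    empty = np.zeros((3, 3), bool)
    some = ~empty.copy()
    assert overlap_ratio(empty, empty).overlap_ratio == 1.0
    assert overlap_ratio(some, empty).overlap_ratio == 0.0
    assert overlap_ratio(empty, some).overlap_ratio == 0.0


def test_symmetric_under_swap(rng):
    det = rng.random((10, 10)) > 0.5
    ref = rng.random((10, 10)) > 0.5
    a, b = overlap_ratio(det, ref), overlap_ratio(ref, det)
    assert a.overlap_ratio == b.overlap_ratio
    assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)


def test_matches_set_based_iou_oracle(rng):
    for _ in range(200):
        det = rng.random((16, 16)) > rng.random()
        ref = rng.random((16, 16)) > rng.random()
        assert overlap_ratio(det, ref).overlap_ratio == iou_scalar(
            det.tolist(), ref.tolist())


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        overlap_ratio(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


def test_nonboolean_mask_rejected():
    with pytest.raises(ValueError, match="bool"):
        overlap_ratio(np.zeros((2, 2), int), np.zeros((2, 2), bool))


def test_histogram_concentrates_constant_region():
    # fold region with constant f_sv: red-ish pixel (0.5, 0.1, 0.3)
    img = np.tile([0.5, 0.1, 0.3], (4, 4, 1))
    ref = np.zeros((4, 4), bool)
    ref[:2] = True
    hist = sv_histograms(img, ref, n_bins=64)
    assert hist.fold_density.max() == 1.0
    assert hist.fold_density.sum() == pytest.approx(1.0)
    assert hist.nonfold_density.sum() == pytest.approx(1.0)
    # same constant everywhere: both masses in the same bin
    assert np.argmax(hist.fold_density) == np.argmax(hist.nonfold_density)


def test_histogram_separates_phantom_regions(clean_phantom):
    _, img, fold_mask, _ = clean_phantom
    hist = sv_histograms(img, fold_mask)
    centers = hist.bin_centers
    assert hist.fold_density[centers > 0].sum() > 0.99
    assert hist.nonfold_density[centers < 0].sum() > 0.99


def test_white_image_nonfold_mass_at_minus_one():
    img = np.ones((4, 4, 3))
    with pytest.warns(UserWarning, match="empty"):
        hist = sv_histograms(img, np.zeros((4, 4), bool), n_bins=8)
    assert hist.fold_density.sum() == 0.0
    assert hist.nonfold_density[0] == 1.0  # bin containing -1


def test_csv_round_trips(tmp_path, rng):
    import pandas as pd

    det = rng.random((8, 8)) > 0.5
    ref = rng.random((8, 8)) > 0.5
    rep = overlap_ratio(det, ref)
    overlap_reports_to_csv({"img1": rep}, tmp_path / "metrics.csv")
    table = pd.read_csv(tmp_path / "metrics.csv")
    assert list(table.columns) == ["sample", "tp", "fp", "fn", "tn",
                                   "overlap_ratio"]
    assert table.loc[0, "tp"] == rep.tp

    img = rng.random((8, 8, 3))
    hist = sv_histograms(img, ref, n_bins=16)
    histogram_to_csv(hist, tmp_path / "hist.csv")
    htab = pd.read_csv(tmp_path / "hist.csv")
    assert len(htab) == 16
    assert htab["fold_density"].sum() == pytest.approx(1.0)
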