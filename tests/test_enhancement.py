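import numpy as np
import pytest

from foldlight import (
    compute_hue,
    compute_luminance,
    compute_saturation,
    decompose,
    enhance,
    predicted_delta_s,
    predicted_delta_v,
    scale,
    unclipped_mask,
)
from scalar_oracles import enhance_scalar


def px(r, g, b):
    return np.array([[[r, g, b]]], dtype=float)


def test_worked_pixel():
    # (0.3, 0.2, 0.5): S = 0.4, V = 1/3, shift = 1.5*(0.4 - 1/3) = 0.1
    res = enhance(px(0.3, 0.2, 0.5), 1.5)
    np.testing.assert_allclose(res.enhanced[0, 0], [0.4, 0.3, 0.6], atol=1e-12)
    assert res.dV[0, 0] == pytest.approx(0.1, abs=1e-12)
    assert res.clip_fraction == 0.0


def test_alpha_zero_is_identity(rng):
    img = rng.random((12, 9, 3))
    res = enhance(img, 0.0)
    np.testing.assert_array_equal(res.enhanced, img)
    assert np.all(res.dV == 0.0)


def test_white_clips_to_black():
    res = enhance(px(1.0, 1.0, 1.0), 1.5)
    np.testing.assert_array_equal(res.enhanced[0, 0], [0.0, 0.0, 0.0])
    assert res.clip_fraction == 1.0


def test_negative_alpha_rejected(rng):
    with pytest.raises(ValueError, match="alpha"):
        enhance(rng.random((2, 2, 3)), -0.1)


def test_enhance_matches_scalar_oracle(rng):
    img = rng.random((10, 10, 3))
    for alpha in (0.5, 1.5):
        res = enhance(img, alpha)
        for i in range(10):
            for j in range(10):
                expected = enhance_scalar(*img[i, j], alpha)
                np.testing.assert_allclose(res.enhanced[i, j], expected,
                                           atol=1e-12)


def test_delta_v_identity_on_unclipped(rng):
    img = rng.random((32, 32, 3))
    for alpha in (0.5, 1.0, 1.5):
        res = enhance(img, alpha)
        ok = unclipped_mask(img, alpha)
        assert ok.any()
        pred = predicted_delta_v(img, alpha)
        np.testing.assert_allclose(res.dV[ok], pred[ok], atol=1e-9)


def test_delta_s_matches_brute_force(rng):
    img = rng.random((32, 32, 3))
    for alpha in (0.5, 1.0, 1.5):
        res = enhance(img, alpha)
        ok = unclipped_mask(img, alpha)
        actual = compute_saturation(res.enhanced) - compute_saturation(img)
        pred = predicted_delta_s(img, alpha)
        np.testing.assert_allclose(pred[ok], actual[ok], atol=1e-9)


def test_delta_s_zero_for_achromatic():
    # channel term 2*f_m - f_a - f_b vanishes when R = G = B
    assert predicted_delta_s(px(0.3, 0.3, 0.3), 1.5)[0, 0] == pytest.approx(
        0.0, abs=1e-12)


def test_delta_s_undefined_marked_nan():
    # black pixel: R+G+B = 0
    assert np.isnan(predicted_delta_s(px(0.0, 0.0, 0.0), 1.5)[0, 0])


def test_sign_law(rng):
    # positive shift desaturates and brightens; negative does the opposite
    img = rng.random((48, 48, 3))
    alpha = 1.5
    res = enhance(img, alpha)
    dec = decompose(img)
    ok = unclipped_mask(img, alpha)
    chroma = img.max(axis=2) - img.min(axis=2) > 0
    ds = compute_saturation(res.enhanced) - dec.S
    pos = ok & chroma & (dec.f_sv > 0)
    neg = ok & chroma & (dec.f_sv < 0)
    assert pos.any() and neg.any()
    assert np.all(ds[pos] < 0) and np.all(res.dV[pos] > 0)
    assert np.all(ds[neg] > 0) and np.all(res.dV[neg] < 0)


def test_hue_preserved_on_unclipped(rng):
    img = rng.random((32, 32, 3))
    alpha = 1.5
    res = enhance(img, alpha)
    ok = unclipped_mask(img, alpha)
    diff = np.abs(compute_hue(res.enhanced) - compute_hue(img))
    assert np.all(diff[ok] <= 1e-6)


def test_luminance_monotone_in_alpha():
    # fold-like pixel (S > V): enhanced luminance never decreases with alpha
    p = px(0.45, 0.20, 0.40)
    lums = [compute_luminance(enhance(p, a).enhanced)[0, 0]
            for a in np.linspace(0, 6, 25)]
    assert np.all(np.diff(lums) >= -1e-12)


def test_clip_fraction_counts_channels():
    img = np.array([[[1.0, 1.0, 1.0], [0.3, 0.2, 0.5]]])  # 3 clipped of 6
    assert enhance(img, 1.5).clip_fraction == pytest.approx(0.5)


@pytest.mark.parametrize(
    "rgb, gamma, expected",
    [
        ((0.2, 0.3, 0.4), 1.0, (0.2, 0.3, 0.4)),
        ((0.2, 0.3, 0.4), 2.0, (0.4, 0.6, 0.8)),
        ((0.6, 0.6, 0.6), 2.0, (1.0, 1.0, 1.0)),
    ],
)
def test_scale_examples(rgb, gamma, expected):
    np.testing.assert_allclose(scale(px(*rgb), gamma)[0, 0], expected,
                               atol=1e-12)


def test_scale_doubles_luminance_before_clipping():
    img = px(0.2, 0.3, 0.4)
    assert compute_luminance(scale(img, 2.0))[0, 0] == pytest.approx(
        2.0 * compute_luminance(img)[0, 0])


def test_scale_rejects_nonpositive_gamma(rng):
    with pytest.raises(ValueError):
        scale(rng.random((2, 2, 3)), 0.0)
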