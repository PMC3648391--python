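"""Temporal/spatial contrast estimators and the 1/k^2 flow index."""

import numpy as np
import pytest

from strokeflow import (
    AcquisitionSpec,
    RawSpeckleStack,
    flow_index,
    generate_speckle_stack,
    spatial_contrast,
    temporal_contrast,
    uniform_phantom,
    tau_c_from_contrast,
)


def make_stack(frames, **kw):
    defaults = dict(
        exposure_time_s=0.005, frame_rate_fps=23.0, pixel_pitch_mm=0.2, bregma_px=(0, 0)
    )
    defaults.update(kw)
    return RawSpeckleStack(frames=np.asarray(frames, dtype=float), **defaults)


def brute_force_temporal(frames, block_size):
    """Independent loop oracle for block-wise temporal contrast."""
    t, h, w = frames.shape
    n_blocks = t // block_size
    out = np.zeros((h, w))
    for i in range(h):
        for j in range(w):
            ks = []
            for b in range(n_blocks):
                seg = frames[b * block_size : (b + 1) * block_size, i, j]
                ks.append(np.std(seg, ddof=1) / np.mean(seg))
            out[i, j] = np.mean(ks)
    return out


def test_constant_stack_gives_zero_contrast():
    stack = make_stack(np.full((120, 4, 5), 7.0))
    c = temporal_contrast(stack, block_size=100)
    assert c.mask.all()
    assert np.all(c.k == 0.0)


def test_two_frame_toy_block_hand_value():
    # values 1 and 3: sample SD sqrt(2), mean 2 -> k = sqrt(2)/2
    frames = np.stack([np.full((2, 2), 1.0), np.full((2, 2), 3.0)])
    c = temporal_contrast(make_stack(frames), block_size=2)
    assert c.k == pytest.approx(np.sqrt(2) / 2, abs=1e-12)


def test_matches_brute_force_loop_exactly():
    rng = np.random.default_rng(7)
    frames = rng.gamma(4.0, 10.0, size=(200, 5, 5))
    stack = make_stack(frames)
    c = temporal_contrast(stack, block_size=50)
    np.testing.assert_allclose(c.k, brute_force_temporal(frames, 50), rtol=1e-12)
    assert c.params["n_blocks"] == 4


def test_gamma_shape_4_recovers_half():
    # CV of gamma(shape 4) = 0.5; 50 blocks x 100 frames
    phantom = uniform_phantom(tau_c_from_contrast(0.25, 0.005), pixel_pitch_mm=0.5)
    stack = generate_speckle_stack(phantom, AcquisitionSpec(n_frames=5000, seed=11))
    c = temporal_contrast(stack, block_size=100)
    assert c.k.mean() == pytest.approx(0.5, rel=0.02)


def test_fewer_frames_than_block_raises_with_count():
    with pytest.raises(ValueError, match="100"):
        temporal_contrast(make_stack(np.ones((50, 2, 2))), block_size=100)
    with pytest.raises(ValueError):
        temporal_contrast(make_stack(np.ones((50, 2, 2))), block_size=1)


def test_block_averaging_is_permutation_invariant():
    rng = np.random.default_rng(3)
    frames = rng.gamma(9.0, 5.0, size=(300, 3, 3))
    k1 = temporal_contrast(make_stack(frames), block_size=100).k
    # permute whole blocks
    order = [2, 0, 1]
    permuted = np.concatenate([frames[b * 100 : (b + 1) * 100] for b in order])
    k2 = temporal_contrast(make_stack(permuted), block_size=100).k
    np.testing.assert_allclose(k1, k2, rtol=1e-12)


def test_gain_invariance_of_contrast_and_flow_index():
    rng = np.random.default_rng(5)
    frames = rng.gamma(16.0, 3.0, size=(200, 4, 4))
    c1 = temporal_contrast(make_stack(frames), 100)
    c2 = temporal_contrast(make_stack(frames * 10.0), 100)
    np.testing.assert_allclose(c2.k, c1.k, rtol=1e-9)
    f1, f2 = flow_index(c1), flow_index(c2)
    np.testing.assert_allclose(f2.flow_index, f1.flow_index, rtol=1e-9)


def test_zero_mean_pixels_are_masked_not_zeroed():
    frames = np.ones((100, 2, 2))
    frames[:, 0, 0] = 0.0  # block mean 0 at this pixel
    c = temporal_contrast(make_stack(frames), 100)
    assert not c.mask[0, 0]
    assert np.isnan(c.k[0, 0])
    assert c.mask[1, 1]


# ---------------------------------------------------------------- spatial


def test_spatial_constant_frame_zero_contrast_with_border_mask():
    c = spatial_contrast(np.full((20, 30), 5.0), window=7)
    assert np.all(c.k[c.mask] == 0.0)
    assert not c.mask[:3].any() and not c.mask[:, :3].any()
    assert c.mask[3:-3, 3:-3].all()


def test_spatial_matches_window_multiset_statistics():
    # checkerboard of a and b: every interior 3x3 window holds a fixed multiset
    a, b = 2.0, 6.0
    frame = np.fromfunction(lambda i, j: np.where((i + j) % 2 == 0, a, b), (12, 12))
    c = spatial_contrast(frame, window=3)
    # center parity 0 window: 5 of a, 4 of b (and mirrored); brute-force both
    for vals in ([a] * 5 + [b] * 4, [a] * 4 + [b] * 5):
        k_expected = np.std(vals, ddof=1) / np.mean(vals)
        assert np.isclose(c.k[c.mask], k_expected).any()
    uniform = spatial_contrast(np.full((12, 12), a), window=3)
    assert np.all(uniform.k[uniform.mask] == 0.0)


def test_spatial_gamma_shape_16_recovers_quarter():
    rng = np.random.default_rng(21)
    frame = rng.gamma(16.0, 10.0, size=(400, 400))
    c = spatial_contrast(frame, window=7)
    assert c.k[c.mask].mean() == pytest.approx(0.25, rel=0.03)


@pytest.mark.parametrize("window", [2, 4, 1, -3])
def test_spatial_rejects_bad_window(window):
    with pytest.raises(ValueError):
        spatial_contrast(np.ones((10, 10)), window=window)


# ---------------------------------------------------------------- flow index


def test_flow_index_algebra_and_floor():
    k = np.array([[0.5, 0.0], [2.0, 0.5]])
    from strokeflow import ContrastImage

    c = ContrastImage(k=k, mask=np.ones_like(k, bool), method="temporal")
    f = flow_index(c, k_floor=1e-3)
    assert f.flow_index[0, 0] == pytest.approx(4.0)
    assert f.flow_index[0, 1] == pytest.approx(1e6)
    assert f.floor_applied[0, 1] and not f.floor_applied[0, 0]
    assert f.flow_index[1, 0] == pytest.approx(0.25)


def test_flow_index_monotone_decreasing_in_k():
    from strokeflow import ContrastImage

    k = np.linspace(0.05, 1.0, 50)[None, :]
    c = ContrastImage(k=k, mask=np.ones_like(k, bool), method="temporal")
    fi = flow_index(c).flow_index[0]
    assert np.all(np.diff(fi) < 0)


def test_flow_index_propagates_invalid_mask():
    from strokeflow import ContrastImage

    k = np.array([[0.5, np.nan]])
    c = ContrastImage(k=k, mask=np.array([[True, False]]), method="temporal")
    f = flow_index(c)
    assert not f.mask[0, 1] and np.isnan(f.flow_index[0, 1])
    with pytest.raises(ValueError):
        flow_index(c, k_floor=0.0)
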