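"""Ground-truth generators: statistical calibration and determinism."""

import numpy as np
import pytest

from strokeflow import (
    AcquisitionSpec,
    FlowPhantom,
    TTCPhantomSpec,
    VesselFieldSpec,
    generate_score_table,
    generate_speckle_stack,
    generate_ttc_phantom,
    generate_vessel_fields,
    mca_phantom,
    tau_c_from_contrast,
    uniform_phantom,
)
from strokeflow.infarct import PALE


def test_flow_phantom_invariants():
    with pytest.raises(ValueError):
        FlowPhantom(np.zeros((5, 5)), 0.2, (0, 0), (1.0, 1.0))  # tau = 0
    with pytest.raises(ValueError):
        FlowPhantom(np.ones((5, 5)), 0.2, (0, 0), (5.0, 5.0))  # extent mismatch


def test_acquisition_spec_validation():
    with pytest.raises(ValueError):
        AcquisitionSpec(n_frames=0)
    with pytest.raises(ValueError):
        AcquisitionSpec(n_frames=10, beta=1.5)
    with pytest.raises(ValueError):
        AcquisitionSpec(n_frames=10, mean_intensity=5000.0, bit_depth=12)
    acq = AcquisitionSpec(n_frames=10, bit_depth=12)
    assert acq.full_scale == 4095
    assert acq.effective_mean == pytest.approx(409.5)


def test_single_pixel_temporal_contrast_converges_to_model_k():
    # gamma with shape M has CV 1/sqrt(M) = k; k^2 = 0.25 -> k = 0.5
    tau = tau_c_from_contrast(0.25, 0.005)
    phantom = FlowPhantom(np.full((1, 1), tau), 0.2, (0, 0), (0.2, 0.2))
    stack = generate_speckle_stack(phantom, AcquisitionSpec(n_frames=10_000, seed=42))
    x = stack.frames[:, 0, 0].astype(float)
    assert np.std(x, ddof=1) / np.mean(x) == pytest.approx(0.5, rel=0.02)


def test_static_phantom_gives_fully_developed_speckle():
    phantom = uniform_phantom(1e3, pixel_pitch_mm=1.0)  # tau_c >> T
    stack = generate_speckle_stack(phantom, AcquisitionSpec(n_frames=4000, seed=0))
    x = stack.frames[:, 0, 0].astype(float)
    assert np.std(x, ddof=1) / np.mean(x) == pytest.approx(1.0, rel=0.05)


def test_contrast_error_scales_as_inverse_sqrt_frames():
    # slope of log(|k_hat - k|) vs log(n) about -1/2 for the sample contrast
    tau = tau_c_from_contrast(0.25, 0.005)
    phantom = FlowPhantom(np.full((16, 16), tau), 0.2, (0, 0), (3.2, 3.2))
    stack = generate_speckle_stack(phantom, AcquisitionSpec(n_frames=6400, seed=9))
    x = stack.frames.astype(float)
    ns, errs = [], []
    for n in (100, 400, 1600, 6400):
        k_hat = np.std(x[:n], axis=0, ddof=1) / np.mean(x[:n], axis=0)
        errs.append(np.sqrt(np.mean((k_hat - 0.5) ** 2)))
        ns.append(n)
    slope = np.polyfit(np.log(ns), np.log(errs), 1)[0]
    assert slope == pytest.approx(-0.5, abs=0.15)


def test_speckle_stack_quantized_and_seed_deterministic():
    phantom = uniform_phantom(0.01, pixel_pitch_mm=1.0)
    acq = AcquisitionSpec(n_frames=50, seed=123)
    s1 = generate_speckle_stack(phantom, acq)
    s2 = generate_speckle_stack(phantom, acq)
    assert s1.frames.dtype == np.uint16
    assert s1.frames.max() <= 4095
    np.testing.assert_array_equal(s1.frames, s2.frames)
    s3 = generate_speckle_stack(phantom, AcquisitionSpec(n_frames=50, seed=124))
    assert (s1.frames != s3.frames).any()


def test_k2_floor_guard():
    phantom = uniform_phantom(1e-9, pixel_pitch_mm=1.0)  # k^2 ~ 1e-7
    with pytest.raises(ValueError, match="floor"):
        generate_speckle_stack(phantom, AcquisitionSpec(n_frames=10))


def test_mca_phantom_region_and_ratio_construction():
    base, sess = mca_phantom(0.31, pixel_pitch_mm=0.2)
    assert np.unique(base.tau_map).size == 1
    assert np.unique(sess.tau_map).size == 2
    from strokeflow import contrast_model

    k2 = contrast_model(np.unique(sess.tau_map), 0.005)
    ratio = (1 / k2.max()) / (1 / k2.min())  # occluded region has larger k2
    assert ratio == pytest.approx(0.31, rel=1e-6)
    with pytest.raises(ValueError):
        mca_phantom(0.1, baseline_k2=0.2)  # would need k^2 > beta


# ---------------------------------------------------------------- TTC


def test_ttc_sham_phantom_is_infarct_free():
    ss, gt = generate_ttc_phantom(TTCPhantomSpec(infarct_fraction=0.0, seed=1))
    assert gt.infarct_percent == 0.0
    assert all((lab == PALE).sum() == 0 for lab in gt.label_images)
    assert len(ss.sections) == 6 and ss.section_thickness_mm == 2.0


def test_ttc_uniform_fraction_forces_percentage():
    # every section pale area = 35% of hemisphere -> indirect formula gives 35%
    _, gt = generate_ttc_phantom(TTCPhantomSpec(infarct_fraction=0.35, seed=2))
    assert gt.infarct_percent_analytic == pytest.approx(35.0, abs=1e-9)
    assert gt.infarct_percent == pytest.approx(35.0, abs=0.5)  # discretization


def test_ttc_ground_truth_equals_pixel_count_oracle():
    rng = np.random.default_rng(8)
    fracs = rng.uniform(0.1, 0.6, size=6)
    _, gt = generate_ttc_phantom(TTCPhantomSpec(infarct_fraction=fracs, seed=3))
    pale = sum(int((lab == PALE).sum()) for lab in gt.label_images)
    contra = sum(
        int((lab[:, lab.shape[1] // 2 :] != 0).sum()) for lab in gt.label_images
    )
    assert gt.infarct_percent == pytest.approx(100.0 * pale / contra, abs=1e-12)
    # area-weighted analytic value agrees to within discretization error
    assert gt.infarct_percent == pytest.approx(gt.infarct_percent_analytic, abs=0.5)


def test_ttc_pale_region_strictly_inside_ipsilateral_hemisphere():
    _, gt = generate_ttc_phantom(TTCPhantomSpec(infarct_fraction=0.8, seed=4))
    for lab in gt.label_images:
        w = lab.shape[1]
        assert (lab[:, w // 2 :] == PALE).sum() == 0  # never crosses midline
        pale = lab == PALE
        border = np.zeros_like(pale)
        border[[0, -1], :] = True
        border[:, [0, -1]] = True
        assert not (pale & border).any()


def test_ttc_rejects_impossible_fraction():
    with pytest.raises(ValueError):
        generate_ttc_phantom(TTCPhantomSpec(infarct_fraction=1.0))
    with pytest.raises(ValueError):
        TTCPhantomSpec(infarct_fraction=[0.2] * 3).fractions()  # wrong length


def test_ttc_deterministic_at_fixed_seed():
    s1, _ = generate_ttc_phantom(TTCPhantomSpec(infarct_fraction=0.3, seed=77))
    s2, _ = generate_ttc_phantom(TTCPhantomSpec(infarct_fraction=0.3, seed=77))
    for a, b in zip(s1.sections, s2.sections):
        np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------- vessels


def test_vessel_zero_density_gives_empty_fields():
    fields, cents = generate_vessel_fields(VesselFieldSpec(density_per_mm2=0.0, seed=5))
    assert all(len(c) == 0 for c in cents)


def test_vessel_counts_are_poisson_with_rate_lambda_area():
    # lambda = 20 /mm^2, area 0.25 mm^2 -> mean count 5
    spec = VesselFieldSpec(density_per_mm2=20.0, n_fields=10_000, seed=6)
    _, cents = generate_vessel_fields(spec, render=False)
    counts = np.array([len(c) for c in cents])
    assert counts.mean() == pytest.approx(5.0, abs=3 * np.sqrt(5.0 / 10_000))
    assert counts.var(ddof=1) == pytest.approx(5.0, rel=0.1)  # Poisson: var = mean


def test_vessel_blob_radius_guard():
    with pytest.raises(ValueError, match="too large"):
        generate_vessel_fields(
            VesselFieldSpec(density_per_mm2=5.0, cell_radius_px=100.0, seed=0)
        )


def test_vessel_fields_deterministic():
    spec = VesselFieldSpec(density_per_mm2=15.0, seed=31)
    f1, c1 = generate_vessel_fields(spec)
    f2, c2 = generate_vessel_fields(spec)
    for a, b in zip(c1, c2):
        np.testing.assert_array_equal(a, b)
    for a, b in zip(f1, f2):
        np.testing.assert_array_equal(a.image, b.image)


# ---------------------------------------------------------------- scores


def test_score_table_degenerate_at_zero():
    df = generate_score_table({"sham": 0.0}, n_per_group=10, sd=1e-9, seed=0)
    assert (df["score"] == 0).all()


def test_score_table_bounds_and_regime():
    df = generate_score_table(
        {"non_exercise": 4.06, "early_exercise": 4.12}, n_per_group=200, sd=1.0, seed=1
    )
    assert df["score"].between(0, 7).all()
    means = df.groupby("group")["score"].mean()
    assert means["non_exercise"] == pytest.approx(4.06, abs=0.25)
    assert means["early_exercise"] == pytest.approx(4.12, abs=0.25)


def test_score_table_rejects_out_of_scale_mean():
    with pytest.raises(ValueError):
        generate_score_table({"g": 7.5})


def test_score_table_deterministic():
    a = generate_score_table({"g": 3.0}, seed=9)
    b = generate_score_table({"g": 3.0}, seed=9)
    assert a.equals(b)
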