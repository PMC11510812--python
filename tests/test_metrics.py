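"""Closed-form and oracle checks for the image-quality metrics."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity

from spectral_n2i.metrics import (
    MetricError,
    MetricReport,
    RoiMask,
    circular_roi,
    cnr,
    evaluate_stack,
    mse,
    profile_mse,
    psnr,
    roi_profile,
    ssim,
)
from spectral_n2i.phantom import CircleShape, MaterialSpec, build_phantom
from spectral_n2i.recon import SpectralImageStack


# ----------------------------------------------------------------------- MSE
def test_mse_closed_forms(rng):
    f = np.zeros((2, 2))
    g = f.copy()
    assert mse(f, g) == 0.0
    g[0, 0] = 1.0
    assert mse(f, g) == 0.25
    a, b = rng.standard_normal((5, 7)), rng.standard_normal((5, 7))
    loop = sum(
        (a[i, j] - b[i, j]) ** 2 for i in range(5) for j in range(7)
    ) / 35.0
    assert mse(a, b) == pytest.approx(loop, rel=1e-12)
    assert mse(a, b) == mse(b, a)


def test_mse_shape_mismatch():
    with pytest.raises(MetricError):
        mse(np.zeros((2, 2)), np.zeros((3, 2)))


# ---------------------------------------------------------------------- PSNR
def test_psnr_closed_forms():
    f = np.array([[1.0, 0.0], [0.0, 0.0]])
    assert psnr(f, f) == float("inf")
    g = np.zeros((2, 2))
    # max(f, g) = 1, MSE = 0.25 -> 20*log10(1) - 10*log10(0.25) = 6.0206 dB
    assert psnr(f, g) == pytest.approx(6.0206, abs=1e-4)


def test_psnr_scale_invariance(rng):
    f = np.abs(rng.standard_normal((8, 8))) + 0.1
    g = np.abs(rng.standard_normal((8, 8))) + 0.1
    assert psnr(3.7 * f, 3.7 * g) == pytest.approx(psnr(f, g), abs=1e-10)


def test_psnr_reference_peak_convention(rng):
    f = np.full((4, 4), 2.0)
    g = np.full((4, 4), 4.0)
    assert psnr(f, g, peak="reference") < psnr(f, g)  # smaller peak, smaller PSNR


# ---------------------------------------------------------------------- SSIM
def test_ssim_perfect_agreement(rng):
    f = rng.standard_normal((32, 32))
    assert ssim(f, f.copy()) == pytest.approx(1.0, abs=1e-9)


def test_ssim_sign_flip_negative():
    # sinusoid with period == window width: every 7x7 window has zero mean,
    # so the (negative) covariance term sets the sign
    x = np.sin(2 * np.pi * np.arange(35) / 7.0)
    f = np.outer(np.ones(35), x) + 0.5 * np.outer(x, np.ones(35))
    assert ssim(f, -f) < 0


def test_ssim_single_global_window_matches_formula(rng):
    f = rng.standard_normal((8, 8))
    g = f + 0.3 * rng.standard_normal((8, 8))
    c1, c2 = 1e-4, 9e-4
    val = ssim(f, g, window=8, constants=(c1, c2))
    mu_f, mu_g = f.mean(), g.mean()
    var_f, var_g = f.var(), g.var()
    cov = ((f - mu_f) * (g - mu_g)).mean()
    expected = ((2 * mu_f * mu_g + c1) * (2 * cov + c2)) / (
        (mu_f**2 + mu_g**2 + c1) * (var_f + var_g + c2)
    )
    # window == image: a single window at the unpadded centre dominates;
    # compare against the global formula loosely (border handling differs)
    assert val == pytest.approx(expected, rel=0.2)


def test_ssim_symmetry_and_skimage_crosscheck(rng):
    f = rng.random((40, 40))
    g = np.clip(f + 0.1 * rng.standard_normal((40, 40)), 0, 1.5)
    # exactly symmetric for fixed constants; nearly so when the constants
    # are derived from the reference image's data range
    c = (1e-4, 9e-4)
    assert ssim(f, g, constants=c) == pytest.approx(ssim(g, f, constants=c), rel=1e-12)
    assert ssim(f, g) == pytest.approx(ssim(g, f), rel=1e-3)
    reference = structural_similarity(
        f, g, win_size=7, gaussian_weights=False, data_range=f.max() - f.min()
    )
    assert ssim(f, g) == pytest.approx(reference, abs=1e-3)


# ----------------------------------------------------------------------- CNR
def make_masks():
    t = np.zeros((6, 6), bool)
    b = np.zeros((6, 6), bool)
    t[:2] = True
    b[4:] = True
    return RoiMask(t, "t"), RoiMask(b, "b")


def test_cnr_closed_forms():
    t, b = make_masks()
    img = np.zeros((6, 6))
    img[:2] = [[4.0, 6.0, 4.0, 6.0, 4.0, 6.0]] * 2  # mean 5, sd 1
    img[4:] = [[0.0, 2.0, 0.0, 2.0, 0.0, 2.0]] * 2  # mean 1, sd 1
    assert cnr(img, t, b) == pytest.approx(2.0)
    assert cnr(np.ones((6, 6)), t, b) == 0.0
    img2 = np.zeros((6, 6))
    img2[:2] = 5.0
    assert cnr(img2, t, b) == float("inf")  # constant ROIs, nonzero contrast


def test_cnr_requires_disjoint_rois():
    t, _ = make_masks()
    with pytest.raises(MetricError):
        cnr(np.zeros((6, 6)), t, t)


# --------------------------------------------------------------- ROI profile
def test_roi_profile_constant_stack():
    stack = SpectralImageStack(np.full((3, 8, 8), 2.5), np.array([20.0, 21, 22.0]))
    roi = circular_roi((8, 8), 4, 4, 2, "c")
    mean, sd, avg_sd = roi_profile(stack, roi)
    np.testing.assert_allclose(mean, 2.5)
    np.testing.assert_allclose(sd, 0.0)
    assert avg_sd == 0.0


def test_roi_profile_hand_statistics():
    px = np.zeros((1, 4, 4))
    px[0, 0, :2] = [1.0, 3.0]
    mask = np.zeros((4, 4), bool)
    mask[0, :2] = True
    mean, sd, avg_sd = roi_profile(
        SpectralImageStack(px, np.array([20.0])), RoiMask(mask)
    )
    assert mean[0] == 2.0 and sd[0] == 1.0 and avg_sd == 1.0


def test_roi_profile_matches_phantom_ground_truth():
    ph = build_phantom(
        [MaterialSpec("water", modulation_amplitude=0.0)],
        [CircleShape(50, 50, 10)],
        energies=np.array([30.0, 60.0, 90.0]),
    )
    stack = SpectralImageStack(ph.lac, ph.energies)
    roi = RoiMask(ph.labels == 1, "water")
    mean, sd, _ = roi_profile(stack, roi)
    from spectral_n2i.materials import MATERIALS, get_mass_attenuation

    expected = np.asarray(
        get_mass_attenuation("water", ph.energies)
    ) * MATERIALS["water"].density
    np.testing.assert_allclose(mean, expected, rtol=1e-12)
    np.testing.assert_allclose(sd, 0.0, atol=1e-14)


# --------------------------------------------------------------- profile MSE
def test_profile_mse_closed_forms(rng):
    p = rng.standard_normal(10)
    assert profile_mse(p, p.copy()) == (0.0, 0.0)
    m, s = profile_mse(p + 0.5, p)
    assert m == pytest.approx(0.25, rel=1e-12) and s == pytest.approx(0.0, abs=1e-12)
    q = rng.standard_normal(10)
    sq = [(a - b) ** 2 for a, b in zip(p, q)]
    m2, s2 = profile_mse(p, q)
    assert m2 == pytest.approx(np.mean(sq), rel=1e-12)
    assert s2 == pytest.approx(np.std(sq), rel=1e-12)
    with pytest.raises(MetricError):
        profile_mse(p, q[:5])


# ------------------------------------------------------------ evaluate_stack
def test_evaluate_identical_stack_is_perfect(tiny_bundle):
    ph = tiny_bundle["phantom"]
    stack = SpectralImageStack(ph.lac.copy(), ph.energies)
    report = evaluate_stack(stack, ph)
    assert np.all(np.isinf(report.per_channel["psnr"]))
    np.testing.assert_allclose(report.per_channel["ssim"], 1.0, atol=1e-9)


def test_report_summary_recomputable_and_serialisable(study_bundle, tmp_path):
    ph = study_bundle["phantom"]
    report = evaluate_stack(
        study_bundle["fbp_full"], ph, rois=[RoiMask(ph.labels == 1, "water")]
    )
    pc = report.per_channel
    assert report.summary["psnr_mean"] == pytest.approx(pc["psnr"].mean())
    assert report.summary["ssim_sd"] == pytest.approx(pc["ssim"].std(ddof=0))
    back = MetricReport.from_json(report.to_json())
    np.testing.assert_allclose(back.per_channel["psnr"], pc["psnr"])
    assert back.summary == report.summary
    assert back.roi_stats["water"]["channel_averaged_sd"] == pytest.approx(
        report.roi_stats["water"]["channel_averaged_sd"]
    )
    report.save_csv(tmp_path / "report.csv")
    assert (tmp_path / "report.csv").exists()
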