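"""Phantom construction, K-edge detection and cropping."""

import numpy as np
import pytest

from spectral_n2i.materials import MATERIALS, get_mass_attenuation
from spectral_n2i.phantom import (
    CircleShape,
    MaterialSpec,
    PhantomError,
    build_phantom,
    center_crop,
    find_k_edge,
    load_phantom_h5,
    preset_phantom,
    save_phantom_h5,
)


@pytest.fixture(scope="module")
def phantom1():
    return preset_phantom(1, energies=np.array([45.0, 70.0]))


def test_preset1_four_regions_zero_background(phantom1):
    assert sorted(np.unique(phantom1.labels)) == [0, 1, 2, 3, 4]
    for obj in range(1, 5):
        assert np.all(phantom1.lac[:, phantom1.labels == obj] > 0)
    assert np.all(phantom1.lac[:, phantom1.labels == 0] == 0)


def test_labels_zero_iff_lac_zero(phantom1):
    zero_lac = np.all(phantom1.lac == 0, axis=0)
    np.testing.assert_array_equal(zero_lac, phantom1.labels == 0)


def test_no_modulation_gives_constant_objects():
    specs = [MaterialSpec("water", modulation_amplitude=0.0)]
    ph = build_phantom(specs, [CircleShape(50, 50, 10)], energies=[70.0])
    vals = ph.lac[0, ph.labels == 1]
    assert np.ptp(vals) == 0.0


def test_single_pixel_object_equals_mu_rho_times_density():
    specs = [MaterialSpec("aluminium", modulation_amplitude=0.0)]
    ph = build_phantom(
        specs, [CircleShape(50, 50, 0.4)], energies=[30.0, 80.0, 120.0]
    )
    assert (ph.labels == 1).sum() == 1
    expected = np.asarray(
        get_mass_attenuation("aluminium", np.array([30.0, 80.0, 120.0]))
    ) * MATERIALS["aluminium"].density
    np.testing.assert_allclose(ph.lac[:, ph.labels == 1][:, 0], expected, rtol=1e-12)


def test_lac_linear_in_density():
    shapes = [CircleShape(50, 50, 10)]
    base = build_phantom(
        [MaterialSpec("water", density=1.0)], shapes, energies=[70.0]
    )
    double = build_phantom(
        [MaterialSpec("water", density=2.0)], shapes, energies=[70.0]
    )
    np.testing.assert_allclose(double.lac, 2.0 * base.lac, rtol=1e-12)


def test_water_lac_strictly_decreasing_with_energy():
    ph = preset_phantom(1, n_materials=1, energies=np.arange(20.0, 151.0, 5.0))
    profile = ph.lac[:, ph.labels == 1].mean(axis=1)
    assert np.all(np.diff(profile) < 0)


def test_overlapping_shapes_raise():
    with pytest.raises(PhantomError, match="overlap"):
        build_phantom(
            ["water", "acetone"],
            [CircleShape(50, 50, 10), CircleShape(55, 50, 10)],
            energies=[70.0],
        )


def test_shape_outside_grid_raises():
    with pytest.raises(PhantomError, match="outside"):
        build_phantom(["water"], [CircleShape(95, 50, 10)], energies=[70.0])


def test_unknown_material_raises():
    with pytest.raises(Exception):
        build_phantom(["vibranium"], [CircleShape(50, 50, 10)], energies=[70.0])


# ------------------------------------------------------------- K-edge finder
def test_find_k_edge_iodine():
    e = np.arange(25.0, 45.0 + 1e-9, 0.05)
    mu = np.asarray(get_mass_attenuation("iodine", e))
    edge = find_k_edge(e, mu)
    assert edge == pytest.approx(33.17, abs=0.1)


def test_find_k_edge_water_none():
    e = np.arange(20.0, 50.0 + 1e-9, 0.05)
    mu = np.asarray(get_mass_attenuation("water", e))
    assert find_k_edge(e, mu) is None


def test_find_k_edge_synthetic_step():
    e = np.arange(10.0, 20.0, 0.5)
    v = np.where(e < 15.9, 1.0, 2.0)  # doubles between samples 11 and 12
    edge = find_k_edge(e, v)
    k = int(np.searchsorted(e, 15.9))
    assert edge == pytest.approx(0.5 * (e[k - 1] + e[k]))


def test_find_k_edge_nonmonotone_grid_raises():
    with pytest.raises(PhantomError):
        find_k_edge([1.0, 3.0, 2.0], [1.0, 1.0, 1.0])


def test_find_k_edge_window_selects_samples():
    e = np.arange(25.0, 45.0, 0.05)
    mu = np.asarray(get_mass_attenuation("iodine", e))
    with pytest.raises(PhantomError):
        find_k_edge(e, mu, window=(44.9, 45.0))  # fewer than 3 samples


# ---------------------------------------------------------------- center_crop
def test_center_crop_dimensions():
    ph = preset_phantom(1, energies=np.arange(20.0, 151.0))
    assert ph.lac.shape == (131, 100, 100)
    cropped = center_crop(ph, 96, 128)
    assert cropped.lac.shape == (128, 96, 96)
    # highest-energy channels dropped, energies follow
    np.testing.assert_array_equal(cropped.energies, ph.energies[:128])
    assert cropped.energies[-1] == pytest.approx(147.0)


def test_center_crop_identity_and_bookkeeping(phantom1):
    same = center_crop(phantom1, 100, 2)
    np.testing.assert_array_equal(same.lac, phantom1.lac)
    small = center_crop(phantom1, 40, 1)
    np.testing.assert_array_equal(small.lac[0], phantom1.lac[0, 30:70, 30:70])
    np.testing.assert_array_equal(small.labels, phantom1.labels[30:70, 30:70])


def test_center_crop_too_large_raises(phantom1):
    with pytest.raises(PhantomError):
        center_crop(phantom1, 200, 2)


def test_phantom_h5_round_trip(tmp_path, phantom1):
    path = tmp_path / "ph.h5"
    save_phantom_h5(phantom1, path)
    back = load_phantom_h5(path)
    np.testing.assert_array_equal(back.lac, phantom1.lac)
    np.testing.assert_array_equal(back.labels, phantom1.labels)
    assert back.metadata["materials"][0]["name"] == "water"
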