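"""Scan geometry, fan-beam projection and Poisson corruption."""

import numpy as np
import pytest

from spectral_n2i.forward import add_poisson_noise, magnification, project
from spectral_n2i.geometry import GeometryError, ScanGeometry, default_geometry
from spectral_n2i.materials import get_mass_attenuation

# water mu/rho at 70 keV, used to construct a disc with a round LAC value
MATERIAL_WATER_MU70 = float(get_mass_attenuation("water", 70.0))
from spectral_n2i.phantom import CircleShape, MaterialSpec, build_phantom
from spectral_n2i.projector import Projector
from spectral_n2i.spectrum import EnergySpectrum


def geom(n_angles=60, det=64, beam="fan"):
    return default_geometry(n_angles=n_angles, detector_pixels=det, beam=beam)


# ------------------------------------------------------------- magnification
def test_magnification_real_scan_distances():
    g = ScanGeometry(33.20, 27.00, 80, 0.25, np.array([0.0]))
    assert round(magnification(g), 2) == 1.81


def test_magnification_detector_at_object():
    g = ScanGeometry(50.0, 0.0, 16, 1.0, np.array([0.0]))
    assert magnification(g) == 1.0


def test_magnification_synthetic_geometry():
    assert magnification(default_geometry()) == pytest.approx(2.0096, abs=5e-4)


def test_geometry_validation():
    with pytest.raises(GeometryError):
        ScanGeometry(-1.0, 1.0, 16, 1.0, np.array([0.0]))
    with pytest.raises(GeometryError):
        ScanGeometry(1.0, 1.0, 16, 1.0, np.array([0.0, 0.0]))  # duplicate
    with pytest.raises(GeometryError):
        ScanGeometry(1.0, 1.0, 16, 1.0, np.array([361.0]))


# ------------------------------------------------------------------ project
def test_zero_phantom_projects_to_zero():
    ph = build_phantom([], [], grid=(32, 32), energies=[70.0])
    sino = project(ph, geom())
    assert np.all(sino.attenuation == 0)


def test_default_configuration_shape():
    ph = build_phantom(["water"], [CircleShape(50, 50, 10)], energies=[70.0])
    sino = project(ph, default_geometry())
    assert sino.attenuation.shape == (1, 360, 256)


def test_disc_central_ray_matches_chord_length():
    mu = 0.2
    ph = build_phantom(
        [MaterialSpec("water", density=mu / MATERIAL_WATER_MU70, modulation_amplitude=0.0)],
        [CircleShape(49.5, 49.5, 30.0)],
        energies=[70.0],
    )
    sino = project(ph, default_geometry())
    proj = Projector(default_geometry(), 100)
    center = sino.attenuation[0, 0, 127:129].mean()
    lac = ph.lac[0].max()
    expected = 2 * 30.0 * proj.pixel_size * lac
    assert center == pytest.approx(expected, rel=0.02)


def test_projection_linear_in_phantom(tiny_bundle):
    sino = tiny_bundle["clean_sinogram"]
    ph = tiny_bundle["phantom"]
    geometry = tiny_bundle["geometry"]
    scaled = project(
        type(ph)(ph.lac * 3.0, ph.energies, ph.labels, ph.metadata), geometry
    )
    np.testing.assert_allclose(scaled.attenuation, 3.0 * sino.attenuation, atol=1e-10)


def test_centred_disc_gives_angle_independent_profiles():
    ph = build_phantom(
        [MaterialSpec("water", modulation_amplitude=0.0)],
        [CircleShape(49.5, 49.5, 20.0)],
        energies=[70.0],
    )
    sino = project(ph, default_geometry(n_angles=36)).attenuation[0]
    spread = sino.std(axis=0).max()
    assert spread < 0.02 * sino.max()


# ---------------------------------------------------------------- add noise
def _flat_spectrum(n, counts_per_bin):
    return EnergySpectrum(
        20.0 + np.arange(n) * 1.0, np.full(n, float(counts_per_bin)), 1.0
    )


def test_noise_is_seed_reproducible(tiny_bundle):
    clean = tiny_bundle["clean_sinogram"]
    spec = tiny_bundle["spectrum"]
    a = add_poisson_noise(clean, spec, seed=11)
    b = add_poisson_noise(clean, spec, seed=11)
    np.testing.assert_array_equal(a.attenuation, b.attenuation)
    c = add_poisson_noise(clean, spec, seed=12)
    assert not np.array_equal(a.attenuation, c.attenuation)
    # different seeds give (nearly) uncorrelated noise
    na = (a.attenuation - clean.attenuation).ravel()
    nc = (c.attenuation - clean.attenuation).ravel()
    corr = np.corrcoef(na, nc)[0, 1]
    assert abs(corr) < 0.02


def test_poisson_counts_match_expected_mean():
    # y = 0 everywhere: counts ~ Poisson(I0); sample mean within 3 sigma
    i0 = 1e4
    n_draws = 10000
    geometry = ScanGeometry(50.0, 50.0, n_draws, 1.0, np.array([0.0]))
    from spectral_n2i.forward import SpectralSinogram

    clean = SpectralSinogram(
        np.zeros((1, 1, n_draws)), np.array([20.0]), geometry,
        grid_n=8, pixel_size_cm=0.1,
    )
    spec = EnergySpectrum(np.array([20.0]), np.array([i0]), 1.0)
    noisy = add_poisson_noise(clean, spec, seed=5)
    counts = i0 * np.exp(-noisy.attenuation)
    assert counts.mean() == pytest.approx(i0, abs=3 * np.sqrt(i0 / n_draws))


def test_large_flux_recovers_clean_attenuation(tiny_bundle):
    clean = tiny_bundle["clean_sinogram"]
    width = float(clean.energies[1] - clean.energies[0])
    big = EnergySpectrum(clean.energies, np.full(clean.n_channels, 1e8), width)
    noisy = add_poisson_noise(clean, big, seed=3)
    mask = clean.attenuation > 0.1
    rel = np.abs(noisy.attenuation[mask] - clean.attenuation[mask]) / clean.attenuation[mask]
    assert np.median(rel) < 0.01


def test_unattenuated_ray_collects_60000_expected_counts(tiny_bundle):
    spec = tiny_bundle["spectrum"]
    clean = tiny_bundle["clean_sinogram"]
    # rays that miss the object have y == 0 in every channel
    miss = np.all(clean.attenuation == 0, axis=0)
    assert miss.any()
    expected = spec.fluence.sum()
    assert expected == pytest.approx(60000.0, abs=1e-6)


def test_misaligned_energy_grid_raises(tiny_bundle):
    clean = tiny_bundle["clean_sinogram"]
    bad = _flat_spectrum(clean.n_channels, 100.0)  # wrong bin centres
    with pytest.raises(ValueError):
        add_poisson_noise(clean, bad, seed=0)
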