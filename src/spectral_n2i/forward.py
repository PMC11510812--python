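"""Beer-Lambert forward projection of spectral phantoms and Poisson noise.

The clean measurement for channel E is the line integral y = integral of
mu(E, r) dr along each fan-beam ray.  Photon noise enters through the
poly-energetic Beer-Lambert model: the detected count in a channel is
Poisson with mean I0(E) * exp(-y), and the noisy attenuation value is
recovered as y~ = ln(I0(E) / counts), with counts clipped to >= 1 before
the log (the clip is recorded in provenance).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .geometry import GeometryError, ScanGeometry, magnification
from .phantom import SpectralPhantom
from .projector import Projector
from .spectrum import EnergySpectrum

__all__ = [
    "SpectralSinogram",
    "project",
    "add_poisson_noise",
    "magnification",
    "save_sinogram_h5",
    "load_sinogram_h5",
]


@dataclass
class SpectralSinogram:
    """Per-channel attenuation line integrals over (angle, detector)."""

    attenuation: np.ndarray  # (energy, angle, detector), unitless
    energies: np.ndarray  # keV
    geometry: ScanGeometry
    noisy: bool = False
    grid_n: int = 0  # reconstruction grid used to generate/reconstruct
    pixel_size_cm: float = 0.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.attenuation = np.asarray(self.attenuation, dtype=np.float64)
        self.energies = np.asarray(self.energies, dtype=np.float64)
        if self.attenuation.ndim != 3:
            raise GeometryError("attenuation must be (energy, angle, detector)")
        if not np.all(np.isfinite(self.attenuation)):
            raise GeometryError("attenuation must be finite")
        e, a, d = self.attenuation.shape
        if e != len(self.energies):
            raise GeometryError("energies length mismatch")
        if a != len(self.geometry.angles) or d != self.geometry.detector_pixels:
            raise GeometryError("sinogram shape inconsistent with geometry")

    @property
    def n_channels(self) -> int:
        return self.attenuation.shape[0]

    def projector(self) -> Projector:
        return Projector(self.geometry, self.grid_n, self.pixel_size_cm)


def project(
    phantom: SpectralPhantom,
    geometry: ScanGeometry,
    pixel_size_cm: float | None = None,
) -> SpectralSinogram:
    """Fan-beam line integrals of every energy channel of the phantom.

    The reconstruction pixel size defaults to field-of-view / grid size, so
    the phantom exactly spans the field of view implied by the geometry; a
    larger explicit pixel size raises a geometry error.
    """
    if phantom.lac.shape[1] != phantom.lac.shape[2]:
        raise GeometryError("phantom grid must be square")
    grid_n = phantom.lac.shape[1]
    proj = Projector(geometry, grid_n, pixel_size_cm)
    sino = proj.forward(phantom.lac)
    return SpectralSinogram(
        sino,
        phantom.energies,
        geometry,
        noisy=False,
        grid_n=grid_n,
        pixel_size_cm=proj.pixel_size,
        provenance={"source": "project", "beam": geometry.beam},
    )


def add_poisson_noise(
    sino: SpectralSinogram, spectrum: EnergySpectrum, seed: int
) -> SpectralSinogram:
    """Poisson-corrupt a clean sinogram channel-wise.

    ``spectrum`` supplies I0(E) per channel (photons per detector pixel);
    its bin centres must match the sinogram energies.  Counts are drawn
    independently per channel, angle and detector pixel, clipped to >= 1,
    and converted back to attenuation values.
    """
    if len(spectrum) != sino.n_channels or not np.allclose(
        spectrum.bin_centers, sino.energies, atol=1e-6
    ):
        raise ValueError("spectrum energy grid does not match sinogram energies")
    rng = np.random.default_rng(seed)
    i0 = spectrum.fluence[:, None, None]
    expected = i0 * np.exp(-sino.attenuation)
    counts = rng.poisson(expected).astype(np.float64)
    noisy = np.log(i0 / np.clip(counts, 1.0, None))
    prov = dict(sino.provenance)
    prov.update({"noise": "poisson", "seed": int(seed), "zero_count_clip": 1})
    return replace(sino, attenuation=noisy, noisy=True, provenance=prov)


def save_sinogram_h5(sino: SpectralSinogram, path) -> None:
    g = sino.geometry
    with h5py.File(path, "w") as f:
        f.create_dataset("attenuation", data=sino.attenuation, track_times=False)
        f.create_dataset("energies", data=sino.energies, track_times=False)
        f.create_dataset("angles", data=g.angles, track_times=False)
        f.attrs.update(
            {
                "source_to_object": g.source_to_object,
                "object_to_detector": g.object_to_detector,
                "detector_pixels": g.detector_pixels,
                "detector_pitch": g.detector_pitch,
                "beam": g.beam,
                "noisy": sino.noisy,
                "grid_n": sino.grid_n,
                "pixel_size_cm": sino.pixel_size_cm,
                "provenance": json.dumps(sino.provenance),
            }
        )


def load_sinogram_h5(path) -> SpectralSinogram:
    with h5py.File(path, "r") as f:
        geom = ScanGeometry(
            float(f.attrs["source_to_object"]),
            float(f.attrs["object_to_detector"]),
            int(f.attrs["detector_pixels"]),
            float(f.attrs["detector_pitch"]),
            f["angles"][()],
            str(f.attrs["beam"]),
        )
        return SpectralSinogram(
            f["attenuation"][()],
            f["energies"][()],
            geom,
            noisy=bool(f.attrs["noisy"]),
            grid_n=int(f.attrs["grid_n"]),
            pixel_size_cm=float(f.attrs["pixel_size_cm"]),
            provenance=json.loads(f.attrs.get("provenance", "{}")),
        )
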