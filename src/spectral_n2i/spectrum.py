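"""Poly-energetic X-ray source spectra: generation, rebinning, normalisation.

The source model is a semi-empirical thick-target tungsten-anode model:

* Kramers-type bremsstrahlung production, distributed over electron
  penetration depth with the Thomson-Whiddington energy-loss relation, so
  that photons created deeper in the anode are attenuated along their
  oblique escape path (anode self-filtration at the take-off angle).
* The absolute scale is fixed by the Kramers radiative efficiency
  eta = k_e * Z * V with k_e = 1.1e-9 / volt, emission taken as isotropic,
  and fluence referenced at ``reference_cm`` (default 100 cm, matching a
  1 m air path) per mAs of tube load.
* Tungsten K characteristic lines (K-alpha/K-beta) are added above the
  69.525 keV K-shell threshold with a (U0-1)^1.63 overvoltage yield law.
* External filtration applies Beer-Lambert factors from the packaged
  attenuation tables.

The model reproduces the shape and order of magnitude of measured tungsten
spectra; it is not a Monte-Carlo code.  In the simulation pipeline the
absolute scale is irrelevant anyway, because the spectrum is renormalised
to a fixed total photon count per detector pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .attenuation import UnknownMaterialError
from .materials import MATERIALS, Material

__all__ = [
    "EnergySpectrum",
    "SpectrumError",
    "build_source_spectrum",
    "interpolate_density",
    "rebin_average",
    "normalize_total_counts",
    "study_channel_spectrum",
    "save_spectrum_csv",
    "load_spectrum_csv",
]

ELECTRONS_PER_MAS = 6.241509e15
KRAMERS_K = 1.1e-9  # radiative efficiency per volt (thick target)
TW_CONSTANT = 7.85e5  # Thomson-Whiddington, keV^2 cm^2 / g
W_K_EDGE = 69.525  # keV
# (line energy keV, relative intensity) for tungsten K lines
W_K_LINES = [(57.982, 0.58), (59.318, 1.00), (67.244, 0.30), (69.067, 0.08)]
K_LINE_YIELD = 1.1e-3  # photons/electron at unit reduced overvoltage


class SpectrumError(ValueError):
    """Raised for invalid spectrum configurations."""


@dataclass(frozen=True)
class EnergySpectrum:
    """Photon fluence per energy bin (one detector pixel's incident flux).

    ``fluence[i]`` is the number of photons (per cm^2 per mAs unless
    renormalised) in the bin centred on ``bin_centers[i]`` of width
    ``bin_width`` keV.
    """

    bin_centers: np.ndarray  # keV, uniform pitch, strictly increasing
    fluence: np.ndarray  # photons per bin, >= 0
    bin_width: float  # keV

    def __post_init__(self):
        centers = np.asarray(self.bin_centers, dtype=float)
        fluence = np.asarray(self.fluence, dtype=float)
        if centers.ndim != 1 or centers.shape != fluence.shape:
            raise SpectrumError("bin_centers and fluence must be 1-D, same length")
        if len(centers) >= 2:
            steps = np.diff(centers)
            if np.any(steps <= 0) or not np.allclose(
                steps, self.bin_width, rtol=1e-6, atol=1e-9
            ):
                raise SpectrumError("bin_centers must be uniform at bin_width")
        if np.any(fluence < 0):
            raise SpectrumError("fluence must be non-negative")
        object.__setattr__(self, "bin_centers", centers)
        object.__setattr__(self, "fluence", fluence)

    def __len__(self) -> int:
        return len(self.bin_centers)

    @property
    def density(self) -> np.ndarray:
        """Fluence per keV (photons/cm^2/mAs/keV for a raw source spectrum)."""
        return self.fluence / self.bin_width

    @property
    def total(self) -> float:
        return float(self.fluence.sum())


_FILTER_DENSITY = {  # g/cm^3 for filtration materials accepted by name
    "al": MATERIALS["aluminium"],
    "aluminium": MATERIALS["aluminium"],
    "be": MATERIALS["beryllium"],
    "beryllium": MATERIALS["beryllium"],
    "air": MATERIALS["air"],
    "water": MATERIALS["water"],
}


def _filter_material(name: str) -> Material:
    try:
        return _FILTER_DENSITY[name.strip().lower()]
    except KeyError:
        raise UnknownMaterialError(f"unknown filtration material {name!r}") from None


def build_source_spectrum(
    kvp: float = 150.0,
    anode_angle_deg: float = 12.0,
    filtration: list[tuple[str, float]] | None = None,
    bin_width_kev: float = 0.5,
    exposure_mas: float = 1.0,
    reference_cm: float = 100.0,
    grid_start_kev: float = 1.0,
) -> EnergySpectrum:
    """Simulate a filtered tungsten-anode spectrum.

    Parameters
    ----------
    kvp : tube potential in kV (max photon energy in keV).
    anode_angle_deg : take-off angle of the reflection target.
    filtration : list of (material name, thickness in mm).
    bin_width_kev : output bin width.
    exposure_mas : tube load; fluence scales linearly with it.
    reference_cm : distance at which fluence per cm^2 is referenced.

    Returns photons per bin per cm^2; zero fluence above ``kvp``.
    """
    if kvp <= 0 or bin_width_kev <= 0 or exposure_mas <= 0:
        raise SpectrumError("kvp, bin width and exposure must be positive")
    if kvp <= grid_start_kev:
        raise SpectrumError(f"kvp={kvp} below the {grid_start_kev} keV grid start")
    if filtration is None:
        filtration = [("Al", 4.0), ("Be", 1.0), ("air", 1000.0)]

    n_bins = int(np.floor(kvp / bin_width_kev))
    centers = (np.arange(n_bins) + 0.5) * bin_width_kev
    keep = centers >= grid_start_kev
    centers = centers[keep]

    tungsten = MATERIALS["tungsten"]
    mu_w = np.asarray(tungsten.linear_attenuation(centers))  # 1/cm
    cosec = 1.0 / np.sin(np.deg2rad(anode_angle_deg))

    # Depth-resolved Kramers production.  Electron energy T decays with mass
    # depth following Thomson-Whiddington: x(T) = (T0^2 - T^2) / (rho * C).
    t_grid = np.linspace(0.0, kvp, 400)
    dt = t_grid[1] - t_grid[0]
    depth = (kvp**2 - t_grid**2) / (tungsten.density * TW_CONSTANT)  # cm
    # S(E) = integral_E^T0 exp(-mu_w(E) * depth(T) * cosec) dT
    atten = np.exp(-np.outer(mu_w, depth) * cosec)  # (n_E, n_T)
    produced = t_grid[None, :] > centers[:, None]
    s_of_e = (atten * produced).sum(axis=1) * dt

    z_w = 74
    c_kramers = 2.0 * KRAMERS_K * 1000.0  # photons keV / (electron keV^2)
    per_electron_density = c_kramers * z_w * s_of_e / centers  # ph/el/keV (4pi)

    geom = exposure_mas * ELECTRONS_PER_MAS / (4.0 * np.pi * reference_cm**2)
    density = per_electron_density * geom  # photons/cm^2/keV
    fluence = density * bin_width_kev

    # Tungsten K characteristic lines.
    if kvp > W_K_EDGE:
        u0 = kvp / W_K_EDGE
        n_k_total = K_LINE_YIELD * (u0 - 1.0) ** 1.63  # photons/electron
        weight_sum = sum(w for _, w in W_K_LINES)
        # depth-averaged anode self-attenuation at the line energy
        for e_line, w in W_K_LINES:
            if e_line >= kvp:
                continue
            mu_line = float(tungsten.linear_attenuation(e_line))
            atten_line = np.exp(-mu_line * depth * cosec)
            sel = t_grid > e_line
            self_att = float(atten_line[sel].mean()) if sel.any() else 0.0
            n_line = n_k_total * (w / weight_sum) * self_att * geom
            idx = int(np.clip((e_line - centers[0]) / bin_width_kev, 0, len(centers) - 1))
            fluence[idx] += n_line

    # External filtration (Beer-Lambert through each filter slab).
    transmission = np.ones_like(centers)
    for name, thickness_mm in filtration:
        mat = _filter_material(name)
        mu = np.asarray(mat.linear_attenuation(centers))
        transmission *= np.exp(-mu * thickness_mm / 10.0)
    fluence = fluence * transmission

    fluence[centers > kvp] = 0.0
    return EnergySpectrum(centers, fluence, bin_width_kev)


def interpolate_density(
    s: EnergySpectrum, start_kev: float, stop_kev: float, step_kev: float
) -> EnergySpectrum:
    """Linearly interpolate the spectral density onto a fine uniform grid.

    The new per-bin fluence is density * step, so rebinning by block
    averaging afterwards reproduces the coarse flux.
    """
    n = int(round((stop_kev - start_kev) / step_kev)) + 1
    grid = start_kev + step_kev * np.arange(n)
    density = np.interp(grid, s.bin_centers, s.density, left=0.0, right=0.0)
    return EnergySpectrum(grid, density * step_kev, step_kev)


def rebin_average(s: EnergySpectrum, group: int) -> EnergySpectrum:
    """Average blocks of ``group`` neighbouring bins into coarse bins."""
    if group < 1:
        raise SpectrumError("group must be >= 1")
    if len(s) % group != 0:
        raise SpectrumError(
            f"spectrum length {len(s)} not divisible by group {group}"
        )
    fluence = s.fluence.reshape(-1, group).mean(axis=1)
    centers = s.bin_centers.reshape(-1, group).mean(axis=1)
    return EnergySpectrum(centers, fluence, s.bin_width * group)


def normalize_total_counts(s: EnergySpectrum, total: float) -> EnergySpectrum:
    """Scale the spectrum so the summed fluence equals ``total`` photons."""
    if total <= 0:
        raise SpectrumError("total must be positive")
    current = s.fluence.sum()
    if current <= 0:
        raise SpectrumError("cannot normalise an all-zero spectrum")
    return replace(s, fluence=s.fluence * (total / current))


def study_channel_spectrum(
    total_counts: float = 60000.0,
    kvp: float = 150.0,
    fine_start: float = 19.550,
    fine_stop: float = 150.450,
    fine_step: float = 0.1,
    group: int = 10,
) -> EnergySpectrum:
    """The study's channel spectrum: 0.5 keV source -> 0.1 keV grid on
    [19.55, 150.45] -> average groups of 10 -> 131 one-keV channels at
    20..150 keV -> renormalise to ``total_counts`` photons per pixel."""
    raw = build_source_spectrum(kvp=kvp)
    fine = interpolate_density(raw, fine_start, fine_stop, fine_step)
    coarse = rebin_average(fine, group)
    return normalize_total_counts(coarse, total_counts)


def save_spectrum_csv(s: EnergySpectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write("energy_keV,photons_per_bin\n")
        for e, f in zip(s.bin_centers, s.fluence):
            fh.write(f"{e:.6g},{f:.10g}\n")


def load_spectrum_csv(path) -> EnergySpectrum:
    data = np.loadtxt(path, delimiter=",", skiprows=1)
    data = np.atleast_2d(data)
    centers, fluence = data[:, 0], data[:, 1]
    if len(centers) < 2:
        raise SpectrumError("spectrum CSV needs at least two bins")
    width = float(centers[1] - centers[0])
    return EnergySpectrum(centers, fluence, width)
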