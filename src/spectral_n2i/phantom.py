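"""Energy-resolved material phantoms and K-edge utilities.

A phantom is a stack of 2-D linear-attenuation-coefficient (LAC) maps, one
per energy channel: lac(E, r) = (mu/rho)(material(r), E) * rho(r), with the
density spatially modulated by a sinusoid along x to mimic relative density
variations, and exactly zero background.  Two four-material presets are
provided; object geometry (circles) is explicit and recorded in metadata so
results are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np

from .materials import Material, resolve_material

__all__ = [
    "MaterialSpec",
    "CircleShape",
    "SpectralPhantom",
    "PhantomError",
    "build_phantom",
    "preset_phantom",
    "PRESETS",
    "find_k_edge",
    "center_crop",
    "save_phantom_h5",
    "load_phantom_h5",
]


class PhantomError(ValueError):
    """Raised for invalid phantom configurations."""


@dataclass(frozen=True)
class MaterialSpec:
    """A material plus its sinusoidal density modulation.

    density modulation: rho(x) = density * (1 + amplitude * sin(2*pi*x/period)),
    applied along the x (column) axis.
    """

    name: str
    density: float | None = None  # g/cm^3; None = registry nominal value
    modulation_amplitude: float = 0.05
    modulation_period: float = 25.0  # pixels

    def __post_init__(self):
        if not (0.0 <= self.modulation_amplitude < 1.0):
            raise PhantomError("modulation amplitude must be in [0, 1)")
        if self.density is not None and self.density <= 0:
            raise PhantomError("density must be positive")

    def resolved(self) -> tuple[Material, float]:
        mat = resolve_material(self.name)
        rho = self.density if self.density is not None else mat.density
        if not np.isfinite(rho) or rho <= 0:
            raise PhantomError(f"no density known for material {self.name!r}")
        return mat, rho


@dataclass(frozen=True)
class CircleShape:
    cx: float  # column, pixels
    cy: float  # row, pixels
    radius: float  # pixels


@dataclass
class SpectralPhantom:
    """Ground-truth LAC stack: (energy, height, width) in 1/cm."""

    lac: np.ndarray
    energies: np.ndarray  # keV, strictly increasing
    labels: np.ndarray  # 2-D int map, 0 = background
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lac = np.asarray(self.lac, dtype=np.float64)
        self.energies = np.asarray(self.energies, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.lac.ndim != 3:
            raise PhantomError("lac must be (energy, height, width)")
        if len(self.energies) != self.lac.shape[0]:
            raise PhantomError("energies length must match lac channels")
        if np.any(np.diff(self.energies) <= 0):
            raise PhantomError("energies must be strictly increasing")
        if self.labels.shape != self.lac.shape[1:]:
            raise PhantomError("labels shape must match spatial dims")
        if np.any(self.lac < 0):
            raise PhantomError("lac must be non-negative")
        if np.any(self.lac[:, self.labels == 0] != 0):
            raise PhantomError("background (labels==0) must have zero lac")

    @property
    def n_channels(self) -> int:
        return self.lac.shape[0]


# Default presets: four circles at the quadrant centres of the 100x100 grid.
_DEFAULT_SHAPES = [
    CircleShape(25.0, 25.0, 16.0),
    CircleShape(75.0, 25.0, 14.0),
    CircleShape(25.0, 75.0, 15.0),
    CircleShape(75.0, 75.0, 13.0),
]

PRESETS: dict[int, list[str]] = {
    1: ["water", "olive oil", "nitromethane", "acetone"],
    2: ["methanol", "ethylenediamine", "aluminium", "nitrobenzene"],
}


def build_phantom(
    materials: list[MaterialSpec | str],
    shapes: list[CircleShape] | None = None,
    grid: tuple[int, int] = (100, 100),
    energies=None,
) -> SpectralPhantom:
    """Rasterise material discs into an energy-resolved LAC stack.

    Shapes must be non-overlapping and fully inside the grid; one material
    per shape.  A pixel belongs to a disc when its centre is inside.
    """
    if energies is None:
        energies = np.arange(20.0, 151.0)
    energies = np.asarray(energies, dtype=float)
    specs = [m if isinstance(m, MaterialSpec) else MaterialSpec(m) for m in materials]
    if shapes is None:
        shapes = _DEFAULT_SHAPES[: len(specs)]
    if len(shapes) != len(specs):
        raise PhantomError("one material per shape required")

    h, w = grid
    yy, xx = np.mgrid[0:h, 0:w]
    labels = np.zeros((h, w), dtype=np.int32)
    for obj_id, shape in enumerate(shapes, start=1):
        if (
            shape.cx - shape.radius < 0
            or shape.cy - shape.radius < 0
            or shape.cx + shape.radius > w - 1
            or shape.cy + shape.radius > h - 1
        ):
            raise PhantomError(f"shape {obj_id} extends outside the grid")
        inside = (xx - shape.cx) ** 2 + (yy - shape.cy) ** 2 <= shape.radius**2
        if np.any(labels[inside] != 0):
            raise PhantomError(f"shape {obj_id} overlaps an earlier shape")
        labels[inside] = obj_id

    lac = np.zeros((len(energies), h, w), dtype=np.float64)
    for obj_id, spec in enumerate(specs, start=1):
        mat, rho0 = spec.resolved()
        mu_rho = np.asarray(mat.mass_attenuation(energies))  # (E,)
        mask = labels == obj_id
        modulation = 1.0 + spec.modulation_amplitude * np.sin(
            2.0 * np.pi * xx[mask] / spec.modulation_period
        )
        lac[:, mask] = mu_rho[:, None] * (rho0 * modulation)[None, :]

    meta = {
        "materials": [
            {
                "name": s.name,
                "density": s.resolved()[1],
                "modulation_amplitude": s.modulation_amplitude,
                "modulation_period": s.modulation_period,
            }
            for s in specs
        ],
        "shapes": [{"cx": s.cx, "cy": s.cy, "radius": s.radius} for s in shapes],
    }
    return SpectralPhantom(lac, energies, labels, meta)


def preset_phantom(
    preset: int,
    grid: tuple[int, int] = (100, 100),
    energies=None,
    n_materials: int | None = None,
    modulation_amplitude: float = 0.05,
    modulation_period: float = 25.0,
    shapes: list[CircleShape] | None = None,
) -> SpectralPhantom:
    """One of the two four-material presets (optionally truncated)."""
    if preset not in PRESETS:
        raise PhantomError(f"unknown preset {preset}; choose from {list(PRESETS)}")
    names = PRESETS[preset][: n_materials or None]
    if shapes is None and grid != (100, 100):
        # rescale the default quadrant layout to the requested grid
        sy, sx = grid[0] / 100.0, grid[1] / 100.0
        scale = min(sy, sx)
        shapes = [
            CircleShape(s.cx * sx, s.cy * sy, s.radius * scale)
            for s in _DEFAULT_SHAPES[: len(names)]
        ]
    specs = [
        MaterialSpec(n, modulation_amplitude=modulation_amplitude,
                     modulation_period=modulation_period)
        for n in names
    ]
    ph = build_phantom(specs, shapes=shapes, grid=grid, energies=energies)
    ph.metadata["preset"] = preset
    return ph


def find_k_edge(
    energies,
    values,
    window: tuple[float, float] | None = None,
    rel_threshold: float = 0.2,
) -> float | None:
    """Locate an absorption edge as the largest positive jump between
    consecutive samples, if it exceeds ``rel_threshold`` of the local value.

    Returns the midpoint energy of the jumping pair, or None if no jump
    qualifies (smoothly varying attenuation).
    """
    energies = np.asarray(energies, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(energies) <= 0):
        raise PhantomError("energy grid must be strictly increasing")
    if window is not None:
        sel = (energies >= window[0]) & (energies <= window[1])
        energies, values = energies[sel], values[sel]
    if len(energies) < 3:
        raise PhantomError("need at least 3 samples in the window")
    jumps = np.diff(values)
    i = int(np.argmax(jumps))
    if jumps[i] <= rel_threshold * abs(values[i]):
        return None
    return float(0.5 * (energies[i] + energies[i + 1]))


def center_crop(stack, spatial: int | tuple[int, int], channels: int | None = None):
    """Centre-crop the spatial dims and keep the lowest-energy channels.

    Works on SpectralPhantom (lac) and SpectralImageStack (pixels).  The
    channel crop keeps a contiguous block starting at the lowest energy
    (the highest-energy channels carry the least flux and are dropped).
    """
    attr = "lac" if hasattr(stack, "lac") else "pixels"
    data = getattr(stack, attr)
    energies = np.asarray(stack.energies)
    if isinstance(spatial, int):
        spatial = (spatial, spatial)
    n_e = data.shape[0] if channels is None else channels
    th, tw = spatial
    e0, h0, w0 = data.shape
    if th > h0 or tw > w0 or n_e > e0:
        raise PhantomError("crop target exceeds source dimensions")
    r0 = (h0 - th) // 2
    c0 = (w0 - tw) // 2
    cropped = data[:n_e, r0 : r0 + th, c0 : c0 + tw]
    kwargs = {attr: cropped, "energies": energies[:n_e]}
    if hasattr(stack, "labels"):
        kwargs["labels"] = stack.labels[r0 : r0 + th, c0 : c0 + tw]
    return replace(stack, **kwargs)


def save_phantom_h5(ph: SpectralPhantom, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("lac", data=ph.lac, track_times=False)
        f.create_dataset("energies", data=ph.energies, track_times=False)
        f.create_dataset("labels", data=ph.labels, track_times=False)
        f.attrs["metadata"] = json.dumps(ph.metadata)


def load_phantom_h5(path) -> SpectralPhantom:
    with h5py.File(path, "r") as f:
        return SpectralPhantom(
            f["lac"][()],
            f["energies"][()],
            f["labels"][()],
            json.loads(f.attrs.get("metadata", "{}")),
        )
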