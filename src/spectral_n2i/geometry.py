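"""Scan geometry for the 2-D fan-beam (or parallel-beam) acquisition."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanGeometry", "GeometryError", "magnification", "default_geometry"]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class ScanGeometry:
    """Fan-beam geometry: point source, flat linear detector.

    Distances in cm, detector pitch in mm, angles in degrees.  ``beam`` may
    be "fan" or "parallel" (parallel ignores the distances except for the
    field-of-view convention).
    """

    source_to_object: float  # cm
    object_to_detector: float  # cm
    detector_pixels: int
    detector_pitch: float  # mm
    angles: np.ndarray  # degrees, in [0, 360), pairwise distinct
    beam: str = "fan"

    def __post_init__(self):
        if self.source_to_object <= 0 or self.object_to_detector < 0:
            raise GeometryError("distances must be positive")
        if self.detector_pixels < 1 or self.detector_pitch <= 0:
            raise GeometryError("invalid detector configuration")
        angles = np.asarray(self.angles, dtype=float)
        if np.any(angles < 0) or np.any(angles >= 360):
            raise GeometryError("angles must lie in [0, 360)")
        if len(np.unique(angles)) != len(angles):
            raise GeometryError("angles must be pairwise distinct")
        if self.beam not in ("fan", "parallel"):
            raise GeometryError(f"unknown beam type {self.beam!r}")
        object.__setattr__(self, "angles", angles)

    @property
    def source_to_detector(self) -> float:
        return self.source_to_object + self.object_to_detector

    @property
    def detector_width_cm(self) -> float:
        return self.detector_pixels * self.detector_pitch / 10.0

    @property
    def fov_cm(self) -> float:
        """Diameter of the field of view at the isocentre."""
        if self.beam == "parallel":
            return self.detector_width_cm
        half_fan = np.arctan(
            0.5 * self.detector_width_cm / self.source_to_detector
        )
        return 2.0 * self.source_to_object * np.sin(half_fan)

    def with_angles(self, angles) -> "ScanGeometry":
        return ScanGeometry(
            self.source_to_object,
            self.object_to_detector,
            self.detector_pixels,
            self.detector_pitch,
            np.asarray(angles, dtype=float),
            self.beam,
        )


def magnification(g: ScanGeometry) -> float:
    """Geometric magnification (source-detector over source-object)."""
    return (g.source_to_object + g.object_to_detector) / g.source_to_object


def default_geometry(
    n_angles: int = 360,
    detector_pixels: int = 256,
    beam: str = "fan",
) -> ScanGeometry:
    """The synthetic-study geometry: 57.50 cm source-object, 58.05 cm
    object-detector, 0.8 mm detector pitch, 1-degree steps over 360."""
    angles = np.arange(n_angles) * (360.0 / n_angles)
    return ScanGeometry(57.50, 58.05, detector_pixels, 0.8, angles, beam)
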