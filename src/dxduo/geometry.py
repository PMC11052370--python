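"""Debye-Scherrer ring geometry for dual-probe diffraction analysis.

Predicts where the Au and ZnO powder rings fall on a flat photon-counting
detector, builds annular pixel ROIs (with rectangular masking), and routes an
observed radius to a unique ring so the two probes are analysed independently.

Conventions
-----------
* Pixel coordinates are 0-based ``(row, col)``; a pixel's center sits at
  integer coordinates and radii are measured to pixel centers.
* The flat-detector projection uses ``r = L * tan(2*theta_B)`` with no
  polarization or solid-angle correction.
* Energies in keV, lattice constants and d-spacings in angstrom, distances
  in mm, radii in pixels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HC_KEV_A",
    "CrystalPhase",
    "BeamSpec",
    "DetectorGeometry",
    "RingROI",
    "InvalidInputError",
    "ConfigError",
    "NoReflectionError",
    "EmptyROIError",
    "AmbiguousAssignmentError",
    "wavelength_from_energy",
    "d_spacing",
    "ring_radius",
    "radius_band",
    "build_ring_roi",
    "assign_ring",
    "detector_template",
]

#: hc in keV * angstrom, so that lambda[A] = HC_KEV_A / E[keV].
HC_KEV_A = 12.3984


class InvalidInputError(ValueError):
    """An argument violates a precondition (non-positive energy, (000) hkl, ...)."""


class ConfigError(ValueError):
    """A configuration object is internally inconsistent."""


class NoReflectionError(ValueError):
    """Bragg condition unreachable: lambda >= 2d."""


class EmptyROIError(ValueError):
    """Ring ROI contains no pixels after masking / detector clipping."""


class AmbiguousAssignmentError(ValueError):
    """An observed radius matches two or more candidate rings."""


@dataclass(frozen=True)
class CrystalPhase:
    """A probe crystal lattice (cubic Au or hexagonal ZnO)."""

    name: str
    system: str  # "cubic" | "hexagonal"
    a: float
    c: float | None = None

    def __post_init__(self) -> None:
        if self.system not in ("cubic", "hexagonal"):
            raise ConfigError(f"unknown crystal system {self.system!r}")
        if self.a <= 0:
            raise ConfigError("lattice constant a must be > 0")
        if self.system == "hexagonal":
            if self.c is None or self.c <= 0:
                raise ConfigError("hexagonal phase requires lattice constant c > 0")
        elif self.c is not None:
            raise ConfigError("cubic phase must not set c")


@dataclass(frozen=True)
class BeamSpec:
    """Incident beam: monochromatic (DXB) or pink/broad-band (DXT)."""

    energy_keV: float
    bandwidth: float = 0.0  # fractional dE/E
    mode: str = "mono"  # "mono" | "pink"

    def __post_init__(self) -> None:
        if self.energy_keV <= 0:
            raise ConfigError("energy_keV must be > 0")
        if self.bandwidth < 0:
            raise ConfigError("bandwidth must be >= 0")
        if self.mode not in ("mono", "pink"):
            raise ConfigError(f"unknown beam mode {self.mode!r}")
        if self.mode == "pink" and self.bandwidth <= 0:
            raise ConfigError("pink beam requires bandwidth > 0")


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat pixel detector plus recording cadence.

    ``mask_rects`` are half-open rectangles ``(row0, row1, col0, col1)`` in
    pixel indices, excluded from every ROI (the intermodule gap regions of a
    tiled detector are the typical use).
    """

    pixel_pitch_mm: float
    n_rows: int
    n_cols: int
    beam_center_px: tuple[float, float]  # (row, col), fractional
    distance_mm: float
    frame_interval_s: float
    mask_rects: tuple[tuple[int, int, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.pixel_pitch_mm <= 0:
            raise ConfigError("pixel_pitch_mm must be > 0")
        if self.distance_mm <= 0:
            raise ConfigError("distance_mm must be > 0")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be > 0")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ConfigError("detector must have positive pixel counts")
        for rect in self.mask_rects:
            r0, r1, c0, c1 = rect
            if not (0 <= r0 < r1 <= self.n_rows and 0 <= c0 < c1 <= self.n_cols):
                raise ConfigError(f"mask rectangle {rect} outside detector bounds")

    def mask_array(self) -> np.ndarray:
        """Boolean (n_rows, n_cols) array, True where pixels are masked out."""
        m = np.zeros((self.n_rows, self.n_cols), dtype=bool)
        for r0, r1, c0, c1 in self.mask_rects:
            m[r0:r1, c0:c1] = True
        return m


def detector_template(
    name: str = "PILATUS-100K",
    *,
    distance_mm: float,
    frame_interval_s: float,
    beam_center_px: tuple[float, float] | None = None,
    mask_rects: Sequence[tuple[int, int, int, int]] = (),
) -> DetectorGeometry:
    """Instantiate a named detector template at a given working distance.

    Only "PILATUS-100K" is built in: 195 x 487 pixels, 172 um pitch,
    intermodule gap not modelled (supply ``mask_rects`` to reproduce one).
    """
    if name != "PILATUS-100K":
        raise ConfigError(f"unknown detector template {name!r}")
    center = beam_center_px if beam_center_px is not None else (97.0, 243.0)
    return DetectorGeometry(
        pixel_pitch_mm=0.172,
        n_rows=195,
        n_cols=487,
        beam_center_px=center,
        distance_mm=distance_mm,
        frame_interval_s=frame_interval_s,
        mask_rects=tuple(tuple(r) for r in mask_rects),
    )


@dataclass(frozen=True)
class RingROI:
    """Annular pixel ROI for one indexed powder ring.

    ``radius_band_px`` is ``(radius, radius)`` for a monochromatic beam; for a
    pink beam it spans the radii of the band edges ``E*(1 +/- bw/2)``, which
    is the acceptance window used when validating Laue-spot radii.
    """

    phase: str
    hkl: tuple[int, int, int]
    d_spacing_A: float
    radius_px: float
    half_width_px: float
    pixels: np.ndarray  # (N, 2) int array of (row, col)
    radius_band_px: tuple[float, float]

    @property
    def label(self) -> str:
        h, k, l = self.hkl
        return f"{self.phase}({h}{k}{l})"

    def to_json(self) -> str:
        """Serialize for audit (label, d, radius, pixel list)."""
        return json.dumps(
            {
                "label": self.label,
                "phase": self.phase,
                "hkl": list(self.hkl),
                "d_spacing_A": self.d_spacing_A,
                "radius_px": self.radius_px,
                "half_width_px": self.half_width_px,
                "radius_band_px": list(self.radius_band_px),
                "pixels": self.pixels.tolist(),
            }
        )


def wavelength_from_energy(energy_keV: float) -> float:
    """Photon wavelength in angstrom: lambda = 12.3984 / E[keV]."""
    if energy_keV <= 0:
        raise InvalidInputError("energy_keV must be > 0")
    return HC_KEV_A / energy_keV


def d_spacing(phase: CrystalPhase, hkl: tuple[int, int, int]) -> float:
    """Interplanar spacing of reflection ``hkl`` in angstrom.

    cubic:      d = a / sqrt(h^2 + k^2 + l^2)
    hexagonal:  1/d^2 = (4/3) (h^2 + h k + k^2) / a^2 + l^2 / c^2
    """
    h, k, l = hkl
    if (h, k, l) == (0, 0, 0):
        raise InvalidInputError("hkl (0,0,0) has no reflection")
    if phase.system == "cubic":
        return phase.a / math.sqrt(h * h + k * k + l * l)
    if phase.c is None:  # defensive; CrystalPhase already validates
        raise ConfigError("hexagonal phase without c")
    inv_d2 = (4.0 / 3.0) * (h * h + h * k + k * k) / phase.a**2 + l * l / phase.c**2
    return 1.0 / math.sqrt(inv_d2)


def ring_radius(d: float, beam: BeamSpec, geom: DetectorGeometry) -> float:
    """Ring radius in pixels at the beam's nominal energy.

    theta_B = arcsin(lambda / 2d); r = L tan(2 theta_B) / pitch.
    """
    return _radius_at_energy(d, beam.energy_keV, geom)


def _radius_at_energy(d: float, energy_keV: float, geom: DetectorGeometry) -> float:
    lam = wavelength_from_energy(energy_keV)
    s = lam / (2.0 * d)
    if s >= 1.0:
        raise NoReflectionError(
            f"Bragg condition unreachable: lambda/2d = {s:.3f} >= 1"
        )
    theta = math.asin(s)
    return geom.distance_mm * math.tan(2.0 * theta) / geom.pixel_pitch_mm


def radius_band(d: float, beam: BeamSpec, geom: DetectorGeometry) -> tuple[float, float]:
    """Radius interval spanned by the beam bandwidth (degenerate for mono).

    For a pink beam the low-energy edge ``E(1 - bw/2)`` has the longer
    wavelength and hence the larger scattering angle / radius.
    """
    if beam.mode == "mono" or beam.bandwidth == 0:
        r = ring_radius(d, beam, geom)
        return (r, r)
    e_lo = beam.energy_keV * (1.0 - beam.bandwidth / 2.0)
    e_hi = beam.energy_keV * (1.0 + beam.bandwidth / 2.0)
    r_hi = _radius_at_energy(d, e_lo, geom)
    r_lo = _radius_at_energy(d, e_hi, geom)
    return (min(r_lo, r_hi), max(r_lo, r_hi))


def build_ring_roi(
    phase: CrystalPhase,
    hkl: tuple[int, int, int],
    beam: BeamSpec,
    geom: DetectorGeometry,
    half_width_px: float = 2.0,
) -> RingROI:
    """Annulus of detector pixels within ``half_width_px`` of the predicted ring.

    Pixels inside mask rectangles or off the detector are removed. For a pink
    beam the annulus spans the full bandwidth radius band widened by
    ``half_width_px`` on each side.
    """
    if half_width_px <= 0:
        raise InvalidInputError("half_width_px must be > 0")
    d = d_spacing(phase, hkl)
    r_nom = ring_radius(d, beam, geom)
    band = radius_band(d, beam, geom)

    rows = np.arange(geom.n_rows)[:, None]
    cols = np.arange(geom.n_cols)[None, :]
    cr, cc = geom.beam_center_px
    dist = np.hypot(rows - cr, cols - cc)
    inside = (dist >= band[0] - half_width_px) & (dist <= band[1] + half_width_px)
    inside &= ~geom.mask_array()
    pixels = np.argwhere(inside)
    if pixels.size == 0:
        raise EmptyROIError(
            f"ring {phase.name}{hkl} at r={r_nom:.1f} px has no unmasked pixels"
        )
    return RingROI(
        phase=phase.name,
        hkl=tuple(int(i) for i in hkl),
        d_spacing_A=d,
        radius_px=r_nom,
        half_width_px=float(half_width_px),
        pixels=pixels,
        radius_band_px=band,
    )


def assign_ring(
    observed_radius_px: float,
    candidate_rois: Sequence[RingROI],
    tolerance_px: float,
) -> RingROI | None:
    """Route an observed radius to the unique matching ring.

    A candidate matches when the observed radius lies within ``tolerance_px``
    of its radius band (a point band for mono beams). Returns ``None`` when
    nothing matches ("unassigned"); raises when two or more match — an
    ambiguous radius must never be silently attributed to one probe.
    """
    if not candidate_rois:
        raise InvalidInputError("candidate ROI list is empty")
    if tolerance_px <= 0:
        raise InvalidInputError("tolerance_px must be > 0")
    matches = [
        roi
        for roi in candidate_rois
        if roi.radius_band_px[0] - tolerance_px
        <= observed_radius_px
        <= roi.radius_band_px[1] + tolerance_px
    ]
    if len(matches) > 1:
        labels = [m.label for m in matches]
        raise AmbiguousAssignmentError(
            f"radius {observed_radius_px:.2f} px matches {labels}"
        )
    return matches[0] if matches else None
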