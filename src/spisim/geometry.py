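"""Detector and beam geometry for single-particle diffraction.

Maps detector pixels onto the Ewald sphere and provides the small amount of
beam arithmetic (fluence, edge resolution) the simulation needs.

Conventions
-----------
* Scattering vector ``q = 2 sin(theta) / lambda`` (no 2*pi), where ``theta``
  is *half* the diffraction angle.  With this convention ``1/q`` is the
  full-period resolution and the structure-factor phase is ``exp(2*pi*i q.r)``.
* The beam travels along +z; the detector plane is normal to the beam at
  ``distance`` downstream.  Pixel centres sit at integer coordinates, 0-based;
  for an odd array the beam centre defaults to the exact central pixel.
* Units: lengths in the unit stated per field (um, mm, nm, A), energies in
  keV, q in 1/A.  ``hc = 12.3984 keV*A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Planck constant times speed of light, keV * Angstrom.
HC_KEV_A = 12.3984

#: One keV in joule.
KEV_TO_J = 1.602176634e-16


class GeometryError(ValueError):
    """Invalid detector or beam geometry."""


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat square-pixel detector centred on the beam axis.

    Defaults reproduce the central region of a megapixel detector used for
    single-particle imaging at a hard-X-ray FEL: an 81 x 81 array of
    1200 um pixels, 13 cm downstream, at 4.96 keV photon energy.
    """

    n_fast: int = 81
    n_slow: int = 81
    pixel_size_um: float = 1200.0
    distance_mm: float = 130.0
    photon_energy_kev: float = 4.96
    #: Fractional pixel coordinates (slow, fast) of the beam axis.  ``None``
    #: puts it at the exact central pixel (requires odd pixel counts there).
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_fast < 1 or self.n_slow < 1:
            raise GeometryError("pixel counts must be positive")
        if self.pixel_size_um <= 0:
            raise GeometryError("pixel size must be positive")
        if self.distance_mm <= 0:
            raise GeometryError("detector distance must be positive")
        if self.photon_energy_kev <= 0:
            raise GeometryError("photon energy must be positive")

    @property
    def wavelength_A(self) -> float:
        """X-ray wavelength, Angstrom."""
        return HC_KEV_A / self.photon_energy_kev

    @property
    def beam_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        return ((self.n_slow - 1) / 2.0, (self.n_fast - 1) / 2.0)


@dataclass
class PixelMap:
    """Per-pixel scattering vectors on the Ewald sphere.

    ``q`` has shape (n_slow, n_fast, 3); ``qmag`` and ``weight`` have shape
    (n_slow, n_fast).  The integration weight is 1 everywhere (solid-angle and
    polarization corrections are deliberately omitted; the field exists so
    they can be added).
    """

    geom: DetectorGeometry
    q: np.ndarray
    qmag: np.ndarray
    weight: np.ndarray

    @property
    def n_pixels(self) -> int:
        return self.qmag.size

    @property
    def q_flat(self) -> np.ndarray:
        """(n_pixels, 3) view of the q vectors."""
        return self.q.reshape(-1, 3)

    @property
    def q_edge(self) -> float:
        """|q| at the midpoint of a detector edge (the 'edge q')."""
        cy, cx = self.geom.beam_center
        row = int(round(cy))
        return float(self.qmag[row, -1])

    @property
    def q_corner(self) -> float:
        """Largest |q| on the detector."""
        return float(self.qmag.max())

    def to_hdf5(self, group) -> None:
        group.create_dataset("qx", data=self.q[..., 0])
        group.create_dataset("qy", data=self.q[..., 1])
        group.create_dataset("qz", data=self.q[..., 2])
        group.create_dataset("qmag", data=self.qmag)
        group.create_dataset("weight", data=self.weight)


@dataclass(frozen=True)
class BeamParameters:
    """Pulse parameters used for the photon-budget arithmetic."""

    photons_per_pulse: float
    photon_energy_kev: float
    focus_fwhm_nm: tuple[float, float]
    pulse_fdhm_fs: float = 9.0

    def __post_init__(self) -> None:
        if self.photons_per_pulse < 0:
            raise GeometryError("photon count must be non-negative")
        if self.photon_energy_kev <= 0:
            raise GeometryError("photon energy must be positive")
        if min(self.focus_fwhm_nm) <= 0:
            raise GeometryError("focus FWHM must be positive")
        if self.pulse_fdhm_fs <= 0:
            raise GeometryError("pulse duration must be positive")


def build_pixel_map(geom: DetectorGeometry) -> PixelMap:
    """Map every pixel to its scattering vector on the Ewald sphere.

    Each pixel sees the scattered wave-vector ``k_s = s_hat / lambda`` with
    ``s_hat`` the unit vector from sample to pixel; the incident wave-vector
    is ``k_i = z_hat / lambda``.  Then ``q = k_s - k_i`` and
    ``|q| = 2 sin(theta) / lambda``.
    """
    lam = geom.wavelength_A
    p_mm = geom.pixel_size_um * 1e-3
    cy, cx = geom.beam_center
    ys = (np.arange(geom.n_slow) - cy) * p_mm
    xs = (np.arange(geom.n_fast) - cx) * p_mm
    yy, xx = np.meshgrid(ys, xs, indexing="ij")
    zz = np.full_like(xx, geom.distance_mm)
    norm = np.sqrt(xx**2 + yy**2 + zz**2)
    q = np.empty(xx.shape + (3,))
    q[..., 0] = xx / norm / lam
    q[..., 1] = yy / norm / lam
    q[..., 2] = (zz / norm - 1.0) / lam
    qmag = np.sqrt((q**2).sum(axis=-1))
    return PixelMap(geom=geom, q=q, qmag=qmag, weight=np.ones_like(qmag))


def resolution_at_edge(geom: DetectorGeometry) -> float:
    """Full-period resolution 1/|q| at the detector edge midpoint, Angstrom."""
    q_edge = build_pixel_map(geom).q_edge
    if q_edge <= 0:
        raise GeometryError("detector has no extent; edge q is zero")
    return 1.0 / q_edge


def fluence(beam: BeamParameters) -> float:
    """Pulse fluence in J/cm^2 over the rectangular-FWHM focal area."""
    energy_j = beam.photons_per_pulse * beam.photon_energy_kev * KEV_TO_J
    fx, fy = beam.focus_fwhm_nm
    area_cm2 = (fx * 1e-7) * (fy * 1e-7)
    return energy_j / area_cm2


def geometry_from_config(cfg: dict) -> DetectorGeometry:
    """Build a DetectorGeometry from the YAML geometry block."""
    return DetectorGeometry(
        n_fast=int(cfg.get("n_fast", 81)),
        n_slow=int(cfg.get("n_slow", 81)),
        pixel_size_um=float(cfg.get("pixel_size_um", 1200.0)),
        distance_mm=float(cfg.get("distance_mm", 130.0)),
        photon_energy_kev=float(cfg.get("photon_energy_keV", cfg.get("photon_energy_kev", 4.96))),
    )
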