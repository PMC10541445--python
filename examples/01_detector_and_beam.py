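"""Detector geometry and beam arithmetic.

Builds the 81 x 81 single-particle-imaging detector (1200 um pixels, 13 cm
from the sample, 4.96 keV) and prints the scattering-vector range and the
pulse fluence of the simulated beamline.
"""

from spisim import BeamParameters, DetectorGeometry, build_pixel_map, fluence, resolution_at_edge

geom = DetectorGeometry()  # 81 x 81, 1200 um, 130 mm, 4.96 keV
pixmap = build_pixel_map(geom)

print(f"wavelength            : {geom.wavelength_A:.4f} A")
print(f"|q| at edge midpoint  : {pixmap.q_edge:.4f} 1/A")
print(f"|q| at detector corner: {pixmap.q_corner:.4f} 1/A")
print(f"full-period resolution: {resolution_at_edge(geom):.2f} A")
# The edge q of ~0.14 1/A means the detector records speckles down to a
# full-period resolution of ~7 A.

beam = BeamParameters(
    photons_per_pulse=7.5e12,
    photon_energy_kev=4.96,
    focus_fwhm_nm=(250.0, 160.0),
    pulse_fdhm_fs=9.0,
)
print(f"fluence               : {fluence(beam):.3g} J/cm^2")
# ~1.5e7 J/cm^2: enough to trigger significant ionization within the 9 fs
# pulse, which is why the damage stand-in exists.
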