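"""Simulate photon-sparse diffraction patterns of a hydrated particle.

A 40-atom toy particle gets a 6 A water shell; the ideal reciprocal-space
intensity is computed on a cubic grid and sliced on the Ewald sphere at
uniform random orientations with Poisson noise at ~500 photons/pattern.
"""

import numpy as np

from spisim import (
    DetectorGeometry,
    WaterShellSpec,
    add_water_shell,
    build_pixel_map,
    default_volume_grid,
    generate_dataset,
    ideal_intensity_volume,
    make_toy_particle,
)

geom = DetectorGeometry(n_fast=31, n_slow=31, pixel_size_um=1200.0,
                        distance_mm=45.0, photon_energy_kev=4.96)
pixmap = build_pixel_map(geom)

dry = make_toy_particle(40, extent_A=30.0, seed=7)
wet = add_water_shell(dry, WaterShellSpec(thickness_A=6.0, seed=5))
print(f"particle atoms: {dry.n_atoms}, water sites added: {wet.n_atoms - dry.n_atoms}")

edge, dq = default_volume_grid(pixmap)
volume = ideal_intensity_volume(wet, edge, dq)
print(f"intensity volume: {edge}^3 voxels, dq = {dq:.4f} 1/A")

patterns = generate_dataset(volume, 200, pixmap, mean_photons=500.0, seed=1,
                            background_fraction=0.05)
counts = patterns.photon_counts
print(f"patterns: {patterns.n_patterns}, photons/pattern: "
      f"{counts.mean():.1f} +/- {counts.std():.1f}")
occ = np.diff(patterns.offsets).mean()
print(f"occupied pixels per pattern: {occ:.0f} of {patterns.n_pixels}")
# At ~500 photons on ~1000 pixels most pixels are empty -- single patterns
# carry far too little information to orient on their own, which is what
# makes the EMC clustering necessary.
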