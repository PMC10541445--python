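"""Reconstruct a 3D intensity volume from unoriented patterns with EMC.

Generates 1500 patterns of a toy particle at ~500 photons each, runs the
expand-maximize-compress iteration with the beta / num_div annealing
schedule, aligns the result to the ground truth and reports the agreement.
Takes a couple of minutes on one CPU.
"""

import numpy as np

from spisim import (
    DetectorGeometry,
    EMCConfig,
    align_to_reference,
    build_pixel_map,
    default_volume_grid,
    generate_dataset,
    ideal_intensity_volume,
    make_toy_particle,
    run_emc,
    sample_rotations,
)

geom = DetectorGeometry(n_fast=31, n_slow=31, pixel_size_um=1200.0,
                        distance_mm=45.0, photon_energy_kev=4.96)
pixmap = build_pixel_map(geom)
particle = make_toy_particle(40, extent_A=30.0, seed=7)
edge, dq = default_volume_grid(pixmap)
ground_truth = ideal_intensity_volume(particle, edge, dq)
patterns = generate_dataset(ground_truth, 1500, pixmap, 500.0, seed=3)

config = EMCConfig(
    beta_start=0.1, beta_factor=2.0, beta_period=4,
    num_div_start=2, num_div_cap=4,
    main_iterations=20, final_iterations=8, init_seed=0,
)
state = run_emc(patterns, config, pixmap, verbose=True)

aligned, rotation, corr = align_to_reference(
    state.volume, ground_truth, sample_rotations(3)
)
qmag = ground_truth.qmag_grid()
mask = qmag <= 0.8 * pixmap.q_edge
a = np.sqrt(np.maximum(aligned.values[mask], 0.0))
b = np.sqrt(np.maximum(ground_truth.values[mask], 0.0))
a -= a.mean(); b -= b.mean()
masked = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
print(f"\nalignment correlation (sqrt intensity, full ball): {corr:.3f}")
print(f"correlation within 0.8 q_edge                    : {masked:.3f}")
# Values above ~0.9 inside 0.8 q_edge mean the orientation recovery placed
# the speckles correctly out to most of the detector's resolution range.
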