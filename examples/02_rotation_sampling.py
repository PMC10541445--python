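"""Weighted SO(3) sampling from the subdivided 600-cell.

The rotation grid that EMC sorts patterns into: refinement level num_div
controls the number of samples, 10 (5 n^3 + n).
"""

import numpy as np

from spisim import rotation_count, sample_rotations

for level in (1, 2, 5, 16):
    n_formula = rotation_count(level)
    if level <= 5:
        rs = sample_rotations(level)
        spacing = 0.63 / level
        print(
            f"num_div={level:2d}: {len(rs):6d} samples "
            f"(formula {n_formula}), weight sum {rs.weights.sum():.6f}, "
            f"~{np.degrees(spacing):.1f} deg spacing"
        )
    else:
        print(f"num_div={level:2d}: {n_formula} samples (formula only here; "
              "construction takes a few seconds)")
# At num_div 16 the grid has 204960 rotations -- the refinement used for the
# final iterations of a full-scale reconstruction.
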