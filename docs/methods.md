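# Methods

This note documents the models implemented in `spisim`, the assumptions
behind them, the parameters that matter, and the numerical choices made
where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scattering model and conventions

The scattering vector is `q = 2 sin θ / λ` (no 2π), with θ half the
diffraction angle, so `1/q` is the full-period resolution; the structure
factor carries the phase `exp(2πi q·r)`. Wavelength is `hc/E` with
`hc = 12.3984 keV·Å`. Pixel centres sit at integer 0-based coordinates;
for the odd 81×81 array the beam centre is pixel (40, 40) and the "edge q"
is evaluated 40 pixel pitches from the centre — the convention that makes
the default geometry's edge q round to 0.14 Å⁻¹ and its edge resolution to
7 Å. Solid-angle and polarization corrections are omitted (flat pixel
weight 1): the maximum scattering angle in the default geometry is ~20°,
where both corrections are at the few-percent level; the `weight` field of
the pixel map exists so they can be added.

The ideal intensity is `I(q) = |Σ_j s_j f_j(|q|) exp(2πi q·r_j)|²` with
tabulated Cromer–Mann form factors (crystallographic `s = q/2` argument)
for H, C, N, O, P, S, Fe, and an effective one-site water scatterer
`f_O + 2 f_H`. The per-atom scale `s_j` is the handle the damage stand-in
uses for ionization. Fluence uses the rectangular-FWHM convention
(photons × photon energy / FWHM_x·FWHM_y), which reproduces the standard
SPI beamline arithmetic.

## Synthetic data

The generator emulates the study conditions of an SPI solvent/damage
experiment; its defaults are those conditions, not tuning knobs.

* **Particle.** A reproducible random C/N/O cluster in a sphere
  (`make_toy_particle`), optionally exactly C2-symmetrized; real structures
  enter through `read_pdb` (gemmi parser, unsupported elements substituted
  by nearest atomic number with a warning, or skipped).
* **Water layer.** One effective scatterer per water molecule, dart-thrown
  uniformly in the region whose distance to the nearest solute heavy atom
  lies in [contact, contact + T_w], at bulk number density 0.0334 Å⁻³ with
  a 2.8 Å contact distance and 2.8 Å minimum separation. This is a
  deliberate simplification: no hydrogen-bond geometry, no
  structure-correlated first shell, one configuration per seed rather than
  an ensemble. T_w ∈ {0, 2, 4, 6, 10, 20} Å is the scanned range. For a
  compact particle of ~20 Å radius the shell volume overtakes the particle
  volume near T_w ≈ 5 Å — the regime change where the solvent shape starts
  to dominate the diffraction volume.
* **Pulse.** Photon budget ~500 photons per pattern, FDHM 9 fs binned at
  2.6 fs. Spiky profiles are a Gaussian envelope with bounded
  multiplicative jitter (uniform 1 ± 0.6 per bin); the bound keeps the
  half-maximum crossings — and hence the measured FDHM — well defined
  within about one bin, at the cost of milder spike statistics than true
  SASE (whose exponential spikes make FDHM an ill-posed observable at this
  bin width). The envelope width is calibrated against the measured FDHM
  of the spiky profile by a deterministic grid search.
* **Damage stand-in.** Two scalars, not physics: per pulse bin the
  structure is expanded radially about its centroid by
  `1 + expansion_rate · D(t)` and every effective electron count scaled by
  `max(0, 1 − ionization_rate · D(t))`, with `D(t)` the cumulative pulse
  fraction delivered before the bin (so the first snapshot is undamaged).
  Because both factors are uniform across atoms, the intensity of bin b is
  exactly `ι_b² I₀(c_b q)` — the time-integrated pattern can be evaluated
  from the single undamaged volume by q-rescaling (`DamagedVolumeModel`),
  which is what makes damaged datasets cheap. The stand-in reproduces the
  qualitative signatures of real damage (speckle contraction toward the
  centre, late-pulse blurring, small late-bin intensity share) but none of
  the plasma physics; defaults (expansion 0.25, ionization 0.3 over the
  pulse) were chosen once to produce visible but not catastrophic blurring
  at the desk scale.
* **Orientations and noise.** Orientations are uniform on SO(3) (normalized
  Gaussian quaternions); the orientation stream depends only on the seed,
  so different conditions simulated with the same seed share identical
  orientation lists. Inelastic scattering is modelled as a flat isotropic
  background carrying a configurable fraction (default 5% in the pipeline)
  of the photon budget; the expectation (signal + background) is rescaled
  to the photon budget and sampled Poisson per pixel. Patterns are stored
  sparsely (pixel index, count).

What passing desk-scale tests does *not* show about real data: detector
artefacts, per-shot fluence jitter, conformational heterogeneity,
structured (non-flat) inelastic background, and real damage dynamics are
all outside the generator.

## Rotation sampling

SO(3) is discretized by subdividing each tetrahedral cell of the 600-cell
with the barycentric lattice at level n (corner/octahedral/reversed
sub-tetrahedra; the octahedra are fanned around one diagonal), projecting
lattice points to the unit 3-sphere, and identifying antipodal
quaternions. The count is exactly `10(5n³+n)` — 204960 at n = 16. Each
sample's quadrature weight is the summed projected volume of its incident
sub-simplices (each sub-tet contributes a quarter of its spherical volume,
estimated from the parallelotope of its edge vectors and the radial
direction, to each vertex), normalized to sum 1. Antipodal identification
canonicalizes to the hemisphere with first nonzero quaternion component
positive; duplicate boundary points are merged by quantizing coordinates
at 1e-7 (points at any level are ≥ ~2° apart, so the merge is
unambiguous). Only the count is externally anchored; the weight scheme is
this package's choice and is validated by near-uniform nearest-neighbour
statistics (coefficient of variation < 0.3) and by posterior calculations
that treat the weights as quadrature weights.

## EMC

The reconstruction follows the expand–maximize–compress cycle: trilinear
interpolation of the current volume W onto the rotated Ewald map of every
grid rotation (expand), tempered responsibilities and tomogram update
(maximize), and the trilinear scatter-adjoint back into the voxel grid
with responsibility-weighted deposits (compress). The volume grid uses
dq = the central pixel q-pitch and an edge that encloses the detector
corner q.

The likelihood is evaluated in multinomial form — tomograms normalized to
probability maps — which absorbs the per-pattern incident-fluence nuisance
into a single global scale; the M-step (responsibility-weighted mean
pattern) then makes the model track the data's mean photon count by
construction. Responsibilities are `P_dr ∝ w_r exp(β L_dr)` with the
sampling weights `w_r` as prior. Numerical floors: tomogram values are
floored at 1e-300 inside logs; responsibilities below 1e-12 are skipped in
the update; rotations receiving no responsibility keep their expanded
tomogram. After each compress the volume is Friedel-symmetrized
(W(q) = W(−q)), which real elastic scattering guarantees.

Annealing: β starts at 0.01 and multiplies by 1.5, and num_div starts at 5
and increments by 1, every 10 iterations for 120 iterations, then 10 final
iterations at β = 1 and num_div = 16. Literal arithmetic would reach
num_div 17 at iteration 120 while the final refinement is stated as 16;
the level is therefore capped at `num_div_cap` (default 16) — the cap is
also the handle that makes desk-scale runs (cap 3–4) possible. β is capped
at 1. Convergence is schedule-terminated; there is no early stopping.
Responsibilities are recomputed fresh each iteration and are not carried
across num_div changes. Initialization is i.i.d. uniform(0.5, 1.5) voxel
noise scaled to the data, restricted to the sampled q-ball, seeded from
the config.

## Shell R-factor and alignment

R(s) compares √intensities shell by shell after per-shell normalization,
so it is scale-invariant per shell and bounded by [0, 2]. Default shell
width is one grid q-pitch; the named regions split at 0.08 and 0.10 Å⁻¹.
Region means weight shells by voxel count (the binning and weighting are
this package's choice). Empty or zero-intensity shells are skipped with a
warning.

Reconstructions are aligned to the reference by exhaustive search over a
rotation grid (candidates optionally expanded by the symmetry groups),
maximizing the Pearson correlation of √intensities inside the supported
q-ball — the square root compresses the dynamic range so the centre does
not dominate — followed by Nelder–Mead refinement whose initial simplex
spans half a grid step (a smaller simplex cannot cross the sampling
discretization). The aligning rotation returned is the one to *apply to
the volume* to match the reference, i.e. the inverse of the rotation that
produced the misalignment.

## Orientation disconcurrence

Posteriors over the rotation grid use the Poisson likelihood with the
sampling weights as quadrature weights, log-sum-exp stabilized. Because
the Poisson scale is otherwise unidentified, each volume is first rescaled
so its orientation-averaged expected photon count matches the sentinel
mean — with that normalization the whole pipeline is exactly invariant
under W → cW.

Θ² for one sentinel is the double sum of squared quotient angles
`θ_{z,s}` over the truncated posterior supports of the two volumes, the
overall orientations entering as right-compositions of the support
quaternions (by the change of variables Ω_a = Ω_α Ω_A, the integral over
the shifted measure becomes a sum over the grid posteriors with the
distance evaluated between `Ω_a Ω_A⁻¹` and `Ω_b Ω_B⁻¹`). By bi-invariance
of the geodesic metric one overall orientation is redundant: Ω_B is fixed
to the identity and the minimization runs over Ω_A only — a coarse grid
search (level-2 sampling, supports capped at the 32 most probable
rotations) followed by Nelder–Mead refinement with full (capped at 256)
supports. Supports hold ≥ 1 − ε posterior mass (ε = 1e-6); the truncation
error is bounded in absolute terms by ~π²ε, which matters only when Θ²
itself is comparably small. The Friedel group z = {identity, π about the
beam} reflects the flat-Ewald ambiguity and is therefore only approximate
at large scattering angles; s is the particle's point group (C1 for the
asymmetric toy particle, C2 where a dyad exists — for PDB inputs the axis
must be supplied, since nothing in a coordinate file marks it).

Two OD facts worth knowing when reading numbers: self-OD of a single
volume is minimized at Ω_A = identity by construction (both posteriors
shift together), and the two-volume OD of an exactly rotated copy against
the original carries an irreducible floor of about one rotation-grid step,
because the two posterior supports quantize to different grid points.
Desk-scale self-OD floors are therefore a few hundredths of a radian at
posterior level 4, an order of magnitude above the full-scale (num_div 16)
floor.

## Problem sizes

The desk preset — 31×31 detector at 45 mm (edge q 0.151 Å⁻¹), a 40-atom
~30 Å particle, 41³ volume, ≤ 1500 patterns, num_div cap 4, 20 + 8 EMC
iterations, posterior level 4 — was sized so that every experiment in the
test suite runs on a single CPU: an EMC reconstruction takes on the order
of a minute, the water-layer trend test (2 conditions × 5 seeds) a few
minutes. The full preset mirrors the published conditions (81×81 at 13 cm,
20000 patterns per condition, num_div 16, 120 + 10 iterations, 500
sentinels) and is cluster-scale; it is exposed through `full_plan()` and
the replication example but not exercised by the tests. Volumes and
pattern sets are exchanged as HDF5 (sparse ragged pattern layout:
indices/counts/offsets plus quaternions and metadata).

## Known limitations

* The hydration shell is a single dart-thrown configuration; real shells
  are ensembles correlated with the surface.
* The damage stand-in's uniform expansion cannot produce differential
  protein-vs-shell dynamics (real damage expands the solvent more than the
  tamped core); only the common-mode blurring survives.
* Expand/compress use trilinear kernels; sinc-like interpolation would
  reduce the ~5–10% round-trip error on speckle-width features.
* The OD minimization searches one overall orientation (justified by
  bi-invariance); a joint search over both orientations was not
  implemented.
* Posterior rotation levels above ~6 on the full detector need more
  memory than a desk machine (tomogram matrix is n_rot × n_pixels).
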