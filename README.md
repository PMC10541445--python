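# spisim

Simulation and analysis of orientation recovery in X-ray single-particle
imaging (SPI): how much does residual solvent — and how much does radiation
damage — degrade the reconstruction of a molecule's 3D diffraction volume
from photon-sparse single shots?

The package is for researchers studying SPI feasibility at XFEL sources. It
provides, as an importable library:

* a **forward simulator**: atomic structures (toy particles or PDB files),
  Cromer–Mann form factors, hydration shells of thickness `T_w`, spiky
  SASE-like pulse profiles, a parametric expansion/ionization stand-in for
  radiation damage, Ewald-sphere slicing and Poisson sampling at ~500
  photons per pattern;
* an **EMC reconstruction** (expand–maximize–compress): expectation-
  maximization over a weighted 600-cell-based discretization of SO(3) with
  `10(5n³+n)` rotation samples at refinement level `num_div = n`, annealed
  in the tempering factor β and in `num_div`;
* two **quality metrics**: the per-shell R-factor

  `R(s) = Σ_{q∈s} | √I(q)/Σ√I − √I_ideal(q)/Σ√I_ideal |`

  with low/mid/high-q regions split at 0.08 and 0.10 Å⁻¹, and the
  **orientation disconcurrence (OD)**

  `Δθ(W_A, W_B) = min_{Ω_A,Ω_B} sqrt( ⟨ ∬ θ²_{z,s}(Ω_α, Ω_β) dμ(α,A) dμ(β,B) ⟩_sentinels )`

  — the posterior-weighted RMS disagreement in decoding the orientations of
  held-out *sentinel* patterns, on the quotient of SO(3) by the particle's
  point group `s` and the Friedel group `z`, minimized over the unknown
  overall orientation between the volumes. Self-OD (`W_A = W_B`) is the
  default mode;
* a **pipeline** that scans water-layer thickness × damage conditions,
  repeats EMC reconstructions, and aggregates both metrics into a report
  with figures — plus a thin `spisim` CLI
  (`simulate | reconstruct | evaluate | experiment`).

## Worked example

`python examples/05_disconcurrence.py` builds a 40-atom toy particle
(~30 Å), computes its ideal reciprocal-space volume on the desk-scale
31×31-pixel detector, and measures the self-OD of 60 sentinel patterns at
three photon budgets:

```
photons/sentinel   self-OD (rad)
           500   0.0380
           100   0.7808
            20   1.7499
```

At 500 photons the orientation posteriors are sharp and Δθ sits at the
floor set by the rotation-grid spacing (a few hundredths of a radian);
starving the sentinels of photons broadens the Poisson posteriors and the
disconcurrence grows toward the value of a nearly uninformative decoding.

`python examples/06_water_layer_scan.py` runs the central experiment at
desk scale (T_w = 0 vs 20 Å; simulate → EMC → align → shell-R + self-OD)
and prints one line per condition, e.g.

```
T_w =  0.0 A | waters     0 | self-OD 0.256 rad | R_A 0.18  R_B 0.22  R_C 0.32
T_w = 20.0 A | waters  5310 | self-OD 1.607 rad | R_A 0.42  R_B 0.49  R_C 0.62
```

The thick water shell swamps the particle's speckles with solvent
scattering: orientation recovery degrades (higher Δθ) and the reconstructed
volume departs from the ground truth (higher R), most strongly at high q.

Other examples: detector/beam arithmetic (`01`), the SO(3) sampling
(`02`), pattern simulation (`03`), a full EMC reconstruction with alignment
(`04`), and a full-scale replication script for the ideal-volume OD anchor
of the nitrogenase iron protein (`replicate_od_anchor.py`, hours of CPU,
needs PDB 2NIP).

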