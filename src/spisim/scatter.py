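"""Synthetic-data building blocks for the diffraction simulator.

Atomic structures (random toy particles or PDB files), Cromer-Mann atomic
form factors, hydration shells of configurable thickness, spiky SASE-like
pulse temporal profiles, and a deliberately simple parametric stand-in for
radiation damage (uniform expansion plus uniform electron loss driven by the
cumulative pulse dose).

All generators are pure functions of their inputs and an explicit seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "AtomicStructure",
    "WaterShellSpec",
    "PulseProfile",
    "DamageTrajectory",
    "CROMER_MANN",
    "SUPPORTED_ELEMENTS",
    "form_factor",
    "make_toy_particle",
    "read_pdb",
    "add_water_shell",
    "make_sase_pulse",
    "make_damage_trajectory",
    "spherical_shell_crossover",
]

# Cromer-Mann 4-Gaussian coefficients (a1..a4, b1..b4, c), crystallographic
# s = q/2 convention: f(q) = sum_i a_i exp(-b_i (q/2)^2) + c.
# "HOH" is the effective one-site water scatterer f_O + 2 f_H.
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.489918, 0.262003, 0.196767, 0.049879),
          (20.6593, 7.74039, 49.5519, 2.20159), 0.001305),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.529),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "P": ((6.43450, 4.17910, 1.78000, 1.49080),
          (1.90670, 27.1570, 0.526000, 68.1645), 1.11490),
    "S": ((6.90530, 5.20340, 1.43790, 1.58630),
          (1.46790, 22.2151, 0.253600, 56.1720), 0.866900),
    "Fe": ((11.7695, 7.35730, 3.52220, 2.30450),
           (4.76110, 0.307200, 15.3535, 76.8805), 1.03690),
}

SUPPORTED_ELEMENTS = tuple(CROMER_MANN) + ("HOH",)

#: Atomic numbers of the supported real elements (for nearest-Z fallback).
_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "P": 15, "S": 16, "Fe": 26}


def form_factor(element: str, qmag) -> np.ndarray:
    """Elastic atomic form factor in electrons at |q| (1/A).

    Uses the tabulated Cromer-Mann coefficients with the crystallographic
    ``s = q/2`` argument.  ``HOH`` evaluates the effective water scatterer
    ``f_O + 2 f_H``.
    """
    qmag = np.asarray(qmag, dtype=float)
    if element == "HOH":
        return form_factor("O", qmag) + 2.0 * form_factor("H", qmag)
    try:
        a, b, c = CROMER_MANN[element]
    except KeyError:
        raise ValueError(f"unsupported element {element!r}") from None
    s2 = (qmag / 2.0) ** 2
    f = np.full_like(qmag, c, dtype=float)
    for ai, bi in zip(a, b):
        f = f + ai * np.exp(-bi * s2)
    return f


@dataclass
class AtomicStructure:
    """A collection of point scatterers.

    ``elements`` are symbols from the supported table (plus ``HOH`` for
    effective water sites); ``positions`` are in Angstrom; ``scale`` is a
    per-atom effective-electron multiplier (1 = neutral atom), used by the
    damage stand-in to model ionization.
    """

    elements: np.ndarray  # (N,) str
    positions: np.ndarray  # (N, 3) float, A
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=object)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        if len(self.elements) != len(self.positions):
            raise ValueError("elements and positions length mismatch")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        bad = [e for e in set(self.elements) if e not in SUPPORTED_ELEMENTS]
        if bad:
            raise ValueError(f"unsupported elements: {sorted(bad)}")
        if self.scale is None:
            self.scale = np.ones(len(self.elements))
        else:
            self.scale = np.asarray(self.scale, dtype=float)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def centered(self) -> "AtomicStructure":
        return AtomicStructure(
            self.elements,
            self.positions - self.positions.mean(axis=0),
            self.scale.copy(),
        )

    def radius_of_gyration(self) -> float:
        d = self.positions - self.positions.mean(axis=0)
        return float(np.sqrt((d**2).sum(axis=1).mean()))

    def to_hdf5(self, group) -> None:
        group.create_dataset(
            "elements", data=np.array([e.encode() for e in self.elements])
        )
        group.create_dataset("positions", data=self.positions)
        group.create_dataset("scale", data=self.scale)

    @classmethod
    def from_hdf5(cls, group) -> "AtomicStructure":
        return cls(
            elements=np.array([e.decode() for e in group["elements"][...]], dtype=object),
            positions=group["positions"][...],
            scale=group["scale"][...],
        )


def make_toy_particle(
    n_atoms: int,
    extent_A: float = 100.0,
    seed: int = 0,
    symmetrize: bool = False,
) -> AtomicStructure:
    """Random C/N/O cluster within a sphere of diameter ``extent_A``.

    A reproducible stand-in for a rigid asymmetric particle.  With
    ``symmetrize`` the atoms are duplicated under a 180-degree rotation about
    z, giving an exactly C2-symmetric particle.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    rng = np.random.default_rng(seed)
    n_base = (n_atoms + 1) // 2 if symmetrize else n_atoms
    radius = extent_A / 2.0
    # uniform in the ball via radius transform
    u = rng.random(n_base)
    r = radius * u ** (1.0 / 3.0)
    v = rng.standard_normal((n_base, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    pos = r[:, None] * v
    elems = rng.choice(["C", "N", "O"], size=n_base, p=[0.55, 0.2, 0.25])
    if symmetrize:
        flipped = pos * np.array([-1.0, -1.0, 1.0])
        pos = np.vstack([pos, flipped])
        elems = np.concatenate([elems, elems])
    return AtomicStructure(elems.astype(object), pos).centered()


def read_pdb(path, unknown: str = "substitute") -> AtomicStructure:
    """Read ATOM/HETATM records into an AtomicStructure (centroid-centered).

    Elements outside the supported table are either substituted by the
    nearest-Z supported element (default, with a warning) or skipped.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    elems: list[str] = []
    pos: list[tuple[float, float, float]] = []
    occ: list[float] = []
    substituted: set[str] = set()
    for model in st:
        for chain in model:
            for res in chain:
                for atom in res:
                    sym = atom.element.name
                    if sym not in _Z:
                        if unknown == "skip":
                            substituted.add(sym)
                            continue
                        z = atom.element.atomic_number
                        sym_new = min(_Z, key=lambda e: abs(_Z[e] - z))
                        substituted.add(sym)
                        sym = sym_new
                    elems.append(sym)
                    pos.append((atom.pos.x, atom.pos.y, atom.pos.z))
                    occ.append(atom.occ)
        break  # first model only
    if substituted:
        action = "skipped" if unknown == "skip" else "substituted by nearest-Z"
        warnings.warn(f"unsupported elements {sorted(substituted)} {action}")
    if not elems:
        raise ValueError(f"no usable atoms found in {path}")
    return AtomicStructure(
        np.array(elems, dtype=object), np.array(pos), np.array(occ)
    ).centered()


@dataclass(frozen=True)
class WaterShellSpec:
    """Hydration-shell parameters.

    ``thickness_A`` is the layer thickness T_w; waters are placed where the
    distance to the nearest solute heavy atom lies within
    [contact, contact + T_w].  ``number_density`` defaults to bulk water
    (0.0334 molecules/A^3).
    """

    thickness_A: float
    number_density: float = 0.0334
    contact_distance_A: float = 2.8
    min_separation_A: float = 2.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thickness_A < 0:
            raise ValueError("water layer thickness must be >= 0")
        if self.number_density <= 0 or self.min_separation_A <= 0:
            raise ValueError("densities and separations must be positive")


def _shell_volume_mc(
    solute_pos: np.ndarray, lo: float, hi: float, rng: np.random.Generator,
    n_samples: int = 40000,
) -> float:
    """Monte-Carlo volume of {x : lo <= dist(x, solute) <= hi}."""
    mins = solute_pos.min(axis=0) - hi
    maxs = solute_pos.max(axis=0) + hi
    box = np.prod(maxs - mins)
    pts = rng.random((n_samples, 3)) * (maxs - mins) + mins
    d, _ = cKDTree(solute_pos).query(pts, k=1)
    frac = np.mean((d >= lo) & (d <= hi))
    return float(box * frac)


def add_water_shell(structure: AtomicStructure, spec: WaterShellSpec) -> AtomicStructure:
    """Append one effective water scatterer per molecule around the solute.

    Waters are dart-thrown uniformly in the shell region (distance to the
    nearest solute heavy atom in [contact, contact + T_w]), honoring a
    minimum water-water separation; the target count is the bulk number
    density times the Monte-Carlo shell volume.  ``T_w = 0`` returns the
    input unchanged.
    """
    if spec.thickness_A == 0:
        return structure
    rng = np.random.default_rng(spec.seed)
    heavy = structure.positions[np.array([e != "H" for e in structure.elements])]
    lo = spec.contact_distance_A
    hi = spec.contact_distance_A + spec.thickness_A
    volume = _shell_volume_mc(heavy, lo, hi, rng)
    n_target = int(round(spec.number_density * volume))
    tree = cKDTree(heavy)
    mins = heavy.min(axis=0) - hi
    maxs = heavy.max(axis=0) + hi

    # cell-list for accepted waters, cell size = min separation
    cell = spec.min_separation_A
    occupied: dict[tuple[int, int, int], list[np.ndarray]] = {}
    accepted: list[np.ndarray] = []

    def clashes(p: np.ndarray) -> bool:
        ix, iy, iz = (int(np.floor(c / cell)) for c in p)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    for w in occupied.get((ix + dx, iy + dy, iz + dz), ()):
                        if np.sum((w - p) ** 2) < cell * cell:
                            return True
        return False

    max_attempts = 200 * max(n_target, 1)
    attempts = 0
    batch = max(4 * n_target, 256)
    while len(accepted) < n_target and attempts < max_attempts:
        pts = rng.random((batch, 3)) * (maxs - mins) + mins
        d, _ = tree.query(pts, k=1)
        pts = pts[(d >= lo) & (d <= hi)]
        attempts += batch
        for p in pts:
            if len(accepted) >= n_target:
                break
            if clashes(p):
                continue
            accepted.append(p)
            key = tuple(int(np.floor(c / cell)) for c in p)
            occupied.setdefault(key, []).append(p)
    if accepted:
        waters = np.array(accepted)
        elems = np.concatenate(
            [structure.elements, np.array(["HOH"] * len(waters), dtype=object)]
        )
        pos = np.vstack([structure.positions, waters])
        scale = np.concatenate([structure.scale, np.ones(len(waters))])
        return AtomicStructure(elems, pos, scale)
    return structure


def spherical_shell_crossover(radius_A: float, contact_A: float = 0.0) -> float:
    """Shell thickness at which a spherical particle's hydration-shell volume
    equals the particle volume (closed form)."""
    r0 = radius_A + contact_A
    return float(np.cbrt(r0**3 + radius_A**3) - r0)


@dataclass
class PulseProfile:
    """Temporal pulse profile binned at fixed intervals.

    ``bin_times_fs`` are bin centres; ``bin_fractions`` are the fraction of
    pulse energy per bin (non-negative, sum 1).
    """

    bin_times_fs: np.ndarray
    bin_fractions: np.ndarray

    def __post_init__(self) -> None:
        self.bin_times_fs = np.asarray(self.bin_times_fs, dtype=float)
        self.bin_fractions = np.asarray(self.bin_fractions, dtype=float)
        if np.any(self.bin_fractions < 0):
            raise ValueError("bin fractions must be non-negative")
        total = self.bin_fractions.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("bin fractions must sum to 1")

    @property
    def n_bins(self) -> int:
        return len(self.bin_fractions)

    def fdhm_fs(self) -> float:
        """Full duration at half maximum, by linear interpolation between
        the first and last half-maximum crossings."""
        y = self.bin_fractions
        t = self.bin_times_fs
        if len(y) == 1:
            return 0.0  # a single bin has no measurable width
        half = y.max() / 2.0
        above = np.nonzero(y >= half)[0]
        i0, i1 = above[0], above[-1]
        t_lo = t[i0]
        if i0 > 0:
            t_lo = t[i0 - 1] + (half - y[i0 - 1]) / (y[i0] - y[i0 - 1]) * (t[i0] - t[i0 - 1])
        t_hi = t[i1]
        if i1 < len(y) - 1:
            t_hi = t[i1] + (y[i1] - half) / (y[i1] - y[i1 + 1]) * (t[i1 + 1] - t[i1])
        return float(t_hi - t_lo)


def make_sase_pulse(
    n_bins: int,
    fdhm_fs: float = 9.0,
    bin_fs: float = 2.6,
    seed: int = 0,
    jitter: float = 0.6,
) -> PulseProfile:
    """Spiky SASE-like temporal profile binned at ``bin_fs`` intervals.

    A Gaussian envelope of the requested FDHM is modulated by bounded
    multiplicative spikes (uniform in ``1 +/- jitter``); the bound keeps the
    half-maximum crossings well defined so the measured FDHM stays within
    about one bin of the request.  The envelope width is then iteratively
    rescaled against the measured FDHM of the spiky profile.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    times = (np.arange(n_bins) - (n_bins - 1) / 2.0) * bin_fs
    if n_bins == 1:
        return PulseProfile(times, np.array([1.0]))
    rng = np.random.default_rng(seed)
    spikes = 1.0 + jitter * (2.0 * rng.random(n_bins) - 1.0)
    nominal = fdhm_fs / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    # calibrate the envelope width against the measured FDHM of the spiky
    # profile (the spikes shift the half-maximum crossings); deterministic
    # grid search, nearest measured width wins
    best_prof, best_dev = None, np.inf
    for sigma in nominal * np.geomspace(0.5, 2.0, 41):
        env = np.exp(-(times**2) / (2.0 * sigma**2))
        y = env * spikes
        prof = PulseProfile(times, y / y.sum())
        dev = abs(prof.fdhm_fs() - fdhm_fs)
        if dev < best_dev:
            best_prof, best_dev = prof, dev
    return best_prof


@dataclass
class DamageTrajectory:
    """Per-pulse-bin structure snapshots from the parametric damage stand-in.

    Each snapshot is the input structure expanded radially about its centroid
    by ``1 + expansion_rate * D(t)`` with every atomic effective-electron
    scale multiplied by ``max(0, 1 - ionization_rate * D(t))``, where D(t) is
    the cumulative pulse-energy fraction delivered before the bin.  This is a
    two-parameter phenomenological stand-in, not damage physics; it
    reproduces the qualitative signatures (speckle contraction toward the
    centre, late-pulse blurring) of a Coulomb-expanding, ionizing sample.
    """

    pulse: PulseProfile
    snapshots: list[AtomicStructure]
    expansion_factors: np.ndarray
    ionization_factors: np.ndarray
    expansion_rate: float
    ionization_rate: float

    @property
    def n_bins(self) -> int:
        return len(self.snapshots)

    @property
    def cumulative_dose(self) -> np.ndarray:
        """D(t) at each bin start: cumulative fraction before the bin."""
        f = self.pulse.bin_fractions
        return np.concatenate([[0.0], np.cumsum(f)[:-1]])


def make_damage_trajectory(
    structure: AtomicStructure,
    pulse: PulseProfile,
    expansion_rate: float = 0.0,
    ionization_rate: float = 0.0,
) -> DamageTrajectory:
    """Build the time-resolved snapshot sequence of the damage stand-in."""
    if expansion_rate < 0 or ionization_rate < 0:
        raise ValueError("damage rates must be >= 0")
    frac = pulse.bin_fractions
    dose = np.concatenate([[0.0], np.cumsum(frac)[:-1]])
    center = structure.positions.mean(axis=0)
    snapshots = []
    expf = 1.0 + expansion_rate * dose
    ionf = np.maximum(0.0, 1.0 - ionization_rate * dose)
    for c_exp, c_ion in zip(expf, ionf):
        pos = center + (structure.positions - center) * c_exp
        snapshots.append(
            AtomicStructure(structure.elements, pos, structure.scale * c_ion)
        )
    return DamageTrajectory(
        pulse=pulse,
        snapshots=snapshots,
        expansion_factors=expf,
        ionization_factors=ionf,
        expansion_rate=expansion_rate,
        ionization_rate=ionization_rate,
    )
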