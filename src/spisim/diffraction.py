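"""Forward diffraction model.

Ideal reciprocal-space intensity volumes from atomic structures, Ewald-sphere
pattern extraction at arbitrary orientation (exact atom path and fast
volume-interpolation path), time-integration over a damage trajectory,
photon-budget scaling, and Poisson sampling into sparse pattern sets.

Intensity convention: I(q) = |sum_j s_j f_j(|q|) exp(2 pi i q.r_j)|^2 with
q = 2 sin(theta)/lambda, in arbitrary units until a photon budget is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np

from . import _kernels
from .geometry import DetectorGeometry, PixelMap, build_pixel_map
from .rotations import Rotation, quat_canonical, random_rotations
from .scatter import AtomicStructure, DamageTrajectory, form_factor

__all__ = [
    "IntensityVolume",
    "DiffractionPattern",
    "PatternSet",
    "DamagedVolumeModel",
    "default_volume_grid",
    "ideal_intensity_volume",
    "slice_pattern",
    "expected_pattern",
    "simulate_pattern",
    "generate_dataset",
]


@dataclass
class IntensityVolume:
    """Cubic reciprocal-space intensity grid; the central voxel is q = 0."""

    edge: int
    dq: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.edge % 2 == 0:
            raise ValueError("volume edge must be odd")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.edge,) * 3:
            raise ValueError("values shape does not match edge")

    @property
    def q_support(self) -> float:
        """Largest |q| along an axis still inside the grid."""
        return (self.edge - 1) / 2.0 * self.dq

    def q_axis(self) -> np.ndarray:
        return (np.arange(self.edge) - (self.edge - 1) / 2.0) * self.dq

    def qmag_grid(self) -> np.ndarray:
        ax = self.q_axis()
        qx, qy, qz = np.meshgrid(ax, ax, ax, indexing="ij")
        return np.sqrt(qx**2 + qy**2 + qz**2)

    def central_slice(self) -> np.ndarray:
        """The q_z = 0 plane (xy slice through the centre)."""
        return self.values[:, :, (self.edge - 1) // 2]

    def copy(self) -> "IntensityVolume":
        return IntensityVolume(self.edge, self.dq, self.values.copy())

    def to_hdf5(self, group) -> None:
        group.create_dataset("intensity", data=self.values)
        group.attrs["dq"] = self.dq
        group.attrs["edge"] = self.edge

    @classmethod
    def from_hdf5(cls, group) -> "IntensityVolume":
        return cls(
            edge=int(group.attrs["edge"]),
            dq=float(group.attrs["dq"]),
            values=group["intensity"][...],
        )


def default_volume_grid(pixmap: PixelMap) -> tuple[int, float]:
    """(edge, dq) so the full detector Ewald cap fits inside the volume.

    dq equals the detector's central pixel q-pitch; the edge is chosen so the
    corner |q| of the detector lies inside the grid.
    """
    cy, cx = pixmap.geom.beam_center
    row, col = int(round(cy)), int(round(cx))
    dq = float(pixmap.qmag[row, col + 1]) if pixmap.geom.n_fast > 1 else 1.0
    edge = 2 * int(np.ceil(pixmap.q_corner / dq)) + 1
    return edge, dq


def _intensity_at(structure: AtomicStructure, qvecs: np.ndarray) -> np.ndarray:
    """Exact |F|^2 at arbitrary q vectors (M, 3), grouping atoms by element."""
    qvecs = np.ascontiguousarray(qvecs, dtype=float)
    qmag = np.linalg.norm(qvecs, axis=1)
    f_re = np.zeros(len(qvecs))
    f_im = np.zeros(len(qvecs))
    for elem in np.unique(structure.elements):
        mask = structure.elements == elem
        pos = np.ascontiguousarray(structure.positions[mask])
        scl = np.ascontiguousarray(structure.scale[mask])
        a_re = np.empty(len(qvecs))
        a_im = np.empty(len(qvecs))
        _kernels.phase_sums(qvecs, pos, scl, a_re, a_im)
        f = form_factor(str(elem), qmag)
        f_re += f * a_re
        f_im += f * a_im
    return f_re**2 + f_im**2


def ideal_intensity_volume(
    structure: AtomicStructure, edge: int, dq: float
) -> IntensityVolume:
    """Ideal (noise-free, fully oriented) intensity on a cubic q grid."""
    if edge % 2 == 0:
        raise ValueError("volume edge must be odd")
    ax = (np.arange(edge) - (edge - 1) / 2.0) * dq
    qx, qy, qz = np.meshgrid(ax, ax, ax, indexing="ij")
    qvecs = np.stack([qx.ravel(), qy.ravel(), qz.ravel()], axis=1)
    vals = _intensity_at(structure, qvecs).reshape(edge, edge, edge)
    return IntensityVolume(edge=edge, dq=dq, values=vals)


@dataclass
class DamagedVolumeModel:
    """Fast time-integrated model for the uniform-expansion damage stand-in.

    Because the stand-in expands every atom radially by a common factor c_b
    and scales every effective electron count by a common factor i_b, the
    intensity of bin b is i_b^2 I_0(c_b q): the whole trajectory can be
    evaluated from the single undamaged volume by q-rescaling.
    """

    volume: IntensityVolume
    fractions: np.ndarray
    expansion_factors: np.ndarray
    ionization_factors: np.ndarray

    @classmethod
    def from_trajectory(
        cls, volume: IntensityVolume, trajectory: DamageTrajectory
    ) -> "DamagedVolumeModel":
        return cls(
            volume=volume,
            fractions=trajectory.pulse.bin_fractions.copy(),
            expansion_factors=trajectory.expansion_factors.copy(),
            ionization_factors=trajectory.ionization_factors.copy(),
        )


@dataclass
class DiffractionPattern:
    """Sparse integer photon counts on the detector."""

    n_pixels: int
    indices: np.ndarray  # pixel indices with at least one photon
    counts: np.ndarray  # photon count per listed pixel
    true_orientation: Rotation | None = None
    pulse_id: int | None = None
    structure_id: int | None = None

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=np.int64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")

    @property
    def n_photons(self) -> int:
        return int(self.counts.sum())

    def dense(self) -> np.ndarray:
        out = np.zeros(self.n_pixels, dtype=np.int64)
        out[self.indices] = self.counts
        return out


@dataclass
class PatternSet:
    """A set of sparse patterns sharing one detector geometry."""

    geom: DetectorGeometry
    indices: np.ndarray  # concatenated sparse pixel indices
    counts: np.ndarray  # concatenated counts
    offsets: np.ndarray  # (n_patterns + 1,) ragged offsets
    orientations: np.ndarray  # (n_patterns, 4) true orientations (quats)
    meta: dict = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return len(self.offsets) - 1

    @property
    def n_pixels(self) -> int:
        return self.geom.n_fast * self.geom.n_slow

    @property
    def photon_counts(self) -> np.ndarray:
        cum = np.concatenate([[0], np.cumsum(self.counts)])
        return cum[self.offsets[1:]] - cum[self.offsets[:-1]]

    def pattern(self, i: int) -> DiffractionPattern:
        lo, hi = self.offsets[i], self.offsets[i + 1]
        return DiffractionPattern(
            n_pixels=self.n_pixels,
            indices=self.indices[lo:hi],
            counts=self.counts[lo:hi],
            true_orientation=Rotation(self.orientations[i]),
        )

    def dense(self) -> np.ndarray:
        out = np.zeros((self.n_patterns, self.n_pixels), dtype=np.int64)
        for i in range(self.n_patterns):
            lo, hi = self.offsets[i], self.offsets[i + 1]
            out[i, self.indices[lo:hi]] = self.counts[lo:hi]
        return out

    def subset(self, idx) -> "PatternSet":
        idx = np.asarray(idx)
        parts = [
            (self.indices[self.offsets[i]:self.offsets[i + 1]],
             self.counts[self.offsets[i]:self.offsets[i + 1]])
            for i in idx
        ]
        offsets = np.concatenate([[0], np.cumsum([len(p[0]) for p in parts])])
        return PatternSet(
            geom=self.geom,
            indices=np.concatenate([p[0] for p in parts]) if parts else np.empty(0, np.int64),
            counts=np.concatenate([p[1] for p in parts]) if parts else np.empty(0, np.int64),
            offsets=offsets.astype(np.int64),
            orientations=self.orientations[idx],
            meta=dict(self.meta),
        )

    def to_hdf5(self, path_or_group) -> None:
        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        h = h5py.File(path_or_group, "w") if own else path_or_group
        try:
            g = h.create_group("patterns")
            g.create_dataset("indices", data=self.indices)
            g.create_dataset("counts", data=self.counts)
            g.create_dataset("offsets", data=self.offsets)
            g.create_dataset("orientations", data=self.orientations)
            gg = h.create_group("geometry")
            gg.attrs.update(
                n_fast=self.geom.n_fast,
                n_slow=self.geom.n_slow,
                pixel_size_um=self.geom.pixel_size_um,
                distance_mm=self.geom.distance_mm,
                photon_energy_kev=self.geom.photon_energy_kev,
            )
            gm = h.create_group("meta")
            for k, v in self.meta.items():
                gm.attrs[k] = v
        finally:
            if own:
                h.close()

    @classmethod
    def from_hdf5(cls, path_or_group) -> "PatternSet":
        own = isinstance(path_or_group, (str, bytes)) or hasattr(path_or_group, "__fspath__")
        h = h5py.File(path_or_group, "r") if own else path_or_group
        try:
            ga = h["geometry"].attrs
            geom = DetectorGeometry(
                n_fast=int(ga["n_fast"]),
                n_slow=int(ga["n_slow"]),
                pixel_size_um=float(ga["pixel_size_um"]),
                distance_mm=float(ga["distance_mm"]),
                photon_energy_kev=float(ga["photon_energy_kev"]),
            )
            g = h["patterns"]
            meta = {k: v for k, v in h["meta"].attrs.items()}
            return cls(
                geom=geom,
                indices=g["indices"][...],
                counts=g["counts"][...],
                offsets=g["offsets"][...],
                orientations=g["orientations"][...],
                meta=meta,
            )
        finally:
            if own:
                h.close()


def _rotated_pixel_q(orientation: Rotation, pixmap: PixelMap) -> np.ndarray:
    """q vectors at which the model frame is sampled: R^T q_pixel.

    A particle rotated by R has F_rot(q) = F(R^T q), so the pattern at
    orientation R samples the model volume at R^T q_pixel.
    """
    return pixmap.q_flat @ orientation.matrix


def slice_pattern(model, orientation: Rotation, pixmap: PixelMap) -> np.ndarray:
    """Expected (noise-free) intensity per pixel at one orientation.

    ``model`` is an AtomicStructure (exact evaluation) or an IntensityVolume
    (trilinear interpolation).  Returns a flat (n_pixels,) array in the
    model's arbitrary intensity units.
    """
    coords = _rotated_pixel_q(orientation, pixmap)
    if isinstance(model, AtomicStructure):
        return _intensity_at(model, coords)
    if isinstance(model, IntensityVolume):
        if pixmap.q_corner > model.q_support * (1.0 + 1e-9):
            raise ValueError(
                f"detector corner q {pixmap.q_corner:.4f} exceeds volume "
                f"support {model.q_support:.4f}"
            )
        return _kernels.sample_volume(
            model.values, np.ascontiguousarray(coords), model.dq
        )
    raise TypeError(f"cannot slice object of type {type(model).__name__}")


def expected_pattern(model, orientation: Rotation, pixmap: PixelMap) -> np.ndarray:
    """Expected intensity per pixel, time-integrating damage models."""
    if isinstance(model, DamageTrajectory):
        out = np.zeros(pixmap.n_pixels)
        for frac, snap in zip(model.pulse.bin_fractions, model.snapshots):
            if frac > 0:
                out += frac * slice_pattern(snap, orientation, pixmap)
        return out
    if isinstance(model, DamagedVolumeModel):
        coords = _rotated_pixel_q(orientation, pixmap)
        out = np.zeros(pixmap.n_pixels)
        for frac, c_exp, c_ion in zip(
            model.fractions, model.expansion_factors, model.ionization_factors
        ):
            if frac > 0:
                scaled = np.ascontiguousarray(coords * c_exp)
                out += frac * c_ion**2 * _kernels.sample_volume(
                    model.volume.values, scaled, model.volume.dq
                )
        return out
    return slice_pattern(model, orientation, pixmap)


def simulate_pattern(
    model,
    orientation: Rotation,
    pixmap: PixelMap,
    mean_photons: float,
    rng: np.random.Generator,
    background_per_pixel: float = 0.0,
) -> DiffractionPattern:
    """Draw one Poisson pattern.

    The expected intensity (signal plus flat isotropic background) is
    rescaled so its sum over the detector equals ``mean_photons``, then each
    pixel is drawn Poisson.
    """
    if mean_photons <= 0:
        raise ValueError("mean_photons must be positive")
    expect = expected_pattern(model, orientation, pixmap) + background_per_pixel
    total = expect.sum()
    if total <= 0:
        raise ValueError("expected intensity is identically zero")
    lam = expect * (mean_photons / total)
    counts = rng.poisson(lam)
    nz = np.nonzero(counts)[0]
    return DiffractionPattern(
        n_pixels=pixmap.n_pixels,
        indices=nz,
        counts=counts[nz],
        true_orientation=orientation,
    )


def generate_dataset(
    model,
    n_patterns: int,
    pixmap: PixelMap,
    mean_photons: float = 500.0,
    seed: int = 0,
    background_fraction: float = 0.0,
    meta: dict | None = None,
) -> PatternSet:
    """Generate a pattern set at orientations uniform on SO(3).

    The orientation list is a function of ``seed`` only, so two conditions
    simulated with the same seed share identical orientation lists.  An
    optional flat background (inelastic-scattering stand-in) carries the
    stated fraction of the photon budget.
    """
    if n_patterns < 1:
        raise ValueError("n_patterns must be >= 1")
    rng_orient = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    rng_noise = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    quats = random_rotations(n_patterns, rng_orient)

    # background level: flat per-pixel expectation carrying the requested
    # fraction of the *pre-rescale* expected signal
    bg = 0.0
    if background_fraction > 0:
        probe = expected_pattern(model, Rotation(quats[0]), pixmap)
        bg = background_fraction * probe.sum() / (
            (1.0 - background_fraction) * pixmap.n_pixels
        )

    all_idx: list[np.ndarray] = []
    all_cnt: list[np.ndarray] = []
    for i in range(n_patterns):
        pat = simulate_pattern(
            model, Rotation(quats[i]), pixmap, mean_photons, rng_noise,
            background_per_pixel=bg,
        )
        all_idx.append(pat.indices)
        all_cnt.append(pat.counts)
    offsets = np.concatenate([[0], np.cumsum([len(a) for a in all_idx])]).astype(np.int64)
    full_meta = {
        "mean_photons": float(mean_photons),
        "seed": int(seed),
        "background_fraction": float(background_fraction),
        "used_for_reconstruction": False,
    }
    if meta:
        full_meta.update(meta)
    return PatternSet(
        geom=pixmap.geom,
        indices=np.concatenate(all_idx),
        counts=np.concatenate(all_cnt),
        offsets=offsets,
        orientations=quat_canonical(quats),
        meta=full_meta,
    )
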