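"""Forward model: volumes, Ewald slices, Poisson sampling, datasets."""

import numpy as np
import pytest
from scipy.stats import kstest

from spisim.diffraction import (
    DamagedVolumeModel,
    IntensityVolume,
    PatternSet,
    default_volume_grid,
    expected_pattern,
    generate_dataset,
    ideal_intensity_volume,
    simulate_pattern,
    slice_pattern,
)
from spisim.geometry import DetectorGeometry, build_pixel_map
from spisim.rotations import Rotation
from spisim.scatter import (
    AtomicStructure,
    form_factor,
    make_damage_trajectory,
    make_sase_pulse,
    make_toy_particle,
)


class TestIdealVolume:
    def test_single_atom_isotropic(self):
        st = AtomicStructure(np.array(["O"], dtype=object), np.zeros((1, 3)))
        vol = ideal_intensity_volume(st, 15, 0.02)
        expected = form_factor("O", vol.qmag_grid()) ** 2
        assert np.allclose(vol.values, expected, rtol=1e-10)

    def test_two_atom_interference(self):
        d = 10.0
        st = AtomicStructure(
            np.array(["O", "O"], dtype=object),
            np.array([[d / 2, 0, 0], [-d / 2, 0, 0]]),
        )
        vol = ideal_intensity_volume(st, 21, 0.01)
        qx = vol.q_axis()
        line = vol.values[:, 10, 10]
        expected = 4 * form_factor("O", np.abs(qx)) ** 2 * np.cos(np.pi * qx * d) ** 2
        assert np.allclose(line, expected, atol=1e-8 * expected.max())

    def test_friedel_symmetry(self, gt_volume):
        v = gt_volume.values
        assert np.allclose(v, v[::-1, ::-1, ::-1], rtol=1e-6)

    def test_scale_invariance(self, toy_particle, desk_grid):
        edge, dq = desk_grid
        c = 3.0
        scaled = AtomicStructure(
            toy_particle.elements, toy_particle.positions, toy_particle.scale * c
        )
        v1 = ideal_intensity_volume(toy_particle, 15, dq)
        v2 = ideal_intensity_volume(scaled, 15, dq)
        assert np.allclose(v2.values, c**2 * v1.values, rtol=1e-10)

    def test_even_edge_rejected(self, toy_particle):
        with pytest.raises(ValueError):
            ideal_intensity_volume(toy_particle, 16, 0.01)


class TestSlicePattern:
    def test_identity_single_atom(self, desk_pixmap):
        st = AtomicStructure(np.array(["C"], dtype=object), np.zeros((1, 3)))
        vals = slice_pattern(st, Rotation.identity(), desk_pixmap)
        expected = form_factor("C", desk_pixmap.qmag.ravel()) ** 2
        assert np.allclose(vals, expected, rtol=1e-10)

    def test_equivariance(self, toy_particle, desk_pixmap):
        rot = Rotation.from_axis_angle([1, 2, 3], 0.7)
        p1 = slice_pattern(toy_particle, rot, desk_pixmap)
        rotated = AtomicStructure(
            toy_particle.elements,
            toy_particle.positions @ rot.matrix.T,
            toy_particle.scale,
        )
        p2 = slice_pattern(rotated, Rotation.identity(), desk_pixmap)
        assert np.allclose(p1, p2, rtol=1e-10)

    def test_volume_path_matches_atom_path(self, desk_pixmap):
        st = make_toy_particle(5, 25.0, seed=4)
        edge, dq = default_volume_grid(desk_pixmap)
        # oversample the grid 2x: the interpolation error of the fast path
        # scales with the voxel size
        edge, dq = 2 * edge - 1, dq / 2.0
        vol = ideal_intensity_volume(st, edge, dq)
        rot = Rotation.from_axis_angle([0.2, -1, 0.5], 1.0)
        exact = slice_pattern(st, rot, desk_pixmap)
        interp = slice_pattern(vol, rot, desk_pixmap)
        rms = np.sqrt(np.mean((interp - exact) ** 2)) / np.sqrt(np.mean(exact**2))
        assert rms < 0.05

    def test_support_violation(self, desk_pixmap, toy_particle):
        vol = ideal_intensity_volume(toy_particle, 11, 0.001)  # tiny support
        with pytest.raises(ValueError):
            slice_pattern(vol, Rotation.identity(), desk_pixmap)


class TestSimulatePattern:
    def test_mean_total_counts(self, gt_volume, desk_pixmap):
        rng = np.random.default_rng(0)
        rot = Rotation.from_axis_angle([1, 0, 1], 0.4)
        totals = [
            simulate_pattern(gt_volume, rot, desk_pixmap, 500.0, rng).n_photons
            for _ in range(200)
        ]
        assert np.mean(totals) == pytest.approx(500.0, rel=0.05)

    def test_static_expectation_proportional_to_slice(self, gt_volume, desk_pixmap):
        rot = Rotation.from_axis_angle([0, 1, 0], 0.9)
        sl = slice_pattern(gt_volume, rot, desk_pixmap)
        exp = expected_pattern(gt_volume, rot, desk_pixmap)
        assert np.allclose(exp, sl, rtol=1e-12)

    def test_monte_carlo_convergence_to_expectation(self, gt_volume, desk_pixmap):
        # the mean of many Poisson patterns converges to the expectation map
        rot = Rotation.from_axis_angle([1, 1, 0], 1.3)
        lam = expected_pattern(gt_volume, rot, desk_pixmap)
        lam = lam * (500.0 / lam.sum())
        rng = np.random.default_rng(1)
        acc = np.zeros_like(lam)
        n = 10000
        for _ in range(20):
            acc += rng.poisson(lam, size=(n // 20, lam.size)).sum(axis=0)
        mean = acc / n
        cos = mean @ lam / (np.linalg.norm(mean) * np.linalg.norm(lam))
        assert cos > 0.99

    def test_zero_budget_rejected(self, gt_volume, desk_pixmap):
        with pytest.raises(ValueError):
            simulate_pattern(
                gt_volume, Rotation.identity(), desk_pixmap, 0.0,
                np.random.default_rng(0),
            )


class TestGenerateDataset:
    def test_shared_orientations_across_conditions(self, desk_pixmap, gt_volume):
        st = make_toy_particle(10, 20.0, seed=9)
        edge, dq = default_volume_grid(desk_pixmap)
        other = ideal_intensity_volume(st, edge, dq)
        d1 = generate_dataset(gt_volume, 20, desk_pixmap, 500.0, seed=42)
        d2 = generate_dataset(other, 20, desk_pixmap, 500.0, seed=42)
        assert np.array_equal(d1.orientations, d2.orientations)

    def test_orientation_uniformity(self):
        from spisim.rotations import random_rotations

        rng = np.random.default_rng(3)
        q = random_rotations(5000, rng)
        # dot of uniform S^3 vectors with a fixed axis: density (2/pi) sqrt(1-d^2)
        d = q @ np.array([0.0, 1.0, 0.0, 0.0])

        def cdf(x):
            x = np.clip(x, -1, 1)
            return 0.5 + (np.arcsin(x) + x * np.sqrt(1 - x**2)) / np.pi

        assert kstest(d, cdf).pvalue > 0.01

    def test_empty_dataset_rejected(self, gt_volume, desk_pixmap):
        with pytest.raises(ValueError):
            generate_dataset(gt_volume, 0, desk_pixmap, 500.0, seed=0)

    def test_hdf5_roundtrip(self, gt_volume, desk_pixmap, tmp_path):
        ds = generate_dataset(
            gt_volume, 15, desk_pixmap, 500.0, seed=5, meta={"role": "test"}
        )
        path = tmp_path / "patterns.h5"
        ds.to_hdf5(path)
        back = PatternSet.from_hdf5(path)
        assert back.n_patterns == ds.n_patterns
        assert np.array_equal(back.indices, ds.indices)
        assert np.array_equal(back.counts, ds.counts)
        assert np.array_equal(back.orientations, ds.orientations)
        assert back.meta["role"] == "test"
        assert back.geom == ds.geom


class TestTimeIntegration:
    def test_zero_damage_equals_static(self, toy_particle, desk_pixmap, gt_volume):
        pulse = make_sase_pulse(7, seed=2)
        traj = make_damage_trajectory(toy_particle, pulse, 0.0, 0.0)
        rot = Rotation.from_axis_angle([1, 0, 0], 0.5)
        static = slice_pattern(toy_particle, rot, desk_pixmap)
        integrated = expected_pattern(traj, rot, desk_pixmap)
        assert np.allclose(integrated, static, rtol=1e-10)
        fast = DamagedVolumeModel.from_trajectory(gt_volume, traj)
        vol_static = slice_pattern(gt_volume, rot, desk_pixmap)
        assert np.allclose(
            expected_pattern(fast, rot, desk_pixmap), vol_static, rtol=1e-12
        )

    def test_late_bin_contribution_small(self, toy_particle, desk_pixmap):
        # with a spiky 9-fs pulse and strong expansion the final 2.6-fs bin
        # contributes only a small share of the registered intensity
        pulse = make_sase_pulse(9, fdhm_fs=9.0, seed=6)
        traj = make_damage_trajectory(toy_particle, pulse, 1.0, 0.5)
        rot = Rotation.from_axis_angle([0, 1, 1], 0.8)
        shares = []
        for frac, snap in zip(pulse.bin_fractions, traj.snapshots):
            shares.append(frac * slice_pattern(snap, rot, desk_pixmap).sum())
        shares = np.array(shares) / np.sum(shares)
        assert shares[-1] < 0.05

    def test_expansion_contracts_speckles(self, desk_pixmap):
        # an expanded structure samples the undamaged intensity at scaled q:
        # the fast volume path must match the exact atom path of the
        # expanded structure, and interference fringes move toward the centre
        d = 20.0
        st = AtomicStructure(
            np.array(["O", "O"], dtype=object),
            np.array([[d / 2, 0, 0], [-d / 2, 0, 0]]),
        )
        edge, dq = default_volume_grid(desk_pixmap)
        edge, dq = 2 * edge - 1, dq / 2.0
        vol = ideal_intensity_volume(st, edge, dq)
        c = 1.15
        model = DamagedVolumeModel(
            volume=vol, fractions=np.array([1.0]),
            expansion_factors=np.array([c]), ionization_factors=np.array([0.9]),
        )
        rot = Rotation.identity()
        fast = expected_pattern(model, rot, desk_pixmap)
        expanded = AtomicStructure(st.elements, st.positions * c, st.scale * 0.9)
        exact = slice_pattern(expanded, rot, desk_pixmap)
        rms = np.sqrt(np.mean((fast - exact) ** 2)) / np.sqrt(np.mean(exact**2))
        assert rms < 0.05
        # first fringe minimum along x sits at q_x = 1/(2 c d): inward of the
        # undamaged minimum at 1/(2 d)
        row = fast.reshape(desk_pixmap.qmag.shape)[15, 15:]
        static_row = slice_pattern(vol, rot, desk_pixmap).reshape(
            desk_pixmap.qmag.shape
        )[15, 15:]
        assert np.argmin(row[1:]) < np.argmin(static_row[1:])
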