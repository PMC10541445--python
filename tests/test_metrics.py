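"""Shell R-factor, alignment, orientation posteriors and disconcurrence."""

import numpy as np
import pytest

from spisim import _kernels
from spisim.diffraction import (
    DiffractionPattern,
    IntensityVolume,
    default_volume_grid,
    generate_dataset,
    ideal_intensity_volume,
    simulate_pattern,
)
from spisim.emc import expand
from spisim.metrics import (
    ODConfig,
    ShellSpec,
    align_to_reference,
    disconcurrence,
    orientation_posterior,
    pattern_log_likelihood,
    rotate_volume,
    shell_r_factor,
    theta_sq,
)
from spisim.geometry import DetectorGeometry, build_pixel_map
from spisim.rotations import (
    Rotation,
    make_group,
    quat_angle,
    quat_from_axis_angle,
    sample_rotations,
)
from spisim.scatter import AtomicStructure, make_toy_particle


def _normalized_volume(volume, sentinels, rotations, pixmap):
    from spisim.metrics import _normalize_to_budget

    return _normalize_to_budget(volume, sentinels, rotations, pixmap)


class TestShellRFactor:
    def test_proportional_volumes_give_zero(self, gt_volume):
        scaled = gt_volume.copy()
        scaled.values *= 7.3
        res = shell_r_factor(scaled, gt_volume)
        valid = np.isfinite(res.r_values)
        assert np.allclose(res.r_values[valid], 0.0, atol=1e-10)

    def test_two_voxel_hand_example(self):
        # a shell holding intensities (1, 4) vs (4, 1):
        # R = |1/3 - 2/3| + |2/3 - 1/3| = 2/3
        edge, dq = 3, 1.0
        a = np.zeros((3, 3, 3))
        b = np.zeros((3, 3, 3))
        a[0, 1, 1], a[2, 1, 1] = 1.0, 4.0  # |q| = 1 voxels
        b[0, 1, 1], b[2, 1, 1] = 4.0, 1.0
        va = IntensityVolume(edge, dq, a)
        vb = IntensityVolume(edge, dq, b)
        spec = ShellSpec(edges=np.array([0.5, 1.5]))
        res = shell_r_factor(va, vb, spec)
        assert res.r_values[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_disjoint_supports_give_two(self):
        edge, dq = 3, 1.0
        a = np.zeros((3, 3, 3))
        b = np.zeros((3, 3, 3))
        a[0, 1, 1] = 5.0
        b[2, 1, 1] = 3.0
        spec = ShellSpec(edges=np.array([0.5, 1.5]))
        res = shell_r_factor(
            IntensityVolume(edge, dq, a), IntensityVolume(edge, dq, b), spec
        )
        assert res.r_values[0] == pytest.approx(2.0, abs=1e-12)

    def test_bounded_on_random_volumes(self, desk_grid):
        edge, dq = desk_grid
        rng = np.random.default_rng(0)
        va = IntensityVolume(edge, dq, rng.random((edge,) * 3))
        vb = IntensityVolume(edge, dq, rng.random((edge,) * 3))
        res = shell_r_factor(va, vb)
        valid = np.isfinite(res.r_values)
        assert np.all(res.r_values[valid] >= 0)
        assert np.all(res.r_values[valid] <= 2 + 1e-12)

    def test_grid_mismatch_rejected(self, gt_volume):
        other = IntensityVolume(15, gt_volume.dq, np.ones((15,) * 3))
        with pytest.raises(ValueError):
            shell_r_factor(gt_volume, other)

    def test_empty_shell_warns(self, gt_volume):
        spec = ShellSpec(edges=np.array([10.0, 11.0]))  # beyond support
        with pytest.warns(UserWarning):
            shell_r_factor(gt_volume, gt_volume, spec)

    def test_region_ordering_low_q_better(self, gt_volume, desk_pixmap):
        # a mildly perturbed volume: relative error grows with q because the
        # signal decays; the low-q region mean stays below the high-q one
        rng = np.random.default_rng(5)
        noisy = gt_volume.copy()
        noise = 1.0 + 0.2 * rng.standard_normal(noisy.values.shape)
        noisy.values = noisy.values * np.clip(noise, 0.1, None) + 0.01 * np.median(
            noisy.values
        )
        res = shell_r_factor(noisy, gt_volume)
        assert res.region_means["A"] <= res.region_means["C"]


class TestAlignment:
    def test_self_alignment_is_identity(self, gt_volume):
        aligned, rot, corr = align_to_reference(
            gt_volume, gt_volume, sample_rotations(2)
        )
        assert corr == pytest.approx(1.0, abs=1e-9)
        assert rot.angle < 1e-6

    def test_recovers_known_rotation(self, gt_volume, rot_level2):
        g = Rotation.from_axis_angle([0.3, -1.0, 0.5], 0.6)
        rotated = rotate_volume(gt_volume, g)
        aligned, rec, corr = align_to_reference(rotated, gt_volume, rot_level2)
        # the aligning rotation undoes g (volume resampling convention)
        assert quat_angle(rec.q, g.inverse().q) < 0.05
        assert corr > 0.97

    def test_noisy_rotated_copy_beats_other_candidates(self, gt_volume, rot_level2):
        rng = np.random.default_rng(1)
        g = Rotation.from_axis_angle([1.0, 0.2, 0.1], 0.8)
        noisy = rotate_volume(gt_volume, g)
        noisy.values *= 1.0 + 0.2 * rng.standard_normal(noisy.values.shape).clip(-0.9, 0.9)
        aligned, rec, corr = align_to_reference(
            noisy, gt_volume, rot_level2, refine=False
        )
        # exhaustive-search oracle: the returned candidate is the argmax
        from spisim.metrics import _sqrt_pearson
        from spisim.rotations import quat_to_matrix
        from spisim import _kernels as K

        ax = gt_volume.q_axis()
        qx, qy, qz = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = (qx**2 + qy**2 + qz**2) <= gt_volume.q_support**2
        coords = np.stack([qx[mask], qy[mask], qz[mask]], axis=1)
        ref = gt_volume.values[mask]
        scores = []
        for q in rot_level2.quats[::37]:  # spot-check a subset
            vals = K.sample_volume(
                noisy.values, np.ascontiguousarray(coords @ quat_to_matrix(q)),
                noisy.dq,
            )
            scores.append(_sqrt_pearson(vals, ref))
        # candidates are canonicalized/rounded inside the search, so allow
        # float-level slack far below any inter-candidate score gap
        assert corr >= max(scores) - 1e-6


class TestPatternLogLikelihood:
    def test_single_pixel_hand_value(self):
        # one pixel, W = 2, K = 3: ln(2^3 e^-2 / 3!) = 3 ln 2 - 2 - ln 6
        geom = DetectorGeometry(
            n_fast=1, n_slow=1, pixel_size_um=100.0, distance_mm=100.0,
            photon_energy_kev=4.96,
        )
        pm = build_pixel_map(geom)
        vol = IntensityVolume(3, 0.01, np.full((3, 3, 3), 2.0))
        pat = DiffractionPattern(n_pixels=1, indices=[0], counts=[3])
        ll = pattern_log_likelihood(pat, vol, Rotation.identity(), pm)
        assert ll == pytest.approx(np.log(8 * np.exp(-2) / 6), abs=1e-9)

    def test_empty_pattern_closed_form(self, gt_volume, desk_pixmap):
        from spisim.diffraction import slice_pattern

        pat = DiffractionPattern(
            n_pixels=desk_pixmap.n_pixels, indices=[], counts=[]
        )
        rot = Rotation.from_axis_angle([0, 0, 1], 0.3)
        ll = pattern_log_likelihood(pat, gt_volume, rot, desk_pixmap)
        expected = -slice_pattern(gt_volume, rot, desk_pixmap).sum()
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_poisson_scale_identity(self, gt_volume, desk_pixmap):
        rng = np.random.default_rng(2)
        rot = Rotation.from_axis_angle([1, 1, 1], 0.7)
        pat = simulate_pattern(gt_volume, rot, desk_pixmap, 300.0, rng)
        c = 1.7
        scaled = gt_volume.copy()
        scaled.values *= c
        from spisim.diffraction import slice_pattern

        l1 = pattern_log_likelihood(pat, gt_volume, rot, desk_pixmap)
        l2 = pattern_log_likelihood(pat, scaled, rot, desk_pixmap)
        w_sum = slice_pattern(gt_volume, rot, desk_pixmap).sum()
        expected_shift = pat.n_photons * np.log(c) - (c - 1) * w_sum
        assert l2 - l1 == pytest.approx(expected_shift, rel=1e-9)


class TestOrientationPosterior:
    def test_isotropic_volume_gives_prior(self, desk_pixmap, rot_level2, desk_grid):
        edge, dq = desk_grid
        vol = IntensityVolume(edge, dq, np.full((edge,) * 3, 0.5))
        pat = DiffractionPattern(
            n_pixels=desk_pixmap.n_pixels, indices=[10, 200], counts=[2, 1]
        )
        post = orientation_posterior(pat, vol, rot_level2, desk_pixmap)
        assert np.allclose(post, rot_level2.weights, rtol=1e-9)

    def test_normalization(self, gt_volume, sentinels_500, desk_pixmap, rot_level4):
        vol = _normalized_volume(gt_volume, sentinels_500, rot_level4, desk_pixmap)
        post = orientation_posterior(
            sentinels_500.pattern(0), vol, rot_level4, desk_pixmap
        )
        assert post.sum() == pytest.approx(1.0, abs=1e-10)

    def test_concentration_at_high_photon_budget(self, gt_volume, desk_pixmap, rot_level4):
        rng = np.random.default_rng(2)
        true = Rotation.from_axis_angle([1, 2, -1], 0.9)
        pat = simulate_pattern(gt_volume, true, desk_pixmap, 1e5, rng)
        # scale the volume to the pattern budget before the Poisson likelihood
        tomo = expand(gt_volume, rot_level4, desk_pixmap)
        scale = 1e5 / float(tomo.sum(axis=1) @ rot_level4.weights)
        vol = gt_volume.copy()
        vol.values *= scale
        post = orientation_posterior(pat, vol, rot_level4, desk_pixmap)
        fr = quat_from_axis_angle([0, 0, 1], np.pi)
        from spisim.rotations import quat_multiply

        d = np.minimum(
            quat_angle(rot_level4.quats, true.q),
            quat_angle(rot_level4.quats, quat_multiply(true.q, fr)),
        )
        # one sampling step at level 4 is ~0.16 rad
        assert post[d < 0.25].sum() > 0.99


class TestThetaSq:
    def test_hand_expansion_of_two_point_posteriors(self):
        # both posteriors 1/2-1/2 on two rotations a quotient angle phi apart
        # => Theta^2 = phi^2 / 2
        a = Rotation.identity().q
        phi = 0.4
        b = quat_from_axis_angle([0, 1, 0], phi)
        supp = np.stack([a, b])[None]  # (1, 2, 4)
        prob = np.array([[0.5, 0.5]])
        ident = np.array([[1.0, 0, 0, 0]])
        val = _kernels.od_objective(
            np.ascontiguousarray(ident), supp, prob, supp, prob, ident, ident
        )[0]
        assert val == pytest.approx(phi**2 / 2.0, abs=1e-12)

    def test_coincident_concentrated_posteriors_give_zero(
        self, gt_volume, sentinels_500, desk_pixmap, rot_level4
    ):
        vol = _normalized_volume(gt_volume, sentinels_500, rot_level4, desk_pixmap)
        s = make_group("C1")
        z = make_group("friedel_z")
        val = theta_sq(
            sentinels_500.pattern(0), vol, vol,
            Rotation.identity(), Rotation.identity(),
            rot_level4, s, z, desk_pixmap,
        )
        # same volume on both sides: the double sum collapses toward zero,
        # bounded by the posterior spread around the decoded orientation
        assert val < 0.1

    def test_truncation_consistency(
        self, gt_volume, sentinels_500, desk_pixmap, rot_level4
    ):
        vol = _normalized_volume(gt_volume, sentinels_500, rot_level4, desk_pixmap)
        s = make_group("C1")
        z = make_group("friedel_z")
        args = (
            sentinels_500.pattern(1), vol, vol,
            Rotation.identity(), Rotation.identity(),
            rot_level4, s, z, desk_pixmap,
        )
        v_trunc = theta_sq(*args, eps=1e-6)
        v_full = theta_sq(*args, eps=0.0)
        # the dropped tail carries <= eps posterior mass; its contribution is
        # bounded by pi^2 * eps in absolute terms
        assert v_trunc == pytest.approx(v_full, rel=1e-3, abs=np.pi**2 * 2e-6)


@pytest.fixture(scope="module")
def od_config():
    return ODConfig(level=4, search_level=2)


class TestDisconcurrence:

    def test_self_od_of_ideal_volume_is_small(
        self, gt_volume, sentinels_500, desk_pixmap, od_config
    ):
        od = disconcurrence(gt_volume, None, sentinels_500, od_config, desk_pixmap)
        assert 0.0 < od.delta_theta < 0.12
        # invariant: delta_theta^2 equals the mean of per-sentinel Theta^2
        assert od.delta_theta**2 == pytest.approx(
            np.mean(od.per_sentinel_theta**2), rel=1e-6
        )

    def test_scale_invariance_of_normalized_pipeline(
        self, gt_volume, sentinels_500, desk_pixmap, od_config
    ):
        scaled = gt_volume.copy()
        scaled.values *= 123.4
        od1 = disconcurrence(gt_volume, None, sentinels_500, od_config, desk_pixmap)
        od2 = disconcurrence(scaled, None, sentinels_500, od_config, desk_pixmap)
        assert od2.delta_theta == pytest.approx(od1.delta_theta, rel=1e-9)

    def test_global_rotation_absorbed_within_sampling_step(
        self, gt_volume, toy_particle, sentinels_500, desk_pixmap, od_config, desk_grid
    ):
        # rotate the particle exactly (atom-level) and compare the two-volume
        # OD against the self-OD: the overall-orientation search must absorb
        # the rotation up to the grid discretization
        edge, dq = desk_grid
        g = Rotation.from_axis_angle([0.3, -1.0, 0.5], 0.6)
        rotated = AtomicStructure(
            toy_particle.elements, toy_particle.positions @ g.matrix.T,
            toy_particle.scale,
        )
        w_rot = ideal_intensity_volume(rotated, edge, dq)
        od_self = disconcurrence(gt_volume, None, sentinels_500, od_config, desk_pixmap)
        od_cross = disconcurrence(w_rot, gt_volume, sentinels_500, od_config, desk_pixmap)
        step = 0.63 / od_config.level
        assert abs(od_cross.delta_theta - od_self.delta_theta) < 1.5 * step

    def test_c2_symmetry_never_increases_od(self, desk_pixmap, desk_grid):
        edge, dq = desk_grid
        sym = make_toy_particle(40, 30.0, seed=13, symmetrize=True)
        vol = ideal_intensity_volume(sym, edge, dq)
        sent = generate_dataset(
            vol, 40, desk_pixmap, 500.0, seed=17, meta={"role": "sentinel"}
        )
        od_c1 = disconcurrence(
            vol, None, sent, ODConfig(level=4, search_level=2), desk_pixmap
        )
        od_c2 = disconcurrence(
            vol, None, sent,
            ODConfig(point_group=make_group("C2"), level=4, search_level=2),
            desk_pixmap,
        )
        assert od_c2.delta_theta <= od_c1.delta_theta + 1e-9

    def test_sentinel_reuse_guard(self, gt_volume, desk_pixmap, od_config):
        sent = generate_dataset(gt_volume, 10, desk_pixmap, 500.0, seed=23)
        sent.meta["used_for_reconstruction"] = True
        with pytest.raises(ValueError, match="reconstruction"):
            disconcurrence(gt_volume, None, sent, od_config, desk_pixmap)
        cfg = ODConfig(level=2, search_level=2, allow_reused_sentinels=True)
        with pytest.warns(UserWarning):
            disconcurrence(gt_volume, None, sent, cfg, desk_pixmap)

    def test_empty_sentinels_rejected(self, gt_volume, desk_pixmap, od_config):
        from spisim.diffraction import PatternSet

        empty = PatternSet(
            geom=desk_pixmap.geom,
            indices=np.empty(0, np.int64), counts=np.empty(0, np.int64),
            offsets=np.array([0], dtype=np.int64),
            orientations=np.empty((0, 4)),
        )
        with pytest.raises(ValueError):
            disconcurrence(gt_volume, None, empty, od_config, desk_pixmap)
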