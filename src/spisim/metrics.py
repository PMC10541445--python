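"""Reconstruction-quality metrics.

Two complementary measures of how well an intensity volume was recovered
from unoriented patterns:

* the **shell R-factor** ``R(s)`` — a per-|q|-shell normalized absolute
  difference between the square-root intensities of a reconstruction and an
  ideal reference, with named low/mid/high-q regions
  (A: q < 0.08 1/A, B: 0.08 <= q < 0.1, C: q >= 0.1);

* the **orientation disconcurrence (OD)** ``delta_theta`` — the
  posterior-weighted RMS angular disagreement in decoding the orientations
  of held-out "sentinel" patterns against one or two volumes, minimized
  over the unknown overall orientation between the volumes, with rotations
  compared on the quotient of SO(3) by the particle point group ``s`` and
  the Friedel group ``z``.  Self-OD evaluates a single volume against
  itself and is the default mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

from . import _kernels
from .diffraction import DiffractionPattern, IntensityVolume, PatternSet, slice_pattern
from .emc import expand
from .geometry import PixelMap, build_pixel_map
from .rotations import (
    Rotation,
    RotationSet,
    SymmetryGroup,
    make_group,
    quat_canonical,
    quat_from_axis_angle,
    quat_multiply,
    sample_rotations,
)

__all__ = [
    "ShellSpec",
    "ShellRFactorResult",
    "ODConfig",
    "ODResult",
    "shell_r_factor",
    "align_to_reference",
    "rotate_volume",
    "pattern_log_likelihood",
    "orientation_posterior",
    "theta_sq",
    "disconcurrence",
]


# ---------------------------------------------------------------------------
# shell R-factor
# ---------------------------------------------------------------------------

@dataclass
class ShellSpec:
    """q-shell binning with named regions.

    Default shell width is one grid q-pitch; region boundaries default to
    the standard 0.08 / 0.10 1/A split.
    """

    edges: np.ndarray
    regions: dict = field(
        default_factory=lambda: {
            "A": (0.0, 0.08),
            "B": (0.08, 0.10),
            "C": (0.10, np.inf),
        }
    )

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("shell edges must be strictly increasing")

    @classmethod
    def for_volume(cls, volume: IntensityVolume, qmax: float | None = None) -> "ShellSpec":
        qmax = qmax if qmax is not None else volume.q_support
        n = int(np.ceil(qmax / volume.dq))
        return cls(edges=np.arange(n + 1) * volume.dq)


@dataclass
class ShellRFactorResult:
    shell_q: np.ndarray  # shell centre |q|
    r_values: np.ndarray  # R(s) per shell (nan where skipped)
    voxel_counts: np.ndarray
    region_means: dict  # region name -> voxel-weighted mean R

    def region(self, name: str) -> float:
        return self.region_means[name]


def shell_r_factor(
    volume: IntensityVolume,
    reference: IntensityVolume,
    shells: ShellSpec | None = None,
) -> ShellRFactorResult:
    """Per-shell R-factor between a reconstruction and the ideal reference.

    R(s) = sum_{q in s} | sqrt(I)/sum sqrt(I) - sqrt(I_ideal)/sum sqrt(I_ideal) |,
    evaluated over the voxels whose |q| falls in the shell.  Scale-invariant
    per shell; bounded by [0, 2].  Region means are voxel-weighted means of
    the shell values within each named q region.
    """
    if volume.edge != reference.edge or not np.isclose(volume.dq, reference.dq):
        raise ValueError("volume and reference must share the same grid")
    shells = shells or ShellSpec.for_volume(volume)
    qmag = volume.qmag_grid().ravel()
    a = np.sqrt(np.maximum(volume.values.ravel(), 0.0))
    b = np.sqrt(np.maximum(reference.values.ravel(), 0.0))
    bins = np.digitize(qmag, shells.edges) - 1
    n_shells = len(shells.edges) - 1
    r_values = np.full(n_shells, np.nan)
    counts = np.zeros(n_shells, dtype=np.int64)
    for s in range(n_shells):
        mask = bins == s
        counts[s] = mask.sum()
        if counts[s] == 0:
            warnings.warn(f"shell {s} is empty; skipped")
            continue
        sa = a[mask].sum()
        sb = b[mask].sum()
        if sa == 0 or sb == 0:
            warnings.warn(f"shell {s} has zero intensity; skipped")
            continue
        r_values[s] = np.abs(a[mask] / sa - b[mask] / sb).sum()
    mid = 0.5 * (shells.edges[:-1] + shells.edges[1:])
    region_means = {}
    for name, (lo, hi) in shells.regions.items():
        sel = (mid >= lo) & (mid < hi) & np.isfinite(r_values)
        if sel.any():
            region_means[name] = float(
                np.average(r_values[sel], weights=counts[sel])
            )
        else:
            region_means[name] = np.nan
    return ShellRFactorResult(
        shell_q=mid, r_values=r_values, voxel_counts=counts,
        region_means=region_means,
    )


# ---------------------------------------------------------------------------
# volume alignment
# ---------------------------------------------------------------------------

def rotate_volume(volume: IntensityVolume, rotation: Rotation) -> IntensityVolume:
    """Resample the volume rotated by ``rotation`` (trilinear, 0 outside)."""
    ax = volume.q_axis()
    qx, qy, qz = np.meshgrid(ax, ax, ax, indexing="ij")
    coords = np.stack([qx.ravel(), qy.ravel(), qz.ravel()], axis=1)
    coords = np.ascontiguousarray(coords @ rotation.matrix)  # R^T q per row
    vals = _kernels.sample_volume(volume.values, coords, volume.dq)
    return IntensityVolume(volume.edge, volume.dq, vals.reshape(volume.values.shape))


def _sqrt_pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.sqrt(np.maximum(a, 0.0))
    b = np.sqrt(np.maximum(b, 0.0))
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / den) if den > 0 else 0.0


def align_to_reference(
    volume: IntensityVolume,
    reference: IntensityVolume,
    rotations: RotationSet | None = None,
    s: SymmetryGroup | None = None,
    z: SymmetryGroup | None = None,
    refine: bool = True,
) -> tuple[IntensityVolume, Rotation, float]:
    """Exhaustively align a volume to a reference over a rotation grid.

    Maximizes the Pearson correlation of square-root intensities (dynamic
    range compressed) inside the supported q ball, searching the grid with
    candidates optionally expanded by the symmetry groups, then locally
    refining around the best candidate.  Returns (aligned volume, rotation,
    correlation).
    """
    if volume.edge != reference.edge or not np.isclose(volume.dq, reference.dq):
        raise ValueError("volume and reference must share the same grid")
    rotations = rotations or sample_rotations(3)
    cands = [rotations.quats]
    if s is not None or z is not None:
        sq = s.quats if s is not None else np.array([[1.0, 0, 0, 0]])
        zq = z.quats if z is not None else np.array([[1.0, 0, 0, 0]])
        expanded = quat_multiply(
            quat_multiply(sq[:, None, None, :], rotations.quats[None, :, None, :]),
            zq[None, None, :, :],
        ).reshape(-1, 4)
        cands = [quat_canonical(expanded)]
    cand_quats = np.unique(np.round(np.concatenate(cands), 9), axis=0)

    ax = volume.q_axis()
    qx, qy, qz = np.meshgrid(ax, ax, ax, indexing="ij")
    mask = (qx**2 + qy**2 + qz**2) <= volume.q_support**2
    coords_base = np.stack([qx[mask], qy[mask], qz[mask]], axis=1)
    ref_vals = reference.values[mask]

    from .rotations import quat_to_matrix

    best_corr, best_q = -np.inf, None
    for q in cand_quats:
        m = quat_to_matrix(q)
        vals = _kernels.sample_volume(
            volume.values, np.ascontiguousarray(coords_base @ m), volume.dq
        )
        c = _sqrt_pearson(vals, ref_vals)
        if c > best_corr:
            best_corr, best_q = c, q

    if refine:
        def objective(delta):
            dq_ = quat_from_axis_angle(
                delta / max(np.linalg.norm(delta), 1e-12),
                np.linalg.norm(delta),
            )
            q = quat_multiply(dq_, best_q)
            m = quat_to_matrix(q / np.linalg.norm(q))
            vals = _kernels.sample_volume(
                volume.values, np.ascontiguousarray(coords_base @ m), volume.dq
            )
            return -_sqrt_pearson(vals, ref_vals)

        # initial simplex spans about half a grid step so the local search
        # can actually cross the sampling discretization
        step = 0.5 * 0.63 / rotations.level
        simplex = np.vstack([np.zeros(3), step * np.eye(3)])
        res = minimize(
            objective, np.zeros(3), method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 200,
                     "initial_simplex": simplex},
        )
        if -res.fun > best_corr:
            delta = res.x
            dq_ = quat_from_axis_angle(
                delta / max(np.linalg.norm(delta), 1e-12), np.linalg.norm(delta)
            )
            best_q = quat_multiply(dq_, best_q)
            best_q /= np.linalg.norm(best_q)
            best_corr = -res.fun

    rot = Rotation(best_q)
    return rotate_volume(volume, rot), rot, best_corr


# ---------------------------------------------------------------------------
# orientation posteriors and disconcurrence
# ---------------------------------------------------------------------------

def pattern_log_likelihood(
    pattern: DiffractionPattern,
    volume: IntensityVolume,
    orientation: Rotation,
    pixmap: PixelMap,
) -> float:
    """Full Poisson log-probability of a pattern at one orientation.

    sum_t [K_t ln W_t - W_t - ln K_t!] with the 0 ln 0 = 0 convention;
    -inf where a photon lands on a zero-intensity pixel.
    """
    w = slice_pattern(volume, orientation, pixmap)
    k = pattern.dense().astype(float)
    if np.any(k < 0):
        raise ValueError("negative photon counts")
    out = -w.sum() - gammaln(k[pattern.indices] + 1.0).sum()
    wk = w[pattern.indices]
    if np.any(wk <= 0):
        return -np.inf
    out += float(pattern.counts @ np.log(wk))
    return float(out)


def _posterior_from_logliks(
    logliks: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    a = logliks + np.log(np.maximum(weights, 1e-300))
    if np.all(~np.isfinite(a)):
        raise ValueError("all orientations have -inf likelihood")
    m = a.max()
    p = np.exp(a - m)
    return p / p.sum()


def orientation_posterior(
    pattern: DiffractionPattern,
    volume: IntensityVolume,
    rotations: RotationSet,
    pixmap: PixelMap,
) -> np.ndarray:
    """Posterior probability of each grid rotation given a pattern.

    Uniform prior over SO(3) discretized with the sampling weights as
    quadrature weights; log-sum-exp stabilized; sums to 1.
    """
    tomo = expand(volume, rotations, pixmap)
    log_tomo = np.log(np.maximum(tomo, 1e-300))
    logliks = _kernels.sparse_logliks_poisson(
        log_tomo, tomo.sum(axis=1),
        pattern.indices, pattern.counts.astype(float),
        np.array([0, len(pattern.indices)], dtype=np.int64),
    )[0]
    return _posterior_from_logliks(logliks, rotations.weights)


def _truncate_support(
    probs: np.ndarray, eps: float, cap: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Smallest index set holding >= 1 - eps posterior mass (optionally
    capped in size), with renormalized probabilities."""
    order = np.argsort(probs)[::-1]
    cum = np.cumsum(probs[order])
    k = int(np.searchsorted(cum, 1.0 - eps)) + 1
    if cap is not None:
        k = min(k, cap)
    idx = order[:k]
    p = probs[idx]
    return idx, p / p.sum()


@dataclass
class ODConfig:
    """Settings for the disconcurrence computation.

    ``level`` sets the rotation grid used to discretize the posteriors;
    ``search_level`` the coarse grid for the overall-orientation search.
    ``eps`` is the posterior-mass truncation; supports are additionally
    capped (largest-probability first) to keep the double sums tractable.
    """

    point_group: SymmetryGroup = field(default_factory=lambda: make_group("C1"))
    friedel_group: SymmetryGroup = field(default_factory=lambda: make_group("friedel_z"))
    level: int = 4
    search_level: int = 2
    eps: float = 1e-6
    grid_support_cap: int = 32
    refine_support_cap: int = 256
    allow_reused_sentinels: bool = False


@dataclass
class ODResult:
    delta_theta: float  # radians
    per_sentinel_theta: np.ndarray  # sqrt(Theta^2) per sentinel at optimum
    overall_orientation: Rotation  # optimal Omega_A (Omega_B = identity)

    def __post_init__(self) -> None:
        assert self.delta_theta >= 0


def _pattern_arrays(sentinels: PatternSet):
    return (
        sentinels.indices,
        sentinels.counts.astype(float),
        sentinels.offsets,
    )


def _sentinel_posteriors(
    volume: IntensityVolume,
    sentinels: PatternSet,
    rotations: RotationSet,
    pixmap: PixelMap,
) -> np.ndarray:
    """(n_sentinels, n_rot) posterior matrix under one volume."""
    tomo = expand(volume, rotations, pixmap)
    log_tomo = np.log(np.maximum(tomo, 1e-300))
    idx, cnt, off = _pattern_arrays(sentinels)
    logliks = _kernels.sparse_logliks_poisson(log_tomo, tomo.sum(axis=1), idx, cnt, off)
    logw = np.log(np.maximum(rotations.weights, 1e-300))
    a = logliks + logw
    m = a.max(axis=1, keepdims=True)
    p = np.exp(a - m)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _padded_supports(
    posteriors: np.ndarray, quats: np.ndarray, eps: float, cap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Truncated supports padded to a rectangle for the numba kernel."""
    supports = []
    probs = []
    for row in posteriors:
        idx, p = _truncate_support(row, eps, cap)
        supports.append(quats[idx])
        probs.append(p)
    k = max(len(p) for p in probs)
    n = len(probs)
    sq = np.zeros((n, k, 4))
    sp = np.zeros((n, k))
    for i, (qq, pp) in enumerate(zip(supports, probs)):
        sq[i, : len(pp)] = qq
        sp[i, : len(pp)] = pp
    return sq, sp


def theta_sq(
    pattern: DiffractionPattern,
    volume_a: IntensityVolume,
    volume_b: IntensityVolume,
    omega_a: Rotation,
    omega_b: Rotation,
    rotations: RotationSet,
    s: SymmetryGroup,
    z: SymmetryGroup,
    pixmap: PixelMap,
    eps: float = 1e-6,
) -> float:
    """Posterior-weighted mean squared quotient angle for one pattern.

    The overall orientations shift the posteriors: the double integral runs
    over the grid posteriors with the quotient distance evaluated between
    ``Omega_alpha Omega_A^-1`` and ``Omega_beta Omega_B^-1``.
    """
    pa = orientation_posterior(pattern, volume_a, rotations, pixmap)
    pb = (
        pa
        if volume_b is volume_a
        else orientation_posterior(pattern, volume_b, rotations, pixmap)
    )
    ia, wa = _truncate_support(pa, eps)
    ib, wb = _truncate_support(pb, eps)
    qb = quat_multiply(rotations.quats[ib], omega_b.inverse().q)
    supp_a = rotations.quats[ia][None]
    supp_b = qb[None]
    val = _kernels.od_objective(
        np.ascontiguousarray(omega_a.q[None]),
        np.ascontiguousarray(supp_a), np.ascontiguousarray(wa[None]),
        np.ascontiguousarray(supp_b), np.ascontiguousarray(wb[None]),
        np.ascontiguousarray(s.quats), np.ascontiguousarray(z.quats),
    )
    return float(val[0])


def _normalize_to_budget(
    volume: IntensityVolume,
    sentinels: PatternSet,
    rotations: RotationSet,
    pixmap: PixelMap,
) -> IntensityVolume:
    """Scale W so the mean expected photons over orientations matches the
    sentinel mean photon count (the global-scale nuisance of the Poisson
    likelihood is otherwise unidentified)."""
    tomo = expand(volume, rotations, pixmap)
    mean_expected = float(tomo.sum(axis=1) @ rotations.weights)
    mean_counts = float(sentinels.photon_counts.mean())
    out = volume.copy()
    if mean_expected > 0:
        out.values *= mean_counts / mean_expected
    return out


def disconcurrence(
    volume_a: IntensityVolume,
    volume_b: IntensityVolume | None,
    sentinels: PatternSet,
    odcfg: ODConfig | None = None,
    pixmap: PixelMap | None = None,
) -> ODResult:
    """Orientation disconcurrence between two volumes (self-OD if one).

    delta_theta = min over the overall orientation of
    sqrt(mean over sentinels of Theta^2), where Theta^2 is the
    posterior-weighted mean squared quotient angle between the orientation
    decodings of each sentinel under the two volumes.  By bi-invariance of
    the geodesic metric one overall orientation is absorbed: Omega_B is
    fixed to the identity and the minimization runs over Omega_A only
    (coarse grid search plus local refinement).
    """
    odcfg = odcfg or ODConfig()
    if sentinels.n_patterns == 0:
        raise ValueError("sentinel set is empty")
    if sentinels.meta.get("used_for_reconstruction"):
        if not odcfg.allow_reused_sentinels:
            raise ValueError(
                "sentinel patterns were used for reconstruction; pass "
                "allow_reused_sentinels=True to override"
            )
        warnings.warn("sentinels were used for reconstruction; OD may overfit")
    pixmap = pixmap or build_pixel_map(sentinels.geom)
    rotations = sample_rotations(odcfg.level)
    self_mode = volume_b is None or volume_b is volume_a

    va = _normalize_to_budget(volume_a, sentinels, rotations, pixmap)
    post_a = _sentinel_posteriors(va, sentinels, rotations, pixmap)
    if self_mode:
        post_b = post_a
    else:
        vb = _normalize_to_budget(volume_b, sentinels, rotations, pixmap)
        post_b = _sentinel_posteriors(vb, sentinels, rotations, pixmap)

    sq = np.ascontiguousarray(odcfg.point_group.quats)
    zq = np.ascontiguousarray(odcfg.friedel_group.quats)

    # coarse grid search over Omega_A
    ga, pa = _padded_supports(post_a, rotations.quats, odcfg.eps, odcfg.grid_support_cap)
    gb, pb = _padded_supports(post_b, rotations.quats, odcfg.eps, odcfg.grid_support_cap)
    cand = sample_rotations(odcfg.search_level).quats
    obj = _kernels.od_objective(
        np.ascontiguousarray(cand), ga, pa, gb, pb, sq, zq
    )
    best = int(np.argmin(obj))
    best_q = cand[best]

    # refinement with full (capped) supports
    fa, qa_p = _padded_supports(post_a, rotations.quats, odcfg.eps, odcfg.refine_support_cap)
    fb, qb_p = _padded_supports(post_b, rotations.quats, odcfg.eps, odcfg.refine_support_cap)

    def objective(delta):
        nrm = np.linalg.norm(delta)
        dq_ = quat_from_axis_angle(delta / max(nrm, 1e-12), nrm)
        q = quat_multiply(dq_, best_q)
        q = q / np.linalg.norm(q)
        return float(
            _kernels.od_objective(
                np.ascontiguousarray(q[None]), fa, qa_p, fb, qb_p, sq, zq
            )[0]
        )

    step = 0.5 * 0.63 / odcfg.search_level
    simplex = np.vstack([np.zeros(3), step * np.eye(3)])
    res = minimize(
        objective, np.zeros(3), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 120,
                 "initial_simplex": simplex},
    )
    base = float(
        _kernels.od_objective(
            np.ascontiguousarray(best_q[None]), fa, qa_p, fb, qb_p, sq, zq
        )[0]
    )
    if res.fun < base:
        nrm = np.linalg.norm(res.x)
        dq_ = quat_from_axis_angle(res.x / max(nrm, 1e-12), nrm)
        best_q = quat_multiply(dq_, best_q)
        best_q /= np.linalg.norm(best_q)
        best_val = float(res.fun)
    else:
        best_val = base

    # per-sentinel Theta at the optimum
    per = np.empty(sentinels.n_patterns)
    for i in range(sentinels.n_patterns):
        per[i] = _kernels.od_objective(
            np.ascontiguousarray(best_q[None]),
            fa[i : i + 1], qa_p[i : i + 1], fb[i : i + 1], qb_p[i : i + 1],
            sq, zq,
        )[0]
    return ODResult(
        delta_theta=float(np.sqrt(max(best_val, 0.0))),
        per_sentinel_theta=np.sqrt(np.maximum(per, 0.0)),
        overall_orientation=Rotation(best_q),
    )
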