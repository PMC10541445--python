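"""SO(3) machinery for orientation recovery.

Quaternion algebra, the 600-cell-based weighted sampling of the rotation
group indexed by a refinement level ``num_div``, geodesic and
symmetry-quotient distances, and small finite symmetry groups.

Rotations are unit quaternions ``(w, x, y, z)`` canonicalized to the
hemisphere ``w >= 0`` (ties broken by the first nonzero component being
positive); ``q`` and ``-q`` denote the same rotation.

The sampling scheme subdivides each of the 600 tetrahedral cells of the
600-cell at refinement level ``n``, projects the barycentric lattice points
onto the unit 3-sphere, and identifies antipodes.  The sample count is
``10 (5 n^3 + n)``; each sample carries a quadrature weight proportional to
the summed projected volume of its incident sub-simplices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rotation",
    "RotationSet",
    "SymmetryGroup",
    "compose",
    "geodesic_angle",
    "quotient_angle",
    "sample_rotations",
    "rotation_count",
    "make_group",
    "random_rotations",
]

_CANON_TOL = 1e-12


# ---------------------------------------------------------------------------
# quaternion primitives (array level; w-first convention)
# ---------------------------------------------------------------------------

def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product of quaternions (broadcasting, w-first)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    w1, x1, y1, z1 = np.moveaxis(a, -1, 0)
    w2, x2, y2, z2 = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ],
        axis=-1,
    )


def quat_conjugate(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] *= -1.0
    return out


def quat_canonical(q: np.ndarray, tol: float = _CANON_TOL) -> np.ndarray:
    """Map quaternions to the canonical hemisphere (first nonzero coord > 0)."""
    q = np.atleast_2d(np.asarray(q, dtype=float))
    signs = np.where(np.abs(q) > tol, np.sign(q), 0.0)
    first = np.argmax(signs != 0.0, axis=1)
    s = signs[np.arange(len(q)), first]
    s = np.where(s == 0.0, 1.0, s)
    return q * s[:, None]


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (or stack of matrices) from unit quaternion(s)."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = np.moveaxis(q, -1, 0)
    m = np.empty(q.shape[:-1] + (3, 3))
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - z * w)
    m[..., 0, 2] = 2 * (x * z + y * w)
    m[..., 1, 0] = 2 * (x * y + z * w)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - x * w)
    m[..., 2, 0] = 2 * (x * z - y * w)
    m[..., 2, 1] = 2 * (y * z + x * w)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def quat_from_axis_angle(axis, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        if angle == 0.0:
            return np.array([1.0, 0.0, 0.0, 0.0])
        raise ValueError("rotation axis must be nonzero")
    axis = axis / n
    half = 0.5 * angle
    return np.concatenate([[np.cos(half)], np.sin(half) * axis])


def quat_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Geodesic angle between rotations given as quaternions (broadcasting)."""
    d = np.abs(np.sum(np.asarray(a) * np.asarray(b), axis=-1))
    return 2.0 * np.arccos(np.clip(d, -1.0, 1.0))


# ---------------------------------------------------------------------------
# Rotation / group types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rotation:
    """A rotation stored as a canonical unit quaternion (w, x, y, z)."""

    q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float).reshape(4)
        n = np.linalg.norm(q)
        if not np.isfinite(n) or n == 0:
            raise ValueError("quaternion must be finite and nonzero")
        q = quat_canonical(q / n)[0]
        object.__setattr__(self, "q", q)

    @classmethod
    def identity(cls) -> "Rotation":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def from_axis_angle(cls, axis, angle: float) -> "Rotation":
        return cls(quat_from_axis_angle(axis, angle))

    @property
    def matrix(self) -> np.ndarray:
        return quat_to_matrix(self.q)

    @property
    def angle(self) -> float:
        """Rotation angle about the rotation axis, in [0, pi]."""
        return float(2.0 * np.arccos(np.clip(abs(self.q[0]), -1.0, 1.0)))

    def inverse(self) -> "Rotation":
        return Rotation(quat_conjugate(self.q))

    def apply(self, vec: np.ndarray) -> np.ndarray:
        """Rotate 3-vector(s) by this rotation."""
        return np.asarray(vec) @ self.matrix.T


def compose(a: Rotation, b: Rotation) -> Rotation:
    """The rotation 'first b, then a' (quaternion product a * b)."""
    return Rotation(quat_multiply(a.q, b.q))


def geodesic_angle(a: Rotation, b: Rotation) -> float:
    """Geodesic distance on SO(3): the angle of a^-1 b, in [0, pi]."""
    return float(quat_angle(a.q, b.q))


@dataclass(frozen=True)
class SymmetryGroup:
    """A small finite rotation group (cyclic, or the Friedel pair about z)."""

    name: str
    elements: tuple[Rotation, ...]

    def __post_init__(self) -> None:
        if len(self.elements) == 0:
            raise ValueError("symmetry group must not be empty")

    @property
    def quats(self) -> np.ndarray:
        return np.stack([r.q for r in self.elements])

    def __len__(self) -> int:
        return len(self.elements)


def make_group(name: str, axis=(0.0, 0.0, 1.0)) -> SymmetryGroup:
    """Build a named finite group.

    ``C1`` is trivial; ``Cn`` is the cyclic group of order n about ``axis``;
    ``friedel_z`` is {identity, pi about the beam (z) axis} and accounts for
    the Friedel ambiguity of flat-Ewald patterns.
    """
    if name == "friedel_z":
        elems = (Rotation.identity(), Rotation.from_axis_angle((0, 0, 1), np.pi))
        return SymmetryGroup(name=name, elements=elems)
    if name.startswith("C") and name[1:].isdigit():
        n = int(name[1:])
        if n < 1:
            raise ValueError(f"invalid cyclic order in {name!r}")
        elems = tuple(
            Rotation.from_axis_angle(axis, 2.0 * np.pi * k / n) for k in range(n)
        )
        return SymmetryGroup(name=name, elements=elems)
    raise ValueError(f"unknown symmetry group {name!r}")


def quotient_angle(
    a: Rotation, b: Rotation, s: SymmetryGroup, z: SymmetryGroup
) -> float:
    """Distance on SO(3) / (s, z): min over sigma in s, zeta in z of the
    geodesic angle between sigma * a * zeta and b."""
    sa = quat_multiply(s.quats[:, None, :], a.q)  # (|s|, 1, 4)
    saz = quat_multiply(sa, z.quats[None, :, :])  # (|s|, |z|, 4)
    return float(np.min(quat_angle(saz, b.q)))


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """n quaternions uniform on SO(3) (Gaussian 4-vectors, normalized)."""
    q = rng.standard_normal((n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return quat_canonical(q)


# ---------------------------------------------------------------------------
# 600-cell sampling
# ---------------------------------------------------------------------------

def rotation_count(level: int) -> int:
    """Closed-form sample count of the 600-cell sampling at a given level."""
    return 10 * (5 * level**3 + level)


def _vertices_600cell() -> np.ndarray:
    """The 120 unit quaternions forming the vertices of the 600-cell."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts: list[np.ndarray] = []
    for i in range(4):
        for s in (1.0, -1.0):
            v = np.zeros(4)
            v[i] = s
            verts.append(v)
    for signs in itertools.product((0.5, -0.5), repeat=4):
        verts.append(np.array(signs))
    base = np.array([phi / 2.0, 0.5, 1.0 / (2.0 * phi), 0.0])
    for perm in itertools.permutations(range(4)):
        # keep even permutations only
        parity = sum(
            1
            for i in range(4)
            for j in range(i + 1, 4)
            if perm[i] > perm[j]
        )
        if parity % 2:
            continue
        for signs in itertools.product((1.0, -1.0), repeat=3):
            v = np.empty(4)
            k = 0
            for slot, src in enumerate(perm):
                if src == 3:  # the zero entry
                    v[slot] = 0.0
                else:
                    v[slot] = base[src] * signs[k]
                    k += 1
            verts.append(v)
    out = np.unique(np.round(np.array(verts), 12), axis=0)
    if len(out) != 120:  # pragma: no cover - construction sanity
        raise RuntimeError(f"600-cell vertex construction produced {len(out)} points")
    return out


def _cells_600cell(verts: np.ndarray) -> np.ndarray:
    """The 600 tetrahedral cells as index quadruples (mutually adjacent)."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    dots = verts @ verts.T
    adj = dots > (phi / 2.0 - 1e-6)
    np.fill_diagonal(adj, False)
    nbrs = [np.nonzero(adj[i])[0] for i in range(len(verts))]
    cells = []
    for i in range(len(verts)):
        ni = nbrs[i][nbrs[i] > i]
        for j in ni:
            common_ij = ni[adj[j, ni] & (ni > j)]
            for k in common_ij:
                common_ijk = common_ij[adj[k, common_ij] & (common_ij > k)]
                for l in common_ijk:
                    cells.append((i, j, k, l))
    cells = np.array(cells, dtype=np.int64)
    if len(cells) != 600:  # pragma: no cover - construction sanity
        raise RuntimeError(f"600-cell cell enumeration produced {len(cells)} cells")
    return cells


def _simplex_lattice(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric lattice of a tetrahedron at level n.

    Returns (points, index) where points is (P, 3) integer offsets
    (u1, u2, u3) with u >= 0 and sum <= n, and index is a dense lookup
    cube of shape (n+1,)*3 mapping offsets to point ids (-1 outside).
    """
    pts = []
    index = -np.ones((n + 1, n + 1, n + 1), dtype=np.int64)
    for u1 in range(n + 1):
        for u2 in range(n + 1 - u1):
            for u3 in range(n + 1 - u1 - u2):
                index[u1, u2, u3] = len(pts)
                pts.append((u1, u2, u3))
    return np.array(pts, dtype=np.int64), index


def _subtet_indices(n: int, index: np.ndarray) -> np.ndarray:
    """The n^3 sub-tetrahedra of the level-n lattice, as point-id quadruples.

    The dilated tetrahedron decomposes into corner tets, four tets per
    octahedral cell (fanned around one diagonal), and reversed tets.
    """
    e = np.eye(3, dtype=np.int64)
    tets: list[tuple[int, int, int, int]] = []

    def pid(u):
        return index[u[0], u[1], u[2]]

    for u1 in range(n):
        for u2 in range(n - u1):
            for u3 in range(n - u1 - u2):
                v = np.array([u1, u2, u3])
                s = u1 + u2 + u3
                a, b, c = v + e[0], v + e[1], v + e[2]
                # corner tet
                tets.append((pid(v), pid(a), pid(b), pid(c)))
                if s <= n - 2:
                    d, ee, f = v + e[0] + e[1], v + e[0] + e[2], v + e[1] + e[2]
                    tets.append((pid(a), pid(f), pid(b), pid(d)))
                    tets.append((pid(a), pid(f), pid(d), pid(ee)))
                    tets.append((pid(a), pid(f), pid(ee), pid(c)))
                    tets.append((pid(a), pid(f), pid(c), pid(b)))
                    if s <= n - 3:
                        g = v + e[0] + e[1] + e[2]
                        tets.append((pid(d), pid(ee), pid(f), pid(g)))
    out = np.array(tets, dtype=np.int64)
    if len(out) != n**3:  # pragma: no cover - construction sanity
        raise RuntimeError(f"simplex subdivision produced {len(out)} != n^3 cells")
    return out


@dataclass
class RotationSet:
    """Weighted quaternion sampling of SO(3) at refinement level ``level``."""

    level: int
    quats: np.ndarray  # (N, 4), canonical hemisphere
    weights: np.ndarray  # (N,), positive, sums to 1

    def __len__(self) -> int:
        return len(self.quats)

    @property
    def rotations(self) -> list[Rotation]:
        return [Rotation(q) for q in self.quats]

    @property
    def matrices(self) -> np.ndarray:
        return quat_to_matrix(self.quats)

    def to_hdf5(self, group) -> None:
        group.create_dataset("quaternions", data=self.quats)
        group.create_dataset("weights", data=self.weights)
        group.attrs["level"] = self.level


def sample_rotations(level: int) -> RotationSet:
    """Weighted SO(3) sampling at refinement level ``num_div = level``.

    Subdivides each tetrahedral cell of the 600-cell with the barycentric
    lattice at the given level, projects the lattice points to the unit
    3-sphere, identifies antipodal quaternions, and weights every sample by
    the summed projected volume of its incident sub-simplices (normalized to
    sum 1).  The count is exactly ``10 (5 level^3 + level)``.
    """
    if level < 1:
        raise ValueError("refinement level must be >= 1")
    n = int(level)
    verts = _vertices_600cell()
    cells = _cells_600cell(verts)
    lat, index = _simplex_lattice(n)
    tets = _subtet_indices(n, index)
    # barycentric coordinates (b0, b1, b2, b3) of the lattice points
    bary = np.empty((len(lat), 4))
    bary[:, 0] = n - lat.sum(axis=1)
    bary[:, 1:] = lat
    bary /= n

    all_pts = np.empty((len(cells) * len(lat), 4))
    all_w = np.empty(len(cells) * len(lat))
    flat_tets = tets.ravel()
    for ci, cell in enumerate(cells):
        pts = bary @ verts[cell]  # (P, 4)
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        p = pts[tets]  # (M, 4, 4)
        edges = p[:, 1:, :] - p[:, :1, :]  # (M, 3, 4)
        cen = p.mean(axis=1)
        cen /= np.linalg.norm(cen, axis=1, keepdims=True)
        mats = np.concatenate([edges, cen[:, None, :]], axis=1)  # (M, 4, 4)
        vol = np.abs(np.linalg.det(mats)) / 6.0
        pw = np.zeros(len(lat))
        np.add.at(pw, flat_tets, np.repeat(vol / 4.0, 4))
        sl = slice(ci * len(lat), (ci + 1) * len(lat))
        all_pts[sl] = pts
        all_w[sl] = pw

    all_pts = quat_canonical(all_pts, tol=1e-7)
    keys = np.round(all_pts / 1e-7).astype(np.int64)
    uniq, first, inverse = np.unique(
        keys, axis=0, return_index=True, return_inverse=True
    )
    quats = all_pts[first]
    weights = np.bincount(inverse, weights=all_w, minlength=len(uniq))
    weights /= weights.sum()
    order = np.lexsort(quats.T[::-1])  # deterministic ordering
    return RotationSet(level=n, quats=quats[order], weights=weights[order])
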