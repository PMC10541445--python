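"""Numba kernels for the compute-heavy inner loops.

Everything here operates on plain arrays; the public modules wrap these in
typed interfaces.  Volumes are cubic grids with odd edge length ``E`` whose
central voxel is q = 0; positions are converted to fractional voxel
coordinates ``q / dq + (E - 1) / 2`` before interpolation.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

_F = "float64"


@njit(cache=False)
def phase_sums(qvecs, positions, scales, out_re, out_im):
    """Accumulate sum_j s_j exp(2 pi i q.r_j) over atoms, per q vector."""
    two_pi = 2.0 * np.pi
    for m in range(qvecs.shape[0]):
        acc_re = 0.0
        acc_im = 0.0
        qx = qvecs[m, 0]
        qy = qvecs[m, 1]
        qz = qvecs[m, 2]
        for j in range(positions.shape[0]):
            ph = two_pi * (
                qx * positions[j, 0] + qy * positions[j, 1] + qz * positions[j, 2]
            )
            acc_re += scales[j] * np.cos(ph)
            acc_im += scales[j] * np.sin(ph)
        out_re[m] = acc_re
        out_im[m] = acc_im


@njit(cache=False, inline="always")
def _trilinear_one(vol, edge, x, y, z):
    """Sample a cubic volume at fractional voxel coordinates (0 outside)."""
    if x < 0.0 or y < 0.0 or z < 0.0:
        return 0.0
    if x > edge - 1.0 or y > edge - 1.0 or z > edge - 1.0:
        return 0.0
    i0 = int(np.floor(x))
    j0 = int(np.floor(y))
    k0 = int(np.floor(z))
    if i0 == edge - 1:
        i0 -= 1
    if j0 == edge - 1:
        j0 -= 1
    if k0 == edge - 1:
        k0 -= 1
    fx = x - i0
    fy = y - j0
    fz = z - k0
    c000 = vol[i0, j0, k0]
    c100 = vol[i0 + 1, j0, k0]
    c010 = vol[i0, j0 + 1, k0]
    c001 = vol[i0, j0, k0 + 1]
    c110 = vol[i0 + 1, j0 + 1, k0]
    c101 = vol[i0 + 1, j0, k0 + 1]
    c011 = vol[i0, j0 + 1, k0 + 1]
    c111 = vol[i0 + 1, j0 + 1, k0 + 1]
    return (
        c000 * (1 - fx) * (1 - fy) * (1 - fz)
        + c100 * fx * (1 - fy) * (1 - fz)
        + c010 * (1 - fx) * fy * (1 - fz)
        + c001 * (1 - fx) * (1 - fy) * fz
        + c110 * fx * fy * (1 - fz)
        + c101 * fx * (1 - fy) * fz
        + c011 * (1 - fx) * fy * fz
        + c111 * fx * fy * fz
    )


@njit(cache=False)
def sample_volume(vol, coords, dq):
    """Trilinear samples of a volume at q-space coordinates (M, 3)."""
    edge = vol.shape[0]
    half = (edge - 1) / 2.0
    out = np.empty(coords.shape[0])
    for m in range(coords.shape[0]):
        x = coords[m, 0] / dq + half
        y = coords[m, 1] / dq + half
        z = coords[m, 2] / dq + half
        out[m] = _trilinear_one(vol, edge, x, y, z)
    return out


@njit(cache=False)
def expand_tomograms(vol, dq, mats, qpix):
    """One tomogram per rotation: W evaluated at R^T q_pixel.

    ``mats`` are rotation matrices (R, 3, 3); ``qpix`` is (T, 3).
    Returns (R, T).
    """
    edge = vol.shape[0]
    half = (edge - 1) / 2.0
    n_rot = mats.shape[0]
    n_pix = qpix.shape[0]
    tomo = np.empty((n_rot, n_pix))
    for r in range(n_rot):
        m = mats[r]
        for t in range(n_pix):
            qx = qpix[t, 0]
            qy = qpix[t, 1]
            qz = qpix[t, 2]
            # v = R^T q
            vx = m[0, 0] * qx + m[1, 0] * qy + m[2, 0] * qz
            vy = m[0, 1] * qx + m[1, 1] * qy + m[2, 1] * qz
            vz = m[0, 2] * qx + m[1, 2] * qy + m[2, 2] * qz
            tomo[r, t] = _trilinear_one(
                vol, edge, vx / dq + half, vy / dq + half, vz / dq + half
            )
    return tomo


@njit(cache=False)
def compress_tomograms(tomo, rot_weights, dq, mats, qpix, edge):
    """Adjoint of expand: deposit tomogram pixels into the voxel grid.

    Each tomogram pixel deposits value * rotation-weight with trilinear
    weights at R^T q_pixel; returns (numerator, denominator) grids so the
    caller can form the weighted mean.
    """
    half = (edge - 1) / 2.0
    num = np.zeros((edge, edge, edge))
    den = np.zeros((edge, edge, edge))
    n_rot = mats.shape[0]
    n_pix = qpix.shape[0]
    for r in range(n_rot):
        m = mats[r]
        wr = rot_weights[r]
        for t in range(n_pix):
            qx = qpix[t, 0]
            qy = qpix[t, 1]
            qz = qpix[t, 2]
            vx = (m[0, 0] * qx + m[1, 0] * qy + m[2, 0] * qz) / dq + half
            vy = (m[0, 1] * qx + m[1, 1] * qy + m[2, 1] * qz) / dq + half
            vz = (m[0, 2] * qx + m[1, 2] * qy + m[2, 2] * qz) / dq + half
            if vx < 0 or vy < 0 or vz < 0:
                continue
            if vx > edge - 1.0 or vy > edge - 1.0 or vz > edge - 1.0:
                continue
            i0 = int(np.floor(vx))
            j0 = int(np.floor(vy))
            k0 = int(np.floor(vz))
            if i0 == edge - 1:
                i0 -= 1
            if j0 == edge - 1:
                j0 -= 1
            if k0 == edge - 1:
                k0 -= 1
            fx = vx - i0
            fy = vy - j0
            fz = vz - k0
            val = tomo[r, t]
            for di in range(2):
                wi = fx if di == 1 else 1.0 - fx
                for dj in range(2):
                    wj = fy if dj == 1 else 1.0 - fy
                    for dk in range(2):
                        wk = fz if dk == 1 else 1.0 - fz
                        w = wi * wj * wk * wr
                        num[i0 + di, j0 + dj, k0 + dk] += w * val
                        den[i0 + di, j0 + dj, k0 + dk] += w
    return num, den


@njit(cache=False)
def sparse_logliks(log_tomo, log_totals, idx, cnt, offsets, photon_counts):
    """Multinomial log-likelihood of each sparse pattern under each tomogram.

    L[d, r] = sum_t K_t log tomo[r, t] - N_d log(sum_t tomo[r, t]);
    per-pattern constants (log K!) are dropped.
    """
    n_pat = offsets.shape[0] - 1
    n_rot = log_tomo.shape[0]
    out = np.empty((n_pat, n_rot))
    for d in range(n_pat):
        lo = offsets[d]
        hi = offsets[d + 1]
        nd = photon_counts[d]
        for r in range(n_rot):
            acc = 0.0
            for j in range(lo, hi):
                acc += cnt[j] * log_tomo[r, idx[j]]
            out[d, r] = acc - nd * log_totals[r]
    return out


@njit(cache=False)
def sparse_logliks_poisson(log_tomo, totals, idx, cnt, offsets):
    """Poisson log-likelihood up to the pattern-only log K! constant.

    L[d, r] = sum_t K_t log tomo[r, t] - sum_t tomo[r, t].
    """
    n_pat = offsets.shape[0] - 1
    n_rot = log_tomo.shape[0]
    out = np.empty((n_pat, n_rot))
    for d in range(n_pat):
        lo = offsets[d]
        hi = offsets[d + 1]
        for r in range(n_rot):
            acc = 0.0
            for j in range(lo, hi):
                acc += cnt[j] * log_tomo[r, idx[j]]
            out[d, r] = acc - totals[r]
    return out


@njit(cache=False)
def weighted_pattern_sums(resp, idx, cnt, offsets, n_pix, thresh):
    """M-step accumulation: tomo_new[r] = sum_d P_dr K_d, wsum[r] = sum_d P_dr.

    Responsibilities below ``thresh`` are skipped (they contribute nothing
    at double precision).
    """
    n_pat, n_rot = resp.shape
    tomo = np.zeros((n_rot, n_pix))
    wsum = np.zeros(n_rot)
    for d in range(n_pat):
        lo = offsets[d]
        hi = offsets[d + 1]
        for r in range(n_rot):
            p = resp[d, r]
            if p < thresh:
                continue
            wsum[r] += p
            for j in range(lo, hi):
                tomo[r, idx[j]] += p * cnt[j]
    return tomo, wsum


@njit(cache=False, inline="always")
def _qmul(a, b, out):
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]


@njit(cache=False)
def od_objective(
    cand,  # (M, 4) candidate overall orientations Omega_A
    supp_a,  # (S, Ka, 4) per-sentinel support quaternions, padded
    prob_a,  # (S, Ka) probabilities (0 padding)
    supp_b,  # (S, Kb, 4)
    prob_b,  # (S, Kb)
    sq,  # (Ns, 4) point-group quaternions
    zq,  # (Nz, 4) Friedel-group quaternions
):
    """Mean over sentinels of Theta^2 as a function of the overall
    orientation Omega_A (Omega_B fixed at identity).

    Theta^2 = sum_ab p_a p_b min_{sigma, zeta}
              angle(sigma (Omega_a Omega_A^-1) zeta, Omega_b)^2
    """
    n_cand = cand.shape[0]
    n_sent = supp_a.shape[0]
    out = np.zeros(n_cand)
    tmp1 = np.empty(4)
    tmp2 = np.empty(4)
    u = np.empty(4)
    cinv = np.empty(4)
    for m in range(n_cand):
        cinv[0] = cand[m, 0]
        cinv[1] = -cand[m, 1]
        cinv[2] = -cand[m, 2]
        cinv[3] = -cand[m, 3]
        total = 0.0
        for s in range(n_sent):
            acc = 0.0
            for ia in range(supp_a.shape[1]):
                pa = prob_a[s, ia]
                if pa <= 0.0:
                    continue
                _qmul(supp_a[s, ia], cinv, u)
                for ib in range(supp_b.shape[1]):
                    pb = prob_b[s, ib]
                    if pb <= 0.0:
                        continue
                    best = -1.0
                    for isig in range(sq.shape[0]):
                        _qmul(sq[isig], u, tmp1)
                        for izet in range(zq.shape[0]):
                            _qmul(tmp1, zq[izet], tmp2)
                            d = (
                                tmp2[0] * supp_b[s, ib, 0]
                                + tmp2[1] * supp_b[s, ib, 1]
                                + tmp2[2] * supp_b[s, ib, 2]
                                + tmp2[3] * supp_b[s, ib, 3]
                            )
                            if d < 0.0:
                                d = -d
                            if d > best:
                                best = d
                    if best > 1.0:
                        best = 1.0
                    ang = 2.0 * np.arccos(best)
                    acc += pa * pb * ang * ang
            total += acc
        out[m] = total / n_sent
    return out
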