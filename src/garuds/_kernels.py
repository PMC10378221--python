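"""Compiled brute-force pair kernels.

All kernels accumulate in a fixed order (outer agent index ``i``
ascending, inner index ``j`` ascending, the self term taken when
``j == i``), with IEEE semantics (no fastmath), so a pure-Python double
loop written in the same order reproduces every float bit-for-bit.  The
self alignment term is taken as exactly 1.0 rather than ``s_i . s_i`` so
that an isolated agent has mean alignment exactly 1.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def adjacency_stats(pos, ori, L, r0):
    """All-pairs metric adjacency with neighbor counts and mean alignments.

    Returns ``(adjacency bool (N,N), counts int64 (N,), mean_align float64 (N,))``.
    Neighborhood rule: strict minimum-image distance < r0; self included.
    """
    N = pos.shape[0]
    adj = np.zeros((N, N), dtype=np.bool_)
    counts = np.zeros(N, dtype=np.int64)
    lsum = np.zeros(N, dtype=np.float64)
    r02 = r0 * r0
    for i in range(N):
        for j in range(N):
            if j == i:
                adj[i, i] = True
                counts[i] += 1
                lsum[i] += 1.0
                continue
            dx = pos[i, 0] - pos[j, 0]
            dx -= L[0] * np.floor(dx / L[0] + 0.5)
            dy = pos[i, 1] - pos[j, 1]
            dy -= L[1] * np.floor(dy / L[1] + 0.5)
            dz = pos[i, 2] - pos[j, 2]
            dz -= L[2] * np.floor(dz / L[2] + 0.5)
            if dx * dx + dy * dy + dz * dz < r02:
                adj[i, j] = True
                counts[i] += 1
                lsum[i] += (
                    ori[i, 0] * ori[j, 0] + ori[i, 1] * ori[j, 1] + ori[i, 2] * ori[j, 2]
                )
    return adj, counts, lsum / counts


@njit(cache=True)
def garud_forces(pos, ori, L, r0, probe, alpha, beta, gamma, delta):
    """Utility-seeking forces for every agent, plus neighborhood stats.

    For each agent the positional force is a central-difference estimate of
    the effective-utility gradient from six candidate displacements of
    length ``probe`` along +/- each axis (the agent's own neighbor count
    and alignment sum are recomputed for each candidate); the row is zeroed
    when no candidate strictly improves the utility.  The orientational
    force is ``gamma * sum_j n_ij s_j`` (self included).

    Requires ``r0 + 2*probe`` below half the smallest box edge so that no
    candidate displacement changes the relevant periodic image (the caller
    validates this).

    Returns ``(f_pos (N,3), f_ori (N,3), counts (N,), mean_align (N,))``.
    """
    N = pos.shape[0]
    r02 = r0 * r0
    reach2 = (r0 + probe) * (r0 + probe)
    counts = np.zeros(N, dtype=np.int64)
    lsum = np.zeros(N, dtype=np.float64)
    cand_n = np.zeros((N, 6), dtype=np.int64)
    cand_ls = np.zeros((N, 6), dtype=np.float64)
    f_ori = np.zeros((N, 3), dtype=np.float64)
    for i in range(N):
        for j in range(N):
            if j == i:
                counts[i] += 1
                lsum[i] += 1.0
                for c in range(6):
                    cand_n[i, c] += 1
                    cand_ls[i, c] += 1.0
                f_ori[i, 0] += gamma * ori[i, 0]
                f_ori[i, 1] += gamma * ori[i, 1]
                f_ori[i, 2] += gamma * ori[i, 2]
                continue
            dx = pos[i, 0] - pos[j, 0]
            dx -= L[0] * np.floor(dx / L[0] + 0.5)
            dy = pos[i, 1] - pos[j, 1]
            dy -= L[1] * np.floor(dy / L[1] + 0.5)
            dz = pos[i, 2] - pos[j, 2]
            dz -= L[2] * np.floor(dz / L[2] + 0.5)
            d2 = dx * dx + dy * dy + dz * dz
            if d2 >= reach2:
                continue  # too far to matter for base or any candidate
            dot = ori[i, 0] * ori[j, 0] + ori[i, 1] * ori[j, 1] + ori[i, 2] * ori[j, 2]
            if d2 < r02:
                counts[i] += 1
                lsum[i] += dot
                f_ori[i, 0] += gamma * ori[j, 0]
                f_ori[i, 1] += gamma * ori[j, 1]
                f_ori[i, 2] += gamma * ori[j, 2]
            # six candidate displacements of agent i: c = 2*axis (+), 2*axis+1 (-)
            for axis in range(3):
                if axis == 0:
                    base = dx
                    rest = dy * dy + dz * dz
                elif axis == 1:
                    base = dy
                    rest = dx * dx + dz * dz
                else:
                    base = dz
                    rest = dx * dx + dy * dy
                dplus = base + probe
                if dplus * dplus + rest < r02:
                    cand_n[i, 2 * axis] += 1
                    cand_ls[i, 2 * axis] += dot
                dminus = base - probe
                if dminus * dminus + rest < r02:
                    cand_n[i, 2 * axis + 1] += 1
                    cand_ls[i, 2 * axis + 1] += dot
    f_pos = np.zeros((N, 3), dtype=np.float64)
    for i in range(N):
        nb = float(counts[i])
        h0 = alpha * nb - beta * nb * nb + gamma * lsum[i] - delta * np.log(nb)
        improving = False
        dh = np.zeros(6, dtype=np.float64)
        for c in range(6):
            m = float(cand_n[i, c])
            hc = alpha * m - beta * m * m + gamma * cand_ls[i, c] - delta * np.log(m)
            dh[c] = hc - h0
            if dh[c] > 0.0:
                improving = True
        if improving:
            for axis in range(3):
                f_pos[i, axis] = (dh[2 * axis] - dh[2 * axis + 1]) / (2.0 * probe)
    return f_pos, f_ori, counts, lsum / counts
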