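"""Independent brute-force oracles used across the test suite.

These re-derive neighborhoods, utilities and candidate-displacement
directions with plain Python double loops, written in the same
accumulation order as the production kernels so that floating-point sums
can be compared bit-for-bit where the contract demands exactness.
"""

from __future__ import annotations

import numpy as np


def adjacency_oracle(pos, ori, L, r0):
    """All-pairs neighborhood oracle: strict distance < r0, self included."""
    N = pos.shape[0]
    adj = np.zeros((N, N), dtype=bool)
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


def agent_utility_oracle(pos, ori, i, L, r0, alpha, beta, gamma, delta, displacement=None):
    """Utility of agent i, optionally with its position displaced,
    recomputing its neighborhood from scratch."""
    p = pos.copy()
    if displacement is not None:
        p[i] = p[i] + displacement
    n, lsum = 1, 1.0
    for j in range(len(p)):
        if j == i:
            continue
        d = p[i] - p[j]
        d = d - L * np.floor(d / L + 0.5)
        if float(d @ d) < r0 * r0:
            n += 1
            lsum += float(ori[i] @ ori[j])
    return alpha * n - beta * n * n + gamma * lsum - delta * np.log(n)


def position_direction_oracle(pos, ori, L, r0, probe, alpha, beta, gamma, delta):
    """Exhaustive candidate-displacement oracle for the positional
    direction of increased utility (central differences over +/- probe
    along each axis; zero when no candidate improves)."""
    N = pos.shape[0]
    out = np.zeros((N, 3))
    for i in range(N):
        h0 = agent_utility_oracle(pos, ori, i, L, r0, alpha, beta, gamma, delta)
        dh = {}
        for axis in range(3):
            for sign in (+1, -1):
                disp = np.zeros(3)
                disp[axis] = sign * probe
                hc = agent_utility_oracle(
                    pos, ori, i, L, r0, alpha, beta, gamma, delta, displacement=disp
                )
                dh[(axis, sign)] = hc - h0
        if max(dh.values()) > 0:
            for axis in range(3):
                out[i, axis] = (dh[(axis, +1)] - dh[(axis, -1)]) / (2.0 * probe)
    return out
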