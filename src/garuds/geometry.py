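"""Periodic-box geometry and metric neighborhoods.

Agents live in a rectangular box with periodic boundary conditions; all
inter-agent displacements are measured under the minimum-image convention
(the shortest displacement among all periodic images).  Two agents are
neighbors when their minimum-image distance is strictly below the
interaction radius ``r0``, and every agent is additionally its own
neighbor, so the neighbor count ``n_i`` is always at least 1 and the mean
alignment ``l_i`` of an isolated agent is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

__all__ = [
    "BoxSpec",
    "FlockState",
    "AdjacencySummary",
    "GeometryError",
    "minimum_image_displacement",
    "wrap_coordinates",
    "wrap_positions",
    "build_adjacency",
]


class GeometryError(ValueError):
    """Invalid geometric configuration (box, radius, or coordinates)."""


@dataclass(frozen=True)
class BoxSpec:
    """A periodic rectangular simulation box.

    Parameters
    ----------
    edge_lengths
        Edge lengths ``(Lx, Ly, Lz)``, all strictly positive.  A scalar is
        broadcast to a cube.
    periodic
        Kept for interface clarity; this package always treats the box as
        periodic.
    """

    edge_lengths: np.ndarray
    periodic: bool = True

    def __post_init__(self) -> None:
        edges = np.atleast_1d(np.asarray(self.edge_lengths, dtype=np.float64))
        if edges.size == 1:
            edges = np.repeat(edges, 3)
        if edges.shape != (3,):
            raise GeometryError(f"edge_lengths must be a scalar or 3-vector, got shape {edges.shape}")
        if not np.all(np.isfinite(edges)) or np.any(edges <= 0):
            raise GeometryError(f"edge lengths must be finite and positive, got {edges}")
        edges.setflags(write=False)
        object.__setattr__(self, "edge_lengths", edges)

    @property
    def max_minimum_image_distance(self) -> float:
        """Upper bound on any minimum-image distance: half the box diagonal."""
        return 0.5 * float(np.linalg.norm(self.edge_lengths))


@dataclass
class FlockState:
    """Positions and velocities of all agents at one time-step.

    Positions are stored wrapped into ``[0, L)`` per axis; orientations
    ``s_i = v_i / |v_i|`` are derived, so every velocity must have strictly
    positive magnitude.
    """

    positions: np.ndarray
    velocities: np.ndarray
    time_index: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.float64)
        vel = np.asarray(self.velocities, dtype=np.float64)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] < 1:
            raise ValueError(f"positions must be (N, 3) with N >= 1, got {pos.shape}")
        if vel.shape != pos.shape:
            raise ValueError(f"velocities shape {vel.shape} != positions shape {pos.shape}")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(vel))):
            raise ValueError("positions and velocities must be finite")
        if np.any(np.linalg.norm(vel, axis=1) == 0.0):
            raise ValueError("every velocity must have strictly positive magnitude")
        if self.time_index < 0:
            raise ValueError("time_index must be nonnegative")
        self.positions = pos
        self.velocities = vel

    @property
    def n_agents(self) -> int:
        return self.positions.shape[0]

    @property
    def speeds(self) -> np.ndarray:
        return np.linalg.norm(self.velocities, axis=1)

    @property
    def orientations(self) -> np.ndarray:
        """Unit velocity directions, shape (N, 3)."""
        return self.velocities / self.speeds[:, None]

    def copy(self) -> "FlockState":
        return FlockState(self.positions.copy(), self.velocities.copy(), self.time_index)


@dataclass(frozen=True)
class AdjacencySummary:
    """Metric neighborhood structure derived from one :class:`FlockState`.

    ``adjacency[i, j]`` is True when j is within ``r0`` of i (minimum
    image, strict inequality) or ``j == i``; ``neighbor_counts[i]`` is the
    row sum and ``mean_alignments[i]`` the neighborhood-averaged dot
    product of unit orientations (self term included).
    """

    adjacency: np.ndarray
    neighbor_counts: np.ndarray
    mean_alignments: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.adjacency, self.neighbor_counts, self.mean_alignments):
            np.asarray(arr).setflags(write=False)


def minimum_image_displacement(p: np.ndarray, q: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Shortest displacement from ``q`` to ``p`` under periodic wrapping.

    Each component of the result lies in ``[-L/2, L/2)``.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise GeometryError("minimum_image_displacement requires finite input")
    L = box.edge_lengths
    d = p - q
    return d - L * np.floor(d / L + 0.5)


def wrap_coordinates(coords: np.ndarray, box: BoxSpec) -> np.ndarray:
    """Map raw coordinates into the primary cell ``[0, L)`` per axis."""
    L = box.edge_lengths
    wrapped = np.mod(np.asarray(coords, dtype=np.float64), L)
    # np.mod can return L itself for tiny negative inputs; fold exactly.
    return np.where(wrapped >= L, wrapped - L, wrapped)


def wrap_positions(state: FlockState, box: BoxSpec) -> FlockState:
    """Return a state with positions wrapped into the primary cell.

    Minimum-image displacements between agents are unchanged.
    """
    return FlockState(wrap_coordinates(state.positions, box), state.velocities.copy(), state.time_index)


def _check_radius(r0: float, box: BoxSpec) -> None:
    if not (r0 > 0):
        raise GeometryError(f"r0 must be positive, got {r0}")
    if r0 >= float(np.min(box.edge_lengths)) / 2.0:
        raise GeometryError(
            f"r0={r0} must be < half the smallest box edge "
            f"({float(np.min(box.edge_lengths)) / 2.0}) for unambiguous minimum-image neighborhoods"
        )


def build_adjacency(state: FlockState, r0: float, box: BoxSpec) -> AdjacencySummary:
    """Compute the metric adjacency, neighbor counts and mean alignments.

    The production path is a compiled brute-force all-pairs double loop;
    its accumulation order (ascending ``j`` for each ``i``) is part of the
    contract so that independent re-implementations agree exactly.
    """
    _check_radius(r0, box)
    adj, counts, mean_align = _kernels.adjacency_stats(
        state.positions, state.orientations, box.edge_lengths, float(r0)
    )
    return AdjacencySummary(adj, counts, mean_align)
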