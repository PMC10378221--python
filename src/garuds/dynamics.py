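"""Time-stepping for utility-driven agents and the Reynolds boids baseline.

Both models share the same protocol: agents start at random positions and
orientations inside a central block of the periodic box, speeds are
clamped into a fixed band after every velocity update, and an isotropic
noise term of magnitude ``noise_level * |v_i|`` models imperfect
decisions.  Per step the order of operations is: neighborhoods -> forces
-> velocity update -> speed clamp -> position update -> wrap, which makes
the speed band a hard invariant of every recorded state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import _kernels
from .geometry import (
    BoxSpec,
    FlockState,
    GeometryError,
    build_adjacency,
    minimum_image_displacement,
    wrap_coordinates,
)
from .observables import SUMMARY_COLUMNS, Snapshot, TrajectoryRecord
from .utility import DEFAULT_PROBE_FRACTION, GarudParams, effective_utility

__all__ = [
    "ReynoldsParams",
    "SimConfig",
    "initialize_flock",
    "clamp_speed",
    "reynolds_step",
    "garud_step",
    "run_simulation",
    "random_unit_vectors",
]


@dataclass(frozen=True)
class ReynoldsParams:
    """Weights of the three boid rules plus shared dynamics constants.

    ``a`` scales cohesion (pull toward the neighborhood), ``b`` separation
    (push away from neighbors), ``c`` alignment (velocity matching).
    """

    a: float
    b: float
    c: float
    r0: float = 3.0
    noise_level: float = 0.01
    speed_min: float = 0.5
    speed_max: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.speed_min <= self.speed_max):
            raise ValueError("require 0 < speed_min <= speed_max")
        if self.noise_level < 0:
            raise ValueError("noise_level must be nonnegative")
        if not (self.r0 > 0):
            raise ValueError("r0 must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Simulation protocol: box, initialization, speed band, noise, steps.

    Defaults follow the reference protocol: 1000 agents in a periodic
    20x20x20 box, neighborhood radius 3, initial positions inside a
    central 10x10x10 block, speeds in [0.5, 1], noise level 0.01 and
    time-step 0.01.
    """

    n_agents: int = 1000
    box_edge: float = 20.0
    r0: float = 3.0
    init_block_edge: float = 10.0
    speed_min: float = 0.5
    speed_max: float = 1.0
    noise_level: float = 0.01
    dt: float = 0.01
    n_steps: int = 1000
    seed: int = 0
    model: str = "garud"
    snapshot_stride: int = 0
    probe_fraction: float = DEFAULT_PROBE_FRACTION
    normalize_force: bool = False

    def __post_init__(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if not (self.box_edge > 0 and self.dt > 0):
            raise ValueError("box_edge and dt must be positive")
        if not (0 < self.init_block_edge <= self.box_edge):
            raise ValueError("init_block_edge must be in (0, box_edge]")
        if not (0 < self.speed_min <= self.speed_max):
            raise ValueError("require 0 < speed_min <= speed_max")
        if self.noise_level < 0 or self.n_steps < 0 or self.snapshot_stride < 0:
            raise ValueError("noise_level, n_steps, snapshot_stride must be nonnegative")
        if self.model not in ("garud", "reynolds"):
            raise ValueError(f"model must be 'garud' or 'reynolds', got {self.model!r}")
        if not (self.r0 > 0) or self.r0 >= self.box_edge / 2.0:
            raise ValueError("require 0 < r0 < box_edge/2 (unambiguous minimum image)")
        if not (0 < self.probe_fraction < 1):
            raise ValueError("probe_fraction must be in (0, 1)")

    @property
    def box(self) -> BoxSpec:
        return BoxSpec(np.full(3, self.box_edge))

    @property
    def probe(self) -> float:
        return self.probe_fraction * self.r0


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    """Directions uniform on the unit sphere (normalized Gaussians)."""
    v = rng.standard_normal((n, 3))
    norms = np.linalg.norm(v, axis=1)
    while np.any(norms == 0.0):  # pragma: no cover - measure zero
        bad = norms == 0.0
        v[bad] = rng.standard_normal((int(bad.sum()), 3))
        norms = np.linalg.norm(v, axis=1)
    return v / norms[:, None]


def initialize_flock(config: SimConfig, rng_seed) -> FlockState:
    """Random initial state inside the central block of the box.

    Positions are uniform in a ``init_block_edge``-cube centered in the
    box; orientations are uniform on the sphere; speeds uniform in the
    configured band.  Deterministic given the seed (draw order: positions,
    orientations, speeds).
    """
    rng = _as_rng(rng_seed)
    low = (config.box_edge - config.init_block_edge) / 2.0
    pos = low + rng.random((config.n_agents, 3)) * config.init_block_edge
    ori = random_unit_vectors(rng, config.n_agents)
    speeds = rng.uniform(config.speed_min, config.speed_max, config.n_agents)
    return FlockState(pos, ori * speeds[:, None], time_index=0)


def clamp_speed(v: np.ndarray, speed_min: float, speed_max: float) -> np.ndarray:
    """Project a velocity's magnitude onto [speed_min, speed_max], keeping
    its direction.  A zero vector has no direction and is rejected."""
    v = np.asarray(v, dtype=np.float64)
    norm = float(np.linalg.norm(v))
    if norm == 0.0:
        raise ValueError("cannot clamp a zero velocity (orientation undefined)")
    return v * (min(max(norm, speed_min), speed_max) / norm)


def _clamp_speeds(
    vel: np.ndarray, speed_min: float, speed_max: float, rng: np.random.Generator | None
) -> np.ndarray:
    norms = np.linalg.norm(vel, axis=1)
    zero = norms == 0.0
    if np.any(zero):
        # Degenerate: a force exactly cancelled the velocity. Re-draw a
        # random orientation at speed_min to keep s_i defined.
        warnings.warn(f"re-drew {int(zero.sum())} zero-velocity agent(s)", RuntimeWarning)
        redraw_rng = rng if rng is not None else np.random.default_rng(0)
        vel = vel.copy()
        vel[zero] = random_unit_vectors(redraw_rng, int(zero.sum())) * speed_min
        norms = np.linalg.norm(vel, axis=1)
    clamped = np.clip(norms, speed_min, speed_max)
    return vel * (clamped / norms)[:, None]


def _noise(vel: np.ndarray, noise_level: float, rng: np.random.Generator | None) -> np.ndarray:
    if rng is None or noise_level == 0.0:
        return np.zeros_like(vel)
    units = random_unit_vectors(rng, vel.shape[0])
    return units * (noise_level * np.linalg.norm(vel, axis=1))[:, None]


def reynolds_step(
    state: FlockState,
    params: ReynoldsParams,
    dt: float,
    box: BoxSpec,
    rng: np.random.Generator | None = None,
) -> FlockState:
    """One boids update: cohesion + separation + alignment + noise.

    The velocity increment is
    ``[(a/n_i) sum_j n_ij (r_j - r_i) + b sum_j n_ij (r_i - r_j)
    + (c/n_i) sum_j n_ij (v_j - v_i) + eta] * dt`` with minimum-image
    displacements, followed by the speed clamp and the position update.
    """
    adj = build_adjacency(state, params.r0, box)
    new_state, _, _ = _reynolds_step_impl(state, adj, params, dt, box, rng)
    return new_state


def _reynolds_step_impl(state, adj, params, dt, box, rng):
    pos, vel = state.positions, state.velocities
    A = adj.adjacency.astype(np.float64)
    n = adj.neighbor_counts.astype(np.float64)
    # disp[i, j] = minimum-image (r_j - r_i)
    disp = minimum_image_displacement(pos[None, :, :], pos[:, None, :], box)
    toward = np.einsum("ij,ijk->ik", A, disp)
    cohesion = (params.a / n)[:, None] * toward
    separation = -params.b * toward
    alignment = (params.c / n)[:, None] * (A @ vel - n[:, None] * vel)
    force = cohesion + separation + alignment + _noise(vel, params.noise_level, rng)
    new_vel = _clamp_speeds(vel + force * dt, params.speed_min, params.speed_max, rng)
    new_pos = wrap_coordinates(pos + new_vel * dt, box)
    return FlockState(new_pos, new_vel, state.time_index + 1), adj.neighbor_counts, adj.mean_alignments


def garud_step(
    state: FlockState,
    params: GarudParams,
    dt: float,
    box: BoxSpec,
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
    probe: float | None = None,
    normalize_force: bool = False,
) -> FlockState:
    """One utility-driven update.

    The force on each agent is the sum of the candidate-displacement
    estimate of the positional utility direction and the orientational
    utility gradient, plus isotropic noise of magnitude
    ``noise_level * |v_i|``; applied additively to the velocity as in the
    boids update, then speed-clamped, then the position advances.
    """
    new_state, _, _ = _garud_step_impl(state, params, dt, box, noise_level, rng, probe, normalize_force)
    return new_state


def _garud_step_impl(
    state, params, dt, box, noise_level, rng, probe=None, normalize_force=False,
    speed_min=0.5, speed_max=1.0,
):
    if probe is None:
        probe = DEFAULT_PROBE_FRACTION * params.r0
    if params.r0 + 2.0 * probe >= float(np.min(box.edge_lengths)) / 2.0:
        raise GeometryError("r0 + 2*probe must stay below half the smallest box edge")
    f_pos, f_ori, counts, mean_align = _kernels.garud_forces(
        state.positions,
        state.orientations,
        box.edge_lengths,
        float(params.r0),
        float(probe),
        params.alpha,
        params.beta,
        params.gamma,
        params.delta,
    )
    force = f_pos + f_ori
    if normalize_force:
        norms = np.linalg.norm(force, axis=1)
        nz = norms > 0
        force[nz] /= norms[nz, None]
    force = force + _noise(state.velocities, noise_level, rng)
    new_vel = _clamp_speeds(state.velocities + force * dt, speed_min, speed_max, rng)
    new_pos = wrap_coordinates(state.positions + new_vel * dt, box)
    return FlockState(new_pos, new_vel, state.time_index + 1), counts, mean_align


def run_simulation(
    config: SimConfig,
    params: GarudParams | ReynoldsParams,
    initial_state: FlockState | None = None,
    rng: np.random.Generator | None = None,
) -> TrajectoryRecord:
    """Run ``config.n_steps`` steps of the configured model from a random
    initial state, recording per-step population summaries.

    Fully reproducible from ``config.seed``; snapshots of the full state
    are stored every ``config.snapshot_stride`` steps (0 disables them)
    and the final state is always available as ``record.final_snapshot``.
    """
    if config.model == "garud" and not isinstance(params, GarudParams):
        raise TypeError("model 'garud' requires GarudParams")
    if config.model == "reynolds" and not isinstance(params, ReynoldsParams):
        raise TypeError("model 'reynolds' requires ReynoldsParams")
    if params.r0 != config.r0:
        raise ValueError(f"params.r0={params.r0} disagrees with config.r0={config.r0}")
    if isinstance(params, ReynoldsParams) and (
        params.speed_min != config.speed_min
        or params.speed_max != config.speed_max
        or params.noise_level != config.noise_level
    ):
        raise ValueError("ReynoldsParams speed band / noise must match the SimConfig")
    box = config.box
    if rng is None:
        rng = np.random.default_rng(config.seed)
    state = initialize_flock(config, rng) if initial_state is None else initial_state.copy()

    rows = np.empty((config.n_steps + 1, len(SUMMARY_COLUMNS)))
    snapshots: list[Snapshot] = []
    final_snapshot: Snapshot | None = None

    def record_row(k, t, counts, mean_align):
        h = effective_utility(counts, mean_align, _as_garud(params))
        rows[k] = (t, counts.mean(), counts.std(), mean_align.mean(), mean_align.std(), h.mean(), h.std())
        return h

    def maybe_snapshot(t, st, counts, mean_align, h, force=False):
        nonlocal final_snapshot
        snap = None
        if config.snapshot_stride > 0 and t % config.snapshot_stride == 0:
            snap = Snapshot(t, st.copy(), counts, mean_align, h)
            snapshots.append(snap)
        if force:
            final_snapshot = snap if snap is not None else Snapshot(t, st.copy(), counts, mean_align, h)

    for k in range(config.n_steps + 1):
        t = state.time_index
        if config.model == "garud":
            if k < config.n_steps:
                new_state, counts, mean_align = _garud_step_impl(
                    state, params, config.dt, box, config.noise_level, rng,
                    probe=config.probe, normalize_force=config.normalize_force,
                    speed_min=config.speed_min, speed_max=config.speed_max,
                )
            else:
                adj = build_adjacency(state, config.r0, box)
                new_state, counts, mean_align = None, adj.neighbor_counts, adj.mean_alignments
        else:
            adj = build_adjacency(state, config.r0, box)
            counts, mean_align = adj.neighbor_counts, adj.mean_alignments
            if k < config.n_steps:
                new_state, _, _ = _reynolds_step_impl(state, adj, params, config.dt, box, rng)
            else:
                new_state = None
        h = record_row(k, t, counts, mean_align)
        maybe_snapshot(t, state, counts, mean_align, h, force=(k == config.n_steps))
        if new_state is not None:
            state = new_state

    summaries = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    summaries["step"] = summaries["step"].astype(int)
    return TrajectoryRecord(summaries, snapshots, final_snapshot, config=config, params=params)


def _as_garud(params) -> GarudParams:
    """Utility bookkeeping for the boids baseline uses the default garud
    coefficients so both models report comparable h summaries."""
    if isinstance(params, GarudParams):
        return params
    return GarudParams(alpha=0.5, beta=0.005, gamma=0.25, delta=1.0, r0=params.r0)
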