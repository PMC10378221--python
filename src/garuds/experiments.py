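"""Scripted studies: equilibrium prediction vs simulation, time-step
sweeps, and disturbance-recovery stability experiments.

The stability experiments run the utility-driven model to its arbitrage
equilibrium, perturb every agent's velocity and/or position, and measure
how quickly the population-mean utility re-enters the pre-disturbance
equilibrium band.  A Lyapunov-style diagnostic tracks
``V(t) = phi_eq - phi(t)`` where ``phi`` is the population-summed
effective utility: V collapses toward zero along recovery trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import SimConfig, initialize_flock, random_unit_vectors, run_simulation
from .geometry import BoxSpec, FlockState, wrap_coordinates
from .observables import TrajectoryRecord, WindowStats, equilibrium_window_stats
from .utility import GarudParams, lyapunov_value, optimal_flock_sizes

__all__ = [
    "DisturbanceSpec",
    "RecoveryResult",
    "apply_disturbance",
    "recovery_experiment",
    "lyapunov_series",
    "nonincreasing_window_fraction",
    "table2_experiment",
    "TABLE2_ROWS",
    "dt_sweep",
    "make_fixture",
    "FIXTURE_BOX",
    "FIXTURE_NAMES",
]

#: The three parameter rows of the prediction-vs-observation comparison
#: (alpha, beta, gamma, delta).
TABLE2_ROWS = [
    (0.1, 0.005, 0.25, 1.0),
    (0.3, 0.005, 0.25, 1.0),
    (0.5, 0.005, 0.02, 1.0),
]


@dataclass(frozen=True)
class DisturbanceSpec:
    """What to randomize, and at which absolute step to apply it."""

    kind: str  # "velocity" | "position" | "both"
    applied_at_step: int = 101

    def __post_init__(self) -> None:
        if self.kind not in ("velocity", "position", "both"):
            raise ValueError(f"unknown disturbance kind {self.kind!r}")
        if self.applied_at_step < 1:
            raise ValueError("applied_at_step must be >= 1")


def apply_disturbance(
    state: FlockState, spec: DisturbanceSpec, config: SimConfig, rng: np.random.Generator
) -> FlockState:
    """Randomize velocities and/or positions of every agent.

    Velocity: new orientation uniform on the sphere, new speed uniform in
    the configured band.  Position: redrawn uniform over the initial
    central block (the same law as initialization, so the combined
    disturbance reproduces a fresh random start in distribution).  The
    untouched component is preserved exactly.
    """
    pos = state.positions.copy()
    vel = state.velocities.copy()
    if spec.kind in ("velocity", "both"):
        ori = random_unit_vectors(rng, state.n_agents)
        speeds = rng.uniform(config.speed_min, config.speed_max, state.n_agents)
        vel = ori * speeds[:, None]
    if spec.kind in ("position", "both"):
        low = (config.box_edge - config.init_block_edge) / 2.0
        pos = low + rng.random((state.n_agents, 3)) * config.init_block_edge
    return FlockState(pos, vel, state.time_index)


@dataclass
class RecoveryResult:
    """Outcome of one disturbance-recovery run."""

    pre_record: TrajectoryRecord
    post_record: TrajectoryRecord
    recovery_step: int | None
    equilibrium: WindowStats
    band_lower: float

    @property
    def disturbance_step(self) -> int:
        return int(self.post_record.summaries["step"].iloc[0])

    @property
    def steps_to_recover(self) -> int | None:
        if self.recovery_step is None:
            return None
        return self.recovery_step - self.disturbance_step


def _equilibrated(record: TrajectoryRecord, window: int) -> bool:
    """Heuristic flatness check: the mean of the last 10 steps should not
    exceed the window mean by more than half the pooled spread."""
    stats = equilibrium_window_stats(record, window)
    recent = float(record.summaries["h_mean"].iloc[-10:].mean())
    return recent <= stats.h_mean + 0.5 * max(stats.h_sd, 1e-12)


def run_to_equilibrium(
    config: SimConfig,
    params: GarudParams,
    rng: np.random.Generator,
    pre_steps: int,
    max_extensions: int = 3,
    extension: int = 50,
) -> TrajectoryRecord:
    """Run ``pre_steps`` steps; extend in blocks while the population-mean
    utility is still climbing (bounded number of extensions)."""
    cfg = replace(config, n_steps=pre_steps)
    record = run_simulation(cfg, params, rng=rng)
    window = min(100, pre_steps)
    for _ in range(max_extensions):
        if _equilibrated(record, window):
            break
        more = run_simulation(
            replace(config, n_steps=extension), params,
            initial_state=record.final_snapshot.state, rng=rng,
        )
        record = _concat_records(record, more)
    return record


def _concat_records(first: TrajectoryRecord, second: TrajectoryRecord) -> TrajectoryRecord:
    # second's row 0 repeats first's final state; drop it.
    summaries = pd.concat(
        [first.summaries, second.summaries.iloc[1:]], ignore_index=True
    )
    return TrajectoryRecord(
        summaries,
        first.snapshots + [s for s in second.snapshots if s.time_index > first.summaries["step"].iloc[-1]],
        second.final_snapshot,
        config=first.config,
        params=first.params,
    )


def recovery_experiment(
    config: SimConfig,
    params: GarudParams,
    spec: DisturbanceSpec,
    post_steps: int,
    pre_record: TrajectoryRecord | None = None,
    rng: np.random.Generator | None = None,
) -> RecoveryResult:
    """Disturb an equilibrated population and track its recovery.

    Runs to equilibrium (``spec.applied_at_step - 1`` steps, extended if
    the utility is still climbing), applies the disturbance, and continues
    for ``post_steps``.  The recovery step is the first post-disturbance
    step whose population-mean utility re-enters
    ``[h_eq - 2*sd_eq, inf)`` where the equilibrium band comes from the
    trailing pre-disturbance window; None if it never does.  A
    pre-computed equilibrium run can be passed to share it across
    disturbance kinds.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if pre_record is None:
        pre_record = run_to_equilibrium(config, params, rng, spec.applied_at_step - 1)
    # Band from the flat tail of the pre-run: its last half (capped at the
    # conventional 100-step window) so the initial transient is excluded.
    window = min(100, max(1, pre_record.n_steps // 2))
    eq = equilibrium_window_stats(pre_record, window)
    band_lower = eq.h_mean - 2.0 * eq.h_sd

    pre_end = int(pre_record.summaries["step"].iloc[-1])
    disturbed = apply_disturbance(pre_record.final_snapshot.state, spec, config, rng)
    # The disturbed state is what the population looks like one step after
    # equilibrium; the post record's clock continues the pre-run's.
    disturbed = FlockState(disturbed.positions, disturbed.velocities, pre_end + 1)
    post = run_simulation(replace(config, n_steps=post_steps), params, initial_state=disturbed, rng=rng)

    in_band = post.summaries["h_mean"].to_numpy() >= band_lower
    recovery_step = int(post.summaries["step"].iloc[int(np.argmax(in_band))]) if in_band.any() else None
    return RecoveryResult(pre_record, post, recovery_step, eq, band_lower)


def lyapunov_series(result: RecoveryResult, n_agents: int | None = None) -> np.ndarray:
    """``V(t) = phi_eq - phi(t)`` along the post-disturbance trajectory,
    using the population-summed utility as the potential proxy."""
    cfg = result.pre_record.config
    n = n_agents if n_agents is not None else cfg.n_agents
    phi_eq = result.equilibrium.h_mean * n
    h_means = result.post_record.summaries["h_mean"].to_numpy()
    return np.array([lyapunov_value(h * n, phi_eq) for h in h_means])


def nonincreasing_window_fraction(
    values: np.ndarray, window: int = 10, until: int | None = None
) -> float:
    """Fraction of successive ``window``-step block means that do not
    increase, evaluated over ``values[:until]`` (the recovery phase)."""
    v = np.asarray(values, dtype=np.float64)
    if until is not None:
        v = v[: max(until, 2 * window)]
    n_blocks = len(v) // window
    if n_blocks < 2:
        return 1.0
    block_means = v[: n_blocks * window].reshape(n_blocks, window).mean(axis=1)
    diffs = np.diff(block_means)
    return float(np.mean(diffs <= 1e-9))


def table2_experiment(
    config: SimConfig,
    rows: list[tuple[float, float, float, float]] | None = None,
    window: int = 100,
) -> pd.DataFrame:
    """Predicted stable flock size vs the simulated equilibrium-window
    neighbor count, one utility-driven run per parameter row."""
    if rows is None:
        rows = TABLE2_ROWS
    out = []
    for alpha, beta, gamma, delta in rows:
        params = GarudParams(alpha, beta, gamma, delta, r0=config.r0)
        pred = optimal_flock_sizes(1.0, params)
        record = run_simulation(config, params)
        stats = equilibrium_window_stats(record, min(window, record.n_steps + 1))
        out.append(
            {
                "alpha": alpha, "beta": beta, "gamma": gamma, "delta": delta,
                "predicted_n_hat_plus": pred.n_hat_plus,
                "observed_n_mean": stats.n_mean,
                "observed_n_sd": stats.n_sd,
            }
        )
    return pd.DataFrame(out)


def dt_sweep(
    config: SimConfig,
    params: GarudParams,
    dts: tuple[float, ...] = (0.01, 0.1, 0.5),
) -> pd.DataFrame:
    """Utility percentile table at the final step for several time-steps."""
    from .observables import utility_percentile_table

    frames = []
    for dt in dts:
        record = run_simulation(replace(config, dt=dt), params)
        table = utility_percentile_table(record.final_snapshot.utilities)
        table.insert(0, "dt", dt)
        frames.append(table)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Deterministic hand-placed fixtures used across unit tests.

FIXTURE_BOX = BoxSpec(np.full(3, 20.0))
FIXTURE_NAMES = (
    "isolated_agent",
    "aligned_pair",
    "anti_aligned_pair",
    "triangle_plus_outlier",
    "dense_block",
)


def make_fixture(name: str) -> FlockState:
    """Hand-coded toy configurations with documented neighborhoods.

    All are placed in the 20-cube ``FIXTURE_BOX`` with r0 = 3 in mind:

    - ``isolated_agent``: one agent, n = 1, l = 1.
    - ``aligned_pair``: two agents 1 apart, both flying +z.
    - ``anti_aligned_pair``: two agents 1 apart, opposite z; the self term
      cancels the anti-aligned term so l = (0, 0).
    - ``triangle_plus_outlier``: unit equilateral triangle near the origin
      plus an agent at (10, 10, 10): n = (3, 3, 3, 1).
    - ``dense_block``: 27 agents on a unit lattice, random-ish headings.
    """
    if name == "isolated_agent":
        return FlockState(np.array([[5.0, 5.0, 5.0]]), np.array([[0.0, 0.0, 0.7]]))
    if name == "aligned_pair":
        pos = np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
        vel = np.array([[0.0, 0.0, 0.8], [0.0, 0.0, 0.8]])
        return FlockState(pos, vel)
    if name == "anti_aligned_pair":
        pos = np.array([[5.0, 5.0, 5.0], [6.0, 5.0, 5.0]])
        vel = np.array([[0.0, 0.0, 0.8], [0.0, 0.0, -0.8]])
        return FlockState(pos, vel)
    if name == "triangle_plus_outlier":
        pos = np.array(
            [
                [2.0, 2.0, 2.0],
                [3.0, 2.0, 2.0],
                [2.5, 2.0 + np.sqrt(3.0) / 2.0, 2.0],
                [10.0, 10.0, 10.0],
            ]
        )
        vel = np.tile(np.array([[0.6, 0.0, 0.0]]), (4, 1))
        return FlockState(pos, vel)
    if name == "dense_block":
        grid = np.arange(3, dtype=np.float64)
        pos = np.array(np.meshgrid(grid, grid, grid)).reshape(3, -1).T + 8.0
        rng = np.random.default_rng(20230711)
        vel = random_unit_vectors(rng, 27) * 0.75
        return FlockState(pos, vel)
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
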