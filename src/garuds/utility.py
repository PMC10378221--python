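"""Effective utility of utility-driven agents and its equilibrium analysis.

An agent with ``n`` neighbors (self included) and mean neighborhood
alignment ``l`` has effective utility

    h(n, l) = alpha*n - beta*n**2 + gamma*n*l - delta*ln(n)

combining a cohesion benefit, a congestion cost, an alignment benefit and
a competition ("entropic restlessness") cost.  For fixed ``l`` the
stationary points of ``h`` in ``n`` solve the quadratic
``2*beta*n**2 - (alpha + gamma*l)*n + delta = 0``; the smaller root is an
unstable optimum and the larger root ``n_hat_plus`` is the stable flock
size agents gravitate toward, with maximum utility ``h_hat``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import AdjacencySummary, BoxSpec, FlockState, GeometryError

__all__ = [
    "GarudParams",
    "EquilibriumPrediction",
    "effective_utility",
    "utility_all_agents",
    "utility_derivative_wrt_n",
    "optimal_flock_sizes",
    "orientation_utility_gradient",
    "position_utility_direction",
    "lyapunov_value",
    "population_potential_proxy",
]

#: Default probe length for the candidate-displacement gradient estimate,
#: as a fraction of the neighborhood radius: small against the
#: neighborhood scale yet large enough to change an integer neighbor
#: count near the boundary shell.
DEFAULT_PROBE_FRACTION = 0.1


@dataclass(frozen=True)
class GarudParams:
    """Coefficients of the effective utility and the neighborhood radius.

    ``alpha`` (cohesion), ``beta`` (congestion) and ``gamma`` (alignment)
    are nonnegative; ``delta`` (competition) is strictly positive and can
    be taken as 1 without loss of generality.
    """

    alpha: float
    beta: float
    gamma: float
    delta: float = 1.0
    r0: float = 3.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0 or self.gamma < 0:
            raise ValueError("alpha, beta, gamma must be nonnegative")
        if not (self.delta > 0):
            raise ValueError("delta must be strictly positive")
        if not (self.r0 > 0):
            raise ValueError("r0 must be strictly positive")


@dataclass(frozen=True)
class EquilibriumPrediction:
    """Closed-form stationary flock sizes for a given alignment.

    ``n_hat_minus`` is the unstable root, ``n_hat_plus`` the stable one,
    and ``h_hat`` the effective utility at ``n_hat_plus``.  When the
    discriminant is negative there is no stationary point;
    ``has_real_roots`` is False and the roots are NaN.
    """

    n_hat_minus: float
    n_hat_plus: float
    h_hat: float
    alignment_used: float
    has_real_roots: bool = True


def effective_utility(n_i, l_i, params: GarudParams):
    """Effective utility ``h = alpha*n - beta*n^2 + gamma*n*l - delta*ln n``.

    Accepts scalars or arrays; ``n_i`` must be >= 1 (an agent is always
    its own neighbor, so the log term is a well-defined cost).
    """
    n = np.asarray(n_i, dtype=np.float64)
    l = np.asarray(l_i, dtype=np.float64)
    if np.any(n < 1):
        raise ValueError("n_i must be >= 1 (every agent is its own neighbor)")
    h = params.alpha * n - params.beta * n**2 + params.gamma * n * l - params.delta * np.log(n)
    return float(h) if h.ndim == 0 else h


def utility_all_agents(state: FlockState, adj: AdjacencySummary, params: GarudParams) -> np.ndarray:
    """Per-agent effective utilities from precomputed neighborhood stats."""
    if adj.neighbor_counts.shape[0] != state.n_agents:
        raise ValueError("adjacency summary does not match the state")
    return effective_utility(adj.neighbor_counts, adj.mean_alignments, params)


def utility_derivative_wrt_n(n, l, params: GarudParams):
    """d h / d n at fixed alignment: ``alpha - 2*beta*n + gamma*l - delta/n``."""
    n = np.asarray(n, dtype=np.float64)
    if np.any(n < 1):
        raise ValueError("n must be >= 1")
    d = params.alpha - 2.0 * params.beta * n + params.gamma * np.asarray(l, dtype=np.float64) - params.delta / n
    return float(d) if d.ndim == 0 else d


def optimal_flock_sizes(l: float, params: GarudParams) -> EquilibriumPrediction:
    """Stationary flock sizes ``n_hat -/+`` and the stable-point utility.

    Solves ``2*beta*n^2 - (alpha + gamma*l)*n + delta = 0``; the larger
    root maximizes the utility (stable), the smaller is the unstable
    threshold below which agents prefer isolation.  ``beta == 0`` has no
    finite optimum and is rejected.
    """
    if params.beta == 0:
        raise ValueError("optimal flock sizes require beta > 0 (no finite optimum otherwise)")
    if not -1.0 <= l <= 1.0:
        raise ValueError("alignment l must lie in [-1, 1]")
    a_eff = params.alpha + params.gamma * l
    disc = a_eff * a_eff - 8.0 * params.beta * params.delta
    if disc < 0:
        return EquilibriumPrediction(math.nan, math.nan, math.nan, l, has_real_roots=False)
    root = math.sqrt(disc)
    n_minus = (a_eff - root) / (4.0 * params.beta)
    n_plus = (a_eff + root) / (4.0 * params.beta)
    h_hat = effective_utility(max(n_plus, 1.0), l, params)
    return EquilibriumPrediction(n_minus, n_plus, h_hat, l, has_real_roots=True)


def orientation_utility_gradient(
    state: FlockState, adj: AdjacencySummary, params: GarudParams
) -> np.ndarray:
    """Gradient of the alignment utility w.r.t. each agent's orientation.

    Row i is ``gamma * sum_j n_ij s_j`` over the neighborhood (self
    included): the direction toward which agent i would rotate to increase
    its alignment utility.
    """
    return params.gamma * (adj.adjacency.astype(np.float64) @ state.orientations)


def position_utility_direction(
    state: FlockState,
    params: GarudParams,
    box: BoxSpec,
    probe: float | None = None,
) -> np.ndarray:
    """Numerical estimate of the direction of increased utility in space.

    The neighbor count is an integer function of position, so no analytic
    gradient exists; instead, for each agent six candidate displacements
    of length ``probe`` along +/- each axis are evaluated (the agent's own
    ``n_i`` and alignment sum recomputed per candidate) and the per-axis
    utility differences are composited into a central-difference vector.
    A row is the zero vector when no candidate strictly improves the
    agent's utility.
    """
    if probe is None:
        probe = DEFAULT_PROBE_FRACTION * params.r0
    if not (0 < probe < params.r0):
        raise ValueError("probe must be positive and small against r0")
    if params.r0 + 2.0 * probe >= float(np.min(box.edge_lengths)) / 2.0:
        raise GeometryError("r0 + 2*probe must stay below half the smallest box edge")
    f_pos, _, _, _ = _kernels.garud_forces(
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
    return f_pos


def population_potential_proxy(utilities: np.ndarray) -> float:
    """Population-summed effective utility, the implementable stand-in for
    the game potential used in stability analysis."""
    return float(np.sum(utilities))


def lyapunov_value(current_potential_proxy: float, equilibrium_potential_proxy: float) -> float:
    """Lyapunov function ``V = phi* - phi``: zero at equilibrium, positive
    below it, and expected to decay along recovery trajectories."""
    if not (math.isfinite(current_potential_proxy) and math.isfinite(equilibrium_potential_proxy)):
        raise ValueError("potential proxies must be finite")
    return equilibrium_potential_proxy - current_potential_proxy
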