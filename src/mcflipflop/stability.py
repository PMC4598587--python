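"""Simulation-based stability classification and memory-time analysis.

The circuit is probed by long constant-input (0, 0) runs started from a
log-spaced grid of medium pheromone initial conditions (intracellular
components pre-equilibrated). Terminal (X_med, Y_med) points are
clustered in log space; two well-separated clusters mean bistability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit_model import CircuitParams, iPHI_X, iPHI_Y, iX, iY, rhs
from .schedule import HOUR, InputSchedule, canonical_sequence, pre_equilibrate
from .simulate import IntegrationError, SolverOptions, integrate, phi_of

__all__ = [
    "StabilityReport",
    "default_ic_grid",
    "classify_stability",
    "memory_time",
    "bistability_boundary",
]

#: Floor applied before taking logs of terminal medium concentrations.
_LOG_FLOOR = 1e-30


@dataclass(frozen=True)
class StabilityReport:
    classification: str                      # "monostable" | "bistable"
    equilibria: tuple[tuple[float, float], ...]  # terminal (X_med, Y_med)
    basin: tuple[int, ...]                   # cluster index per initial condition
    inconclusive: tuple[int, ...] = ()       # ic indices that did not converge
    memory_time_min: float | None = None

    @property
    def n_equilibria(self) -> int:
        return len(self.equilibria)


def default_ic_grid(
    lo: float = 1e-18, hi: float = 1e-12, n: int = 5
) -> list[tuple[float, float]]:
    """Log-spaced (X_med, Y_med) initial-condition grid spanning the
    medium-pheromone range observed in reference trajectories.

    Exact-diagonal points are excluded: for a symmetric circuit the
    diagonal is an invariant manifold, so X = Y initial conditions would
    converge to the saddle of a bistable circuit instead of probing its
    basins.
    """
    g = np.logspace(np.log10(lo), np.log10(hi), n)
    return [(float(x), float(y)) for x in g for y in g if x != y]


def _cluster_log(points: np.ndarray, separation_factor: float) -> np.ndarray:
    """Greedy clustering: same cluster iff both coords within the factor."""
    logs = np.log10(np.clip(points, _LOG_FLOOR, None))
    thresh = np.log10(separation_factor)
    centers: list[np.ndarray] = []
    labels = np.empty(len(logs), dtype=int)
    for i, p in enumerate(logs):
        for j, c in enumerate(centers):
            if np.all(np.abs(p - c) < thresh):
                labels[i] = j
                break
        else:
            centers.append(p)
            labels[i] = len(centers) - 1
    return labels


def classify_stability(
    params: CircuitParams,
    ic_grid: list[tuple[float, float]] | None = None,
    horizon_h: float = 300.0,
    separation_factor: float = 3.0,
    opts: SolverOptions | None = None,
    rhs_tol: float = 1e-10,
) -> StabilityReport:
    """Classify the circuit as monostable or bistable under (0, 0) inputs."""
    ic_grid = ic_grid if ic_grid is not None else default_ic_grid()
    opts = opts or SolverOptions(rtol=1e-9, save_dt=HOUR)
    base = pre_equilibrate(params)
    sched = InputSchedule(segments=((horizon_h * HOUR, 0, 0),))

    terminal = []
    inconclusive = []
    for idx, (x0, y0) in enumerate(ic_grid):
        init = base.copy()
        init[iX], init[iY] = x0, y0
        traj = integrate(params, sched, init, opts)
        y_end = traj.y[:, -1]
        # converged when the state-scaled derivative is small; components
        # far below the dominant scale are judged against that scale
        dy = rhs(y_end, traj.t[-1], params, (0.0, 0.0), validate=False)
        scale = np.maximum(np.abs(y_end), 1e-6 * np.max(np.abs(y_end)))
        if np.max(np.abs(dy) / scale) > rhs_tol:
            inconclusive.append(idx)
        terminal.append((y_end[iX], y_end[iY]))

    pts = np.array(terminal)
    labels = _cluster_log(pts, separation_factor)
    n_clusters = labels.max() + 1
    centers = tuple(
        tuple(np.exp(np.mean(np.log(np.clip(pts[labels == j], _LOG_FLOOR, None)),
                             axis=0)))
        for j in range(n_clusters)
    )
    classification = "bistable" if n_clusters == 2 else "monostable"
    return StabilityReport(
        classification=classification,
        equilibria=centers,
        basin=tuple(int(v) for v in labels),
        inconclusive=tuple(inconclusive),
    )


def memory_time(
    params: CircuitParams,
    schedule: InputSchedule | None = None,
    opts: SolverOptions | None = None,
    noise_floor: float = 1e-6,
) -> float:
    """Minutes for which Phi < 0 during the (0, 0) hold after a (1, 0) write.

    Returns the full hold-window length when Phi stays negative
    throughout (persistent memory). Phi values within
    ``noise_floor * max(phi_x, phi_y)`` of zero count as zero: once the
    latch has relaxed to the symmetric state, Phi sits at integrator
    noise level and its sign is meaningless.
    """
    if schedule is None:
        schedule = InputSchedule(segments=((3 * HOUR, 1, 0), (297 * HOUR, 0, 0)))
    dur0, r0, s0 = schedule.segments[0]
    if (r0, s0) != (1, 0):
        raise ValueError("schedule must begin with a (1, 0) write")
    if len(schedule.segments) < 2 or schedule.segments[1][1:] != (0, 0):
        raise ValueError("second segment must be the (0, 0) hold")
    opts = opts or SolverOptions(rtol=1e-9, save_dt=300.0)
    init = pre_equilibrate(params)
    traj = integrate(params, schedule, init, opts)
    phi = phi_of(traj)
    t1 = schedule.breakpoints[1]
    t2 = schedule.breakpoints[2]
    scale = float(max(traj.y[iPHI_X].max(), traj.y[iPHI_Y].max(), 0.0))
    sel = (phi.t >= t1) & (phi.t <= t2)
    tt = phi.t[sel]
    yy = phi.phi[sel] + noise_floor * scale
    neg = yy < 0
    # accumulate time where Phi < 0 (interval counted if either end negative,
    # refined by linear interpolation at sign changes)
    total = 0.0
    for i in range(len(tt) - 1):
        dt = tt[i + 1] - tt[i]
        if neg[i] and neg[i + 1]:
            total += dt
        elif neg[i] != neg[i + 1] and yy[i + 1] != yy[i]:
            frac = abs(yy[i] / (yy[i + 1] - yy[i])) if neg[i] else abs(
                yy[i + 1] / (yy[i + 1] - yy[i])
            )
            total += dt * min(frac, 1.0)
    return total / 60.0


def bistability_boundary(
    params: CircuitParams,
    k_low: float,
    k_high: float,
    tol: float = 0.01,
    **classify_kwargs,
) -> float:
    """Bisect ``k_alpha_deg`` between differing stability classifications.

    ``tol`` is the relative bracket width at which bisection stops; the
    bracket midpoint (geometric) is returned.
    """
    def classify(k: float) -> str:
        return classify_stability(
            params.with_(k_alpha_deg=k), **classify_kwargs
        ).classification

    c_low, c_high = classify(k_low), classify(k_high)
    if c_low == c_high:
        raise ValueError(
            f"no bracket: both ends classified {c_low} "
            f"(k = {k_low}, {k_high})"
        )
    lo, hi = k_low, k_high
    while (hi - lo) / hi > tol:
        mid = float(np.sqrt(lo * hi))
        if classify(mid) == c_low:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))
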