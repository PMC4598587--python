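"""Parameter sweeps: quality maps over 1-D/2-D grids and lambda scans.

Each grid point runs the full pipeline (pre-equilibrate, simulate the
protocol, score Theta_S); amplitude normalization for Theta_A uses the
sweep-wide extrema m_T = min m, M_T = max M over the whole grid, so the
normalizer is shared by every point of a map.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .circuit_model import CircuitParams
from .quality import QualityScore, theta_A, theta_S
from .schedule import InputSchedule, canonical_sequence, pre_equilibrate
from .simulate import IntegrationError, SolverOptions, integrate, phi_of

__all__ = ["GridAxis", "QualityMap", "sweep1d", "sweep2d", "lambda_scan",
           "evaluate_point"]


@dataclass(frozen=True)
class GridAxis:
    """A named parameter grid, linear or logarithmic."""

    name: str
    values: np.ndarray

    @classmethod
    def log(cls, name: str, lo: float, hi: float, n: int) -> "GridAxis":
        return cls(name, np.logspace(np.log10(lo), np.log10(hi), n))

    @classmethod
    def lin(cls, name: str, lo: float, hi: float, n: int) -> "GridAxis":
        return cls(name, np.linspace(lo, hi, n))

    def __post_init__(self) -> None:
        valid = {f.name for f in dc_fields(CircuitParams)}
        if self.name not in valid:
            raise ValueError(f"unknown parameter {self.name!r}")
        if len(self.values) == 0:
            raise ValueError("empty grid")


@dataclass(frozen=True)
class QualityMap:
    """Grid of quality scores with shared amplitude normalizers."""

    axes: tuple[GridAxis, ...]
    scores: np.ndarray            # object array of QualityScore, shape = grid
    failed: np.ndarray            # bool, same shape
    m_T: float
    M_T: float
    lam: float

    def theta_S_grid(self) -> np.ndarray:
        return np.vectorize(lambda s: s.theta_S)(self.scores)

    def theta_A_grid(self) -> np.ndarray:
        return np.vectorize(lambda s: 0.0 if s.theta_A is None else s.theta_A)(
            self.scores
        )

    def to_frame(self) -> pd.DataFrame:
        idx = np.indices(self.scores.shape).reshape(len(self.axes), -1)
        rows = []
        for flat, pos in enumerate(zip(*idx)):
            s: QualityScore = self.scores[tuple(pos)]
            row = {
                ax.name: ax.values[i] for ax, i in zip(self.axes, pos)
            }
            row.update(
                theta_S=s.theta_S,
                theta_A=0.0 if s.theta_A is None else s.theta_A,
                S_r=s.S_r,
                S_m=s.S_m,
                m=s.m,
                M=s.M,
                failed=bool(self.failed[tuple(pos)]),
            )
            rows.append(row)
        return pd.DataFrame(rows)


_ZERO = QualityScore(
    S_r=0.0, S_m=0.0, theta_S=0.0, lam=0.0, R=(0.0,) * 4, P=(0.0,) * 4,
    m=np.nan, M=np.nan, zero_ruled=True, theta_A=0.0,
)


def evaluate_point(
    params: CircuitParams,
    lam: float,
    schedule: InputSchedule | None = None,
    opts: SolverOptions | None = None,
) -> QualityScore:
    """Pre-equilibrate, simulate the protocol and score one parameter set."""
    schedule = schedule or canonical_sequence(3, 12, 1)
    opts = opts or SolverOptions(rtol=1e-9)
    init = pre_equilibrate(params)
    traj = integrate(params, schedule, init, opts)
    return theta_S(phi_of(traj), lam)


def _finalize(axes, scores, failed, lam) -> QualityMap:
    ms = np.array([s.m for s in scores.flat])
    Ms = np.array([s.M for s in scores.flat])
    ok = np.isfinite(ms) & np.isfinite(Ms)
    if ok.any():
        m_T = float(np.min(ms[ok]))
        M_T = float(np.max(Ms[ok]))
    else:
        m_T, M_T = np.nan, np.nan
    if ok.any() and m_T < 0 < M_T:
        for pos in np.ndindex(scores.shape):
            s = scores[pos]
            if np.isfinite(s.m) and np.isfinite(s.M):
                ta = theta_A(s, m_T, M_T)
            else:
                ta = 0.0
            scores[pos] = QualityScore(
                **{**s.__dict__, "theta_A": ta}
            )
    return QualityMap(
        axes=tuple(axes), scores=scores, failed=failed, m_T=m_T, M_T=M_T,
        lam=lam,
    )


def _run_grid(axes, base, lam, schedule, opts, progress=None) -> QualityMap:
    shape = tuple(len(ax.values) for ax in axes)
    scores = np.empty(shape, dtype=object)
    failed = np.zeros(shape, dtype=bool)
    for pos in np.ndindex(shape):
        overrides = {
            ax.name: float(ax.values[i]) for ax, i in zip(axes, pos)
        }
        try:
            scores[pos] = evaluate_point(
                base.with_(**overrides), lam, schedule, opts
            )
        except (IntegrationError, RuntimeError):
            scores[pos] = _ZERO
            failed[pos] = True
        if progress is not None:
            progress(pos)
    return _finalize(axes, scores, failed, lam)


def sweep1d(
    axis: GridAxis,
    base: CircuitParams,
    lam: float = 0.4,
    schedule: InputSchedule | None = None,
    opts: SolverOptions | None = None,
    progress=None,
) -> QualityMap:
    """Quality map along a single parameter axis."""
    return _run_grid((axis,), base, lam, schedule, opts, progress)


def sweep2d(
    axis_x: GridAxis,
    axis_y: GridAxis,
    base: CircuitParams,
    lam: float = 0.4,
    schedule: InputSchedule | None = None,
    opts: SolverOptions | None = None,
    progress=None,
) -> QualityMap:
    """Quality map over the product grid (axis_x, axis_y)."""
    return _run_grid((axis_x, axis_y), base, lam, schedule, opts, progress)


def lambda_scan(
    axis: GridAxis,
    base: CircuitParams,
    lambda_grid,
    schedule: InputSchedule | None = None,
    opts: SolverOptions | None = None,
) -> dict[float, QualityMap]:
    """Theta_S along one parameter axis for several lambda values.

    One simulation per parameter value: Theta_S is affine in lambda, so
    every lambda reuses the cached (S_r, S_m, m, M).
    """
    lambda_grid = [float(v) for v in lambda_grid]
    for lam in lambda_grid:
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda values must lie in [0, 1]")
    base_map = sweep1d(axis, base, lam=lambda_grid[0], schedule=schedule,
                       opts=opts)
    out: dict[float, QualityMap] = {}
    for lam in lambda_grid:
        scores = np.empty_like(base_map.scores)
        for pos in np.ndindex(base_map.scores.shape):
            s: QualityScore = base_map.scores[pos]
            if s.zero_ruled:
                scores[pos] = QualityScore(**{**s.__dict__, "lam": lam})
                continue
            ts = float(min(max(lam * s.S_r + (1 - lam) * s.S_m, 0.0), 1.0))
            ta = None
            if s.theta_A is not None and s.theta_S > 0:
                ta = s.theta_A / s.theta_S * ts
            elif s.theta_A is not None:
                ta = (
                    ts * (s.m * s.M) / (base_map.m_T * base_map.M_T)
                    if np.isfinite(s.m) and base_map.m_T * base_map.M_T != 0
                    else 0.0
                )
            scores[pos] = QualityScore(
                **{**s.__dict__, "lam": lam, "theta_S": ts, "theta_A": ta}
            )
        out[lam] = QualityMap(
            axes=base_map.axes, scores=scores, failed=base_map.failed,
            m_T=base_map.m_T, M_T=base_map.M_T, lam=lam,
        )
    return out
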