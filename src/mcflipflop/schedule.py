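"""Piecewise-constant input protocols and pre-equilibration."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit_model import CircuitParams, N_STATE, iX, iY, rhs

__all__ = ["InputSchedule", "canonical_sequence", "inputs_at", "pre_equilibrate"]

HOUR = 3600.0
MINUTE = 60.0


@dataclass(frozen=True)
class InputSchedule:
    """Ordered (duration_s, R_level, S_level) segments starting at t = 0.

    Logical levels are 0/1; the concentration applied for level 1 comes
    from ``CircuitParams.input_conc``. The combination R = S = 1 is an
    invalid flip-flop input and is rejected.
    """

    segments: tuple[tuple[float, int, int], ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        for dur, r, s in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if r not in (0, 1) or s not in (0, 1):
                raise ValueError("input levels must be 0 or 1")
            if r == 1 and s == 1:
                raise ValueError("R = S = 1 is an invalid flip-flop input")

    @property
    def total_duration(self) -> float:
        return float(sum(dur for dur, _, _ in self.segments))

    @property
    def breakpoints(self) -> np.ndarray:
        """Times t_0 .. t_n (s) delimiting the segments, t_0 = 0."""
        return np.concatenate(
            [[0.0], np.cumsum([dur for dur, _, _ in self.segments])]
        )


def canonical_sequence(
    activation_h: float, memory_h: float, repeats: int = 1
) -> InputSchedule:
    """(1,0) act / (0,0) mem / (0,1) act / (0,0) mem, repeated.

    ``canonical_sequence(3, 12, 1)`` reproduces the standard 30-h scoring
    protocol with breakpoints at 0, 180, 900, 1080 and 1800 min.
    """
    if activation_h <= 0 or memory_h <= 0:
        raise ValueError("activation_h and memory_h must be > 0")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    act = activation_h * HOUR
    mem = memory_h * HOUR
    cycle = ((act, 1, 0), (mem, 0, 0), (act, 0, 1), (mem, 0, 0))
    return InputSchedule(segments=cycle * repeats)


def segment_index_at(schedule: InputSchedule, t: float) -> int:
    """Index of the segment containing t (right-continuous at breakpoints)."""
    if t < 0 or t > schedule.total_duration:
        raise ValueError(f"t = {t} s outside schedule [0, {schedule.total_duration}]")
    bp = schedule.breakpoints
    # right-continuous: at an interior breakpoint the NEW segment applies
    idx = int(np.searchsorted(bp, t, side="right")) - 1
    return min(idx, len(schedule.segments) - 1)


def inputs_at(
    schedule: InputSchedule, t: float, input_conc: float
) -> tuple[float, float]:
    """(R, S) concentrations in ug/ml at time t."""
    _, r, s = schedule.segments[segment_index_at(schedule, t)]
    return (input_conc * r, input_conc * s)


def pre_equilibrate(
    params: CircuitParams,
    hours: float = 7.0,
    rtol: float = 1e-10,
) -> np.ndarray:
    """Relax each cell type independently before the first input.

    Integrates the consortium for ``hours`` with the medium pools clamped
    at zero (no cell communication) and inputs (0, 0), then returns the
    combined state with the clock reset to 0.
    """
    from scipy.integrate import solve_ivp

    y0 = np.zeros(N_STATE)

    def f(t, y):
        return rhs(y, t, params, (0.0, 0.0), clamp_medium=True, validate=False)

    sol = solve_ivp(
        f,
        (0.0, hours * HOUR),
        y0,
        method="LSODA",
        rtol=rtol,
        atol=1e-28,
    )
    if not sol.success:
        raise RuntimeError(f"pre-equilibration failed: {sol.message}")
    y = np.clip(sol.y[:, -1], 0.0, None)
    y[iX] = 0.0
    y[iY] = 0.0
    return y
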