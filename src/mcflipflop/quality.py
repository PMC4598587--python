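"""Flip-flop quality statistics.

The readout Phi(t) over the four-window protocol
(write-0, hold, write-1, hold; breakpoints t_0 .. t_4) is compared with
the ideal rectangular latch signal:

* real areas R_1..R_4 — trapezoidal integrals of Phi over each window,
  with sign gates theta1 (keep Phi < 0) on window 1 and theta3 (keep
  Phi > 0) on window 3; the hold-window integrals R_2, R_4 are signed,
  so wrong-sign excursions subtract;
* perfect areas P_1..P_4 — rectangles built from the global extrema
  m = min Phi (windows 1, 2) and M = max Phi (windows 3, 4);
* S_r = (R1/P1 + R3/P3)/2 scores the write response,
  S_m = (R2/P2 + R4/P4)/2 scores memory persistence;
* Theta_S = lambda * S_r + (1 - lambda) * S_m, clamped to [0, 1], with
  zero quality when Phi never goes negative in the first half of the
  protocol or never goes positive in the second half;
* Theta_A = Theta_S * (m * M) / (m_T * M_T) weights quality by signal
  amplitude relative to sweep-wide extrema m_T, M_T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import PhiSeries

__all__ = [
    "QualityScore",
    "real_areas",
    "perfect_areas",
    "theta_S",
    "theta_A",
    "ideal_signal",
]


@dataclass(frozen=True)
class QualityScore:
    S_r: float
    S_m: float
    theta_S: float
    lam: float
    R: tuple[float, float, float, float]   # mmol*min/ml, signed
    P: tuple[float, float, float, float]
    m: float                               # mmol/ml
    M: float
    zero_ruled: bool = False
    theta_A: float | None = None

    def as_dict(self) -> dict:
        d = {
            "S_r": self.S_r,
            "S_m": self.S_m,
            "theta_S": self.theta_S,
            "theta_A": self.theta_A,
            "lambda": self.lam,
            "m": self.m,
            "M": self.M,
        }
        for i in range(4):
            d[f"R{i + 1}"] = self.R[i]
            d[f"P{i + 1}"] = self.P[i]
        return d


def _scoring_breakpoints(phi: PhiSeries) -> np.ndarray:
    bp = np.asarray(phi.breakpoints, dtype=float)
    if bp.size < 5:
        raise ValueError("quality scoring needs breakpoints t_0 .. t_4")
    bp = bp[:5]
    if phi.t[0] > bp[0] + 1e-9 or phi.t[-1] < bp[4] - 1e-9:
        raise ValueError("Phi series does not cover [t_0, t_4]")
    return bp


def _window_integral(t, y, lo, hi, gate=None):
    """Trapezoid of (optionally gated) y over [lo, hi], in mmol*min/ml."""
    sel = (t >= lo - 1e-9) & (t <= hi + 1e-9)
    tt, yy = t[sel], y[sel]
    if tt.size < 2:
        raise ValueError("window contains fewer than 2 grid points")
    if gate is not None:
        yy = np.where(gate(yy), yy, 0.0)
    return float(np.trapezoid(yy, tt)) / 60.0


def real_areas(phi: PhiSeries) -> tuple[float, float, float, float]:
    """R_1 .. R_4 in mmol*min/ml (signed)."""
    bp = _scoring_breakpoints(phi)
    t, y = phi.t, phi.phi
    r1 = _window_integral(t, y, bp[0], bp[1], gate=lambda v: v < 0)
    r2 = _window_integral(t, y, bp[1], bp[2])
    r3 = _window_integral(t, y, bp[2], bp[3], gate=lambda v: v > 0)
    r4 = _window_integral(t, y, bp[3], bp[4])
    return (r1, r2, r3, r4)


def perfect_areas(phi: PhiSeries) -> tuple[float, float, float, float]:
    """P_1 .. P_4: signed rectangles from the global extrema m, M."""
    bp = _scoring_breakpoints(phi)
    m, M = phi.m, phi.M
    w = np.diff(bp) / 60.0  # min
    return (m * w[0], m * w[1], M * w[2], M * w[3])


def _clamp01(x: float) -> float:
    return float(min(max(x, 0.0), 1.0))


def theta_S(phi: PhiSeries, lam: float) -> QualityScore:
    """Shape quality Theta_S = lam * S_r + (1 - lam) * S_m."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    bp = _scoring_breakpoints(phi)
    m, M = phi.m, phi.M

    half = 0.5 * (bp[0] + bp[4])
    sel_lo = (phi.t >= bp[0]) & (phi.t <= half)
    sel_hi = (phi.t >= half) & (phi.t <= bp[4])
    zero_ruled = (
        not np.any(phi.phi[sel_lo] < 0)
        or not np.any(phi.phi[sel_hi] > 0)
        or m >= 0
        or M <= 0
    )
    R = real_areas(phi)
    P = perfect_areas(phi)
    if zero_ruled:
        return QualityScore(
            S_r=0.0, S_m=0.0, theta_S=0.0, lam=lam, R=R, P=P, m=m, M=M,
            zero_ruled=True,
        )
    ratios = [_clamp01(R[i] / P[i]) for i in range(4)]
    s_r = 0.5 * (ratios[0] + ratios[2])
    s_m = 0.5 * (ratios[1] + ratios[3])
    ts = _clamp01(lam * s_r + (1.0 - lam) * s_m)
    return QualityScore(
        S_r=s_r, S_m=s_m, theta_S=ts, lam=lam, R=R, P=P, m=m, M=M
    )


def theta_A(score: QualityScore, m_T: float, M_T: float) -> float:
    """Amplitude-weighted quality Theta_A = Theta_S * m*M / (m_T*M_T)."""
    if m_T * M_T == 0:
        raise ValueError("m_T * M_T must be non-zero")
    if score.zero_ruled or score.m >= 0 or score.M <= 0:
        return 0.0
    return score.theta_S * (score.m * score.M) / (m_T * M_T)


def ideal_signal(
    m: float,
    M: float,
    breakpoints,
    dt: float = 60.0,
    relax_rate: float = 0.0,
    flip_delay: float = 0.0,
) -> PhiSeries:
    """Rectangular reference latch signal, with optional degradations.

    Phi = m on [t_0, t_2] and M on (t_2, t_4]. ``relax_rate`` makes Phi
    relax exponentially toward 0 during the hold windows; ``flip_delay``
    postpones each write transition by a fixed lag (s), holding the
    previous value meanwhile.
    """
    if not (m < 0 < M):
        raise ValueError("need m < 0 < M")
    bp = np.asarray(breakpoints, dtype=float)
    if bp.size != 5:
        raise ValueError("breakpoints must be t_0 .. t_4")
    n = int(np.ceil((bp[4] - bp[0]) / dt))
    t = np.unique(np.concatenate([np.linspace(bp[0], bp[4], n + 1), bp]))
    phi = np.empty_like(t)

    def hold_value(level, t_start, tt):
        return level * np.exp(-relax_rate * (tt - t_start))

    prev_end = 0.0
    for i, tt in enumerate(t):
        if tt <= bp[1]:  # write m
            phi[i] = m if tt - bp[0] >= flip_delay else prev_end
        elif tt <= bp[2]:  # hold m
            phi[i] = hold_value(m, bp[1], tt)
        elif tt <= bp[3]:  # write M
            if tt - bp[2] >= flip_delay:
                phi[i] = M
            else:
                phi[i] = hold_value(m, bp[1], tt)
        else:  # hold M
            phi[i] = hold_value(M, bp[3], tt)

    # represent the jump at t_2 exactly: duplicate the breakpoint sample
    # with the right-side value so trapezoidal quadrature sees a true step
    i2 = int(np.searchsorted(t, bp[2]))
    right = M if flip_delay <= 0 else hold_value(m, bp[1], bp[2])
    t = np.insert(t, i2 + 1, bp[2])
    phi = np.insert(phi, i2 + 1, right)
    return PhiSeries(t=t, phi=phi, breakpoints=bp)
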