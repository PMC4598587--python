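"""Consortium state variables and ODE right-hand side.

The circuit is a distributed set-reset latch built from four engineered
yeast cell types communicating through two orthogonal alpha-factor
pheromones in a well-mixed medium:

* cells 1 and 2 ("senders") respond to the external inputs R and S and
  secrete pheromone Y and X respectively;
* cells 3 and 4 ("NOT cells") sense Y and X respectively; pathway
  activation drives production of a LacI-type repressor Z that shuts
  down transcription of the cell's own prepro alpha-factor (phi_x in
  cell 3, phi_y in cell 4);
* cell 3 secretes X and cell 4 secretes Y, closing the cross-repression
  loop through the medium;
* a GFP reporter is co-expressed with phi_y in cell 4.

The readout of the latch is Phi(t) = phi_x(t) - phi_y(t); input (1, 0)
drives Phi negative, input (0, 1) drives it positive.

All intracellular and medium concentrations are in mmol/ml; external
input concentrations are in ug/ml and only enter through a dimensionless
Hill term; time is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

import numpy as np

__all__ = [
    "STATE_NAMES",
    "N_STATE",
    "CircuitParams",
    "default_params",
    "repressible_promoter_activity",
    "rhs",
    "mirror_state",
]

#: Order of the state vector components.
STATE_NAMES = (
    "M1", "A1",            # sender cell 1: mRNA, prepro pool
    "M2", "A2",            # sender cell 2
    "F3", "Z3", "phi_x",   # NOT cell 3: pathway activity, repressor, prepro X
    "F4", "Z4", "phi_y",   # NOT cell 4
    "X_med", "Y_med",      # medium alpha-factors
    "G",                   # GFP reporter (cell 4)
)
N_STATE = len(STATE_NAMES)

_IDX = {name: i for i, name in enumerate(STATE_NAMES)}

# Component indices, exported for convenience.
iM1, iA1, iM2, iA2, iF3, iZ3, iPHI_X, iF4, iZ4, iPHI_Y, iX, iY, iG = range(N_STATE)

#: Effective yeast cell volume (ml); together with ``cell_density`` it
#: sets the intracellular-to-medium dilution factor for secretion.
_V_CELL = 4.0e-11

_CELL_NAMES = ("cell1", "cell2", "cell3", "cell4")


@dataclass(frozen=True)
class CircuitParams:
    """All rate constants of the reference consortium model.

    The four tunables highlighted throughout the analysis are ``gamma``
    (prepro alpha-factor transcription rate in the NOT cells), ``beta_c``
    (repression constant of Z on the repressible promoter), ``k34``
    (pathway-activated repressor production rate) and ``k_alpha_deg``
    (elimination rate of both alpha-factors in the medium).

    ``overrides`` maps a cell name (``cell1`` .. ``cell4``) to a dict of
    per-cell parameter replacements, enabling asymmetric circuits.
    """

    # -- headline tunables -------------------------------------------------
    gamma: float = 10.0 ** -11.5     # mmol/(ml s)
    beta_c: float = 10.0 ** -11.5    # mmol/ml
    k34: float = 10.0 ** -3.25       # 1/s (scaled by z_scale, see below)
    k_alpha_deg: float = 0.134       # 1/s
    k_gfp_deg: float = 0.00215       # 1/s
    input_conc: float = 192.0        # ug/ml applied at logical 1
    cell_density: float = 5.0e6      # cells/ml

    # -- Hill terms --------------------------------------------------------
    hill_rep: float = 3.0            # repression cooperativity
    hill_in: float = 2.0             # input-induction cooperativity
    K_u: float = 40.0                # ug/ml, input half-saturation

    # -- sender cells ------------------------------------------------------
    k_tx: float = 4.0e-12            # mmol/(ml s) max induced transcription
    k_tx0: float = 1.0e-16           # mmol/(ml s) basal transcription
    k_tl: float = 1.0e-2             # 1/s translation
    k_sec: float = 1.0e-3            # 1/s secretion
    d_m: float = 1.0e-3              # 1/s mRNA decay
    d_p: float = 1.0e-4              # 1/s protein decay

    # -- pheromone pathway / NOT cells ------------------------------------
    k_act: float = 1.0e-2            # 1/s pathway activation
    k_deact: float = 3.0e-3          # 1/s pathway deactivation
    K_L: float = 5.9e-16             # mmol/ml ligand half-saturation
    F_tot: float = 1.0e-9            # mmol/ml total pathway capacity
    d_Z: float = 7.0e-4              # 1/s repressor decay
    z_scale: float = 2.4e-11         # mmol/ml reference conc. turning k34 into a flux

    # -- reporter ----------------------------------------------------------
    k_gfp: float = 1.0               # dimensionless co-expression factor

    # -- asymmetric circuits ----------------------------------------------
    overrides: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rates = (
            "gamma", "k34", "k_alpha_deg", "k_gfp_deg", "input_conc",
            "k_tx", "k_tx0", "k_tl", "k_sec", "d_m", "d_p",
            "k_act", "k_deact", "K_L", "F_tot", "d_Z", "z_scale", "k_gfp",
        )
        for name in rates:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.beta_c <= 0:
            raise ValueError("beta_c must be > 0")
        if self.cell_density <= 0:
            raise ValueError("cell_density must be > 0")
        if self.hill_rep < 1 or self.hill_in < 1:
            raise ValueError("Hill coefficients must be >= 1")
        unknown_cells = set(self.overrides) - set(_CELL_NAMES)
        if unknown_cells:
            raise ValueError(f"unknown override cells: {sorted(unknown_cells)}")
        valid = {f.name for f in fields(self)} - {"overrides"}
        for cell, mapping in self.overrides.items():
            bad = set(mapping) - valid
            if bad:
                raise ValueError(f"unknown override keys for {cell}: {sorted(bad)}")

    # -- helpers -----------------------------------------------------------

    @property
    def vol_frac(self) -> float:
        """Fraction of culture volume occupied by one cell type."""
        return self.cell_density * _V_CELL

    def for_cell(self, cell: str) -> "CircuitParams":
        """Effective parameter view for one cell type (applies overrides)."""
        over = self.overrides.get(cell)
        if not over:
            return self
        return replace(self, overrides={}, **dict(over))

    def is_symmetric(self) -> bool:
        """True when the X side and Y side see identical parameters."""
        return self.for_cell("cell1") == self.for_cell("cell2") and (
            self.for_cell("cell3") == self.for_cell("cell4")
        )

    def with_(self, **kwargs: object) -> "CircuitParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


def default_params() -> CircuitParams:
    """Reference parameter set for the symmetric consortium.

    The auxiliary constants were calibrated (see package docs) so that,
    at ``input_conc`` = 192 ug/ml, the circuit is bistable at
    ``k_alpha_deg`` = 0.134 1/s and monostable at 30 1/s.
    """
    return CircuitParams()


def repressible_promoter_activity(
    Z: float, gamma: float, beta_c: float, hill_rep: float
) -> float:
    """Transcription rate of the Z-repressible promoter.

    Returns ``gamma / (1 + (Z / beta_c) ** hill_rep)``; equals ``gamma``
    with no repressor and decays to zero as Z grows.
    """
    if beta_c <= 0:
        raise ValueError("beta_c must be > 0")
    if np.any(np.asarray(Z) < 0):
        raise ValueError("repressor concentration must be >= 0")
    return gamma / (1.0 + (Z / beta_c) ** hill_rep)


def _sender_derivs(M, A, level, p: CircuitParams):
    if level > 0:
        u = level ** p.hill_in
        induction = p.k_tx * u / (p.K_u ** p.hill_in + u)
    else:
        induction = 0.0
    dM = induction + p.k_tx0 - p.d_m * M
    dA = p.k_tl * M - (p.k_sec + p.d_p) * A
    return dM, dA


def _not_cell_derivs(F, Z, phi, ligand, p: CircuitParams):
    u = ligand / (p.K_L + ligand) if ligand > 0 else 0.0
    dF = p.k_act * u * (p.F_tot - F) - p.k_deact * F
    dZ = p.k34 * p.z_scale * (F / p.F_tot) - p.d_Z * Z
    dphi = repressible_promoter_activity(Z, p.gamma, p.beta_c, p.hill_rep) - (
        p.k_sec + p.d_p
    ) * phi
    return dF, dZ, dphi


def rhs(
    state: np.ndarray,
    t: float,
    params: CircuitParams,
    inputs: tuple[float, float],
    *,
    clamp_medium: bool = False,
    validate: bool = True,
) -> np.ndarray:
    """Time derivative of the full consortium state.

    ``inputs`` is the pair of external concentrations (R, S) in ug/ml.
    With ``clamp_medium`` the medium pools are held fixed (used for
    pre-equilibration without cell communication).
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (N_STATE,):
        raise ValueError(f"state must have {N_STATE} components")
    R, S = inputs
    if validate:
        if np.any(y < 0):
            raise ValueError("negative state component (integrator failure?)")
        if R < 0 or S < 0:
            raise ValueError("inputs must be >= 0")

    p1 = params.for_cell("cell1")
    p2 = params.for_cell("cell2")
    p3 = params.for_cell("cell3")
    p4 = params.for_cell("cell4")

    d = np.empty(N_STATE)
    d[iM1], d[iA1] = _sender_derivs(y[iM1], y[iA1], R, p1)
    d[iM2], d[iA2] = _sender_derivs(y[iM2], y[iA2], S, p2)

    # cell 3 senses Y, produces/secretes X; cell 4 the mirror image
    d[iF3], d[iZ3], d[iPHI_X] = _not_cell_derivs(
        y[iF3], y[iZ3], y[iPHI_X], y[iY], p3
    )
    d[iF4], d[iZ4], d[iPHI_Y] = _not_cell_derivs(
        y[iF4], y[iZ4], y[iPHI_Y], y[iX], p4
    )

    if clamp_medium:
        d[iX] = 0.0
        d[iY] = 0.0
    else:
        # cell 1 secretes Y (sensed by cell 3), cell 2 secretes X
        d[iY] = (
            p1.vol_frac * p1.k_sec * y[iA1]
            + p4.vol_frac * p4.k_sec * y[iPHI_Y]
            - params.k_alpha_deg * y[iY]
        )
        d[iX] = (
            p2.vol_frac * p2.k_sec * y[iA2]
            + p3.vol_frac * p3.k_sec * y[iPHI_X]
            - params.k_alpha_deg * y[iX]
        )

    d[iG] = (
        p4.k_gfp
        * repressible_promoter_activity(y[iZ4], p4.gamma, p4.beta_c, p4.hill_rep)
        - params.k_gfp_deg * y[iG]
    )
    return d


#: Permutation realizing the X<->Y relabeling (cells 1<->2, 3<->4).
#: The reporter G is left in place: it tracks cell 4 only and has no
#: feedback on the rest of the system.
_MIRROR_PERM = np.array(
    [iM2, iA2, iM1, iA1, iF4, iZ4, iPHI_Y, iF3, iZ3, iPHI_X, iY, iX, iG]
)


def mirror_state(state: np.ndarray) -> np.ndarray:
    """Relabel a state under the X<->Y exchange symmetry."""
    return np.asarray(state, dtype=float)[_MIRROR_PERM]
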