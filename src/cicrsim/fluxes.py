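"""Pointwise reaction-flux kernels for the coupled cytosol/SR model.

Every function here is a pure, local (elementwise) kernel operating on
concentration fields in the internal uM / um / ms unit system — pass
``ModelParams.internal()``, not raw literature-unit parameters.  Sign
conventions follow the transport equations: a flux is the term as it appears
on the right-hand side of the cytosolic Ca2+ equation, so dye/buffer fluxes
are negative while Ca2+ is being bound.

The Ca2+ release unit (CRU) source is a sum of Dirac deltas at lattice
sites.  On the grid each delta is realised as a point deposition into its
containing cell: the molar source strength (uM um^ndim / ms) divided by the
cell measure (dx in 1-D, dx*dy in 2-D).  Converting the three-dimensional
molar flux sigma3 = I_CRU / (2 F_c) to its 1-D line and 2-D sheet
equivalents uses fixed factors (0.19 and 0.51 by default), because a line
or sheet source is not equivalent to a row of discrete point sources.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .params import InternalParams, GridSpec

__all__ = [
    "pump_flux",
    "passive_leaks",
    "dye_flux",
    "buffer_rhs",
    "cru_source_strength",
    "cru_source",
    "ryr_source",
    "dye_equilibrium",
    "buffer_equilibrium",
]

#: uM um^3 per mol: 1 mol spread over 1 L equals 1e6 uM, and 1 L = 1e15 um^3.
_MOL_TO_UM3_UM = 1e21


def _check_nonnegative(name: str, field: np.ndarray) -> None:
    if np.any(np.asarray(field) < 0):
        raise ValueError(f"{name} must be nonnegative everywhere")


def pump_flux(C: np.ndarray, p: InternalParams) -> np.ndarray:
    """SERCA uptake J_pump = V_pump C^n / (K_pump^n + C^n), uM/ms.

    Monotone nondecreasing in C and bounded above by V_pump.
    """
    C = np.asarray(C, dtype=float)
    _check_nonnegative("C", C)
    Cn = C ** p.n_pump
    return p.V_pump * Cn / (p.K_pump ** p.n_pump + Cn)


def passive_leaks(C: np.ndarray, C_S: np.ndarray,
                  p: InternalParams) -> Tuple[np.ndarray, np.ndarray]:
    """Linear leaks (J_Ca2+leak, J_SRleak) = (k*C, k_f*C_S), uM/ms."""
    C = np.asarray(C, dtype=float)
    C_S = np.asarray(C_S, dtype=float)
    _check_nonnegative("C", C)
    _check_nonnegative("C_S", C_S)
    return p.k * C, p.k_f * C_S


def _dye_constants(p: InternalParams, compartment: str):
    if compartment == "cytosol":
        return p.kf_plus, p.kf_minus, p.F_T
    if compartment == "SR":
        return p.K_F_plus, p.K_F_minus, p.F_T_SR
    raise ValueError(f"compartment must be 'cytosol' or 'SR', got {compartment!r}")


def _buffer_constants(p: InternalParams, compartment: str):
    if compartment == "cytosol":
        return p.kB_plus, p.kB_minus, p.B_T
    if compartment == "SR":
        return p.K_CSQ_plus, p.K_CSQ_minus, p.B_T_SR
    raise ValueError(f"compartment must be 'cytosol' or 'SR', got {compartment!r}")


def dye_flux(C: np.ndarray, CaF: np.ndarray, p: InternalParams,
             compartment: str = "cytosol") -> np.ndarray:
    """Net dye exchange J_dye = -k+ C ([F]_T - [CaF]) + k- [CaF], uM/ms.

    Negative while Ca2+ binds to free dye; zero at binding equilibrium.
    """
    kp, km, FT = _dye_constants(p, compartment)
    C = np.asarray(C, dtype=float)
    CaF = np.asarray(CaF, dtype=float)
    if np.any(CaF > FT * (1 + 1e-12) + 1e-12):
        raise ValueError(f"CaF exceeds the total dye pool {FT}")
    return -kp * C * (FT - CaF) + km * CaF


def buffer_rhs(C: np.ndarray, CaB: np.ndarray, p: InternalParams,
               compartment: str = "cytosol") -> np.ndarray:
    """Mass-action d[CaB]/dt = k+ C ([B]_T - [CaB]) - k- [CaB], uM/ms.

    The transport-equation flux is J_buffer = -d[CaB]/dt.
    """
    kp, km, BT = _buffer_constants(p, compartment)
    C = np.asarray(C, dtype=float)
    CaB = np.asarray(CaB, dtype=float)
    if np.any(CaB > BT * (1 + 1e-12) + 1e-12):
        raise ValueError(f"CaB exceeds the total buffer pool {BT}")
    return kp * C * (BT - CaB) - km * CaB


def dye_equilibrium(C: float, p: InternalParams, compartment: str = "cytosol"):
    """Bound-dye concentration at binding equilibrium with free Ca2+ level C."""
    kp, km, FT = _dye_constants(p, compartment)
    return kp * C * FT / (kp * C + km)


def buffer_equilibrium(C: float, p: InternalParams, compartment: str = "cytosol"):
    """Bound-buffer concentration at binding equilibrium with Ca2+ level C."""
    kp, km, BT = _buffer_constants(p, compartment)
    return kp * C * BT / (kp * C + km)


def sigma3(p: InternalParams) -> float:
    """Three-dimensional molar source strength I_CRU / (2 F_c), uM um^3 / ms."""
    # pA -> A (1e-12), /C mol^-1 -> mol/s, -> uM um^3/s (1e21), -> per ms (1e-3)
    return p.I_CRU * 1e-12 / (2.0 * p.F_c) * _MOL_TO_UM3_UM * 1e-3


def cru_source_strength(p: InternalParams, grid: GridSpec, ndim: int) -> float:
    """On-grid CRU deposition rate per open channel, uM/ms at the channel node.

    sigma3 = I_CRU/(2 F_c) converted to uM um^3/ms, scaled by the
    dimensional conversion factor (sigma_factor_1d or sigma_factor_2d) and
    divided by the grid cell measure to realise the Dirac delta.
    """
    if ndim == 1:
        factor, measure = p.sigma_factor_1d, grid.dx
    elif ndim == 2:
        factor, measure = p.sigma_factor_2d, grid.dx * grid.dy
    else:
        raise ValueError(f"unsupported dimensionality ndim={ndim!r} (use 1 or 2)")
    return factor * sigma3(p) / measure


def cru_source(lattice, p: InternalParams, grid: GridSpec) -> np.ndarray:
    """J_CRU field, uM/ms: point deposition at every open channel node."""
    J = np.zeros(grid.shape)
    open_idx = lattice.open_indices()
    if len(open_idx):
        amp = cru_source_strength(p, grid, grid.ndim)
        if grid.ndim == 1:
            np.add.at(J, open_idx[:, 0], amp)
        else:
            np.add.at(J, (open_idx[:, 0], open_idx[:, 1]), amp)
    return J


def ryr_source(C: np.ndarray, C_S: np.ndarray, lattice, p: InternalParams,
               grid: GridSpec) -> np.ndarray:
    """J_RyR field, uM/ms, for the SR equation of the improved variant.

    At each open channel node the flux is sigma_RyR = I_RyR/(2 F_c * cell
    measure) times the local concentration difference (C - C_S); since the
    cytosol sits far below the SR during release the term drains the SR.
    Zero away from open channels.
    """
    C = np.asarray(C, dtype=float)
    C_S = np.asarray(C_S, dtype=float)
    if C.shape != grid.shape or C_S.shape != grid.shape:
        raise ValueError(
            f"field shapes {C.shape}, {C_S.shape} do not match grid {grid.shape}"
        )
    J = np.zeros(grid.shape)
    open_idx = lattice.open_indices()
    if len(open_idx):
        coef = (p.I_RyR * 1e-12 / (2.0 * p.F_c) * _MOL_TO_UM3_UM * 1e-3) / grid.cell_measure
        if grid.ndim == 1:
            ix = open_idx[:, 0]
            np.add.at(J, ix, coef * (C[ix] - C_S[ix]))
        else:
            ix, iy = open_idx[:, 0], open_idx[:, 1]
            np.add.at(J, (ix, iy), coef * (C[ix, iy] - C_S[ix, iy]))
    return J
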