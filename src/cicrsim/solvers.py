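"""Deterministic numerical stepping: Crank-Nicolson, ADI and forward Euler.

The transport equations all share the pattern

    du/dt = D_x u_xx + D_y u_yy - decay * u + source(x, t)

with zero-flux (reflecting) boundaries.  In 1-D they are advanced with the
Crank-Nicolson scheme; in 2-D with Peaceman-Rachford ADI: an x-implicit /
y-explicit half sweep followed by a y-implicit / x-explicit one.  The linear
decay (the k or k_f leak term) enters the implicit diagonal; every nonlinear
reaction term is evaluated at time n and passed in ``source`` (split evenly
across the two ADI sweeps).  Zero-flux boundaries use mirror ghost nodes,
which is second-order accurate and, together with trapezoid cell weights,
makes the schemes conserve discrete mass exactly when decay and source
vanish.

Each implicit sweep is a tridiagonal solve (Thomas algorithm, O(n)),
delegated to LAPACK's banded solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
from scipy.linalg import solve_banded
from scipy.linalg.lapack import dgtsv as _dgtsv

from .params import InternalParams

__all__ = [
    "TridiagonalSystem",
    "StateFields",
    "thomas_solve",
    "cn_step_1d",
    "adi_step_2d",
    "euler_step",
    "total_mass",
]


@dataclass
class TridiagonalSystem:
    """A*x = rhs with A tridiagonal.

    ``lower``/``upper`` have length n-1 (sub/super diagonal), ``diag`` and
    ``rhs`` length n.
    """

    lower: np.ndarray
    diag: np.ndarray
    upper: np.ndarray
    rhs: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.diag = np.atleast_1d(np.asarray(self.diag, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        self.rhs = np.asarray(self.rhs, dtype=float)
        n = len(self.diag)
        if n > 1 and (len(self.lower) != n - 1 or len(self.upper) != n - 1):
            raise ValueError("lower/upper must have length n-1")
        if self.rhs.shape[0] != n:
            raise ValueError("rhs length does not match diag")


def thomas_solve(system: TridiagonalSystem) -> np.ndarray:
    """Solve the tridiagonal system in O(n); raises on a singular matrix."""
    n = len(system.diag)
    if n == 1:
        if system.diag[0] == 0:
            raise np.linalg.LinAlgError("singular tridiagonal system (zero pivot)")
        return system.rhs / system.diag[0]
    ab = np.zeros((3, n))
    ab[0, 1:] = system.upper
    ab[1, :] = system.diag
    ab[2, :-1] = system.lower
    try:
        return solve_banded((1, 1), ab, system.rhs)
    except np.linalg.LinAlgError:
        raise
    except Exception as exc:  # LAPACK signals singularity via ValueError
        raise np.linalg.LinAlgError(f"singular tridiagonal system: {exc}") from exc


def _mirror_stencil(u: np.ndarray, axis: int = 0) -> np.ndarray:
    """Unscaled second difference u_{i-1} - 2 u_i + u_{i+1} with mirror ghosts.

    At the boundaries the ghost value equals the first interior neighbour,
    giving 2*(u_1 - u_0) — the discrete zero-flux condition.
    """
    out = np.empty_like(u)
    if axis == 0:
        out[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
        out[0] = 2.0 * (u[1] - u[0])
        out[-1] = 2.0 * (u[-2] - u[-1])
    else:
        out[:, 1:-1] = u[:, :-2] - 2.0 * u[:, 1:-1] + u[:, 2:]
        out[:, 0] = 2.0 * (u[:, 1] - u[:, 0])
        out[:, -1] = 2.0 * (u[:, -2] - u[:, -1])
    return out


def _tridiag_solve_fast(n: int, r: float, theta: float, rhs: np.ndarray) -> np.ndarray:
    """Solve ((1+r+theta) I - (r/2) mirror-Laplacian) x = rhs via LAPACK gtsv.

    ``rhs`` is (n,) or (n, nrhs); the boundary rows carry the doubled
    off-diagonal entry of the mirror-ghost discretisation.
    """
    dl = np.full(n - 1, -r / 2.0)
    du = np.full(n - 1, -r / 2.0)
    du[0] = -r
    dl[-1] = -r
    d = np.full(n, 1.0 + r + theta)
    b = np.asfortranarray(rhs) if rhs.ndim == 2 else rhs.copy()
    _, _, _, x, info = _dgtsv(dl, d, du, b, 1, 1, 1, 1)
    if info != 0:
        raise np.linalg.LinAlgError(f"tridiagonal solve failed (info={info})")
    return x


def cn_step_1d(field: np.ndarray, Dcoef: float, decay: float,
               source: Optional[np.ndarray], dx: float, dt: float) -> np.ndarray:
    """One Crank-Nicolson step of du/dt = D u_xx - decay*u + source.

    Diffusion and the linear decay are time-centred (half explicit, half
    implicit); ``source`` holds all lagged reaction terms at time n and is
    applied with weight dt.  Zero-flux boundaries.
    """
    if Dcoef < 0:
        raise ValueError(f"negative diffusivity {Dcoef!r}")
    field = np.asarray(field, dtype=float)
    n = field.shape[0]
    r = Dcoef * dt / dx**2
    theta = decay * dt / 2.0
    rhs = (1.0 - theta) * field + (r / 2.0) * _mirror_stencil(field)
    if source is not None:
        rhs += dt * np.asarray(source, dtype=float)
    return _tridiag_solve_fast(n, r, theta, rhs)


def adi_step_2d(field: np.ndarray, Dx: float, Dy: float, decay: float,
                source: Optional[np.ndarray], dx: float, dy: float,
                dt: float) -> np.ndarray:
    """One Peaceman-Rachford ADI step of du/dt = Dx u_xx + Dy u_yy - decay*u + source.

    Half sweep 1 is implicit in x, explicit in y; half sweep 2 the reverse.
    The decay term sits on the implicit diagonal of each sweep and the
    lagged reaction bundle ``source`` is added with weight dt/2 per sweep.
    For a y-uniform field with decay = 0 the step reduces exactly to
    :func:`cn_step_1d` on every x slice.
    """
    if Dx < 0 or Dy < 0:
        raise ValueError(f"negative diffusivity ({Dx!r}, {Dy!r})")
    field = np.asarray(field, dtype=float)
    nx, ny = field.shape
    rx = Dx * dt / dx**2
    ry = Dy * dt / dy**2
    theta = decay * dt / 2.0
    half_src = None if source is None else (dt / 2.0) * np.asarray(source, dtype=float)

    rhs = field + (ry / 2.0) * _mirror_stencil(field, axis=1)
    if half_src is not None:
        rhs += half_src
    star = _tridiag_solve_fast(nx, rx, theta, rhs)

    rhs = star + (rx / 2.0) * _mirror_stencil(star, axis=0)
    if half_src is not None:
        rhs += half_src
    return _tridiag_solve_fast(ny, ry, theta, rhs.T).T


def euler_step(field: np.ndarray, rhs: np.ndarray, dt: float) -> np.ndarray:
    """Forward Euler: field + dt * rhs (used for the immobile-buffer ODEs)."""
    return np.asarray(field, dtype=float) + dt * np.asarray(rhs, dtype=float)


def total_mass(field: np.ndarray, dx: float, dy: Optional[float] = None) -> float:
    """Trapezoid-weighted integral of a field over the domain.

    Boundary nodes own half cells under the mirror-ghost discretisation;
    with these weights the CN and ADI steps conserve the integral exactly
    when decay and source are zero.
    """
    field = np.asarray(field, dtype=float)
    wx = np.ones(field.shape[0]) * dx
    wx[0] = wx[-1] = dx / 2.0
    if field.ndim == 1:
        return float(np.sum(wx * field))
    wy = np.ones(field.shape[1]) * dy
    wy[0] = wy[-1] = dy / 2.0
    return float(wx @ field @ wy)


# ---------------------------------------------------------------------------
# Simulation state
# ---------------------------------------------------------------------------

_BOUND_TOL = 1e-9


@dataclass
class StateFields:
    """Concentration fields on the grid, uM.

    ``C``/``CaF``/``CaB`` are the cytosolic free Ca2+, bound dye and bound
    buffer; ``C_S`` the SR free Ca2+; ``CaF_SR``/``CaB_SR`` the SR bound
    dye/buffer (present only in the improved variant).
    """

    C: np.ndarray
    C_S: np.ndarray
    CaF: Optional[np.ndarray] = None
    CaB: Optional[np.ndarray] = None
    CaF_SR: Optional[np.ndarray] = None
    CaB_SR: Optional[np.ndarray] = None

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {k: v for k, v in self.__dict__.items() if v is not None}

    def enforce_bounds(self, p: InternalParams) -> None:
        """Clip round-off excursions (< 1e-9) and abort on real violations.

        Fields must stay nonnegative and bound pools below their totals; a
        breach beyond the tolerance indicates an unstable step and raises.
        """
        caps = {"C": None, "C_S": None, "CaF": p.F_T, "CaB": p.B_T,
                "CaF_SR": p.F_T_SR, "CaB_SR": p.B_T_SR}
        for name, arr in self.as_dict().items():
            lo = arr.min()
            if lo < -_BOUND_TOL:
                raise FloatingPointError(
                    f"{name} reached {lo:g} < 0: unstable step (reduce dt)"
                )
            cap = caps[name]
            if cap is not None:
                hi = arr.max()
                if hi > cap + _BOUND_TOL:
                    raise FloatingPointError(
                        f"{name} reached {hi:g} > total {cap:g}: unstable step"
                    )
                np.clip(arr, 0.0, cap, out=arr)
            else:
                np.maximum(arr, 0.0, out=arr)
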