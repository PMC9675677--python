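"""Stochastic Ca2+ release-unit (CRU) lattice and gating.

A CRU is the atomic stochastic unit: a cluster of RyRs opening together.
Units sit on a regular lattice (spacing lx_chan longitudinally, ly_chan
transversely, aligned to grid nodes starting at x = 0) and obey a
three-state life cycle::

    closed --fire--> open --T_open elapsed--> spent

Closure is absorbing: a spent unit never reopens, so a single run models a
single wave.  Firing is a per-step Bernoulli trial driven by the local
cytosolic Ca2+ through the saturating probability rate

    P(C) = P_max * C^n_prob / (K_prob + C^n_prob)        [ms^-1 internally]

Under the default "rate" rule a closed unit fires when u < P(C) * dt with
u ~ U(0,1); the opt-in "literal" rule compares u < P(C)/P_max instead (a
published alternative that ignores the step size and therefore makes the
firing rate grid-dependent).  One uniform draw is consumed per channel per
step in fixed row-major channel order from a single PCG64 stream, so
trajectories are bit-reproducible for a given seed regardless of how the
update is vectorised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InternalParams, GridSpec, ValidationError

__all__ = [
    "CRULattice",
    "build_lattice",
    "firing_probability",
    "step_gates",
    "force_initiation",
    "CLOSED",
    "OPEN",
    "SPENT",
]

CLOSED, OPEN, SPENT = 0, 1, 2


@dataclass
class CRULattice:
    """Release-unit positions (grid indices) and per-unit gate state.

    ``positions`` has shape (n, ndim) with integer grid indices; ``state``
    holds CLOSED/OPEN/SPENT codes and ``remaining_open`` the open time left
    in ms (positive iff open).
    """

    positions: np.ndarray
    state: np.ndarray
    remaining_open: np.ndarray
    ndim: int

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.intp))
        self.state = np.asarray(self.state, dtype=np.int8)
        self.remaining_open = np.asarray(self.remaining_open, dtype=float)
        n = len(self.positions)
        if not (len(self.state) == len(self.remaining_open) == n):
            raise ValueError("positions, state and remaining_open lengths differ")

    @property
    def n_channels(self) -> int:
        return len(self.positions)

    def open_indices(self) -> np.ndarray:
        """Grid indices of currently open channels, shape (n_open, ndim)."""
        return self.positions[self.state == OPEN]

    def copy(self) -> "CRULattice":
        return CRULattice(self.positions.copy(), self.state.copy(),
                          self.remaining_open.copy(), self.ndim)


def build_lattice(grid: GridSpec) -> CRULattice:
    """Uniform all-closed CRU lattice over the full domain.

    Channels sit at x = 0, lx_chan, ..., Lx (boundaries included) and, in
    2-D, y = 0, ly_chan, ..., Ly; the GridSpec invariants guarantee these
    coincide with grid nodes.
    """
    sx = int(round(grid.lx_chan / grid.dx))
    xs = np.arange(0, grid.nx, sx, dtype=np.intp)
    if grid.ndim == 1:
        positions = xs[:, None]
    else:
        sy = int(round(grid.ly_chan / grid.dy))
        ys = np.arange(0, grid.ny, sy, dtype=np.intp)
        gx, gy = np.meshgrid(xs, ys, indexing="ij")
        positions = np.column_stack([gx.ravel(), gy.ravel()])
    n = len(positions)
    return CRULattice(positions, np.zeros(n, dtype=np.int8), np.zeros(n), grid.ndim)


def firing_probability(C_at_channels: np.ndarray, p: InternalParams) -> np.ndarray:
    """Per-channel firing probability rate P(C), ms^-1 for internal params.

    ``P = P_max C^n / (K_prob + C^n)`` as the source model prints it; with
    ``p.kprob_hill`` the denominator constant is raised to n_prob as well
    (the form the SERCA pump uses).
    """
    C = np.asarray(C_at_channels, dtype=float)
    Cn = C ** p.n_prob
    K = p.K_prob ** p.n_prob if p.kprob_hill else p.K_prob
    return p.P_max * Cn / (K + Cn)


def _field_at(field: np.ndarray, positions: np.ndarray, ndim: int) -> np.ndarray:
    if ndim == 1:
        return field[positions[:, 0]]
    return field[positions[:, 0], positions[:, 1]]


def step_gates(lattice: CRULattice, C: np.ndarray, p: InternalParams,
               dt: float, rng: np.random.Generator) -> CRULattice:
    """Advance all gates by one step of length dt (in place; also returned).

    Open channels first run down their remaining open time and become spent
    at zero; then every closed channel draws one uniform and fires according
    to the configured rule.  Newly fired channels start their T_open clock
    on the next step.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    # Countdown for channels that were already open.
    was_open = lattice.state == OPEN
    lattice.remaining_open[was_open] -= dt
    expired = was_open & (lattice.remaining_open <= 1e-12)
    lattice.state[expired] = SPENT
    lattice.remaining_open[expired] = 0.0

    # One draw per channel per step, fixed order (vectorisation-independent).
    u = rng.random(lattice.n_channels)
    P = firing_probability(_field_at(C, lattice.positions, lattice.ndim), p)
    if p.firing_rule == "literal":
        threshold = P / p.P_max
    else:
        threshold = P * dt
        if np.any(threshold > 1.0):
            raise ValidationError(
                f"P*dt reaches {threshold.max():g} > 1: not a per-step probability"
            )
    fired = (lattice.state == CLOSED) & (u < threshold)
    lattice.state[fired] = OPEN
    lattice.remaining_open[fired] = p.T_open
    return lattice


def force_initiation(lattice: CRULattice, grid: GridSpec,
                     p: InternalParams) -> CRULattice:
    """Open the two central initiation columns at t = 0 (in place).

    Two columns of point sources one grid spacing apart at the middle of
    the domain (x = 50 and 50.4 um on the default mesh) are force-activated
    to start a wave.  The columns live on grid columns nearest Lx/2 and
    Lx/2 + dx; rows follow the channel lattice.  Channels not already in
    the lattice are appended.  Idempotent.
    """
    ix1 = int(round((grid.Lx / 2.0) / grid.dx))
    ix2 = ix1 + 1
    if ix2 >= grid.nx:
        raise ValueError("domain too small for the two initiation columns")
    if grid.ndim == 1:
        wanted = np.array([[ix1], [ix2]], dtype=np.intp)
    else:
        sy = int(round(grid.ly_chan / grid.dy))
        ys = np.arange(0, grid.ny, sy, dtype=np.intp)
        wanted = np.array([(ix, iy) for ix in (ix1, ix2) for iy in ys], dtype=np.intp)

    existing = {tuple(pos) for pos in lattice.positions}
    to_add = [pos for pos in wanted if tuple(pos) not in existing]
    if to_add:
        lattice.positions = np.vstack([lattice.positions, np.array(to_add, dtype=np.intp)])
        lattice.state = np.concatenate([lattice.state, np.zeros(len(to_add), dtype=np.int8)])
        lattice.remaining_open = np.concatenate([lattice.remaining_open, np.zeros(len(to_add))])

    pos_map = {tuple(pos): i for i, pos in enumerate(lattice.positions)}
    idx = np.array([pos_map[tuple(pos)] for pos in wanted], dtype=np.intp)
    fresh = lattice.state[idx] != SPENT
    lattice.state[idx[fresh]] = OPEN
    lattice.remaining_open[idx[fresh]] = np.maximum(
        lattice.remaining_open[idx[fresh]], p.T_open
    )
    return lattice
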