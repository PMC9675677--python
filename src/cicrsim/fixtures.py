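"""Miniature test scenarios: tiny grids, single channels, analytic profiles.

``make_fixture`` writes small config/state files so every module can be
exercised in seconds; the in-memory builders it wraps are also used directly
by the test suite.  All fixtures are synthetic constructions, not recorded
data.
"""

from __future__ import annotations

import os
from typing import Dict, Tuple

import numpy as np

from . import fluxes
from .params import GridSpec, ModelParams, write_config
from .solvers import StateFields

__all__ = [
    "FIXTURE_KINDS",
    "make_fixture",
    "tiny_grid",
    "single_channel_setup",
    "gaussian_profile",
    "equilibrium_state",
]

FIXTURE_KINDS = ("tiny-grid", "single-channel", "gaussian-ic", "equilibrium-state")


def tiny_grid(ndim: int = 1, duration: float = 1.0) -> GridSpec:
    """A 10 x 1.6 um domain at the production mesh: fast but fully featured."""
    return GridSpec(Lx=10.0, Ly=1.6, dx=0.4, dy=0.8 / 3.0, dt=0.003125,
                    duration=duration, ndim=ndim, lx_chan=2.0, ly_chan=0.8)


def single_channel_setup(ndim: int = 1) -> Tuple[ModelParams, GridSpec]:
    """Tiny domain whose channel lattice reduces to very few sites.

    With the firing probability forced to zero only the two forced-init
    columns (one channel each in 1-D) release, giving a deterministic
    single-spark trace.
    """
    params = ModelParams(P_max=0.0)
    return params, tiny_grid(ndim=ndim, duration=5.0)


def gaussian_profile(grid: GridSpec, amplitude: float = 10.0,
                     width_um: float = 1.0) -> np.ndarray:
    """Gaussian bump centred in the domain, for closed-form diffusion checks."""
    x = grid.x()
    gx = np.exp(-((x - grid.Lx / 2.0) ** 2) / (2.0 * width_um**2))
    if grid.ndim == 1:
        return amplitude * gx
    y = grid.y()
    gy = np.exp(-((y - grid.Ly / 2.0) ** 2) / (2.0 * width_um**2))
    return amplitude * gx[:, None] * gy[None, :]


def equilibrium_state(params: ModelParams, grid: GridSpec,
                      variant: str = "improved") -> StateFields:
    """Uniform resting state with every dye/buffer pool at detailed balance."""
    from .simulator import initial_state

    return initial_state(params, grid, variant, include_buffer_dye=True)


def make_fixture(kind: str, seed: int, out_dir: str) -> Dict[str, str]:
    """Write the requested fixture files under ``out_dir``; returns the paths."""
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from {FIXTURE_KINDS}")
    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    if kind == "tiny-grid":
        grid = tiny_grid()
        path = os.path.join(out_dir, "tiny_grid.ini")
        write_config(path, ModelParams(), grid, {"seed": seed, "model": "basic"})
        paths["config"] = path

    elif kind == "single-channel":
        params, grid = single_channel_setup()
        path = os.path.join(out_dir, "single_channel.ini")
        write_config(path, params, grid, {"seed": seed, "model": "basic"})
        paths["config"] = path

    elif kind == "gaussian-ic":
        grid = tiny_grid(ndim=1)
        field = gaussian_profile(grid)
        path = os.path.join(out_dir, "gaussian_ic.csv")
        np.savetxt(path, np.column_stack([grid.x(), field]),
                   delimiter=",", header="x_um,value_uM", comments="")
        paths["initial_condition"] = path

    else:  # equilibrium-state
        params = ModelParams()
        grid = tiny_grid(ndim=1)
        st = equilibrium_state(params, grid)
        path = os.path.join(out_dir, "equilibrium_state.csv")
        cols = st.as_dict()
        np.savetxt(path, np.column_stack([grid.x()] + [v for v in cols.values()]),
                   delimiter=",", header=",".join(["x_um"] + list(cols)), comments="")
        paths["state"] = path

    return paths
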