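"""Model parameters and grid geometry for the coupled Ca2+ spark/blink model.

Two parameter containers are defined:

``ModelParams``
    Every rate constant, diffusivity, pool total and gating parameter of the
    coupled cytosol/SR model, stored in the units the cardiac-myocyte
    literature quotes them in (concentrations in uM, diffusivities in
    um^2 s^-1, first-order rates in s^-1, currents in pA).  The defaults are
    the standard parameter set for a diseased ventricular myocyte with fluo-3
    in the cytosol and, for the improved SR variant, fluo-5N and
    calsequestrin in the SR.

``GridSpec``
    The finite-difference domain: a 100 x 20 um slab of cytosol meshed at
    0.4 um longitudinally (x) and 0.8/3 um transversely (y), stepped at
    0.003125 ms.  x is the long axis of the cell; the release-unit lattice
    spacings (lx = 2 um, ly = 0.8 um) and the sensor transverse offset
    (9.6 um) are integer multiples of the grid only under this convention.

Because the time step is in milliseconds, every computation inside the
package runs in a uniform uM / um / ms unit system: :meth:`ModelParams.internal`
returns a converted view with all per-second rates and diffusivities divided
by 1000.  Nothing outside that method converts units.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from typing import Any, Dict, Mapping, Optional, Tuple

__all__ = [
    "ModelParams",
    "InternalParams",
    "GridSpec",
    "ConfigError",
    "ValidationError",
    "load_config",
    "write_config",
    "validate_stability",
    "improved_params",
]

FIRING_RULES = ("rate", "literal")


class ConfigError(ValueError):
    """A config file could not be parsed (message names the offending line)."""


class ValidationError(ValueError):
    """A parameter violated an invariant (message names the field)."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set, in literature units (uM, um^2/s, s^-1, pA, ms).

    Attributes
    ----------
    D_Cx, D_Cy : float
        Cytosolic free-Ca2+ diffusivity, um^2/s.
    D_Dx, D_Dy : float
        Cytosolic Ca2+-bound dye (fluo-3) diffusivity, um^2/s.
    D_CSx, D_CSy : float
        SR free-Ca2+ diffusivity, um^2/s.
    D_F : float
        SR Ca2+-bound dye (fluo-5N) diffusivity, um^2/s.
    C_rest, CS_rest : float
        Resting cytosolic and SR Ca2+, uM.  The basic coupled variant uses
        an SR resting level of 640 uM; the improved SR variant uses 954 uM.
    V_pump, K_pump, n_pump : float
        SERCA uptake: maximal rate (uM/s), affinity (uM), Hill coefficient.
    k, k_f : float
        Passive efflux rates, s^-1: cytosol -> extracellular (k) and
        SR -> cytosol leak (k_f).
    P_max, K_prob, n_prob : float
        Release-unit firing: maximal firing rate (s^-1), Ca2+ sensitivity
        (uM) and Hill coefficient of the firing-probability function.
    I_CRU, I_RyR : float
        Release currents, pA: the Ca2+ release unit current feeding the
        cytosol and the per-site RyR current used for the SR drain in the
        improved variant.
    F_c : float
        Faraday constant, C/mol.
    kB_plus, kB_minus, B_T : float
        Cytosolic stationary buffer on-rate ((uM s)^-1), off-rate (s^-1)
        and total (uM).
    kf_plus, kf_minus, F_T : float
        Cytosolic dye on-rate ((uM s)^-1), off-rate (s^-1) and total (uM).
    K_CSQ_plus, K_CSQ_minus, B_T_SR : float
        SR buffer (calsequestrin) kinetics and total.
    K_F_plus, K_F_minus, F_T_SR : float
        SR dye (fluo-5N) kinetics and total.
    T_open : float
        Duration a fired release unit stays open, ms.
    sigma_factor_1d, sigma_factor_2d : float
        Dimensionless source-strength conversion factors applied to the 3-D
        molar flux when the release is represented on a 1-D line or 2-D
        sheet (a line source is not equivalent to a row of point sources).
    firing_rule : str
        "rate" (default): a closed unit fires when u < P(C) * dt.
        "literal": a closed unit fires when u < P(C) / P_max, a published
        alternative that ignores the step size (kept for comparison runs).
    kprob_hill : bool
        If True the sensitivity constant in the firing probability is raised
        to n_prob (P = P_max C^n / (K^n + C^n)); default False uses the
        un-exponentiated denominator K + C^n as printed in the source model.
    """

    D_Cx: float = 200.0
    D_Cy: float = 200.0
    D_Dx: float = 20.0
    D_Dy: float = 20.0
    D_CSx: float = 12.0
    D_CSy: float = 12.0
    D_F: float = 1.6

    C_rest: float = 0.1
    CS_rest: float = 640.0

    V_pump: float = 0.208
    K_pump: float = 0.184
    n_pump: float = 3.9

    k: float = 10.0
    k_f: float = 1.0

    P_max: float = 0.3
    K_prob: float = 15.0
    n_prob: float = 1.6

    I_CRU: float = 20.0
    I_RyR: float = 0.07
    F_c: float = 96500.0

    kB_plus: float = 100.0
    kB_minus: float = 100.0
    kf_plus: float = 80.0
    kf_minus: float = 90.0
    B_T: float = 123.0
    F_T: float = 50.0

    K_CSQ_plus: float = 100.0
    K_CSQ_minus: float = 60000.0
    K_F_plus: float = 48.8
    K_F_minus: float = 19520.0
    B_T_SR: float = 0.014
    F_T_SR: float = 20.0

    T_open: float = 10.0

    sigma_factor_1d: float = 0.19
    sigma_factor_2d: float = 0.51

    firing_rule: str = "rate"
    kprob_hill: bool = False

    _NONNEG = (
        "D_Cx", "D_Cy", "D_Dx", "D_Dy", "D_CSx", "D_CSy", "D_F",
        "C_rest", "CS_rest", "V_pump", "K_pump", "n_pump", "k", "k_f",
        "P_max", "K_prob", "n_prob", "I_CRU", "I_RyR",
        "kB_plus", "kB_minus", "kf_plus", "kf_minus", "B_T", "F_T",
        "K_CSQ_plus", "K_CSQ_minus", "K_F_plus", "K_F_minus",
        "B_T_SR", "F_T_SR", "T_open",
        "sigma_factor_1d", "sigma_factor_2d",
    )

    def __post_init__(self) -> None:
        for name in self._NONNEG:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {value!r}")
        if self.F_c <= 0:
            raise ValidationError(f"F_c must be > 0, got {self.F_c!r}")
        if self.firing_rule not in FIRING_RULES:
            raise ValidationError(
                f"firing_rule must be one of {FIRING_RULES}, got {self.firing_rule!r}"
            )
        if self.firing_rule == "literal" and self.P_max == 0:
            raise ValidationError("firing_rule='literal' requires P_max > 0")

    def internal(self) -> "InternalParams":
        """Return the parameter set converted to the uM / um / ms system.

        Diffusivities and all per-second rates are divided by 1000; pool
        totals, affinities, currents and T_open are unchanged.
        """
        c = dict(
            (f.name, getattr(self, f.name)) for f in dataclasses.fields(InternalParams)
        )
        for name in _PER_SECOND:
            c[name] = c[name] / 1000.0
        return InternalParams(**c)

    def replace(self, **changes: Any) -> "ModelParams":
        return dataclasses.replace(self, **changes)


# Fields whose literature unit contains s^-1 and therefore scale by 1/1000
# when moving to the ms-based internal system.
_PER_SECOND = (
    "D_Cx", "D_Cy", "D_Dx", "D_Dy", "D_CSx", "D_CSy", "D_F",
    "V_pump", "k", "k_f", "P_max",
    "kB_plus", "kB_minus", "kf_plus", "kf_minus",
    "K_CSQ_plus", "K_CSQ_minus", "K_F_plus", "K_F_minus",
)


@dataclass(frozen=True)
class InternalParams(ModelParams):
    """``ModelParams`` converted to the internal uM / um / ms unit system.

    Produced only by :meth:`ModelParams.internal`; flux kernels and solvers
    accept this type so that mixed-unit stepping bugs cannot occur.
    """

    def internal(self) -> "InternalParams":  # idempotent
        return self


def improved_params(**overrides: Any) -> ModelParams:
    """Parameter set for the improved SR buffer/dye variant.

    Relative to the basic defaults: passive efflux rates k = 8 s^-1 and
    k_f = 0.25 s^-1, SR resting Ca2+ 954 uM; the SR dye/buffer constants are
    already in the shared defaults.
    """
    base: Dict[str, Any] = dict(k=8.0, k_f=0.25, CS_rest=954.0)
    base.update(overrides)
    return ModelParams(**base)


def _is_integral(ratio: float, rtol: float = 1e-9) -> bool:
    return abs(ratio - round(ratio)) <= rtol * max(1.0, abs(ratio))


@dataclass(frozen=True)
class GridSpec:
    """Finite-difference domain, mesh and time step.

    x (index 0) is the longitudinal axis (default 100 um at dx = 0.4 um);
    y is transverse (default 20 um at dy = 0.8/3 um).  ``lx_chan`` /
    ``ly_chan`` are the release-unit lattice spacings; the domain extents,
    channel spacings and grid spacings must be commensurate.
    """

    Lx: float = 100.0
    Ly: float = 20.0
    dx: float = 0.4
    dy: float = 0.8 / 3.0
    dt: float = 0.003125
    duration: float = 100.0
    ndim: int = 2
    lx_chan: float = 2.0
    ly_chan: float = 0.8

    def __post_init__(self) -> None:
        for name in ("Lx", "Ly", "dx", "dy", "dt", "duration", "lx_chan", "ly_chan"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and > 0, got {v!r}")
        if self.duration < self.dt:
            raise ValidationError("duration must be >= dt")
        if self.ndim not in (1, 2):
            raise ValidationError(f"ndim must be 1 or 2, got {self.ndim!r}")
        checks = [("Lx/dx", self.Lx / self.dx), ("lx_chan/dx", self.lx_chan / self.dx)]
        if self.ndim == 2:
            checks += [("Ly/dy", self.Ly / self.dy), ("ly_chan/dy", self.ly_chan / self.dy)]
        for label, ratio in checks:
            if not _is_integral(ratio):
                raise ValidationError(f"{label} = {ratio!r} is not an integer")

    @property
    def nx(self) -> int:
        return int(round(self.Lx / self.dx)) + 1

    @property
    def ny(self) -> int:
        return int(round(self.Ly / self.dy)) + 1 if self.ndim == 2 else 1

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    @property
    def cell_measure(self) -> float:
        """Measure of one grid cell: dx in 1-D, dx*dy in 2-D."""
        return self.dx if self.ndim == 1 else self.dx * self.dy

    @property
    def shape(self) -> Tuple[int, ...]:
        return (self.nx,) if self.ndim == 1 else (self.nx, self.ny)

    def x(self):  # noqa: ANN201 - numpy import kept local to keep module light
        import numpy as np

        return np.arange(self.nx) * self.dx

    def y(self):
        import numpy as np

        return np.arange(self.ny) * self.dy

    def replace(self, **changes: Any) -> "GridSpec":
        return dataclasses.replace(self, **changes)


# ---------------------------------------------------------------------------
# Config file handling
# ---------------------------------------------------------------------------

_PARAM_FIELDS = {f.name: f for f in dataclasses.fields(ModelParams)}
_GRID_FIELDS = {f.name: f for f in dataclasses.fields(GridSpec)}

#: Keys that describe the scenario rather than the model or mesh.
_SCENARIO_KEYS = {
    "model": str,            # "basic" | "improved"
    "scenario": str,         # named published configuration
    "seed": int,
    "include_buffer_dye": bool,
    "force_init": bool,
    "sample_stride": int,
    "sensors": str,          # comma-separated longitudinal positions, um
    "out": str,
}


def _parse_value(key: str, raw: str, line_no: int):
    raw = raw.strip()
    if key in _SCENARIO_KEYS:
        target = _SCENARIO_KEYS[key]
    elif key in _PARAM_FIELDS:
        target = type(_PARAM_FIELDS[key].default)
    elif key in _GRID_FIELDS:
        target = type(_GRID_FIELDS[key].default)
    else:  # pragma: no cover - callers reject unknown keys first
        raise ConfigError(f"line {line_no}: unknown key {key!r}")
    try:
        if target is bool:
            low = raw.lower()
            if low in ("true", "1", "yes", "on"):
                return True
            if low in ("false", "0", "no", "off"):
                return False
            raise ValueError(raw)
        if target is int:
            return int(raw)
        if target is float:
            return float(raw)
        return raw
    except ValueError as exc:
        raise ConfigError(f"line {line_no}: cannot parse {key}={raw!r}") from exc


def _read_kv_file(path) -> Dict[str, Any]:
    values: Dict[str, Any] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", ";")) or stripped.startswith("["):
                continue
            if "=" not in stripped:
                raise ConfigError(f"line {line_no}: expected 'key = value', got {line.rstrip()!r}")
            key, raw = stripped.split("=", 1)
            key = key.strip()
            if key not in _PARAM_FIELDS and key not in _GRID_FIELDS and key not in _SCENARIO_KEYS:
                raise ConfigError(f"line {line_no}: unknown key {key!r}")
            values[key] = _parse_value(key, raw, line_no)
    return values


def load_config(
    path: Optional[str] = None,
    overrides: Optional[Mapping[str, Any]] = None,
) -> Tuple[ModelParams, GridSpec, Dict[str, Any]]:
    """Build validated ``(ModelParams, GridSpec, scenario)`` from a config file.

    ``path`` may be None (defaults only).  ``overrides`` is a flat mapping of
    the same keys (e.g. from repeated ``--set key=value`` CLI flags); override
    values win over the file, file values win over defaults.  Unknown keys
    are rejected; invariant violations raise :class:`ValidationError` naming
    the field.  String override values are parsed with the same rules as the
    file.
    """
    merged: Dict[str, Any] = {}
    if path is not None:
        merged.update(_read_kv_file(path))
    for key, value in dict(overrides or {}).items():
        if key not in _PARAM_FIELDS and key not in _GRID_FIELDS and key not in _SCENARIO_KEYS:
            raise ConfigError(f"unknown key {key!r} in overrides")
        if isinstance(value, str):
            value = _parse_value(key, value, 0)
        merged[key] = value

    param_kwargs = {k: v for k, v in merged.items() if k in _PARAM_FIELDS}
    grid_kwargs = {k: v for k, v in merged.items() if k in _GRID_FIELDS}
    scenario = {k: v for k, v in merged.items() if k in _SCENARIO_KEYS}
    params = ModelParams(**param_kwargs)
    grid = GridSpec(**grid_kwargs)
    # Per-step firing probability must be a probability for the configured dt.
    if params.P_max / 1000.0 * grid.dt > 1.0:
        raise ValidationError(
            f"P_max*dt = {params.P_max / 1000.0 * grid.dt:g} exceeds 1; "
            "reduce P_max or dt"
        )
    return params, grid, scenario


def write_config(path, params: ModelParams, grid: GridSpec,
                 scenario: Optional[Mapping[str, Any]] = None) -> None:
    """Write a flat key=value config that :func:`load_config` reads back.

    Values are written with ``repr`` so decimal-representable entries
    round-trip bit-exactly.
    """
    def fmt(value):
        return value if isinstance(value, str) else repr(value)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cicrsim configuration (uM / um / ms / s^-1 literature units)\n")
        for f in dataclasses.fields(ModelParams):
            fh.write(f"{f.name} = {fmt(getattr(params, f.name))}\n")
        for f in dataclasses.fields(GridSpec):
            fh.write(f"{f.name} = {fmt(getattr(grid, f.name))}\n")
        for key, value in dict(scenario or {}).items():
            if key not in _SCENARIO_KEYS:
                raise ConfigError(f"unknown scenario key {key!r}")
            fh.write(f"{key} = {fmt(value)}\n")


def validate_stability(params: ModelParams, grid: GridSpec) -> list:
    """Return a list of warning strings for explicit-update stability limits.

    The diffusion steps are implicit and unconditionally stable; the checks
    here concern the per-step firing probability and the explicitly-stepped
    reaction terms (dye/buffer mass action, SR buffer Euler update).  Inputs
    are not mutated and nothing is raised.
    """
    warnings = []
    p = params.internal()
    dt = grid.dt
    if p.P_max * dt > 1.0:
        warnings.append(
            f"P_max*dt = {p.P_max * dt:g} > 1: per-step firing probability is not a probability"
        )
    max_on = max(p.kB_plus, p.kf_plus, p.K_CSQ_plus, p.K_F_plus)
    max_conc = max(p.C_rest, p.CS_rest, p.B_T, p.F_T, p.B_T_SR, p.F_T_SR)
    stiffness = max_on * max_conc * dt
    if stiffness > 0.5:
        warnings.append(
            f"explicit reaction stiffness (max on-rate * max concentration * dt) = "
            f"{stiffness:.3g} > 0.5: reduce dt"
        )
    if p.K_CSQ_minus * dt > 0.5:
        warnings.append(
            f"SR buffer Euler step K_CSQ_minus*dt = {p.K_CSQ_minus * dt:.3g} > 0.5: reduce dt"
        )
    return warnings
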