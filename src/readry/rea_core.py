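"""Lumped activated-evaporation drying model: energy laws, balances, simulator.

Evaporation is treated as an activated process: the surface relative
humidity is ``RH_s = exp(-dEv / (R T_s))`` where the apparent activation
energy ``dEv`` is the product of a material "fingerprint" — a cubic in the
free moisture content ``X - X_b`` — and the equilibrium activation energy
``-R T_b ln(RH_b)`` of the current ambient.  The mass balance couples to a
lumped energy balance with convective heating and evaporative cooling; the
pair is integrated phase-by-phase over a drying/tempering schedule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import ConfigurationError, DomainError, SimulationError
from .physics import (
    AmbientState,
    R_GAS,
    rho_v_bulk,
    rho_v_sat,
    transfer_coefficients,
)
from .schedule import DRYING, Schedule

logger = logging.getLogger(__name__)

#: Fitted cubic fingerprint coefficients for soybean, highest order first,
#: in the free moisture content (X - X_b): c3, c2, c1, c0.
SOYBEAN_COEFFS = (-213.38, 38.831, -4.2124, 0.9958)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleState:
    """Lumped grain-batch state at one instant."""

    X: float  # moisture content, kg water / kg dry solid
    T: float  # lumped (surface) temperature, K
    t: float = 0.0  # elapsed time, s

    def __post_init__(self):
        if self.X < 0.0:
            raise DomainError(f"moisture content {self.X} must be non-negative")


def default_cp(cp_solid: float = 1650.0, cp_water: float = 4186.0) -> Callable[[float], float]:
    """Mass-weighted wet-sample specific heat, J/(kg K): (cp_s + X cp_w)/(1+X)."""

    def cp(X: float) -> float:
        return (cp_solid + X * cp_water) / (1.0 + X)

    return cp


def default_latent_heat() -> Callable[[float], float]:
    """Latent heat of vaporization of water, J/kg, linear in T.

    Fit to steam-table values: 2.501e6 J/kg at 273.15 K, slope -2361 J/(kg K).
    """

    def dHv(T: float) -> float:
        return 2.501e6 - 2361.0 * (T - 273.15)

    return dHv


@dataclass(frozen=True)
class MaterialProps:
    """Batch-level material properties of the grain sample."""

    m_s: float  # dry solid mass, kg
    X_b: float  # equilibrium moisture at the reference drying condition, kg/kg
    X0: float  # initial moisture, kg/kg
    T0: float  # initial temperature, K
    cp_fn: Callable[[float], float] = field(default_factory=default_cp)
    dHv_fn: Callable[[float], float] = field(default_factory=default_latent_heat)

    def __post_init__(self):
        if self.m_s <= 0.0:
            raise DomainError("dry solid mass must be positive")
        if not (0.0 <= self.X_b < self.X0):
            raise DomainError("require 0 <= X_b < X0")

    def wet_mass(self, X: float) -> float:
        return self.m_s * (1.0 + X)


@dataclass(frozen=True)
class GrainGeometry:
    """Batch geometry with linear moisture shrinkage of length and area.

    ``shrink_L = (l0, l1)`` gives the characteristic length
    ``L(X) = l0 + l1 X`` (m) and ``shrink_A = (a0, a1)`` the exchange surface
    area ``A(X) = a0 + a1 X`` (m^2).  ``axes0`` records the three full
    ellipsoid axes of an average grain at the initial moisture; the default
    characteristic length is their geometric mean.
    """

    axes0: Tuple[float, float, float]
    n_grains: int
    shrink_L: Tuple[float, float]
    shrink_A: Tuple[float, float]

    def length(self, X: float) -> float:
        L = self.shrink_L[0] + self.shrink_L[1] * X
        if L <= 0.0:
            raise DomainError(f"characteristic length non-positive at X = {X}")
        return L

    def area(self, X: float) -> float:
        A = self.shrink_A[0] + self.shrink_A[1] * X
        if A <= 0.0:
            raise DomainError(f"surface area non-positive at X = {X}")
        return A

    @staticmethod
    def ellipsoid_area(axes: Tuple[float, float, float]) -> float:
        """Thomsen approximation of the ellipsoid surface area (full axes)."""
        a, b, c = (ax / 2.0 for ax in axes)
        p = 1.6075
        s = (a**p * b**p + a**p * c**p + b**p * c**p) / 3.0
        return 4.0 * math.pi * s ** (1.0 / p)


@dataclass(frozen=True)
class ActivationEnergyModel:
    """Cubic fingerprint of the relative activation energy.

    ``coeffs = (c3, c2, c1, c0)`` define the cubic in the free moisture
    content ``x = X - X_b``.  ``x_max`` is the upper edge of the fitted
    range; evaluations beyond it are clamped to the edge value (cubic
    extrapolation is unphysical).
    """

    coeffs: Tuple[float, float, float, float]
    X_b: float
    x_max: Optional[float] = None

    def poly(self, x):
        c3, c2, c1, c0 = self.coeffs
        return ((c3 * x + c2) * x + c1) * x + c0


def relative_activation_energy(model: ActivationEnergyModel, X: float) -> float:
    """Relative activation energy dE_R at moisture ``X`` (dimensionless).

    Raises
    ------
    DomainError
        If ``X < X_b`` (the fingerprint is undefined below equilibrium).
    """
    if X < model.X_b:
        raise DomainError(
            f"X = {X} below the reference equilibrium moisture X_b = {model.X_b}"
        )
    x = X - model.X_b
    if model.x_max is not None and x > model.x_max:
        x = model.x_max
    return float(model.poly(x))


_clamp_count = 0


def _dER_clamped(model: ActivationEnergyModel, X: float) -> float:
    """Fingerprint evaluation used inside the balances.

    Clamps the free moisture at 0 from below and at ``x_max`` from above,
    then clips the cubic's value into [0, 1]; clips are counted and logged.
    """
    global _clamp_count
    x = max(X - model.X_b, 0.0)
    if model.x_max is not None and x > model.x_max:
        x = model.x_max
    v = float(model.poly(x))
    if v < 0.0 or v > 1.0:
        _clamp_count += 1
        logger.debug("clamped dE_R = %.4f to [0, 1] at X = %.5f", v, X)
        v = min(max(v, 0.0), 1.0)
    return v


def equilibrium_activation_energy(ambient: AmbientState) -> float:
    """Equilibrium (maximum) activation energy of an ambient, J/mol.

    ``dEv_b = -R T_b ln(RH_b)``; zero for saturated air.
    """
    if ambient.RH_b <= 0.0:
        raise DomainError("RH_b = 0 implies an infinite activation barrier")
    return -R_GAS * ambient.T_b * math.log(ambient.RH_b)


def surface_relative_humidity(dEv: float, T_s: float) -> float:
    """Surface relative humidity ``exp(-dEv / (R T_s))``, in (0, 1]."""
    if dEv < 0.0:
        raise DomainError("apparent activation energy must be non-negative")
    return math.exp(-dEv / (R_GAS * T_s))


@dataclass(frozen=True)
class Diagnostics:
    """Per-sample model diagnostics."""

    RH_s: float
    rho_v_s: float
    rho_v_sat: float
    dEv: float  # apparent activation energy, J/mol
    dEvb: float  # equilibrium activation energy of the active ambient, J/mol


# ---------------------------------------------------------------------------
# balances
# ---------------------------------------------------------------------------


def _film_T(T_s: float, T_b: float) -> float:
    return 0.5 * (T_s + T_b)


def apparent_activation_energy(
    model: ActivationEnergyModel,
    X: float,
    ambient: AmbientState,
    equilibrium_ambient: Optional[AmbientState] = None,
) -> float:
    """dEv = dE_R(X - X_b) * dEv_b, with dEv_b from ``equilibrium_ambient``
    (defaults to the active ambient)."""
    ref = ambient if equilibrium_ambient is None else equilibrium_ambient
    return _dER_clamped(model, X) * equilibrium_activation_energy(ref)


def mass_balance_rhs(
    state: SampleState,
    ambient: AmbientState,
    model: ActivationEnergyModel,
    material: MaterialProps,
    geometry: GrainGeometry,
    equilibrium_ambient: Optional[AmbientState] = None,
) -> float:
    """Moisture rate dX/dt (1/s).

    ``dX/dt = -(h_m A(X) / m_s) (RH_s rho_v_sat(T_s) - rho_v_b)``.
    Negative while the surface vapor concentration exceeds the bulk value
    (drying); positive values (condensation) are permitted.
    """
    L = geometry.length(state.X)
    tc = transfer_coefficients(ambient, L, _film_T(state.T, ambient.T_b))
    dEv = apparent_activation_energy(model, state.X, ambient, equilibrium_ambient)
    rho_s = surface_relative_humidity(dEv, state.T) * rho_v_sat(state.T)
    rho_b = rho_v_bulk(ambient)
    return -(tc.h_m * geometry.area(state.X) / material.m_s) * (rho_s - rho_b)


def energy_balance_rhs(
    state: SampleState,
    ambient: AmbientState,
    dXdt: float,
    material: MaterialProps,
    geometry: GrainGeometry,
    expanded: bool = False,
) -> float:
    """Temperature rate dT/dt (K/s).

    Simplified form (default): ``m Cp dT/dt = h A (T_b - T) + m_s dX/dt dHv``
    with ``m = m_s (1 + X)`` and Cp refreshed each evaluation.  With
    ``expanded=True`` the ``T d(m Cp)/dt`` term is retained
    (``d(m Cp)/dX`` by central finite difference).
    """
    L = geometry.length(state.X)
    tc = transfer_coefficients(ambient, L, _film_T(state.T, ambient.T_b))
    A = geometry.area(state.X)
    m = material.wet_mass(state.X)
    cp = material.cp_fn(state.X)
    rhs = tc.h * A * (ambient.T_b - state.T) + material.m_s * dXdt * material.dHv_fn(
        state.T
    )
    if expanded:
        dX = 1e-6
        mcp_hi = material.wet_mass(state.X + dX) * material.cp_fn(state.X + dX)
        mcp_lo = material.wet_mass(max(state.X - dX, 0.0)) * material.cp_fn(
            max(state.X - dX, 0.0)
        )
        dmcp_dX = (mcp_hi - mcp_lo) / (state.X + dX - max(state.X - dX, 0.0))
        rhs -= state.T * dmcp_dX * dXdt
    return rhs / (m * cp)


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverConfig:
    """Integration settings for :func:`simulate`."""

    rtol: float = 1e-6
    atol_X: float = 1e-8
    atol_T: float = 1e-5
    output_dt: float = 60.0  # output sampling interval, s
    method: str = "LSODA"
    renormalize_per_phase: bool = True  # dEv_b from the active phase's ambient
    expanded_energy: bool = False
    x_target: Optional[float] = None  # stop when X first reaches this value


@dataclass
class DryingCurve:
    """Simulated (or measured) drying trajectory with model diagnostics.

    The sample exactly at a phase boundary is attributed to the *ending*
    phase: its diagnostics are computed with that phase's ambient, so it
    represents the phase's final state.
    """

    t: np.ndarray  # s
    X: np.ndarray  # kg/kg dry basis
    T: np.ndarray  # K
    phase_index: np.ndarray
    phase_kind: np.ndarray  # "drying" / "tempering"
    RH_s: np.ndarray
    rho_v_s: np.ndarray
    rho_v_sat: np.ndarray
    dEv: np.ndarray  # J/mol
    dEvb: np.ndarray  # J/mol
    phase_spans: List[Tuple[str, float, float]] = field(default_factory=list)
    reached_target: Optional[bool] = None
    n_clamped: int = 0

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t_s": self.t,
                "X_db": self.X,
                "T_K": self.T,
                "phase": self.phase_kind,
                "RH_s": self.RH_s,
                "rho_v_s": self.rho_v_s,
                "rho_v_sat": self.rho_v_sat,
                "dEv_J_mol": self.dEv,
            }
        )

    def phase_samples(self, index: int) -> np.ndarray:
        """Positions of the samples attributed to phase ``index``."""
        return np.nonzero(self.phase_index == index)[0]


def _diagnostics_arrays(X, T, ambient, model, cfg, reference_ambient):
    ref = ambient if cfg.renormalize_per_phase else reference_ambient
    dEvb = equilibrium_activation_energy(ref)
    dEv = np.array([_dER_clamped(model, x) for x in X]) * dEvb
    RH_s = np.exp(-dEv / (R_GAS * np.asarray(T)))
    rv_sat = rho_v_sat(np.asarray(T))
    return RH_s, RH_s * rv_sat, rv_sat, dEv, np.full(len(np.atleast_1d(X)), dEvb)


def simulate(
    schedule: Schedule,
    model: ActivationEnergyModel,
    material: MaterialProps,
    geometry: GrainGeometry,
    solver: Optional[SolverConfig] = None,
) -> DryingCurve:
    """Integrate the coupled moisture/temperature balances over a schedule.

    Integration restarts at every phase boundary (ambient steps are not
    smoothed).  State and diagnostics are recorded on a regular output grid;
    when ``solver.x_target`` is set, integration stops at the first crossing.

    Raises
    ------
    ConfigurationError
        If ``x_target`` is below the model's equilibrium moisture ``X_b``,
        or the initial moisture does not exceed ``X_b``.
    SimulationError
        On integrator failure; carries the last good state.
    """
    global _clamp_count
    cfg = solver or SolverConfig()
    if material.X0 <= model.X_b:
        raise ConfigurationError("initial moisture X0 must exceed X_b")
    if cfg.x_target is not None and cfg.x_target < model.X_b:
        raise ConfigurationError(
            f"x_target = {cfg.x_target} is below the equilibrium moisture "
            f"X_b = {model.X_b} and can never be reached"
        )

    clamp0 = _clamp_count
    reference_ambient = next(
        (p.ambient for p in schedule.phases if p.kind == DRYING),
        schedule.phases[0].ambient if schedule.phases else None,
    )

    ts: List[np.ndarray] = [np.array([0.0])]
    Xs: List[np.ndarray] = [np.array([material.X0])]
    Ts: List[np.ndarray] = [np.array([material.T0])]
    idxs: List[np.ndarray] = [np.array([0])]
    kinds: List[np.ndarray] = [np.array([schedule.phases[0].kind if schedule.phases else "none"])]
    diag: List[Tuple] = []
    if schedule.phases:
        diag.append(
            _diagnostics_arrays(
                [material.X0],
                [material.T0],
                schedule.phases[0].ambient,
                model,
                cfg,
                reference_ambient,
            )
        )
    else:
        nan = np.array([np.nan])
        diag.append((nan, nan, nan, nan, nan))

    reached = None if cfg.x_target is None else False
    spans: List[Tuple[str, float, float]] = []
    t0 = 0.0
    y = [material.X0, material.T0]

    for i, phase in enumerate(schedule.phases):
        t1 = t0 + phase.duration
        ambient = phase.ambient
        eq_amb = ambient if cfg.renormalize_per_phase else reference_ambient

        def rhs(t, yv, _amb=ambient, _eq=eq_amb):
            X, T = max(yv[0], 0.0), yv[1]
            st = SampleState(X=X, T=T, t=t)
            dX = mass_balance_rhs(st, _amb, model, material, geometry, _eq)
            dT = energy_balance_rhs(
                st, _amb, dX, material, geometry, expanded=cfg.expanded_energy
            )
            return [dX, dT]

        events = None
        if cfg.x_target is not None:

            def hit_target(t, yv, _xt=cfg.x_target):
                return yv[0] - _xt

            hit_target.terminal = True
            hit_target.direction = -1.0
            events = [hit_target]

        # output grid: points strictly inside (t0, t1], boundary included
        k0 = math.floor(t0 / cfg.output_dt) + 1
        grid = np.arange(k0, math.ceil(t1 / cfg.output_dt) + 1) * cfg.output_dt
        grid = grid[(grid > t0 + 1e-9) & (grid < t1 - 1e-9)]
        t_eval = np.concatenate([grid, [t1]])

        sol = solve_ivp(
            rhs,
            (t0, t1),
            y,
            method=cfg.method,
            rtol=cfg.rtol,
            atol=[cfg.atol_X, cfg.atol_T],
            t_eval=t_eval,
            events=events,
            dense_output=events is not None,
        )
        if not sol.success and sol.status != 1:
            raise SimulationError(
                f"integrator failed in phase {i} ({phase.kind}): {sol.message}",
                last_state=SampleState(X=y[0], T=y[1], t=t0),
            )

        if sol.status == 1 and sol.t_events and sol.t_events[0].size:
            t_hit = float(sol.t_events[0][0])
            y_hit = sol.sol(t_hit)
            keep = sol.t < t_hit - 1e-9
            tt = np.concatenate([sol.t[keep], [t_hit]])
            yy = np.vstack(
                [np.append(sol.y[0, keep], y_hit[0]), np.append(sol.y[1, keep], y_hit[1])]
            )
            reached = True
            end_t = t_hit
        else:
            tt = sol.t
            yy = sol.y
            end_t = t1

        spans.append((phase.kind, t0, end_t))
        if tt.size:
            ts.append(tt)
            Xs.append(yy[0])
            Ts.append(yy[1])
            idxs.append(np.full(tt.size, i))
            kinds.append(np.full(tt.size, phase.kind, dtype=object))
            diag.append(
                _diagnostics_arrays(yy[0], yy[1], ambient, model, cfg, reference_ambient)
            )
        y = [float(yy[0][-1]) if tt.size else y[0], float(yy[1][-1]) if tt.size else y[1]]
        t0 = end_t
        if reached:
            break

    RH_s = np.concatenate([d[0] for d in diag])
    rho_s = np.concatenate([d[1] for d in diag])
    rv_sat = np.concatenate([d[2] for d in diag])
    dEv = np.concatenate([d[3] for d in diag])
    dEvb = np.concatenate([d[4] for d in diag])
    n_clamped = _clamp_count - clamp0
    if n_clamped:
        logger.warning("fingerprint value clipped into [0, 1] %d times", n_clamped)
    return DryingCurve(
        t=np.concatenate(ts),
        X=np.concatenate(Xs),
        T=np.concatenate(Ts),
        phase_index=np.concatenate(idxs).astype(int),
        phase_kind=np.concatenate(kinds).astype(object),
        RH_s=RH_s,
        rho_v_s=rho_s,
        rho_v_sat=rv_sat,
        dEv=dEv,
        dEvb=dEvb,
        phase_spans=spans,
        reached_target=reached,
        n_clamped=n_clamped,
    )
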