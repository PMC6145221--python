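"""Psychrometrics of humid air and convective heat/mass-transfer coefficients.

Saturated water-vapor concentration comes from a quartic polynomial in
(T - 273) fitted to standard saturation data, valid for 273.15 K < T < 430 K.
Dry-air thermophysical properties are explicit correlations fitted to the
1-atm dry-air table of Incropera & DeWitt, *Fundamentals of Heat and Mass
Transfer* (Table A.4), valid 270-430 K:

* density        rho = p / (R_air * T)         (ideal gas, p = 101325 Pa)
* viscosity      mu  = 1.458e-6 * T^1.5 / (T + 110.4)   (Sutherland)
* conductivity   k   = 0.02624 * (T / 300)^0.8646
* diffusivity    D   = 1.87e-10 * T^2.072      (water vapor in air at 1 atm,
                                                Marrero & Mason)
* specific heat  cp  = 4.4571e-4*T^2 - 0.2392*T + 1038.35  (quadratic fit)

Forced-convection transfer coefficients use the short-cylinder/particle
correlations Sh = 0.511 Re^0.5 Sc^0.37 and Nu = 0.511 Re^0.5 Pr^0.37.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ConfigurationError, DomainError

#: Universal gas constant, J/(mol K).
R_GAS = 8.314

#: Specific gas constant of dry air, J/(kg K).
R_AIR = 287.058

#: Reference pressure, Pa.
P_ATM = 101_325.0

#: Validity range of the saturated-vapor-concentration polynomial, K.
T_SAT_MIN = 273.0
T_SAT_MAX = 430.0

#: Validity range of the dry-air property correlations, K.
T_AIR_MIN = 270.0
T_AIR_MAX = 430.0


@dataclass(frozen=True)
class AmbientState:
    """Drying-medium condition.

    Parameters
    ----------
    T_b : float
        Absolute temperature of the drying air, K.
    RH_b : float
        Relative humidity of the drying air, fraction in (0, 1].
    u : float
        Air speed over the sample, m/s.
    """

    T_b: float
    RH_b: float
    u: float

    def __post_init__(self):
        if not (273.15 < self.T_b < T_SAT_MAX):
            raise DomainError(
                f"ambient temperature {self.T_b} K outside (273.15, {T_SAT_MAX}) K"
            )
        if not (0.0 < self.RH_b <= 1.0):
            raise DomainError(f"ambient relative humidity {self.RH_b} outside (0, 1]")
        if self.u < 0.0:
            raise DomainError(f"air speed {self.u} m/s must be non-negative")


@dataclass(frozen=True)
class AirProperties:
    """Thermophysical and transport properties of dry air at one temperature."""

    rho: float  # density, kg/m^3
    mu: float  # dynamic viscosity, Pa s
    k: float  # thermal conductivity, W/(m K)
    D: float  # diffusivity of water vapor in air, m^2/s
    cp_air: float  # specific heat, J/(kg K)


@dataclass(frozen=True)
class TransferCoefficients:
    """Dimensionless groups and convective transfer coefficients."""

    Re: float
    Sc: float
    Pr: float
    Sh: float
    Nu: float
    h: float  # heat transfer coefficient, W/(m^2 K)
    h_m: float  # mass transfer coefficient, m/s
    L: float  # characteristic length used, m


def rho_v_sat(T_s):
    """Saturated water-vapor concentration at temperature ``T_s``, kg/m^3.

    Quartic polynomial in ``(T_s - 273)``; accepts a float or a numpy array.

    Raises
    ------
    DomainError
        If any temperature lies outside [273, 430] K, the fitted range.
    """
    import numpy as np

    arr = np.asarray(T_s, dtype=float)
    if np.any(arr < T_SAT_MIN) or np.any(arr > T_SAT_MAX):
        raise DomainError(
            f"temperature outside [{T_SAT_MIN}, {T_SAT_MAX}] K, the fitted "
            "range of the saturated-vapor-concentration polynomial"
        )
    x = arr - 273.0
    out = (
        ((4.844e-9 * x - 1.4807e-7) * x + 2.6572e-5) * x - 4.8613e-5
    ) * x + 8.342e-3
    if np.ndim(T_s) == 0:
        return float(out)
    return out


def rho_v_bulk(ambient: AmbientState = None, *, T_b: float = None, RH_b: float = None) -> float:
    """Bulk (drying-air) water-vapor concentration, kg/m^3.

    Defined through the ambient relative humidity:
    ``rho_v_b = RH_b * rho_v_sat(T_b)``.  Accepts either an
    :class:`AmbientState` or explicit ``T_b``/``RH_b`` keywords; the latter
    form permits the perfectly-dry edge ``RH_b = 0`` (returns 0), which
    ``AmbientState`` itself rejects.
    """
    if ambient is not None:
        T_b, RH_b = ambient.T_b, ambient.RH_b
    if T_b is None or RH_b is None:
        raise DomainError("provide an AmbientState or both T_b and RH_b")
    if RH_b == 0.0:
        return 0.0
    return RH_b * rho_v_sat(T_b)


def air_properties(T_film: float) -> AirProperties:
    """Dry-air properties at ``T_film`` (K) from the module-level correlations.

    Raises
    ------
    DomainError
        If ``T_film`` is outside [270, 430] K.
    """
    if not (T_AIR_MIN <= T_film <= T_AIR_MAX):
        raise DomainError(
            f"film temperature {T_film} K outside "
            f"[{T_AIR_MIN}, {T_AIR_MAX}] K validity range of air correlations"
        )
    rho = P_ATM / (R_AIR * T_film)
    mu = 1.458e-6 * T_film**1.5 / (T_film + 110.4)
    k = 0.02624 * (T_film / 300.0) ** 0.8646
    D = 1.87e-10 * T_film**2.072
    cp = (4.4571e-4 * T_film - 0.2392) * T_film + 1038.35
    return AirProperties(rho=rho, mu=mu, k=k, D=D, cp_air=cp)


def sherwood(Re: float, Sc: float) -> float:
    """Sherwood number: ``0.511 Re^0.5 Sc^0.37``."""
    return 0.511 * math.sqrt(Re) * Sc**0.37


def nusselt(Re: float, Pr: float) -> float:
    """Nusselt number: ``0.511 Re^0.5 Pr^0.37``."""
    return 0.511 * math.sqrt(Re) * Pr**0.37


def transfer_coefficients(
    ambient: AmbientState, L: float, T_film: float
) -> TransferCoefficients:
    """Convective heat- and mass-transfer coefficients for forced flow.

    Parameters
    ----------
    ambient : AmbientState
        Drying-medium condition (supplies the air speed ``u``).
    L : float
        Characteristic length of the sample, m.
    T_film : float
        Film temperature at which air properties are evaluated, K
        (conventionally the mean of air and surface temperatures).

    Raises
    ------
    ConfigurationError
        If ``ambient.u == 0``: the forced-convection correlation has no
        still-air limit.  Configure a small nonzero speed (the tempering
        default is 0.3 m/s) instead.
    """
    if L <= 0.0:
        raise DomainError(f"characteristic length {L} m must be positive")
    if ambient.u == 0.0:
        raise ConfigurationError(
            "forced-convection correlation undefined at u = 0; set a small "
            "nonzero air speed (e.g. 0.3 m/s for tempering in still room air)"
        )
    p = air_properties(T_film)
    Re = p.rho * ambient.u * L / p.mu
    Sc = p.mu / (p.rho * p.D)
    Pr = p.mu * p.cp_air / p.k
    Sh = sherwood(Re, Sc)
    Nu = nusselt(Re, Pr)
    h_m = Sh * p.D / L
    h = Nu * p.k / L
    return TransferCoefficients(Re=Re, Sc=Sc, Pr=Pr, Sh=Sh, Nu=Nu, h=h, h_m=h_m, L=L)


def wet_basis(X_db: float) -> float:
    """Convert dry-basis moisture (kg/kg) to wet-basis fraction."""
    if X_db < 0.0:
        raise DomainError("dry-basis moisture must be non-negative")
    return X_db / (1.0 + X_db)


def dry_basis(w_wb: float) -> float:
    """Convert wet-basis moisture fraction to dry basis (kg/kg)."""
    if not (0.0 <= w_wb < 1.0):
        raise DomainError("wet-basis moisture must lie in [0, 1)")
    return w_wb / (1.0 - w_wb)
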