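"""Constitutive relations for a maize bulk and its interstitial air.

All grain-side correlations take the units used by the underlying
experimental fits: specific heat and thermal conductivity of maize are
functions of wet-basis moisture (%) and temperature (degC) respectively,
while the vapor diffusivity correlation takes absolute temperature (K).
Unit-misuse guards enforce this at the API boundary.

The sorption closure (equilibrium relative humidity of maize as a function
of temperature and dry-basis moisture) is the Modified Chung-Pfost
isotherm with published shelled-corn coefficients; saturation vapor
pressure is the Magnus formula.  From these the two vapor-pressure partial
derivatives that drive moisture transport are obtained analytically:
``sigma`` = dp/dWg at constant T and ``omega`` = dp/dT at constant Wg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialParams",
    "DiffusionCoeffs",
    "specific_heat_maize",
    "thermal_conductivity_maize",
    "wet_from_dry_basis",
    "dry_from_wet_basis",
    "vapor_diffusivity",
    "saturation_vapor_pressure",
    "equilibrium_rh",
    "isotherm_vapor_partials",
    "diffusion_coeffs",
]

#: Water-vapor specific gas constant, J/(kg K).
RV = 461.52

#: Modified Chung-Pfost coefficients for shelled maize
#: (erh = exp(-A/(T_C + C) * exp(-B * Wg)), Wg dry-basis decimal, T in degC).
CHUNG_PFOST_MAIZE = (312.31, 16.958, 30.205)


@dataclass(frozen=True)
class MaterialParams:
    """Physical constants and correlation coefficients of the grain bulk.

    Defaults reproduce the maize/air property table used throughout;
    quantities the source table does not print (porosity, permeability,
    latent heat, expansion coefficient) carry standard literature values
    and are freely configurable.
    """

    rho_b: float = 735.0          # grain bulk density, kg/m^3
    rho_a: float = 1.205          # air density, kg/m^3
    rho_0: float = 1.205          # air density at reference T0, kg/m^3
    c_a: float = 1.006            # air specific heat, kJ/(kg degC)
    cb_coeffs: tuple[float, float] = (1.465, 0.0356)       # kJ/(kg degC) vs M%
    kb_coeffs: tuple[float, float, float] = (0.0654, 0.0040, -3.6071e-5)
    k_a: float = 0.026            # air thermal conductivity, W/(m degC)
    mu: float = 1.79e-5           # dynamic viscosity, Pa s
    tau_b: float = 1.53           # tortuosity
    porosity: float = 0.40        # epsilon
    permeability: float = 4.8e-8  # K, m^2 (Kozeny-Carman, 7 mm kernels)
    phi_drag: float = 7.0         # equivalent kernel diameter (mm), Darcy drag factor
    beta: float = 3.4e-3          # thermal expansion coefficient, 1/K
    g: float = 9.81               # gravity, m/s^2
    h_fg: float = 2.501e6         # latent heat of sorption, J/kg
    rv: float = RV                # water-vapor gas constant, J/(kg K)
    T0: float = 291.15            # reference temperature, K
    isotherm_coeffs: tuple[float, float, float] = CHUNG_PFOST_MAIZE
    #: use the literally printed air correlations ca=1.01+0.87T,
    #: ka=0.0076T+0.02441 and Deff=Dv*eps*tau_b*Rv instead of the
    #: physically consistent defaults.
    paper_literal: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.porosity < 1.0):
            raise ValueError(f"porosity must lie in (0,1), got {self.porosity}")
        for name in ("rho_b", "rho_a", "rho_0", "mu", "tau_b", "permeability",
                     "beta", "g", "h_fg", "T0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rv != RV:
            raise ValueError(f"rv is fixed at {RV} J/(kg K)")

    def with_(self, **kwargs) -> "MaterialParams":
        return replace(self, **kwargs)

    def air_specific_heat(self, T_C: float) -> float:
        """kJ/(kg degC); constant by default, printed correlation if literal."""
        if self.paper_literal:
            return 1.01 + 0.87 * T_C
        return self.c_a

    def air_conductivity(self, T_C: float) -> float:
        """W/(m degC); constant by default, printed correlation if literal."""
        if self.paper_literal:
            return 0.0076 * T_C + 0.02441
        return self.k_a


@dataclass(frozen=True)
class DiffusionCoeffs:
    """Vapor-transport coefficients at one thermodynamic state.

    ``DM = Deff * sigma`` and ``DT = Deff * omega`` hold by construction.
    """

    Dv: float        # binary vapor diffusivity in air, m^2/s
    Deff: float      # effective diffusivity in the pore network, m^2/s
    sigma: float     # dp_vapor/dWg at constant T, Pa
    omega: float     # dp_vapor/dT at constant Wg, Pa/K
    rh: float        # equilibrium relative humidity, fraction
    DM: float = field(init=False)
    DT: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "DM", self.Deff * self.sigma)
        object.__setattr__(self, "DT", self.Deff * self.omega)


def specific_heat_maize(M, params: MaterialParams | None = None):
    """Specific heat of maize, kJ/(kg degC), from wet-basis moisture M (%).

    Linear correlation cb = 1.465 + 0.0356 M, valid for 0 <= M <= 40.
    """
    coeffs = (params or MaterialParams()).cb_coeffs
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M > 40):
        raise ValueError("wet-basis moisture outside correlation range [0, 40] %")
    out = coeffs[0] + coeffs[1] * M
    return float(out) if out.ndim == 0 else out


def thermal_conductivity_maize(T_C, params: MaterialParams | None = None):
    """Thermal conductivity of maize, W/(m K), from temperature (degC).

    Quadratic correlation kb = 0.0654 + 0.0040 T - 3.6071e-5 T^2,
    guarded to -10..60 degC where it stays positive (the correlation
    itself changes sign near -14.5 degC, well below storage conditions).
    """
    a, b, c = (params or MaterialParams()).kb_coeffs
    T_C = np.asarray(T_C, dtype=float)
    if np.any(T_C < -10) or np.any(T_C > 60):
        raise ValueError("temperature outside correlation range [-10, 60] degC")
    out = a + b * T_C + c * T_C**2
    return float(out) if out.ndim == 0 else out


def wet_from_dry_basis(Wg):
    """Convert dry-basis moisture fraction Wg to wet-basis percent M.

    M = 100 * Wg / (1 + Wg).
    """
    Wg = np.asarray(Wg, dtype=float)
    if np.any(Wg < 0):
        raise ValueError("dry-basis moisture must be non-negative")
    out = 100.0 * Wg / (1.0 + Wg)
    return float(out) if out.ndim == 0 else out


def dry_from_wet_basis(M):
    """Inverse of :func:`wet_from_dry_basis`: Wg = M / (100 - M)."""
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M >= 100):
        raise ValueError("wet-basis moisture must lie in [0, 100) %")
    out = M / (100.0 - M)
    return float(out) if out.ndim == 0 else out


def _check_kelvin(T_K) -> np.ndarray:
    T_K = np.asarray(T_K, dtype=float)
    if np.any(T_K < 100.0):
        raise ValueError(
            "temperature looks like degC, this correlation takes Kelvin")
    if np.any(T_K <= 230.0) or np.any(T_K >= 330.0):
        raise ValueError("temperature outside guard range (230, 330) K")
    return T_K


def vapor_diffusivity(T_K, params: MaterialParams | None = None) -> DiffusionCoeffs:
    """Binary and effective vapor diffusivity at absolute temperature T (K).

    Dv = 9.1e-9 T^2.5 / (T + 245.18); Deff = Dv * porosity / tortuosity
    (standard porous-medium reduction).  sigma/omega are not evaluated here
    (returned as 0); use :func:`diffusion_coeffs` for the full set.
    """
    p = params or MaterialParams()
    T_K = _check_kelvin(T_K)
    Dv = 9.1e-9 * T_K**2.5 / (T_K + 245.18)
    if p.paper_literal:
        Deff = Dv * p.porosity * p.tau_b * p.rv
    else:
        Deff = Dv * p.porosity / p.tau_b
    Dv = float(Dv) if np.ndim(Dv) == 0 else Dv
    Deff = float(Deff) if np.ndim(Deff) == 0 else Deff
    return DiffusionCoeffs(Dv=Dv, Deff=Deff, sigma=0.0, omega=0.0, rh=0.0)


def saturation_vapor_pressure(T_C):
    """Saturation vapor pressure over water, Pa (Magnus formula, T in degC)."""
    T_C = np.asarray(T_C, dtype=float)
    out = 610.94 * np.exp(17.625 * T_C / (T_C + 243.04))
    return float(out) if out.ndim == 0 else out


def equilibrium_rh(T_K, Wg, params: MaterialParams | None = None):
    """Equilibrium relative humidity (fraction) of maize at (T, Wg).

    Modified Chung-Pfost: rh = exp(-A/(T_C + C) * exp(-B Wg)) with Wg the
    dry-basis decimal moisture.  Strictly increasing in both T and Wg.
    """
    A, B, C = (params or MaterialParams()).isotherm_coeffs
    T_K = _check_kelvin(T_K)
    Wg = np.asarray(Wg, dtype=float)
    if np.any(Wg < 0.03) or np.any(Wg > 0.40):
        raise ValueError("dry-basis moisture outside isotherm validity [0.03, 0.40]")
    T_C = T_K - 273.15
    out = np.exp(-A / (T_C + C) * np.exp(-B * Wg))
    return float(out) if out.ndim == 0 else out


def isotherm_vapor_partials(T_K, Wg, params: MaterialParams | None = None) -> DiffusionCoeffs:
    """Vapor-pressure partial derivatives and RH at state (T [K], Wg).

    The interstitial vapor pressure is p = rh(T, Wg) * psat(T).  Both
    partials are analytic:

      sigma = dp/dWg|_T = psat * rh * (A/(T_C+C)) * B * exp(-B Wg)
      omega = dp/dT|_Wg = psat * drh/dT + rh * dpsat/dT

    Both are positive for mid-range states: wetter or warmer grain raises
    the interstitial vapor pressure.
    """
    p = params or MaterialParams()
    A, B, C = p.isotherm_coeffs
    T_K = _check_kelvin(T_K)
    Wg = np.asarray(Wg, dtype=float)
    T_C = T_K - 273.15

    rh = equilibrium_rh(T_K, Wg, p)
    psat = saturation_vapor_pressure(T_C)
    E = np.exp(-B * Wg)
    sigma = psat * rh * (A / (T_C + C)) * B * E
    drh_dT = rh * A * E / (T_C + C) ** 2
    dpsat_dT = psat * 17.625 * 243.04 / (T_C + 243.04) ** 2
    omega = psat * drh_dT + rh * dpsat_dT

    base = vapor_diffusivity(T_K, p)
    sigma = float(sigma) if np.ndim(sigma) == 0 else sigma
    omega = float(omega) if np.ndim(omega) == 0 else omega
    rh = float(rh) if np.ndim(rh) == 0 else rh
    return DiffusionCoeffs(Dv=base.Dv, Deff=base.Deff, sigma=sigma, omega=omega, rh=rh)


def diffusion_coeffs(T_K, Wg, params: MaterialParams | None = None) -> DiffusionCoeffs:
    """Full vapor-transport coefficient set at (T [K], Wg)."""
    return isotherm_vapor_partials(T_K, Wg, params)
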