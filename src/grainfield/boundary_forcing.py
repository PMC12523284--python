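"""Dynamic envelope boundary conditions from weather.

Exterior air temperature and solar radiation are folded into a sol-air
temperature per envelope face, and the heat flux into the grain domain is
q = U_face * (T_solair - T_inside_surface), with the wall/roof overall
heat-transfer coefficients taken from the warehouse property table
(k_wall = 0.62, k_roof = 1.25 W/(m^2 degC)).  Orientation factors scale
the irradiance per face (the south wall of a Changchun warehouse receives
far more sun than the north wall).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ForcingScenario", "ambient_temperature", "solar_irradiance",
           "envelope_flux", "load_ambient_series"]

DAY_S = 86400.0
HOUR_S = 3600.0

_FACES = ("south", "north", "east", "west", "roof")


@dataclass(frozen=True)
class ForcingScenario:
    """Ambient-weather forcing and envelope coefficients.

    The ambient temperature comes either from a supplied (time, degC)
    series (piecewise-linear) or, if ``series`` is None, from the
    parametric diurnal model::

        T(t) = mean + drift * t/30d + amplitude * sin(2*pi*(t - t_peak)/24h)

    Times are seconds from the campaign start.  Defaults describe an
    August heat-season campaign in a continental climate (mean 24 degC,
    diurnal swing +-6 degC, afternoon peak).
    """

    mean_C: float = 24.0
    amplitude_C: float = 6.0
    drift_C_per_30d: float = 0.0
    t_peak_h: float = 15.0
    series: tuple[tuple[float, float], ...] | None = None  # (t_s, degC)
    horizon_s: float = 31 * DAY_S

    peak_irradiance: float = 800.0   # W/m^2 at solar noon on a factor-1 face
    sunrise_h: float = 5.0
    sunset_h: float = 19.0
    absorptivity: float = 0.6        # wall solar absorptivity alpha
    h_out: float = 15.0              # exterior film coefficient, W/(m^2 K)
    orientation_factors: dict = field(default_factory=lambda: {
        "south": 1.0, "roof": 1.0, "north": 0.3, "east": 0.6, "west": 0.6})
    k_wall: float = 0.62             # wall overall U, W/(m^2 degC)
    k_roof: float = 1.25             # roof overall U, W/(m^2 degC)
    h_surface: float = 5.0           # grain-surface film coefficient, W/(m^2 K)

    def __post_init__(self) -> None:
        if self.k_wall <= 0 or self.k_roof <= 0:
            raise ValueError("envelope heat-transfer coefficients must be positive")
        if self.sunset_h <= self.sunrise_h:
            raise ValueError("sunset must come after sunrise")
        for face, f in self.orientation_factors.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"orientation factor for {face} outside [0,1]")
        if self.orientation_factors.get("south", 1.0) < self.orientation_factors.get("north", 0.0):
            raise ValueError("south orientation factor must be >= north")

    def with_(self, **kwargs) -> "ForcingScenario":
        return replace(self, **kwargs)

    def face_U(self, face: str) -> float:
        """Overall heat-transfer coefficient of a face, W/(m^2 degC)."""
        if face in ("south", "north", "east", "west"):
            return self.k_wall
        if face == "roof":
            return self.k_roof
        if face == "grain_surface":
            # roof and headspace film in series; headspace not resolved
            return 1.0 / (1.0 / self.k_roof + 1.0 / self.h_surface)
        if face == "floor":
            return 0.0  # adiabatic default
        raise ValueError(f"unknown envelope face {face!r}")


def ambient_temperature(scenario: ForcingScenario, t_s) -> float | np.ndarray:
    """Exterior air temperature (degC) at time t (seconds from start)."""
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0) or np.any(t > scenario.horizon_s):
        raise ValueError("time outside the scenario horizon")
    if scenario.series is not None:
        pts = np.asarray(scenario.series, dtype=float)
        ts, Ts = pts[:, 0], pts[:, 1]
        if np.any(t < ts[0]) or np.any(t > ts[-1]):
            raise ValueError("time outside the supplied ambient series")
        out = np.interp(t, ts, Ts)
    else:
        out = (scenario.mean_C
               + scenario.drift_C_per_30d * t / (30 * DAY_S)
               + scenario.amplitude_C
               * np.sin(2 * np.pi * (t - scenario.t_peak_h * HOUR_S) / DAY_S
                        + np.pi / 2))
        # sin(...) written so the daily maximum falls at t_peak_h
    return float(out) if out.ndim == 0 else out


def solar_irradiance(scenario: ForcingScenario, t_s, face: str) -> float | np.ndarray:
    """Incident solar irradiance (W/m^2) on a face at time t.

    Half-sine day shape between sunrise and sunset, scaled by the face
    orientation factor; zero at night and on the floor.
    """
    if face in ("floor",):
        return 0.0
    factor = scenario.orientation_factors.get(
        "roof" if face == "grain_surface" else face)
    if factor is None:
        raise ValueError(f"unknown envelope face {face!r}")
    t = np.asarray(t_s, dtype=float)
    h = (t / HOUR_S) % 24.0
    span = scenario.sunset_h - scenario.sunrise_h
    shape = np.sin(np.pi * (h - scenario.sunrise_h) / span)
    day = (h >= scenario.sunrise_h) & (h <= scenario.sunset_h)
    out = np.where(day, np.maximum(shape, 0.0), 0.0) * factor * scenario.peak_irradiance
    return float(out) if out.ndim == 0 else out


def sol_air_temperature(scenario: ForcingScenario, t_s, face: str):
    """Sol-air temperature (degC): ambient plus absorbed-radiation lift."""
    T_amb = ambient_temperature(scenario, t_s)
    I = solar_irradiance(scenario, t_s, face)
    return T_amb + scenario.absorptivity * I / scenario.h_out


def envelope_flux(scenario: ForcingScenario, face: str, T_inside_surface, t_s):
    """Heat flux (W/m^2, positive into the grain) through an envelope face.

    q = U_face * (T_solair(t, face) - T_inside_surface); the floor is
    adiabatic by default (U = 0).
    """
    U = scenario.face_U(face)
    if U == 0.0:
        return np.zeros_like(np.asarray(T_inside_surface, dtype=float)) \
            if np.ndim(T_inside_surface) else 0.0
    T_sa = sol_air_temperature(scenario, t_s, face)
    out = U * (T_sa - np.asarray(T_inside_surface, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


def load_ambient_series(path, horizon_s: float | None = None) -> ForcingScenario:
    """Build a scenario from a CSV with columns ``time_s, temperature_C``."""
    df = pd.read_csv(path)
    missing = {"time_s", "temperature_C"} - set(df.columns)
    if missing:
        raise ValueError(f"ambient series CSV missing columns {sorted(missing)}")
    series = tuple(zip(df["time_s"].astype(float), df["temperature_C"].astype(float)))
    return ForcingScenario(series=series,
                           horizon_s=horizon_s or float(df["time_s"].max()))
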