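"""Physical chemistry of dissolved CO2 and CH4 in freshwater.

Implements the CO2 solubility coefficient (Weiss-form polynomial), the
air-water gas exchange flux F = k * alpha * dpCO2, the conversion of areal
fluxes to area-integrated carbon fluxes, and the two-phase mass balance that
recovers an original dissolved CH4 concentration from a headspace
equilibration measurement.

Unit contract (package-wide): temperatures in degrees Celsius, pCO2 in ppm
(treated as uatm at 1 atm total pressure), k in m d-1, areas in km2, areal
fluxes in mmol m-2 d-1, integrated fluxes in PgC yr-1, dissolved CH4 in
nmol L-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GasConstants",
    "HeadspaceSetup",
    "FluxValue",
    "co2_solubility",
    "ch4_solubility",
    "co2_flux",
    "areal_to_integrated",
    "headspace_to_dissolved_ch4",
    "dissolved_ch4_to_headspace",
    "DAYS_PER_YEAR",
    "MOLAR_MASS_C",
]

#: Ideal-gas constant, L atm mol-1 K-1.
R_L_ATM = 0.08205736

#: Molar volume of an ideal gas at STP (0 degC, 1 atm), L mol-1. Converts a
#: Bunsen coefficient (L gas at STP per L water per atm) to mol L-1 atm-1.
MOLAR_VOLUME_STP = 22.414

DAYS_PER_YEAR = 365.25
MOLAR_MASS_C = 12.011  # g mol-1

# Weiss-form coefficients for CO2 solubility in mol L-1 atm-1:
#   ln a = A1 + A2*(100/T) + A3*ln(T/100) + S*(B1 + B2*(T/100) + B3*(T/100)^2)
_CO2_A = (-58.0931, 90.5069, 22.2940)
_CO2_B = (0.027766, -0.025888, 0.0050578)

# Same functional form for the CH4 Bunsen solubility coefficient
# (L CH4 at STP per L water per atm of CH4 partial pressure).
_CH4_A = (-67.1962, 99.1624, 27.9015)
_CH4_B = (-0.072909, 0.041674, -0.0064603)


@dataclass(frozen=True)
class GasConstants:
    """Fixed physical conditions used in flux computations.

    The defaults are the upscaling conventions used throughout the package:
    a constant water temperature of 25 degC for the solubility coefficient,
    a constant atmospheric pCO2 of 390 ppm, and freshwater (salinity 0).
    ``atm_ch4_nmol`` is the approximate dissolved CH4 concentration at
    atmospheric equilibrium (~2 nmol L-1); it is reported for reference and
    does not enter the CO2 flux arithmetic.
    """

    water_temp: float = 25.0   # degC
    atm_pco2: float = 390.0    # ppm (~uatm)
    salinity: float = 0.0      # per mil
    atm_ch4_nmol: float = 2.0  # nmol L-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.water_temp <= 40.0:
            raise ValueError(
                f"water_temp={self.water_temp} outside supported range [0, 40] degC"
            )
        if self.atm_pco2 <= 0:
            raise ValueError("atm_pco2 must be positive")
        if self.salinity < 0:
            raise ValueError("salinity must be >= 0")

    @property
    def alpha(self) -> float:
        """CO2 solubility coefficient at these conditions, mol L-1 atm-1."""
        return co2_solubility(self.water_temp, self.salinity)


@dataclass(frozen=True)
class HeadspaceSetup:
    """Geometry and conditions of a headspace-equilibration CH4 measurement.

    Models the standard protocol: a serum vial holds a water sample under a
    headspace of pure N2; after equilibration the CH4 mixing ratio in the
    headspace is measured by gas chromatography. Defaults correspond to a
    50 mL vial with a 20 mL N2 headspace over 30 mL of water.

    The lab equilibration temperature and pressure are configurable inputs
    because they depend on the laboratory, not on the field protocol.
    """

    measured_mixing_ratio: float        # ppm CH4 in headspace at equilibrium
    vial_volume: float = 50.0           # mL
    headspace_volume: float = 20.0      # mL
    water_volume: float = 30.0          # mL
    equilibration_temp: float = 25.0    # degC
    lab_pressure: float = 1.0           # atm

    def __post_init__(self) -> None:
        if min(self.vial_volume, self.headspace_volume, self.water_volume) <= 0:
            raise ValueError("all volumes must be positive")
        if self.headspace_volume + self.water_volume > self.vial_volume + 1e-9:
            raise ValueError(
                "headspace_volume + water_volume exceeds vial_volume "
                f"({self.headspace_volume} + {self.water_volume} > {self.vial_volume})"
            )
        if self.measured_mixing_ratio < 0:
            raise ValueError("measured_mixing_ratio must be >= 0")
        if self.lab_pressure <= 0:
            raise ValueError("lab_pressure must be positive")


@dataclass(frozen=True)
class FluxValue:
    """An areal air-water CO2 flux together with the terms that produced it.

    Positive ``areal_flux`` means evasion from water to atmosphere.
    """

    areal_flux: float   # mmol m-2 d-1
    alpha: float        # mol L-1 atm-1
    k: float            # m d-1
    delta_pco2: float   # uatm


def _weiss_form(temp_c, salinity, a, b):
    t = np.asarray(temp_c, dtype=float) + 273.15
    th = t / 100.0
    ln_sol = a[0] + a[1] * (100.0 / t) + a[2] * np.log(th)
    ln_sol = ln_sol + np.asarray(salinity, dtype=float) * (
        b[0] + b[1] * th + b[2] * th**2
    )
    return np.exp(ln_sol)


def co2_solubility(temp: float, salinity: float = 0.0):
    """CO2 solubility coefficient alpha, mol L-1 atm-1.

    Weiss-form polynomial in absolute temperature and salinity; strictly
    decreasing in temperature. At 25 degC in freshwater alpha ~ 0.0340
    mol L-1 atm-1.

    Parameters
    ----------
    temp : float or array-like
        Water temperature in degrees Celsius; must lie in [-1, 45].
    salinity : float, default 0
        Salinity in per mil (0 for freshwater).
    """
    t = np.asarray(temp, dtype=float)
    if np.any((t < -1.0) | (t > 45.0)):
        raise ValueError(f"temperature {temp} outside valid range [-1, 45] degC")
    if np.any(np.asarray(salinity) < 0):
        raise ValueError("salinity must be >= 0")
    out = _weiss_form(t, salinity, _CO2_A, _CO2_B)
    return float(out) if np.isscalar(temp) else out


def ch4_solubility(temp: float, salinity: float = 0.0, *, as_molar: bool = True):
    """CH4 solubility at 1 atm CH4 partial pressure.

    Returns the molar solubility in mol L-1 atm-1 by default, or the raw
    Bunsen coefficient (L CH4 at STP per L water per atm) when
    ``as_molar=False``. At 25 degC in freshwater the molar value is
    ~1.41e-3 mol L-1 atm-1.
    """
    t = np.asarray(temp, dtype=float)
    if np.any((t < -1.0) | (t > 45.0)):
        raise ValueError(f"temperature {temp} outside valid range [-1, 45] degC")
    bunsen = _weiss_form(t, salinity, _CH4_A, _CH4_B)
    out = bunsen / MOLAR_VOLUME_STP if as_molar else bunsen
    return float(out) if np.isscalar(temp) else out


def co2_flux(alpha: float, k, pco2_water, pco2_air: float):
    """Air-water CO2 flux F = k * alpha * (pCO2_water - pCO2_air), mmol m-2 d-1.

    ``alpha`` in mol L-1 atm-1 is numerically equal to mmol m-3 uatm-1, so no
    explicit conversion factor appears: with k in m d-1 and the gradient in
    uatm the product is already in mmol m-2 d-1. Positive values are evasion
    to the atmosphere; a sub-atmospheric pCO2_water yields a negative flux
    (invasion).
    """
    if np.any(np.asarray(alpha) <= 0):
        raise ValueError("alpha must be positive")
    if np.any(np.asarray(k) < 0):
        raise ValueError("gas transfer velocity k must be >= 0")
    out = np.asarray(k, dtype=float) * np.asarray(alpha, dtype=float) * (
        np.asarray(pco2_water, dtype=float) - float(pco2_air)
    )
    scalar = all(np.isscalar(v) or np.ndim(v) == 0 for v in (alpha, k, pco2_water))
    return float(out) if scalar else out


def areal_to_integrated(areal_flux, area):
    """Convert an areal flux (mmol CO2 m-2 d-1) over an area (km2) to PgC yr-1.

    mmol -> mol (1e-3), km2 -> m2 (1e6), d -> yr (365.25), mol C -> g C
    (12.011), g -> Pg (1e-15).
    """
    if np.any(np.asarray(area) < 0):
        raise ValueError("area must be >= 0")
    out = (
        np.asarray(areal_flux, dtype=float)
        * 1e-3
        * np.asarray(area, dtype=float)
        * 1e6
        * DAYS_PER_YEAR
        * MOLAR_MASS_C
        * 1e-15
    )
    scalar = np.ndim(areal_flux) == 0 and np.ndim(area) == 0
    return float(out) if scalar else out


def headspace_to_dissolved_ch4(setup: HeadspaceSetup) -> float:
    """Original dissolved CH4 concentration (nmol L-1) from a headspace run.

    Two-phase mass balance at equilibrium. With x the measured headspace
    mixing ratio (as a fraction), P the lab pressure and pCH4 = x * P:

    * gas phase:       n_g = pCH4 * V_g / (R * T_lab)      (ideal gas)
    * dissolved phase: n_w = pCH4 * beta(T_lab) * V_w      (Henry's law,
      beta the molar CH4 solubility in mol L-1 atm-1)

    All CH4 came from the water sample, so the original concentration is
    (n_g + n_w) / V_w. The result is linear in the measured mixing ratio.
    """
    x_atm = setup.measured_mixing_ratio * 1e-6 * setup.lab_pressure  # atm CH4
    t_k = setup.equilibration_temp + 273.15
    v_g = setup.headspace_volume / 1000.0  # L
    v_w = setup.water_volume / 1000.0      # L
    beta = ch4_solubility(setup.equilibration_temp)
    n_gas = x_atm * v_g / (R_L_ATM * t_k)
    n_dissolved = x_atm * beta * v_w
    return (n_gas + n_dissolved) / v_w * 1e9  # nmol L-1


def dissolved_ch4_to_headspace(
    concentration_nmol: float,
    vial_volume: float = 50.0,
    headspace_volume: float = 20.0,
    water_volume: float = 30.0,
    equilibration_temp: float = 25.0,
    lab_pressure: float = 1.0,
) -> HeadspaceSetup:
    """Inverse mass balance: the equilibrium headspace mixing ratio (ppm)
    implied by an original dissolved concentration.

    Exists so the forward calculation can be verified by round-trip; also
    useful for designing vial geometries. Returns a :class:`HeadspaceSetup`
    whose ``measured_mixing_ratio`` is the implied equilibrium value.
    """
    if water_volume <= 0:
        raise ValueError("water_volume must be positive")
    t_k = equilibration_temp + 273.15
    v_g = headspace_volume / 1000.0
    v_w = water_volume / 1000.0
    beta = ch4_solubility(equilibration_temp)
    total_mol = concentration_nmol * 1e-9 * v_w
    # total = pCH4 * (V_g/(R T) + beta V_w); solve for pCH4, express as ppm
    p_ch4 = total_mol / (v_g / (R_L_ATM * t_k) + beta * v_w)
    x_ppm = p_ch4 / lab_pressure * 1e6
    return HeadspaceSetup(
        measured_mixing_ratio=x_ppm,
        vial_volume=vial_volume,
        headspace_volume=headspace_volume,
        water_volume=water_volume,
        equilibration_temp=equilibration_temp,
        lab_pressure=lab_pressure,
    )
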