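"""Headspace flux, potential denitrification, and the N2O/(N2O+N2) product ratio.

A sealed-bottle incubation accumulates N2O in the headspace; the mass flux
per kg dry soil per hour is obtained from the concentration change by the
ideal-gas conversion

    F = rho * V * dC * 273/(273 + T) * f_N / (W * dt)

with rho the standard-state density of N2O (kg m^-3 at 0 degC, 1 atm), V the
bottle volume, dC the headspace N2O change (ppm by volume), T the incubation
temperature (degC), f_N = 28/44 the mass fraction of N in N2O, W the dry soil
mass (kg) and dt the accumulation interval (h).  For multi-timepoint series
dC/dt is the least-squares slope of ppm against time.

Potential denitrification activity (PDA) comes from a slurry amended with
non-limiting nitrate and carbon under 10% acetylene, which blocks the N2O
reductase so the measured N2O equals total denitrification (N2O + N2).  The
paired bottle without acetylene measures net N2O; the quotient is the
denitrification product ratio N2O/(N2O+N2), clamped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .study_io import IncubationSeries

__all__ = [
    "FluxEstimate",
    "ProductRatio",
    "GasParams",
    "DEFAULT_GAS_PARAMS",
    "flux_eq",
    "slope_rate",
    "product_ratio",
    "pda",
]

N2O_DENSITY_STP = 1.964  # kg m^-3 at 0 degC, 1 atm
N_FRACTION_N2O = 28.0 / 44.0  # mass fraction of N in N2O
SEALED_INTERVAL_H = 6.0  # default sealed-accumulation interval


@dataclass(frozen=True)
class GasParams:
    """Constants of the headspace conversion; override for other gases/protocols."""

    gas_density: float = N2O_DENSITY_STP  # kg m^-3, standard state
    n_fraction: float = N_FRACTION_N2O
    interval_h: float = SEALED_INTERVAL_H


DEFAULT_GAS_PARAMS = GasParams()


@dataclass(frozen=True)
class FluxEstimate:
    """A derived soil N2O flux for one bottle."""

    sample_id: str
    rate: float
    unit: str = "ug N kg-1 h-1"
    r2_of_slope: float | None = None
    method: str = "two_point"  # or "regression"


@dataclass(frozen=True)
class ProductRatio:
    """N2O/(N2O+N2) denitrification product ratio, clamped to [0, 1]."""

    sample_id: str
    ratio: float
    raw_ratio: float
    clamped: bool


def flux_eq(
    delta_c: float,
    volume: float,
    temperature_c: float,
    soil_mass: float,
    interval_h: float = SEALED_INTERVAL_H,
    gas_density: float = N2O_DENSITY_STP,
    n_fraction: float = N_FRACTION_N2O,
) -> float:
    """Headspace concentration change to mass flux, ug N per kg dry soil per hour.

    ``delta_c`` is the ppm (by volume) change over ``interval_h`` hours in a
    bottle of ``volume`` litres holding ``soil_mass`` kg dry soil at
    ``temperature_c`` degC.  The rate is exactly linear in ``delta_c`` and in
    1/``soil_mass`` and may be negative (net N2O uptake).
    """
    if volume <= 0:
        raise ValueError("volume must be > 0")
    if soil_mass <= 0:
        raise ValueError("soil_mass must be > 0")
    if interval_h <= 0:
        raise ValueError("interval_h must be > 0")
    volume_m3 = volume * 1e-3
    gas_kg = gas_density * volume_m3 * (delta_c * 1e-6) * (273.0 / (273.0 + temperature_c))
    n_ug = gas_kg * n_fraction * 1e9
    return n_ug / (soil_mass * interval_h)


def slope_rate(series: IncubationSeries, gas: GasParams = DEFAULT_GAS_PARAMS) -> FluxEstimate:
    """Flux from the least-squares slope of headspace ppm against time.

    The slope (ppm h^-1) feeds :func:`flux_eq` with a 1-hour interval.  With
    exactly two timepoints this is the two-point difference quotient
    (``method="two_point"``); with three or more, an ordinary regression with
    its r2 reported.
    """
    series.validate()
    t = np.asarray(series.timepoints, dtype=float)
    c = np.asarray(series.headspace_ppm, dtype=float)
    if np.unique(t).size != t.size:
        raise ValueError("duplicate timepoints")
    slope, intercept = np.polyfit(t, c, 1)
    resid = c - (slope * t + intercept)
    tss = float(np.sum((c - c.mean()) ** 2))
    r2 = None
    method = "two_point"
    if t.size >= 3:
        method = "regression"
        r2 = 1.0 if tss == 0 else 1.0 - float(np.sum(resid**2)) / tss
        r2 = min(max(r2, 0.0), 1.0)
    rate = flux_eq(
        delta_c=float(slope),
        volume=series.bottle_volume,
        temperature_c=series.temperature_c,
        soil_mass=series.soil_dry_mass,
        interval_h=1.0,
        gas_density=gas.gas_density,
        n_fraction=gas.n_fraction,
    )
    return FluxEstimate(sample_id=series.sample_id, rate=rate, r2_of_slope=r2, method=method)


def product_ratio(
    rate_without_c2h2: float, rate_with_c2h2: float, sample_id: str = ""
) -> ProductRatio:
    """N2O/(N2O+N2) from the paired-bottle acetylene assay.

    The acetylene-blocked bottle measures total denitrification (N2O+N2);
    the unblocked bottle net N2O.  The raw quotient may stray outside [0, 1]
    through measurement noise and is clamped with a flag.
    """
    if rate_with_c2h2 <= 0:
        raise ValueError("acetylene-blocked rate must be > 0 (no denitrification signal)")
    raw = rate_without_c2h2 / rate_with_c2h2
    clamped = min(max(raw, 0.0), 1.0)
    return ProductRatio(
        sample_id=sample_id, ratio=clamped, raw_ratio=raw, clamped=clamped != raw
    )


def pda(series: IncubationSeries, gas: GasParams = DEFAULT_GAS_PARAMS) -> FluxEstimate:
    """Potential denitrification activity from an acetylene-blocked series.

    Same slope calculation as :func:`slope_rate` but reported in
    mg N kg^-1 h^-1, the customary PDA unit.
    """
    if not series.acetylene:
        raise ValueError("PDA requires an acetylene-blocked series")
    est = slope_rate(series, gas)
    return FluxEstimate(
        sample_id=est.sample_id,
        rate=est.rate * 1e-3,
        unit="mg N kg-1 h-1",
        r2_of_slope=est.r2_of_slope,
        method=est.method,
    )
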