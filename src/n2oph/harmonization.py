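"""Harmonize heterogeneous field records to a common basis.

Soil pH reported in salt suspensions (CaCl2, KCl) reads systematically lower
than pH in water; observations are converted to a water basis with
configurable affine maps before any binning.  Sites are grouped into climate
zones by absolute latitude — tropical [0, 23.4], subtropical (23.4, 35.0],
temperate (35.0, 90] — and soils are labelled with the USDA acidity classes
(ultra-acidic below pH 3.5 up to strongly alkaline at 8.5-9.0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .ef_meta import compute_ef
from .study_io import FieldObservation

__all__ = [
    "PhConversion",
    "DEFAULT_PH_CONVERSIONS",
    "convert_ph",
    "harmonize_observations",
    "classify_climate_zone",
    "classify_acidity",
    "zone_summary",
    "CLIMATE_ZONES",
    "ACIDITY_CLASSES",
]

CLIMATE_ZONES = ("tropical", "subtropical", "temperate")

TROPICAL_MAX_LAT = 23.4
SUBTROPICAL_MAX_LAT = 35.0


@dataclass(frozen=True)
class PhConversion:
    """Affine map from salt-suspension pH to water pH: ``ph_h2o = slope*ph + intercept``."""

    medium: str
    slope: float
    intercept: float

    def __post_init__(self):
        if self.medium not in ("CaCl2", "KCl"):
            raise ValueError("conversion medium must be CaCl2 or KCl")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")

    def apply(self, ph: float) -> float:
        return self.slope * ph + self.intercept


# Salt-suspension pH typically reads ~0.5-1 unit below water pH; these offsets
# are deliberately simple defaults and should be overridden with
# region-calibrated maps for publication-grade work.
DEFAULT_PH_CONVERSIONS: Mapping[str, PhConversion] = {
    "CaCl2": PhConversion("CaCl2", slope=1.0, intercept=0.6),
    "KCl": PhConversion("KCl", slope=1.0, intercept=1.0),
}


def convert_ph(
    value: float,
    medium: str,
    conversions: Mapping[str, PhConversion] = DEFAULT_PH_CONVERSIONS,
) -> float:
    """Convert a reported pH to the water basis.

    H2O values pass through unchanged; ``unknown`` media are assumed to be
    water-measured (with a warning); CaCl2/KCl apply the configured affine
    map.  The result is clamped to the open interval (0, 14).
    """
    if not 0 < value < 14:
        raise ValueError("pH must lie in (0, 14)")
    if medium == "H2O":
        return value
    if medium == "unknown":
        warnings.warn(
            "pH medium unknown; assuming water-based measurement", stacklevel=2
        )
        return value
    if medium in ("CaCl2", "KCl"):
        conv = conversions.get(medium)
        if conv is None:
            raise ValueError(f"no conversion configured for medium {medium!r}")
        out = conv.apply(value)
        return min(max(out, math.nextafter(0.0, 1.0)), math.nextafter(14.0, 0.0))
    raise ValueError(f"unrecognized pH medium: {medium!r}")


def harmonize_observations(
    obs: Iterable[FieldObservation],
    conversions: Mapping[str, PhConversion] = DEFAULT_PH_CONVERSIONS,
) -> list[FieldObservation]:
    """Fill ``ph_h2o`` for every observation (in place) and return the list."""
    out = list(obs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # one unknown-medium warning per run is enough
        n_unknown = 0
        for o in out:
            if o.ph_medium == "unknown":
                n_unknown += 1
            o.ph_h2o = convert_ph(o.ph_reported, o.ph_medium, conversions)
    if n_unknown:
        warnings.warn(
            f"{n_unknown} observation(s) had unknown pH medium; assumed water",
            stacklevel=2,
        )
    return out


def classify_climate_zone(latitude: float) -> str:
    """Climate zone from absolute latitude.

    tropical |lat| <= 23.4; subtropical 23.4 < |lat| <= 35.0; temperate
    |lat| > 35.0.  Boundary latitudes belong to the lower (closer to the
    equator) zone.
    """
    if not -90 <= latitude <= 90:
        raise ValueError("latitude must lie in [-90, 90]")
    a = abs(latitude)
    if a <= TROPICAL_MAX_LAT:
        return "tropical"
    if a <= SUBTROPICAL_MAX_LAT:
        return "subtropical"
    return "temperate"


# USDA acidity classes; (lower, upper) closed at one-decimal resolution.
ACIDITY_CLASSES = (
    ("ultra-acidic", 0.0, 3.4),
    ("extremely acidic", 3.5, 4.4),
    ("very strongly acidic", 4.5, 5.0),
    ("strongly acidic", 5.1, 5.5),
    ("moderately acidic", 5.6, 6.0),
    ("slightly acidic", 6.1, 6.5),
    ("neutral", 6.6, 7.3),
    ("slightly alkaline", 7.4, 7.8),
    ("moderately alkaline", 7.9, 8.4),
    ("strongly alkaline", 8.5, 9.0),
)


def classify_acidity(ph: float) -> str:
    """USDA acidity class for a water-basis pH.

    The pH is rounded to one decimal before lookup (class edges are printed
    at that resolution).  Values above 9.0 fall outside the published table
    and are labelled ``strongly alkaline`` with a warning.
    """
    if not 0 < ph < 14:
        raise ValueError("pH must lie in (0, 14)")
    p = round(ph, 1)
    for label, lo, hi in ACIDITY_CLASSES:
        if lo <= p <= hi:
            return label
    warnings.warn(
        f"pH {ph} above the strongly-alkaline upper edge (9.0); "
        "labelling strongly alkaline (out of table)",
        stacklevel=2,
    )
    return "strongly alkaline"


def zone_summary(obs: Iterable[FieldObservation]) -> pd.DataFrame:
    """Per-climate-zone means of pH, emission factor and N rate.

    One row per zone with mean, standard error of the mean (sd/sqrt(n), null
    for n < 2) and count; zones with no observations get n=0 and null means.
    Observations without a latitude are skipped; the EF column uses only
    observations with n_rate > 0 (an EF is undefined otherwise).
    """
    rows = []
    for o in obs:
        if o.latitude is None:
            continue
        ph = o.ph_h2o if o.ph_h2o is not None else o.ph_reported
        ef = (
            compute_ef(o.emission_fertilized, o.emission_control, o.n_rate)
            if o.n_rate > 0
            else None
        )
        rows.append(
            {
                "zone": classify_climate_zone(o.latitude),
                "ph": ph,
                "ef_percent": ef,
                "n_rate": o.n_rate,
            }
        )
    df = pd.DataFrame(rows, columns=["zone", "ph", "ef_percent", "n_rate"])
    out = []
    for zone in CLIMATE_ZONES:
        sub = df[df["zone"] == zone]
        rec: dict = {"zone": zone, "n": int(len(sub))}
        for col in ("ph", "ef_percent", "n_rate"):
            vals = sub[col].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                rec[f"mean_{col}"] = None
                rec[f"sem_{col}"] = None
            else:
                rec[f"mean_{col}"] = float(np.mean(vals))
                rec[f"sem_{col}"] = (
                    float(np.std(vals, ddof=1) / np.sqrt(vals.size))
                    if vals.size > 1
                    else None
                )
        out.append(rec)
    return pd.DataFrame(out)
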