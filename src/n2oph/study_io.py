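"""Domain records and CSV I/O for the three tabular inputs.

Three kinds of tables enter the pipeline:

* field fertilization studies (paired fertilized/control cumulative N2O
  emissions, N rate, replicate count, soil pH and covariates),
* functional-gene abundance surveys (qPCR copy numbers per g soil for
  nitrifier and denitrifier marker genes, paired with pH and optionally an
  N2O flux), and
* laboratory incubation series (timed headspace N2O concentrations per
  bottle, with soil mass, volume, temperature, and an acetylene flag).

Readers are permissive by default: a malformed row becomes a
:class:`RejectedRow` with a reason instead of aborting the run; ``strict=True``
upgrades any reject to an error.  Missing optional covariates are stored as
``None``, never as sentinel numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FieldObservation",
    "GeneObservation",
    "IncubationSeries",
    "RejectedRow",
    "SchemaError",
    "read_field_observations",
    "read_gene_observations",
    "read_incubation_series",
    "write_report",
]

ECOSYSTEMS = ("cropland", "grassland", "forest")
PH_MEDIA = ("H2O", "CaCl2", "KCl", "unknown")
GENES = ("AOA_amoA", "AOB_amoA", "nirK", "nirS", "nosZI", "nosZII")

# case-insensitive synonyms seen in compiled literature tables
_GENE_SYNONYMS = {
    "aoa_amoa": "AOA_amoA",
    "aoa amoa": "AOA_amoA",
    "aoa": "AOA_amoA",
    "amoa-aoa": "AOA_amoA",
    "aob_amoa": "AOB_amoA",
    "aob amoa": "AOB_amoA",
    "aob": "AOB_amoA",
    "amoa-aob": "AOB_amoA",
    "nirk": "nirK",
    "nirs": "nirS",
    "noszi": "nosZI",
    "nosz1": "nosZI",
    "nosz clade i": "nosZI",
    "nosz-i": "nosZI",
    "nosz": "nosZI",  # bare nosZ in this pipeline refers to clade I
    "noszii": "nosZII",
    "nosz2": "nosZII",
    "nosz clade ii": "nosZII",
    "nosz-ii": "nosZII",
}

_PH_MEDIUM_SYNONYMS = {
    "h2o": "H2O",
    "water": "H2O",
    "cacl2": "CaCl2",
    "kcl": "KCl",
    "unknown": "unknown",
    "": "unknown",
}


class SchemaError(ValueError):
    """A required column is missing or the file is structurally unreadable."""


@dataclass(frozen=True)
class RejectedRow:
    row_index: int
    reason: str


@dataclass
class FieldObservation:
    """One fertilization-experiment observation.

    ``emission_fertilized`` / ``emission_control`` are cumulative N2O-N
    emissions (kg N ha^-1) from the fertilized and unfertilized plots,
    ``n_rate`` the N fertilization rate (kg N ha^-1), ``replicates`` the plot
    replication of the experiment.  ``ph_h2o`` is filled by harmonization and
    left None by the reader when the medium is not water.
    """

    study_id: str
    ph_reported: float
    n_rate: float
    emission_fertilized: float
    emission_control: float
    replicates: int | None
    site_id: str | None = None
    latitude: float | None = None
    ecosystem: str | None = None
    ph_medium: str = "unknown"
    ph_h2o: float | None = None
    map_mm: float | None = None
    mat_c: float | None = None
    soc: float | None = None
    tn: float | None = None
    sand_pct: float | None = None
    silt_pct: float | None = None
    clay_pct: float | None = None

    def validate(self) -> None:
        if not 0 < self.ph_reported < 14:
            raise ValueError("ph_reported must lie in (0, 14)")
        if self.n_rate < 0:
            raise ValueError("n_rate must be >= 0")
        if self.replicates is not None and self.replicates < 1:
            raise ValueError("replicates >= 1")
        if self.ecosystem is not None and self.ecosystem not in ECOSYSTEMS:
            raise ValueError(f"ecosystem must be one of {ECOSYSTEMS}")
        if self.ph_medium not in PH_MEDIA:
            raise ValueError(f"ph_medium must be one of {PH_MEDIA}")
        if self.latitude is not None and not -90 <= self.latitude <= 90:
            raise ValueError("latitude must lie in [-90, 90]")
        texture = (self.sand_pct, self.silt_pct, self.clay_pct)
        if all(v is not None for v in texture):
            total = sum(texture)
            if not 98 <= total <= 102:
                raise ValueError(
                    f"sand+silt+clay = {total:.1f} outside 100 +/- 2"
                )


@dataclass
class GeneObservation:
    """A functional-gene abundance estimate (copies per g dry soil)."""

    study_id: str
    gene: str
    copies_per_g: float
    ph_h2o: float
    n2o_flux: float | None = None  # ug N m^-2 h^-1
    ecosystem: str | None = None
    sample_id: str | None = None

    def validate(self) -> None:
        if self.gene not in GENES:
            raise ValueError(f"gene must be one of {GENES}")
        if not self.copies_per_g > 0 or not math.isfinite(self.copies_per_g):
            raise ValueError("copies_per_g must be finite and > 0")
        if not 0 < self.ph_h2o < 14:
            raise ValueError("ph_h2o must lie in (0, 14)")
        if self.ecosystem is not None and self.ecosystem not in ECOSYSTEMS:
            raise ValueError(f"ecosystem must be one of {ECOSYSTEMS}")


@dataclass
class IncubationSeries:
    """Timed headspace N2O concentrations for one incubation bottle."""

    sample_id: str
    soil_dry_mass: float  # kg
    bottle_volume: float  # L
    temperature_c: float
    acetylene: bool
    timepoints: list[float] = field(default_factory=list)  # hours
    headspace_ppm: list[float] = field(default_factory=list)

    def validate(self) -> None:
        if self.soil_dry_mass <= 0:
            raise ValueError("soil_dry_mass must be > 0")
        if self.bottle_volume <= 0:
            raise ValueError("bottle_volume must be > 0")
        if len(self.timepoints) != len(self.headspace_ppm):
            raise ValueError("timepoints and headspace_ppm lengths differ")
        if len(self.timepoints) < 2:
            raise ValueError("need at least 2 timepoints")
        t = self.timepoints
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if any(c < 0 for c in self.headspace_ppm):
            raise ValueError("headspace_ppm must be >= 0")


def normalize_gene_name(name: str) -> str:
    key = " ".join(str(name).strip().lower().split())
    canon = _GENE_SYNONYMS.get(key) or _GENE_SYNONYMS.get(key.replace(" ", "_"))
    if canon is None:
        canon = _GENE_SYNONYMS.get(key.replace("_", " "))
    if canon is None:
        raise ValueError(f"unrecognized gene name: {name!r}")
    return canon


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def _opt_float(row, col) -> float | None:
    if col not in row or pd.isna(row[col]):
        return None
    return float(row[col])


def _apply_overrides(df: pd.DataFrame, overrides: Mapping[str, str] | None) -> pd.DataFrame:
    if overrides:
        # user map: canonical name -> column name present in the file
        df = df.rename(columns={v: k for k, v in overrides.items()})
    return df


def read_field_observations(
    path,
    schema_overrides: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[list[FieldObservation], list[RejectedRow]]:
    """Read field-study observations from CSV.

    Required columns: ``study_id, ph_reported, n_rate, emission_fertilized,
    emission_control, replicates``.  If a ``ph_medium`` column is absent the
    medium is recorded as ``unknown`` for every row (downstream harmonization
    treats unknown media as water-measured).  Returns ``(observations,
    rejects)`` preserving input row order; ``strict=True`` raises on the first
    bad row instead.
    """
    df = _apply_overrides(pd.read_csv(path), schema_overrides)
    _require_columns(
        df,
        ["study_id", "ph_reported", "n_rate", "emission_fertilized",
         "emission_control", "replicates"],
        path,
    )
    obs: list[FieldObservation] = []
    rejects: list[RejectedRow] = []
    for i, row in df.iterrows():
        try:
            medium_raw = str(row["ph_medium"]).strip().lower() if "ph_medium" in df.columns and not pd.isna(row.get("ph_medium")) else "unknown"
            medium = _PH_MEDIUM_SYNONYMS.get(medium_raw)
            if medium is None:
                raise ValueError(f"unrecognized ph_medium: {row['ph_medium']!r}")
            reps = None if pd.isna(row["replicates"]) else int(row["replicates"])
            eco = None
            if "ecosystem" in df.columns and not pd.isna(row.get("ecosystem")):
                eco = str(row["ecosystem"]).strip().lower()
            o = FieldObservation(
                study_id=str(row["study_id"]),
                site_id=str(row["site_id"]) if "site_id" in df.columns and not pd.isna(row.get("site_id")) else None,
                latitude=_opt_float(row, "latitude"),
                ecosystem=eco,
                ph_reported=float(row["ph_reported"]),
                ph_medium=medium,
                n_rate=float(row["n_rate"]),
                emission_fertilized=float(row["emission_fertilized"]),
                emission_control=float(row["emission_control"]),
                replicates=reps,
                map_mm=_opt_float(row, "map_mm"),
                mat_c=_opt_float(row, "mat_c"),
                soc=_opt_float(row, "soc"),
                tn=_opt_float(row, "tn"),
                sand_pct=_opt_float(row, "sand_pct"),
                silt_pct=_opt_float(row, "silt_pct"),
                clay_pct=_opt_float(row, "clay_pct"),
            )
            o.validate()
            obs.append(o)
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"{path} row {i}: {exc}") from exc
            rejects.append(RejectedRow(row_index=int(i), reason=str(exc)))
    return obs, rejects


def read_gene_observations(
    path,
    schema_overrides: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[list[GeneObservation], list[RejectedRow]]:
    """Read gene-abundance observations from CSV.

    Required columns: ``study_id, gene, copies_per_g, ph_h2o``.  Gene names
    are matched case-insensitively against common synonyms ("nosZ clade I"
    -> nosZI; a bare "nosZ" is taken as clade I).
    """
    df = _apply_overrides(pd.read_csv(path), schema_overrides)
    _require_columns(df, ["study_id", "gene", "copies_per_g", "ph_h2o"], path)
    obs: list[GeneObservation] = []
    rejects: list[RejectedRow] = []
    for i, row in df.iterrows():
        try:
            eco = None
            if "ecosystem" in df.columns and not pd.isna(row.get("ecosystem")):
                eco = str(row["ecosystem"]).strip().lower()
            o = GeneObservation(
                study_id=str(row["study_id"]),
                gene=normalize_gene_name(row["gene"]),
                copies_per_g=float(row["copies_per_g"]),
                ph_h2o=float(row["ph_h2o"]),
                n2o_flux=_opt_float(row, "n2o_flux"),
                ecosystem=eco,
                sample_id=str(row["sample_id"]) if "sample_id" in df.columns and not pd.isna(row.get("sample_id")) else None,
            )
            o.validate()
            obs.append(o)
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"{path} row {i}: {exc}") from exc
            rejects.append(RejectedRow(row_index=int(i), reason=str(exc)))
    return obs, rejects


def read_incubation_series(
    path,
    schema_overrides: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[list[IncubationSeries], list[RejectedRow]]:
    """Read long-format incubation series from CSV.

    Required columns: ``sample_id, acetylene, soil_dry_mass, bottle_volume,
    temperature_c, time_h, ppm`` — one row per headspace sampling, grouped by
    ``sample_id`` into :class:`IncubationSeries`.  A group that fails
    validation (e.g. a single timepoint, duplicate times) is rejected whole;
    the reject's ``row_index`` is the first file row of the group.
    """
    df = _apply_overrides(pd.read_csv(path), schema_overrides)
    _require_columns(
        df,
        ["sample_id", "acetylene", "soil_dry_mass", "bottle_volume",
         "temperature_c", "time_h", "ppm"],
        path,
    )
    series: list[IncubationSeries] = []
    rejects: list[RejectedRow] = []
    for sample_id, grp in df.groupby("sample_id", sort=False):
        first_row = int(grp.index[0])
        try:
            grp = grp.sort_values("time_h")
            ace = grp["acetylene"].astype(float).unique()
            mass = grp["soil_dry_mass"].astype(float).unique()
            vol = grp["bottle_volume"].astype(float).unique()
            temp = grp["temperature_c"].astype(float).unique()
            for name, vals in [("acetylene", ace), ("soil_dry_mass", mass),
                               ("bottle_volume", vol), ("temperature_c", temp)]:
                if len(vals) != 1:
                    raise ValueError(f"{name} varies within sample {sample_id!r}")
            s = IncubationSeries(
                sample_id=str(sample_id),
                soil_dry_mass=float(mass[0]),
                bottle_volume=float(vol[0]),
                temperature_c=float(temp[0]),
                acetylene=bool(ace[0]),
                timepoints=[float(v) for v in grp["time_h"]],
                headspace_ppm=[float(v) for v in grp["ppm"]],
            )
            s.validate()
            series.append(s)
        except (ValueError, TypeError) as exc:
            if strict:
                raise ValueError(f"{path} sample {sample_id!r}: {exc}") from exc
            rejects.append(RejectedRow(row_index=first_row, reason=str(exc)))
    return series, rejects


def write_report(tables: Mapping[str, pd.DataFrame], path, format: str = "tsv") -> None:
    """Write named result tables to disk.

    ``format="tsv"`` writes one ``<name>.tsv`` per table under directory
    ``path`` (created if needed) with floats at 12 significant digits so a
    re-read reproduces them to that precision.  ``format="json"`` writes a
    single JSON file mapping each table name to a list of row records.
    """
    if not tables:
        raise ValueError("tables must be non-empty")
    path = Path(path)
    if format == "tsv":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(path / f"{name}.tsv", sep="\t", index=False,
                      float_format="%.12g")
    elif format == "json":
        payload = {
            name: json.loads(df.to_json(orient="records", double_precision=15))
            for name, df in tables.items()
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError("format must be 'tsv' or 'json'")


def field_observations_to_frame(obs: Iterable[FieldObservation]) -> pd.DataFrame:
    """Tabulate observations (one column per dataclass field)."""
    cols = [f.name for f in fields(FieldObservation)]
    return pd.DataFrame([{c: getattr(o, c) for c in cols} for o in obs])


def gene_observations_to_frame(obs: Iterable[GeneObservation]) -> pd.DataFrame:
    cols = [f.name for f in fields(GeneObservation)]
    return pd.DataFrame([{c: getattr(o, c) for c in cols} for o in obs])
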