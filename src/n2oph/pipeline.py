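"""End-to-end runs: field-study meta-analysis, gene meta-analysis, incubations.

Each ``run_*`` function takes a :class:`RunConfig`, reads and validates its
input CSV, executes the corresponding analysis, and returns a report dict
containing result tables (DataFrames), fit summaries, stage counts, the
fully resolved configuration and SHA-256 checksums of the inputs, so a
report is reproducible from its own header.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ef_meta, gene_meta, harmonization, incubation, model_fitting, study_io

__all__ = ["RunConfig", "run_meta1", "run_meta2", "run_field", "write_run_report"]

log = logging.getLogger("n2oph")

MIN_EF_OBSERVATIONS = 10

EXIT_SCHEMA_ERROR = 2
EXIT_INSUFFICIENT_DATA = 3


@dataclass
class RunConfig:
    """Resolved settings of a pipeline run; defaults match the standard protocol.

    ``ph_bin_width`` 0.1 pH units, AICc threshold 2, gas constants of the
    6-hour sealed N2O incubation.  ``weight_bins`` switches the averaged-EF
    regression from unweighted (default) to bin-weight-weighted.
    """

    field_csv: str | None = None
    gene_csv: str | None = None
    incubation_csv: str | None = None
    out_dir: str = "n2oph-out"
    ph_bin_width: float = 0.1
    n_rate_width: float = 100.0
    aicc_threshold: float = 2.0
    weight_bins: bool = False
    strict: bool = False
    cacl2_slope: float = 1.0
    cacl2_intercept: float = 0.6
    kcl_slope: float = 1.0
    kcl_intercept: float = 1.0
    gas_density: float = incubation.N2O_DENSITY_STP
    n_fraction: float = incubation.N_FRACTION_N2O
    interval_h: float = incubation.SEALED_INTERVAL_H
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def ph_conversions(self):
        return {
            "CaCl2": harmonization.PhConversion("CaCl2", self.cacl2_slope, self.cacl2_intercept),
            "KCl": harmonization.PhConversion("KCl", self.kcl_slope, self.kcl_intercept),
        }

    def gas_params(self) -> incubation.GasParams:
        return incubation.GasParams(
            gas_density=self.gas_density,
            n_fraction=self.n_fraction,
            interval_h=self.interval_h,
        )


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _provenance(config: RunConfig, inputs: dict[str, str]) -> dict:
    return {
        "config": config.to_dict(),
        "inputs": {name: {"path": str(p), "sha256": _checksum(p)} for name, p in inputs.items()},
    }


def _fit_pair(x, y, threshold, weights=None):
    lin = model_fitting.fit_polynomial(x, y, degree=1, weights=weights)
    quad = model_fitting.fit_polynomial(x, y, degree=2, weights=weights)
    sel = model_fitting.select_model(lin, quad, threshold=threshold)
    return {
        "linear": lin.to_dict(),
        "quadratic": quad.to_dict(),
        "chosen": sel.chosen.to_dict(),
        "delta_aicc": sel.delta_aicc,
        "tie": sel.tie,
    }


def run_meta1(config: RunConfig) -> dict:
    """Field-study meta-analysis: EFs, pH bins, coarse and averaged fits.

    The coarse fit regresses every individual EF on pH; the averaged fit
    regresses one replicate-weighted mean EF per 0.1-pH bin on the bin
    centers.  Both undergo linear/quadratic AICc competition; concave
    quadratic winners report their peak pH.
    """
    if config.field_csv is None:
        raise ValueError("config.field_csv is required for meta1")
    obs, rejects = study_io.read_field_observations(config.field_csv, strict=config.strict)
    log.info("meta1: read %d observations, rejected %d rows", len(obs), len(rejects))
    harmonization.harmonize_observations(obs, config.ph_conversions())

    efs = []
    n_negative = 0
    for o in obs:
        if o.n_rate <= 0:
            continue
        ef = ef_meta.compute_ef(o.emission_fertilized, o.emission_control, o.n_rate)
        efs.append(
            ef_meta.EFObservation(
                study_id=o.study_id,
                ef_percent=ef,
                ph_h2o=o.ph_h2o,
                n_rate=o.n_rate,
                replicates=o.replicates,
                negative=ef < 0,
            )
        )
        n_negative += ef < 0
    if len(efs) < MIN_EF_OBSERVATIONS:
        raise ValueError(
            f"insufficient data: {len(efs)} EF observations (< {MIN_EF_OBSERVATIONS})"
        )
    log.info("meta1: %d EF observations (%d negative)", len(efs), n_negative)

    bins = ef_meta.assign_bins(efs, width=config.ph_bin_width)
    bins_df = ef_meta.bin_table(bins)
    log.info("meta1: %d non-empty pH bins", len(bins))

    coarse = _fit_pair(
        [e.ph_h2o for e in efs], [e.ef_percent for e in efs], config.aicc_threshold
    )
    averaged = _fit_pair(
        bins_df["bin_center"],
        bins_df["weighted_mean_ef"],
        config.aicc_threshold,
        weights=bins_df["sum_weights"] if config.weight_bins else None,
    )
    nrate_df = ef_meta.aggregate_by_n_rate(efs, width=config.n_rate_width)
    zones_df = harmonization.zone_summary(obs)

    return {
        "provenance": _provenance(config, {"field": config.field_csv}),
        "counts": {
            "read": len(obs) + len(rejects),
            "rejected": len(rejects),
            "ef_observations": len(efs),
            "negative_efs": n_negative,
            "bins": len(bins),
        },
        "rejects": rejects,
        "tables": {"bins": bins_df, "n_rate": nrate_df, "zones": zones_df},
        "fits": {"coarse": coarse, "averaged": averaged},
    }


def run_meta2(config: RunConfig) -> dict:
    """Gene meta-analysis: per-gene pH fits, ratio fits, flux-ratio fit."""
    if config.gene_csv is None:
        raise ValueError("config.gene_csv is required for meta2")
    obs, rejects = study_io.read_gene_observations(config.gene_csv, strict=config.strict)
    log.info("meta2: read %d gene observations, rejected %d rows", len(obs), len(rejects))
    n_noszii = sum(1 for o in obs if o.gene == "nosZII")

    fits: dict[str, dict] = {}
    tables: dict[str, pd.DataFrame] = {}
    for gene in ("nirK", "nirS", "nosZI"):
        sub = [(o.ph_h2o, o.copies_per_g) for o in obs if o.gene == gene]
        if len(sub) >= 5:
            x, raw = zip(*sub)
            fits[f"{gene}_coarse"] = _fit_pair(
                x, np.log10(raw), config.aicc_threshold
            )
        binned = gene_meta.bin_average_log_abundance(obs, gene, width=config.ph_bin_width)
        tables[f"{gene}_bins"] = binned
        if len(binned) >= 5:
            fits[f"{gene}_averaged"] = _fit_pair(
                binned["bin_center"], binned["mean_log10"], config.aicc_threshold
            )

    records, skipped = gene_meta.ratio_records_from_observations(obs)
    log.info(
        "meta2: %d ratio records (%d samples missing a gene, %d nosZII rows set aside)",
        len(records), skipped, n_noszii,
    )
    if len(records) >= 5:
        fits["ratio_coarse"] = _fit_pair(
            [r.ph_h2o for r in records],
            [r.log10_ratio for r in records],
            config.aicc_threshold,
        )
    flux_fit = None
    if sum(r.n2o_flux is not None for r in records) >= 3:
        flux_fit = gene_meta.fit_flux_vs_ratio(records).to_dict()
    tables["ratios"] = pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "sample_id": r.sample_id,
                "ph_h2o": r.ph_h2o,
                "ratio": r.ratio,
                "log10_ratio": r.log10_ratio,
                "n2o_flux": r.n2o_flux,
            }
            for r in records
        ]
    )
    return {
        "provenance": _provenance(config, {"genes": config.gene_csv}),
        "counts": {
            "read": len(obs) + len(rejects),
            "rejected": len(rejects),
            "ratio_records": len(records),
            "ratio_skipped_missing_gene": skipped,
            "noszii_set_aside": n_noszii,
        },
        "rejects": rejects,
        "tables": tables,
        "fits": fits,
        "flux_vs_ratio": flux_fit,
    }


def run_field(config: RunConfig) -> dict:
    """Incubation analysis: per-bottle fluxes, PDA, product ratios, pH fits.

    Bottles are paired by sample id stem (everything before the last ``-``);
    a pair needs one acetylene-blocked and one open bottle.  When the
    incubation CSV carries a per-sample pH column (``ph_h2o``), pH responses
    of net N2O, PDA and the product ratio are fitted as well.
    """
    if config.incubation_csv is None:
        raise ValueError("config.incubation_csv is required for the field analysis")
    series, rejects = study_io.read_incubation_series(config.incubation_csv, strict=config.strict)
    log.info("field: read %d series, rejected %d", len(series), len(rejects))
    gas = config.gas_params()

    flux_rows = []
    pairs: dict[str, dict] = {}
    for s in series:
        est = incubation.slope_rate(s, gas)
        stem = s.sample_id.rsplit("-", 1)[0] if "-" in s.sample_id else s.sample_id
        side = "with_c2h2" if s.acetylene else "without_c2h2"
        pairs.setdefault(stem, {})[side] = est.rate
        row = {
            "sample_id": s.sample_id,
            "acetylene": s.acetylene,
            "rate_ug_n_kg_h": est.rate,
            "r2_of_slope": est.r2_of_slope,
            "method": est.method,
        }
        if s.acetylene:
            row["pda_mg_n_kg_h"] = incubation.pda(s, gas).rate
        flux_rows.append(row)

    ratio_rows = []
    for stem, sides in pairs.items():
        if "with_c2h2" in sides and "without_c2h2" in sides and sides["with_c2h2"] > 0:
            pr = incubation.product_ratio(
                sides["without_c2h2"], sides["with_c2h2"], sample_id=stem
            )
            ratio_rows.append(
                {
                    "sample_id": stem,
                    "ratio": pr.ratio,
                    "raw_ratio": pr.raw_ratio,
                    "clamped": pr.clamped,
                    "total_rate_ug_n_kg_h": sides["with_c2h2"],
                    "net_rate_ug_n_kg_h": sides["without_c2h2"],
                }
            )
    log.info("field: %d flux estimates, %d product-ratio pairs", len(flux_rows), len(ratio_rows))

    fits: dict[str, dict] = {}
    ph_map = _sample_ph(config.incubation_csv)
    if ph_map:
        ratio_df = pd.DataFrame(ratio_rows)
        ratio_df["ph_h2o"] = ratio_df["sample_id"].map(ph_map)
        with_ph = ratio_df.dropna(subset=["ph_h2o"])
        if len(with_ph) >= 5:
            fits["net_n2o_vs_ph"] = _fit_pair(
                with_ph["ph_h2o"], with_ph["net_rate_ug_n_kg_h"], config.aicc_threshold
            )
            fits["pda_vs_ph"] = _fit_pair(
                with_ph["ph_h2o"],
                with_ph["total_rate_ug_n_kg_h"] * 1e-3,
                config.aicc_threshold,
            )
            fits["product_ratio_vs_ph"] = _fit_pair(
                with_ph["ph_h2o"], with_ph["ratio"], config.aicc_threshold
            )
        ratio_rows = ratio_df.to_dict("records")

    return {
        "provenance": _provenance(config, {"incubation": config.incubation_csv}),
        "counts": {
            "series": len(series),
            "rejected": len(rejects),
            "pairs": len(ratio_rows),
        },
        "rejects": rejects,
        "tables": {
            "fluxes": pd.DataFrame(flux_rows),
            "product_ratios": pd.DataFrame(ratio_rows),
        },
        "fits": fits,
    }


def _sample_ph(path) -> dict[str, float]:
    """Optional per-sample pH from the incubation CSV (column ph_h2o)."""
    df = pd.read_csv(path)
    if "ph_h2o" not in df.columns:
        return {}
    out = {}
    for sid, grp in df.groupby("sample_id"):
        vals = grp["ph_h2o"].dropna().unique()
        if len(vals) == 1:
            stem = str(sid).rsplit("-", 1)[0] if "-" in str(sid) else str(sid)
            out[stem] = float(vals[0])
    return out


def write_run_report(report: dict, out_dir, name: str) -> None:
    """Persist a run report: tables as TSV, fits/counts/provenance as JSON."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if report.get("tables"):
        tables = {k: v for k, v in report["tables"].items() if len(v)}
        if tables:
            study_io.write_report(tables, out / name, format="tsv")
    meta = {
        k: v
        for k, v in report.items()
        if k not in ("tables", "rejects")
    }
    meta["rejects"] = [dataclasses.asdict(r) for r in report.get("rejects", [])]
    (out / f"{name}.json").write_text(json.dumps(meta, indent=1, default=str))
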