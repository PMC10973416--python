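"""Denitrifier functional-gene meta-analysis.

The marker genes nirK and nirS (nitrite reductases, N2O producers) and nosZ
clade I (N2O reductase, the biological N2O sink) are compared through the
abundance ratio (nirK+nirS)/nosZI.  Published abundances are usually
log10-transformed; bin averages are computed on the linear (copies per g)
scale and only then re-logged, which by Jensen's inequality is never smaller
than the mean of the member logs.  pH responses of single genes and of the
ratio are fitted with the shared linear/quadratic AICc machinery; nosZII is
stored but excluded from ratio work (too few records pair it with flux data).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ef_meta import _bin_index
from .model_fitting import FitResult, ModelSelection, fit_polynomial, select_model
from .study_io import GeneObservation

__all__ = [
    "GeneRatioRecord",
    "compute_gene_ratio",
    "ratio_records_from_observations",
    "bin_average_log_abundance",
    "fit_gene_ph",
    "fit_flux_vs_ratio",
    "RATIO_GENES",
]

RATIO_GENES = ("nirK", "nirS", "nosZI")


@dataclass(frozen=True)
class GeneRatioRecord:
    """(nirK+nirS)/nosZI abundance ratio for one sample, linear and log10."""

    study_id: str
    ratio: float
    log10_ratio: float
    ph_h2o: float
    n2o_flux: float | None = None
    sample_id: str | None = None


def compute_gene_ratio(nirK: float, nirS: float, nosZI: float) -> tuple[float, float]:
    """(nirK+nirS)/nosZI and its log10; all three abundances must be > 0."""
    for name, v in (("nirK", nirK), ("nirS", nirS), ("nosZI", nosZI)):
        if v is None or not v > 0:
            raise ValueError(f"{name} abundance must be > 0 (got {v!r})")
    ratio = (nirK + nirS) / nosZI
    return ratio, math.log10(ratio)


def ratio_records_from_observations(
    obs: Iterable[GeneObservation],
) -> tuple[list[GeneRatioRecord], int]:
    """Pair per-sample nirK/nirS/nosZI abundances into ratio records.

    Observations are grouped by (study_id, sample_id, pH); a ratio is formed
    only when all three genes are present for the group.  Returns the records
    and the number of groups skipped for missing genes.  nosZII never enters.
    """
    groups: dict[tuple, dict] = {}
    for o in obs:
        key = (o.study_id, o.sample_id, o.ph_h2o)
        g = groups.setdefault(key, {"flux": o.n2o_flux})
        if o.gene in RATIO_GENES:
            g[o.gene] = o.copies_per_g
        if o.n2o_flux is not None:
            g["flux"] = o.n2o_flux
    records: list[GeneRatioRecord] = []
    skipped = 0
    for (study_id, sample_id, ph), g in groups.items():
        if all(gene in g for gene in RATIO_GENES):
            ratio, log_ratio = compute_gene_ratio(g["nirK"], g["nirS"], g["nosZI"])
            records.append(
                GeneRatioRecord(
                    study_id=study_id,
                    sample_id=sample_id,
                    ratio=ratio,
                    log10_ratio=log_ratio,
                    ph_h2o=ph,
                    n2o_flux=g.get("flux"),
                )
            )
        else:
            skipped += 1
    return records, skipped


def bin_average_log_abundance(
    obs: Iterable[GeneObservation],
    gene: str,
    width: float = 0.1,
    anchor: float = 0.0,
) -> pd.DataFrame:
    """Per-pH-bin mean abundance of one gene, averaged on the linear scale.

    Within each half-open bin [anchor+k*w, anchor+(k+1)*w) the copies-per-g
    values are averaged arithmetically and the mean is then log10-transformed
    (column ``mean_log10``) — the order matters: log of the mean, not mean of
    the logs.  Returns an empty frame if no observations carry the gene.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    groups: dict[int, list[float]] = {}
    for o in obs:
        if o.gene != gene:
            continue
        groups.setdefault(_bin_index(o.ph_h2o, width, anchor), []).append(o.copies_per_g)
    rows = []
    for k in sorted(groups):
        vals = np.asarray(groups[k], dtype=float)
        rows.append(
            {
                "bin_lower": anchor + k * width,
                "bin_center": anchor + (k + 0.5) * width,
                "n": vals.size,
                "mean_copies": float(vals.mean()),
                "mean_log10": float(np.log10(vals.mean())),
            }
        )
    return pd.DataFrame(
        rows, columns=["bin_lower", "bin_center", "n", "mean_copies", "mean_log10"]
    )


def fit_gene_ph(
    x: Sequence[float],
    y: Sequence[float],
    threshold: float = 2.0,
) -> ModelSelection:
    """Linear-vs-quadratic competition for a pH response series.

    ``y`` is typically a log10 abundance or log10 ratio (coarse: one point
    per sample; averaged: one point per pH bin).  Requires at least 5 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points for model competition")
    lin = fit_polynomial(x, y, degree=1)
    quad = fit_polynomial(x, y, degree=2)
    return select_model(lin, quad, threshold=threshold)


def fit_flux_vs_ratio(records: Sequence[GeneRatioRecord]) -> FitResult:
    """Linear fit of N2O flux on log10[(nirK+nirS)/nosZI].

    A positive slope indicates that samples enriched in N2O-producing
    relative to N2O-consuming denitrifiers emit more N2O.  Requires at least
    3 records with paired flux.
    """
    pairs = [(r.log10_ratio, r.n2o_flux) for r in records if r.n2o_flux is not None]
    if len(pairs) < 3:
        raise ValueError("need at least 3 records with paired N2O flux")
    x, y = zip(*pairs)
    return fit_polynomial(x, y, degree=1)
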