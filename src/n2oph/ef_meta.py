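"""Emission factors, pH binning, and replicate-weighted bin means.

The fertilizer-induced N2O emission factor of an observation is

    EF (%) = 100 * (E_N - E_O) / N

with E_N and E_O the cumulative N2O-N emissions (kg N ha^-1) of the
fertilized and control plots and N the fertilization rate (kg N ha^-1).
Because field experiments pile up in popular pH ranges, a regression on raw
("coarse") EFs over-weights those ranges; the averaged analysis therefore
bins observations into 0.1-pH-unit groups and computes one weighted mean per
bin,

    M = sum(Y_i * W_i) / sum(W_i),   W_i = n_i / o,

where n_i is the replicate count of observation i and o the number of
observations in the bin — well-replicated experiments count more within a
bin, while every bin then enters the averaged regression with equal weight.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EFObservation",
    "PhBin",
    "compute_ef",
    "assign_bins",
    "weighted_mean_ef",
    "aggregate_by_n_rate",
    "bin_table",
]


@dataclass
class EFObservation:
    """A derived emission factor with its pH, weight and bin assignment."""

    study_id: str
    ef_percent: float
    ph_h2o: float
    n_rate: float
    replicates: int | None = None
    weight: float | None = None
    bin_id: int | None = None
    negative: bool = False
    weight_imputed: bool = False  # replicates missing -> W_i = 1/o


@dataclass
class PhBin:
    """One half-open pH bin [lower, upper) and its member observations."""

    bin_id: int
    lower: float
    upper: float
    members: list[EFObservation] = field(default_factory=list)

    @property
    def center(self) -> float:
        return self.lower + (self.upper - self.lower) / 2.0

    @property
    def o(self) -> int:
        return len(self.members)

    @property
    def sum_weights(self) -> float:
        return sum(m.weight for m in self.members if m.weight is not None)


def compute_ef(
    emission_fertilized: float, emission_control: float, n_rate: float
) -> float:
    """Fertilizer-induced N2O emission factor, % of applied N.

    ``100 * (E_N - E_O) / N``.  Negative values (the fertilized plot emitted
    less than the control) are legitimate and returned as-is; callers flag
    them.  ``n_rate`` must be > 0 — an unfertilized plot yields no EF.
    """
    if n_rate <= 0:
        raise ValueError("n_rate must be > 0 to define an emission factor")
    ef = 100.0 * (emission_fertilized - emission_control) / n_rate
    if not math.isfinite(ef):
        raise ValueError("emission factor is not finite")
    return ef


def _bin_index(value: float, width: float, anchor: float) -> int:
    # round before floor so values sitting exactly on an edge (5.7 with
    # width 0.1) go to the bin whose lower edge they are
    return int(math.floor(round((value - anchor) / width, 9)))


def assign_bins(
    efs: Iterable[EFObservation], width: float = 0.1, anchor: float = 0.0
) -> list[PhBin]:
    """Assign each observation to a half-open pH bin [anchor+k*w, anchor+(k+1)*w).

    Mutates each observation's ``bin_id`` and returns the non-empty bins in
    ascending pH order.  The number of non-empty bins depends on the data;
    with observations spanning pH 2.8-9.7 at 0.1 resolution there are up to
    70 candidate bins.
    """
    if width <= 0:
        raise ValueError("bin width must be > 0")
    bins: dict[int, PhBin] = {}
    for ef in efs:
        if ef.ph_h2o is None:
            raise ValueError(f"observation {ef.study_id!r} has no harmonized pH")
        k = _bin_index(ef.ph_h2o, width, anchor)
        ef.bin_id = k
        b = bins.get(k)
        if b is None:
            b = PhBin(bin_id=k, lower=anchor + k * width, upper=anchor + (k + 1) * width)
            bins[k] = b
        b.members.append(ef)
    return [bins[k] for k in sorted(bins)]


def weighted_mean_ef(bin: PhBin) -> float:
    """Replicate-weighted mean EF of a bin: M = sum(Y_i W_i)/sum(W_i), W_i = n_i/o.

    An observation with unknown replicate count receives the neutral weight
    W_i = 1/o (flagged via ``weight_imputed``).  Weights are stored on the
    members as a side effect.
    """
    o = bin.o
    if o == 0:
        raise ValueError("bin is empty")
    num = 0.0
    den = 0.0
    for m in bin.members:
        if m.replicates is None:
            m.weight = 1.0 / o
            m.weight_imputed = True
        else:
            m.weight = m.replicates / o
        num += m.ef_percent * m.weight
        den += m.weight
    return num / den


def bin_table(bins: Sequence[PhBin]) -> pd.DataFrame:
    """Summarize bins: edges, center, member count, weights, weighted mean EF."""
    rows = []
    for b in bins:
        m = weighted_mean_ef(b)
        rows.append(
            {
                "bin_id": b.bin_id,
                "bin_lower": b.lower,
                "bin_upper": b.upper,
                "bin_center": b.center,
                "o": b.o,
                "sum_weights": b.sum_weights,
                "weighted_mean_ef": m,
                "n_negative": sum(1 for x in b.members if x.ef_percent < 0),
            }
        )
    return pd.DataFrame(rows)


def aggregate_by_n_rate(
    efs: Iterable[EFObservation], width: float = 100.0, anchor: float = 0.0
) -> pd.DataFrame:
    """Weighted mean EF within N-rate intervals [anchor+k*w, anchor+(k+1)*w).

    Same replicate weighting as :func:`weighted_mean_ef`, applied within
    N-rate intervals instead of pH bins.  Returns one row per non-empty
    interval, ascending.
    """
    if width <= 0:
        raise ValueError("interval width must be > 0")
    groups: dict[int, list[EFObservation]] = {}
    for ef in efs:
        if ef.n_rate <= 0:
            raise ValueError("n_rate must be > 0 for N-rate aggregation")
        groups.setdefault(_bin_index(ef.n_rate, width, anchor), []).append(ef)
    rows = []
    for k in sorted(groups):
        members = groups[k]
        o = len(members)
        w = np.array([(m.replicates if m.replicates is not None else 1.0) / o for m in members])
        y = np.array([m.ef_percent for m in members])
        rows.append(
            {
                "rate_lower": anchor + k * width,
                "rate_upper": anchor + (k + 1) * width,
                "o": o,
                "weighted_mean_ef": float(np.sum(y * w) / np.sum(w)),
            }
        )
    return pd.DataFrame(rows)
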