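"""Synthetic datasets with known ground truth for every pipeline stage.

The generators emulate the structure of compiled global field datasets: a
soil-pH distribution concentrated between 5.5 and 7.5, study-specific
replicate counts, a concave (hump-shaped) true EF-pH response with additive
noise, log-scale gene abundances quadratic in pH with a flat nosZI response,
and linear headspace N2O accumulation.  Every generator is deterministic in
(config, seed) and returns a truth record sufficient to score any downstream
estimate exactly; none of them calls pipeline code, so truth and subject
stay independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .study_io import FieldObservation, GeneObservation, IncubationSeries

__all__ = [
    "SyntheticConfig",
    "generate_field_dataset",
    "generate_gene_dataset",
    "generate_incubation_pairs",
]


def _quad(coeffs: Sequence[float], x):
    """Evaluate c2*x^2 + c1*x + c0 for coeffs given curvature-first."""
    c2, c1, c0 = coeffs
    return c2 * np.asarray(x, dtype=float) ** 2 + c1 * np.asarray(x, dtype=float) + c0


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults encode the study conditions being emulated.

    ``ef_curve`` and the gene curves are (curvature, slope, intercept)
    triples on the scale of the response (EF in %, gene abundance in log10
    copies per g); the default EF curve peaks at pH ~6.0.  The pH mixture is
    three normal components centred at 5.0/6.5/8.0 so that roughly 60% of
    draws land between pH 5.5 and 7.5; draws are truncated to ``ph_range``.
    """

    seed: int = 0
    # field meta-analysis
    n_obs: int = 2000
    n_studies: int = 200
    ph_mixture_means: tuple[float, ...] = (5.0, 6.5, 8.0)
    ph_mixture_sds: tuple[float, ...] = (0.8, 0.6, 0.5)
    ph_mixture_weights: tuple[float, ...] = (0.3, 0.5, 0.2)
    ph_range: tuple[float, float] = (2.8, 9.7)
    ef_curve: tuple[float, float, float] = (-0.1000, 1.198, -2.537)  # % vs pH
    ef_noise_sd: float = 0.5  # % EF
    replicate_choices: tuple[int, ...] = (3, 4, 5, 6)
    n_rate_range: tuple[float, float] = (50.0, 600.0)
    control_lognormal: tuple[float, float] = (0.0, 0.5)  # (mu, sigma) of ln E_O
    # gene meta-analysis
    n_gene_samples: int = 500
    gene_curves: dict = field(
        default_factory=lambda: {
            "nirK": (-0.129, 1.546, 2.782),
            "nirS": (-0.114, 1.429, 2.833),
        }
    )
    nosZI_flat: bool = True
    nosZI_level: float = 6.8  # log10 copies per g
    nosZI_curve: tuple[float, float, float] = (-0.02, 0.24, 6.1)
    gene_noise_sd: float = 0.3  # log10 units
    flux_law: tuple[float, float] = (20.0, 30.0)  # flux = a + b*log10(ratio)
    flux_noise_sd: float = 10.0  # ug N m^-2 h^-1
    # incubations
    ratio_law: tuple[float, float] = (-0.082, 1.265)  # ratio = slope*pH + intercept
    incubation_ph_range: tuple[float, float] = (4.7, 8.0)
    n_incubation_samples: int = 35
    total_rate_curve: tuple[float, float, float] = (-33.4, 446.0, -1304.0)  # ug N kg-1 h-1
    bottle_volume_l: float = 0.1
    soil_dry_mass_kg: float = 0.005
    incubation_temperature_c: float = 25.0
    sampling_times_h: tuple[float, ...] = (2.0, 4.0, 6.0)
    baseline_ppm: float = 0.33
    ppm_noise_sd: float = 0.0  # multiplicative, fraction of signal
    gas_density: float = 1.964  # kg m^-3 N2O at standard state
    n_fraction: float = 28.0 / 44.0

    def validate(self) -> None:
        if self.n_obs < 1 or self.n_studies < 1:
            raise ValueError("n_obs and n_studies must be >= 1")
        if len(self.ph_mixture_means) != len(self.ph_mixture_sds) or len(
            self.ph_mixture_means
        ) != len(self.ph_mixture_weights):
            raise ValueError("pH mixture components must have equal lengths")
        if any(s < 0 for s in self.ph_mixture_sds):
            raise ValueError("mixture sds must be >= 0")
        if not math.isclose(sum(self.ph_mixture_weights), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if self.ef_curve[0] >= 0:
            raise ValueError("ef_curve curvature must be < 0 (hump-shaped truth)")
        if self.ef_noise_sd < 0 or self.gene_noise_sd < 0 or self.ppm_noise_sd < 0:
            raise ValueError("noise sds must be >= 0")
        if not self.ph_range[0] < self.ph_range[1]:
            raise ValueError("ph_range must be increasing")
        lo, hi = self.incubation_ph_range
        for ph in (lo, hi):
            r = self.ratio_law[0] * ph + self.ratio_law[1]
            if not 0.0 <= r <= 1.0:
                raise ValueError(
                    f"ratio law leaves [0, 1] at pH {ph} (ratio {r:.3f})"
                )

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)


def _draw_ph(rng: np.random.Generator, cfg: SyntheticConfig, n: int) -> np.ndarray:
    """Truncated-mixture pH draws (redraw out-of-range values)."""
    means = np.asarray(cfg.ph_mixture_means)
    sds = np.asarray(cfg.ph_mixture_sds)
    weights = np.asarray(cfg.ph_mixture_weights)
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = n - filled
        comp = rng.choice(len(means), size=m, p=weights)
        draw = rng.normal(means[comp], sds[comp])
        ok = (draw >= cfg.ph_range[0]) & (draw <= cfg.ph_range[1])
        k = int(ok.sum())
        out[filled : filled + k] = draw[ok]
        filled += k
    return out


def generate_field_dataset(
    config: SyntheticConfig,
) -> tuple[list[FieldObservation], dict]:
    """Field fertilization observations with a known EF-pH truth.

    Per observation: pH from the truncated mixture, N rate uniform in range,
    true EF from the concave curve plus Gaussian noise, control emission E_O
    lognormal, fertilized emission E_N = E_O + EF_noisy/100 * N (so the EF
    computed downstream recovers curve + noise exactly), replicates uniform
    over the configured choices.  The truth record carries the generating
    curve, its vertex, and the per-observation noise-free and noisy EFs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_obs
    ph = _draw_ph(rng, config, n)
    n_rate = rng.uniform(*config.n_rate_range, size=n)
    true_ef = _quad(config.ef_curve, ph)
    noisy_ef = true_ef + rng.normal(0.0, config.ef_noise_sd, size=n)
    mu, sigma = config.control_lognormal
    e_o = rng.lognormal(mu, sigma, size=n)
    e_n = e_o + noisy_ef / 100.0 * n_rate
    reps = rng.choice(config.replicate_choices, size=n)
    study = rng.integers(0, config.n_studies, size=n)
    # latitude tied loosely to pH component so zone summaries have structure
    lat = rng.uniform(0.0, 60.0, size=n) * rng.choice([-1.0, 1.0], size=n)
    obs = [
        FieldObservation(
            study_id=f"S{study[i]:04d}",
            site_id=f"S{study[i]:04d}-1",
            latitude=float(lat[i]),
            ecosystem=("cropland", "grassland", "forest")[int(rng.integers(0, 3))],
            ph_reported=float(ph[i]),
            ph_medium="H2O",
            n_rate=float(n_rate[i]),
            emission_fertilized=float(e_n[i]),
            emission_control=float(e_o[i]),
            replicates=int(reps[i]),
        )
        for i in range(n)
    ]
    c2, c1, c0 = config.ef_curve
    truth = {
        "ef_curve": config.ef_curve,
        "peak_ph": -c1 / (2 * c2),
        "peak_ef": _quad(config.ef_curve, -c1 / (2 * c2)).item(),
        "true_ef": true_ef,
        "noisy_ef": noisy_ef,
        "ph": ph,
    }
    return obs, truth


def generate_gene_dataset(
    config: SyntheticConfig,
) -> tuple[list[GeneObservation], dict]:
    """Gene-abundance observations (nirK, nirS, nosZI per sample) with truth.

    log10 copies of each gene follow its configured quadratic in pH plus
    Gaussian noise; nosZI is flat at ``nosZI_level`` when ``nosZI_flat``.
    Each sample also receives an N2O flux increasing linearly in the true
    log10[(nirK+nirS)/nosZI] ratio plus noise, attached to every gene row of
    the sample.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_gene_samples
    ph = _draw_ph(rng, config, n)
    log_abund: dict[str, np.ndarray] = {}
    true_log: dict[str, np.ndarray] = {}
    for gene, curve in config.gene_curves.items():
        true_log[gene] = _quad(curve, ph)
        log_abund[gene] = true_log[gene] + rng.normal(0, config.gene_noise_sd, n)
    if config.nosZI_flat:
        true_log["nosZI"] = np.full(n, config.nosZI_level)
    else:
        true_log["nosZI"] = _quad(config.nosZI_curve, ph)
    log_abund["nosZI"] = true_log["nosZI"] + rng.normal(0, config.gene_noise_sd, n)

    true_ratio = (10.0 ** true_log["nirK"] + 10.0 ** true_log["nirS"]) / (
        10.0 ** true_log["nosZI"]
    )
    a, b = config.flux_law
    flux = a + b * np.log10(true_ratio) + rng.normal(0, config.flux_noise_sd, n)

    obs: list[GeneObservation] = []
    for i in range(n):
        for gene in log_abund:
            obs.append(
                GeneObservation(
                    study_id=f"G{i // 5:04d}",
                    sample_id=f"G{i:05d}",
                    gene=gene,
                    copies_per_g=float(10.0 ** log_abund[gene][i]),
                    ph_h2o=float(ph[i]),
                    n2o_flux=float(flux[i]),
                )
            )
    truth = {
        "gene_curves": dict(config.gene_curves),
        "nosZI_flat": config.nosZI_flat,
        "nosZI_level": config.nosZI_level,
        "ph": ph,
        "true_log_abundance": true_log,
        "true_log_ratio": np.log10(true_ratio),
        "flux_law": config.flux_law,
    }
    return obs, truth


def generate_incubation_pairs(
    config: SyntheticConfig,
    ph_values: Sequence[float] | None = None,
    true_total_rates: Sequence[float] | None = None,
) -> tuple[list[IncubationSeries], dict]:
    """Paired with/without-acetylene bottles consistent with a known product ratio.

    For each sample at pH p the acetylene-blocked bottle accumulates N2O at
    the total denitrification rate R(p) (default: the configured concave
    curve, ug N kg^-1 h^-1) and the unblocked bottle at R(p) * ratio(p) with
    ratio(p) from the linear product-ratio law.  Rates are translated to
    headspace ppm slopes by an inline ideal-gas dimensional analysis (kept
    independent of the flux calculator under test); multiplicative Gaussian
    noise perturbs each ppm reading when ``ppm_noise_sd`` > 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if ph_values is None:
        ph = np.linspace(*config.incubation_ph_range, config.n_incubation_samples)
    else:
        ph = np.asarray(ph_values, dtype=float)
    if true_total_rates is None:
        total = _quad(config.total_rate_curve, ph)
    else:
        total = np.asarray(true_total_rates, dtype=float)
        if total.shape != ph.shape:
            raise ValueError("true_total_rates must match ph_values in length")
    if np.any(total <= 0):
        raise ValueError("true total denitrification rates must be > 0")
    s, c = config.ratio_law
    ratio = s * ph + c
    if np.any((ratio < 0) | (ratio > 1)):
        raise ValueError("true product ratio leaves [0, 1] over the pH values")

    # ug N kg^-1 h^-1 produced by a 1 ppm h^-1 headspace slope (ideal gas):
    # rho[kg m^-3] * V[m^3] * 1e-6 * 273/(273+T) * f_N * 1e9 / W[kg]
    conv = (
        config.gas_density
        * (config.bottle_volume_l * 1e-3)
        * 1e-6
        * (273.0 / (273.0 + config.incubation_temperature_c))
        * config.n_fraction
        * 1e9
        / config.soil_dry_mass_kg
    )
    times = np.asarray(config.sampling_times_h)
    series: list[IncubationSeries] = []
    for i, p in enumerate(ph):
        for tag, rate in (("c2h2", total[i]), ("open", total[i] * ratio[i])):
            slope_ppm = rate / conv
            ppm = config.baseline_ppm + slope_ppm * times
            if config.ppm_noise_sd > 0:
                ppm = ppm * (1.0 + rng.normal(0, config.ppm_noise_sd, times.size))
            ppm = np.maximum(ppm, 0.0)
            series.append(
                IncubationSeries(
                    sample_id=f"I{i:04d}-{tag}",
                    soil_dry_mass=config.soil_dry_mass_kg,
                    bottle_volume=config.bottle_volume_l,
                    temperature_c=config.incubation_temperature_c,
                    acetylene=tag == "c2h2",
                    timepoints=[float(t) for t in times],
                    headspace_ppm=[float(v) for v in ppm],
                )
            )
    truth = {
        "ph": ph,
        "total_rate": total,
        "ratio": ratio,
        "ratio_law": config.ratio_law,
        "ppm_per_rate": 1.0 / conv,
    }
    return series, truth
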