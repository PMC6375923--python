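"""Seeded generators for every pipeline stage.

The raw bench data behind the screening and optimization designs are not
deposited, so each stage is exercised on synthetic inputs carrying the
statistical structure that stage assumes:

* screening — a 2^(7-3) fraction with duplicate centre points; the
  response is grand mean + half-effect contrasts + additive Gaussian
  noise, with true effects defaulting to the published screening pattern;
* optimization — an 11-run rotatable central composite (alpha = 1.414,
  three centres) with responses from a true quadratic surface plus noise;
* validation — homoscedastic linear calibration data, day x level
  precision tables with within-run and between-day variance components,
  recovery replicates, and a dilution series with S/N proportional to
  concentration;
* application — peak tables back-computed from the packaged composition
  fixture through the inverse quantification chain, so the zero-noise
  round trip reproduces the fixture exactly.

All generators draw from ``numpy.random.default_rng(seed)``: same seed,
same table, bit for bit.  Noise is Gaussian throughout — the minimal
model consistent with the t/F statistics applied downstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import CCDSpec, DesignTable, build_central_composite, build_fractional_factorial
from .quantification import (
    QUANTIFIED,
    AnalyteSpec,
    SamplePrep,
    fixture_samples,
)
from .rsm import QuadraticModel, predict_surface
from .screening import _contrast_column

#: true screening effects mirroring the published pattern (peak-area units)
DEFAULT_TRUE_EFFECTS = {"TF": {"A": -93.0, "D": 149.0}, "CA": {"A": -20.0, "D": 32.0}}

#: nominal peak areas of the external standards at their reference
#: concentrations (detector counts; only ratios matter downstream)
DEFAULT_STANDARD_AREAS = {"CA": 1360.0, "VX": 1512.0, "RU": 774.0}

#: default preparation: 50 mL flask, 1:2 dilution, 1:30 mass/solvent ratio
DEFAULT_PREP = SamplePrep(sample_mass_g=50.0 / 30.0, final_volume_ml=50.0,
                          dilution_factor=2.0)


def gen_screening_study(
    true_effects: dict[str, float],
    noise_sd: float,
    seed: int,
    grand_mean: float = 500.0,
    n_center_replicates: int = 2,
    response_name: str = "y",
) -> DesignTable:
    """2^(7-3) screening design with a synthetic response.

    y = grand_mean + sum(effect/2 x contrast) + N(0, noise_sd); centre
    rows sit at the grand mean (all contrasts zero there).
    """
    design = build_fractional_factorial(
        n_factors=7, n_generators=3, n_center_replicates=n_center_replicates
    )
    rng = np.random.default_rng(seed)
    y = np.full(design.n_runs, grand_mean)
    for name, effect in true_effects.items():
        y = y + 0.5 * effect * _contrast_column(design, name)
    y = y + rng.normal(0.0, noise_sd, size=design.n_runs)
    design.add_response(response_name, y)
    return design


def gen_ccd_study(
    true_model: QuadraticModel,
    noise_sd: float,
    seed: int,
    spec: CCDSpec | None = None,
    response_name: str = "y",
) -> DesignTable:
    """Central composite design with responses from a true quadratic surface."""
    if spec is None:
        spec = CCDSpec(n_factors=true_model.k, axial_distance=1.414, n_center=3)
    if spec.n_factors != true_model.k:
        raise ValueError("model dimension does not match the design spec")
    design = build_central_composite(spec)
    rng = np.random.default_rng(seed)
    y = predict_surface(true_model, design.coded_matrix)
    y = y + rng.normal(0.0, noise_sd, size=design.n_runs)
    design.add_response(response_name, y)
    return design


def gen_calibration(
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int,
    levels: tuple[float, ...] = (0.16, 0.8, 4.0, 10.0, 25.0, 50.0),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Homoscedastic straight-line calibration points (conc, area)."""
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    conc = np.repeat(levels, n_replicates)
    area = intercept + slope * conc + rng.normal(0.0, noise_sd, size=conc.size)
    return pd.DataFrame(
        {
            "level_id": np.repeat(np.arange(1, len(levels) + 1), n_replicates),
            "conc": conc,
            "area": area,
            "replicate": np.tile(np.arange(1, n_replicates + 1), len(levels)),
        }
    )


def gen_precision(
    level_means: dict[str, float],
    sigma_r: float,
    sigma_day: float,
    seed: int,
    n_days: int = 4,
    n_replicates: int = 6,
) -> pd.DataFrame:
    """day x level x replicate determinations with two variance components.

    determination = level mean + day effect N(0, sigma_day) + residual
    N(0, sigma_r); defaults mirror a four-day, three-level, six-replicate
    protocol.
    """
    if sigma_r < 0 or sigma_day < 0:
        raise ValueError("standard deviations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for day in range(1, n_days + 1):
        day_shift = rng.normal(0.0, sigma_day) if sigma_day > 0 else 0.0
        for level, mu in level_means.items():
            vals = mu + day_shift + rng.normal(0.0, sigma_r, size=n_replicates)
            for rep, v in enumerate(vals, start=1):
                rows.append((day, level, rep, v))
    return pd.DataFrame(rows, columns=["day", "level", "replicate", "determination"])


def gen_recovery(
    true_recovery: float,
    noise_sd: float,
    seed: int,
    levels: tuple[float, ...] = (75.0, 100.0, 125.0),
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Spike-recovery replicates around a true recovery percentage."""
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for lvl in levels:
        vals = true_recovery + rng.normal(0.0, noise_sd, size=n_replicates)
        for rep, v in enumerate(vals, start=1):
            rows.append((lvl, rep, v))
    return pd.DataFrame(rows, columns=["level", "replicate", "recovery_pct"])


def gen_dilution_series(
    base_conc: float,
    base_sn: float,
    seed: int,
    n_dilutions: int = 8,
    rsd_at_base: float = 1.0,
) -> pd.DataFrame:
    """Serial 1:2 dilutions with S/N decaying proportionally to concentration.

    %RSD grows inversely with concentration (noise floor dominates at the
    bottom of the series), emulating measured data around LoD/LoQ.
    """
    rng = np.random.default_rng(seed)
    conc = base_conc / (2.0 ** np.arange(n_dilutions))
    sn = base_sn * conc / base_conc * np.exp(rng.normal(0, 0.05, n_dilutions))
    rsd = rsd_at_base * base_conc / conc * np.exp(rng.normal(0, 0.05, n_dilutions))
    return pd.DataFrame({"conc": conc, "sn": sn, "rsd_pct": rsd})


def gen_validation_data(kind: str, seed: int, **truth) -> pd.DataFrame:
    """Dispatch to the per-kind generator with its truth parameters."""
    kinds = {
        "calibration": gen_calibration,
        "precision": gen_precision,
        "recovery": gen_recovery,
        "dilution_series": gen_dilution_series,
    }
    if kind not in kinds:
        raise ValueError(f"unknown validation data kind {kind!r}")
    return kinds[kind](seed=seed, **truth)


def gen_peak_tables(
    area_noise_cv: float,
    seed: int,
    prep: SamplePrep = DEFAULT_PREP,
    standard_areas: dict[str, float] = DEFAULT_STANDARD_AREAS,
    n_replicates: int = 3,
) -> tuple[pd.DataFrame, dict[int, AnalyteSpec], dict[str, float], SamplePrep]:
    """Back-compute peak tables from the packaged composition fixture.

    Each quantified mass fraction is pushed backwards through the
    quantification chain (ug/g -> ug/mL -> area via its standard) and
    multiplied by lognormal noise of coefficient of variation
    ``area_noise_cv`` per replicate.  At zero noise, quantifying the
    output reproduces the fixture exactly.  Censored cells are omitted
    from the peak table.
    """
    if area_noise_cv < 0:
        raise ValueError("noise cv must be >= 0")
    rng = np.random.default_rng(seed)
    samples, specs = fixture_samples()
    rows = []
    for s in samples:
        for cid, row in s.values.iterrows():
            if row["status"] != QUANTIFIED:
                continue
            spec = specs[cid]
            conc = row["mean"] * prep.sample_mass_g / (
                prep.final_volume_ml * prep.dilution_factor
            )
            area = conc / spec.reference_conc * standard_areas[spec.standard]
            if area_noise_cv > 0:
                sigma = np.sqrt(np.log1p(area_noise_cv ** 2))
                noise = rng.lognormal(-0.5 * sigma ** 2, sigma, size=n_replicates)
            else:
                noise = np.ones(n_replicates)
            for rep in range(n_replicates):
                rows.append((s.sample_id, cid, rep + 1, area * noise[rep]))
    peaks = pd.DataFrame(rows, columns=["sample_id", "compound_id", "replicate", "area"])
    return peaks, specs, dict(standard_areas), prep
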