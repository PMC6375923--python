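"""External-standard HPLC quantification and composition roll-ups.

Peak areas become concentrations via a single-point external standard
(conc = area / area_std x conc_std) or a calibration curve, then mass
fractions of dry leaf material through the sample-preparation chain
(volumetric flask volume, dilution factor, weighed mass).  Compounds whose
content falls below their quantification limit are censored: they
contribute zero to totals and category sums, and a total whose members are
all censored is itself reported as censored.

Totals follow the reporting convention of the reference workflow: TF
(total flavonoids) is the sum of all quantified flavonoid compounds
(flavone C-glycosides as vitexin equivalents, flavonol O-glycosides as
rutin equivalents) and total FL sums the flavonolignans (vitexin
equivalents at 390 nm).  An 8-category roll-up (CA, LG, AG, LMG, AMG, DG,
QG, FL) supports the chemometric analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .validation import CalibrationFit, DetectionLimits

CATEGORIES = ("CA", "LG", "AG", "LMG", "AMG", "DG", "QG", "FL")

#: reference-standard working concentrations, ug/mL
STANDARD_CONCENTRATIONS = {"CA": 20.12, "VX": 20.32, "RU": 18.69}

QUANTIFIED = "quantified"
BELOW_LOQ = "<LOQ"
BELOW_LOD = "<LOD"


@dataclass(frozen=True)
class AnalyteSpec:
    compound_id: int
    name: str
    cls: str                      # phenolic_acid | flavonoid | flavonolignan
    category: str                 # one of CATEGORIES
    standard: str                 # CA | VX | RU
    wavelength_nm: int
    standard_conc: float = 0.0    # ug/mL; 0 -> look up STANDARD_CONCENTRATIONS

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.standard not in STANDARD_CONCENTRATIONS:
            raise ValueError(f"unknown quantification standard {self.standard!r}")

    @property
    def reference_conc(self) -> float:
        return self.standard_conc or STANDARD_CONCENTRATIONS[self.standard]


@dataclass(frozen=True)
class SamplePrep:
    """Extraction bookkeeping: weighed mass, flask volume, dilution."""

    sample_mass_g: float
    final_volume_ml: float = 50.0
    dilution_factor: float = 2.0

    def __post_init__(self) -> None:
        if min(self.sample_mass_g, self.final_volume_ml, self.dilution_factor) <= 0:
            raise ValueError("sample mass, volume and dilution must all be > 0")


@dataclass
class QuantifiedSample:
    """Per-compound mass fractions (ug/g dry leaf) for one sample."""

    sample_id: str
    values: pd.DataFrame  # index compound_id; columns mean, sd, status

    def members(self, specs: dict[int, AnalyteSpec], cls: str) -> pd.DataFrame:
        ids = [i for i, s in specs.items() if s.cls == cls and i in self.values.index]
        return self.values.loc[ids]


def concentration_from_area(
    area,
    standard: AnalyteSpec,
    mode: str = "single_point",
    standard_area: float | None = None,
    curve: CalibrationFit | None = None,
):
    """Peak area -> concentration (ug/mL).

    ``single_point``: proportional to the external standard's area at its
    reference concentration.  ``curve``: invert a fitted calibration line;
    negative back-calculations are floored at zero with a warning.
    """
    area = np.asarray(area, dtype=float)
    if mode == "single_point":
        if standard_area is None or standard_area <= 0:
            raise ValueError("single_point mode needs the standard's peak area > 0")
        conc = area / standard_area * standard.reference_conc
    elif mode == "curve":
        if curve is None:
            raise ValueError("curve mode needs a CalibrationFit")
        conc = curve.invert(area)
    else:
        raise ValueError("mode must be 'single_point' or 'curve'")
    if np.any(conc < 0):
        warnings.warn("negative back-calculated concentration floored at 0",
                      stacklevel=2)
        conc = np.maximum(conc, 0.0)
    return float(conc) if conc.ndim == 0 else conc


def to_mass_fraction(conc, prep: SamplePrep):
    """Concentration (ug/mL) -> mass fraction of dry material (ug/g)."""
    return (
        np.asarray(conc, dtype=float)
        * prep.final_volume_ml
        * prep.dilution_factor
        / prep.sample_mass_g
    )


def quantify_peak_table(
    peaks: pd.DataFrame,
    specs: dict[int, AnalyteSpec],
    standard_areas: dict[str, float],
    prep: SamplePrep,
    limits: dict[int, DetectionLimits] | None = None,
) -> list[QuantifiedSample]:
    """Full chain: areas -> concentrations -> ug/g with censoring.

    ``peaks`` columns: sample_id, compound_id, replicate, area.  Replicates
    are averaged after conversion; censoring compares the mean mass
    fraction against the compound's LoQ/LoD (also on the ug/g scale) when
    ``limits`` are given.
    """
    if (peaks["area"] < 0).any():
        raise ValueError("peak areas must be >= 0")
    out = []
    for sample_id, g in peaks.groupby("sample_id", sort=False):
        rows = {}
        for cid, gg in g.groupby("compound_id"):
            spec = specs.get(int(cid))
            if spec is None:
                raise KeyError(f"no AnalyteSpec for compound {cid}")
            conc = concentration_from_area(
                gg["area"].to_numpy(),
                spec,
                standard_area=standard_areas[spec.standard],
            )
            mf = to_mass_fraction(conc, prep)
            mean = float(np.mean(mf))
            sd = float(np.std(mf, ddof=1)) if len(mf) > 1 else 0.0
            status = QUANTIFIED
            if limits is not None and int(cid) in limits:
                lim = limits[int(cid)]
                if mean < lim.lod:
                    status, mean, sd = BELOW_LOD, np.nan, np.nan
                elif mean < lim.loq:
                    status, mean, sd = BELOW_LOQ, np.nan, np.nan
            rows[int(cid)] = (mean, sd, status)
        df = pd.DataFrame.from_dict(
            rows, orient="index", columns=["mean", "sd", "status"]
        )
        df.index.name = "compound_id"
        out.append(QuantifiedSample(sample_id=str(sample_id), values=df.sort_index()))
    return out


def aggregate_totals(
    sample: QuantifiedSample, specs: dict[int, AnalyteSpec]
) -> pd.Series:
    """TF and total-FL sums over non-censored member compounds.

    A censored compound contributes 0; if every member of a class is
    censored the total itself is reported as NaN (i.e. <LOQ).
    """
    totals = {}
    for label, cls in (("TF", "flavonoid"), ("FL_total", "flavonolignan")):
        part = sample.members(specs, cls)
        quantified = part[part["status"] == QUANTIFIED]
        totals[label] = float(quantified["mean"].sum()) if len(quantified) else np.nan
    return pd.Series(totals, name=sample.sample_id)


def rollup_categories(
    samples: list[QuantifiedSample], specs: dict[int, AnalyteSpec]
) -> pd.DataFrame:
    """Samples x 8 categories matrix of summed quantified mass fractions."""
    rows = {}
    for s in samples:
        unmapped = [i for i in s.values.index if i not in specs]
        if unmapped:
            raise KeyError(f"compounds without category mapping: {unmapped}")
        acc = dict.fromkeys(CATEGORIES, 0.0)
        for cid, row in s.values.iterrows():
            if row["status"] == QUANTIFIED:
                acc[specs[cid].category] += float(row["mean"])
        rows[s.sample_id] = acc
    m = pd.DataFrame.from_dict(rows, orient="index", columns=list(CATEGORIES))
    m.index.name = "sample_id"
    return m


# ---------------------------------------------------------------------------
# Packaged composition fixture (printed reference table)


def _fixture_path():
    return resources.files("phytoquant.data") / "table8_composition.csv"


def load_composition_fixture() -> tuple[pd.DataFrame, dict[int, AnalyteSpec]]:
    """Load the packaged per-compound composition table.

    Returns the raw wide table (cells ``mean/sd`` in ug/g or a censoring
    marker) and the analyte specifications parsed from its metadata
    columns.
    """
    with _fixture_path().open() as fh:
        df = pd.read_csv(fh)
    specs = {
        int(r.compound_id): AnalyteSpec(
            compound_id=int(r.compound_id),
            name=r.compound,
            cls=r.cls,
            category=r.category,
            standard=r.standard,
            wavelength_nm=int(r.wavelength_nm),
        )
        for r in df.itertuples()
    }
    return df, specs


def fixture_samples() -> tuple[list[QuantifiedSample], dict[int, AnalyteSpec]]:
    """Parse the packaged table into QuantifiedSample objects."""
    df, specs = load_composition_fixture()
    meta = {"compound_id", "compound", "cls", "category", "standard", "wavelength_nm"}
    sample_ids = [c for c in df.columns if c not in meta]
    indexed = df.set_index("compound_id")
    samples = []
    for sid in sample_ids:
        rows = {
            int(cid): _parse_cell(str(cell).strip())
            for cid, cell in indexed[sid].items()
        }
        values = pd.DataFrame.from_dict(
            rows, orient="index", columns=["mean", "sd", "status"]
        )
        values.index.name = "compound_id"
        samples.append(QuantifiedSample(sample_id=sid, values=values))
    return samples, specs


def _parse_cell(cell: str) -> tuple[float, float, str]:
    if cell in (BELOW_LOQ, BELOW_LOD):
        return (np.nan, np.nan, cell)
    mean_s, _, sd_s = cell.partition("/")
    sd = float(sd_s) if sd_s else np.nan
    return (float(mean_s), sd, QUANTIFIED)


def fixture_composition_matrix() -> pd.DataFrame:
    """8-category composition matrix of the packaged reference samples."""
    samples, specs = fixture_samples()
    return rollup_categories(samples, specs)
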