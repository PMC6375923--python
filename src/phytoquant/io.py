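"""Shared CSV readers/writers and loaders for the packaged reference tables.

All CSVs are UTF-8, comma-separated with a header row and "." decimal.
Design tables use columns ``run_id``, ``center_flag``, one column per
coded factor, then one column per response.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignTable
from .rsm import QuadraticModel, quadratic_from_coefficients


class InputError(ValueError):
    """Raised for malformed or empty pipeline inputs."""


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise InputError(f"{path}: malformed CSV ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise InputError(f"{path}: empty input table") from exc
    if df.empty:
        raise InputError(f"{path}: empty input table")
    return df


def write_design_table(design: DesignTable, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design_table(path, factor_names: list[str] | None = None) -> DesignTable:
    df = _read_csv(path)
    for col in ("run_id", "center_flag"):
        if col not in df.columns:
            raise InputError(f"{path}: design table missing column {col!r}")
    other = [c for c in df.columns if c not in ("run_id", "center_flag")]
    if factor_names is None:
        # factors are the leading coded columns whose values lie in the
        # coded level alphabet; everything after the first response column
        # is a response
        factor_names = []
        for c in other:
            vals = df[c].to_numpy(float)
            if np.all(np.abs(vals) <= 2.0) and len(np.unique(np.round(vals, 3))) <= 5:
                factor_names.append(c)
            else:
                break
    responses = {c: df[c].to_numpy(float) for c in other if c not in factor_names}
    return DesignTable(
        factor_names=factor_names,
        coded_matrix=df[factor_names].to_numpy(float),
        run_ids=[str(r) for r in df["run_id"]],
        center_point_flags=df["center_flag"].to_numpy(bool),
        responses=responses,
    )


def read_table(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Packaged reference tables (printed values shipped in phytoquant.data)


def _data(name: str) -> pd.DataFrame:
    with (resources.files("phytoquant.data") / name).open() as fh:
        return pd.read_csv(fh)


def load_screening_effects() -> pd.DataFrame:
    """Printed screening effects: one row per contrast, TF/CA/FL columns."""
    return _data("table1_effects.csv").set_index("effect")


def load_surface_models() -> dict[str, QuadraticModel]:
    """Printed quadratic surface coefficients as ready-made models."""
    df = _data("table2_models.csv")
    return {
        r.response: quadratic_from_coefficients(
            ["X1", "X2"], r.b0, [r.b1, r.b2], [r.b11, r.b22], [r.b12]
        )
        for r in df.itertuples()
    }


def load_verification_table() -> pd.DataFrame:
    return _data("table4_verification.csv").set_index("response")


def load_calibration_parameters() -> pd.DataFrame:
    return _data("table5_calibration.csv").set_index("analyte")


def load_precision_table() -> pd.DataFrame:
    return _data("table6_precision.csv").set_index("analyte")


def load_recovery_table() -> pd.DataFrame:
    return _data("table7_recovery.csv").set_index("analyte")


def recovery_long_table() -> pd.DataFrame:
    """Recovery fixture reshaped to (analyte, level, recovery_pct) rows."""
    df = load_recovery_table().reset_index()
    long = df.melt(
        id_vars="analyte",
        value_vars=["level_75", "level_100", "level_125"],
        var_name="level",
        value_name="recovery_pct",
    )
    long["level"] = long["level"].str.removeprefix("level_").astype(int)
    return long


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
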