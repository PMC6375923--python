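"""Effect estimation and significance screening for unreplicated two-level designs.

An effect E_x is the difference between the mean response at the high and
low coded levels of a contrast column.  Because a saturated fraction leaves
no residual degrees of freedom, significance is judged against a critical
effect derived from the small effects themselves (Dong-style pseudo
standard error): the retained "null" effects give a robust estimate of the
effect standard error (SE)_e, and E_critical = t(1-alpha, one-sided) x (SE)_e.
Effects with |E_x| > E_critical are declared active.

Two retention rules are provided:

``lowest75``
    keep the floor(0.75 m) smallest |E_x| of the m effects and take their
    root-mean-square as (SE)_e.
``dong_classic``
    initial scale s0 = 1.5 x median|E_x|; keep effects with |E_x| <= 2.5 s0;
    (SE)_e is the RMS of the kept effects.

Both rules use a one-sided t quantile with dof equal to the total number of
effects m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable

VARIANTS = ("lowest75", "dong_classic")


@dataclass
class EffectTable:
    """Estimated effects, one per estimable contrast, in response units."""

    effect_names: list[str]
    effects: np.ndarray
    response_name: str = ""

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (len(self.effect_names),):
            raise ValueError("one effect value per effect name required")

    def to_series(self) -> pd.Series:
        return pd.Series(self.effects, index=self.effect_names, name=self.response_name)


@dataclass
class DongResult:
    s0: float
    se_effect: float
    critical_effect: float
    retained_effects: list[str]
    variant: str
    alpha: float
    dof: int


@dataclass
class ScreeningReport:
    """Per-effect significance verdicts, sorted by |effect| descending."""

    table: pd.DataFrame
    dong: DongResult

    @property
    def significant(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "effect"])


def _contrast_column(design: DesignTable, name: str) -> np.ndarray:
    """Coded column for a main effect 'A' or interaction 'A×B' / 'A*B' / 'AB'."""
    raw = name.replace("×", "*").replace(" ", "")
    if "*" in raw:
        parts = raw.split("*")
    elif raw in design.factor_names:
        parts = [raw]
    else:
        parts = list(raw)  # e.g. "AB" with single-letter factors
    cols = [design.column(p) for p in parts]
    return np.prod(cols, axis=0)


def estimate_effects(
    design: DesignTable,
    response_name: str,
    contrasts: list[str] | None = None,
) -> EffectTable:
    """Estimate E_x = mean(y | contrast=+1) - mean(y | contrast=-1).

    Centre points are excluded: the contrasts are evaluated over the
    factorial portion only.  ``contrasts`` defaults to all main effects.
    Requesting two contrasts that are aliased in the fraction raises an
    error naming the alias chain.
    """
    if response_name not in design.responses:
        raise KeyError(f"design has no response {response_name!r}")
    if contrasts is None:
        contrasts = list(design.factor_names)
    mask = design.factorial_mask
    y = design.responses[response_name][mask]

    seen: dict[bytes, str] = {}
    effects = np.empty(len(contrasts))
    for i, name in enumerate(contrasts):
        col = _contrast_column(design, name)[mask]
        if not np.all(np.isin(col, (-1.0, 1.0))):
            raise ValueError(f"contrast {name!r} is not a +/-1 column")
        key = col.tobytes()
        negkey = (-col).tobytes()
        clash = seen.get(key) or seen.get(negkey)
        if clash is not None:
            chain = ""
            if design.alias_structure:
                chain = f" (alias chain: {design.alias_structure.get(clash, [])})"
            raise ValueError(
                f"contrast {name!r} is aliased with {clash!r} in this fraction{chain}"
            )
        seen[key] = name
        effects[i] = y[col > 0].mean() - y[col < 0].mean()
    return EffectTable(list(contrasts), effects, response_name)


def dong_critical(
    effects: EffectTable,
    alpha: float = 0.05,
    variant: str = "lowest75",
    dof: int | None = None,
) -> DongResult:
    """Critical effect from the pseudo standard error of the small effects."""
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    e = np.abs(effects.effects)
    m = e.size
    if m < 4:
        raise ValueError("need at least 4 effects to estimate a pseudo error")
    if dof is None:
        dof = m
    names = np.asarray(effects.effect_names)

    if np.all(e == 0):
        warnings.warn("all effects are zero; degenerate E_critical = 0", stacklevel=2)
        return DongResult(0.0, 0.0, 0.0, list(names), variant, alpha, dof)

    if variant == "lowest75":
        k = int(np.floor(0.75 * m))
        order = np.argsort(e, kind="stable")
        keep = order[:k]
        s0 = float(np.sqrt(np.mean(e[keep] ** 2)))
        se = s0
    else:  # dong_classic
        s0 = float(1.5 * np.median(e))
        keep = np.flatnonzero(e <= 2.5 * s0)
        if keep.size == 0:  # pathological: median 0 but some huge effects
            keep = np.argsort(e, kind="stable")[: max(1, m // 2)]
        se = float(np.sqrt(np.mean(e[keep] ** 2)))

    t = float(stats.t.ppf(1 - alpha, dof))
    return DongResult(
        s0=s0,
        se_effect=se,
        critical_effect=t * se,
        retained_effects=list(names[np.sort(np.asarray(keep))]),
        variant=variant,
        alpha=alpha,
        dof=dof,
    )


def classify_effects(effects: EffectTable, dong: DongResult) -> ScreeningReport:
    """Flag |E_x| > E_critical; report sorted by |E_x| descending."""
    df = pd.DataFrame(
        {
            "effect": effects.effect_names,
            "estimate": effects.effects,
            "abs_estimate": np.abs(effects.effects),
            "e_critical": dong.critical_effect,
            "significant": np.abs(effects.effects) > dong.critical_effect,
        }
    )
    df = df.sort_values("abs_estimate", ascending=False, kind="stable").reset_index(
        drop=True
    )
    return ScreeningReport(table=df, dong=dong)


def screen(
    design: DesignTable,
    response_name: str,
    contrasts: list[str] | None = None,
    alpha: float = 0.05,
    variant: str = "lowest75",
) -> ScreeningReport:
    """estimate_effects -> dong_critical -> classify_effects in one call."""
    eff = estimate_effects(design, response_name, contrasts)
    dong = dong_critical(eff, alpha=alpha, variant=variant)
    return classify_effects(eff, dong)
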