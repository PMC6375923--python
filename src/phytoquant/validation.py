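"""Analytical method-validation statistics (ICH-style).

Covers the computational side of a chromatographic method validation:

* linearity — OLS calibration with r^2, intercept/slope t tests and CIs,
  per-level residual %RSD, and Mandel's fitting test (first- vs
  second-order calibration function);
* precision — repeatability and intermediate precision from a balanced
  day x level x replicate table, variance homogeneity by Cochran's C, and
  Horwitz acceptability limits RSD_R = 2^(1 - 0.5 log10 C) with the
  repeatability limit at 2/3 of it;
* accuracy — recovery means, %RSD and 95% CI with the three pass criteria
  (CI contains 100%, mean within 98-102%, %RSD at or below a reference);
* detection limits — LoD = 3.3 sigma/slope and LoQ = 10 sigma/slope from
  the calibration curve, or empirical S/N and %RSD thresholds on a
  dilution series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Linearity


@dataclass
class CalibrationFit:
    slope: float
    intercept: float
    r_squared: float
    intercept_se: float
    slope_se: float
    intercept_ci: tuple[float, float]
    slope_ci: tuple[float, float]
    intercept_p: float
    slope_p: float
    n_points: int
    level_rsd: pd.Series | None = None  # per-level %RSD of replicate responses
    residuals: np.ndarray | None = None

    @property
    def intercept_includes_zero(self) -> bool:
        lo, hi = self.intercept_ci
        return lo <= 0.0 <= hi

    def predict(self, conc):
        return self.intercept + self.slope * np.asarray(conc, float)

    def invert(self, area):
        return (np.asarray(area, float) - self.intercept) / self.slope


@dataclass
class MandelResult:
    s_lin: float
    s_quad: float
    ds2: float
    f_statistic: float
    f_critical: float
    alpha: float
    n_points: int
    decision: str  # "linear" | "quadratic"


@dataclass
class PrecisionResult:
    grand_mean: float
    per_day_rsd: pd.Series
    per_level_rsd: pd.Series
    rsd_r: float          # overall repeatability %RSD (pooled within-cell)
    rsd_R: float          # intermediate precision %RSD
    s_r2: float
    s_between2: float


@dataclass
class HorwitzLimits:
    c: float
    rsd_R_max: float
    rsd_r_max: float


@dataclass
class CochranResult:
    c_statistic: float
    n_groups: int
    n_per_group: int
    c_critical: float
    alpha: float
    homogeneous: bool


@dataclass
class RecoveryResult:
    per_level: pd.Series      # mean recovery % per spike level
    mean_recovery: float
    rsd_pct: float
    ci95: tuple[float, float]
    ci_contains_100: bool
    mean_in_98_102: bool
    rsd_within_reference: bool | None = None


@dataclass
class DetectionLimits:
    lod: float
    loq: float
    method: str  # "calibration" | "empirical"
    inputs: dict = field(default_factory=dict)


def _as_calibration_frame(points) -> pd.DataFrame:
    df = pd.DataFrame(points)
    if not {"conc", "area"} <= set(df.columns):
        df.columns = ["conc", "area"][: df.shape[1]] + list(df.columns[2:])
    return df


def fit_calibration(points, alpha: float = 0.05, min_levels: int = 5) -> CalibrationFit:
    """OLS straight-line calibration y(area) = a + b * concentration.

    ``points`` is a DataFrame (or records) with columns ``conc`` and
    ``area`` (replicates as repeated rows).  Two-sided t tests against
    zero use N-2 dof.  Per-level %RSD of replicate areas is reported for
    the 5 % homoscedasticity screen when replicates are present.
    """
    df = _as_calibration_frame(points)
    levels = df["conc"].nunique()
    if levels < min_levels:
        raise ValueError(f"need at least {min_levels} concentration levels, got {levels}")
    x = df["conc"].to_numpy(float)
    y = df["area"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in concentration")
    n = len(x)
    res = stats.linregress(x, y)
    dof = n - 2
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    fitted = res.intercept + res.slope * x
    resid = y - fitted
    intercept_p = 2 * stats.t.sf(abs(res.intercept / res.intercept_stderr), dof) \
        if res.intercept_stderr > 0 else (0.0 if res.intercept != 0 else 1.0)
    level_rsd = None
    counts = df.groupby("conc")["area"].count()
    if (counts > 1).any():
        g = df.groupby("conc")["area"]
        level_rsd = (g.std(ddof=1) / g.mean() * 100).rename("rsd_pct")
    return CalibrationFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        intercept_se=float(res.intercept_stderr),
        slope_se=float(res.stderr),
        intercept_ci=(
            float(res.intercept - tcrit * res.intercept_stderr),
            float(res.intercept + tcrit * res.intercept_stderr),
        ),
        slope_ci=(
            float(res.slope - tcrit * res.stderr),
            float(res.slope + tcrit * res.stderr),
        ),
        intercept_p=float(intercept_p),
        slope_p=float(res.pvalue),
        n_points=n,
        level_rsd=level_rsd,
        residuals=resid,
    )


def mandel_test(points, alpha: float = 0.01) -> MandelResult:
    """Mandel's fitting test: does a second-order term significantly help?

    DS^2 = (N-2) s_lin^2 - (N-3) s_quad^2 (= RSS_1 - RSS_2) is compared as
    F = DS^2 / s_quad^2 against F(1-alpha; 1, N-3).  A non-significant F
    justifies the first-order calibration function.
    """
    df = _as_calibration_frame(points)
    x = df["conc"].to_numpy(float)
    y = df["area"].to_numpy(float)
    n = len(x)
    if df["conc"].nunique() < 5 or n < 4:
        raise ValueError("Mandel's test needs >= 5 levels and N >= 4 points")
    rss1 = float(np.sum((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2))
    rss2 = float(np.sum((y - np.polyval(np.polyfit(x, y, 2), x)) ** 2))
    # exact fits leave only rounding residue; treat those as zero
    tiny = 1e-20 * max(float(np.sum((y - y.mean()) ** 2)), 1.0)
    rss1 = 0.0 if rss1 <= tiny else rss1
    rss2 = 0.0 if rss2 <= tiny else rss2
    s_lin = np.sqrt(rss1 / (n - 2))
    s_quad = np.sqrt(rss2 / (n - 3))
    ds2 = rss1 - rss2
    f_crit = float(stats.f.ppf(1 - alpha, 1, n - 3))
    if rss1 == 0.0:
        return MandelResult(0.0, 0.0, 0.0, 0.0, f_crit, alpha, n, "linear")
    if rss2 == 0.0:
        return MandelResult(s_lin, 0.0, ds2, np.inf, f_crit, alpha, n, "quadratic")
    f = ds2 / s_quad ** 2
    decision = "quadratic" if f > f_crit else "linear"
    return MandelResult(float(s_lin), float(s_quad), float(ds2), float(f),
                        f_crit, alpha, n, decision)


# ---------------------------------------------------------------------------
# Precision


def cochran_c(group_variances, n_per_group: int, alpha: float = 0.05) -> CochranResult:
    """Cochran's C = s^2_max / sum(s^2_j) for balanced groups.

    The upper critical value uses the exact F-based closed form
    C_crit = [1 + (k-1)/F(alpha/k; n-1, (k-1)(n-1))]^-1.
    """
    v = np.asarray(group_variances, dtype=float)
    k = v.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.any(v < 0):
        raise ValueError("variances must be >= 0")
    n = n_per_group
    fcrit = stats.f.isf(alpha / k, n - 1, (k - 1) * (n - 1))
    c_crit = 1.0 / (1.0 + (k - 1) / fcrit)
    total = v.sum()
    if total == 0:
        return CochranResult(1.0 / k, k, n, float(c_crit), alpha, True)
    c = float(v.max() / total)
    return CochranResult(c, k, n, float(c_crit), alpha, c <= c_crit)


def precision_summary(table, value_col: str = "determination") -> PrecisionResult:
    """Repeatability and intermediate precision from day x level x replicate data.

    ``table`` needs columns ``day``, ``level``, ``replicate`` and the value
    column.  Repeatability s_r^2 pools the within-cell variances (a cell is
    one day x level combination); intermediate precision adds a
    between-cell component from a one-way random-effects decomposition over
    the day/level cells: s_R^2 = s_r^2 + max(0, (MS_between - MS_within)/n).
    Both are expressed as %RSD on the grand mean.
    """
    df = pd.DataFrame(table)
    for col in ("day", "level", value_col):
        if col not in df.columns:
            raise ValueError(f"precision table missing column {col!r}")
    cells = df.groupby(["day", "level"])[value_col]
    sizes = cells.size()
    if (sizes < 2).any():
        raise ValueError("repeatability undefined: a cell has fewer than 2 replicates")
    n = int(sizes.iloc[0])
    cell_var = cells.var(ddof=1)
    cell_mean = cells.mean()
    grand = df[value_col].mean()
    # balanced pooling; with unbalanced cells, weight by dof
    dofs = sizes - 1
    s_r2 = float((cell_var * dofs).sum() / dofs.sum())
    ms_within = s_r2
    ms_between = float(n * cell_mean.var(ddof=1)) if len(cell_mean) > 1 else 0.0
    s_between2 = max(0.0, (ms_between - ms_within) / n)
    s_R2 = s_r2 + s_between2
    per_day = df.groupby("day")[value_col].agg(
        lambda v: v.std(ddof=1) / v.mean() * 100
    )
    per_level = df.groupby("level")[value_col].agg(
        lambda v: v.std(ddof=1) / v.mean() * 100
    )
    return PrecisionResult(
        grand_mean=float(grand),
        per_day_rsd=per_day.rename("rsd_pct"),
        per_level_rsd=per_level.rename("rsd_pct"),
        rsd_r=float(np.sqrt(s_r2) / grand * 100),
        rsd_R=float(np.sqrt(s_R2) / grand * 100),
        s_r2=s_r2,
        s_between2=float(s_between2),
    )


def horwitz_limits(c: float) -> HorwitzLimits:
    """Horwitz acceptability limits at dimensionless mass fraction ``c``."""
    if c <= 0:
        raise ValueError("mass fraction C must be > 0")
    rsd_R = 2.0 ** (1.0 - 0.5 * np.log10(c))
    return HorwitzLimits(c=c, rsd_R_max=float(rsd_R), rsd_r_max=float(rsd_R * 2 / 3))


def rsd_r_from_rsd_R(rsd_R: float) -> float:
    """Repeatability limit as two-thirds of the reproducibility limit."""
    return rsd_R * 2.0 / 3.0


# ---------------------------------------------------------------------------
# Accuracy


def recovery_stats(
    recoveries,
    rsd_r_reference: float | None = None,
    alpha: float = 0.05,
) -> RecoveryResult:
    """Recovery summary over spike levels.

    ``recoveries`` is a DataFrame with columns ``level`` and
    ``recovery_pct`` — either one mean per level or raw replicates.  The
    headline mean is the unweighted mean of the per-level means; %RSD and
    the t-based 95 % CI use the raw replicates when present, otherwise the
    level means.
    """
    df = pd.DataFrame(recoveries)
    if "recovery_pct" not in df.columns:
        raise ValueError("recovery table needs a 'recovery_pct' column")
    if "level" not in df.columns:
        df["level"] = np.arange(len(df))
    if (df["recovery_pct"] <= 0).any():
        raise ValueError("recoveries must be positive percentages")
    per_level = df.groupby("level")["recovery_pct"].mean()
    if len(per_level) < 2:
        raise ValueError("need at least 2 spike levels")
    mean = float(per_level.mean())
    replicated = len(df) > len(per_level)
    basis = df["recovery_pct"].to_numpy(float) if replicated \
        else per_level.to_numpy(float)
    sd = float(np.std(basis, ddof=1))
    nb = len(basis)
    rsd = sd / float(np.mean(basis)) * 100
    tcrit = stats.t.ppf(1 - alpha / 2, nb - 1)
    half = tcrit * sd / np.sqrt(nb)
    center = float(np.mean(basis))
    ci = (center - half, center + half)
    return RecoveryResult(
        per_level=per_level,
        mean_recovery=mean,
        rsd_pct=float(rsd),
        ci95=ci,
        ci_contains_100=ci[0] <= 100.0 <= ci[1],
        mean_in_98_102=98.0 <= mean <= 102.0,
        rsd_within_reference=(rsd <= rsd_r_reference)
        if rsd_r_reference is not None
        else None,
    )


# ---------------------------------------------------------------------------
# Detection / quantification limits


def detection_limits_from_calibration(
    fit: CalibrationFit, sigma: float | None = None
) -> DetectionLimits:
    """LoD = 3.3 sigma / slope, LoQ = 10 sigma / slope.

    ``sigma`` defaults to the standard error of the calibration intercept
    (the experimental-error proxy); units follow the concentration axis.
    """
    if fit.slope <= 0:
        raise ValueError("calibration slope must be positive")
    s = fit.intercept_se if sigma is None else sigma
    return DetectionLimits(
        lod=3.3 * s / fit.slope,
        loq=10.0 * s / fit.slope,
        method="calibration",
        inputs={"sigma": s, "slope": fit.slope},
    )


def detection_limits_empirical(
    series,
    sn_threshold: float = 3.0,
    rsd_threshold: float = 5.0,
) -> DetectionLimits:
    """LoD/LoQ from a measured dilution series.

    ``series`` has columns ``conc``, ``sn`` (signal-to-noise) and
    ``rsd_pct``; LoD is the lowest concentration whose S/N clears
    ``sn_threshold`` and LoQ the lowest whose %RSD is at most
    ``rsd_threshold``.
    """
    df = pd.DataFrame(series).sort_values("conc")
    det = df[df["sn"] >= sn_threshold]
    quant = df[df["rsd_pct"] <= rsd_threshold]
    if det.empty or quant.empty:
        raise ValueError("no concentration in the series meets the thresholds")
    return DetectionLimits(
        lod=float(det["conc"].iloc[0]),
        loq=float(quant["conc"].iloc[0]),
        method="empirical",
        inputs={"sn_threshold": sn_threshold, "rsd_threshold": rsd_threshold},
    )
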