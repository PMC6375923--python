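"""Headless pipeline runner: synthetic inputs -> every stage -> reports.

The config is a flat mapping (unknown keys are rejected):

seed            int, master seed for all generators (default 0)
stages          list of stage names to run, default all, in dependency
                order: screening, optimization, validation, quantification,
                multivariate
noise           mapping with per-stage noise levels (screening_sd, ccd_sd,
                calibration_sd, sigma_r, sigma_day, recovery_sd, area_cv)
alpha           significance level for screening/validation tests (0.05)
dong_variant    'lowest75' (default) or 'dong_classic'
optimizer       mapping: mode (desirability|single), region (square|disk),
                radius
pca_scaling     'unit-variance' (default) or 'none'

Each stage writes machine-readable CSVs under ``out_dir`` and contributes
lines to a flat key = value summary (report.txt), with statistics at two
decimals.  Same config + seed -> byte-identical outputs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import multivariate as mv
from . import quantification as qt
from . import rsm
from . import screening as scr
from . import synthetic as syn
from . import validation as val

STAGES = ("screening", "optimization", "validation", "quantification", "multivariate")

_KNOWN_KEYS = {
    "seed", "stages", "noise", "alpha", "dong_variant", "optimizer", "pca_scaling",
}
_KNOWN_NOISE = {
    "screening_sd", "ccd_sd", "calibration_sd", "sigma_r", "sigma_day",
    "recovery_sd", "area_cv",
}


def run_pipeline(config: dict, out_dir) -> str:
    """Execute the requested stages; returns the human-readable summary."""
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    noise = dict(config.get("noise") or {})
    unknown = set(noise) - _KNOWN_NOISE
    if unknown:
        raise KeyError(f"unknown noise keys: {sorted(unknown)}")

    seed = int(config.get("seed", 0))
    stages = config.get("stages") or list(STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise KeyError(f"unknown stages: {bad}")
    alpha = float(config.get("alpha", 0.05))
    variant = config.get("dong_variant", "lowest75")
    opt = {"mode": "desirability", "region": "square", "radius": 1.414}
    opt.update(config.get("optimizer") or {})
    scaling = config.get("pca_scaling", "unit-variance")

    out = pio.ensure_dir(out_dir)
    lines: list[str] = [f"seed = {seed}", f"stages = {','.join(stages)}"]

    if "screening" in stages:
        d = syn.gen_screening_study(
            syn.DEFAULT_TRUE_EFFECTS["TF"],
            noise_sd=float(noise.get("screening_sd", 20.0)),
            seed=seed,
            response_name="TF",
        )
        pio.write_design_table(d, out / "screening_design.csv")
        contrasts = list("ABCDEFG") + ["A*B", "A*C", "A*D", "A*E", "A*F", "A*G", "B*D"]
        report = scr.screen(d, "TF", contrasts=contrasts, alpha=alpha, variant=variant)
        report.table.to_csv(out / "screening_report.csv", index=False)
        lines += [
            f"screening.e_critical = {report.dong.critical_effect:.2f}",
            f"screening.significant = {','.join(report.significant)}",
        ]

    if "optimization" in stages:
        models = pio.load_surface_models()
        d = syn.gen_ccd_study(
            models["TF"], noise_sd=float(noise.get("ccd_sd", 0.0)),
            seed=seed + 1, response_name="TF",
        )
        rng = np.random.default_rng(seed + 2)
        for name in ("CA", "FL"):
            d.add_response(
                name,
                rsm.predict_surface(models[name], d.coded_matrix)
                + rng.normal(0, float(noise.get("ccd_sd", 0.0)), d.n_runs),
            )
        pio.write_design_table(d, out / "ccd_design.csv")
        fits = {n: rsm.fit_quadratic(d, n) for n in ("TF", "CA", "FL")}
        pd.concat(
            {n: m.summary_frame().set_index("term") for n, m in fits.items()}, axis=1
        ).to_csv(out / "ccd_fits.csv")
        result = rsm.optimize_response(
            list(fits.values()), mode=opt["mode"], region=opt["region"],
            radius=float(opt["radius"]), response_names=list(fits),
        )
        lines += [
            "optimization.coded_optimum = "
            + ",".join(f"{v:.3f}" for v in result.coded_optimum),
        ] + [
            f"optimization.predicted.{n} = {v:.2f}"
            for n, v in result.predicted.items()
        ]

    if "validation" in stages:
        cal = syn.gen_calibration(
            slope=67.6, intercept=0.0,
            noise_sd=float(noise.get("calibration_sd", 5.0)), seed=seed + 3,
        )
        cal.to_csv(out / "calibration.csv", index=False)
        fit = val.fit_calibration(cal, alpha=alpha)
        mandel = val.mandel_test(cal)
        limits = val.detection_limits_from_calibration(fit)
        # determinations as % of nominal content: levels share a mean
        prec = syn.gen_precision(
            {"50": 100.0, "100": 100.0, "150": 100.0},
            sigma_r=float(noise.get("sigma_r", 1.0)),
            sigma_day=float(noise.get("sigma_day", 0.5)),
            seed=seed + 4,
        )
        prec.to_csv(out / "precision.csv", index=False)
        psum = val.precision_summary(prec)
        cells = prec.groupby(["day", "level"])["determination"]
        coch = val.cochran_c(cells.var(ddof=1).to_numpy(), int(cells.size().iloc[0]))
        rec = syn.gen_recovery(
            100.0, float(noise.get("recovery_sd", 0.5)), seed=seed + 5)
        rec.to_csv(out / "recovery.csv", index=False)
        rstats = val.recovery_stats(rec)
        lines += [
            f"validation.slope = {fit.slope:.2f}",
            f"validation.r2 = {fit.r_squared:.4f}",
            f"validation.mandel_decision = {mandel.decision}",
            f"validation.lod = {limits.lod:.4f}",
            f"validation.loq = {limits.loq:.4f}",
            f"validation.rsd_r = {psum.rsd_r:.2f}",
            f"validation.rsd_R = {psum.rsd_R:.2f}",
            f"validation.cochran_homogeneous = {coch.homogeneous}",
            f"validation.mean_recovery = {rstats.mean_recovery:.2f}",
        ]

    quantified = None
    if "quantification" in stages:
        peaks, specs, std_areas, prep = syn.gen_peak_tables(
            area_noise_cv=float(noise.get("area_cv", 0.0)), seed=seed + 6)
        peaks.to_csv(out / "peak_table.csv", index=False)
        quantified = qt.quantify_peak_table(peaks, specs, std_areas, prep)
        totals = pd.DataFrame([qt.aggregate_totals(s, specs) for s in quantified])
        totals.to_csv(out / "totals.csv")
        lines += [
            f"quantification.samples = {len(quantified)}",
            f"quantification.tf_max = {totals['TF'].max():.1f}",
        ]

    if "multivariate" in stages:
        if quantified is not None:
            _, specs = qt.load_composition_fixture()
            matrix = qt.rollup_categories(quantified, specs)
        else:
            matrix = qt.fixture_composition_matrix()
        matrix.to_csv(out / "composition.csv")
        corr = mv.correlation_matrix(matrix)
        corr.to_csv(out / "correlation.csv")
        res = mv.pca(matrix, scaling=scaling)
        res.scores.to_csv(out / "scores.csv")
        res.loadings.to_csv(out / "loadings.csv")
        pd.Series(
            res.explained_variance_ratio, name="explained_variance"
        ).to_csv(out / "explained_variance.csv", index_label="component")
        lines.append(
            f"multivariate.cum_pc1_3 = {res.cumulative_variance(3) * 100:.1f}"
        )

    summary = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(summary)
    return summary
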