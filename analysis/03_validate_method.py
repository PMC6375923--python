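#!/usr/bin/env python
"""Method-validation statistics: linearity, precision, accuracy, limits.

Runs the ICH-style battery on (a) the published summary tables shipped
with the package and (b) synthetic raw data generated under the study
conditions (six-level calibration in triplicate, four days x three
levels x six replicates, three spike levels in triplicate), confirming
that each statistic recovers its planted truth.

Outputs under results/validation/.
"""

import sys
from pathlib import Path

import pandas as pd

from phytoquant import io as pio
from phytoquant.synthetic import gen_calibration, gen_precision, gen_recovery
from phytoquant.validation import (
    cochran_c,
    detection_limits_from_calibration,
    fit_calibration,
    horwitz_limits,
    mandel_test,
    precision_summary,
    recovery_stats,
    rsd_r_from_rsd_R,
)

OUT = pio.ensure_dir(Path(__file__).resolve().parents[1] / "results" / "validation")


def main(seed: int = 0) -> None:
    # --- linearity on synthetic calibration data (slope from the CA curve)
    cal = gen_calibration(slope=67.6, intercept=-15.2, noise_sd=5.0, seed=seed)
    fit = fit_calibration(cal)
    mandel = mandel_test(cal, alpha=0.01)
    limits = detection_limits_from_calibration(fit)
    print("Linearity (synthetic CA-like curve, 6 levels x 3):")
    print(f"  y = {fit.slope:.1f}x {fit.intercept:+.1f}, r^2 = {fit.r_squared:.4f}")
    print(f"  95% CI of intercept: ({fit.intercept_ci[0]:.2f}, "
          f"{fit.intercept_ci[1]:.2f}); includes zero: {fit.intercept_includes_zero}")
    print(f"  Mandel: F = {mandel.f_statistic:.2f} vs critical "
          f"{mandel.f_critical:.2f} -> {mandel.decision}")
    print(f"  LoD = {limits.lod * 1000:.0f} ng/mL, LoQ = {limits.loq * 1000:.0f} ng/mL")
    pd.DataFrame([{
        "slope": fit.slope, "intercept": fit.intercept, "r2": fit.r_squared,
        "ci_low": fit.intercept_ci[0], "ci_high": fit.intercept_ci[1],
        "mandel_F": mandel.f_statistic, "mandel_decision": mandel.decision,
        "lod_ug_ml": limits.lod, "loq_ug_ml": limits.loq,
    }]).round(4).to_csv(OUT / "linearity.csv", index=False)

    # --- precision on synthetic day x level determinations; determinations
    # are expressed as % of nominal content so the three levels share a
    # common mean and the day/level pooling is meaningful
    prec = gen_precision({"50": 100.0, "100": 100.0, "150": 100.0},
                         sigma_r=1.0, sigma_day=0.75, seed=seed + 1)
    res = precision_summary(prec)
    cells = prec.groupby(["day", "level"])["determination"]
    coch = cochran_c(cells.var(ddof=1).to_numpy(), int(cells.size().iloc[0]))
    print("\nPrecision (4 days x 3 levels x 6 replicates, synthetic):")
    print(f"  repeatability RSD_r = {res.rsd_r:.2f}%, "
          f"intermediate RSD_R = {res.rsd_R:.2f}%")
    print(f"  Cochran C = {coch.c_statistic:.3f} vs critical "
          f"{coch.c_critical:.3f} -> homogeneous: {coch.homogeneous}")
    pd.DataFrame([{
        "grand_mean": res.grand_mean, "rsd_r": res.rsd_r, "rsd_R": res.rsd_R,
        "cochran_C": coch.c_statistic, "cochran_critical": coch.c_critical,
        "homogeneous": coch.homogeneous,
    }]).round(4).to_csv(OUT / "precision.csv", index=False)

    # --- Horwitz acceptability: published RSD_R limits imply the RSD_r ones
    table = pio.load_precision_table()
    table["rsd_r_from_R"] = (table["horwitz_rsd_R"].map(rsd_r_from_rsd_R)).round(2)
    print("\nHorwitz consistency of the published precision table:")
    print(table[["horwitz_rsd_R", "horwitz_rsd_r", "rsd_r_from_R"]].to_string())
    table.to_csv(OUT / "horwitz_consistency.csv")
    # a worked example at a typical mass fraction
    h = horwitz_limits(2e-3)
    print(f"  (at C = 2e-3: RSD_R limit {h.rsd_R_max:.2f}%, "
          f"RSD_r limit {h.rsd_r_max:.2f}%)")

    # --- accuracy: published level means and a synthetic replicate
    print("\nRecovery means from the published level recoveries:")
    rows = []
    long = pio.recovery_long_table()
    for analyte, grp in long.groupby("analyte"):
        r = recovery_stats(grp)
        rows.append({"analyte": analyte, "mean": round(r.mean_recovery, 2),
                     "in_98_102": r.mean_in_98_102})
        print(f"  {analyte}: mean recovery {r.mean_recovery:.2f}% "
              f"(within 98-102%: {r.mean_in_98_102})")
    pd.DataFrame(rows).to_csv(OUT / "recovery_published.csv", index=False)

    synth = recovery_stats(gen_recovery(100.0, 0.5, seed=seed + 2),
                           rsd_r_reference=2.0)
    print(f"  synthetic (truth 100%): mean {synth.mean_recovery:.2f}%, "
          f"CI ({synth.ci95[0]:.2f}, {synth.ci95[1]:.2f}), "
          f"all criteria pass: "
          f"{synth.ci_contains_100 and synth.mean_in_98_102 and synth.rsd_within_reference}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
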