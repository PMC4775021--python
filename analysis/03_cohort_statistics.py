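#!/usr/bin/env python
"""Nonparametric cohort analysis of the simulated study population.

Reproduces the standard reporting battery on results/cohort_truths.csv:
the summary table of both angles (all / by sex / by ethnicity, with
Mann-Whitney p-values and exclusion of under-represented groups), the
retroversion sub-analysis (share, sex split, BMI comparison), the young-
vs-old torsion comparison, and Spearman correlations of both angles with
age and BMI. Writes results/table1.{csv,json}, retroversion.json,
age_groups.json, correlations.json.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import pandas as pd  # noqa: E402

from femur3d.io import write_report  # noqa: E402
from femur3d.stats import (  # noqa: E402
    age_group_comparison,
    correlation_analyses,
    retroversion_analysis,
    subgroup_table,
)


def main() -> None:
    results = ROOT / "results"
    truths_path = results / "cohort_truths.csv"
    if not truths_path.exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    frame = pd.read_csv(truths_path).rename(
        columns={"true_ccd_deg": "neck_shaft_angle_deg", "true_torsion_deg": "torsion_deg"}
    )

    table1 = subgroup_table(frame, group_floor=30)
    write_report(table1, results, "table1")
    cells = table1["cells"]
    print("CCD angle medians [deg]:",
          {g: round(c["neck_shaft_angle_deg"].median, 1) for g, c in cells.items()})
    print("torsion medians [deg]:",
          {g: round(c["torsion_deg"].median, 1) for g, c in cells.items()})
    print("excluded ethnic groups (n below floor):", table1["excluded"])
    for name, t in table1["tests"].items():
        print(f"  {name}: p = {t.p_value:.4g}")

    retro = retroversion_analysis(frame)
    write_report(retro, results, "retroversion")
    print(f"retroversion: {retro['n_retroverted']} / {retro['n_total']} "
          f"({retro['percent_retroverted']:.1f}%), {retro.get('percent_male', 0):.0f}% male")
    if "bmi_test" in retro:
        print(f"  BMI retroverted {retro['bmi_retroverted'].median:.1f} vs "
              f"normal {retro['bmi_normal'].median:.1f}, p = {retro['bmi_test'].p_value:.4g}")

    bands = age_group_comparison(frame)
    write_report(bands, results, "age_groups")
    print(f"torsion young (19-50, n={bands['young'].n}) median {bands['young'].median:.1f} "
          f"vs old (75-109, n={bands['old'].n}) median {bands['old'].median:.1f}, "
          f"p = {bands['test'].p_value:.4g}")

    corr = correlation_analyses(frame)
    write_report(corr, results, "correlations")
    for name, t in corr.items():
        print(f"  Spearman {name}: rho = {t.statistic:+.2f}, p = {t.p_value:.3g} ({t.note})")


if __name__ == "__main__":
    main()
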