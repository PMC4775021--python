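#!/usr/bin/env python
"""Age-trend views of both angles (scatter with a running-median trend).

Exports results/age_trends.png and the per-decade trend table
results/age_trend_table.csv for the simulated cohort.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(ROOT / "src"))

import matplotlib  # noqa: E402

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from femur3d.stats import spearman_rho, summarize  # noqa: E402


def main() -> None:
    results = ROOT / "results"
    truths_path = results / "cohort_truths.csv"
    if not truths_path.exists():
        sys.exit("run analysis/01_simulate_cohort.py first")
    frame = pd.read_csv(truths_path).dropna(subset=["age"])

    decades = np.arange(10, 120, 10)
    rows = []
    for lo in decades[:-1]:
        sub = frame[(frame.age >= lo) & (frame.age < lo + 10)]
        if len(sub) < 5:
            continue
        for col, label in (("true_ccd_deg", "ccd"), ("true_torsion_deg", "torsion")):
            s = summarize(sub[col])
            rows.append({"decade": f"{lo}-{lo + 9}", "angle": label, "n": s.n,
                         "median_deg": round(s.median, 1),
                         "q1_deg": round(s.q1, 1), "q3_deg": round(s.q3, 1)})
    trend = pd.DataFrame(rows)
    trend.to_csv(results / "age_trend_table.csv", index=False)

    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharex=True)
    for axis, col, label in (
        (axes[0], "true_ccd_deg", "neck-shaft (CCD) angle [deg]"),
        (axes[1], "true_torsion_deg", "femoral torsion [deg]"),
    ):
        axis.scatter(frame.age, frame[col], s=4, alpha=0.3, color="tab:gray")
        t = trend[trend.angle == ("ccd" if "ccd" in col else "torsion")]
        mids = [int(d.split("-")[0]) + 5 for d in t.decade]
        axis.plot(mids, t.median_deg, "o-", color="tab:red", label="decade median")
        axis.set_xlabel("age [years]")
        axis.set_ylabel(label)
        rho = spearman_rho(frame.age, frame[col])
        axis.set_title(f"Spearman rho = {rho.statistic:+.2f}")
        axis.legend()
    fig.tight_layout()
    fig.savefig(results / "age_trends.png", dpi=130)
    print(f"wrote {results / 'age_trends.png'} and age_trend_table.csv "
          f"({len(frame)} subjects with age)")


if __name__ == "__main__":
    main()
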