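#!/usr/bin/env python
"""Stage 4: indentation depth versus distance from the canal lumen.

Summarizes total indentation distance in 100-um bins per group, compares
bins with one-way ANOVA plus Bonferroni-adjusted pairwise tests, compares
treated versus control depths within 200 um of the lumen (Welch), and
fits the logarithmic depth-distance trend per group.
"""

import json
from pathlib import Path

import pandas as pd

from ramident.indentation import (
    anova_bins,
    bin_depths,
    compare_near_lumen,
    fit_log_trend,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    records = pd.read_csv(DATA / "indentation.csv")
    test = records[records["group"] == "test"]
    ctrl = records[records["group"] == "control"]

    summaries = []
    report = {}
    for name, sub in (("test", test), ("control", ctrl)):
        summary = bin_depths(sub)
        summary.insert(0, "group", name)
        summaries.append(summary)
        try:
            res = anova_bins(sub)
            n_sig = int((res.pairwise["p_bonferroni"] < 0.05).sum())
            report[f"anova_{name}"] = {"F": res.f, "p": res.p,
                                       "significant_pairs": n_sig}
            print(f"{name}: ANOVA across bins F={res.f:.2f}, p={res.p:.2g} "
                  f"({n_sig} Bonferroni-significant pairs)")
        except ValueError as err:
            print(f"{name}: ANOVA skipped ({err})")
        fit = fit_log_trend(sub)
        report[f"log_trend_{name}"] = {"a": fit.a, "b": fit.b, "c": fit.c,
                                       "r2": fit.r2}
        print(f"{name}: depth = {fit.a:.1f} - {fit.b:.2f} ln(d + {fit.c:.0f}), "
              f"r2 = {fit.r2:.2f}")

    pd.concat(summaries, ignore_index=True).to_csv(
        RESULTS / "indentation_summary.csv", index=False, float_format="%.2f"
    )

    cmp_res = compare_near_lumen(test, ctrl)
    report["near_lumen"] = {
        "difference_um": cmp_res.mean_difference,
        "ci": [cmp_res.ci_lo, cmp_res.ci_hi],
        "p": cmp_res.p,
        "n": [cmp_res.n_test, cmp_res.n_control],
    }
    print(f"within 200 um of the lumen, test indentations are "
          f"{cmp_res.mean_difference:.1f} um deeper than control "
          f"(95% CI {cmp_res.ci_lo:.1f} to {cmp_res.ci_hi:.1f}, "
          f"Welch p = {cmp_res.p:.3g})")

    with open(RESULTS / "indentation_stats.json", "w") as fh:
        json.dump(report, fh, indent=2)


if __name__ == "__main__":
    main()
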