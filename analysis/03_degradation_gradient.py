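#!/usr/bin/env python
"""Stage 3: spatial gradient of collagen band areas and the degradation
boundary.

Fits the distance-binned linear models of Amide band area on distance
(per 100 um), the saturating-exponential decay of Amide I height, and the
quality-vs-distance trend. The boundary of the NaOCl effect is the
distance at which the fitted Amide I amplitude recovers 95% of its
lumen-to-asymptote deficit (lambda * ln 20).
"""

import json
from pathlib import Path

import pandas as pd

from ramident.gradient import (
    ENTIRE_LABEL,
    binned_linear_models,
    fit_decay,
    gradient_table,
    quality_trend,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    feats = pd.read_csv(SCRATCH / "features.csv")

    fits = binned_linear_models(feats, strata=None)
    tab = gradient_table(fits)
    tab.to_csv(RESULTS / "gradient.csv", index=False, float_format="%.4f")
    a1 = tab[(tab["band"] == "area_amide1") & ~tab["insufficient_data"]]
    near = a1[a1["bin"] == "Up to 100 um"]["coefficient"].iloc[0]
    entire = a1[a1["bin"] == ENTIRE_LABEL]["coefficient"].iloc[0]
    print("Amide I area gradient (normalized area units per 100 um):")
    for _, row in a1.iterrows():
        print(f"  {row['bin']:>18}: {row['coefficient']:7.3f} "
              f"[{row['ci_lo']:.3f}, {row['ci_hi']:.3f}]  n={row['n_sites']}")
    print(f"near-lumen / entire-thickness coefficient ratio: {near / entire:.1f}")

    naocl = feats[(feats["treatment"] == "naocl") & feats["accepted"]]
    decay = fit_decay(naocl["distance_um"], naocl["h_amide1"])
    qt = quality_trend(feats[feats["treatment"] == "naocl"].dropna(subset=["qi"]))
    report = {
        "decay": {
            "y0": decay.y0,
            "y_inf": decay.y_inf,
            "lambda_um": decay.lam,
            "boundary_um": decay.boundary_um,
            "r2": decay.r2,
        },
        "quality_trend": {"r2": qt["r2"], "caution": qt["caution"]},
    }
    with open(RESULTS / "decay_fit.json", "w") as fh:
        json.dump(report, fh, indent=2)
    print(f"Amide I decay: y0={decay.y0:.3f}, y_inf={decay.y_inf:.3f}, "
          f"lambda={decay.lam:.0f} um (r2={decay.r2:.3f})")
    print(f"estimated boundary of effect: {decay.boundary_um:.0f} um from the lumen")
    print(f"QI-vs-distance trend r2={qt['r2']:.3f}"
          + (" (interpret with caution)" if qt["caution"] else ""))


if __name__ == "__main__":
    main()
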