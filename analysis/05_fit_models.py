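#!/usr/bin/env python
"""Fit the ordinal model battery: full linear, full quadratic, the three
experience-stratified quadratic models (simple slopes), the experience
interaction model, and the top-5 logistic robustness check."""

import json
from pathlib import Path

import pandas as pd

from squadperf.ordinal import OrdinalFit
from squadperf.pipeline import analyze_cohort, coefficient_table, fit_to_dict

ROOT = Path(__file__).resolve().parents[1]

def main():
    cohort = pd.read_csv(ROOT / "results" / "cohort.csv")
    fits, _ = analyze_cohort(
        cohort, models=("full1", "full2", "strata", "interaction", "top5"),
        min_stratum_rows=50,
    )
    out = ROOT / "results" / "fits"
    out.mkdir(exist_ok=True)
    for name, f in fits.items():
        (out / f"{name}.json").write_text(json.dumps(fit_to_dict(name, f), indent=2, default=float))
    ord_fits = {k: v for k, v in fits.items() if isinstance(v, OrdinalFit)}
    coefficient_table(ord_fits).to_csv(out / "coefficient_table.csv")
    for s in ("LOW", "MEDIUM", "HIGH"):
        f = fits[f"stratum_{s}"]
        q, lo_ci, hi_ci = (f.params["share_high_sq"], f.ci_low["share_high_sq"],
                           f.ci_high["share_high_sq"])
        print(f"{s:6s} n={f.n:4d} r2ML={f.r2_ml:.3f} quadratic(share_high) "
              f"{q:+.2f} [{lo_ci:+.2f}, {hi_ci:+.2f}]")
    fi = fits["interaction"]
    print(f"interaction share_high x z_experience: "
          f"{fi.params['share_high_x_z_experience']:+.2f} "
          f"(p={fi.pvalues['share_high_x_z_experience']:.4f})")

if __name__ == "__main__":
    main()
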