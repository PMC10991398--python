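#!/usr/bin/env python
"""Assemble the team-match cohort: inner join of features and ranks,
single-pass |z| > 3 outlier filter, match-level controls, conjoint
experience, K-means experience strata."""

import json
from pathlib import Path

import pandas as pd

from squadperf.cohort import prepare_cohort
from squadperf.pipeline import profiles_table, ranks_table
from squadperf.telemetry import read_telemetry

ROOT = Path(__file__).resolve().parents[1]

def main():
    matches = [read_telemetry(p) for p in sorted((ROOT / "scratch" / "analysis" / "telemetry").glob("*.jsonl"))]
    cohort, report = prepare_cohort(
        pd.read_csv(ROOT / "results" / "behavior_full.csv"),
        pd.read_csv(ROOT / "results" / "risk.csv"),
        ranks_table(matches),
        profiles_table(matches),
        seed=20240,
    )
    cohort.to_csv(ROOT / "results" / "cohort.csv", index=False)
    (ROOT / "results" / "prep_report.json").write_text(json.dumps(report, indent=2, default=float))
    print(f"kept {report['n_kept']}/{report['n_input']} rows "
          f"({report['n_dropped']} dropped at |z|>3)")
    print(f"stratum sizes {report['stratum_sizes']}, centers "
          f"{[round(c, 3) for c in report['stratum_centers']]}")
    print(f"conjoint experience: {report['conjoint_experience']}")

if __name__ == "__main__":
    main()
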