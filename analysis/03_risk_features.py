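#!/usr/bin/env python
"""Landing and overtime risk per team-match against the held-out reference
landing heatmap (10 m cells, median nonzero-cell cutoff)."""

from pathlib import Path

from squadperf.risk import read_heatmap, risk_table
from squadperf.telemetry import location_table, read_telemetry

ROOT = Path(__file__).resolve().parents[1]

def main():
    matches = [read_telemetry(p) for p in sorted((ROOT / "scratch" / "analysis" / "telemetry").glob("*.jsonl"))]
    hm = read_heatmap(ROOT / "results" / "reference_heatmap.csv")
    tables = {m.meta.match_id: location_table(m) for m in matches}
    tab = risk_table(matches, hm, tables)
    tab.to_csv(ROOT / "results" / "risk.csv", index=False)
    cats = tab["risk_category"].value_counts().sort_index().to_dict()
    print(f"{len(tab)} rows; landing risk high median "
          f"{tab['landing_risk_high'].median():.0f}; risk categories {cats}")

if __name__ == "__main__":
    main()
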