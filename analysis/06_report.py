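#!/usr/bin/env python
"""Render the run report (coefficient table, calibration and stratified
effect figures, risk-category counts) from the fitted artifacts."""

from pathlib import Path

from squadperf.pipeline import make_report

ROOT = Path(__file__).resolve().parents[1]

def main():
    path = make_report(ROOT / "results")
    print(f"report written to {path}")

if __name__ == "__main__":
    main()
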