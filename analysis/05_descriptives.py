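#!/usr/bin/env python
"""Descriptive tables for the simulated hepatotoxicity case series.

Stratum counts/proportions (gender, age, weight, region, outcome, year) and
annual report counts, written to results/demographics.csv and
results/annual.csv.
"""

import importlib.util
from pathlib import Path

import pandas as pd

from faerspv.faers_io import extract_cases
from faerspv.report import annual_counts, demographics_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
TARGET_PT = "Hepatotoxicity"

spec = importlib.util.spec_from_file_location(
    "signal_step", Path(__file__).parent / "02_signal_detection.py"
)
signal_step = importlib.util.module_from_spec(spec)
spec.loader.exec_module(signal_step)


def main() -> None:
    reports, _ = signal_step.load_reports()
    flags = extract_cases(reports, TARGET_PT)
    cases = [r for r, f in zip(reports, flags) if f]
    print(f"{len(cases)} de-duplicated hepatotoxicity case reports")

    demo = demographics_table(cases)
    RESULTS.mkdir(exist_ok=True)
    demo.to_csv(RESULTS / "demographics.csv", index=False)
    for dim in ("gender", "age", "outcome"):
        block = demo[demo["dimension"] == dim]
        print(f"\n{dim}:")
        print(block[["level", "count", "proportion_display"]]
              .to_string(index=False))

    years, missing = annual_counts(cases)
    pd.DataFrame({"year": list(years), "count": list(years.values())}).to_csv(
        RESULTS / "annual.csv", index=False
    )
    print(f"\nannual case counts: {years} ({missing} with unparseable year)")


if __name__ == "__main__":
    main()
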