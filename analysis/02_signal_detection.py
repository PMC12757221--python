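#!/usr/bin/env python
"""Disproportionality analysis of the simulated corpus.

Reads the corpus written by 01_simulate_corpus.py, de-duplicates cases,
normalizes drug names, builds the per-drug 2x2 tables against the target PT
and writes the ranked signal table (ROR criterion) to results/signals.csv.
Drugs injected with a true reporting OR above 1 should surface at the top.
"""

from pathlib import Path

import pandas as pd

from faerspv import faers_io, signal

ROOT = Path(__file__).resolve().parents[1]
CORPUS = ROOT / "scratch" / "corpus"
RESULTS = ROOT / "results"
TARGET_PT = "Hepatotoxicity"


def load_reports():
    tables, _ = faers_io.load_corpus(CORPUS)
    reports = faers_io.assemble_reports(tables)
    reports, dedup_log = faers_io.deduplicate(reports)
    mapping = faers_io.load_atc_table(CORPUS / "atc_table.csv")
    faers_io.normalize_drugs(reports, mapping)
    return reports, dedup_log


def main() -> None:
    reports, dedup_log = load_reports()
    print(f"{dedup_log.n_in} raw reports -> {dedup_log.n_out} after "
          f"de-duplication ({dedup_log.n_removed} stale versions removed)")

    score_table = signal.compute_signal_table(reports, TARGET_PT)
    ranked = signal.rank_signals(score_table)
    RESULTS.mkdir(exist_ok=True)
    score_table.to_csv(RESULTS / "signals_all.csv", index=False)
    ranked.to_csv(RESULTS / "signals.csv", index=False)

    truth = pd.read_csv(RESULTS / "01_truth_summary.csv").set_index("drug")
    print(f"\n{len(ranked)} of {len(score_table)} drugs meet the ROR signal "
          "criterion (lower 95% bound > 1, >= 3 cases):")
    view = ranked[["rank", "drug", "cases", "ror", "ror_ci_low", "ror_ci_high"]].copy()
    view["true_ror"] = truth.loc[view["drug"], "true_ror"].to_numpy()
    print(view.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
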