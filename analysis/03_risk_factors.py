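#!/usr/bin/env python
"""Risk-factor modelling on the simulated corpus.

Univariate screen (ROR lower bound > 1, > 100 target-event reports,
Bonferroni-adjusted p < 0.01) -> LASSO selection -> multivariate logistic
with demographic covariates. Writes results/screen.csv and
results/forest.csv.
"""

import importlib.util
import sys
from pathlib import Path

from faerspv import riskmodel

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SEED = 42
TARGET_PT = "Hepatotoxicity"

spec = importlib.util.spec_from_file_location(
    "signal_step", Path(__file__).parent / "02_signal_detection.py"
)
signal_step = importlib.util.module_from_spec(spec)
spec.loader.exec_module(signal_step)


def main() -> None:
    reports, _ = signal_step.load_reports()
    from faerspv.faers_io import extract_cases

    flags = extract_cases(reports, TARGET_PT)
    drugs = sorted(
        {e.drugname_norm for r in reports for e in r.ps_drugs() if e.drugname_norm}
    )
    design = riskmodel.build_design(reports, flags, drugs)

    screen = riskmodel.univariate_screen(design, drugs)
    screened = [s.drug for s in screen if s.passes_screen]
    RESULTS.mkdir(exist_ok=True)
    import pandas as pd

    pd.DataFrame(
        [
            {"drug": s.drug, "case_count": s.case_count, "ror": s.ror,
             "p_adjusted": s.p_adjusted, "passes_screen": s.passes_screen,
             "reason": s.reason}
            for s in screen
        ]
    ).to_csv(RESULTS / "screen.csv", index=False)
    print(f"{len(screened)} of {len(drugs)} drugs pass the univariate screen: "
          f"{screened}")

    if len(screened) >= 2:
        selection = riskmodel.lasso_select(design, screened, seed=SEED, rule="1se")
        selected = selection.selected
        print(f"LASSO (1-SE rule, C={selection.c_chosen:.4g}) keeps {selected}")
    else:
        selected = screened
        print("fewer than two screened drugs; LASSO skipped")

    if not selected:
        print("no drug survived selection; no multivariate model fitted")
        return
    terms = riskmodel.multivariate_logistic(design, selected)
    forest = riskmodel.terms_to_frame(terms)
    forest.to_csv(RESULTS / "forest.csv", index=False)
    print("\nmultivariate logistic model (OR, 95% CI, Bonferroni-adjusted p):")
    print(forest.round(4).to_string(index=False))


if __name__ == "__main__":
    sys.exit(main())
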