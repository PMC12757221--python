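# faerspv

Pharmacovigilance analysis of FAERS-style spontaneous adverse-event reports,
built around the question of which anti-neoplastic agents are
disproportionately reported with hepatotoxicity, how strong those signals
are, which agents remain independent risk factors after mutual adjustment,
and how onset times are distributed over the treatment course.

The package is aimed at pharmacoepidemiologists and safety scientists who
work with the FDA Adverse Event Reporting System (FAERS) quarterly ASCII
extracts or any similarly structured spontaneous-reporting data. Because no
public accession accompanies such analyses, the package ships a synthetic
FAERS corpus generator with a full ground-truth ledger, so every stage of
the pipeline is testable end to end without external data.

## What it computes

**Case extraction.** Quarterly `$`-delimited tables (DEMO, DRUG, REAC,
THER, OUTC, INDI) are joined on PRIMARYID; duplicate case versions are
removed by keeping the latest FDA receipt date per CASEID; a report is a
case when the target MedDRA Preferred Term (here "hepatotoxicity") appears
among its reactions and a Primary Suspect (PS) drug is present. Drug names
are normalised against a user-supplied ATC table.

**Disproportionality.** For each drug the corpus collapses to the 2×2 table
with cells a (drug ∧ event), b (drug ∧ other events), c (other drugs ∧
event), d (neither), N = a+b+c+d, giving

- ROR = (a/c)/(b/d), signal if the lower 95% bound > 1 and a ≥ 3 (the
  primary criterion);
- PRR = (a/(a+b))/(c/(c+d)) with Pearson's χ² = Σ(O−E)²/E, signal if
  χ² ≥ 4, PRR ≥ 2, a ≥ 3;
- EBGM = aN/((a+b)(a+c)) (observed/expected reporting ratio, reported
  without empirical-Bayes shrinkage), signal if EBGM05 > 2;
- IC = log₂ EBGM, signal if IC025 > 0.

All interval bounds share the log-scale variance v = 1/a+1/b+1/c+1/d.

**Risk-factor modelling.** A case/non-case design at one row per
de-duplicated report: univariate logistic screen (ROR lower bound > 1,
> 100 event reports, Bonferroni-adjusted p < 0.01), LASSO selection with
10-fold cross-validated penalty, then a multivariate logistic model of the
selected drugs plus age-group, sex and weight-group covariates (missing
demographics as explicit levels).

**Time to onset.** TTO = EVENT_DT − START_DT in whole days (invalid,
partial and negative intervals excluded with reasons), summarised by
median/IQR and a two-parameter Weibull ML fit; the shape β and its 95% CI
label each drug early-failure (CI < 1, falling hazard), random-failure
(CI spans 1) or wear-out-failure (CI > 1, rising hazard). Subgroups are
compared with the two-sided Wilcoxon rank-sum test.

## Worked example

```python
from faerspv.signal import ContingencyTable, score_signal

t = ContingencyTable(a=67, b=2500, c=1800, d=180_000)
s = score_signal(t)
print(f"ROR  = {s.ror:.2f} (95% CI {s.ror_ci95[0]:.2f}-{s.ror_ci95[1]:.2f})")
print(f"PRR  = {s.prr:.2f} (chi2 = {s.chi2:.1f})")
print(f"EBGM = {s.ebgm:.2f} (EBGM05 = {s.ebgm05:.2f})")
print(f"IC   = {s.ic:.2f} (IC025 = {s.ic025:.2f})")
```

prints

```
ROR  = 2.68 (95% CI 2.09-3.43)
PRR  = 2.64 (chi2 = 66.3)
EBGM = 2.58 (EBGM05 = 2.09)
IC   = 1.37 (IC025 = 1.01)
```

i.e. this drug is reported with the event about 2.7 times as often as the
odds in the rest of the corpus would predict, and all four algorithms flag
it (the ROR lower bound 2.09 > 1 with 67 cases). A Weibull onset fit works
the same way:

```python
import numpy as np
from faerspv import tto

onsets = np.maximum(np.ceil(50 * np.random.default_rng(0).weibull(0.7, 200)), 1)
fit = tto.fit_weibull(onsets)
print(f"beta = {fit.beta:.2f} (95% CI {fit.beta_ci95[0]:.2f}-{fit.beta_ci95[1]:.2f})",
      fit.failure_type)
```

```
beta = 0.79 (95% CI 0.70-0.87) early
```

a shape below 1 with the whole CI under 1: the hazard falls with time on
drug — an early-failure profile.

## Analysis scripts

The `analysis/` directory walks the full study on a simulated corpus of
20,000 reports with three injected hepatotoxicity signals (run them in
order; 01 writes the corpus under `scratch/`, the others write tables under
`results/`):

1. `01_simulate_corpus.py` — generate and serialise the corpus + truth ledger
2. `02_signal_detection.py` — de-duplicate, normalise, rank ROR signals
3. `03_risk_factors.py` — screen → LASSO → multivariate logistic forest table
4. `04_time_to_onset.py` — per-drug Weibull fits, 30-day bins, subgroup tests
5. `05_descriptives.py` — demographic strata and annual report counts
6. `06_published_consistency.py` — failure-type classification of published
   shape estimates and the IC = log₂(EBGM) identity check

Equivalently, `faerspv.report.run_pipeline` executes the whole chain in one
call and writes the same bundle plus a JSON run log with flow accounting.

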