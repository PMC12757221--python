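# Methods

## Data model and case definition

The pipeline operates on FAERS-style quarterly ASCII extracts: one
`$`-delimited file per table (DEMO, DRUG, REAC, THER, OUTC, INDI) joined on
the PRIMARYID report identifier. The reader takes an explicit schema per
table (the shipped default is the modern, post-2014 column set) instead of
sniffing headers, because FAERS column dialects changed across years and
silent misalignment is worse than a named schema error. Malformed lines are
skipped and counted, never silently dropped; empty fields become absent
values, not sentinels.

De-duplication keeps one report per CASEID — the one with the latest FDA
receipt date (FDA_DT). The receipt date is the recency key because the
quarterly files guarantee it on every row; ties are broken by the larger
PRIMARYID compared as a zero-padded numeric string. The operation is
idempotent.

A report is a **case** when the target Preferred Term matches one of its
reaction PTs exactly (case-insensitively) and the report carries at least
one Primary Suspect (PS) drug. Matching is deliberately a single PT, not a
MedDRA hierarchy expansion: the analysis this package implements targets
the one PT "hepatotoxicity", and widening to an SMQ would change the
estimand. Only PS entries attract exposure attribution; secondary-suspect
and concomitant roles never do.

Demographic harmonisation: age unit codes are converted to years
(DEC ×10, MON /12, WK /52, DY /365.25), weights to kg (LBS, GMS
supported), and ages above 120 years are treated as implausible and set
absent. Country is the upper-cased reporter country with no further ISO
harmonisation. Drug-name normalisation is an exact lookup on trimmed,
case-folded names with outer punctuation stripped — spontaneous reports
frequently carry names like `MERCAPTOPURINE.` — against a user-supplied
drug-name → (normalised name, ATC code) table; anything unmapped stays
unmapped and is tallied.

## Disproportionality statistics

For drug *D* and event *E* the corpus collapses to the 2×2 table
(a, b, c, d) with N = a+b+c+d. Point estimates follow the standard printed
forms: ROR = (a/c)/(b/d); PRR = (a/(a+b))/(c/(c+d)); Pearson's
χ² = Σ(O−E)²/E over all four cells without continuity correction;
EBGM = aN/((a+b)(a+c)); IC = log₂ EBGM. The EBGM here is the *unshrunk*
observed/expected relative reporting ratio — full gamma-Poisson shrinkage
(DuMouchel's MGPS) is intentionally not implemented, because the quantity
this pipeline reproduces is the unshrunk form; with shrinkage the identity
IC = log₂ EBGM, which holds exactly here and in the reference results,
would break.

Interval bounds share a single log-scale variance term
v = 1/a + 1/b + 1/c + 1/d:

* ROR 95% CI: exp(ln ROR ± 1.96√v) (two-sided Wald);
* EBGM05: exp(ln EBGM − 1.645√v) (one-sided 95% lower bound);
* IC025: IC − 1.96√v / ln 2.

These conventions were chosen because they are mutually consistent with
published (EBGM, EBGM05, IC, IC025) quadruples under a single shared v; the
acceptance suite checks that consistency as a constraint-satisfaction test.

Zero handling: a zero *marginal* yields no scores at all (a structured
reason, never ±∞); a zero *cell* yields the finite point estimates but no
interval bounds and all signal flags false. No Haldane correction is
applied by default; a +0.5 continuity-correction flag exists but is off.

Signal flags reproduce the standard criteria — ROR lower bound > 1 with
a ≥ 3; PRR ≥ 2 with χ² ≥ 4 and a ≥ 3; EBGM05 > 2; IC025 > 0. The ROR
criterion is the primary signal definition and drives the ranked table;
the other three flags are reported alongside, not intersected, since no
intersection rule is part of the reproduced procedure.

A note on monotonicity: ROR and PRR are strictly increasing in a with
b, c, d fixed; the observed/expected ratio (EBGM, IC) is not — on tiny
tables (e.g. a=5, b=c=d=1) increasing a can *decrease* EBGM because a also
inflates both margins. The property tests therefore assert EBGM/IC
monotonicity only on the spontaneous-reporting regime (b, c ≫ a) where it
holds.

## Risk-factor procedure

Unit of analysis: one row per de-duplicated report; outcome = case flag
(a case/non-case design). Missing demographics are explicit "Missing"
factor levels rather than listwise deletions, so heavily incomplete strata
(FAERS weight is ~83% missing) stay in the model.

1. **Univariate screen.** Outcome on a single PS-exposure indicator. For a
   binary predictor the logistic MLE has the closed form
   coef = ln(ad/bc), se = √v, so the screen computes the Wald p directly
   (the tests verify the identity against an iterative fit). A drug passes
   with ROR lower bound > 1, more than 100 event reports, and
   Bonferroni-adjusted p < 0.01 (family = drugs tested). Tables with a zero
   cell are flagged non-estimable (complete separation) and excluded with
   a reason.
2. **LASSO.** L1-penalised logistic regression over the screened
   indicators; penalty chosen by 10-fold stratified cross-validated
   deviance on a 25-point log-spaced grid, shuffled with the run seed.
   The default rule is the deviance minimum; the one-standard-error rule
   is available as `rule="1se"`. In practice the CV deviance curve is flat
   over a wide penalty range at realistic sample sizes, so the minimum
   rule retains noise variables alongside the true ones (CV-min LASSO is
   screening-consistent, not selection-consistent); the 1-SE rule is the
   parsimonious choice and is what the recovery experiments use for the
   selected-set bound. Zero-variance columns are dropped before fitting
   and can never be selected. Selection is fully deterministic for a fixed
   seed.
3. **Multivariate logistic.** Joint ML fit of the selected drugs plus age
   group (<18, 18–64.9, 65–85, >85, Missing), sex and weight group (<50,
   50–100, >100 kg, Missing), each dummy-coded against its largest stratum
   as reference. Per-term OR = exp(coef) with Wald 95% CI; Bonferroni over
   the reported terms; significant ⇔ adjusted p < 0.01. Terms with
   pathologically large standard errors are flagged as quasi-separated;
   non-convergence raises with the largest offending terms named.

The univariate p-value is the Wald p from the logistic fit (equivalently
the 2×2 Wald z); covariates enter only at the multivariate stage, not
inside the LASSO.

## Time to onset

TTO = (EVENT_DT − START_DT) in whole days, computed only where both dates
are complete, valid 8-digit dates and the event does not precede the start;
every exclusion is tallied by reason (missing/partial/invalid date,
negative interval). Same-day onsets are recorded as **1 day** rather than
excluded: reporting data genuinely contain same-day events (published
per-drug medians go down to 1 day) and the Weibull support requires
positivity. Quartiles use linear interpolation between order statistics,
which produces the fractional quartile values seen in published tables.

The Weibull fit maximises the likelihood of
f(t) = (β/α)(t/α)^(β−1) exp(−(t/α)^β) via the profile likelihood: for
fixed β the scale optimum is α(β) = (Σtᵢ^β/n)^(1/β); the remaining score
equation in β is strictly decreasing and solved by Brent's method to 1e−12.
Wald 95% CIs come from the inverse of the analytic observed information on
the **natural** parameter scale. Natural-scale (rather than log-scale)
intervals are the deliberate convention: with small n or a heavy-tailed
sample they produce negative lower bounds, exactly as published
time-to-onset tables show, whereas log-scale intervals cannot. Degenerate
inputs: fewer than 3 onsets is an error; an all-tied sample is rejected
(β diverges at the boundary). In pipeline runs, drugs with fewer than 10
onset values are reported descriptively with the fit marked unavailable.

Failure types from the shape CI: early iff the CI lies entirely below 1
(decreasing hazard), wear-out iff entirely above 1 (increasing hazard),
random otherwise — exhaustive and mutually exclusive, with CI bounds
touching 1 classed as random.

Subgroup contrasts use the two-sided Wilcoxon rank-sum test: exact
enumeration of all C(n₁+n₂, n₁) group assignments (with midranks for ties)
when both groups have ≤ 8 observations, otherwise the normal approximation
with tie and continuity correction. The enumeration conditions on the
observed tie pattern, so with ties it can legitimately differ from
implementations that use the tie-free null distribution.

## Descriptive tabulation

Outcome codes collapse to one label per report by severity precedence
Death > Life-Threatening > Disability > Hospitalization > Other/Unknown,
making outcome proportions sum to 100% (the precedence order is this
package's documented choice; published tables imply mutual exclusivity but
not the order). Display proportions are rounded half-up to two decimals.
Annual counts use the calendar year of the FDA receipt date (the recency
date that is always present), with unparseable years tallied separately.

## Synthetic corpus generator

The generator emulates the statistical structure the pipeline must
survive, with every injected quantity recorded in a truth ledger:

* **Association strength.** Each suspect-drug profile carries a target
  reporting odds ratio r; its event probability solves
  p/(1−p) = r·p₀/(1−p₀) against the baseline event rate p₀ (default 0.02).
  The odds ratio (not the risk ratio) is calibrated because the ROR is the
  primary downstream measure. Note the calibration is against the *null
  baseline*: when several elevated drugs coexist, the empirical 2×2 ROR —
  computed against *all other* drugs — sits somewhat below r because the
  comparator pool is itself contaminated; the multivariate logistic
  coefficient, whose implicit reference is the null background pool,
  recovers log r without that dilution. Recovery tests are designed around
  this distinction.
* **Onset times.** Per-drug Weibull(α, β) draws, ceiled to whole days with
  a floor of 1 day (matching the 1-day convention above). Optionally,
  fatal cases draw on a reduced scale (the demo uses factor 0.5, mirroring
  the roughly halved fatal median seen in reporting data).
* **Demographics.** Age is a stratum mixture with most mass in 18–64.9
  years; weight and sex distributions and per-field missingness default to
  the pattern of oncology safety reporting (age ~41% missing, sex ~27%,
  weight ~83%). An optional per-stratum event-odds multiplier plus
  per-drug age-stratum exposure weights creates genuine confounding for
  adjustment experiments.
* **Data pathology.** A configurable fraction of caseids receives a stale
  duplicate version (same CASEID, earlier receipt date, smaller
  PRIMARYID); a configurable fraction of reports gets a corrupted date
  (partial event date, partial start date, or swapped start/event giving a
  negative interval). Defaults: 10% duplicates, 5% corrupted dates.
* **Determinism.** The seed is mandatory; a fixed seed yields a
  byte-identical serialised corpus.

Each synthetic report carries exactly one PS drug so that 2×2 counts are
unambiguous; concomitant-role drugs appear as noise. What the generator
does **not** emulate: free-text drug-name misspellings beyond
case/punctuation noise, multi-suspect reports, reporting-volume secular
trends within a drug, and indication channeling. Passing recovery tests
therefore demonstrate correctness of the *procedure* under a faithful but
idealised reporting model, not performance on real FAERS text.

## Problem sizes and numerical choices

The recovery benchmark uses 50,000 reports with 5 injected drugs
(reporting OR 5–10) over 15 null drugs — large enough that every injected
drug exceeds the 100-case screening threshold while the whole experiment
fits in a routine test run. Weibull recovery uses n = 500 per sample and
20 seeds per shape regime (β ∈ {0.5, 1, 2}); shape CIs are then tight
enough that coverage and regime labelling are sharp. The Weibull solver
bracket expands geometrically from β ∈ [10⁻³, 1] and the profile root is
found to xtol 1e−12; the scale-equivariance property holds to 1e−6
relative. Demo analyses use 20,000 reports with three injected signals.

## Known limitations

* Disproportionality quantifies reporting, not incidence or causality; no
  causality instrument (e.g. RUCAM) is computed, and laboratory-based
  injury phenotyping is out of scope because FAERS carries no lab values.
* The unshrunk EBGM overstates association for very sparse cells compared
  to shrinkage estimators; the zero-cell policy (no bounds, no flags)
  guards the worst cases but small-count signals should be read with care.
* Weibull fits treat onsets as fully observed; there is no censoring or
  competing-risk handling.
* The exact Wilcoxon path is limited to both-groups ≤ 8 by design;
  mid-sized samples use the tie-corrected normal approximation.
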