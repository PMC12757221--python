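"""Descriptive tabulation and full-pipeline orchestration.

The demographic table stratifies de-duplicated case reports by gender, age
group, weight group, reporting region, outcome and receipt year, each
stratum reported as a count and a proportion of the grand total. Outcomes
are made mutually exclusive by a severity precedence (Death > Life-
Threatening > Disability > Hospitalization > Other/Unknown) so that the
proportions of one dimension always sum to 100%. Display proportions are
rounded half-up to two decimals.

``run_pipeline`` chains the whole analysis — read (or generate) -> de-
duplicate -> normalize -> extract -> disproportionality signals -> screen/
LASSO/logistic -> time-to-onset -> descriptive tables — writing one CSV per
product and a JSON run log with flow accounting at every stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import faers_io, riskmodel, signal, synth, tto
from .errors import ConfigurationError, FaerspvError, PipelineStageError
from .faers_io import CaseReport, parse_faers_date
from .strata import AGE_LEVELS, MISSING, SEX_LEVELS, WEIGHT_LEVELS, age_group, sex_group, weight_group

__all__ = [
    "OUTCOME_PRECEDENCE",
    "primary_outcome",
    "demographics_table",
    "annual_counts",
    "PipelineConfig",
    "run_pipeline",
]

#: Severity precedence for collapsing a report's outcome set to one label.
OUTCOME_PRECEDENCE = ["DE", "LT", "DS", "HO"]

_OUTCOME_LABELS = {
    "DE": "Death",
    "LT": "Life-Threatening",
    "DS": "Disability",
    "HO": "Hospitalization",
}
_OTHER_OUTCOME = "Other and Unknown"


def primary_outcome(outcomes: set[str]) -> str:
    """Collapse an outcome-code set to its most severe label."""
    for code in OUTCOME_PRECEDENCE:
        if code in outcomes:
            return _OUTCOME_LABELS[code]
    return _OTHER_OUTCOME


def _display(proportion: float) -> float:
    """Percentage rounded half-up to 2 decimals (display convention)."""
    return float(
        Decimal(repr(proportion * 100)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )


def demographics_table(reports: Sequence[CaseReport]) -> pd.DataFrame:
    """Stratum counts and proportions over de-duplicated case reports.

    Returns columns ``dimension, level, count, proportion,
    proportion_display``; within each dimension the counts (including the
    Missing level) sum to the grand total and the raw proportions to 1.
    Empty input yields an empty table.
    """
    cols = ["dimension", "level", "count", "proportion", "proportion_display"]
    total = len(reports)
    if total == 0:
        return pd.DataFrame(columns=cols)

    def tally(dimension: str, values: list[str], level_order: list[str]) -> list[dict]:
        counts: dict[str, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        levels = [lv for lv in level_order if lv in counts]
        levels += sorted(set(counts) - set(level_order))
        return [
            {
                "dimension": dimension,
                "level": lv,
                "count": counts[lv],
                "proportion": counts[lv] / total,
                "proportion_display": _display(counts[lv] / total),
            }
            for lv in levels
        ]

    records = []
    records += tally("gender", [sex_group(r.sex) for r in reports], SEX_LEVELS)
    records += tally("age", [age_group(r.age_years) for r in reports], AGE_LEVELS)
    records += tally("weight", [weight_group(r.weight_kg) for r in reports], WEIGHT_LEVELS)
    records += tally("region", [r.country or MISSING for r in reports], [])
    outcome_order = [_OUTCOME_LABELS[c] for c in OUTCOME_PRECEDENCE] + [_OTHER_OUTCOME]
    records += tally("outcome", [primary_outcome(r.outcomes) for r in reports], outcome_order)
    years = []
    for r in reports:
        d = parse_faers_date(r.version_date)
        years.append(str(d.year) if d else MISSING)
    records += tally("year", years, sorted({y for y in years if y != MISSING}))
    return pd.DataFrame.from_records(records, columns=cols)


def annual_counts(reports: Sequence[CaseReport]) -> tuple[dict[int, int], int]:
    """Report counts per calendar year of the FDA receipt date.

    Returns ``(year -> count, n_missing)``; reports whose receipt date cannot
    be parsed are tallied separately, never dropped.
    """
    counts: dict[int, int] = {}
    missing = 0
    for rep in reports:
        d = parse_faers_date(rep.version_date)
        if d is None:
            missing += 1
        else:
            counts[d.year] = counts.get(d.year, 0) + 1
    return dict(sorted(counts.items())), missing


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    Exactly one of ``synth_config`` (generate a corpus, then read it back
    through the ASCII readers) or ``input_dir`` (pre-existing corpus) must be
    given. ``atc_table`` may be a path or DataFrame; for synthetic runs it
    defaults to the generator's own roster.
    """

    out_dir: str | Path
    seed: int
    target_pt: str = "Hepatotoxicity"
    synth_config: synth.SynthConfig | None = None
    input_dir: str | Path | None = None
    atc_table: str | Path | pd.DataFrame | None = None
    screen_min_cases: int = 100
    alpha: float = 0.01
    lasso_rule: str = "min"
    tto_min_n: int = 10


def _stage(log: dict, name: str, n_in: int):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, n_in, exc) from exc
            return False

    log.setdefault("stages", []).append({"stage": name, "n_in": n_in})
    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write the output bundle.

    Products under ``out_dir``: ``signals.csv`` (ranked disproportionality
    table), ``screen.csv``, ``forest.csv`` (multivariate model), ``tto.csv``
    and ``tto_bins.csv``, ``demographics.csv``, ``annual.csv`` and
    ``run_log.json``. The run log records the seed and row counts at every
    stage so that raw rows = retained + excluded throughout. Reruns with the
    same config and seed are byte-identical.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: dict = {"seed": config.seed, "target_pt": config.target_pt, "stages": []}

    # --- acquire corpus -------------------------------------------------
    if (config.synth_config is None) == (config.input_dir is None):
        raise ConfigurationError("provide exactly one of synth_config or input_dir")
    if config.synth_config is not None:
        with _stage(log, "generate", 0):
            reports_true, truth = synth.generate(config.synth_config)
            corpus_dir = out_dir / "corpus"
            synth.write_corpus(reports_true, corpus_dir)
            atc_source = synth.make_atc_table(config.synth_config)
            atc_source.to_csv(corpus_dir / "atc_table.csv", index=False)
            log["stages"][-1]["n_out"] = len(reports_true)
    else:
        corpus_dir = Path(config.input_dir)
        atc_source = config.atc_table
        if atc_source is None:
            raise ConfigurationError("atc_table is required for a pre-existing corpus")

    with _stage(log, "read", 0):
        tables, parse_logs = faers_io.load_corpus(corpus_dir)
        reports = faers_io.assemble_reports(tables)
        log["stages"][-1].update(
            n_out=len(reports),
            raw_rows={t: sum(pl.n_rows for pl in pls) for t, pls in parse_logs.items()},
            skipped_rows={t: sum(pl.n_skipped for pl in pls) for t, pls in parse_logs.items()},
        )

    with _stage(log, "deduplicate", len(reports)):
        reports, dedup_log = faers_io.deduplicate(reports)
        log["stages"][-1].update(n_out=dedup_log.n_out, n_removed=dedup_log.n_removed)

    with _stage(log, "normalize", len(reports)):
        mapping = faers_io.load_atc_table(atc_source)
        norm_log = faers_io.normalize_drugs(reports, mapping)
        log["stages"][-1].update(n_mapped=norm_log.n_mapped, n_unmapped=norm_log.n_unmapped)

    with _stage(log, "extract_cases", len(reports)):
        case_flags = faers_io.extract_cases(reports, config.target_pt)
        cases = [r for r, f in zip(reports, case_flags) if f]
        log["stages"][-1].update(n_cases=len(cases), n_noncases=len(reports) - len(cases))

    with _stage(log, "signals", len(reports)):
        score_table = signal.compute_signal_table(reports, config.target_pt)
        ranked = signal.rank_signals(score_table)
        score_table.to_csv(out_dir / "signals_all.csv", index=False)
        ranked.to_csv(out_dir / "signals.csv", index=False)
        log["stages"][-1].update(n_drugs=len(score_table), n_signals=len(ranked))

    with _stage(log, "riskmodel", len(reports)):
        drugs = list(score_table["drug"])
        design = riskmodel.build_design(reports, case_flags, drugs)
        screen = riskmodel.univariate_screen(
            design, drugs, min_cases=config.screen_min_cases, alpha=config.alpha
        )
        pd.DataFrame.from_records(
            [
                {
                    "drug": s.drug, "case_count": s.case_count, "ror": s.ror,
                    "ci_low": s.ror_ci95[0] if s.ror_ci95 else None,
                    "ci_high": s.ror_ci95[1] if s.ror_ci95 else None,
                    "p_raw": s.p_raw, "p_adjusted": s.p_adjusted,
                    "passes_screen": s.passes_screen, "estimable": s.estimable,
                    "reason": s.reason,
                }
                for s in screen
            ]
        ).to_csv(out_dir / "screen.csv", index=False)
        screened = [s.drug for s in screen if s.passes_screen]
        log["stages"][-1].update(n_screened=len(screened))
        if len(screened) >= 2:
            selection = riskmodel.lasso_select(
                design, screened, seed=config.seed, rule=config.lasso_rule
            )
            selected = selection.selected
            log["stages"][-1].update(n_selected=len(selected), lasso_c=selection.c_chosen)
        else:
            selected = screened
            log["stages"][-1].update(n_selected=len(selected), lasso_c=None)
        if selected:
            terms = riskmodel.multivariate_logistic(design, selected, alpha=config.alpha)
            riskmodel.terms_to_frame(terms).to_csv(out_dir / "forest.csv", index=False)
        else:
            log["stages"][-1]["warning"] = "no drug survived screening/selection"
            riskmodel.terms_to_frame([]).to_csv(out_dir / "forest.csv", index=False)

    with _stage(log, "tto", len(cases)):
        samples, excl = tto.compute_tto(cases)
        records = []
        all_onsets: list[int] = []
        for drug in sorted(samples):
            s = samples[drug]
            all_onsets.extend(s.onsets)
            med, q1, q3 = tto.median_iqr(s.onsets)
            row = {
                "drug": drug, "n": len(s.onsets), "median": med, "q1": q1, "q3": q3,
                "alpha": None, "alpha_ci_low": None, "alpha_ci_high": None,
                "beta": None, "beta_ci_low": None, "beta_ci_high": None,
                "failure_type": None, "converged": None,
            }
            if len(s.onsets) >= config.tto_min_n:
                try:
                    f = tto.fit_weibull(s.onsets)
                    row.update(
                        alpha=f.alpha, alpha_ci_low=f.alpha_ci95[0],
                        alpha_ci_high=f.alpha_ci95[1], beta=f.beta,
                        beta_ci_low=f.beta_ci95[0], beta_ci_high=f.beta_ci95[1],
                        failure_type=f.failure_type, converged=f.converged,
                    )
                except FaerspvError:
                    pass  # fit unavailable; the descriptive row still stands
            records.append(row)
        pd.DataFrame.from_records(records).to_csv(out_dir / "tto.csv", index=False)
        tto.bin_onsets(all_onsets).to_csv(out_dir / "tto_bins.csv", index=False)
        log["stages"][-1].update(
            n_included=excl.n_included, n_excluded=excl.n_excluded,
            excluded_by_reason=dict(sorted(excl.excluded.items())),
        )
        # subgroup contrasts: sex and fatal status
        group_rows = []
        by_sex = {"Male": [], "Female": []}
        by_fatal = {"fatal": [], "nonfatal": []}
        for rep in cases:
            s_map, _ = tto.compute_tto([rep])
            onsets = [o for smp in s_map.values() for o in smp.onsets]
            if not onsets:
                continue
            g = sex_group(rep.sex)
            if g in by_sex:
                by_sex[g].extend(onsets)
            by_fatal["fatal" if "DE" in rep.outcomes else "nonfatal"].extend(onsets)
        for label, (ga, gb) in {
            "male_vs_female": (by_sex["Male"], by_sex["Female"]),
            "fatal_vs_nonfatal": (by_fatal["fatal"], by_fatal["nonfatal"]),
        }.items():
            if ga and gb:
                cmp = tto.compare_groups(ga, gb)
                group_rows.append(
                    {"contrast": label, "median_a": cmp.median_a,
                     "median_b": cmp.median_b, "p_value": cmp.p_value,
                     "method": cmp.method, "n_a": len(ga), "n_b": len(gb)}
                )
        pd.DataFrame.from_records(group_rows).to_csv(out_dir / "tto_groups.csv", index=False)

    with _stage(log, "report", len(cases)):
        demographics_table(cases).to_csv(out_dir / "demographics.csv", index=False)
        years, missing_years = annual_counts(cases)
        pd.DataFrame(
            {"year": list(years), "count": list(years.values())}
        ).to_csv(out_dir / "annual.csv", index=False)
        log["stages"][-1].update(n_year_missing=missing_years)

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return log
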