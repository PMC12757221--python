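"""Synthetic FAERS-style corpora with known ground truth.

The generator emulates the statistical structure a spontaneous-reporting
pipeline has to survive: drug-event associations with a configured reporting
odds ratio, drug-specific Weibull onset-time distributions, demographic
strata with heavy missingness, duplicate case versions and partial/invalid
dates. Every injected quantity is recorded in a :class:`TruthLedger` so that
downstream stages (case extraction, 2x2 tables, screening, Weibull fits) can
be tested against bookkeeping rather than against themselves.

Calibration of the association: with baseline event probability ``p0`` the
event probability for a profile with target reporting odds ratio ``r``
solves ``p/(1-p) = r * p0/(1-p0)`` — the reporting odds ratio, not the risk
ratio, is the calibrated quantity, because the ROR is the primary
disproportionality measure downstream.

Onset times are drawn from the continuous Weibull, rounded up to whole days
with a floor of one day; spontaneous reports carry genuine same-day onsets
and the Weibull support excludes zero.

Each synthetic report carries exactly one Primary Suspect drug (keeping 2x2
counts unambiguous); concomitant-role drugs are added as noise but never
attract suspect attribution.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .faers_io import CaseReport, DrugEntry, TABLE_SCHEMAS, parse_faers_date

__all__ = [
    "SynthDrugProfile",
    "SynthConfig",
    "DrugTruth",
    "TruthLedger",
    "generate",
    "write_corpus",
    "make_atc_table",
    "demo_config",
]

#: PT strings used for non-target reactions.
_OTHER_PTS = [
    "Nausea", "Rash", "Headache", "Fatigue", "Pyrexia",
    "Diarrhoea", "Vomiting", "Dizziness", "Anaemia", "Pruritus",
]

_COUNTRY_DEFAULT = {"US": 0.18, "CA": 0.14, "IT": 0.08, "ES": 0.08, "DE": 0.06, "OTHER": 0.46}

#: Age strata as (label, low, high, probability of the stratum when observed).
#: Mass is concentrated in 18-64.9 years as in oncology safety reporting.
_AGE_STRATA_DEFAULT = (
    ("<18", 1.0, 18.0, 0.096),
    ("18-64.9", 18.0, 64.9, 0.610),
    ("65-85", 65.0, 85.0, 0.286),
    (">85", 85.1, 100.0, 0.008),
)

_WEIGHT_STRATA_DEFAULT = ((30.0, 50.0, 0.135), (50.0, 100.0, 0.776), (100.1, 140.0, 0.089))


@dataclass
class SynthDrugProfile:
    """Generative profile of one suspect drug.

    ``use_probability`` is the per-report probability of this drug being the
    Primary Suspect; ``true_ror`` the injected reporting odds ratio of the
    target event versus the baseline; onset times follow
    Weibull(``tto_scale_alpha`` days, ``tto_shape_beta``). An optional
    ``age_group_weights`` map multiplies the use probability within an age
    stratum (then renormalised), which creates exposure-demographics
    confounding for adjustment experiments.
    """

    name: str
    atc_code: str
    use_probability: float
    true_ror: float = 1.0
    tto_scale_alpha: float = 45.0
    tto_shape_beta: float = 1.0
    age_group_weights: dict[str, float] | None = None

    def validate(self) -> None:
        if not (0 < self.use_probability < 1):
            raise ConfigurationError(f"{self.name}: use_probability must be in (0,1)")
        if self.true_ror <= 0:
            raise ConfigurationError(f"{self.name}: true_ror must be positive")
        if self.tto_scale_alpha <= 0 or self.tto_shape_beta <= 0:
            raise ConfigurationError(f"{self.name}: Weibull parameters must be positive")


@dataclass
class SynthConfig:
    """Full generative specification of a synthetic corpus. Seed is mandatory."""

    n_reports: int
    drug_profiles: list[SynthDrugProfile]
    seed: int
    baseline_event_rate: float = 0.02
    n_background_drugs: int = 10
    target_pt: str = "Hepatotoxicity"
    sex_distribution: dict[str, float] = field(
        default_factory=lambda: {"F": 0.635, "M": 0.365}
    )
    age_strata: tuple = _AGE_STRATA_DEFAULT
    weight_strata: tuple = _WEIGHT_STRATA_DEFAULT
    country_distribution: dict[str, float] = field(
        default_factory=lambda: dict(_COUNTRY_DEFAULT)
    )
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.41, "sex": 0.27, "wt": 0.83, "country": 0.05, "event_dt": 0.10
        }
    )
    duplicate_fraction: float = 0.10
    invalid_date_fraction: float = 0.05
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {"DE": 0.105, "LT": 0.045, "DS": 0.005, "HO": 0.173}
    )
    fatal_tto_scale_factor: float = 1.0
    age_event_multiplier: dict[str, float] | None = None
    concomitant_probability: float = 0.2
    background_tto: tuple[float, float] = (45.0, 1.0)
    years: tuple[int, int] = (2015, 2023)
    yearly_volumes: dict[int, int] | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        if self.n_reports <= 0 and not self.yearly_volumes:
            raise ConfigurationError("n_reports must be positive")
        if not (0 < self.baseline_event_rate < 1):
            raise ConfigurationError("baseline_event_rate must be in (0,1)")
        for prof in self.drug_profiles:
            prof.validate()
            p = _event_probability(prof.true_ror, self.baseline_event_rate)
            if not (0 < p < 1):
                raise ConfigurationError(
                    f"{prof.name}: implied event probability {p} outside (0,1)"
                )
        total_use = sum(p.use_probability for p in self.drug_profiles)
        if total_use >= 1:
            raise ConfigurationError(
                f"profile use probabilities sum to {total_use:.3f} >= 1; "
                "no probability mass left for the background drug pool"
            )
        if self.n_background_drugs < 1:
            raise ConfigurationError("need at least one background drug")
        for name, rate in {
            "duplicate_fraction": self.duplicate_fraction,
            "invalid_date_fraction": self.invalid_date_fraction,
            **{f"missingness[{k}]": v for k, v in self.missingness.items()},
            **{f"outcome_probs[{k}]": v for k, v in self.outcome_probs.items()},
        }.items():
            if not (0 <= rate <= 1):
                raise ConfigurationError(f"{name} must be in [0,1], got {rate}")


def _event_probability(true_ror: float, baseline: float) -> float:
    odds = true_ror * baseline / (1 - baseline)
    return odds / (1 + odds)


@dataclass
class DrugTruth:
    """Injected ground truth for one drug, plus realised bookkeeping."""

    name: str
    atc_code: str
    true_ror: float
    tto_alpha: float
    tto_beta: float
    is_background: bool
    n_exposed: int = 0
    n_events: int = 0
    tto_days: list[int] = field(default_factory=list)


@dataclass
class TruthLedger:
    """Everything injected into one corpus, for oracle-style testing."""

    config: SynthConfig
    drugs: dict[str, DrugTruth]
    n_unique_reports: int
    n_duplicates: int
    n_cases: int
    case_flags: list[bool]
    year_counts: dict[int, int]
    n_invalid_dates: int

    def contingency(self, drug: str) -> tuple[int, int, int, int]:
        """The (a, b, c, d) cross-tabulation of ``drug`` vs all other drugs."""
        t = self.drugs[drug]
        a = t.n_events
        b = t.n_exposed - a
        c = self.n_cases - a
        d = self.n_unique_reports - t.n_exposed - c
        return a, b, c, d


def _fmt_date(d: _dt.date) -> str:
    return f"{d.year:04d}{d.month:02d}{d.day:02d}"


def generate(config: SynthConfig) -> tuple[list[CaseReport], TruthLedger]:
    """Draw a corpus of :class:`CaseReport` objects plus its truth ledger.

    The returned list contains the unique reports followed by the injected
    stale duplicate versions (same CASEID, earlier FDA receipt date, smaller
    PRIMARYID); de-duplication must recover exactly the unique reports.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    # --- report volume and receipt years -------------------------------
    if config.yearly_volumes:
        years = np.concatenate(
            [np.full(v, y) for y, v in sorted(config.yearly_volumes.items())]
        )
        n = len(years)
    else:
        n = config.n_reports
        years = rng.integers(config.years[0], config.years[1] + 1, size=n)

    # --- drug roster ----------------------------------------------------
    background_names = [f"backgrounddrug{i:02d}" for i in range(1, config.n_background_drugs + 1)]
    profiles = list(config.drug_profiles)
    all_names = [p.name for p in profiles] + background_names
    bg_alpha, bg_beta = config.background_tto
    truth = {
        p.name: DrugTruth(p.name, p.atc_code, p.true_ror, p.tto_scale_alpha,
                          p.tto_shape_beta, is_background=False)
        for p in profiles
    }
    for i, name in enumerate(background_names, start=1):
        truth[name] = DrugTruth(name, f"X00XX{i:02d}", 1.0, bg_alpha, bg_beta,
                                is_background=True)

    # --- demographics ---------------------------------------------------
    strata = config.age_strata
    stratum_p = np.array([s[3] for s in strata], dtype=float)
    stratum_p = stratum_p / stratum_p.sum()
    stratum_idx = rng.choice(len(strata), size=n, p=stratum_p)
    ages = np.array(
        [round(rng.uniform(strata[i][1], strata[i][2]), 1) for i in stratum_idx]
    )
    stratum_labels = [strata[i][0] for i in stratum_idx]

    # --- PS drug assignment (optionally age-biased) ---------------------
    base_use = np.array([p.use_probability for p in profiles], dtype=float)
    bg_share = (1 - base_use.sum()) / config.n_background_drugs
    if any(p.age_group_weights for p in profiles):
        drug_idx = np.empty(n, dtype=int)
        for s, (label, *_rest) in enumerate(strata):
            mask = stratum_idx == s
            w = np.array(
                [
                    p.use_probability * (p.age_group_weights or {}).get(label, 1.0)
                    for p in profiles
                ]
                + [bg_share] * config.n_background_drugs
            )
            w = w / w.sum()
            drug_idx[mask] = rng.choice(len(all_names), size=int(mask.sum()), p=w)
    else:
        probs = np.concatenate([base_use, np.full(config.n_background_drugs, bg_share)])
        drug_idx = rng.choice(len(all_names), size=n, p=probs)

    # --- event assignment, calibrated on the reporting odds -------------
    p0 = config.baseline_event_rate
    p_by_drug = np.array(
        [_event_probability(p.true_ror, p0) for p in profiles]
        + [p0] * config.n_background_drugs
    )
    mult = config.age_event_multiplier
    odds = p_by_drug[drug_idx] / (1 - p_by_drug[drug_idx])
    if mult:
        odds = odds * np.array([mult.get(lbl, 1.0) for lbl in stratum_labels])
    p_event = odds / (1 + odds)
    is_case = rng.random(n) < p_event

    # --- outcomes (for cases; non-cases are Other/Unknown) --------------
    out_levels = list(config.outcome_probs) + ["OT"]
    out_p = np.array(list(config.outcome_probs.values()) + [0.0])
    out_p[-1] = 1 - out_p[:-1].sum()
    outcome_idx = rng.choice(len(out_levels), size=n, p=out_p)

    # --- dates and onset intervals --------------------------------------
    alphas = np.array([truth[all_names[i]].tto_alpha for i in drug_idx])
    betas = np.array([truth[all_names[i]].tto_beta for i in drug_idx])
    fatal = np.array([is_case[i] and out_levels[outcome_idx[i]] == "DE" for i in range(n)])
    alphas = np.where(fatal, alphas * config.fatal_tto_scale_factor, alphas)
    tto_cont = alphas * rng.weibull(betas, size=n)
    tto_days = np.maximum(np.ceil(tto_cont).astype(int), 1)
    delays = rng.integers(7, 91, size=n)
    doy = rng.integers(0, 365, size=n)

    # --- missingness and invalid-date injection -------------------------
    _zeros = np.zeros(n, dtype=bool)
    miss = {k: rng.random(n) < v for k, v in config.missingness.items()}
    corrupt = rng.random(n) < config.invalid_date_fraction
    corrupt_kind = rng.integers(0, 3, size=n)  # 0: partial event, 1: partial start, 2: negative
    sexes = rng.choice(list(config.sex_distribution), size=n,
                       p=np.array(list(config.sex_distribution.values())))
    wstrata = config.weight_strata
    wp = np.array([w[2] for w in wstrata])
    widx = rng.choice(len(wstrata), size=n, p=wp / wp.sum())
    weights = np.array([round(rng.uniform(wstrata[i][0], wstrata[i][1]), 1) for i in widx])
    countries = rng.choice(list(config.country_distribution), size=n,
                           p=np.array(list(config.country_distribution.values())))
    has_conc = rng.random(n) < config.concomitant_probability
    conc_idx = rng.integers(0, len(all_names), size=n)
    extra_pt = rng.random(n) < 0.3
    other_pt_idx = rng.integers(0, len(_OTHER_PTS), size=n)
    extra_outcome = rng.random(n) < 0.3

    reports: list[CaseReport] = []
    n_invalid = 0
    year_counts: dict[int, int] = {}
    for i in range(n):
        year = int(years[i])
        fda = _dt.date(year, 1, 1) + _dt.timedelta(days=int(doy[i]))
        event = fda - _dt.timedelta(days=int(delays[i]))
        start = event - _dt.timedelta(days=int(tto_days[i]))
        year_counts[fda.year] = year_counts.get(fda.year, 0) + 1

        event_raw: str | None = _fmt_date(event)
        start_raw: str | None = _fmt_date(start)
        drug_name = all_names[drug_idx[i]]
        dt = truth[drug_name]
        dt.n_exposed += 1

        valid_dates = True
        if miss.get("event_dt", _zeros)[i]:
            event_raw = None
            valid_dates = False
        elif corrupt[i]:
            n_invalid += 1
            valid_dates = False
            if corrupt_kind[i] == 0:
                event_raw = event_raw[:6]
            elif corrupt_kind[i] == 1:
                start_raw = start_raw[:6]
            else:
                event_raw, start_raw = start_raw, event_raw  # event precedes start

        if is_case[i]:
            dt.n_events += 1
            if valid_dates:
                dt.tto_days.append(int(tto_days[i]))

        caseid = str(100000 + i)
        raw_name = drug_name.upper() + ("." if (i + drug_idx[i]) % 3 == 0 else "")
        drugs = [
            DrugEntry(
                drugname_raw=raw_name,
                role="PS",
                drug_seq="1",
                start_dt=parse_faers_date(start_raw),
                start_dt_raw=start_raw,
            )
        ]
        if has_conc[i]:
            drugs.append(
                DrugEntry(
                    drugname_raw=all_names[conc_idx[i]].upper(),
                    role="C",
                    drug_seq="2",
                )
            )

        pts = {_OTHER_PTS[other_pt_idx[i]]}
        if is_case[i]:
            pts = {config.target_pt} | (pts if extra_pt[i] else set())
        outcome = out_levels[outcome_idx[i]] if is_case[i] else "OT"
        outcomes = {outcome}
        if outcome in ("DE", "LT") and extra_outcome[i]:
            outcomes.add("HO")

        reports.append(
            CaseReport(
                primaryid=f"{caseid}1",
                caseid=caseid,
                version_date=_fmt_date(fda),
                event_dt=parse_faers_date(event_raw),
                event_dt_raw=event_raw,
                age_years=None if miss.get("age", _zeros)[i] else float(ages[i]),
                sex=None if miss.get("sex", _zeros)[i] else str(sexes[i]),
                weight_kg=None if miss.get("wt", _zeros)[i] else float(weights[i]),
                country=None if miss.get("country", _zeros)[i] else str(countries[i]),
                outcomes=outcomes,
                drugs=drugs,
                reaction_pts=pts,
            )
        )

    # --- duplicate versions (stale copies, earlier receipt dates) -------
    n_dup = int(round(config.duplicate_fraction * n))
    dup_targets = rng.choice(n, size=n_dup, replace=False) if n_dup else np.array([], int)
    dup_backdate = rng.integers(30, 181, size=n_dup)
    duplicates = []
    for j, i in enumerate(sorted(int(x) for x in dup_targets)):
        orig = reports[i]
        fda = parse_faers_date(orig.version_date) - _dt.timedelta(days=int(dup_backdate[j]))
        stale = replace(
            orig,
            primaryid=f"{orig.caseid}0",
            version_date=_fmt_date(fda),
            age_years=None,  # stale versions tend to be sparser
            outcomes=set(orig.outcomes),
            drugs=[replace(d) for d in orig.drugs],
            reaction_pts=set(orig.reaction_pts),
        )
        duplicates.append(stale)

    ledger = TruthLedger(
        config=config,
        drugs=truth,
        n_unique_reports=n,
        n_duplicates=n_dup,
        n_cases=int(is_case.sum()),
        case_flags=[bool(f) for f in is_case],
        year_counts=year_counts,
        n_invalid_dates=n_invalid,
    )
    return reports + duplicates, ledger


def make_atc_table(config: SynthConfig) -> pd.DataFrame:
    """Normalization table covering every drug name the generator can emit."""
    rows = [
        {"drugname": p.name, "norm_name": p.name, "atc_code": p.atc_code}
        for p in config.drug_profiles
    ]
    rows += [
        {
            "drugname": f"backgrounddrug{i:02d}",
            "norm_name": f"backgrounddrug{i:02d}",
            "atc_code": f"X00XX{i:02d}",
        }
        for i in range(1, config.n_background_drugs + 1)
    ]
    return pd.DataFrame(rows)


def _quarter_label(version_date: str | None) -> str:
    d = parse_faers_date(version_date)
    if d is None:
        return "00Q0"
    return f"{d.year % 100:02d}Q{(d.month - 1) // 3 + 1}"


def _demo_row(r: CaseReport) -> dict[str, str]:
    return {
        "primaryid": r.primaryid,
        "caseid": r.caseid,
        "caseversion": "1",
        "event_dt": r.event_dt_raw or "",
        "fda_dt": r.version_date or "",
        "age": "" if r.age_years is None else f"{r.age_years:.1f}",
        "age_cod": "" if r.age_years is None else "YR",
        "sex": r.sex or "",
        "wt": "" if r.weight_kg is None else f"{r.weight_kg:.1f}",
        "wt_cod": "" if r.weight_kg is None else "KG",
        "reporter_country": r.country or "",
    }


def write_corpus(reports: list[CaseReport], out_dir: str | Path) -> list[Path]:
    """Serialize reports into "$"-delimited quarterly table files.

    One DEMO/DRUG/REAC/THER/OUTC file set is written per calendar quarter of
    the FDA receipt date (e.g. ``DEMO21Q3.txt``), rows sorted by zero-padded
    PRIMARYID, in the same dialect the readers expect. Output is
    deterministic: a fixed seed and config yields byte-identical files.
    """
    if not reports:
        raise ConfigurationError("write_corpus requires at least one report")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    by_quarter: dict[str, list[CaseReport]] = {}
    for rep in reports:
        by_quarter.setdefault(_quarter_label(rep.version_date), []).append(rep)

    written: list[Path] = []
    for quarter in sorted(by_quarter):
        batch = sorted(by_quarter[quarter], key=lambda r: r.primaryid.zfill(20))
        tables: dict[str, list[dict[str, str]]] = {
            t: [] for t in ("DEMO", "DRUG", "REAC", "THER", "OUTC")
        }
        for rep in batch:
            tables["DEMO"].append(_demo_row(rep))
            for entry in rep.drugs:
                tables["DRUG"].append(
                    {
                        "primaryid": rep.primaryid,
                        "caseid": rep.caseid,
                        "drug_seq": entry.drug_seq,
                        "role_cod": entry.role,
                        "drugname": entry.drugname_raw,
                    }
                )
                if entry.start_dt_raw:
                    tables["THER"].append(
                        {
                            "primaryid": rep.primaryid,
                            "caseid": rep.caseid,
                            "dsg_drug_seq": entry.drug_seq,
                            "start_dt": entry.start_dt_raw,
                        }
                    )
            for pt in sorted(rep.reaction_pts):
                tables["REAC"].append(
                    {"primaryid": rep.primaryid, "caseid": rep.caseid, "pt": pt}
                )
            for outc in sorted(rep.outcomes):
                tables["OUTC"].append(
                    {"primaryid": rep.primaryid, "caseid": rep.caseid, "outc_cod": outc}
                )
        for table_id, rows in tables.items():
            columns = TABLE_SCHEMAS[table_id]
            path = out_dir / f"{table_id}{quarter}.txt"
            with open(path, "w", encoding="latin-1", newline="\n") as fh:
                fh.write("$".join(columns) + "\n")
                for row in rows:
                    fh.write("$".join(row.get(c, "") for c in columns) + "\n")
            written.append(path)
    return written


def demo_config(n_reports: int = 20_000, seed: int = 42) -> SynthConfig:
    """A small bundled scenario: three hepatotoxicity-associated antineoplastic
    agents injected over a null background, sized for quick end-to-end runs."""
    profiles = [
        SynthDrugProfile("mercaptopurine", "L01BB02", 0.04, true_ror=8.0,
                         tto_scale_alpha=120.0, tto_shape_beta=0.6),
        SynthDrugProfile("letrozole", "L02BG04", 0.07, true_ror=5.0,
                         tto_scale_alpha=86.0, tto_shape_beta=0.95),
        SynthDrugProfile("pemetrexed", "L01BA04", 0.04, true_ror=4.0,
                         tto_scale_alpha=45.0, tto_shape_beta=3.0),
        SynthDrugProfile("carboplatin", "L01XA02", 0.05, true_ror=1.0,
                         tto_scale_alpha=64.0, tto_shape_beta=1.2),
        SynthDrugProfile("rituximab", "L01FA01", 0.05, true_ror=1.0,
                         tto_scale_alpha=49.0, tto_shape_beta=0.6),
    ]
    # fatal cases onset on roughly half the scale of non-fatal ones,
    # mirroring the shorter fatal time-to-onset seen in reporting data
    return SynthConfig(n_reports=n_reports, drug_profiles=profiles, seed=seed,
                       baseline_event_rate=0.02, fatal_tto_scale_factor=0.5)
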