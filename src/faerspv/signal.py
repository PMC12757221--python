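"""Disproportionality analysis on 2x2 contingency tables.

For a target (drug, event) pair the spontaneous-reporting corpus is collapsed
into the classic 2x2 table

    =============  ==============  =============
    .              target event    other events
    =============  ==============  =============
    target drug         a               b
    other drugs         c               d
    =============  ==============  =============

and four frequentist/Bayesian-flavoured statistics are computed with their
usual signal criteria:

* ROR  = (a/c)/(b/d), signal if lower 95% CI > 1 and a >= 3
* PRR  = (a/(a+b))/(c/(c+d)) with Pearson's chi-square (no continuity
  correction), signal if chi2 >= 4, PRR >= 2 and a >= 3
* EBGM = a*N/((a+b)(a+c)) (the observed/expected relative reporting ratio,
  reported without empirical-Bayes shrinkage), signal if EBGM05 > 2
* IC   = log2 of the same ratio, signal if IC025 > 0 and a > 0

Interval bounds share a single log-scale variance term
v = 1/a + 1/b + 1/c + 1/d:

* ROR 95% CI  : exp(ln ROR +- 1.96 sqrt(v))
* EBGM05      : exp(ln EBGM - 1.645 sqrt(v))   (one-sided 95% lower bound)
* IC025       : IC - 1.96 sqrt(v)/ln 2

Zero cells receive no Haldane correction by default: a table with a zero cell
yields point estimates where finite but absent interval bounds and all flags
False; a zero marginal yields no scores at all, with a structured reason
rather than propagated infinities. An optional +0.5 continuity correction is
available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .faers_io import CaseReport

__all__ = [
    "ContingencyTable",
    "SignalScores",
    "build_contingency",
    "score_signal",
    "compute_signal_table",
    "rank_signals",
    "SIGNAL_TABLE_COLUMNS",
]

_Z_TWO_SIDED = 1.959963984540054  # Phi^-1(0.975)
_Z_ONE_SIDED = 1.6448536269514722  # Phi^-1(0.95)


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a, b, c, d of the drug-by-event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v!r}")
        if self.n == 0:
            raise ValueError("empty table: a+b+c+d must be positive")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self, k: float = 0.5) -> "ContingencyTable":
        """Haldane-style continuity correction (adds k to every cell)."""
        t = object.__new__(ContingencyTable)
        object.__setattr__(t, "a", self.a + k)
        object.__setattr__(t, "b", self.b + k)
        object.__setattr__(t, "c", self.c + k)
        object.__setattr__(t, "d", self.d + k)
        return t


@dataclass
class SignalScores:
    """Point estimates, interval bounds and per-algorithm signal flags."""

    n_cases: int
    ror: float | None = None
    ror_ci95: tuple[float, float] | None = None
    prr: float | None = None
    chi2: float | None = None
    ebgm: float | None = None
    ebgm05: float | None = None
    ic: float | None = None
    ic025: float | None = None
    ror_signal: bool = False
    prr_signal: bool = False
    mgps_signal: bool = False
    bcpnn_signal: bool = False
    reason: str | None = None


def _pearson_chi2(a: float, b: float, c: float, d: float) -> float:
    """Pearson's chi-square over the four cells, no continuity correction."""
    n = a + b + c + d
    total = 0.0
    for obs, row, col in (
        (a, a + b, a + c),
        (b, a + b, b + d),
        (c, c + d, a + c),
        (d, c + d, b + d),
    ):
        exp = row * col / n
        total += (obs - exp) ** 2 / exp
    return total


def score_signal(t: ContingencyTable, continuity_correction: bool = False) -> SignalScores:
    """Compute all four disproportionality statistics for one table.

    Returns a :class:`SignalScores`; when a marginal is zero the scores are
    absent and ``reason`` explains why. When a single cell is zero, finite
    point estimates are reported but interval bounds are absent and every
    signal flag is False (unless ``continuity_correction`` adds 0.5 to each
    cell, in which case the corrected table is scored normally).
    """
    n_cases = t.a
    work = t
    if continuity_correction and min(t.a, t.b, t.c, t.d) == 0:
        work = t.corrected()

    a, b, c, d = float(work.a), float(work.b), float(work.c), float(work.d)
    n = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        return SignalScores(n_cases=n_cases, reason="zero marginal")

    scores = SignalScores(n_cases=n_cases)
    scores.chi2 = _pearson_chi2(a, b, c, d)
    if a > 0:
        scores.ebgm = a * n / ((a + b) * (a + c))
        scores.ic = math.log2(scores.ebgm)
        scores.prr = (a / (a + b)) / (c / (c + d)) if c > 0 else None
        scores.ror = (a / c) / (b / d) if (b > 0 and c > 0) else None

    if min(a, b, c, d) == 0:
        scores.reason = "zero cell: interval bounds unavailable"
        return scores

    v = 1 / a + 1 / b + 1 / c + 1 / d
    sv = math.sqrt(v)
    ln_ror = math.log(scores.ror)
    scores.ror_ci95 = (
        math.exp(ln_ror - _Z_TWO_SIDED * sv),
        math.exp(ln_ror + _Z_TWO_SIDED * sv),
    )
    scores.ebgm05 = math.exp(math.log(scores.ebgm) - _Z_ONE_SIDED * sv)
    scores.ic025 = scores.ic - _Z_TWO_SIDED * sv / math.log(2)

    scores.ror_signal = scores.ror_ci95[0] > 1 and n_cases >= 3
    scores.prr_signal = scores.chi2 >= 4 and scores.prr >= 2 and n_cases >= 3
    scores.mgps_signal = scores.ebgm05 > 2
    scores.bcpnn_signal = scores.ic025 > 0 and n_cases > 0
    return scores


def _is_exposed(report: CaseReport, drug: str) -> bool:
    key = drug.strip().casefold()
    return any(
        (e.drugname_norm or "").strip().casefold() == key for e in report.ps_drugs()
    )


def build_contingency(
    reports: Sequence[CaseReport], drug: str, target_pt: str
) -> ContingencyTable:
    """Cross-tabulate one normalized drug name against the target PT.

    Exposure is attribution to a Primary Suspect drug whose normalized name
    matches ``drug``; the event is presence of ``target_pt`` among the
    report's reaction PTs. Reports are assumed de-duplicated and normalized.
    A drug absent from the corpus yields a valid table with a = b = 0.
    """
    a = b = c = d = 0
    pt = target_pt.strip().casefold()
    for rep in reports:
        exposed = _is_exposed(rep, drug)
        event = any(p.strip().casefold() == pt for p in rep.reaction_pts)
        if exposed and event:
            a += 1
        elif exposed:
            b += 1
        elif event:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


#: Fixed column order of the signal table CSV.
SIGNAL_TABLE_COLUMNS = [
    "drug", "atc_code", "cases", "ror", "ror_ci_low", "ror_ci_high",
    "prr", "chi2", "ebgm", "ebgm05", "ic", "ic025",
    "ror_signal", "prr_signal", "mgps_signal", "bcpnn_signal",
]


def compute_signal_table(
    reports: Sequence[CaseReport],
    target_pt: str,
    drugs: Iterable[str] | None = None,
    atc_codes: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Score every drug (default: all normalized PS drug names in the corpus).

    Returns one row per drug in :data:`SIGNAL_TABLE_COLUMNS` order, unsorted.
    """
    if drugs is None:
        seen: dict[str, None] = {}
        for rep in reports:
            for entry in rep.ps_drugs():
                if entry.drugname_norm:
                    seen.setdefault(entry.drugname_norm, None)
        drugs = list(seen)
    if atc_codes is None:
        atc_codes = {}
        for rep in reports:
            for entry in rep.ps_drugs():
                if entry.drugname_norm and entry.atc_code:
                    atc_codes.setdefault(entry.drugname_norm, entry.atc_code)

    records = []
    for drug in drugs:
        table = build_contingency(reports, drug, target_pt)
        s = score_signal(table)
        records.append(
            {
                "drug": drug,
                "atc_code": atc_codes.get(drug, ""),
                "cases": s.n_cases,
                "ror": s.ror,
                "ror_ci_low": s.ror_ci95[0] if s.ror_ci95 else None,
                "ror_ci_high": s.ror_ci95[1] if s.ror_ci95 else None,
                "prr": s.prr,
                "chi2": s.chi2,
                "ebgm": s.ebgm,
                "ebgm05": s.ebgm05,
                "ic": s.ic,
                "ic025": s.ic025,
                "ror_signal": s.ror_signal,
                "prr_signal": s.prr_signal,
                "mgps_signal": s.mgps_signal,
                "bcpnn_signal": s.bcpnn_signal,
            }
        )
    return pd.DataFrame.from_records(records, columns=SIGNAL_TABLE_COLUMNS)


def rank_signals(score_table: pd.DataFrame) -> pd.DataFrame:
    """Keep ROR-positive drugs and rank them by descending ROR.

    The ROR criterion (lower 95% CI > 1 with at least 3 cases) is the primary
    signal definition; the other three flags travel along for reporting. A
    ``rank`` column (1-based) is prepended. Ties on ROR break by drug name
    for a stable, reproducible order.
    """
    kept = score_table[score_table["ror_signal"]].copy()
    kept = kept.sort_values(["ror", "drug"], ascending=[False, True], kind="mergesort")
    kept.insert(0, "rank", range(1, len(kept) + 1))
    return kept.reset_index(drop=True)
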