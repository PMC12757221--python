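"""Time-to-onset (TTO) analysis: Weibull fitting and failure-type labels.

TTO is the interval in whole days between therapy start (THER.START_DT) and
the adverse-event date (DEMO.EVENT_DT). Rows with missing, partial or
invalid dates, or an event preceding the start, are excluded and tallied by
reason. Same-day onsets are recorded as 1 day: the two-parameter Weibull has
positive support and spontaneous reports do carry genuine same-day events.

The Weibull density with scale alpha (days) and shape beta is

    f(t) = (beta/alpha) * (t/alpha)**(beta-1) * exp(-(t/alpha)**beta),  t > 0.

Maximum likelihood uses the profile likelihood: for fixed beta the scale
optimum is alpha(beta) = (sum(t**beta)/n)**(1/beta), leaving a monotone
one-dimensional score equation in beta. Wald 95% confidence intervals come
from the inverse observed information on the NATURAL parameter scale — with
small samples or large variance the lower bound can be negative, which is a
property of the convention, not a bug.

The hazard interpretation of beta drives the failure-type label:

* early failure    — beta < 1 with 95% CI entirely below 1 (falling hazard)
* random failure   — 95% CI encompassing 1 (roughly constant hazard)
* wear-out failure — beta > 1 with 95% CI entirely above 1 (rising hazard)

Subgroup TTO comparisons use the two-sided Wilcoxon rank-sum test, with
exact enumeration for small samples (both n <= 8) and the normal
approximation with tie correction otherwise.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateSampleError, InsufficientDataError
from .faers_io import CaseReport, classify_date

__all__ = [
    "TTOSample",
    "TTOExclusionLog",
    "WeibullFit",
    "GroupComparison",
    "compute_tto",
    "median_iqr",
    "fit_weibull",
    "classify_failure",
    "bin_onsets",
    "compare_groups",
]

_Z = 1.959963984540054

EARLY = "early"
RANDOM = "random"
WEAR_OUT = "wear_out"


@dataclass
class TTOSample:
    """Onset intervals (days, each >= 1) attributed to one drug."""

    drug: str
    onsets: list[int] = field(default_factory=list)


@dataclass
class TTOExclusionLog:
    """Flow accounting for TTO extraction: included + excluded-by-reason."""

    n_included: int = 0
    excluded: Counter = field(default_factory=Counter)

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())


def compute_tto(
    reports: Iterable[CaseReport],
) -> tuple[dict[str, TTOSample], TTOExclusionLog]:
    """Extract per-drug onset intervals from (case) reports.

    Each Primary Suspect drug entry contributes one interval when both the
    therapy start date and the report's event date are complete valid 8-digit
    dates and the event does not precede the start. A 0-day difference is
    recorded as 1 day. Every excluded entry is tallied by reason
    (``missing/partial/invalid`` for either date, or ``negative interval``);
    nothing is silently dropped.
    """
    samples: dict[str, TTOSample] = {}
    log = TTOExclusionLog()
    for rep in reports:
        event_status = classify_date(rep.event_dt_raw)
        for entry in rep.ps_drugs():
            drug = entry.drugname_norm or entry.drugname_raw.strip().casefold()
            start_status = classify_date(entry.start_dt_raw)
            if event_status != "ok":
                log.excluded[f"{event_status} event date"] += 1
                continue
            if start_status != "ok":
                log.excluded[f"{start_status} start date"] += 1
                continue
            days = (rep.event_dt - entry.start_dt).days
            if days < 0:
                log.excluded["negative interval"] += 1
                continue
            samples.setdefault(drug, TTOSample(drug=drug)).onsets.append(max(days, 1))
            log.n_included += 1
    return samples, log


def median_iqr(onsets: Sequence[float]) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics."""
    if len(onsets) == 0:
        raise InsufficientDataError("median_iqr requires at least one onset")
    arr = np.asarray(onsets, dtype=float)
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


@dataclass
class WeibullFit:
    """Weibull ML fit with natural-scale Wald intervals and the failure label."""

    alpha: float
    alpha_ci95: tuple[float, float]
    beta: float
    beta_ci95: tuple[float, float]
    n: int
    failure_type: str
    converged: bool
    loglik: float


def weibull_loglik(alpha: float, beta: float, t: np.ndarray) -> float:
    """Log-likelihood of the two-parameter Weibull at (alpha, beta)."""
    n = len(t)
    z = t / alpha
    return float(
        n * math.log(beta)
        - n * beta * math.log(alpha)
        + (beta - 1) * np.log(t).sum()
        - np.power(z, beta).sum()
    )


def _profile_score(beta: float, t: np.ndarray, mean_log_t: float) -> float:
    # d/d(beta) of the profile log-likelihood; strictly decreasing in beta.
    tb = np.power(t, beta)
    return 1 / beta + mean_log_t - float((tb * np.log(t)).sum() / tb.sum())


def _observed_information(alpha: float, beta: float, t: np.ndarray) -> np.ndarray:
    """Negative Hessian of the log-likelihood at (alpha, beta), analytic."""
    n = len(t)
    u = np.power(t / alpha, beta)
    w = np.log(t / alpha)
    s = u.sum()
    d2_aa = (beta / alpha**2) * (n - s) - (beta**2 / alpha**2) * s
    d2_bb = -n / beta**2 - float((u * w**2).sum())
    d2_ab = (s - n) / alpha + (beta / alpha) * float((u * w).sum())
    return -np.array([[d2_aa, d2_ab], [d2_ab, d2_bb]])


def fit_weibull(onsets: Sequence[float], min_n: int = 3) -> WeibullFit:
    """Maximum-likelihood Weibull fit via the profile likelihood.

    Parameters
    ----------
    onsets
        Strictly positive onset times (days). ``n >= min_n`` required.

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_n`` observations.
    DegenerateSampleError
        All onsets identical — the shape diverges (beta -> infinity) and the
        fit is rejected rather than reported at the boundary.
    """
    t = np.asarray(onsets, dtype=float)
    if len(t) < min_n:
        raise InsufficientDataError(f"need >= {min_n} onsets, got {len(t)}")
    if np.any(t <= 0):
        raise ValueError("onsets must be strictly positive")
    if np.ptp(t) == 0:
        raise DegenerateSampleError("all onsets identical: shape parameter diverges")

    mean_log_t = float(np.log(t).mean())
    lo, hi = 1e-3, 1.0
    while _profile_score(hi, t, mean_log_t) > 0 and hi < 1e4:
        hi *= 2
    converged = True
    try:
        beta = optimize.brentq(
            _profile_score, lo, hi, args=(t, mean_log_t), xtol=1e-12, rtol=1e-14
        )
    except ValueError:
        beta = hi
        converged = False
    alpha = float((np.power(t, beta).mean()) ** (1 / beta))

    info = _observed_information(alpha, beta, t)
    try:
        cov = np.linalg.inv(info)
        se_alpha, se_beta = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    except (np.linalg.LinAlgError, ValueError):
        converged = False
        se_alpha = se_beta = math.nan

    alpha_ci = (alpha - _Z * se_alpha, alpha + _Z * se_alpha)
    beta_ci = (beta - _Z * se_beta, beta + _Z * se_beta)
    return WeibullFit(
        alpha=alpha,
        alpha_ci95=alpha_ci,
        beta=beta,
        beta_ci95=beta_ci,
        n=len(t),
        failure_type=classify_failure(beta, beta_ci) if converged else RANDOM,
        converged=converged,
        loglik=weibull_loglik(alpha, beta, t),
    )


def classify_failure(beta: float, beta_ci95: tuple[float, float]) -> str:
    """Map a shape estimate and its 95% CI to a failure-type label.

    Early iff the CI lies entirely below 1, wear-out iff entirely above 1,
    random otherwise — exhaustive and mutually exclusive by construction.
    """
    low, high = beta_ci95
    if low > high:
        raise ValueError("CI bounds out of order")
    if high < 1:
        return EARLY
    if low > 1:
        return WEAR_OUT
    return RANDOM


def bin_onsets(onsets: Sequence[float], width: int = 30) -> pd.DataFrame:
    """Histogram onsets into right-closed bins [1, width], [width+1, 2*width], ...

    Returns columns ``bin_start, bin_end, count, proportion``; proportions sum
    to 1. Empty input yields an empty frame.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    cols = ["bin_start", "bin_end", "count", "proportion"]
    if len(onsets) == 0:
        return pd.DataFrame(columns=cols)
    arr = np.asarray(onsets)
    idx = (arr - 1) // width
    counts = Counter(int(i) for i in idx)
    total = len(arr)
    records = [
        {
            "bin_start": i * width + 1,
            "bin_end": (i + 1) * width,
            "count": counts[i],
            "proportion": counts[i] / total,
        }
        for i in range(max(counts) + 1)
    ]
    return pd.DataFrame.from_records(records, columns=cols)


@dataclass
class GroupComparison:
    median_a: float
    median_b: float
    p_value: float
    method: str  # "exact" or "normal"


def _exact_ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact Wilcoxon rank-sum p by enumerating all group splits.

    Uses midranks for ties; the p-value is the fraction of the
    C(n_a + n_b, n_a) equally likely assignments whose rank sum deviates from
    its null mean at least as much as the observed one.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a, n_total = len(a), len(pooled)
    mu = n_a * (n_total + 1) / 2
    w_obs = ranks[:n_a].sum()
    d_obs = abs(w_obs - mu) - 1e-9  # guard against float fuzz on tied sums
    hits = total = 0
    for combo in itertools.combinations(range(n_total), n_a):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= d_obs:
            hits += 1
    return hits / total


def compare_groups(
    onsets_a: Sequence[float], onsets_b: Sequence[float]
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of two onset samples.

    Exact enumeration when both groups have at most 8 observations, otherwise
    the normal approximation with tie correction (and continuity correction).
    """
    a = np.asarray(onsets_a, dtype=float)
    b = np.asarray(onsets_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise InsufficientDataError("both groups must be non-empty")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if len(a) <= 8 and len(b) <= 8:
        return GroupComparison(med_a, med_b, _exact_ranksum_p(a, b), "exact")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupComparison(med_a, med_b, float(res.pvalue), "normal")
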