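"""Published reference values for antineoplastic-agent hepatotoxicity in FAERS.

These are the summary statistics reported by a published FAERS
disproportionality study of hepatotoxicity with anti-neoplastic agents
(2004 Q1 - 2024 Q3): the 30 agents with the highest reporting odds ratios,
their time-to-onset / Weibull results, and the demographic breakdown of the
4,195 de-duplicated hepatotoxicity case reports. They serve as fixed inputs
for convention cross-checks (e.g. that IC equals log2(EBGM) at printed
precision, that the failure-type rule reproduces every printed label, and
that the tabulation conventions reproduce the printed percentages) — they
are not outputs of this package.

Notes: one agent (doxorubicin) has no Weibull fit in the source (dashes);
two agents (mercaptopurine, methotrexate) carry identical TTO rows there,
kept verbatim here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SignalRow",
    "WeibullRow",
    "TOP30_SIGNALS",
    "TOP30_WEIBULL",
    "CASE_DEMOGRAPHICS",
    "TOTAL_CASES",
]


@dataclass(frozen=True)
class SignalRow:
    rank: int
    atc: str
    drug: str
    cases: int
    ror: float
    ror_low: float
    ror_high: float
    prr: float
    chi2: float
    ebgm: float
    ebgm05: float
    ic: float
    ic025: float


TOP30_SIGNALS: list[SignalRow] = [
    SignalRow(1, "L01BB02", "mercaptopurine", 67, 26.57, 20.84, 33.89, 25.89, 1599.01, 25.8, 21.05, 4.69, 4.33),
    SignalRow(2, "L01XX24", "pegaspargase", 60, 13.67, 10.59, 17.64, 13.49, 692.46, 13.45, 10.87, 3.75, 3.38),
    SignalRow(3, "L01FX07", "blinatumomab", 85, 11.93, 9.63, 14.78, 11.8, 837.18, 11.75, 9.82, 3.55, 3.24),
    SignalRow(4, "L02BG04", "letrozole", 221, 11.01, 9.63, 12.58, 10.9, 1965.08, 10.78, 9.64, 3.43, 3.23),
    SignalRow(5, "L01EA02", "dasatinib", 299, 10.25, 9.14, 11.5, 10.16, 2431.52, 10.01, 9.09, 3.32, 3.15),
    SignalRow(6, "L01EF02", "ribociclib", 141, 8.42, 7.13, 9.94, 8.36, 907.11, 8.3, 7.22, 3.05, 2.81),
    SignalRow(7, "L01EF03", "abemaciclib", 86, 7.3, 5.9, 9.03, 7.25, 461.7, 7.22, 6.04, 2.85, 2.54),
    SignalRow(8, "L01EX03", "pazopanib", 174, 7.05, 6.07, 8.19, 7.01, 888.74, 6.95, 6.13, 2.8, 2.58),
    SignalRow(9, "L01EC01", "vemurafenib", 65, 6.87, 5.38, 8.77, 6.82, 322.34, 6.8, 5.55, 2.77, 2.41),
    SignalRow(10, "L01BC01", "cytarabine", 74, 6.13, 4.88, 7.71, 6.1, 314.5, 6.08, 5.02, 2.6, 2.27),
    SignalRow(11, "L01DB01", "doxorubicin", 198, 6.06, 5.27, 6.98, 6.03, 823.4, 5.98, 5.32, 2.58, 2.37),
    SignalRow(12, "L01BA01", "methotrexate", 766, 6.01, 5.59, 6.46, 5.98, 3052.02, 5.78, 5.44, 2.53, 2.42),
    SignalRow(13, "L01EC02", "dabrafenib", 72, 5.49, 4.35, 6.92, 5.46, 261.75, 5.45, 4.48, 2.45, 2.11),
    SignalRow(14, "L01FF02", "pembrolizumab", 245, 5.23, 4.61, 5.93, 5.2, 822.33, 5.15, 4.63, 2.36, 2.18),
    SignalRow(15, "L01FX04", "ipilimumab", 91, 5.15, 4.19, 6.34, 5.13, 301.66, 5.11, 4.3, 2.35, 2.05),
    SignalRow(16, "L01EH01", "lapatinib", 62, 5.04, 3.92, 6.47, 5.01, 198.84, 5.0, 4.06, 2.32, 1.96),
    SignalRow(17, "L01FF05", "atezolizumab", 106, 4.87, 4.02, 5.9, 4.85, 322.47, 4.83, 4.11, 2.27, 1.99),
    SignalRow(18, "L01BA04", "pemetrexed", 61, 4.81, 3.74, 6.19, 4.79, 182.52, 4.78, 3.87, 2.26, 1.89),
    SignalRow(19, "L01FD01", "trastuzumab", 146, 4.31, 3.66, 5.08, 4.3, 367.19, 4.27, 3.73, 2.1, 1.86),
    SignalRow(20, "L01EK01", "axitinib", 54, 3.53, 2.7, 4.62, 3.52, 97.39, 3.52, 2.81, 1.81, 1.42),
    SignalRow(21, "L01XA02", "carboplatin", 147, 3.39, 2.88, 3.99, 3.38, 245.11, 3.36, 2.94, 1.75, 1.51),
    SignalRow(22, "L01EX09", "nintedanib", 71, 3.35, 2.66, 4.24, 3.35, 116.47, 3.34, 2.75, 1.74, 1.4),
    SignalRow(23, "L01AA01", "cyclophosphamide", 97, 3.2, 2.62, 3.91, 3.19, 145.54, 3.18, 2.69, 1.67, 1.38),
    SignalRow(24, "L01FA01", "rituximab", 306, 3.15, 2.82, 3.53, 3.15, 441.13, 3.11, 2.83, 1.64, 1.47),
    SignalRow(25, "L01EA01", "imatinib", 176, 3.06, 2.64, 3.55, 3.05, 240.84, 3.03, 2.68, 1.6, 1.38),
    SignalRow(26, "L04AC07", "tocilizumab", 176, 3.06, 2.64, 3.55, 3.06, 241.4, 3.04, 2.68, 1.6, 1.38),
    SignalRow(27, "L01CD01", "paclitaxel", 108, 2.98, 2.46, 3.6, 2.97, 140.47, 2.96, 2.53, 1.57, 1.29),
    SignalRow(28, "L01BC05", "gemcitabine", 78, 2.92, 2.34, 3.65, 2.92, 97.95, 2.91, 2.41, 1.54, 1.21),
    SignalRow(29, "L01FF01", "nivolumab", 188, 2.89, 2.5, 3.33, 2.88, 228.65, 2.86, 2.54, 1.52, 1.31),
    SignalRow(30, "L01XA03", "oxaliplatin", 88, 2.76, 2.24, 3.4, 2.75, 98.03, 2.75, 2.3, 1.46, 1.15),
]


@dataclass(frozen=True)
class WeibullRow:
    rank: int
    drug: str
    cases: int
    median: float
    q1: float
    q3: float
    alpha: float | None
    alpha_low: float | None
    alpha_high: float | None
    beta: float | None
    beta_low: float | None
    beta_high: float | None
    label: str | None  # "early", "random", "wear_out" or None when unfitted


TOP30_WEIBULL: list[WeibullRow] = [
    WeibullRow(1, "mercaptopurine", 67, 72, 10.5, 315, 235.14, 17.16, 453.11, 0.43, 0.31, 0.55, "early"),
    WeibullRow(2, "pegaspargase", 60, 1, 1, 7.5, 4.66, -2.33, 11.64, 0.80, 0.11, 1.50, "random"),
    WeibullRow(3, "blinatumomab", 85, 4, 1, 10, 11.30, -0.87, 23.46, 0.54, 0.34, 0.74, "early"),
    WeibullRow(4, "letrozole", 221, 51, 27.5, 91, 86.35, 64.58, 108.12, 0.93, 0.78, 1.07, "random"),
    WeibullRow(5, "dasatinib", 299, 64, 36, 94.5, 68.87, -1.38, 139.12, 1.16, 0.03, 2.29, "random"),
    WeibullRow(6, "ribociclib", 141, 26, 10.5, 114.5, 70.14, -9.90, 150.19, 0.69, 0.30, 1.08, "random"),
    WeibullRow(7, "abemaciclib", 86, 60, 21, 84, 76.99, 16.45, 137.53, 0.88, 0.45, 1.31, "random"),
    WeibullRow(8, "pazopanib", 174, 40.5, 21, 49, 49.52, 30.08, 68.97, 1.13, 0.81, 1.44, "random"),
    WeibullRow(9, "vemurafenib", 65, 43.5, 12, 56.25, 48.53, 19.13, 77.92, 1.08, 0.57, 1.59, "random"),
    WeibullRow(10, "cytarabine", 74, 15, 12, 15, 15.77, 10.28, 21.26, 2.64, 0.77, 4.52, "random"),
    WeibullRow(11, "doxorubicin", 198, 1, None, None, None, None, None, None, None, None, None),
    WeibullRow(12, "methotrexate", 766, 72, 10.5, 315, 235.14, 17.16, 453.11, 0.43, 0.31, 0.55, "early"),
    WeibullRow(13, "dabrafenib", 72, 107, 58, 195, 184.32, 83.89, 284.74, 0.93, 0.61, 1.24, "random"),
    WeibullRow(14, "pembrolizumab", 245, 50.5, 21, 71.75, 73.55, 36.59, 110.50, 0.84, 0.61, 1.08, "random"),
    WeibullRow(15, "ipilimumab", 91, 44, 22, 96, 82.92, 41.31, 124.52, 0.91, 0.63, 1.18, "random"),
    WeibullRow(16, "lapatinib", 62, 42, 36, 91, 77.21, 48.73, 105.70, 1.46, 0.91, 2.01, "random"),
    WeibullRow(17, "atezolizumab", 106, 27, 19.5, 112.5, 74.98, 37.45, 112.50, 0.75, 0.55, 0.94, "early"),
    WeibullRow(18, "pemetrexed", 61, 41, 41, 41, 45.17, 37.09, 53.25, 3.10, 1.94, 4.26, "wear_out"),
    WeibullRow(19, "trastuzumab", 146, 49, 23, 101, 212.76, 32.21, 393.31, 0.54, 0.37, 0.71, "early"),
    WeibullRow(20, "axitinib", 54, 19, 11.5, 37, 27.13, -1.67, 55.93, 1.12, 0.09, 2.16, "random"),
    WeibullRow(21, "carboplatin", 147, 45, 31, 78.5, 63.91, 40.60, 87.23, 1.17, 0.78, 1.56, "random"),
    WeibullRow(22, "nintedanib", 71, 9.5, 3.5, 71, 33.34, -13.08, 79.77, 0.61, 0.23, 0.99, "early"),
    WeibullRow(23, "cyclophosphamide", 97, 37, 16, 63, 39.10, -8.55, 86.75, 0.84, 0.12, 1.55, "random"),
    WeibullRow(24, "rituximab", 306, 25, 9, 39, 48.73, -13.87, 111.34, 0.61, 0.28, 0.94, "early"),
    WeibullRow(25, "imatinib", 176, 75.5, 53.75, 87.75, 73.85, 37.88, 109.82, 2.09, 0.23, 3.95, "random"),
    WeibullRow(26, "tocilizumab", 176, 18, 7.25, 40.75, 29.90, -1.40, 61.20, 0.99, 0.24, 1.75, "random"),
    WeibullRow(27, "paclitaxel", 108, 56, 32, 73, 55.94, 42.16, 69.72, 1.82, 1.18, 2.46, "wear_out"),
    WeibullRow(28, "gemcitabine", 78, 19.5, 5.5, 54.5, 35.06, -11.22, 81.33, 0.79, 0.19, 1.39, "random"),
    WeibullRow(29, "nivolumab", 188, 47.5, 20.25, 71, 68.38, 50.14, 86.61, 1.06, 0.85, 1.27, "random"),
    WeibullRow(30, "oxaliplatin", 88, 10.5, 4, 14, 16.36, 3.01, 29.71, 0.90, 0.46, 1.35, "random"),
]

#: Total de-duplicated hepatotoxicity case reports in the reference study.
TOTAL_CASES = 4195

#: Stratum counts of the reference case series, by dimension.
CASE_DEMOGRAPHICS: dict[str, dict[str, int]] = {
    "gender": {"Female": 1949, "Male": 1121, "Missing": 1125},
    "age": {"<18": 237, "18-64.9": 1512, "65-85": 709, ">85": 21, "Missing": 1716},
    "weight": {"<50": 97, "50-100": 558, ">100": 64, "Missing": 3476},
    "outcome": {
        "Death": 439,
        "Disability": 21,
        "Hospitalization": 725,
        "Life-Threatening": 188,
        "Other and Unknown": 2822,
    },
}
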