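"""Shared demographic stratification conventions.

Age bins follow the reporting convention <18, 18-64.9, 65-85, >85 years;
weight bins <50, 50-100, >100 kg. Missing values get an explicit "Missing"
level so that reports with absent demographics stay in every analysis.
"""

from __future__ import annotations

MISSING = "Missing"

AGE_LEVELS = ["<18", "18-64.9", "65-85", ">85", MISSING]
WEIGHT_LEVELS = ["<50", "50-100", ">100", MISSING]
SEX_LEVELS = ["Female", "Male", MISSING]


def age_group(age_years: float | None) -> str:
    if age_years is None:
        return MISSING
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64.9"
    if age_years <= 85:
        return "65-85"
    return ">85"


def weight_group(weight_kg: float | None) -> str:
    if weight_kg is None:
        return MISSING
    if weight_kg < 50:
        return "<50"
    if weight_kg <= 100:
        return "50-100"
    return ">100"


def sex_group(sex: str | None) -> str:
    if sex == "F":
        return "Female"
    if sex == "M":
        return "Male"
    return MISSING
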