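"""Descriptive cohort tables: demographics, outcomes, time to onset.

Reproduces the layout of a study's "basic information" table for each
drug cohort: sex, age (mean +/- SD of unit-normalized years), reporter
country, reporter occupation, outcome distribution, and days from
therapy start to event binned 0-7 / 7-28 / 28-60 / >=60 / Unknown.  An
Unknown category absorbs all missingness in every block, so counts
always sum to the cohort's report total.

Outcome reporting uses a severity precedence (Death > Hospitalization >
Life threatening > Disability > Other serious > Unknown): FAERS allows
several outcome codes per report, but descriptive tables that sum to
100% need each report counted once, at its most severe outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .faers_io import CaseReport, percentage, round2

__all__ = [
    "ProfileTable", "demographic_summary", "outcome_distribution",
    "onset_bins", "dili_profile", "OUTCOME_PRECEDENCE",
]

#: (code(s), label) in decreasing severity; first match wins.
OUTCOME_PRECEDENCE = [
    (("DE",), "Death"),
    (("HO",), "Hospitalization-initial or prolonged"),
    (("LT",), "Life threatening"),
    (("DS",), "Disability"),
    (("OT", "CA", "RI"), "Other serious outcomes"),
]

REPORTER_LABELS = {
    "MD": "Physician",
    "PH": "Pharmacist",
    "CN": "Consumer",
    "OT": "Other health professionals",
    "HP": "Other health professionals",
}

COUNTRY_LABELS = {"US": "United States", "JP": "Japan", "CN": "China"}

ONSET_BINS = [(0, 7, "0-7"), (7, 28, "7-28"), (28, 60, "28-60")]


@dataclass
class ProfileTable:
    drug: str
    total: int
    age_mean: Optional[float] = None
    age_sd: Optional[float] = None
    age_n: int = 0
    age_all_missing: bool = False
    age_sd_degenerate: bool = False
    #: block name -> list of (category, count, percent)
    blocks: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("Total", "", self.total, 100.0)]
        if self.age_mean is not None:
            rows.append(("Age (years)", "mean", self.age_mean, math.nan))
            rows.append(("Age (years)", "sd", self.age_sd, math.nan))
        for name, cats in self.blocks.items():
            for cat, count, pct in cats:
                rows.append((name, cat, count, pct))
        return pd.DataFrame(rows, columns=["block", "category", "count", "percent"])


def _filter_drug(cases: Sequence[CaseReport], drug: str,
                 ps_only: bool = True) -> list[CaseReport]:
    roles = ("PS",) if ps_only else ("PS", "SS", "C", "I")
    return [
        c for c in cases
        if any(name == drug and role in roles for name, role in c.drugs)
    ]


def _block(pairs: list[tuple[str, int]], total: int) -> list[tuple[str, int, float]]:
    return [(cat, n, percentage(n, total) if total else 0.0) for cat, n in pairs]


def _sex_block(cohort: Sequence[CaseReport], total: int):
    counts = {"Female": 0, "Male": 0, "Unknown": 0}
    for c in cohort:
        if c.sex == "F":
            counts["Female"] += 1
        elif c.sex == "M":
            counts["Male"] += 1
        else:
            counts["Unknown"] += 1
    return _block(list(counts.items()), total)


def _country_block(cohort: Sequence[CaseReport], total: int):
    order = ["United States", "Japan", "China", "Other", "Unknown"]
    counts = {k: 0 for k in order}
    for c in cohort:
        if c.country is None:
            counts["Unknown"] += 1
        else:
            counts[COUNTRY_LABELS.get(c.country.upper(), "Other")] += 1
    return _block([(k, counts[k]) for k in order], total)


def _reporter_block(cohort: Sequence[CaseReport], total: int):
    order = ["Physician", "Consumer", "Pharmacist",
             "Other health professionals", "Unknown"]
    counts = {k: 0 for k in order}
    for c in cohort:
        counts[REPORTER_LABELS.get(c.reporter or "", "Unknown")] += 1
    return _block([(k, counts[k]) for k in order], total)


def _outcome_block(cohort: Sequence[CaseReport], total: int):
    labels = [label for _, label in OUTCOME_PRECEDENCE] + ["Unknown"]
    counts = {k: 0 for k in labels}
    for c in cohort:
        for codes, label in OUTCOME_PRECEDENCE:
            if any(code in c.outcomes for code in codes):
                counts[label] += 1
                break
        else:
            counts["Unknown"] += 1
    return _block([(k, counts[k]) for k in labels], total)


def _onset_block(cohort: Sequence[CaseReport], total: int):
    labels = [label for _, _, label in ONSET_BINS] + [">=60", "Unknown"]
    counts = {k: 0 for k in labels}
    for c in cohort:
        if c.event_date is None or c.therapy_start is None:
            counts["Unknown"] += 1
            continue
        days = (c.event_date - c.therapy_start).days
        if days < 0:
            counts["Unknown"] += 1
            continue
        for lo, hi, label in ONSET_BINS:
            if lo <= days < hi:
                counts[label] += 1
                break
        else:
            counts[">=60"] += 1
    return _block([(k, counts[k]) for k in labels], total)


def _profile(cohort: list[CaseReport], drug: str) -> ProfileTable:
    total = len(cohort)
    table = ProfileTable(drug=drug, total=total)
    ages = [c.age_years for c in cohort if c.age_years is not None]
    table.age_n = len(ages)
    if not ages:
        table.age_all_missing = True
    else:
        mean = sum(ages) / len(ages)
        if len(ages) < 2:
            sd, table.age_sd_degenerate = 0.0, True
        else:
            sd = math.sqrt(sum((x - mean) ** 2 for x in ages) / (len(ages) - 1))
        table.age_mean, table.age_sd = round2(mean), round2(sd)
    table.blocks["Sex"] = _sex_block(cohort, total)
    table.blocks["Reporter country"] = _country_block(cohort, total)
    table.blocks["Reporter"] = _reporter_block(cohort, total)
    table.blocks["Outcome"] = _outcome_block(cohort, total)
    table.blocks["Onset (days)"] = _onset_block(cohort, total)
    return table


def demographic_summary(cases: Sequence[CaseReport], drug: str,
                        ps_only: bool = True) -> ProfileTable:
    """Full descriptive profile of one drug's (deduplicated) cohort."""
    cohort = _filter_drug(cases, drug, ps_only)
    if not cohort:
        raise ValueError(f"no reports for drug {drug!r}")
    return _profile(cohort, drug)


def outcome_distribution(cases: Sequence[CaseReport], drug: str,
                         ps_only: bool = True) -> list[tuple[str, int, float]]:
    """Severity-precedence outcome block alone."""
    cohort = _filter_drug(cases, drug, ps_only)
    return _outcome_block(cohort, len(cohort))


def onset_bins(cases: Sequence[CaseReport], drug: str,
               ps_only: bool = True) -> list[tuple[str, int, float]]:
    """Time-to-onset block alone (event date minus earliest therapy start)."""
    cohort = _filter_drug(cases, drug, ps_only)
    return _onset_block(cohort, len(cohort))


def dili_profile(cases: Sequence[CaseReport], drug: str,
                 ps_only: bool = True) -> ProfileTable:
    """Profile restricted to reports carrying the consolidated "DILI"
    event; a drug with zero DILI reports yields an all-zero profile."""
    cohort = [c for c in _filter_drug(cases, drug, ps_only) if "DILI" in c.pts]
    if not cohort:
        return ProfileTable(drug=drug, total=0, age_all_missing=True)
    return _profile(cohort, drug)
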