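"""Case deduplication for re-submitted spontaneous reports.

A FAERS case (CASEID) accumulates one report row (PRIMARYID) per
submission or follow-up.  Counting each submission would inflate every
disproportionality statistic, so within each case exactly one report is
kept, following the FDA-recommended rules: take the submission with the
latest FDA receipt date (FDA_DT); if receipt dates tie, take the higher
PRIMARYID (the later version).  A report with a missing FDA_DT loses all
tie-breaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

from .faers_io import CaseReport

__all__ = ["DedupReport", "deduplicate"]


@dataclass
class DedupReport:
    kept: list[CaseReport]
    removed_count: int
    rule_tally: dict[str, int] = field(default_factory=dict)


def _primaryid_key(pid: str, width: int) -> str:
    # numeric-style comparison: left-zero-pad to the group's max width,
    # then compare lexicographically (exact for digit strings, a sane
    # fallback otherwise)
    return pid.rjust(width, "0")


def deduplicate(cases: Sequence[CaseReport]) -> DedupReport:
    """Collapse each CASEID group to a single report.

    Deterministic: output sorted by caseid.  ``rule_tally`` counts how
    often each rule decided a group ('latest_fda_dt', 'higher_primaryid')
    and how many candidates had a missing FDA_DT ('missing_fda_dt').
    """
    groups: dict[str, list[CaseReport]] = {}
    for case in cases:
        groups.setdefault(case.caseid, []).append(case)

    tally = {"latest_fda_dt": 0, "higher_primaryid": 0, "missing_fda_dt": 0}
    kept: list[CaseReport] = []
    for caseid in sorted(groups):
        group = groups[caseid]
        if len(group) == 1:
            kept.append(group[0])
            continue
        tally["missing_fda_dt"] += sum(1 for c in group if c.fda_dt is None)
        width = max(len(c.primaryid) for c in group)
        best = max(
            group,
            key=lambda c: (c.fda_dt or date.min, _primaryid_key(c.primaryid, width)),
        )
        dates = {c.fda_dt for c in group}
        if len(dates) > 1:
            tally["latest_fda_dt"] += 1
        # ties on the winning date are broken by primaryid
        if sum(1 for c in group if c.fda_dt == best.fda_dt) > 1:
            tally["higher_primaryid"] += 1
        kept.append(best)
    return DedupReport(kept, len(cases) - len(kept), tally)
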