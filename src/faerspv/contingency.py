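"""2x2 contingency tables for drug-event disproportionality.

Every comparison is report-level: a deduplicated safety report either
mentions the target drug (as primary suspect, by default) or not, and
either lists the target event or not, so the four cells partition the
report set.  The background is the whole ingested dataset minus the
drug's reports, mirroring the "target drug vs rest of the database"
design of spontaneous-reporting-system analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = ["ContingencyTable", "count_cells", "all_tables"]

Level = Literal["PT", "SOC"]


@dataclass(frozen=True)
class ContingencyTable:
    """Cell counts (a, b, c, d) for one drug-event pair.

    a : reports with target drug and target event
    b : reports with target drug, without target event
    c : reports with target event, without target drug
    d : reports with neither

    Cells are floats so the same container can hold the generator's exact
    expected counts; observed tables carry integral values.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be nonnegative")
        if self.n <= 0:
            raise ValueError("contingency table is empty (N == 0)")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected(self) -> float:
        """Expected a under independence: E = (a+b)(a+c)/N."""
        return (self.a + self.b) * (self.a + self.c) / self.n

    def transposed(self) -> "ContingencyTable":
        """Swap the drug and event roles (b and c exchange)."""
        return ContingencyTable(self.a, self.c, self.b, self.d)


def _event_sets(case, level: Level, hierarchy) -> set[str]:
    """Events a report contributes to at the requested level."""
    if level == "PT":
        return set(case.pts)
    if hierarchy is None:
        raise ValueError("SOC-level counting requires a PT->SOC hierarchy")
    return {hierarchy.soc_of(pt) for pt in case.pts}


def _has_drug(case, drug: str, ps_only: bool) -> bool:
    roles = ("PS",) if ps_only else ("PS", "SS", "C", "I")
    return any(name == drug and role in roles for name, role in case.drugs)


def count_cells(
    cases: Sequence,
    drug: str,
    event: str,
    level: Level = "PT",
    hierarchy=None,
    ps_only: bool = True,
) -> ContingencyTable:
    """Count the 2x2 table for one drug-event pair.

    ``cases`` must already be deduplicated and, if a consolidated event
    such as "DILI" is analysed, consolidated.  A report counts once in
    the drug margin however many qualifying PTs it lists; at SOC level it
    is in the event margin if at least one PT maps to the SOC.
    """
    if not cases:
        raise ValueError("empty case list")
    a = b = c = d = 0
    for case in cases:
        drug_hit = _has_drug(case, drug, ps_only)
        event_hit = event in _event_sets(case, level, hierarchy)
        if drug_hit and event_hit:
            a += 1
        elif drug_hit:
            b += 1
        elif event_hit:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def all_tables(
    cases: Sequence,
    drug: str,
    level: Level = "PT",
    hierarchy=None,
    ps_only: bool = True,
) -> list[tuple[str, ContingencyTable]]:
    """One table per event observed with the drug (a >= 1), in one pass.

    Events never co-reported with the drug are omitted.  For a fixed case
    set every returned table has the same N (the report count), and the
    per-event ``a`` values sum to the number of (report, event) pairs of
    the drug's reports.
    """
    if not cases:
        raise ValueError("empty case list")
    n_total = len(cases)
    n_drug = 0
    a_counts: dict[str, int] = {}
    event_margin: dict[str, int] = {}
    for case in cases:
        events = _event_sets(case, level, hierarchy)
        drug_hit = _has_drug(case, drug, ps_only)
        if drug_hit:
            n_drug += 1
        for ev in events:
            event_margin[ev] = event_margin.get(ev, 0) + 1
            if drug_hit:
                a_counts[ev] = a_counts.get(ev, 0) + 1
    out = []
    for ev in sorted(a_counts):
        a = a_counts[ev]
        b = n_drug - a
        c = event_margin[ev] - a
        d = n_total - a - b - c
        out.append((ev, ContingencyTable(a, b, c, d)))
    return out
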