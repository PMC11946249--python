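"""Drug-name canonicalisation, PT->SOC mapping and DILI consolidation.

FAERS drug names are free text: the same active substance appears under
generic and brand spellings, arbitrary case and stray whitespace.  A
``DrugDictionary`` maps those verbatim strings to canonical study-drug
ids.  Adverse events are MedDRA Preferred Terms (PTs), each rolled up to
one of ~27 System Organ Classes (SOCs); since MedDRA is licensed, the
package ships a synthetic hierarchy covering the terms it generates and
accepts a user-supplied mapping for real data.

Liver-injury analysis uses a consolidated case definition: every PT in a
configurable lexicon is replaced by the single event "DILI" before the
drug search, so one report with several liver PTs contributes one DILI
event.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "DrugDictionary", "MedDRAHierarchy", "PTLexicon", "UnknownPTError",
    "canonicalize_drug", "map_pt_to_soc", "consolidate_dili",
    "default_drug_dictionary", "default_hierarchy", "default_dili_lexicon",
    "default_exclusions", "normalize_term",
]


def normalize_term(text: str) -> str:
    """Case-fold and collapse internal/surrounding whitespace."""
    return " ".join(text.lower().split())


def _data_text(name: str) -> str:
    return resources.files("faerspv.data").joinpath(name).read_text("utf-8")


class UnknownPTError(KeyError):
    """A PT missing from the hierarchy (collected, not fatal, pipeline-side)."""


@dataclass
class DrugDictionary:
    """canonical drug id -> set of verbatim spellings (case-insensitive)."""

    spellings: dict[str, set[str]]

    def __post_init__(self) -> None:
        norm: dict[str, set[str]] = {}
        seen: dict[str, str] = {}
        for drug, names in self.spellings.items():
            cleaned = {normalize_term(n) for n in names}
            for n in cleaned:
                if n in seen and seen[n] != drug:
                    raise ValueError(
                        f"spelling {n!r} claimed by both {seen[n]!r} and {drug!r}"
                    )
                seen[n] = drug
            norm[drug] = cleaned
        self.spellings = norm
        self._lookup = seen

    @property
    def drugs(self) -> list[str]:
        return sorted(self.spellings)

    def canonicalize(self, verbatim: str) -> Optional[str]:
        return self._lookup.get(normalize_term(verbatim))

    @classmethod
    def from_yaml(cls, path=None) -> "DrugDictionary":
        text = _data_text("drug_dictionary.yaml") if path is None \
            else Path(path).read_text("utf-8")
        raw = yaml.safe_load(text)
        return cls({drug: set(names) for drug, names in raw.items()})


@dataclass
class MedDRAHierarchy:
    """Total map PT -> primary SOC on the analysis vocabulary."""

    pt_to_soc: dict[str, str]

    def __post_init__(self) -> None:
        self.pt_to_soc = {
            normalize_term(pt): soc for pt, soc in self.pt_to_soc.items()
        }

    @property
    def socs(self) -> list[str]:
        return sorted(set(self.pt_to_soc.values()))

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self.pt_to_soc

    def soc_of(self, pt: str) -> str:
        key = normalize_term(pt)
        try:
            return self.pt_to_soc[key]
        except KeyError:
            raise UnknownPTError(pt) from None

    @classmethod
    def from_yaml(cls, path=None) -> "MedDRAHierarchy":
        """Load a SOC -> [PTs] YAML document (the bundled synthetic
        hierarchy when ``path`` is None)."""
        text = _data_text("meddra_synthetic.yaml") if path is None \
            else Path(path).read_text("utf-8")
        raw = yaml.safe_load(text)
        mapping: dict[str, str] = {}
        for soc, pts in raw.items():
            for pt in pts:
                mapping[pt] = soc
        return cls(mapping)


@dataclass
class PTLexicon:
    """A named set of PTs to consolidate into one event (e.g. "DILI")."""

    name: str
    terms: set[str]

    def __post_init__(self) -> None:
        if not self.terms:
            raise ValueError("lexicon must be nonempty")
        self.terms = {normalize_term(t) for t in self.terms}

    def __contains__(self, pt: str) -> bool:
        return normalize_term(pt) in self.terms

    @classmethod
    def from_yaml(cls, path=None) -> "PTLexicon":
        text = _data_text("dili_lexicon.yaml") if path is None \
            else Path(path).read_text("utf-8")
        raw = yaml.safe_load(text)
        return cls(name=raw["name"], terms=set(raw["terms"]))


def canonicalize_drug(verbatim: str, dictionary: DrugDictionary) -> Optional[str]:
    """Exact case-insensitive, whitespace-normalized match; None if unmatched
    (a verbatim name outside the study dictionary is a valid outcome)."""
    return dictionary.canonicalize(verbatim)


def map_pt_to_soc(pt: str, hierarchy: MedDRAHierarchy) -> str:
    """Primary SOC of a PT; raises UnknownPTError for terms outside the
    hierarchy."""
    return hierarchy.soc_of(pt)


def consolidate_dili(case, lexicon: PTLexicon):
    """Replace every lexicon PT of a report by the lexicon's event name.

    Returns a new CaseReport; the PT set is deduplicated, so a report
    listing several liver PTs contributes a single consolidated event.
    Idempotent, and never increases the PT count.
    """
    hit = any(pt in lexicon for pt in case.pts)
    if not hit:
        return case
    new_case = copy.copy(case)
    new_pts = {pt for pt in case.pts if pt not in lexicon}
    new_pts.add(lexicon.name)
    new_case.pts = new_pts
    return new_case


def default_drug_dictionary() -> DrugDictionary:
    return DrugDictionary.from_yaml(None)


def default_hierarchy() -> MedDRAHierarchy:
    return MedDRAHierarchy.from_yaml(None)


def default_dili_lexicon() -> PTLexicon:
    return PTLexicon.from_yaml(None)


def default_exclusions() -> dict[str, list[str]]:
    """Ranking-stage PT exclusion patterns (death, COVID, malignancy lists)."""
    return yaml.safe_load(_data_text("exclusions.yaml"))
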