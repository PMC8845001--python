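"""Kinship degrees, parental lineage sides, and counting scopes.

Every relationship label maps to a degree of relatedness (1 = parents,
siblings, children; 2 = grandparents, aunts/uncles, half-siblings,
nieces/nephews, grandchildren; 3 = first cousins) and to the subset of
parental lineages the person belongs to.  The bilateral-lineage convention:
the proband, full siblings and descendants carry BOTH sides, so one
same-side evaluation can combine, say, the proband's own diagnosis with a
paternal aunt's.  The mapping ships as a data file so the label vocabulary
can be extended without code changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional

from .fhx import Pedigree, Person
from .vocabulary import VocabularyError, _read_tsv

__all__ = [
    "KinshipTable",
    "default_kinship_table",
    "relation_degree",
    "sides_of",
    "annotate",
    "scope_members",
    "mirror_label",
    "mirror_pedigree",
    "SCOPES",
    "SIDES",
]

SCOPES = ("self", "first_degree", "close", "close_or_self", "any", "any_or_self")
SIDES = ("maternal", "paternal", "either")

#: Lineage mirror: swap maternal- and paternal-side labels.
_MIRROR_PAIRS = [
    ("mother", "father"),
    ("maternal_grandmother", "paternal_grandmother"),
    ("maternal_grandfather", "paternal_grandfather"),
    ("maternal_aunt", "paternal_aunt"),
    ("maternal_uncle", "paternal_uncle"),
    ("maternal_half_sister", "paternal_half_sister"),
    ("maternal_half_brother", "paternal_half_brother"),
    ("maternal_cousin", "paternal_cousin"),
]
_MIRROR: Dict[str, str] = {}
for a, b in _MIRROR_PAIRS:
    _MIRROR[a] = b
    _MIRROR[b] = a


@dataclass(frozen=True)
class KinEntry:
    degree: int
    sides: FrozenSet[str]
    expected_sex: Optional[str]


class KinshipTable:
    """Total mapping from relationship label to degree and lineage sides."""

    def __init__(self, entries: Dict[str, KinEntry]):
        for label, e in entries.items():
            if not e.sides:
                raise ValueError(f"kinship entry {label!r} has empty sides")
        self._entries = dict(entries)

    def labels(self) -> List[str]:
        return list(self._entries)

    def entry(self, label: str) -> KinEntry:
        try:
            return self._entries[label]
        except KeyError:
            raise VocabularyError(f"unknown relation label {label!r}") from None

    def degree(self, label: str) -> int:
        return self.entry(label).degree

    def sides(self, label: str) -> FrozenSet[str]:
        return self.entry(label).sides

    def expected_sex(self, label: str) -> Optional[str]:
        return self.entry(label).expected_sex


def load_kinship_table(path: Optional[Path] = None) -> KinshipTable:
    if path is None:
        path = Path(str(resources.files("fhxscreen").joinpath("data", "kinship.tsv")))
    entries = {}
    for label, degree, sides, sex in _read_tsv(path):
        entries[label] = KinEntry(
            degree=int(degree),
            sides=frozenset(s for s in sides.split("|") if s),
            expected_sex=sex or None,
        )
    return KinshipTable(entries)


_DEFAULT: Optional[KinshipTable] = None


def default_kinship_table() -> KinshipTable:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_kinship_table()
    return _DEFAULT


def relation_degree(label: str) -> int:
    """Degree of relatedness of a relation label (0 for the proband)."""
    return default_kinship_table().degree(label)


def sides_of(label: str) -> FrozenSet[str]:
    """The parental lineage side(s) a relation label belongs to."""
    return default_kinship_table().sides(label)


def mirror_label(label: str) -> str:
    """Swap a label's maternal/paternal lineage (identity for both-side labels)."""
    return _MIRROR.get(label, label)


def mirror_pedigree(pedigree: Pedigree) -> Pedigree:
    """Relabel every relative maternal<->paternal; recorded sexes are kept."""
    out = pedigree.copy()
    for p in out.persons():
        p.relation = mirror_label(p.relation)
        p.degree = None
        p.sides = None
    return annotate(out)


def annotate(pedigree: Pedigree, table: Optional[KinshipTable] = None) -> Pedigree:
    """Set the derived ``degree`` and ``sides`` annotations on every person."""
    table = table or default_kinship_table()
    for p in pedigree.persons():
        p.degree = table.degree(p.relation)
        p.sides = table.sides(p.relation)
    return pedigree


def _in_scope(degree: int, scope: str, close_degree: int) -> bool:
    if scope == "self":
        return degree == 0
    if scope == "first_degree":
        return degree == 1
    if scope == "close":
        return 1 <= degree <= close_degree
    if scope == "close_or_self":
        return degree <= close_degree
    if scope == "any":
        return degree >= 1
    if scope == "any_or_self":
        return True
    raise ValueError(f"unknown scope {scope!r}")


def scope_members(
    pedigree: Pedigree,
    scope: str,
    side: str = "either",
    close_degree: int = 2,
) -> List[Person]:
    """Persons whose degree falls in *scope* and whose lineage covers *side*.

    ``side='either'`` imposes no lineage filter.  The result is sorted by
    person id so downstream witness selection is deterministic.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    if side not in SIDES:
        raise ValueError(f"unknown side {side!r}")
    if not pedigree.annotated:
        annotate(pedigree)
    out = [
        p
        for p in pedigree.persons()
        if _in_scope(p.degree, scope, close_degree)
        and (side == "either" or side in p.sides)
    ]
    return sorted(out, key=lambda p: p.id)
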