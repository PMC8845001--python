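"""Controlled vocabularies for the hereditary-cancer screening domain.

The engine never hard-codes clinical concepts: cancers (with subtype
subsumption), genes, syndromes, disease factors, histologies, hormone
statuses, lateralities, tissue origins, polyp types, ancestries, traits and
sexes all live in editable tab-separated tables shipped with the package.
Concept ids are ``lower_snake_case`` and matched case-insensitively, with
alias support (``"ER_Positive"`` resolves to ``er_positive``).
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Set

__all__ = [
    "VocabularyError",
    "Concept",
    "ConceptTable",
    "default_table",
    "FEMALE_ONLY_CANCERS",
    "MALE_ONLY_CANCERS",
]


class VocabularyError(KeyError):
    """Raised when a term does not resolve to a known concept."""


@dataclass(frozen=True)
class Concept:
    id: str
    category: str
    parent_id: Optional[str] = None
    label: str = ""
    aliases: tuple = ()


#: Cancer sites that are anatomically restricted to one sex; used by payload
#: validation (sex-site consistency) and by the test-case generator when it
#: picks relatives to carry a diagnosis.
FEMALE_ONLY_CANCERS = frozenset(
    {"ovarian", "fallopian_tube", "primary_peritoneal", "endometrial", "cervical", "vulvar", "vaginal"}
)
MALE_ONLY_CANCERS = frozenset({"prostate", "testicular", "penile"})

#: Derived hormone-status alias: triple-negative breast disease is the
#: conjunction of the three receptor-negative flags.
TRIPLE_NEGATIVE_EXPANSION = frozenset({"er_negative", "pr_negative", "her2_negative"})


def _norm(term: str) -> str:
    term = unicodedata.normalize("NFKC", term).strip().lower()
    return term.replace("-", "_").replace(" ", "_")


class ConceptTable:
    """In-memory index over all concept categories.

    Subsumption (``is_a``) is defined by the ``parent_id`` links in the
    cancer table: a subtype such as ``lobular_breast`` *is a* ``breast``
    cancer, so a criterion predicate written against ``breast`` also matches
    the subtype after compile-time expansion.
    """

    def __init__(self, concepts: Iterable[Concept], syndrome_genes: Dict[str, FrozenSet[str]]):
        self._concepts: Dict[str, Concept] = {}
        self._lookup: Dict[str, str] = {}
        self._children: Dict[str, List[str]] = {}
        self._syndrome_genes = dict(syndrome_genes)
        for c in concepts:
            if c.id in self._concepts:
                raise VocabularyError(f"duplicate concept id {c.id!r}")
            self._concepts[c.id] = c
            self._lookup[_norm(c.id)] = c.id
            for a in c.aliases:
                self._lookup.setdefault(_norm(a), c.id)
            if c.parent_id:
                self._children.setdefault(c.parent_id, []).append(c.id)
        for c in self._concepts.values():
            if c.parent_id and c.parent_id not in self._concepts:
                raise VocabularyError(f"{c.id!r} has unknown parent {c.parent_id!r}")
        for sid, genes in self._syndrome_genes.items():
            if sid not in self._concepts:
                raise VocabularyError(f"syndrome-gene map references unknown syndrome {sid!r}")
            for g in genes:
                if g not in self._concepts:
                    raise VocabularyError(f"syndrome {sid!r} references unknown gene {g!r}")
        # acyclicity of the subsumption links
        for cid in self._concepts:
            seen = set()
            cur: Optional[str] = cid
            while cur is not None:
                if cur in seen:
                    raise VocabularyError(f"subsumption cycle through {cid!r}")
                seen.add(cur)
                cur = self._concepts[cur].parent_id

    # -- lookup ---------------------------------------------------------

    def __contains__(self, concept_id: str) -> bool:
        return concept_id in self._concepts

    def get(self, concept_id: str) -> Concept:
        try:
            return self._concepts[concept_id]
        except KeyError:
            raise VocabularyError(f"unknown concept id {concept_id!r}") from None

    def label(self, concept_id: str) -> str:
        return self.get(concept_id).label or concept_id

    def category_of(self, concept_id: str) -> str:
        return self.get(concept_id).category

    def resolve(self, term: str, category: Optional[str] = None) -> str:
        """Case-insensitive, alias-aware lookup to the canonical id."""
        cid = self._lookup.get(_norm(term))
        if cid is not None and (category is None or self._concepts[cid].category == category):
            return cid
        near = self._nearest(term, category)
        want = f" in category {category!r}" if category else ""
        hint = f" (nearest: {', '.join(near)})" if near else ""
        raise VocabularyError(f"unknown term {term!r}{want}{hint}")

    def _nearest(self, term: str, category: Optional[str], k: int = 3) -> List[str]:
        import difflib

        pool = [
            key
            for key, cid in self._lookup.items()
            if category is None or self._concepts[cid].category == category
        ]
        return difflib.get_close_matches(_norm(term), pool, n=k)

    # -- subsumption ----------------------------------------------------

    def is_a(self, concept_id: str, ancestor_id: str) -> bool:
        """True iff *concept_id* equals *ancestor_id* or is a transitive subtype."""
        self.get(ancestor_id)
        cur: Optional[str] = self.get(concept_id).id
        while cur is not None:
            if cur == ancestor_id:
                return True
            cur = self._concepts[cur].parent_id
        return False

    def descendants(self, concept_id: str) -> Set[str]:
        """The concept together with all transitive subtypes."""
        out = {self.get(concept_id).id}
        stack = [concept_id]
        while stack:
            for child in self._children.get(stack.pop(), ()):
                if child not in out:
                    out.add(child)
                    stack.append(child)
        return out

    # -- domain helpers -------------------------------------------------

    def genes_for_syndrome(self, syndrome_id: str) -> FrozenSet[str]:
        c = self.get(syndrome_id)
        if c.category != "syndrome":
            raise VocabularyError(f"{syndrome_id!r} is not a syndrome")
        return self._syndrome_genes.get(c.id, frozenset())

    def expand_factors(self, terms: Iterable[str]) -> FrozenSet[str]:
        """Resolve disease-factor-like terms, expanding derived aliases.

        Accepts ids from the disease_factor, hormone_status, histology and
        tissue_origin categories, plus the derived alias ``triple_negative``.
        """
        out: Set[str] = set()
        for t in terms:
            if _norm(t) == "triple_negative":
                out |= TRIPLE_NEGATIVE_EXPANSION
                continue
            cid = self.resolve(t)
            if self.category_of(cid) not in {
                "disease_factor",
                "hormone_status",
                "histology",
                "tissue_origin",
            }:
                raise VocabularyError(f"{t!r} is not a disease factor concept")
            out.add(cid)
        return frozenset(out)

    def counts(self) -> Dict[str, int]:
        """Concept tallies per category; cancer subtypes counted separately."""
        out: Dict[str, int] = {}
        for c in self._concepts.values():
            cat = c.category
            if cat == "cancer" and c.parent_id is not None:
                cat = "cancer_subtype"
            out[cat] = out.get(cat, 0) + 1
        return out

    def ids(self, category: str) -> List[str]:
        return sorted(c.id for c in self._concepts.values() if c.category == category)


# -- loading -------------------------------------------------------------


def _read_tsv(path: Path) -> List[List[str]]:
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                header = cells
                continue
            cells += [""] * (len(header) - len(cells))
            rows.append(cells)
    return rows


def load_table(data_dir: Optional[Path] = None) -> ConceptTable:
    """Load the concept tables shipped with the package (or from *data_dir*)."""
    if data_dir is None:
        data_dir = Path(str(resources.files("fhxscreen").joinpath("data")))
    concepts: List[Concept] = []
    for fname, category in (("cancers.tsv", "cancer"), ("genes.tsv", "gene"), ("syndromes.tsv", "syndrome")):
        for cid, parent, label, aliases in _read_tsv(data_dir / fname):
            concepts.append(
                Concept(cid, category, parent or None, label, tuple(a for a in aliases.split("|") if a))
            )
    for category, cid, parent, label, aliases in _read_tsv(data_dir / "misc_concepts.tsv"):
        concepts.append(
            Concept(cid, category, parent or None, label, tuple(a for a in aliases.split("|") if a))
        )
    syndrome_genes = {
        sid: frozenset(g for g in genes.split("|") if g)
        for sid, genes in _read_tsv(data_dir / "syndrome_genes.tsv")
    }
    return ConceptTable(concepts, syndrome_genes)


_DEFAULT: Optional[ConceptTable] = None


def default_table() -> ConceptTable:
    """The package's shipped vocabulary, loaded once per process."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_table()
    return _DEFAULT
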