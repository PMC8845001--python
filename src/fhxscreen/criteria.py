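"""Declarative clinical-practice-guideline criterion DSL and rulebase.

A criterion is an AND/OR tree whose leaves are *count clauses*: "at least
``min_count`` units in scope ``scope`` matching a predicate, on one side of
the family".  Units are either distinct individuals or distinct cancer
cases (one case per primary tumor; a bilateral diagnosis contributes two).
This mirrors how guideline thresholds are minimum-cardinality constraints
over a pedigree.  Criteria are negation-free: every clause is a monotone
lower bound, so adding history can only add met criteria.

The rulebase ships as a YAML document; predicates are compiled at load time
(vocabulary resolution, cancer-subtype expansion, derived-alias expansion)
and the load fails loudly on any id that does not resolve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Dict, FrozenSet, Iterator, List, Optional, Sequence, Tuple

import yaml

from .kinship import SCOPES
from .vocabulary import ConceptTable, VocabularyError, default_table

__all__ = [
    "RulebaseError",
    "Predicate",
    "CountClause",
    "Logic",
    "Criterion",
    "Rulebase",
    "load_rulebase",
    "default_rulebase",
    "rulebase_stats",
    "coverage_report",
]


class RulebaseError(ValueError):
    """Raised when a rulebase file cannot be compiled."""


@dataclass(frozen=True)
class Predicate:
    """What one counted unit must look like.

    Case-level fields (cancer site, ages, factors, laterality) constrain a
    diagnosis; person-level fields (sex, variants, syndromes, ancestry,
    polyps, ``min_primaries``) constrain the person carrying it.  At least
    one field must be set.  An unknown age at diagnosis never satisfies an
    age bound: criteria do not fire on missing data.
    """

    cancer_in: Optional[FrozenSet[str]] = None
    max_age_at_dx: Optional[int] = None
    min_age_at_dx: Optional[int] = None
    required_factors: FrozenSet[str] = frozenset()
    laterality: Optional[str] = None
    sex: Optional[str] = None
    min_primaries: Optional[int] = None
    variant_in: Optional[FrozenSet[str]] = None
    syndrome_in: Optional[FrozenSet[str]] = None
    ancestry_in: Optional[FrozenSet[str]] = None
    polyp_type: Optional[str] = None
    polyp_min_count: Optional[int] = None

    def is_empty(self) -> bool:
        return all(
            v in (None, frozenset())
            for v in (
                self.cancer_in,
                self.max_age_at_dx,
                self.min_age_at_dx,
                self.required_factors,
                self.laterality,
                self.sex,
                self.min_primaries,
                self.variant_in,
                self.syndrome_in,
                self.ancestry_in,
                self.polyp_type,
                self.polyp_min_count,
            )
        )

    @property
    def case_level(self) -> bool:
        """True if the predicate constrains individual diagnoses."""
        return self.cancer_in is not None or bool(self.required_factors) or (
            self.laterality is not None
            or self.max_age_at_dx is not None
            or self.min_age_at_dx is not None
        )


@dataclass(frozen=True)
class CountClause:
    """MIN-cardinality restriction: >= min_count units in scope matching predicate."""

    ref: str
    predicate: Predicate
    min_count: int = 1
    unit: str = "individuals"  # "individuals" | "cases"
    scope: str = "close_or_self"
    same_side: bool = True
    close_degree_override: Optional[int] = None
    distinct_from: FrozenSet[str] = frozenset()

    @property
    def close_degree(self) -> int:
        return self.close_degree_override if self.close_degree_override is not None else 2


@dataclass(frozen=True)
class Logic:
    """AND/OR tree; leaves hold count clauses. No negation (v1)."""

    op: str  # "and" | "or" | "leaf"
    children: Tuple["Logic", ...] = ()
    clause: Optional[CountClause] = None

    def leaves(self) -> Iterator[CountClause]:
        if self.op == "leaf":
            yield self.clause
        else:
            for c in self.children:
                yield from c.leaves()

    def branches(self) -> List[Tuple[CountClause, ...]]:
        """Disjunctive normal form: each branch is a set of clauses that
        must hold jointly for the criterion to be met."""
        if self.op == "leaf":
            return [(self.clause,)]
        if self.op == "or":
            out: List[Tuple[CountClause, ...]] = []
            for c in self.children:
                out.extend(c.branches())
            return out
        # and: cross-product of child branches
        combos: List[Tuple[CountClause, ...]] = [()]
        for c in self.children:
            combos = [a + b for a in combos for b in c.branches()]
        return combos


@dataclass(frozen=True)
class Criterion:
    """One guideline criterion: id ``<SOURCE>.<Group>.<NN>``, printed label,
    and the logic tree that encodes it."""

    id: str
    source: str  # "ACMG" | "NCCN"
    group: str
    label: str
    logic: Logic
    provenance: str = ""

    def clauses(self) -> List[CountClause]:
        return list(self.logic.leaves())

    def branches(self) -> List[Tuple[CountClause, ...]]:
        return self.logic.branches()

    @property
    def needs_side(self) -> bool:
        return any(c.same_side for c in self.clauses())


@dataclass
class Rulebase:
    """An ordered collection of compiled criteria."""

    criteria: List[Criterion]
    version: str = "1"
    vocabulary_version: str = ""

    def __iter__(self) -> Iterator[Criterion]:
        return iter(self.criteria)

    def __len__(self) -> int:
        return len(self.criteria)

    def get(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(criterion_id)

    def filter(self, sources: Sequence[str]) -> "Rulebase":
        """Sub-rulebase restricted to the given guideline sources."""
        wanted = {s.upper() for s in sources}
        unknown = wanted - {c.source for c in self.criteria} - {"ACMG", "NCCN"}
        if unknown:
            raise RulebaseError(f"unknown guideline source(s): {sorted(unknown)}")
        return Rulebase(
            [c for c in self.criteria if c.source in wanted],
            version=self.version,
            vocabulary_version=self.vocabulary_version,
        )

    def labels(self) -> Dict[str, str]:
        return {c.id: c.label for c in self.criteria}


# -- compilation ----------------------------------------------------------

_CLAUSE_KEYS = {
    "ref",
    "cancer",
    "max_age_at_dx",
    "min_age_at_dx",
    "factors",
    "laterality",
    "sex",
    "min_primaries",
    "variants",
    "syndromes",
    "ancestry",
    "polyp_type",
    "polyp_min_count",
    "min_count",
    "unit",
    "scope",
    "same_side",
    "close_degree",
    "distinct_from",
}


def _err(cid: str, msg: str) -> RulebaseError:
    return RulebaseError(f"criterion {cid}: {msg}")


def _compile_clause(cid: str, obj: dict, table: ConceptTable, counter: List[int]) -> CountClause:
    if not isinstance(obj, dict):
        raise _err(cid, "clause must be a mapping")
    unknown = set(obj) - _CLAUSE_KEYS
    if unknown:
        raise _err(cid, f"unknown clause key(s) {sorted(unknown)}")

    def resolve_set(key: str, category: Optional[str]) -> Optional[FrozenSet[str]]:
        if key not in obj or obj[key] is None:
            return None
        terms = obj[key] if isinstance(obj[key], list) else [obj[key]]
        try:
            return frozenset(table.resolve(t, category) for t in terms)
        except VocabularyError as exc:
            raise _err(cid, f"field {key!r}: {exc}") from None

    cancers = resolve_set("cancer", "cancer")
    if cancers is not None:
        expanded = set()
        for c in cancers:
            expanded |= table.descendants(c)
        cancers = frozenset(expanded)
    try:
        factors = table.expand_factors(obj.get("factors") or [])
    except VocabularyError as exc:
        raise _err(cid, f"field 'factors': {exc}") from None
    laterality = obj.get("laterality")
    if laterality is not None and laterality not in ("left", "right", "bilateral"):
        raise _err(cid, f"unknown laterality {laterality!r}")
    sex = obj.get("sex")
    if sex is not None and sex not in ("female", "male"):
        raise _err(cid, f"unknown sex {sex!r}")
    polyp_type = None
    if obj.get("polyp_type") is not None:
        try:
            polyp_type = table.resolve(obj["polyp_type"], "polyp_type")
        except VocabularyError as exc:
            raise _err(cid, f"field 'polyp_type': {exc}") from None
    pred = Predicate(
        cancer_in=cancers,
        max_age_at_dx=obj.get("max_age_at_dx"),
        min_age_at_dx=obj.get("min_age_at_dx"),
        required_factors=factors,
        laterality=laterality,
        sex=sex,
        min_primaries=obj.get("min_primaries"),
        variant_in=resolve_set("variants", "gene"),
        syndrome_in=resolve_set("syndromes", "syndrome"),
        ancestry_in=resolve_set("ancestry", "ancestry"),
        polyp_type=polyp_type,
        polyp_min_count=obj.get("polyp_min_count"),
    )
    if pred.is_empty():
        raise _err(cid, "clause predicate has no matching field set")
    if (
        pred.min_age_at_dx is not None
        and pred.max_age_at_dx is not None
        and pred.min_age_at_dx > pred.max_age_at_dx
    ):
        raise _err(cid, "min_age_at_dx > max_age_at_dx")
    min_count = int(obj.get("min_count", 1))
    if min_count < 1:
        raise _err(cid, "min_count must be >= 1")
    unit = obj.get("unit", "individuals")
    if unit not in ("individuals", "cases"):
        raise _err(cid, f"unknown unit {unit!r}")
    if unit == "cases" and pred.cancer_in is None and not pred.required_factors:
        raise _err(cid, "unit 'cases' requires a cancer predicate")
    scope = obj.get("scope", "close_or_self")
    if scope not in SCOPES:
        raise _err(cid, f"unknown scope {scope!r}")
    counter[0] += 1
    ref = str(obj.get("ref") or f"c{counter[0]}")
    return CountClause(
        ref=ref,
        predicate=pred,
        min_count=min_count,
        unit=unit,
        scope=scope,
        same_side=bool(obj.get("same_side", True)),
        close_degree_override=obj.get("close_degree"),
        distinct_from=frozenset(obj.get("distinct_from") or []),
    )


def _compile_logic(cid: str, obj: dict, table: ConceptTable, counter: List[int]) -> Logic:
    if not isinstance(obj, dict) or len(obj) != 1:
        raise _err(cid, "logic node must be one of {clause: ...}, {all: [...]}, {any: [...]}")
    (op, body), = obj.items()
    if op == "clause":
        return Logic("leaf", clause=_compile_clause(cid, body, table, counter))
    if op in ("all", "any"):
        if not isinstance(body, list) or not body:
            raise _err(cid, f"{op!r} needs a non-empty list")
        children = tuple(_compile_logic(cid, b, table, counter) for b in body)
        return Logic("and" if op == "all" else "or", children=children)
    if op == "not":
        raise _err(cid, "negation is not supported (criteria are monotone lower bounds)")
    raise _err(cid, f"unknown logic operator {op!r}")


def _compile_criterion(obj: dict, table: ConceptTable) -> Criterion:
    cid = str(obj.get("id") or "").strip()
    if not cid:
        raise RulebaseError("criterion without id")
    source = str(obj.get("source") or "").strip().upper()
    if source not in ("ACMG", "NCCN"):
        raise _err(cid, f"unknown source {obj.get('source')!r}")
    group = str(obj.get("group") or "").strip()
    if not group:
        raise _err(cid, "missing group")
    label = str(obj.get("label") or "").strip()
    if not label:
        raise _err(cid, "missing label")
    if "logic" in obj:
        logic_obj = obj["logic"]
    elif "clause" in obj:
        logic_obj = {"clause": obj["clause"]}
    else:
        raise _err(cid, "missing logic")
    counter = [0]
    logic = _compile_logic(cid, logic_obj, table, counter)
    clauses = list(logic.leaves())
    refs = [c.ref for c in clauses]
    if len(refs) != len(set(refs)):
        raise _err(cid, "duplicate clause refs")
    for c in clauses:
        missing = c.distinct_from - set(refs)
        if missing:
            raise _err(cid, f"distinct_from references unknown clause(s) {sorted(missing)}")
        if c.ref in c.distinct_from:
            raise _err(cid, f"clause {c.ref!r} marked distinct from itself")
    return Criterion(
        id=cid,
        source=source,
        group=group,
        label=label,
        logic=logic,
        provenance=str(obj.get("provenance") or ""),
    )


def load_rulebase(path: Path, table: Optional[ConceptTable] = None) -> Rulebase:
    """Load and compile a rulebase file, verifying vocabulary closure."""
    table = table or default_table()
    try:
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    except FileNotFoundError:
        raise RulebaseError(f"rulebase file not found: {path}") from None
    except yaml.YAMLError as exc:
        raise RulebaseError(f"rulebase parse error in {path}: {exc}") from None
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise RulebaseError("rulebase document must be a mapping")
    raw = doc.get("criteria") or []
    criteria = [_compile_criterion(o, table) for o in raw]
    seen = set()
    for c in criteria:
        if c.id in seen:
            raise RulebaseError(f"duplicate criterion id {c.id}")
        seen.add(c.id)
    return Rulebase(
        criteria=criteria,
        version=str(doc.get("version", "1")),
        vocabulary_version=str(doc.get("vocabulary", "")),
    )


_DEFAULT: Optional[Rulebase] = None


def default_rulebase() -> Rulebase:
    """The rulebase shipped with the package (73 ACMG + 40 NCCN criteria)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_rulebase(
            Path(str(resources.files("fhxscreen").joinpath("data", "rulebase.yaml")))
        )
    return _DEFAULT


# -- statistics -----------------------------------------------------------


def rulebase_stats(rulebase: Rulebase) -> Dict[str, object]:
    """Exact criterion counts: total, per source, per (source, group)."""
    per_source: Dict[str, int] = {}
    per_group: Dict[str, Dict[str, int]] = {}
    for c in rulebase:
        per_source[c.source] = per_source.get(c.source, 0) + 1
        per_group.setdefault(c.source, {})
        per_group[c.source][c.group] = per_group[c.source].get(c.group, 0) + 1
    return {"total": len(rulebase), "per_source": per_source, "per_group": per_group}


def coverage_report(rulebase: Rulebase) -> Dict[str, List[str]]:
    """Distinct guideline groups present per source."""
    out: Dict[str, List[str]] = {}
    for c in rulebase:
        out.setdefault(c.source, [])
        if c.group not in out[c.source]:
            out[c.source].append(c.group)
    return {s: sorted(g) for s, g in out.items()}
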