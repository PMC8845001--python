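"""Family-health-history (FHx) data model and its JSON dialect.

The payload is a single proband object whose ``relatives`` list holds family
members in the exact same shape (minus ``relatives``).  All relationships are
labelled relative to the proband (``mother``, ``paternal_aunt``, ...); no
explicit parent-pointer graph is required.  Parsing canonicalizes vocabulary
terms case-insensitively, preserves unknown fields in a pass-through map, and
``write_fhx`` emits a canonical form (schema key order, nulls omitted,
sorted sets) that is stable across runs and round-trips byte-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, FrozenSet, Iterator, List, Optional, Tuple

from .vocabulary import (
    FEMALE_ONLY_CANCERS,
    MALE_ONLY_CANCERS,
    ConceptTable,
    VocabularyError,
    default_table,
)

__all__ = [
    "FhxError",
    "FhxParseError",
    "FhxSchemaError",
    "FhxSerializationError",
    "Finding",
    "CancerDiagnosis",
    "PolypRecord",
    "Person",
    "Pedigree",
    "RELATION_LABELS",
    "parse_fhx",
    "validate_fhx",
    "write_fhx",
]


class FhxError(ValueError):
    """Base class for FHx payload errors."""


class FhxParseError(FhxError):
    """The payload is not syntactically valid JSON."""


class FhxSchemaError(FhxError):
    """The payload violates the dialect's structural rules."""


class FhxSerializationError(FhxError):
    """A pedigree cannot be serialized (required field unset)."""


#: Closed relationship-label vocabulary, all relative to the proband.
RELATION_LABELS = (
    "self",
    "mother",
    "father",
    "sister",
    "brother",
    "daughter",
    "son",
    "maternal_grandmother",
    "maternal_grandfather",
    "paternal_grandmother",
    "paternal_grandfather",
    "maternal_aunt",
    "maternal_uncle",
    "paternal_aunt",
    "paternal_uncle",
    "maternal_half_sister",
    "maternal_half_brother",
    "paternal_half_sister",
    "paternal_half_brother",
    "niece",
    "nephew",
    "granddaughter",
    "grandson",
    "maternal_cousin",
    "paternal_cousin",
)

_SEXES = ("female", "male", "unknown")
_LATERALITIES = ("left", "right", "bilateral", "unknown")
_AGE_RANGE = (0, 130)


@dataclass(frozen=True)
class Finding:
    """One validation finding; findings are data, never exceptions."""

    level: str  # "error" | "warning"
    path: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.level}: {self.path}: {self.message}"


@dataclass
class CancerDiagnosis:
    """One primary cancer diagnosis of a person.

    ``primary_index`` distinguishes multiple primaries of the same site in
    one person; a ``bilateral`` laterality is counted as two cases by
    case-unit criteria.
    """

    cancer_type: str
    age_at_dx: Optional[int] = None
    laterality: str = "unknown"
    tissue_origin: Optional[str] = None
    histology: Optional[str] = None
    hormone_status: FrozenSet[str] = frozenset()
    factors: FrozenSet[str] = frozenset()
    primary_index: int = 1
    extra: Dict[str, object] = field(default_factory=dict)

    @property
    def all_factors(self) -> FrozenSet[str]:
        """Factor-like ids attached to this diagnosis, across categories."""
        out = set(self.factors) | set(self.hormone_status)
        if self.histology:
            out.add(self.histology)
        if self.tissue_origin:
            out.add(self.tissue_origin)
        return frozenset(out)


@dataclass
class PolypRecord:
    polyp_type: str
    count: int
    age: Optional[int] = None


@dataclass
class Person:
    """A proband or relative; ``degree``/``sides`` are derived annotations."""

    id: str
    relation: str
    sex: str = "unknown"
    current_age: Optional[int] = None
    deceased: Optional[bool] = None
    ancestry: FrozenSet[str] = frozenset()
    cancers: List[CancerDiagnosis] = field(default_factory=list)
    polyps: Optional[PolypRecord] = None
    variants: FrozenSet[str] = frozenset()
    syndromes: FrozenSet[str] = frozenset()
    extra: Dict[str, object] = field(default_factory=dict)
    degree: Optional[int] = None
    sides: Optional[FrozenSet[str]] = None

    def copy(self) -> "Person":
        return replace(
            self,
            ancestry=frozenset(self.ancestry),
            cancers=[replace(c, extra=dict(c.extra)) for c in self.cancers],
            polyps=replace(self.polyps) if self.polyps else None,
            variants=frozenset(self.variants),
            syndromes=frozenset(self.syndromes),
            extra=dict(self.extra),
        )


@dataclass
class Pedigree:
    """The proband plus labelled relatives."""

    proband: Person
    relatives: List[Person] = field(default_factory=list)
    extra: Dict[str, object] = field(default_factory=dict)

    def persons(self) -> Iterator[Person]:
        yield self.proband
        yield from self.relatives

    @property
    def annotated(self) -> bool:
        return all(p.degree is not None and p.sides is not None for p in self.persons())

    def copy(self) -> "Pedigree":
        return Pedigree(self.proband.copy(), [r.copy() for r in self.relatives], dict(self.extra))


# -- parsing --------------------------------------------------------------


def _canon(term: object, category: Optional[str], table: ConceptTable, strict: bool, path: str) -> str:
    if not isinstance(term, str) or not term.strip():
        raise FhxSchemaError(f"{path}: expected a non-empty string, got {term!r}")
    try:
        return table.resolve(term, category)
    except VocabularyError:
        if strict:
            raise FhxSchemaError(f"{path}: unresolvable vocabulary term {term!r}") from None
        return term.strip().lower().replace("-", "_").replace(" ", "_")


def _canon_set(terms: object, category: Optional[str], table: ConceptTable, strict: bool, path: str) -> FrozenSet[str]:
    if terms is None:
        return frozenset()
    if not isinstance(terms, list):
        raise FhxSchemaError(f"{path}: expected a list")
    return frozenset(_canon(t, category, table, strict, f"{path}[{i}]") for i, t in enumerate(terms))


def _opt_int(value: object, path: str) -> Optional[int]:
    if value is None:
        return None
    if isinstance(value, bool) or not isinstance(value, int):
        raise FhxSchemaError(f"{path}: expected an integer or null, got {value!r}")
    return value


_DX_KEYS = (
    "type",
    "age_at_dx",
    "laterality",
    "tissue_origin",
    "histology",
    "hormone_status",
    "factors",
    "primary_index",
)
_PERSON_KEYS = (
    "id",
    "relation",
    "sex",
    "age",
    "deceased",
    "ancestry",
    "cancers",
    "polyps",
    "variants",
    "syndromes",
)


def _parse_diagnosis(obj: object, table: ConceptTable, strict: bool, path: str) -> CancerDiagnosis:
    if not isinstance(obj, dict):
        raise FhxSchemaError(f"{path}: diagnosis must be an object")
    if "type" not in obj:
        raise FhxSchemaError(f"{path}: diagnosis missing 'type'")
    lat = obj.get("laterality")
    if lat is not None:
        lat = _canon(lat, "laterality", table, False, f"{path}.laterality")
    raw_hormones = obj.get("hormone_status") or []
    if not isinstance(raw_hormones, list):
        raise FhxSchemaError(f"{path}.hormone_status: expected a list")
    expanded: List[str] = []
    for h in raw_hormones:
        # derived alias: triple-negative = the three receptor-negative flags
        if isinstance(h, str) and h.strip().lower().replace("-", "_") == "triple_negative":
            expanded += ["er_negative", "pr_negative", "her2_negative"]
        else:
            expanded.append(h)
    hormones = _canon_set(expanded, None, table, strict, f"{path}.hormone_status")
    return CancerDiagnosis(
        cancer_type=_canon(obj["type"], "cancer", table, strict, f"{path}.type"),
        age_at_dx=_opt_int(obj.get("age_at_dx"), f"{path}.age_at_dx"),
        laterality=lat or "unknown",
        tissue_origin=(
            _canon(obj["tissue_origin"], None, table, strict, f"{path}.tissue_origin")
            if obj.get("tissue_origin")
            else None
        ),
        histology=(
            _canon(obj["histology"], None, table, strict, f"{path}.histology")
            if obj.get("histology")
            else None
        ),
        hormone_status=hormones,
        factors=_canon_set(obj.get("factors"), None, table, strict, f"{path}.factors"),
        primary_index=obj.get("primary_index", 0) or 0,  # 0 = auto-assign below
        extra={k: v for k, v in obj.items() if k not in _DX_KEYS},
    )


def _parse_person(obj: object, table: ConceptTable, strict: bool, path: str, is_proband: bool) -> Person:
    if not isinstance(obj, dict):
        raise FhxSchemaError(f"{path}: person must be an object")
    relation = obj.get("relation")
    if relation is None:
        raise FhxSchemaError(f"{path}: missing 'relation'")
    relation = str(relation).strip().lower()
    if strict and relation not in RELATION_LABELS:
        raise FhxSchemaError(f"{path}: unknown relation label {relation!r}")
    sex = str(obj.get("sex") or "unknown").strip().lower()
    if strict and sex not in _SEXES:
        raise FhxSchemaError(f"{path}: unknown sex {sex!r}")
    polyps = None
    if obj.get("polyps") is not None:
        pobj = obj["polyps"]
        if not isinstance(pobj, dict) or "type" not in pobj:
            raise FhxSchemaError(f"{path}.polyps: expected an object with 'type'")
        polyps = PolypRecord(
            polyp_type=_canon(pobj["type"], "polyp_type", table, strict, f"{path}.polyps.type"),
            count=int(pobj.get("count", 0)),
            age=_opt_int(pobj.get("age"), f"{path}.polyps.age"),
        )
    cancers = []
    if obj.get("cancers") is not None:
        if not isinstance(obj["cancers"], list):
            raise FhxSchemaError(f"{path}.cancers: expected a list")
        cancers = [
            _parse_diagnosis(d, table, strict, f"{path}.cancers[{i}]")
            for i, d in enumerate(obj["cancers"])
        ]
    # auto-assign primary indices per site in listed order
    counters: Dict[str, int] = {}
    for dx in cancers:
        if dx.primary_index <= 0:
            counters[dx.cancer_type] = counters.get(dx.cancer_type, 0) + 1
            dx.primary_index = counters[dx.cancer_type]
        else:
            counters[dx.cancer_type] = max(counters.get(dx.cancer_type, 0), dx.primary_index)
    extra_keys = set(_PERSON_KEYS) | ({"relatives"} if is_proband else set())
    return Person(
        id=str(obj.get("id") or ""),
        relation=relation,
        sex=sex,
        current_age=_opt_int(obj.get("age"), f"{path}.age"),
        deceased=obj.get("deceased") if isinstance(obj.get("deceased"), bool) else None,
        ancestry=_canon_set(obj.get("ancestry"), "ancestry", table, strict, f"{path}.ancestry"),
        cancers=cancers,
        polyps=polyps,
        variants=_canon_set(obj.get("variants"), "gene", table, strict, f"{path}.variants"),
        syndromes=_canon_set(obj.get("syndromes"), "syndrome", table, strict, f"{path}.syndromes"),
        extra={k: v for k, v in obj.items() if k not in extra_keys},
    )


def parse_fhx(payload: str, mode: str = "lenient", table: Optional[ConceptTable] = None) -> Pedigree:
    """Parse an FHx JSON payload into a :class:`Pedigree`.

    The root object is the proband (``relation`` must be ``self``) carrying a
    ``relatives`` list of same-shaped objects.  Derived kinship annotations
    are *not* set here; see :func:`fhxscreen.kinship.annotate`.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    strict = mode == "strict"
    table = table or default_table()
    try:
        root = json.loads(payload)
    except json.JSONDecodeError as exc:
        raise FhxParseError(f"malformed JSON: {exc}") from None
    if not isinstance(root, dict):
        raise FhxSchemaError("payload root must be a JSON object (the proband)")
    proband = _parse_person(root, table, strict, "proband", is_proband=True)
    if proband.relation != "self":
        raise FhxSchemaError(f"proband relation must be 'self', got {proband.relation!r}")
    rel_objs = root.get("relatives", [])
    if not isinstance(rel_objs, list):
        raise FhxSchemaError("'relatives' must be a list")
    relatives = [
        _parse_person(o, table, strict, f"relatives[{i}]", is_proband=False)
        for i, o in enumerate(rel_objs)
    ]
    for i, r in enumerate(relatives):
        if r.relation == "self":
            raise FhxSchemaError(f"relatives[{i}]: duplicate proband (relation 'self')")
    # assign stable ids where absent: relation label, suffixed on repeats
    seen: Dict[str, int] = {}
    for p in [proband] + relatives:
        base = p.id or ("proband" if p.relation == "self" else p.relation)
        seen[base] = seen.get(base, 0) + 1
        if not p.id:
            p.id = base if seen[base] == 1 else f"{base}_{seen[base]}"
    return Pedigree(proband=proband, relatives=relatives)


# -- validation -----------------------------------------------------------


def _vocab_level(mode: str) -> str:
    return "error" if mode == "strict" else "warning"


def validate_fhx(
    pedigree: Pedigree, mode: str = "lenient", table: Optional[ConceptTable] = None
) -> List[Finding]:
    """Check a parsed pedigree against the dialect's invariants.

    Structural violations (duplicate ids, out-of-range ages, duplicate
    primaries) are always errors.  Vocabulary resolution and sex-site /
    sex-relation consistency are warnings in lenient mode and errors in
    strict mode, matching a patient-facing intake that must not hard-fail.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"unknown mode {mode!r}")
    table = table or default_table()
    out: List[Finding] = []
    vlevel = _vocab_level(mode)

    def vocab_check(term: str, category: Optional[str], path: str) -> None:
        try:
            table.resolve(term, category)
        except VocabularyError:
            out.append(Finding(vlevel, path, f"unresolvable vocabulary term {term!r}"))

    selves = [p for p in pedigree.persons() if p.relation == "self"]
    if len(selves) != 1:
        out.append(Finding("error", "proband", f"expected exactly one 'self', found {len(selves)}"))
    ids = [p.id for p in pedigree.persons()]
    for dup in sorted({i for i in ids if ids.count(i) > 1}):
        out.append(Finding("error", f"person[{dup}]", "duplicate person id"))

    from .kinship import default_kinship_table  # local import to avoid cycle

    ktable = default_kinship_table()
    for p in pedigree.persons():
        path = f"person[{p.id}]"
        if p.relation not in RELATION_LABELS:
            out.append(Finding("error", f"{path}.relation", f"unknown relation label {p.relation!r}"))
        else:
            expected = ktable.expected_sex(p.relation)
            if expected and p.sex != "unknown" and p.sex != expected:
                out.append(
                    Finding(vlevel, f"{path}.sex", f"{p.relation} recorded as {p.sex}, expected {expected}")
                )
        if p.sex not in _SEXES:
            out.append(Finding("error", f"{path}.sex", f"unknown sex {p.sex!r}"))
        if p.current_age is not None and not _AGE_RANGE[0] <= p.current_age <= _AGE_RANGE[1]:
            out.append(Finding("error", f"{path}.age", f"age {p.current_age} outside {_AGE_RANGE}"))
        for a in sorted(p.ancestry):
            vocab_check(a, "ancestry", f"{path}.ancestry")
        for g in sorted(p.variants):
            vocab_check(g, "gene", f"{path}.variants")
        for s in sorted(p.syndromes):
            vocab_check(s, "syndrome", f"{path}.syndromes")
        if p.polyps is not None:
            vocab_check(p.polyps.polyp_type, "polyp_type", f"{path}.polyps.type")
            if p.polyps.count < 0:
                out.append(Finding("error", f"{path}.polyps.count", "polyp count must be >= 0"))
            if p.polyps.age is not None and not _AGE_RANGE[0] <= p.polyps.age <= _AGE_RANGE[1]:
                out.append(Finding("error", f"{path}.polyps.age", f"age {p.polyps.age} outside {_AGE_RANGE}"))
        seen_primaries: set = set()
        for i, dx in enumerate(p.cancers):
            dpath = f"{path}.cancers[{i}]"
            vocab_check(dx.cancer_type, "cancer", f"{dpath}.type")
            if dx.age_at_dx is not None and not _AGE_RANGE[0] <= dx.age_at_dx <= _AGE_RANGE[1]:
                out.append(Finding("error", f"{dpath}.age_at_dx", f"age {dx.age_at_dx} outside {_AGE_RANGE}"))
            if dx.age_at_dx is None:
                out.append(
                    Finding(
                        "warning",
                        f"{dpath}.age_at_dx",
                        "age at diagnosis unknown; age-bounded criteria will not count this case",
                    )
                )
            if dx.laterality not in _LATERALITIES:
                out.append(Finding("error", f"{dpath}.laterality", f"unknown laterality {dx.laterality!r}"))
            for f in sorted(dx.factors | dx.hormone_status):
                vocab_check(f, None, f"{dpath}.factors")
            for f in (dx.histology, dx.tissue_origin):
                if f:
                    vocab_check(f, None, dpath)
            if dx.primary_index < 1:
                out.append(Finding("error", f"{dpath}.primary_index", "primary_index must be >= 1"))
            key = (dx.cancer_type, dx.primary_index)
            if key in seen_primaries:
                out.append(
                    Finding("error", f"{dpath}", f"duplicate primary {key[0]}#{key[1]} within person")
                )
            seen_primaries.add(key)
            if dx.cancer_type in table:
                site_sex = (
                    "female"
                    if any(table.is_a(dx.cancer_type, c) for c in FEMALE_ONLY_CANCERS)
                    else "male"
                    if any(table.is_a(dx.cancer_type, c) for c in MALE_ONLY_CANCERS)
                    else None
                )
                if site_sex and p.sex != "unknown" and p.sex != site_sex:
                    out.append(
                        Finding(
                            vlevel,
                            f"{dpath}.type",
                            f"{dx.cancer_type} recorded for a {p.sex} person",
                        )
                    )
    return out


# -- canonical serialization ----------------------------------------------


def _dx_to_json(dx: CancerDiagnosis) -> Dict[str, object]:
    if not dx.cancer_type:
        raise FhxSerializationError("diagnosis without cancer_type")
    out: Dict[str, object] = {"type": dx.cancer_type}
    if dx.age_at_dx is not None:
        out["age_at_dx"] = dx.age_at_dx
    if dx.laterality != "unknown":
        out["laterality"] = dx.laterality
    if dx.tissue_origin:
        out["tissue_origin"] = dx.tissue_origin
    if dx.histology:
        out["histology"] = dx.histology
    if dx.hormone_status:
        out["hormone_status"] = sorted(dx.hormone_status)
    if dx.factors:
        out["factors"] = sorted(dx.factors)
    out["primary_index"] = dx.primary_index
    for k in sorted(dx.extra):
        out[k] = dx.extra[k]
    return out


def _person_to_json(p: Person, is_proband: bool) -> Dict[str, object]:
    if not p.relation:
        raise FhxSerializationError(f"person {p.id!r} has no relation")
    if not p.id:
        raise FhxSerializationError("person has no id")
    out: Dict[str, object] = {"id": p.id, "relation": p.relation, "sex": p.sex}
    if p.current_age is not None:
        out["age"] = p.current_age
    if p.deceased is not None:
        out["deceased"] = p.deceased
    if p.ancestry:
        out["ancestry"] = sorted(p.ancestry)
    if p.cancers:
        out["cancers"] = [_dx_to_json(d) for d in p.cancers]
    if p.polyps is not None:
        pol: Dict[str, object] = {"type": p.polyps.polyp_type, "count": p.polyps.count}
        if p.polyps.age is not None:
            pol["age"] = p.polyps.age
        out["polyps"] = pol
    if p.variants:
        out["variants"] = sorted(p.variants)
    if p.syndromes:
        out["syndromes"] = sorted(p.syndromes)
    for k in sorted(p.extra):
        out[k] = p.extra[k]
    if is_proband:
        out["relatives"] = []
    return out


def write_fhx(pedigree: Pedigree) -> str:
    """Serialize a pedigree to the canonical FHx JSON dialect."""
    root = _person_to_json(pedigree.proband, is_proband=True)
    root["relatives"] = [_person_to_json(r, is_proband=False) for r in pedigree.relatives]
    return json.dumps(root, indent=2, ensure_ascii=False) + "\n"
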