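"""Rule engine: evaluates guideline criteria against an annotated pedigree.

Each criterion is met if some single-side assignment (paternal or maternal;
side-free clauses use ``either``) satisfies its AND/OR tree with enough
distinct witness units per count clause.  Matching is exhaustive with
backtracking, not greedy: when ``distinct_from`` links clauses, a greedy
per-clause pick can miss a satisfying assignment, so the engine searches
combinations in deterministic (lexicographic) order.  Witness tie-break:
paternal before maternal, then smallest person ids — evidence is
reproducible even though many assignments may satisfy a criterion.

Evaluation is stateless: :func:`assess` works on a private copy of the
pedigree with a fresh evaluation context per call, so one payload can never
leak into the next.

:func:`oracle_evaluate` is an independent brute-force verifier of the
minimum-cardinality semantics (all side choices x all unit-to-clause
assignments, distinctness by explicit set construction).  It is test-only
and refuses instances above a small size cap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, List, Optional, Sequence, Tuple

from .criteria import CountClause, Criterion, Logic, Predicate, Rulebase
from .fhx import Pedigree, Person
from .kinship import annotate, scope_members

__all__ = [
    "ClauseEvidence",
    "EvidenceBinding",
    "Assessment",
    "count_matching",
    "evaluate_criterion",
    "assess",
    "oracle_evaluate",
    "OracleSizeError",
]

ENGINE_VERSION = "0.1.0"

#: A counted unit: (person_id, case_key). ``case_key`` is None for
#: individual units; for case units it is "site#primary" with a "/L" or
#: "/R" suffix when a bilateral diagnosis is expanded into two cases.
Unit = Tuple[str, Optional[str]]


class OracleSizeError(ValueError):
    """The brute-force oracle refuses instances above its size cap."""


# -- predicate matching ---------------------------------------------------


def _dx_matches(pred: Predicate, dx) -> bool:
    if pred.cancer_in is not None and dx.cancer_type not in pred.cancer_in:
        return False
    if pred.max_age_at_dx is not None:
        if dx.age_at_dx is None or dx.age_at_dx > pred.max_age_at_dx:
            return False
    if pred.min_age_at_dx is not None:
        if dx.age_at_dx is None or dx.age_at_dx < pred.min_age_at_dx:
            return False
    if pred.required_factors and not pred.required_factors <= dx.all_factors:
        return False
    if pred.laterality is not None and dx.laterality != pred.laterality:
        return False
    return True


def _case_units(pred: Predicate, person: Person) -> List[str]:
    """Case keys of *person*'s diagnoses matching the case-level predicate.

    A bilateral diagnosis is two cases (two primary tumors), so it expands
    into left/right keys.
    """
    out = []
    for dx in person.cancers:
        if not _dx_matches(pred, dx):
            continue
        base = f"{dx.cancer_type}#{dx.primary_index}"
        if dx.laterality == "bilateral":
            out.extend([f"{base}/L", f"{base}/R"])
        else:
            out.append(base)
    return out


def _person_level_ok(pred: Predicate, person: Person) -> bool:
    if pred.sex is not None and person.sex != pred.sex:
        return False
    if pred.variant_in is not None and not (person.variants & pred.variant_in):
        return False
    if pred.syndrome_in is not None and not (person.syndromes & pred.syndrome_in):
        return False
    if pred.ancestry_in is not None and not (person.ancestry & pred.ancestry_in):
        return False
    if pred.polyp_type is not None or pred.polyp_min_count is not None:
        if person.polyps is None:
            return False
        if pred.polyp_type is not None and person.polyps.polyp_type != pred.polyp_type:
            return False
        if pred.polyp_min_count is not None and person.polyps.count < pred.polyp_min_count:
            return False
    return True


def _person_matches(pred: Predicate, person: Person) -> bool:
    """Individual-unit match: person-level fields plus, if the predicate is
    case-level, at least one (or ``min_primaries``) matching case."""
    if not _person_level_ok(pred, person):
        return False
    if pred.case_level or pred.min_primaries is not None:
        need = pred.min_primaries if pred.min_primaries is not None else 1
        if len(_case_units(pred, person)) < need:
            return False
    return True


def clause_units(pedigree: Pedigree, clause: CountClause, side: str) -> List[Unit]:
    """All distinct units in the clause's scope/side matching its predicate,
    sorted for deterministic witness selection."""
    members = scope_members(pedigree, clause.scope, side, clause.close_degree)
    units: List[Unit] = []
    for p in members:
        if clause.unit == "individuals":
            if _person_matches(clause.predicate, p):
                units.append((p.id, None))
        else:  # cases
            if not _person_level_ok(clause.predicate, p):
                continue
            for key in _case_units(clause.predicate, p):
                units.append((p.id, key))
    return sorted(units, key=lambda u: (u[0], u[1] or ""))


def count_matching(
    pedigree: Pedigree, clause: CountClause, side: str = "either"
) -> Tuple[int, List[Unit]]:
    """Number of distinct matching units for one clause, plus the witnesses."""
    if not pedigree.annotated:
        annotate(pedigree)
    units = clause_units(pedigree, clause, side if clause.same_side else "either")
    return len(units), units


# -- evidence -------------------------------------------------------------


@dataclass(frozen=True)
class ClauseEvidence:
    clause_ref: str
    units: Tuple[Unit, ...]

    def to_json(self) -> dict:
        return {
            "clause": self.clause_ref,
            "units": [
                {"person": pid, **({"case": key} if key else {})} for pid, key in self.units
            ],
        }


@dataclass(frozen=True)
class EvidenceBinding:
    """Why one criterion is met: the side used and the counted units per clause."""

    criterion_id: str
    side: str  # "maternal" | "paternal" | "either"
    clauses: Tuple[ClauseEvidence, ...]

    def to_json(self) -> dict:
        return {
            "criterion": self.criterion_id,
            "side": self.side,
            "evidence": [c.to_json() for c in self.clauses],
        }


@dataclass
class Assessment:
    """Outcome of evaluating a rulebase against one pedigree."""

    proband_id: str
    met: List[EvidenceBinding]
    rulebase_version: str
    engine_version: str = ENGINE_VERSION
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    @property
    def recommendation(self) -> bool:
        """Recommend a cancer genetic consultation iff any criterion is met."""
        return len(self.met) > 0

    @property
    def met_ids(self) -> List[str]:
        return [b.criterion_id for b in self.met]

    def to_json(self) -> dict:
        return {
            "schema": "fhxscreen.assessment/1",
            "proband": self.proband_id,
            "recommendation": self.recommendation,
            "met": [b.to_json() for b in self.met],
            "rulebase_version": self.rulebase_version,
            "engine_version": self.engine_version,
            "timestamp": self.timestamp,
        }


# -- criterion evaluation -------------------------------------------------


def _distinct(a: CountClause, b: CountClause) -> bool:
    return a.ref in b.distinct_from or b.ref in a.distinct_from


def _solve_branch(
    pedigree: Pedigree, branch: Sequence[CountClause], side: str
) -> Optional[List[Tuple[CountClause, Tuple[Unit, ...]]]]:
    """Pick ``min_count`` units per clause, honoring distinct_from person-
    disjointness, by deterministic backtracking. Returns the first (smallest)
    satisfying assignment or None."""
    pools: List[List[Unit]] = []
    for clause in branch:
        units = clause_units(pedigree, clause, side if clause.same_side else "either")
        if len(units) < clause.min_count:
            return None
        pools.append(units)

    chosen: List[Tuple[CountClause, Tuple[Unit, ...]]] = []

    def backtrack(i: int) -> bool:
        if i == len(branch):
            return True
        clause = branch[i]
        for combo in itertools.combinations(pools[i], clause.min_count):
            persons = {u[0] for u in combo}
            ok = True
            for j in range(i):
                if _distinct(clause, branch[j]):
                    if persons & {u[0] for u in chosen[j][1]}:
                        ok = False
                        break
            if not ok:
                continue
            chosen.append((clause, combo))
            if backtrack(i + 1):
                return True
            chosen.pop()
        return False

    return chosen if backtrack(0) else None


def evaluate_criterion(pedigree: Pedigree, criterion: Criterion) -> Optional[EvidenceBinding]:
    """Evaluate one compiled criterion; returns an evidence binding or None.

    Sides are tried paternal first, then maternal; criteria whose clauses
    are all side-free are evaluated once with side ``either``.
    """
    if not pedigree.annotated:
        annotate(pedigree)
    sides = ("paternal", "maternal") if criterion.needs_side else ("either",)
    for side in sides:
        for branch in criterion.branches():
            solution = _solve_branch(pedigree, branch, side)
            if solution is not None:
                return EvidenceBinding(
                    criterion_id=criterion.id,
                    side=side,
                    clauses=tuple(
                        ClauseEvidence(clause.ref, tuple(units)) for clause, units in solution
                    ),
                )
    return None


def assess(pedigree: Pedigree, rulebase: Rulebase) -> Assessment:
    """Evaluate every criterion independently against a fresh copy of the
    pedigree (stateless per call); met criteria sorted by id."""
    ped = pedigree.copy()
    annotate(ped)
    met = []
    for criterion in rulebase:
        binding = evaluate_criterion(ped, criterion)
        if binding is not None:
            met.append(binding)
    met.sort(key=lambda b: b.criterion_id)
    return Assessment(
        proband_id=ped.proband.id,
        met=met,
        rulebase_version=rulebase.version,
    )


# -- independent brute-force oracle --------------------------------------

_ORACLE_MAX_RELATIVES = 12
_ORACLE_MAX_DX = 6


def _tree_true(node: Logic, truth: Dict[str, bool]) -> bool:
    if node.op == "leaf":
        return truth[node.clause.ref]
    if node.op == "and":
        return all(_tree_true(c, truth) for c in node.children)
    return any(_tree_true(c, truth) for c in node.children)


def _oracle_units(pedigree: Pedigree, clause: CountClause, side: str) -> List[Unit]:
    """Straight-line re-derivation of a clause's unit pool (no shared
    matching path with the engine beyond the data model)."""
    pred = clause.predicate
    units: List[Unit] = []
    for p in pedigree.persons():
        deg = p.degree
        scope_ok = {
            "self": deg == 0,
            "first_degree": deg == 1,
            "close": 1 <= deg <= clause.close_degree,
            "close_or_self": deg <= clause.close_degree,
            "any": deg >= 1,
            "any_or_self": True,
        }[clause.scope]
        if not scope_ok:
            continue
        if side != "either" and side not in p.sides:
            continue
        if pred.sex is not None and p.sex != pred.sex:
            continue
        if pred.variant_in is not None and not set(p.variants) & set(pred.variant_in):
            continue
        if pred.syndrome_in is not None and not set(p.syndromes) & set(pred.syndrome_in):
            continue
        if pred.ancestry_in is not None and not set(p.ancestry) & set(pred.ancestry_in):
            continue
        if pred.polyp_type is not None or pred.polyp_min_count is not None:
            if p.polyps is None:
                continue
            if pred.polyp_type is not None and p.polyps.polyp_type != pred.polyp_type:
                continue
            if pred.polyp_min_count is not None and p.polyps.count < pred.polyp_min_count:
                continue
        cases = []
        for dx in p.cancers:
            ok = True
            if pred.cancer_in is not None and dx.cancer_type not in pred.cancer_in:
                ok = False
            if ok and pred.max_age_at_dx is not None:
                ok = dx.age_at_dx is not None and dx.age_at_dx <= pred.max_age_at_dx
            if ok and pred.min_age_at_dx is not None:
                ok = dx.age_at_dx is not None and dx.age_at_dx >= pred.min_age_at_dx
            if ok and pred.required_factors:
                ok = set(pred.required_factors) <= set(dx.all_factors)
            if ok and pred.laterality is not None:
                ok = dx.laterality == pred.laterality
            if ok:
                n = 2 if dx.laterality == "bilateral" else 1
                for k in range(n):
                    suffix = ("/L", "/R")[k] if n == 2 else ""
                    cases.append(f"{dx.cancer_type}#{dx.primary_index}{suffix}")
        case_constrained = (
            pred.cancer_in is not None
            or pred.required_factors
            or pred.laterality is not None
            or pred.max_age_at_dx is not None
            or pred.min_age_at_dx is not None
        )
        if clause.unit == "cases":
            units.extend((p.id, c) for c in cases)
        else:
            need = pred.min_primaries if pred.min_primaries is not None else (1 if case_constrained else 0)
            if len(cases) >= need:
                units.append((p.id, None))
    return units


def oracle_evaluate(pedigree: Pedigree, criterion: Criterion) -> bool:
    """Brute-force satisfiability of one criterion on a small pedigree.

    Enumerates every side choice, every truth assignment to the leaf
    clauses that satisfies the logic tree, and every unit-to-clause
    assignment, enforcing distinctness by explicit set construction.
    Test-only; refuses instances above the size cap.
    """
    if len(pedigree.relatives) > _ORACLE_MAX_RELATIVES:
        raise OracleSizeError(f"more than {_ORACLE_MAX_RELATIVES} relatives")
    if any(len(p.cancers) > _ORACLE_MAX_DX for p in pedigree.persons()):
        raise OracleSizeError(f"a person has more than {_ORACLE_MAX_DX} diagnoses")
    ped = pedigree.copy()
    annotate(ped)
    leaves = criterion.clauses()
    refs = [c.ref for c in leaves]
    sides = ("maternal", "paternal") if criterion.needs_side else ("either",)
    for side in sides:
        for bits in itertools.product((False, True), repeat=len(leaves)):
            truth = dict(zip(refs, bits))
            if not _tree_true(criterion.logic, truth):
                continue
            chosen = [c for c in leaves if truth[c.ref]]
            if _oracle_assignment(ped, chosen, side):
                return True
    return False


def _oracle_assignment(ped: Pedigree, clauses: List[CountClause], side: str) -> bool:
    pools = []
    for c in clauses:
        units = _oracle_units(ped, c, side if c.same_side else "either")
        if len(units) < c.min_count:
            return False
        pools.append(list(itertools.combinations(units, c.min_count)))
    constrained = {
        i
        for i, ci in enumerate(clauses)
        for j, cj in enumerate(clauses)
        if i != j and (ci.ref in cj.distinct_from or cj.ref in ci.distinct_from)
    }
    if not constrained:
        return True  # every pool already has >= min_count units
    free = [i for i in range(len(clauses)) if i not in constrained]
    idxs = sorted(constrained)
    for pick in itertools.product(*(pools[i] for i in idxs)):
        sets = {i: {u[0] for u in combo} for i, combo in zip(idxs, pick)}
        ok = True
        for ai, i in enumerate(idxs):
            for j in idxs[ai + 1 :]:
                if clauses[i].ref in clauses[j].distinct_from or clauses[j].ref in clauses[i].distinct_from:
                    if sets[i] & sets[j]:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            # free clauses are unconstrained; their pools are non-empty
            assert all(pools[i] for i in free)
            return True
    return False
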