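"""Target+payload test-case generation: meet cases, near-misses, random pedigrees.

For every criterion the generator can construct a minimal pedigree that
satisfies its logic tree (one witness unit per required count, ages placed
exactly at the inclusive bounds) and near-miss perturbations that fall just
short: one counted unit removed, one age pushed one year past its bound, or
the counted units split across the two sides of the family.  Every generated
case is verified against the brute-force oracle before it is emitted, so a
case's expected outcome is correct by construction.

Seeded and reproducible: the same (criterion, seed) always yields the same
payload bytes.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .criteria import CountClause, Criterion, Rulebase
from .engine import oracle_evaluate
from .fhx import CancerDiagnosis, Pedigree, Person, PolypRecord, write_fhx
from .kinship import default_kinship_table, mirror_label
from .vocabulary import FEMALE_ONLY_CANCERS, MALE_ONLY_CANCERS, ConceptTable, default_table

__all__ = [
    "GenerationError",
    "TestCase",
    "generate_meet_case",
    "generate_near_miss",
    "generate_suite",
    "random_pedigree",
    "NEAR_MISS_MODES",
]

NEAR_MISS_MODES = ("count_minus_one", "age_plus_one", "side_split")

#: Age given to diagnoses that no clause bounds; above every age threshold
#: in the shipped rulebase so an unbounded witness never leaks into a
#: sibling age-bounded clause.
_UNBOUNDED_AGE = 65


class GenerationError(ValueError):
    """A test case cannot be generated (inapplicable mode, vocabulary gap)."""


@dataclass(frozen=True)
class TestCase:
    """A payload plus the outcome one criterion must produce on it."""

    criterion_id: str
    expected: str  # "met" | "not_met"
    payload: str  # FHx JSON text
    recipe: Dict[str, object]

    def to_json(self) -> dict:
        return {
            "target": {"criterion": self.criterion_id, "expected": self.expected},
            "payload": json.loads(self.payload),
            "recipe": self.recipe,
        }


# -- relative pools -------------------------------------------------------

# (label, unique) candidates per lineage side; single-side labels first so
# side semantics stay crisp, both-side siblings as fallback.
_SINGLE_SIDE = {
    "paternal": [
        ("father", True),
        ("paternal_uncle", False),
        ("paternal_aunt", False),
        ("paternal_grandfather", True),
        ("paternal_grandmother", True),
        ("paternal_cousin", False),
    ],
    "maternal": [
        ("mother", True),
        ("maternal_uncle", False),
        ("maternal_aunt", False),
        ("maternal_grandfather", True),
        ("maternal_grandmother", True),
        ("maternal_cousin", False),
    ],
}
_BOTH_SIDES = [("brother", False), ("sister", False)]


class _Slot:
    """One counted unit created for a clause: a person and its diagnoses."""

    def __init__(self, clause: CountClause, person: Person, dxs: List[CancerDiagnosis]):
        self.clause = clause
        self.person = person
        self.dxs = dxs


class _Builder:
    def __init__(
        self,
        criterion: Criterion,
        seed: int,
        table: Optional[ConceptTable] = None,
        split_sides: bool = False,
    ):
        self.criterion = criterion
        self.rng = random.Random(seed)
        self.table = table or default_table()
        self.ktable = default_kinship_table()
        self.split_sides = split_sides
        self.used_unique: set = set()
        self.label_counts: Dict[str, int] = {}
        self.proband = Person(id="proband", relation="self", sex="female", current_age=45)
        self.relatives: List[Person] = []
        self.slots: List[_Slot] = []
        self._side_toggle = 0

    # -- helpers --------------------------------------------------------

    def _rep_cancer(self, cancer_in: Iterable[str]) -> str:
        """A representative site: prefer roots of the expanded set, sorted."""
        cancers = sorted(cancer_in)
        roots = [c for c in cancers if self.table.get(c).parent_id not in cancer_in]
        return (roots or cancers)[0]

    def _required_sex(self, clause: CountClause, site: Optional[str]) -> Optional[str]:
        if clause.predicate.sex:
            return clause.predicate.sex
        if site:
            if any(self.table.is_a(site, c) for c in FEMALE_ONLY_CANCERS):
                return "female"
            if any(self.table.is_a(site, c) for c in MALE_ONLY_CANCERS):
                return "male"
        return None

    def _degree_fits(self, label: str, clause: CountClause) -> bool:
        deg = self.ktable.degree(label)
        scope = clause.scope
        if scope == "first_degree":
            return deg == 1
        if scope in ("close", "close_or_self"):
            return 1 <= deg <= clause.close_degree
        return deg >= 1  # any / any_or_self

    def _new_relative(self, clause: CountClause, sex_needed: Optional[str], side: str) -> Person:
        candidates = list(_SINGLE_SIDE[side])
        if not self.split_sides or not clause.same_side:
            candidates += _BOTH_SIDES
        for label, unique in candidates:
            if unique and label in self.used_unique:
                continue
            if not self._degree_fits(label, clause):
                continue
            expected = self.ktable.expected_sex(label)
            if sex_needed and expected and expected != sex_needed:
                continue
            if unique:
                self.used_unique.add(label)
            self.label_counts[label] = self.label_counts.get(label, 0) + 1
            n = self.label_counts[label]
            pid = label if n == 1 else f"{label}_{n}"
            person = Person(id=pid, relation=label, sex=expected or sex_needed or "female")
            self.relatives.append(person)
            return person
        raise GenerationError(
            f"criterion {self.criterion.id}: no relative label fits clause "
            f"{clause.ref!r} (scope {clause.scope}, sex {sex_needed}, side {side})"
        )

    def _unit_side(self, clause: CountClause) -> str:
        # meet cases build on the paternal side; split builds alternate sides
        if self.split_sides and clause.same_side:
            side = ("paternal", "maternal")[self._side_toggle % 2]
            self._side_toggle += 1
            return side
        return "paternal"

    def _make_dx(self, clause: CountClause, site: str, index: int) -> CancerDiagnosis:
        pred = clause.predicate
        if pred.max_age_at_dx is not None:
            age: Optional[int] = pred.max_age_at_dx
        elif pred.min_age_at_dx is not None:
            age = pred.min_age_at_dx
        else:
            age = _UNBOUNDED_AGE
        return CancerDiagnosis(
            cancer_type=site,
            age_at_dx=age,
            laterality=pred.laterality or "unknown",
            factors=frozenset(pred.required_factors),
            primary_index=index,
        )

    def _apply_person_attrs(self, clause: CountClause, person: Person) -> None:
        pred = clause.predicate
        if pred.variant_in is not None:
            person.variants = person.variants | {sorted(pred.variant_in)[0]}
        if pred.syndrome_in is not None:
            person.syndromes = person.syndromes | {sorted(pred.syndrome_in)[0]}
        if pred.ancestry_in is not None:
            person.ancestry = person.ancestry | {sorted(pred.ancestry_in)[0]}
        if pred.polyp_type is not None or pred.polyp_min_count is not None:
            person.polyps = PolypRecord(
                polyp_type=pred.polyp_type or "adenomatous",
                count=pred.polyp_min_count if pred.polyp_min_count is not None else 1,
                age=50,
            )
        if pred.sex:
            person.sex = pred.sex

    def _fill_clause(self, clause: CountClause) -> None:
        pred = clause.predicate
        site = self._rep_cancer(pred.cancer_in) if pred.cancer_in is not None else None
        case_like = site is not None or pred.required_factors or pred.laterality
        n_units = clause.min_count
        n_primaries = pred.min_primaries or 1
        for _ in range(n_units):
            sex_needed = self._required_sex(clause, site)
            if clause.scope == "self":
                person = self.proband
                if sex_needed:
                    person.sex = sex_needed
            else:
                person = self._new_relative(clause, sex_needed, self._unit_side(clause))
            dxs: List[CancerDiagnosis] = []
            if case_like:
                start = 1 + sum(1 for d in person.cancers if d.cancer_type == site)
                for k in range(n_primaries):
                    dx = self._make_dx(clause, site or "breast", start + k)
                    person.cancers.append(dx)
                    dxs.append(dx)
            self._apply_person_attrs(clause, person)
            self.slots.append(_Slot(clause, person, dxs))

    def build(self) -> Tuple[Pedigree, List[_Slot]]:
        branch = self.criterion.branches()[0]
        for clause in branch:
            self._fill_clause(clause)
        ped = Pedigree(proband=self.proband, relatives=self.relatives)
        return ped, self.slots


def _finish(
    criterion: Criterion,
    ped: Pedigree,
    expected: str,
    recipe: Dict[str, object],
) -> TestCase:
    want_met = expected == "met"
    got = oracle_evaluate(ped, criterion)
    if got != want_met:
        raise GenerationError(
            f"criterion {criterion.id}: generated case is {'met' if got else 'not met'}, "
            f"expected {expected} (recipe {recipe})"
        )
    return TestCase(
        criterion_id=criterion.id,
        expected=expected,
        payload=write_fhx(ped),
        recipe=recipe,
    )


def generate_meet_case(criterion: Criterion, seed: int = 0) -> TestCase:
    """A minimal pedigree satisfying the criterion's first logic branch."""
    ped, _ = _Builder(criterion, seed).build()
    return _finish(criterion, ped, "met", {"criterion": criterion.id, "mode": "meet", "seed": seed})


def generate_near_miss(criterion: Criterion, mode: str, seed: int = 0) -> TestCase:
    """Perturb a meet case so the criterion is no longer met.

    Modes: ``count_minus_one`` removes one counted unit; ``age_plus_one``
    pushes one age one year past its inclusive bound; ``side_split``
    scatters the counted units across the two parental lineages.  Every
    output is oracle-verified as not met; an inapplicable mode raises
    :class:`GenerationError`.
    """
    if mode not in NEAR_MISS_MODES:
        raise GenerationError(f"unknown near-miss mode {mode!r}")
    recipe = {"criterion": criterion.id, "mode": mode, "seed": seed}

    if mode == "side_split":
        builder = _Builder(criterion, seed, split_sides=True)
        same_side_units = sum(
            c.min_count for c in criterion.branches()[0] if c.same_side and c.scope != "self"
        )
        if same_side_units < 2:
            raise GenerationError(
                f"criterion {criterion.id}: side_split needs >=2 same-side units"
            )
        ped, _ = builder.build()
        return _finish(criterion, ped, "not_met", recipe)

    if mode == "age_plus_one":
        ped, slots = _Builder(criterion, seed).build()
        for slot in slots:
            pred = slot.clause.predicate
            if not slot.dxs:
                continue
            if pred.max_age_at_dx is not None:
                old = slot.dxs[0].age_at_dx
                slot.dxs[0].age_at_dx = pred.max_age_at_dx + 1
                if not oracle_evaluate(ped, criterion):
                    return _finish(criterion, ped, "not_met", recipe)
                slot.dxs[0].age_at_dx = old
            elif pred.min_age_at_dx is not None and pred.min_age_at_dx > 0:
                old = slot.dxs[0].age_at_dx
                slot.dxs[0].age_at_dx = pred.min_age_at_dx - 1
                if not oracle_evaluate(ped, criterion):
                    return _finish(criterion, ped, "not_met", recipe)
                slot.dxs[0].age_at_dx = old
        raise GenerationError(f"criterion {criterion.id}: no age bound to perturb")

    # count_minus_one: try single-unit removals until the criterion unmeets
    ped, slots = _Builder(criterion, seed).build()
    for slot in slots:
        person = slot.person
        if slot.dxs:
            removed = slot.dxs[-1]
            person.cancers.remove(removed)
            if not oracle_evaluate(ped, criterion):
                return _finish(criterion, ped, "not_met", recipe)
            person.cancers.append(removed)
        else:
            saved = (person.variants, person.syndromes, person.ancestry, person.polyps)
            pred = slot.clause.predicate
            if pred.variant_in is not None:
                person.variants = person.variants - pred.variant_in
            if pred.syndrome_in is not None:
                person.syndromes = person.syndromes - pred.syndrome_in
            if pred.ancestry_in is not None:
                person.ancestry = person.ancestry - pred.ancestry_in
            if pred.polyp_type is not None or pred.polyp_min_count is not None:
                person.polyps = None
            if not oracle_evaluate(ped, criterion):
                return _finish(criterion, ped, "not_met", recipe)
            person.variants, person.syndromes, person.ancestry, person.polyps = saved
    raise GenerationError(f"criterion {criterion.id}: no single-unit removal unmeets")


def generate_suite(
    rulebase: Rulebase, seed: int = 0, with_near_miss: bool = True
) -> List[TestCase]:
    """At least one meet case per criterion, plus every applicable near-miss."""
    cases: List[TestCase] = []
    for i, criterion in enumerate(rulebase):
        case_seed = seed * 1000 + i
        cases.append(generate_meet_case(criterion, case_seed))
        if with_near_miss:
            for mode in NEAR_MISS_MODES:
                try:
                    cases.append(generate_near_miss(criterion, mode, case_seed))
                except GenerationError:
                    continue
    return cases


# -- random pedigrees -----------------------------------------------------

_UNIQUE_LABELS = {
    "mother",
    "father",
    "maternal_grandmother",
    "maternal_grandfather",
    "paternal_grandmother",
    "paternal_grandfather",
}

_VARIANT_POOL = ["apc", "brca1", "brca2", "chek2", "mlh1", "msh2", "pten", "tp53"]
_SYNDROME_POOL = ["li_fraumeni", "lynch_syndrome", "hboc", "cowden"]


def random_pedigree(
    n_relatives: int = 8,
    cancer_rate: float = 0.3,
    seed: int = 0,
    table: Optional[ConceptTable] = None,
) -> Pedigree:
    """A random strict-valid pedigree for property testing.

    Not a population model: diagnoses are drawn uniformly (sex-consistently)
    from the cancer vocabulary at the configured per-person rate, with
    occasional disease factors, hormone statuses, variants, syndromes,
    polyps and ancestry flags, so criterion predicates of every kind get
    exercised.
    """
    if n_relatives < 0 or n_relatives > 30:
        raise ValueError("n_relatives must be in [0, 30]")
    if not 0.0 <= cancer_rate <= 1.0:
        raise ValueError("cancer_rate must be in [0, 1]")
    rng = random.Random(seed)
    table = table or default_table()
    ktable = default_kinship_table()
    all_cancers = table.ids("cancer")
    female_ok = [
        c for c in all_cancers if not any(table.is_a(c, m) for m in MALE_ONLY_CANCERS)
    ]
    male_ok = [
        c for c in all_cancers if not any(table.is_a(c, f) for f in FEMALE_ONLY_CANCERS)
    ]
    lynch_like = sorted(
        set().union(*(table.descendants(c) for c in ("colorectal", "endometrial", "gastric")))
    )

    def make_person(pid: str, relation: str) -> Person:
        expected = ktable.expected_sex(relation)
        sex = expected or rng.choice(["female", "male"])
        person = Person(
            id=pid,
            relation=relation,
            sex=sex,
            current_age=rng.randint(20, 90) if rng.random() < 0.9 else None,
            deceased=rng.choice([True, False]) if rng.random() < 0.3 else None,
        )
        pool = female_ok if sex == "female" else male_ok
        counters: Dict[str, int] = {}
        n_dx = 0
        while n_dx < 3 and rng.random() < cancer_rate:
            n_dx += 1
            site = rng.choice(pool)
            counters[site] = counters.get(site, 0) + 1
            factors = set()
            hormones = set()
            laterality = "unknown"
            if site in lynch_like and rng.random() < 0.2:
                factors.add(rng.choice(["msi_high", "mmr_stable"]))
            if table.is_a(site, "breast"):
                if rng.random() < 0.2:
                    hormones |= {"er_negative", "pr_negative", "her2_negative"}
                elif rng.random() < 0.3:
                    hormones.add(rng.choice(["er_positive", "er_negative", "her2_positive"]))
                if rng.random() < 0.15:
                    laterality = "bilateral"
            if table.is_a(site, "renal") and rng.random() < 0.25:
                factors.add(rng.choice(["clear_cell", "collecting_duct", "papillary"]))
            person.cancers.append(
                CancerDiagnosis(
                    cancer_type=site,
                    age_at_dx=rng.randint(18, 85) if rng.random() < 0.88 else None,
                    laterality=laterality,
                    hormone_status=frozenset(hormones),
                    factors=frozenset(factors),
                    primary_index=counters[site],
                )
            )
        if rng.random() < 0.05:
            person.variants = frozenset({rng.choice(_VARIANT_POOL)})
        if rng.random() < 0.03:
            person.syndromes = frozenset({rng.choice(_SYNDROME_POOL)})
        if rng.random() < 0.05:
            person.polyps = PolypRecord(
                polyp_type=rng.choice(["adenomatous", "juvenile", "hyperplastic"]),
                count=rng.randint(1, 20),
                age=rng.randint(30, 70),
            )
        return person

    proband = make_person("proband", "self")
    if rng.random() < 0.1:
        proband.ancestry = frozenset({"ashkenazi_jewish"})
    relatives: List[Person] = []
    used_unique: set = set()
    label_counts: Dict[str, int] = {}
    for _ in range(n_relatives):
        choices = [l for l in ktable.labels() if l != "self" and (l not in used_unique)]
        label = rng.choice(choices)
        if label in _UNIQUE_LABELS:
            used_unique.add(label)
        label_counts[label] = label_counts.get(label, 0) + 1
        n = label_counts[label]
        pid = label if n == 1 else f"{label}_{n}"
        relatives.append(make_person(pid, label))
    return Pedigree(proband=proband, relatives=relatives)
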