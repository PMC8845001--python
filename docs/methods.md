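# Methods

## Problem and approach

`fhxscreen` screens a family health history (FHx) against hereditary-cancer
referral criteria published by ACMG and NCCN.  The criteria are minimum
thresholds over a pedigree — counts of affected relatives, ages at
diagnosis, tumor features, variants — so the package models them as a
declarative rulebase of minimum-cardinality count clauses and evaluates
them with a deterministic rule engine rather than a description-logic
reasoner.  The engine reproduces the semantics a reasoner-based
classification would give (each criterion an equivalency-class-style
definition; a proband is "reclassified" under every criterion their FHx
satisfies) while staying fast, dependency-light and auditable.

## Pedigree model

The payload is a single proband object with a flat `relatives` list; every
relative is labelled relative to the proband from a closed vocabulary of
25 labels.  No explicit parent-pointer graph is required: the kinship
table (shipped as `data/kinship.tsv`) maps each label to

- **degree**: 1 (parents, full siblings, children), 2 (grandparents,
  aunts/uncles, half-siblings, nieces/nephews, grandchildren),
  3 (first cousins) — standard genetic-counseling definitions; and
- **sides**: the parental lineage(s) the person can transmit through.

Lineage convention: the proband, full siblings and descendants count on
**both** sides.  This is what lets a single same-side evaluation combine
the proband's own case with a paternal relative's, realizing as one rule
the proband-affected / proband-unaffected pair of guideline variants
(e.g. the prostate criterion's two published forms).  Half-siblings carry
the shared parent's side; the label vocabulary distinguishes them so the
rulebase *can* treat them differently even though current criteria do not.
The explicit family graph (with implied connecting ancestors) exists only
in the test oracle, which recomputes every degree from the coefficient of
relationship and every side from the connecting paths.

"Close relative" defaults to degree ≤ 2 and is overridable per clause
(`close_degree`), since published usage varies between degree ≤ 2 and ≤ 3.

## Criterion semantics

A clause is "at least `min_count` units in scope `scope` matching
predicate `P`, on one side of the family".

- **Units.** `individuals` counts distinct persons; `cases` counts
  distinct primary tumors — a person's `(site, primary_index)` pairs, with
  a `bilateral` diagnosis contributing two.  This choice makes "≥2 cases"
  criteria fire for one person with two primaries, which matches the
  guideline intent of counting tumor events.
- **Age bounds are inclusive** ("diagnosed at age ≤55" admits 55, rejects
  56) and an **unknown age never satisfies an age bound**: a screen should
  not fire on missing data.  Validation emits a warning for undated
  diagnoses so the missed potential match is visible.
- **Same-side rule.** All `same_side` clauses of one criterion must be
  satisfied on a single parental lineage; the engine tries paternal, then
  maternal.  Side-free clauses (known familial variant, proband-only
  ancestry or polyp criteria) are evaluated with no side filter.
- **Witness distinctness.** Within a clause, units are distinct by
  construction.  Across clauses of one criterion, reuse is *allowed* by
  default (one relative with breast and ovarian cancer satisfies both
  clauses of a breast-and-ovarian criterion); `distinct_from` markers
  enforce person-disjointness where the printed criterion says "another
  relative".  Because distinctness couples clauses, matching backtracks
  over combinations instead of picking greedily; the brute-force oracle is
  the correctness reference for this search.  Whether reasoner-based
  implementations allow cross-clause reuse is not documented anywhere we
  know of; the default here is a documented choice, verified against the
  oracle, not a claim of behavioral identity.
- **No negation.**  Criteria are monotone lower bounds, which gives the
  engine a checkable law: adding a relative, adding a diagnosis or
  lowering an age at diagnosis never removes a met criterion.
- **Determinism.**  Among satisfying assignments the engine returns the
  paternal side before the maternal and the lexicographically smallest
  person ids, so evidence bindings are reproducible run to run.

## Vocabulary

Concept tables ship as editable TSV (id, parent, label, aliases): 44
cancers (83 with subtypes, linked by acyclic `parent_id` subsumption), 144
genes, 32 syndromes, 10 ancestries, 8 tissue origins, 6 histologies, 6
hormone statuses, 4 traits, 3 lateralities, 3 sexes, 2 disease factors.
Predicates are compiled against the tables at load time (subtype
expansion, alias resolution, `triple_negative` expanding to the three
receptor-negative flags), and loading fails on any unresolved id, so the
rulebase–vocabulary closure is checked before anything is evaluated.
Published tallies of the gene roster differ between 141 and 144 across
sources; the shipped table carries 144 entries.

## Rulebase

`data/rulebase.yaml` transcribes 73 ACMG and 40 NCCN criteria (113 total)
across breast, ovarian, pancreatic, colorectal and endometrial groups for
both sources, Li-Fraumeni and Lynch groups for both, and ACMG-only brain,
gastric, melanoma, prostate, renal and thyroid groups.  The supplementary
tables that enumerate the original criteria verbatim are not public, so
the shipped rulebase was authored from the public ACMG referral guidelines
and NCCN high-risk assessment criteria at the published census and group
coverage; each record carries a provenance note.  The prostate criterion
is transcribed verbatim and serves as the worked example.  Criteria whose
published form would need an absence condition are not included; the
grouping and thresholds are otherwise faithful but the rulebase is a
re-transcription, not the original artifact.

## Test-case generator

`generate_meet_case` builds, per criterion, a minimal pedigree that
satisfies the first branch of the logic tree: one new relative per counted
unit on the paternal side (sex-appropriate labels; duplicate aunt/uncle
labels disambiguated by id), ages placed exactly at the inclusive bound,
required factors/variants/syndromes attached.  Diagnoses no clause bounds
get age 65, above every threshold in the rulebase, so an unbounded witness
cannot leak into a sibling age-bounded clause.  Near-miss modes perturb a
meet case to fall just short: `count_minus_one` removes one counted unit
(searching single-unit removals until the criterion unmeets),
`age_plus_one` pushes one age one year past its bound, `side_split`
alternates the counted units between the two lineages using only
single-side labels.  Every emitted case is verified against the
brute-force oracle, so expected outcomes are correct by construction;
inapplicable modes raise a generation error and are skipped by the suite
builder.  With near-misses the shipped rulebase yields 295 cases
(113 meet, 113 count-minus-one, 30 age, 39 side-split).

`random_pedigree` exists for property testing, not statistical realism:
diagnoses are drawn sex-consistently and uniformly from the cancer
vocabulary at a configured per-person rate (default 8 relatives, rate
0.3), with occasional factors, hormone statuses, variants, syndromes,
polyps and ancestry flags so every predicate kind is exercised.  Passing
property suites therefore demonstrates the engine's laws (oracle
equivalence, monotonicity, mirror symmetry, order invariance, source-split
consistency) on structurally diverse pedigrees; they say nothing about
population incidence, real-world payload noise, or free-text intake.

## Numerical and interface choices

- Canonical serialization: schema key order, nulls omitted, sets sorted,
  `primary_index` always emitted; write∘parse is byte-identity, which the
  tests check on 500 seeded instances.
- Validation severity: structural violations (duplicate ids, out-of-range
  ages, duplicate primaries) are always errors; vocabulary resolution and
  sex–site/sex–relation consistency are warnings in lenient mode (the
  default — a patient-facing intake must not hard-fail) and errors in
  strict mode.
- Statelessness: `assess` deep-copies and re-annotates the pedigree per
  call, mirroring a fresh knowledge-base load per evaluation; assessments
  are byte-identical across calls modulo timestamp.
- Problem sizes in the shipped checks — 1,000 random pedigrees for oracle
  equivalence, 500 perturbation pairs for monotonicity, 500 mirrors, 500
  round-trips, 300 pedigrees in the acceptance script — were chosen to
  exercise the combinatorics densely while keeping a full run in tens of
  seconds on one CPU.
- The oracle caps instances at 12 relatives and 6 diagnoses per person;
  it enumerates truth assignments over the logic tree's leaves and full
  unit-to-clause assignments only where distinctness couples clauses.

## Known limitations

- The rulebase is a faithful re-transcription at the published census, not
  the original supplementary tables; individual thresholds may differ.
- No FHIR FamilyMemberHistory import/export, no consanguinity or adoption
  modelling, no temporal or treatment logic, no report delivery pipeline.
- Relationship labels stop at first cousins; more distant kin cannot be
  expressed.
- Guideline criteria are expert-curated thresholds, not validated
  instruments; the screen flags FHx for professional follow-up and is not
  a diagnostic.
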