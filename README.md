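# fhxscreen

Family-health-history (FHx) screening for hereditary cancer risk.

Identifying patients who should see a genetic counselor is a pedigree
problem: guideline criteria from the American College of Medical Genetics
and Genomics (ACMG) and the National Comprehensive Cancer Network (NCCN)
ask questions like *"are there ≥2 cases of prostate cancer diagnosed at age
≤55 years in close relatives, on the same side of the family?"*.  Providers
rarely have the time or training to apply the 100+ criteria to a family
history by hand.  `fhxscreen` is a deterministic rule engine that does it
automatically: it parses a structured FHx JSON payload (the kind a
patient-facing intake chatbot collects), derives kinship degree and
maternal/paternal lineage for every relative, evaluates a declarative
rulebase of 73 ACMG and 40 NCCN criteria, and returns a
genetic-consultation recommendation with per-criterion evidence.

It is written for clinical-informatics developers and genetic-counseling
researchers who need a transparent, testable, scriptable screener — not a
substitute for professional assessment.

## The model

A pedigree is the proband plus relatives labelled relative to the proband
(`father`, `maternal_aunt`, ...).  Each label maps to a **degree of
relatedness** (1st: parents/siblings/children; 2nd: grandparents,
aunts/uncles, half-siblings, nieces/nephews, grandchildren; 3rd: first
cousins) and to the **parental lineage side(s)** the person belongs to.
The proband, full siblings and descendants carry *both* sides, so one
same-side evaluation can combine the proband's own diagnosis with a
paternal relative's.

Each criterion is an AND/OR tree of **count clauses**

> at least *n* units in scope *S* matching predicate *P*, on one side of
> the family

where a unit is a distinct individual or a distinct cancer case (one case
per primary tumor; a bilateral diagnosis counts as two), the scope bounds
the degree of relatedness (`close` = degree ≤ 2 by default), and the
predicate constrains cancer site (with subtype subsumption, e.g. lobular
carcinoma *is a* breast cancer), inclusive age-at-diagnosis bounds,
disease factors (MSI-high, hormone receptor status, histology), sex,
pathogenic variants, syndromes, ancestry and polyp burden.  Criteria are
negation-free monotone lower bounds: adding family history can only add
met criteria.  `distinct_from` markers force different witnesses where a
criterion demands "another relative", and the engine backtracks over
witness assignments, so it never misses a satisfying combination.  A
brute-force oracle (all side choices × all unit-to-clause assignments)
independently verifies the engine in the test suite.

## Worked example

The shipped example payload (`src/fhxscreen/data/examples/prostate_family.json`)
describes an unaffected proband whose father and brother both had prostate
cancer diagnosed at ages 54 and 53:

```sh
fhxscreen assess --input src/fhxscreen/data/examples/prostate_family.json \
    --guidelines acmg --format text
```

prints

```
========================================================================
FHx hereditary-cancer screening report
========================================================================
Proband: proband

relation              sex       age  cancers
------------------------------------------------------------------------
self                  female     40
father                male       68  prostate@54
brother               male       55  prostate@53

Criteria met (1):
  [ACMG.Prostate.01] ≥2 cases of prostate cancer diagnosed at age ≤55 years in close relatives
      clause c1 (paternal): brother (prostate#1), father (prostate#1)

Based on the family health history provided, a cancer genetic consultation is recommended.
```

The two cases combine on the *paternal* side (a full brother carries both
lineages), so the minimum-cardinality clause (2 cases, age ≤ 55, close
relatives) is satisfied and a consultation is recommended.  Moving the two
cases to opposite sides of the family (a maternal uncle and a paternal
uncle) yields no recommendation — the same-side rule is what makes the
screen reflect hereditary transmission.

Other subcommands: `fhxscreen validate --input FHX.json [--strict]`
(conformance findings), `fhxscreen stats` (rulebase census),
`fhxscreen testgen --out DIR --seed N [--near-miss]` (write a seeded
target+payload test suite, one JSON per case plus a manifest).

## Layout

- `src/fhxscreen/fhx.py` — FHx JSON dialect: parse, validate, canonical write
- `src/fhxscreen/kinship.py` — degrees, lineage sides, counting scopes
- `src/fhxscreen/vocabulary.py` + `data/*.tsv` — controlled vocabularies
- `src/fhxscreen/criteria.py` + `data/rulebase.yaml` — criterion DSL and rulebase
- `src/fhxscreen/engine.py` — evaluator and brute-force oracle
- `src/fhxscreen/testgen.py` — meet/near-miss case generator, random pedigrees
- `src/fhxscreen/reporting.py`, `cli.py` — reports and command line
- `docs/methods.md` — modelling decisions, semantics, limitations
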