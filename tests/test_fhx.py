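"""FHx JSON dialect: parsing, validation findings, canonical round-trip."""

import json

import pytest
from hypothesis import given, settings, strategies as st

from fhxscreen.fhx import (
    CancerDiagnosis,
    FhxParseError,
    FhxSchemaError,
    Pedigree,
    Person,
    parse_fhx,
    validate_fhx,
    write_fhx,
)
from fhxscreen.testgen import random_pedigree
from tests.conftest import make_payload


def test_minimal_payload_parses_to_single_person():
    ped = parse_fhx(make_payload())
    assert ped.proband.relation == "self"
    assert ped.relatives == []
    assert len(list(ped.persons())) == 1


def test_prostate_family_parses_to_three_persons(prostate_pedigree):
    assert len(list(prostate_pedigree.persons())) == 3
    father = next(p for p in prostate_pedigree.relatives if p.relation == "father")
    assert father.cancers[0].cancer_type == "prostate"
    assert father.cancers[0].age_at_dx == 54


def test_malformed_json_raises_parse_error():
    with pytest.raises(FhxParseError):
        parse_fhx("{not json")


def test_missing_or_duplicate_proband_raises_schema_error():
    with pytest.raises(FhxSchemaError):
        parse_fhx(json.dumps({"relation": "mother", "relatives": []}))
    with pytest.raises(FhxSchemaError):
        parse_fhx(make_payload(relatives=[{"relation": "self"}]))


def test_vocabulary_canonicalized_on_parse():
    ped = parse_fhx(
        make_payload(relatives=[{"relation": "sister", "sex": "female",
                                 "cancers": [{"type": "Breast Cancer"}]}])
    )
    assert ped.relatives[0].cancers[0].cancer_type == "breast"


def test_unresolvable_term_strict_vs_lenient():
    payload = make_payload(relatives=[{"relation": "sister", "sex": "female",
                                       "cancers": [{"type": "notacancer"}]}])
    with pytest.raises(FhxSchemaError):
        parse_fhx(payload, mode="strict")
    ped = parse_fhx(payload)  # lenient keeps the term, validation flags it
    findings = validate_fhx(ped, mode="lenient")
    assert [f.level for f in findings if "notacancer" in f.message] == ["warning"]
    findings = validate_fhx(ped, mode="strict")
    assert [f.level for f in findings if "notacancer" in f.message] == ["error"]


def test_sex_site_inconsistency_finding():
    payload = make_payload(relatives=[{"relation": "brother", "sex": "male",
                                       "cancers": [{"type": "ovarian", "age_at_dx": 50}]}])
    ped = parse_fhx(payload)
    lenient = [f for f in validate_fhx(ped, "lenient") if "ovarian" in f.message]
    strict = [f for f in validate_fhx(ped, "strict") if "ovarian" in f.message]
    assert [f.level for f in lenient] == ["warning"]
    assert [f.level for f in strict] == ["error"]


def test_age_out_of_range_is_always_an_error():
    payload = make_payload(relatives=[{"relation": "sister", "sex": "female",
                                       "cancers": [{"type": "breast", "age_at_dx": 200}]}])
    for mode in ("lenient", "strict"):
        findings = validate_fhx(parse_fhx(payload), mode)
        assert any(f.level == "error" and "200" in f.message for f in findings)


def test_valid_payload_has_no_findings(prostate_pedigree):
    assert validate_fhx(prostate_pedigree, "strict") == []


def test_unknown_dx_age_flagged_as_missed_potential_match():
    payload = make_payload(relatives=[{"relation": "sister", "sex": "female",
                                       "cancers": [{"type": "breast"}]}])
    findings = validate_fhx(parse_fhx(payload), "strict")
    assert [f.level for f in findings] == ["warning"]


def test_duplicate_primary_is_an_error():
    payload = make_payload(relatives=[{
        "relation": "sister", "sex": "female",
        "cancers": [{"type": "breast", "age_at_dx": 40, "primary_index": 1},
                    {"type": "breast", "age_at_dx": 45, "primary_index": 1}]}])
    findings = validate_fhx(parse_fhx(payload))
    assert any(f.level == "error" and "duplicate primary" in f.message for f in findings)


def test_write_minimal_pedigree_canonical_form():
    doc = json.loads(write_fhx(parse_fhx(make_payload())))
    assert doc["relation"] == "self"
    assert doc["relatives"] == []
    assert "cancers" not in doc  # empty optionals omitted


def test_write_is_idempotent(prostate_payload):
    once = write_fhx(parse_fhx(prostate_payload))
    assert write_fhx(parse_fhx(once)) == once


def test_unknown_fields_pass_through():
    payload = make_payload(proband={"chatbot_session": "abc123"},
                           relatives=[{"relation": "mother", "sex": "female",
                                       "favourite_color": "blue"}])
    out = write_fhx(parse_fhx(payload))
    doc = json.loads(out)
    assert doc["chatbot_session"] == "abc123"
    assert doc["relatives"][0]["favourite_color"] == "blue"
    assert write_fhx(parse_fhx(out)) == out


@pytest.mark.parametrize("seed", range(0, 60))
def test_random_pedigrees_round_trip_byte_identically(seed):
    ped = random_pedigree(n_relatives=seed % 10, cancer_rate=0.4, seed=seed)
    txt = write_fhx(ped)
    assert write_fhx(parse_fhx(txt, mode="strict")) == txt


# -- hypothesis: round-trip over arbitrary valid pedigrees ----------------

_CANCERS = ["breast", "lobular_breast", "colorectal", "prostate", "melanoma", "renal"]
_LABELS = ["mother", "father", "sister", "brother", "maternal_aunt", "paternal_uncle", "niece"]


@st.composite
def pedigrees(draw):
    def person(pid, relation):
        n_dx = draw(st.integers(0, 3))
        cancers = []
        counters = {}
        for _ in range(n_dx):
            site = draw(st.sampled_from(_CANCERS))
            counters[site] = counters.get(site, 0) + 1
            cancers.append(
                CancerDiagnosis(
                    cancer_type=site,
                    age_at_dx=draw(st.one_of(st.none(), st.integers(0, 130))),
                    laterality=draw(st.sampled_from(["left", "right", "bilateral", "unknown"])),
                    hormone_status=frozenset(
                        draw(st.sets(st.sampled_from(["er_positive", "er_negative", "her2_positive"]), max_size=2))
                    ),
                    factors=frozenset(draw(st.sets(st.sampled_from(["msi_high", "mmr_stable"]), max_size=1))),
                    primary_index=counters[site],
                )
            )
        return Person(
            id=pid,
            relation=relation,
            sex=draw(st.sampled_from(["female", "male", "unknown"])),
            current_age=draw(st.one_of(st.none(), st.integers(0, 130))),
            deceased=draw(st.one_of(st.none(), st.booleans())),
            ancestry=frozenset(draw(st.sets(st.sampled_from(["ashkenazi_jewish", "european"]), max_size=1))),
            cancers=cancers,
            variants=frozenset(draw(st.sets(st.sampled_from(["brca1", "tp53", "mlh1"]), max_size=2))),
            syndromes=frozenset(draw(st.sets(st.sampled_from(["li_fraumeni", "lynch_syndrome"]), max_size=1))),
        )

    relatives = [
        person(f"r{i}", draw(st.sampled_from(_LABELS)))
        for i in range(draw(st.integers(0, 5)))
    ]
    return Pedigree(proband=person("proband", "self"), relatives=relatives)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(pedigrees())
def test_parse_write_identity_property(ped):
    txt = write_fhx(ped)
    reparsed = parse_fhx(txt)
    assert write_fhx(reparsed) == txt
    assert [p.relation for p in reparsed.persons()] == [p.relation for p in ped.persons()]
    assert [len(p.cancers) for p in reparsed.persons()] == [len(p.cancers) for p in ped.persons()]
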