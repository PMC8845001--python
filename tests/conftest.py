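import json

import pytest

from fhxscreen.criteria import default_rulebase
from fhxscreen.fhx import parse_fhx
from fhxscreen.vocabulary import default_table


@pytest.fixture(scope="session")
def table():
    return default_table()


@pytest.fixture(scope="session")
def rulebase():
    return default_rulebase()


def make_payload(proband=None, relatives=()):
    """Assemble a payload dict from person-shaped dicts."""
    root = {"relation": "self", "sex": "female", "age": 40}
    if proband:
        root.update(proband)
    root["relatives"] = list(relatives)
    return json.dumps(root)


@pytest.fixture
def prostate_payload():
    """Unaffected proband; father and brother with prostate cancer at 54/53."""
    return make_payload(
        relatives=[
            {"relation": "father", "sex": "male", "cancers": [{"type": "prostate", "age_at_dx": 54}]},
            {"relation": "brother", "sex": "male", "cancers": [{"type": "prostate", "age_at_dx": 53}]},
        ]
    )


@pytest.fixture
def prostate_pedigree(prostate_payload):
    return parse_fhx(prostate_payload)
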