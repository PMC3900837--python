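import pytest

from claimlink.model import (
    DictEntry,
    DiseaseDictionary,
    IdentityBlock,
    ModifierRule,
    Receipt,
)
from claimlink.keycode import KeyCodeSession


@pytest.fixture
def diabetes_dictionary() -> DiseaseDictionary:
    """Dictionary covering the classic type-2-diabetes spelling variants and
    a four-name rollup onto one ICD-10 renal-complication class."""
    entries = {
        "niddm": DictEntry("type 2 diabetes mellitus", "E11"),
        "diabetes ii": DictEntry("type 2 diabetes mellitus", "E11"),
        "adult diabetes": DictEntry("type 2 diabetes mellitus", "E11"),
        "diabetic nephropathy": DictEntry("diabetic nephropathy", "E142"),
        "diabetic renal failure": DictEntry("diabetic renal failure", "E142"),
        "kimmelstiel-wilson syndrome": DictEntry("Kimmelstiel-Wilson syndrome", "E142"),
        "diabetic nephrosclerosis": DictEntry("diabetic nephrosclerosis", "E142"),
        "type 2 diabetes": DictEntry("type 2 diabetes mellitus", "E11"),
    }
    rules = (
        ModifierRule(token="(susp.)", effect="suspected", position="suffix"),
        ModifierRule(token="suspected", effect="suspected", position="prefix"),
    )
    return DiseaseDictionary(entries=entries, modifier_rules=rules, version=1)


@pytest.fixture
def identity() -> IdentityBlock:
    return IdentityBlock(
        certificate_number="12345678",
        name="sato hiroshi",
        sex="M",
        date_of_birth="1960-04-01",
        relationship="self",
    )


@pytest.fixture
def outpatient_receipt(identity) -> Receipt:
    return Receipt(
        receipt_id="R1",
        receipt_type="outpatient",
        service_month="2005-04",
        institution_id="C0001",
        identity=identity,
        disease_names=("NIDDM",),
        prescription_expense=1200,
        total_expense=5400,
    )


@pytest.fixture
def session() -> KeyCodeSession:
    return KeyCodeSession.from_secret(b"unit-test-secret")
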