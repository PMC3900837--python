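"""Synthetic claims corpora: registries, coupled receipt streams, dictionaries, errors.

No real claims data can ship with this package, so every downstream stage is
exercised on synthetic corpora that emulate the structural features the
methods depend on:

* an insurer registry (certificate number, name, sex, date of birth,
  relationship to the policy holder), with realistic name duplication —
  distinct persons may share a name, and only the certificate number
  disambiguates them;
* monthly receipt issuance per institution, with the prescription-expense
  coupling rule: every outpatient receipt with a positive prescription
  expense spawns exactly one pharmacy receipt for the same person in the
  same month;
* a disease-name dictionary with several registered spelling variants per
  standardized name, many-to-one name-to-ICD-10 rollups, and a sampler that
  emits unregistered novel names at a configured rate;
* field-level data-entry errors injected into receipt identity blocks (never
  the registry, which is the insurer's authoritative roster), with a ground
  truth log so linkage results can be scored exactly.

Everything is reproducible from (config, seed).  Corruption operators
guarantee the serialized value actually changes — an "error" that leaves the
bytes intact would be undetectable and would bias calibration.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from pydantic import BaseModel, Field

from .model import (
    DictEntry,
    DiseaseDictionary,
    IdentityBlock,
    ModifierRule,
    Receipt,
    RegistryRecord,
)

__all__ = [
    "ErrorSpec",
    "SynthConfig",
    "ErrorLogEntry",
    "LinkageCorpus",
    "CALIBRATED_ERROR_SPEC",
    "generate_registry",
    "generate_receipts",
    "inject_errors",
    "generate_disease_dictionary",
    "generate_linkage_corpus",
    "truth_table",
]


class ErrorSpec(BaseModel):
    """Per-field corruption probabilities for receipt identity blocks.

    Each field of each targeted receipt is corrupted independently with its
    probability.  Corruption models: certificate numbers get a digit
    substituted or two adjacent digits swapped; names get one character
    substituted; sex is flipped; dates of birth are replaced by a different
    valid date; relationship is replaced by a different category.
    """

    p_certificate: float = Field(0.0, ge=0.0, le=1.0)
    p_name: float = Field(0.0, ge=0.0, le=1.0)
    p_sex: float = Field(0.0, ge=0.0, le=1.0)
    p_dob: float = Field(0.0, ge=0.0, le=1.0)
    p_relationship: float = Field(0.0, ge=0.0, le=1.0)


# Default error mix for the linkage evaluation corpus.  The field rates are
# back-derived from the evaluation's target operating point: with independent
# errors confined to the pharmacy side, certificate errors at 1.67%, name
# errors at 10%, and date-of-birth errors at 3.4% put the single-pattern
# (certificate+name+sex) match rate at (1-0.0167)(1-0.10) ~ 88.5% and the
# combined two-pattern rate at (1-0.0167)(1-0.10*0.034) ~ 98.0%.
CALIBRATED_ERROR_SPEC = ErrorSpec(
    p_certificate=0.0167, p_name=0.10, p_sex=0.0, p_dob=0.034, p_relationship=0.0
)


class SynthConfig(BaseModel):
    """Parameters of the synthetic corpus generator.

    Visit-model probabilities are monthly.  ``p_prescription`` is the chance
    that an outpatient visit carries a positive prescription expense (and
    therefore a coupled pharmacy receipt).
    """

    n_persons: int = Field(1000, gt=0)
    months: int = Field(12, gt=0)
    start_month: str = "2005-01"
    p_outpatient_visit: float = Field(0.35, ge=0.0, le=1.0)
    p_admission: float = Field(0.02, ge=0.0, le=1.0)
    p_prescription: float = Field(0.7, ge=0.0, le=1.0)
    n_standard_names: int = Field(500, gt=0)
    variants_per_name: int = Field(3, gt=0)
    p_unregistered: float = Field(0.019, ge=0.0, le=1.0)
    seed: int = 0


@dataclass(frozen=True)
class ErrorLogEntry:
    receipt_id: str
    field: str
    original: str
    corrupted: str


# name pools: small enough that distinct persons collide on name+sex at
# realistic corpus sizes (the certificate number must disambiguate)
_SURNAMES = [
    "sato", "suzuki", "takahashi", "tanaka", "watanabe", "ito", "yamamoto",
    "nakamura", "kobayashi", "kato", "yoshida", "yamada", "sasaki", "yamaguchi",
    "matsumoto", "inoue", "kimura", "hayashi", "shimizu", "saito", "mori",
    "abe", "ikeda", "hashimoto", "ishikawa", "ogawa", "goto", "okada",
    "hasegawa", "murakami", "kondo", "ishii", "maeda", "fujita", "sakamoto",
    "endo", "aoki", "fujii", "nishimura", "fukuda",
]
_GIVEN_M = [
    "hiroshi", "takashi", "kenji", "akira", "yuji", "masao", "koji", "shigeru",
    "minoru", "osamu", "tadashi", "kazuo", "noboru", "isamu", "takeshi",
    "daisuke", "kenta", "shota", "ryo", "yuta",
]
_GIVEN_F = [
    "yoko", "keiko", "kazuko", "sachiko", "yumiko", "hiroko", "michiko",
    "noriko", "kyoko", "masako", "junko", "emi", "aya", "naoko", "rie",
    "miyuki", "tomoko", "yuki", "haruka", "sakura",
]


def _months_from(start_month: str, months: int) -> list[str]:
    year, month = int(start_month[:4]), int(start_month[5:7])
    out = []
    for _ in range(months):
        out.append(f"{year:04d}-{month:02d}")
        month += 1
        if month > 12:
            month, year = 1, year + 1
    return out


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


def generate_registry(config: SynthConfig) -> list[RegistryRecord]:
    """Generate the insurer's roster of insured persons.

    Certificate numbers are unique 8-digit strings.  Names are drawn from a
    finite pool so duplicates occur.  Relationship is consistent with age at
    the corpus start: dependents under 18 are always "child"; "child" is
    never assigned above age 24; "self" and "spouse" require age >= 18.
    """
    rng = np.random.default_rng(config.seed)
    start_year = int(config.start_month[:4])
    records: list[RegistryRecord] = []
    cert_base = rng.integers(0, 10_000_000)
    for i in range(config.n_persons):
        cert = f"{(cert_base + i * 7) % 100_000_000:08d}"
        sex = "M" if rng.random() < 0.5 else "F"
        given = _GIVEN_M if sex == "M" else _GIVEN_F
        name = f"{_SURNAMES[rng.integers(len(_SURNAMES))]} {given[rng.integers(len(given))]}"
        birth_year = start_year - int(rng.integers(0, 90))
        birth_month = int(rng.integers(1, 13))
        birth_day = int(rng.integers(1, 29))
        age = start_year - birth_year
        if age < 18:
            relationship = "child"
        elif age < 25 and rng.random() < 0.5:
            relationship = "child"
        else:
            relationship = ("self", "spouse", "other-dependent")[
                int(rng.choice(3, p=[0.55, 0.30, 0.15]))
            ]
        records.append(
            RegistryRecord(
                certificate_number=cert,
                name=name,
                sex=sex,
                date_of_birth=f"{birth_year:04d}-{birth_month:02d}-{birth_day:02d}",
                relationship=relationship,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Receipts
# ---------------------------------------------------------------------------


def generate_receipts(
    registry: Sequence[RegistryRecord],
    config: SynthConfig,
    name_sampler: Callable[[np.random.Generator], str] | None = None,
) -> list[Receipt]:
    """Generate monthly receipt streams for every insured person.

    At most one receipt per (person, institution, month).  Outpatient visits
    occur with ``p_outpatient_visit`` per month; a visit carries a positive
    prescription expense with ``p_prescription``, in which case exactly one
    coupled pharmacy receipt is issued in the same month with the identity
    copied verbatim (errors, if any, are injected afterwards).  Admissions
    add an inpatient receipt.  Disease names come from ``name_sampler``;
    pharmacy receipts list no disease names.
    """
    if not registry:
        raise ValueError("registry must be non-empty")
    rng = np.random.default_rng(config.seed + 1)
    if name_sampler is None:
        _, name_sampler = generate_disease_dictionary(config)
    months = _months_from(config.start_month, config.months)
    n_clinics = max(1, len(registry) // 200)
    n_hospitals = max(1, len(registry) // 1000)
    n_pharmacies = max(1, len(registry) // 300)
    receipts: list[Receipt] = []
    rid = 0

    def next_id() -> str:
        nonlocal rid
        rid += 1
        return f"R{rid:08d}"

    for person in registry:
        identity = person.identity()
        clinic = f"C{int(rng.integers(n_clinics)):04d}"
        hospital = f"H{int(rng.integers(n_hospitals)):04d}"
        pharmacy = f"P{int(rng.integers(n_pharmacies)):04d}"
        for month in months:
            if rng.random() >= config.p_outpatient_visit:
                continue
            n_names = int(rng.integers(1, 4))
            names = tuple(name_sampler(rng) for _ in range(n_names))
            total = int(rng.integers(1_000, 50_000))
            if rng.random() < config.p_prescription:
                rx = int(rng.integers(500, max(501, total // 2 + 1)))
            else:
                rx = 0
            receipts.append(
                Receipt(
                    receipt_id=next_id(),
                    receipt_type="outpatient",
                    service_month=month,
                    institution_id=clinic,
                    identity=identity,
                    disease_names=names,
                    prescription_expense=rx,
                    total_expense=total,
                )
            )
            if rx > 0:
                receipts.append(
                    Receipt(
                        receipt_id=next_id(),
                        receipt_type="pharmacy",
                        service_month=month,
                        institution_id=pharmacy,
                        identity=identity,
                        disease_names=(),
                        prescription_expense=rx,
                        total_expense=rx,
                    )
                )
            if rng.random() < config.p_admission:
                receipts.append(
                    Receipt(
                        receipt_id=next_id(),
                        receipt_type="inpatient",
                        service_month=month,
                        institution_id=hospital,
                        identity=identity,
                        disease_names=tuple(name_sampler(rng) for _ in range(2)),
                        prescription_expense=0,
                        total_expense=int(rng.integers(100_000, 2_000_000)),
                    )
                )
    return receipts


def truth_table(receipts: Sequence[Receipt]) -> dict[str, str]:
    """Ground-truth person assignment: receipt_id -> certificate number.

    Valid on pre-injection corpora, where the identity block is verbatim.
    """
    return {r.receipt_id: r.identity.certificate_number for r in receipts}


# ---------------------------------------------------------------------------
# Error injection
# ---------------------------------------------------------------------------


def _corrupt_certificate(value: str, rng: np.random.Generator) -> str:
    digits = list(value)
    if len(digits) >= 2 and rng.random() < 0.5:
        # swap two adjacent distinct digits
        idxs = [i for i in range(len(digits) - 1) if digits[i] != digits[i + 1]]
        if idxs:
            i = idxs[int(rng.integers(len(idxs)))]
            digits[i], digits[i + 1] = digits[i + 1], digits[i]
            return "".join(digits)
    i = int(rng.integers(len(digits)))
    old = digits[i]
    choices = [c for c in string.digits if c != old]
    digits[i] = choices[int(rng.integers(len(choices)))]
    return "".join(digits)


def _corrupt_name(value: str, rng: np.random.Generator) -> str:
    chars = list(value)
    i = int(rng.integers(len(chars)))
    choices = [c for c in string.ascii_lowercase if c != chars[i]]
    chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


def _corrupt_sex(value: str, rng: np.random.Generator) -> str:
    return "F" if value == "M" else "M"


def _corrupt_dob(value: str, rng: np.random.Generator) -> str:
    while True:
        y = int(rng.integers(1915, 2006))
        m = int(rng.integers(1, 13))
        d = int(rng.integers(1, 29))
        out = f"{y:04d}-{m:02d}-{d:02d}"
        if out != value:
            return out


def _corrupt_relationship(value: str, rng: np.random.Generator) -> str:
    choices = [r for r in ("self", "spouse", "child", "other-dependent") if r != value]
    return choices[int(rng.integers(len(choices)))]


_CORRUPTORS: dict[str, tuple[str, Callable[[str, np.random.Generator], str]]] = {
    "certificate_number": ("p_certificate", _corrupt_certificate),
    "name": ("p_name", _corrupt_name),
    "sex": ("p_sex", _corrupt_sex),
    "date_of_birth": ("p_dob", _corrupt_dob),
    "relationship": ("p_relationship", _corrupt_relationship),
}


def inject_errors(
    receipts: Sequence[Receipt], spec: ErrorSpec, seed: int
) -> tuple[list[Receipt], list[ErrorLogEntry]]:
    """Corrupt identity fields of the given receipts, returning a new corpus.

    Pure function: the input corpus is untouched.  Each identity field of
    each receipt is corrupted independently with its configured probability;
    every corruption changes the serialized value.  The ground-truth log
    records every change.
    """
    rng = np.random.default_rng(seed)
    out: list[Receipt] = []
    log: list[ErrorLogEntry] = []
    probs = spec.model_dump()
    for r in receipts:
        values = {f: r.identity.get(f) for f in _CORRUPTORS}
        changed = False
        for fname, (pkey, fn) in _CORRUPTORS.items():
            p = probs[pkey]
            if p <= 0.0 or not values[fname]:
                continue
            if rng.random() < p:
                original = values[fname]
                corrupted = fn(original, rng)
                assert corrupted != original
                values[fname] = corrupted
                changed = True
                log.append(ErrorLogEntry(r.receipt_id, fname, original, corrupted))
        out.append(r.with_identity(IdentityBlock(**values)) if changed else r)
    return out, log


# ---------------------------------------------------------------------------
# Disease-name dictionary + sampler
# ---------------------------------------------------------------------------

_ADJECTIVES = [
    "acute", "chronic", "atypical", "benign", "recurrent", "idiopathic",
    "juvenile", "latent", "nodular", "diffuse", "focal", "systemic",
    "primary", "secondary", "congenital", "degenerative", "obstructive",
    "ulcerative", "infectious", "allergic",
]
_ORGANS = [
    "hepatic", "renal", "gastric", "cardiac", "pulmonary", "dermal",
    "neural", "ocular", "aural", "osseous", "vascular", "lymphatic",
    "pancreatic", "thyroid", "colonic", "bronchial", "splenic", "biliary",
    "articular", "muscular",
]
_NOUNS = [
    "sclerosis", "dystrophy", "neuropathy", "dermatitis", "carcinoma",
    "stenosis", "fibrosis", "granuloma", "syndrome", "insufficiency",
    "hyperplasia", "atrophy", "lesion", "edema", "infarction", "abscess",
    "cyst", "ulcer", "polyp", "anomaly",
]


def generate_disease_dictionary(
    config: SynthConfig,
) -> tuple[DiseaseDictionary, Callable[[np.random.Generator], str]]:
    """Build a synthetic variant dictionary and a matching name sampler.

    Each of ``n_standard_names`` standardized names gets
    ``variants_per_name`` registered spelling variants (the standardized name
    itself plus abbreviated/reordered forms) and an ICD-10-shaped code.
    Roughly every fifth standardized name shares its code with the previous
    one, emulating several clinically distinct diagnoses rolling up to a
    single ICD-10 class.  The sampler emits a registered variant with
    probability ``1 - p_unregistered`` and an unregistered novel string
    otherwise.
    """
    rng = np.random.default_rng(config.seed + 2)
    entries: dict[str, DictEntry] = {}
    variants: list[str] = []
    code_idx = -1
    for i in range(config.n_standard_names):
        adj = _ADJECTIVES[int(rng.integers(len(_ADJECTIVES)))]
        organ = _ORGANS[int(rng.integers(len(_ORGANS)))]
        noun = _NOUNS[int(rng.integers(len(_NOUNS)))]
        standard = f"{adj} {organ} {noun} type {i}"
        if i % 5 != 1 or i == 0:
            code_idx += 1  # every name with i % 5 == 1 shares the previous code
        code = f"{chr(ord('A') + code_idx // 1000)}{code_idx % 1000:03d}"
        forms = [
            standard,
            f"{organ} {noun} t{i}",
            f"{adj[:4]}. {organ} {noun} {i}",
            f"{noun} {organ} variant {i}",
            f"{adj} {noun} form {i}",
        ]
        for j in range(config.variants_per_name):
            variant = forms[j % len(forms)]
            if variant not in entries:
                entries[variant] = DictEntry(standard, code)
                variants.append(variant)

    dictionary = DiseaseDictionary(
        entries=entries,
        modifier_rules=(ModifierRule(token="(susp.)", effect="suspected", position="suffix"),),
        version=1,
    )
    p_unreg = config.p_unregistered
    n_variants = len(variants)

    def sampler(sampler_rng: np.random.Generator) -> str:
        if sampler_rng.random() < p_unreg:
            # "unlisted" prefix never occurs among registered variants
            return f"unlisted condition {int(sampler_rng.integers(10_000_000))}"
        return variants[int(sampler_rng.integers(n_variants))]

    return dictionary, sampler


# ---------------------------------------------------------------------------
# Calibrated linkage-evaluation corpus
# ---------------------------------------------------------------------------


@dataclass
class LinkageCorpus:
    """Coupled outpatient/pharmacy pairs with pharmacy-side entry errors."""

    registry: list[RegistryRecord]
    outpatient: list[Receipt]
    pharmacy: list[Receipt]
    error_log: list[ErrorLogEntry]


def generate_linkage_corpus(
    n_pairs: int,
    seed: int,
    error_spec: ErrorSpec = CALIBRATED_ERROR_SPEC,
    service_month: str = "2005-04",
) -> LinkageCorpus:
    """Corpus for the match-rate evaluation.

    One insured person per pair; each person has one outpatient receipt with
    a positive prescription expense and the coupled same-month pharmacy
    receipt.  Identity fields are copied verbatim to the pharmacy receipt,
    then entry errors are injected into the pharmacy side only (the
    outpatient side plays the registry-quality reference role).
    """
    config = SynthConfig(
        n_persons=n_pairs,
        months=1,
        start_month=service_month,
        p_outpatient_visit=1.0,
        p_admission=0.0,
        p_prescription=1.0,
        seed=seed,
    )
    registry = generate_registry(config)
    receipts = generate_receipts(registry, config)
    outpatient = [r for r in receipts if r.receipt_type == "outpatient"]
    pharmacy = [r for r in receipts if r.receipt_type == "pharmacy"]
    assert len(outpatient) == n_pairs and len(pharmacy) == n_pairs
    pharmacy, log = inject_errors(pharmacy, error_spec, seed=seed + 3)
    return LinkageCorpus(
        registry=registry, outpatient=outpatient, pharmacy=pharmacy, error_log=log
    )
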