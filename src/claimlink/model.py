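"""Core domain types for the claims database and readers/writers for its file dialects.

A *receipt* is a monthly health-insurance claim issued by one institution for one
insured person.  The insurer additionally holds a *registry* — the authoritative
roster of insured persons, one record per person, present even for persons who
generated no claims.  Disease names on receipts are free text; a
:class:`DiseaseDictionary` maps known spelling variants to standardized disease
names and ICD-10 classes.

File dialects are UTF-8 CSV (quoted) and JSONL.  Dates are ISO-8601: ``YYYY-MM``
for service months and ``YYYY-MM-DD`` for birth dates.  Missing identity fields
are serialized as empty strings.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SEXES",
    "RELATIONSHIPS",
    "RECEIPT_TYPES",
    "IdentityBlock",
    "RegistryRecord",
    "Receipt",
    "DictEntry",
    "ModifierRule",
    "DiseaseDictionary",
    "StandardizedDiagnosis",
    "Violation",
    "RowError",
    "CorpusValidationError",
    "read_receipts",
    "write_receipts",
    "validate_receipt",
    "read_registry",
    "write_registry",
    "read_dictionary",
    "write_dictionary",
    "read_modifier_rules",
    "write_modifier_rules",
]

SEXES = ("M", "F")
RELATIONSHIPS = ("self", "spouse", "child", "other-dependent")
RECEIPT_TYPES = ("inpatient", "outpatient", "pharmacy")

RECEIPT_COLUMNS = [
    "receipt_id",
    "receipt_type",
    "service_month",
    "institution_id",
    "certificate_number",
    "name",
    "sex",
    "date_of_birth",
    "relationship",
    "disease_names",
    "prescription_expense",
    "total_expense",
]

REGISTRY_COLUMNS = ["certificate_number", "name", "sex", "date_of_birth", "relationship"]

DICTIONARY_COLUMNS = ["variant", "standardized_name", "icd10_code"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IdentityBlock:
    """Identity fields as written on a receipt — possibly erroneous or blank.

    All fields are stored as strings so that data-entry errors (a swapped
    digit, a mistyped character) are representable verbatim; an empty string
    means the field is missing on the receipt.
    """

    certificate_number: str = ""
    name: str = ""
    sex: str = ""
    date_of_birth: str = ""
    relationship: str = ""

    def get(self, field_name: str) -> str:
        return getattr(self, field_name)


@dataclass(frozen=True)
class RegistryRecord:
    """One insured person on the insurer's roster."""

    certificate_number: str
    name: str
    sex: str
    date_of_birth: str
    relationship: str

    def identity(self) -> IdentityBlock:
        """The registry record viewed as an (error-free) identity block."""
        return IdentityBlock(
            certificate_number=self.certificate_number,
            name=self.name,
            sex=self.sex,
            date_of_birth=self.date_of_birth,
            relationship=self.relationship,
        )


@dataclass(frozen=True)
class Receipt:
    """One monthly claim from one institution for one person."""

    receipt_id: str
    receipt_type: str
    service_month: str
    institution_id: str
    identity: IdentityBlock
    disease_names: tuple[str, ...] = ()
    prescription_expense: int = 0
    total_expense: int = 0

    def with_identity(self, identity: IdentityBlock) -> "Receipt":
        return replace(self, identity=identity)


@dataclass(frozen=True)
class DictEntry:
    standardized_name: str
    icd10_code: str


@dataclass(frozen=True)
class ModifierRule:
    """A modifier token recognized during standardization.

    ``position`` restricts where the token may appear on a canonical name:
    ``"prefix"`` or ``"suffix"``.  ``effect`` is currently only ``"suspected"``
    — the token marks a provisional diagnosis written to justify tests or
    medication, which must stay distinguishable from a definite diagnosis.
    """

    token: str
    effect: str = "suspected"
    position: str = "suffix"


@dataclass
class DiseaseDictionary:
    """Mapping from canonical variant spellings to standardized names + ICD-10 codes.

    The mapping is a function: one variant resolves to exactly one target.
    ``version`` increases strictly on every update so annotations can record
    which dictionary produced them.
    """

    entries: dict[str, DictEntry] = field(default_factory=dict)
    modifier_rules: tuple[ModifierRule, ...] = ()
    version: int = 1

    def __post_init__(self) -> None:
        for variant, entry in self.entries.items():
            if not entry.icd10_code:
                raise ValueError(f"dictionary entry {variant!r} has empty icd10_code")

    def __len__(self) -> int:
        return len(self.entries)


ABSENT = None  # standardized_name / icd10_code value for unregistered names


@dataclass(frozen=True)
class StandardizedDiagnosis:
    """Outcome of standardizing one raw disease name.

    ``status`` is ``"standardized"`` iff the dictionary resolved the name, in
    which case ``standardized_name`` and ``icd10_code`` are both present;
    for ``"unregistered"`` both are ``None``.  ``base_name`` caches the
    canonical, modifier-stripped form so re-standardization under a newer
    dictionary can re-run the lookup alone.
    """

    raw_name: str
    base_name: str
    standardized_name: str | None
    icd10_code: str | None
    suspected: bool
    status: str

    def __post_init__(self) -> None:
        both = self.standardized_name is not None and self.icd10_code is not None
        if self.status == "standardized" and not both:
            raise ValueError("standardized diagnosis must carry name and code")
        if self.status == "unregistered" and (
            self.standardized_name is not None or self.icd10_code is not None
        ):
            raise ValueError("unregistered diagnosis must carry neither name nor code")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    field: str
    rule: str


@dataclass(frozen=True)
class RowError:
    row: int
    message: str


class CorpusValidationError(ValueError):
    """Raised for corpus-level integrity failures (e.g. duplicate receipt ids)."""


def validate_receipt(r: Receipt) -> list[Violation]:
    """Check a receipt against the type invariants.

    Total function: returns an empty list iff all invariants hold, otherwise
    one :class:`Violation` per broken rule, naming the offending field(s).
    """
    out: list[Violation] = []
    if not r.receipt_id:
        out.append(Violation("receipt_id", "must be non-empty"))
    if r.receipt_type not in RECEIPT_TYPES:
        out.append(Violation("receipt_type", f"must be one of {RECEIPT_TYPES}"))
    if not _is_year_month(r.service_month):
        out.append(Violation("service_month", "must be ISO-8601 YYYY-MM"))
    if not r.institution_id:
        out.append(Violation("institution_id", "must be non-empty"))
    if not r.identity.certificate_number:
        out.append(Violation("certificate_number", "must be non-empty"))
    if r.identity.sex and r.identity.sex not in SEXES:
        out.append(Violation("sex", f"must be one of {SEXES} or blank"))
    if r.identity.relationship and r.identity.relationship not in RELATIONSHIPS:
        out.append(Violation("relationship", f"must be one of {RELATIONSHIPS} or blank"))
    if r.prescription_expense < 0:
        out.append(Violation("prescription_expense", "must be non-negative"))
    if r.total_expense < 0:
        out.append(Violation("total_expense", "must be non-negative"))
    if r.prescription_expense > r.total_expense:
        out.append(
            Violation(
                "prescription_expense,total_expense",
                "prescription_expense must not exceed total_expense",
            )
        )
    if r.receipt_type != "pharmacy" and not r.disease_names:
        # Medical receipts justify their expenses with at least one diagnosis;
        # pharmacy receipts are permitted an empty disease list.
        out.append(Violation("disease_names", "medical receipts must list >=1 disease name"))
    return out


def _is_year_month(s: str) -> bool:
    if len(s) != 7 or s[4] != "-":
        return False
    y, m = s[:4], s[5:]
    return y.isdigit() and m.isdigit() and 1 <= int(m) <= 12


# ---------------------------------------------------------------------------
# Receipt I/O
# ---------------------------------------------------------------------------


def _receipt_to_row(r: Receipt) -> dict[str, str]:
    return {
        "receipt_id": r.receipt_id,
        "receipt_type": r.receipt_type,
        "service_month": r.service_month,
        "institution_id": r.institution_id,
        "certificate_number": r.identity.certificate_number,
        "name": r.identity.name,
        "sex": r.identity.sex,
        "date_of_birth": r.identity.date_of_birth,
        "relationship": r.identity.relationship,
        "disease_names": ";".join(r.disease_names),
        "prescription_expense": str(r.prescription_expense),
        "total_expense": str(r.total_expense),
    }


def _receipt_from_mapping(d: dict, disease_names: Sequence[str]) -> Receipt:
    return Receipt(
        receipt_id=str(d["receipt_id"]),
        receipt_type=str(d["receipt_type"]),
        service_month=str(d["service_month"]),
        institution_id=str(d["institution_id"]),
        identity=IdentityBlock(
            certificate_number=str(d.get("certificate_number", "")),
            name=str(d.get("name", "")),
            sex=str(d.get("sex", "")),
            date_of_birth=str(d.get("date_of_birth", "")),
            relationship=str(d.get("relationship", "")),
        ),
        disease_names=tuple(disease_names),
        prescription_expense=int(d["prescription_expense"]),
        total_expense=int(d["total_expense"]),
    )


def read_receipts(
    path: str | Path, dialect: str = "csv"
) -> tuple[list[Receipt], list[RowError]]:
    """Read a receipt file, preserving file order.

    Malformed rows are collected into the returned error report rather than
    silently dropped.  A duplicate ``receipt_id`` raises
    :class:`CorpusValidationError` naming both rows.
    """
    path = Path(path)
    records: list[Receipt] = []
    errors: list[RowError] = []
    if dialect == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                try:
                    names = [n for n in (row.get("disease_names") or "").split(";") if n]
                    records.append(_receipt_from_mapping(_require(row), names))
                except (KeyError, TypeError, ValueError) as exc:
                    errors.append(RowError(lineno, f"{type(exc).__name__}: {exc}"))
    elif dialect == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    d = json.loads(line)
                    records.append(_receipt_from_mapping(_require(d), d.get("disease_names", [])))
                except (KeyError, TypeError, ValueError) as exc:
                    errors.append(RowError(lineno, f"{type(exc).__name__}: {exc}"))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    seen: dict[str, int] = {}
    for i, r in enumerate(records):
        if r.receipt_id in seen:
            raise CorpusValidationError(
                f"duplicate receipt_id {r.receipt_id!r} at records {seen[r.receipt_id]} and {i}"
            )
        seen[r.receipt_id] = i
    return records, errors


def _require(d: dict) -> dict:
    for key in ("receipt_id", "receipt_type", "service_month", "institution_id",
                "prescription_expense", "total_expense"):
        if d.get(key) in (None, ""):
            raise KeyError(key)
    return d


def write_receipts(records: Iterable[Receipt], path: str | Path, dialect: str = "csv") -> None:
    """Write receipts so that :func:`read_receipts` reproduces them field-for-field."""
    path = Path(path)
    if dialect == "csv":
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=RECEIPT_COLUMNS, quoting=csv.QUOTE_ALL)
            writer.writeheader()
            for r in records:
                writer.writerow(_receipt_to_row(r))
    elif dialect == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for r in records:
                d = _receipt_to_row(r)
                d["disease_names"] = list(r.disease_names)  # type: ignore[assignment]
                d["prescription_expense"] = r.prescription_expense  # type: ignore[assignment]
                d["total_expense"] = r.total_expense  # type: ignore[assignment]
                fh.write(json.dumps(d, ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------


def read_registry(path: str | Path) -> list[RegistryRecord]:
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        return [
            RegistryRecord(
                certificate_number=row["certificate_number"],
                name=row["name"],
                sex=row["sex"],
                date_of_birth=row["date_of_birth"],
                relationship=row["relationship"],
            )
            for row in csv.DictReader(fh)
        ]


def write_registry(records: Iterable[RegistryRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=REGISTRY_COLUMNS, quoting=csv.QUOTE_ALL)
        writer.writeheader()
        for r in records:
            writer.writerow(
                {
                    "certificate_number": r.certificate_number,
                    "name": r.name,
                    "sex": r.sex,
                    "date_of_birth": r.date_of_birth,
                    "relationship": r.relationship,
                }
            )


# ---------------------------------------------------------------------------
# Dictionary I/O
# ---------------------------------------------------------------------------


def read_dictionary(
    path: str | Path,
    rules_path: str | Path | None = None,
    version: int = 1,
) -> DiseaseDictionary:
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        entries = {
            row["variant"]: DictEntry(row["standardized_name"], row["icd10_code"])
            for row in csv.DictReader(fh)
        }
    rules: tuple[ModifierRule, ...] = ()
    if rules_path is not None:
        rules = read_modifier_rules(rules_path)
    return DiseaseDictionary(entries=entries, modifier_rules=rules, version=version)


def write_dictionary(dictionary: DiseaseDictionary, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=DICTIONARY_COLUMNS, quoting=csv.QUOTE_ALL)
        writer.writeheader()
        for variant, entry in dictionary.entries.items():
            writer.writerow(
                {
                    "variant": variant,
                    "standardized_name": entry.standardized_name,
                    "icd10_code": entry.icd10_code,
                }
            )


def read_modifier_rules(path: str | Path) -> tuple[ModifierRule, ...]:
    with Path(path).open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return tuple(
        ModifierRule(
            token=d["token"],
            effect=d.get("effect", "suspected"),
            position=d.get("position", "suffix"),
        )
        for d in raw
    )


def write_modifier_rules(rules: Iterable[ModifierRule], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(
            [{"token": r.token, "effect": r.effect, "position": r.position} for r in rules],
            fh,
            ensure_ascii=False,
            indent=2,
        )
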