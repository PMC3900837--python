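"""Post-entry standardization of raw receipt disease names.

The same disease is written differently across institutions (type 2 diabetes
may appear as "NIDDM", "diabetes II", or "adult diabetes").  Rather than
coding diagnoses at entry time, names are entered as written and standardized
afterwards by exact lookup in an updatable variant dictionary mapping each
known spelling to a standardized disease name and its ICD-10 class.  Names
missing from the dictionary are reported as *unregistered* and feed dictionary
growth, so the automatic-standardization rate improves monotonically over
monthly processing cycles; annotations made under an older dictionary can be
re-standardized retroactively, keeping time series consistent.

Pipeline per raw name: canonicalize -> split modifiers -> exact lookup.
Standardized names are finer-grained than their ICD-10 class (several distinct
standardized names may roll up to one code, e.g. the four renal-complication
diabetes diagnoses under E142), and suspected-diagnosis modifiers are carried
as a flag, never merged into the name.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .model import (
    DictEntry,
    DiseaseDictionary,
    ModifierRule,
    Receipt,
    StandardizedDiagnosis,
)

__all__ = [
    "ICD10_CODE_RE",
    "StandardizationReport",
    "AnnotatedReceipt",
    "DictionaryConflictError",
    "canonicalize_name",
    "split_modifiers",
    "lookup_standard",
    "standardize_batch",
    "update_dictionary",
    "restandardize",
]

logger = logging.getLogger(__name__)

# One letter + 2 digits + optional 1-2 alphanumerics: accepts both dotless
# 4-character codes like E142 and plain 3-character classes like E14.
ICD10_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[0-9A-Z]{0,2}$")

_WS_RUN = re.compile(r"\s+")


# ---------------------------------------------------------------------------
# Name preprocessing
# ---------------------------------------------------------------------------


def canonicalize_name(raw: str) -> str:
    """Deterministically normalize a raw disease name for dictionary lookup.

    Applies Unicode compatibility normalization (NFKC: unifies full-width and
    half-width forms, among others), strips leading/trailing whitespace,
    collapses internal whitespace runs to a single space, and lower-cases
    ASCII letters.  Non-ASCII characters keep their case: the normalization is
    the minimal one that merges trivially distinct spellings.
    """
    s = unicodedata.normalize("NFKC", raw)
    s = _WS_RUN.sub(" ", s).strip()
    return "".join(c.lower() if c.isascii() else c for c in s)


def split_modifiers(
    canonical: str, rules: Sequence[ModifierRule]
) -> tuple[str, bool]:
    """Strip at most one modifier token from a canonical name.

    Each rule's token may match only at its configured position (prefix or
    suffix); among matching rules the longest token wins.  Returns the
    re-canonicalized base name and whether a suspected-effect token matched.
    A token occurring elsewhere in the string is not a modifier.
    """
    best: ModifierRule | None = None
    for rule in rules:
        token = canonicalize_name(rule.token)
        if not token:
            continue
        hit = (
            canonical.startswith(token)
            if rule.position == "prefix"
            else canonical.endswith(token)
        )
        if hit and (best is None or len(token) > len(canonicalize_name(best.token))):
            best = rule
    if best is None:
        return canonical, False
    token = canonicalize_name(best.token)
    if best.position == "prefix":
        base = canonical[len(token):]
    else:
        base = canonical[: len(canonical) - len(token)]
    return canonicalize_name(base), best.effect == "suspected"


# ---------------------------------------------------------------------------
# Lookup
# ---------------------------------------------------------------------------


def lookup_standard(
    dictionary: DiseaseDictionary, base: str, suspected: bool, raw_name: str | None = None
) -> StandardizedDiagnosis:
    """Exact-match lookup of a canonical base name.

    No fuzzy matching: a miss is reported as unregistered and is the signal
    that the variant should be registered in a future dictionary update.
    """
    entry = dictionary.entries.get(base)
    if entry is None:
        return StandardizedDiagnosis(
            raw_name=raw_name if raw_name is not None else base,
            base_name=base,
            standardized_name=None,
            icd10_code=None,
            suspected=suspected,
            status="unregistered",
        )
    return StandardizedDiagnosis(
        raw_name=raw_name if raw_name is not None else base,
        base_name=base,
        standardized_name=entry.standardized_name,
        icd10_code=entry.icd10_code,
        suspected=suspected,
        status="standardized",
    )


def standardize_name(raw: str, dictionary: DiseaseDictionary) -> StandardizedDiagnosis:
    """Full per-name pipeline: canonicalize, split modifiers, look up."""
    canonical = canonicalize_name(raw)
    base, suspected = split_modifiers(canonical, dictionary.modifier_rules)
    return lookup_standard(dictionary, base, suspected, raw_name=raw)


# ---------------------------------------------------------------------------
# Batch standardization and reporting
# ---------------------------------------------------------------------------


@dataclass
class StandardizationReport:
    """Accounting of a standardization run.

    Rates are reported under two denominators: per disease name, and per
    receipt (a receipt counts as standardized only if *all* its names
    standardize).  With single-diagnosis receipts the two coincide.  The
    degenerate empty run has rate 1.0 by convention.
    """

    total_names: int = 0
    standardized: int = 0
    unregistered: int = 0
    total_receipts: int = 0
    receipts_standardized: int = 0
    unregistered_names: Counter = field(default_factory=Counter)
    dictionary_version: int = 0

    @property
    def rate(self) -> float:
        """Per-name automatic standardization rate."""
        if self.total_names == 0:
            return 1.0
        return self.standardized / self.total_names

    @property
    def receipt_rate(self) -> float:
        """Per-receipt rate: all names on the receipt standardized."""
        if self.total_receipts == 0:
            return 1.0
        return self.receipts_standardized / self.total_receipts


@dataclass(frozen=True)
class AnnotatedReceipt:
    """A receipt joined with the standardization outcome of each disease name."""

    receipt: Receipt
    diagnoses: tuple[StandardizedDiagnosis, ...]
    dictionary_version: int

    @property
    def fully_standardized(self) -> bool:
        return all(d.status == "standardized" for d in self.diagnoses)


def _report_from(annotated: Sequence[AnnotatedReceipt], version: int) -> StandardizationReport:
    report = StandardizationReport(dictionary_version=version)
    for ann in annotated:
        report.total_receipts += 1
        if ann.diagnoses and ann.fully_standardized:
            report.receipts_standardized += 1
        elif not ann.diagnoses:
            # A receipt with no names (pharmacy) has nothing to standardize.
            report.receipts_standardized += 1
        for diag in ann.diagnoses:
            report.total_names += 1
            if diag.status == "standardized":
                report.standardized += 1
            else:
                report.unregistered += 1
                report.unregistered_names[diag.base_name] += 1
    return report


def standardize_batch(
    receipts: Iterable[Receipt], dictionary: DiseaseDictionary
) -> tuple[list[AnnotatedReceipt], StandardizationReport]:
    """Standardize every disease name on every receipt.

    Deterministic: identical corpus + dictionary version give identical
    annotations and report.  An empty dictionary is allowed (everything comes
    back unregistered) but logged as a warning.
    """
    if not dictionary.entries:
        logger.warning("standardizing against an empty dictionary: all names unregistered")
    # memoize per distinct raw spelling: corpora repeat names heavily
    cache: dict[str, StandardizedDiagnosis] = {}
    annotated: list[AnnotatedReceipt] = []
    for receipt in receipts:
        diags = []
        for raw in receipt.disease_names:
            diag = cache.get(raw)
            if diag is None:
                diag = standardize_name(raw, dictionary)
                cache[raw] = diag
            diags.append(diag)
        annotated.append(AnnotatedReceipt(receipt, tuple(diags), dictionary.version))
    report = _report_from(annotated, dictionary.version)
    if report.total_names == 0:
        logger.warning("standardization batch contained no disease names")
    return annotated, report


# ---------------------------------------------------------------------------
# Dictionary update and retroactive re-standardization
# ---------------------------------------------------------------------------


class DictionaryConflictError(ValueError):
    """A new entry re-maps an existing variant without the override flag."""


def update_dictionary(
    dictionary: DiseaseDictionary,
    new_entries: dict[str, DictEntry],
    override: bool = False,
) -> DiseaseDictionary:
    """Return a new dictionary with the entries added and the version bumped.

    Re-adding an identical entry is a no-op on the mapping (the version still
    increments).  Re-mapping a variant to a different target requires
    ``override=True``; otherwise the conflict is rejected, naming the variant
    and both targets.
    """
    merged = dict(dictionary.entries)
    for variant, entry in new_entries.items():
        if not ICD10_CODE_RE.match(entry.icd10_code):
            raise ValueError(
                f"new entry {variant!r} has malformed ICD-10 code {entry.icd10_code!r}"
            )
        existing = merged.get(variant)
        if existing is not None and existing != entry and not override:
            raise DictionaryConflictError(
                f"variant {variant!r} already maps to {existing}, refusing to re-map "
                f"to {entry} without override"
            )
        merged[variant] = entry
    return DiseaseDictionary(
        entries=merged,
        modifier_rules=dictionary.modifier_rules,
        version=dictionary.version + 1,
    )


def restandardize(
    annotated: Iterable[AnnotatedReceipt], dictionary: DiseaseDictionary
) -> tuple[list[AnnotatedReceipt], StandardizationReport]:
    """Retroactively re-standardize previously annotated receipts.

    Uses the canonical base name cached on each annotation, so only the
    dictionary lookup is re-run; the result is identical to
    :func:`standardize_batch` from scratch under the new dictionary, including
    target changes introduced by override updates.  Re-running with an
    unchanged dictionary is the identity.
    """
    out: list[AnnotatedReceipt] = []
    cache: dict[tuple[str, bool], StandardizedDiagnosis] = {}
    for ann in annotated:
        diags = []
        for diag in ann.diagnoses:
            key = (diag.base_name, diag.suspected)
            fresh = cache.get(key)
            if fresh is None:
                fresh = lookup_standard(
                    dictionary, diag.base_name, diag.suspected, raw_name=diag.raw_name
                )
                cache[key] = fresh
            elif fresh.raw_name != diag.raw_name:
                fresh = StandardizedDiagnosis(
                    raw_name=diag.raw_name,
                    base_name=fresh.base_name,
                    standardized_name=fresh.standardized_name,
                    icd10_code=fresh.icd10_code,
                    suspected=fresh.suspected,
                    status=fresh.status,
                )
            diags.append(fresh)
        out.append(AnnotatedReceipt(ann.receipt, tuple(diags), dictionary.version))
    return out, _report_from(out, dictionary.version)
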