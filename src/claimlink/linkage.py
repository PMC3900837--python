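"""Anonymous name identification over key-coded records.

Once identity fields are replaced by per-pattern key codes, recognizing the
same person across receipts reduces to digest equality: two records belong to
the same person when any in-use pattern gives them equal codes (union/OR
combination — adding patterns can only recover matches that a single pattern
missed, never lose them).  Records are clustered into persons by the
transitive closure of that relation; insurer registry records participate so
that insured persons who used no health care in a period still appear as
(singleton) clusters.

The evaluation statistic mirrors the prescription-expense coupling of claims:
every outpatient receipt with a positive prescription expense implies a
same-month pharmacy receipt for the same person, so the match rate is the
fraction of such outpatient receipts whose pharmacy counterpart is found via
key codes.
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .keycode import KeyCode, KeyCodePattern, KeyCodeSession, generate_keycodes
from .model import Receipt, RegistryRecord

__all__ = [
    "AnonymousRecord",
    "PersonCluster",
    "MatchReport",
    "KeyCodeIndex",
    "anonymize_receipts",
    "anonymize_registry",
    "build_index",
    "match_sets",
    "cluster_persons",
    "compute_match_report",
    "write_anonymous_records",
    "read_anonymous_records",
]


@dataclass(frozen=True)
class AnonymousRecord:
    """A receipt or registry record stripped to its key codes.

    Contains no identity fields.  ``keycodes`` maps pattern_id to the hex
    digest; a pattern whose code could not be generated is simply absent.
    """

    record_id: str
    record_kind: str  # "receipt" | "registry"
    keycodes: Mapping[int, str]
    receipt_type: str | None = None
    service_month: str | None = None
    prescription_expense: int | None = None


@dataclass(frozen=True)
class PersonCluster:
    """One anonymized person: a stable id and the records attributed to them.

    ``person_id`` is the hash of the sorted member digest set, so it does not
    depend on record ordering.
    """

    person_id: str
    member_record_ids: frozenset[str]


@dataclass
class MatchReport:
    """Match-percentage accounting for one linkage run."""

    method: str
    denominator: int
    matched: int
    unmatched_reasons: Counter = field(default_factory=Counter)

    @property
    def rate(self) -> float | None:
        """Matched fraction; None (undefined) for an empty denominator."""
        if self.denominator == 0:
            return None
        return self.matched / self.denominator

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "denominator": self.denominator,
            "matched": self.matched,
            "rate": self.rate,
            "unmatched_reasons": dict(self.unmatched_reasons),
        }


def _method_name(patterns_in_use: frozenset[int]) -> str:
    if patterns_in_use == frozenset({1}):
        return "pattern1_only"
    if patterns_in_use == frozenset({1, 2}):
        return "combined"
    return "custom"


# ---------------------------------------------------------------------------
# Key-code generation over corpora
# ---------------------------------------------------------------------------


def anonymize_receipts(
    receipts: Iterable[Receipt],
    patterns: Sequence[KeyCodePattern],
    session: KeyCodeSession,
) -> list[AnonymousRecord]:
    """Replace each receipt's identity block with its per-pattern key codes."""
    out = []
    for r in receipts:
        codes = generate_keycodes(r.identity, patterns, session)
        out.append(
            AnonymousRecord(
                record_id=r.receipt_id,
                record_kind="receipt",
                keycodes={
                    pid: kc.digest for pid, kc in codes.items() if kc is not None
                },
                receipt_type=r.receipt_type,
                service_month=r.service_month,
                prescription_expense=r.prescription_expense,
            )
        )
    return out


def anonymize_registry(
    registry: Iterable[RegistryRecord],
    patterns: Sequence[KeyCodePattern],
    session: KeyCodeSession,
) -> list[AnonymousRecord]:
    """Key-code the insurer's roster so zero-receipt persons enter the graph.

    Record ids are positional (``registry:<row>``): even the certificate
    number is an identity field and must not leak into anonymous outputs.
    """
    out = []
    for i, rec in enumerate(registry):
        codes = generate_keycodes(rec.identity(), patterns, session)
        out.append(
            AnonymousRecord(
                record_id=f"registry:{i:06d}",
                record_kind="registry",
                keycodes={
                    pid: kc.digest for pid, kc in codes.items() if kc is not None
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# Indexing and matching
# ---------------------------------------------------------------------------


@dataclass
class KeyCodeIndex:
    """Per-pattern inverted index: digest -> record ids carrying it."""

    by_pattern: dict[int, dict[str, list[str]]]
    skipped: list[str]  # records with no usable code under any in-use pattern

    def lookup(self, pattern_id: int, digest: str) -> list[str]:
        return self.by_pattern.get(pattern_id, {}).get(digest, [])


def build_index(
    records: Iterable[AnonymousRecord], patterns_in_use: Iterable[int]
) -> KeyCodeIndex:
    in_use = frozenset(patterns_in_use)
    by_pattern: dict[int, dict[str, list[str]]] = {p: defaultdict(list) for p in in_use}
    skipped: list[str] = []
    for rec in records:
        usable = False
        for pid in in_use:
            digest = rec.keycodes.get(pid)
            if digest is not None:
                by_pattern[pid][digest].append(rec.record_id)
                usable = True
        if not usable:
            skipped.append(rec.record_id)
    return KeyCodeIndex(
        by_pattern={p: dict(m) for p, m in by_pattern.items()}, skipped=skipped
    )


def match_sets(
    queries: Sequence[AnonymousRecord],
    targets: Sequence[AnonymousRecord],
    patterns_in_use: Iterable[int],
) -> tuple[MatchReport, list[tuple[str, str, int]]]:
    """Match queries against targets by key-code equality under any in-use pattern.

    Union (OR) logic: a query matches iff some in-use pattern's digest equals
    some target's digest for that same pattern.  Returns the report
    (denominator = number of queries) and the witnessed (query_id, target_id,
    pattern_id) pairs.
    """
    in_use = frozenset(patterns_in_use)
    index = build_index(targets, in_use)
    report = MatchReport(method=_method_name(in_use), denominator=len(queries), matched=0)
    if not queries:
        report.unmatched_reasons["empty_query_set"] += 1
        return report, []
    pairs: list[tuple[str, str, int]] = []
    for q in queries:
        hit = False
        q_has_code = False
        for pid in sorted(in_use):
            digest = q.keycodes.get(pid)
            if digest is None:
                continue
            q_has_code = True
            for target_id in index.lookup(pid, digest):
                pairs.append((q.record_id, target_id, pid))
                hit = True
        if hit:
            report.matched += 1
        elif not q_has_code:
            report.unmatched_reasons["query_keycodes_missing"] += 1
        else:
            report.unmatched_reasons["no_keycode_match"] += 1
    return report, pairs


# ---------------------------------------------------------------------------
# Person clustering
# ---------------------------------------------------------------------------


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:  # path compression
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1


def cluster_persons(
    records: Sequence[AnonymousRecord],
    patterns_in_use: Iterable[int],
    diagnostics: bool = False,
    outlier_size: int = 100,
) -> list[PersonCluster]:
    """Partition records into persons by transitive key-code equality.

    Union-find over the relation "shares a digest under some in-use pattern".
    Records with no usable code form singleton clusters.  ``diagnostics``
    additionally logs cluster sizes exceeding ``outlier_size`` — the signature
    of a digest collision or a degenerate pattern.
    """
    in_use = frozenset(patterns_in_use)
    uf = _UnionFind(len(records))
    first_seen: dict[tuple[int, str], int] = {}
    for i, rec in enumerate(records):
        for pid in in_use:
            digest = rec.keycodes.get(pid)
            if digest is None:
                continue
            key = (pid, digest)
            j = first_seen.setdefault(key, i)
            if j != i:
                uf.union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(records)):
        groups[uf.find(i)].append(i)

    clusters = []
    for members in groups.values():
        digests = sorted(
            {
                f"{pid}:{d}"
                for i in members
                for pid, d in records[i].keycodes.items()
                if pid in in_use
            }
        )
        seed = "\n".join(digests) if digests else "\n".join(
            sorted(records[i].record_id for i in members)
        )
        person_id = hashlib.sha256(seed.encode("utf-8")).hexdigest()[:16]
        clusters.append(
            PersonCluster(
                person_id=person_id,
                member_record_ids=frozenset(records[i].record_id for i in members),
            )
        )
    if diagnostics:
        import logging

        big = [c for c in clusters if len(c.member_record_ids) > outlier_size]
        if big:
            logging.getLogger(__name__).warning(
                "%d clusters exceed %d members (possible digest collisions)",
                len(big),
                outlier_size,
            )
    return sorted(clusters, key=lambda c: c.person_id)


# ---------------------------------------------------------------------------
# The prescription-expense match statistic
# ---------------------------------------------------------------------------


def compute_match_report(
    outpatient: Sequence[AnonymousRecord],
    pharmacy: Sequence[AnonymousRecord],
    patterns_in_use: Iterable[int],
) -> MatchReport:
    """Match rate of outpatient receipts to their pharmacy counterparts.

    Denominator: outpatient receipts with prescription_expense > 0 (those are
    exactly the receipts for which a pharmacy receipt must exist).  An
    outpatient receipt is matched iff some pharmacy receipt in the *same
    service month* shares a key code under an in-use pattern.
    """
    in_use = frozenset(patterns_in_use)
    report = MatchReport(method=_method_name(in_use), denominator=0, matched=0)

    # index pharmacy digests per (pattern, month)
    index: dict[tuple[int, str, str], bool] = {}
    for rec in pharmacy:
        month = rec.service_month or ""
        for pid in in_use:
            digest = rec.keycodes.get(pid)
            if digest is not None:
                index[(pid, month, digest)] = True

    for rec in outpatient:
        if not rec.prescription_expense or rec.prescription_expense <= 0:
            continue
        report.denominator += 1
        month = rec.service_month or ""
        hit = False
        has_code = False
        for pid in in_use:
            digest = rec.keycodes.get(pid)
            if digest is None:
                continue
            has_code = True
            if (pid, month, digest) in index:
                hit = True
                break
        if hit:
            report.matched += 1
        elif not has_code:
            report.unmatched_reasons["query_keycodes_missing"] += 1
        else:
            report.unmatched_reasons["no_pharmacy_keycode_match"] += 1
    if report.denominator == 0:
        report.unmatched_reasons["no_qualifying_outpatient_receipts"] += 1
    return report


# ---------------------------------------------------------------------------
# Anonymous-record I/O (identity-free by construction)
# ---------------------------------------------------------------------------


def write_anonymous_records(records: Iterable[AnonymousRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(
                json.dumps(
                    {
                        "record_id": rec.record_id,
                        "record_kind": rec.record_kind,
                        "receipt_type": rec.receipt_type,
                        "service_month": rec.service_month,
                        "prescription_expense": rec.prescription_expense,
                        "keycodes": {str(k): v for k, v in rec.keycodes.items()},
                    }
                )
                + "\n"
            )


def read_anonymous_records(path: str | Path) -> list[AnonymousRecord]:
    out = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            out.append(
                AnonymousRecord(
                    record_id=d["record_id"],
                    record_kind=d["record_kind"],
                    keycodes={int(k): v for k, v in d["keycodes"].items()},
                    receipt_type=d.get("receipt_type"),
                    service_month=d.get("service_month"),
                    prescription_expense=d.get("prescription_expense"),
                )
            )
    return out
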