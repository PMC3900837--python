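"""Anonymous name identification: indexing, matching, clustering, match reports."""

import dataclasses
from collections import defaultdict

import pytest

from claimlink.keycode import DEFAULT_PATTERNS, KeyCodeSession
from claimlink.linkage import (
    AnonymousRecord,
    anonymize_receipts,
    anonymize_registry,
    build_index,
    cluster_persons,
    compute_match_report,
    match_sets,
    read_anonymous_records,
    write_anonymous_records,
)
from claimlink.model import IdentityBlock, Receipt
from claimlink.synth import (
    ErrorSpec,
    SynthConfig,
    generate_receipts,
    generate_registry,
    inject_errors,
    truth_table,
)


def _receipt(i, identity, rtype="outpatient", month="2005-04", rx=100):
    return Receipt(
        receipt_id=f"R{i:05d}",
        receipt_type=rtype,
        service_month=month,
        institution_id="C0001",
        identity=identity,
        disease_names=() if rtype == "pharmacy" else ("x",),
        prescription_expense=rx,
        total_expense=max(rx, 1000),
    )


def _identity(i, **overrides):
    base = dict(
        certificate_number=f"{i:08d}",
        name=f"person {i}",
        sex="M" if i % 2 else "F",
        date_of_birth=f"19{50 + i % 50:02d}-01-01",
        relationship="self",
    )
    base.update(overrides)
    return IdentityBlock(**base)


@pytest.fixture
def keyed(session):
    def _keyed(receipts):
        return anonymize_receipts(receipts, DEFAULT_PATTERNS, session)

    return _keyed


class TestIndex:
    def test_shared_digest_maps_to_both_records(self, keyed):
        rs = [_receipt(0, _identity(7)), _receipt(1, _identity(7)), _receipt(2, _identity(8))]
        records = keyed(rs)
        index = build_index(records, {1})
        shared = records[0].keycodes[1]
        assert sorted(index.lookup(1, shared)) == ["R00000", "R00001"]

    def test_record_with_no_codes_is_skipped_and_tallied(self):
        empty = AnonymousRecord("X", "receipt", {})
        index = build_index([empty], {1, 2})
        assert index.skipped == ["X"]
        assert all(not m for m in index.by_pattern.values())

    def test_index_scope_ignores_out_of_use_patterns(self, keyed):
        records = keyed([_receipt(0, _identity(1))])
        index = build_index(records, {1})
        assert 2 not in index.by_pattern


class TestMatchSets:
    def test_error_free_pairs_match_under_any_pattern_set(self, keyed):
        queries = keyed([_receipt(i, _identity(i)) for i in range(5)])
        targets = keyed([_receipt(100 + i, _identity(i), rtype="pharmacy") for i in range(5)])
        for patterns in ({1}, {2}, {1, 2}):
            report, pairs = match_sets(queries, targets, patterns)
            assert report.rate == 1.0

    def test_name_error_rescued_by_pattern_2(self, keyed):
        queries = keyed([_receipt(0, _identity(3))])
        corrupted = keyed([_receipt(1, _identity(3, name="persom 3"), rtype="pharmacy")])
        r1, _ = match_sets(queries, corrupted, {1})
        r12, pairs = match_sets(queries, corrupted, {1, 2})
        assert r1.matched == 0 and r12.matched == 1
        assert pairs == [("R00000", "R00001", 2)]

    def test_certificate_error_breaks_both_patterns(self, keyed):
        queries = keyed([_receipt(0, _identity(3))])
        corrupted = keyed(
            [_receipt(1, _identity(3, certificate_number="99999999"), rtype="pharmacy")]
        )
        report, _ = match_sets(queries, corrupted, {1, 2})
        assert report.matched == 0
        assert report.unmatched_reasons["no_keycode_match"] == 1

    def test_empty_query_set_flagged(self, keyed):
        report, pairs = match_sets([], keyed([_receipt(0, _identity(0))]), {1})
        assert report.denominator == 0 and report.rate is None
        assert report.unmatched_reasons["empty_query_set"] == 1

    def test_monotone_in_pattern_set(self, keyed):
        queries = keyed([_receipt(i, _identity(i)) for i in range(20)])
        targets = []
        for i in range(20):
            overrides = {}
            if i % 3 == 0:
                overrides["name"] = f"wrong {i}"
            if i % 5 == 0:
                overrides["date_of_birth"] = "2000-12-31"
            targets.append(_receipt(100 + i, _identity(i, **overrides), rtype="pharmacy"))
        targets = keyed(targets)
        r1 = match_sets(queries, targets, {1})[0].rate
        r12 = match_sets(queries, targets, {1, 2})[0].rate
        assert r1 <= r12


class TestClustering:
    def test_one_person_three_receipt_month_forms_single_cluster(self, session):
        """Clinic visit, hospital admission, and pharmacy dispensing in one
        month: three receipts plus the registry record, one person."""
        ident = _identity(42)
        receipts = [
            _receipt(0, ident, rtype="outpatient"),
            _receipt(1, ident, rtype="inpatient", rx=0),
            _receipt(2, ident, rtype="pharmacy"),
        ]
        from claimlink.model import RegistryRecord

        registry = [
            RegistryRecord(
                certificate_number=ident.certificate_number,
                name=ident.name,
                sex=ident.sex,
                date_of_birth=ident.date_of_birth,
                relationship=ident.relationship,
            )
        ]
        records = anonymize_receipts(receipts, DEFAULT_PATTERNS, session)
        records += anonymize_registry(registry, DEFAULT_PATTERNS, session)
        clusters = cluster_persons(records, {1, 2})
        assert len(clusters) == 1
        assert len(clusters[0].member_record_ids) == 4

    def test_distinct_persons_stay_separate(self, keyed):
        records = keyed([_receipt(0, _identity(1)), _receipt(1, _identity(2))])
        assert len(cluster_persons(records, {1, 2})) == 2

    def test_partition_property(self, keyed):
        receipts = [_receipt(i, _identity(i % 7)) for i in range(30)]
        records = keyed(receipts)
        clusters = cluster_persons(records, {1, 2})
        seen = [rid for c in clusters for rid in c.member_record_ids]
        assert sorted(seen) == sorted(r.record_id for r in records)
        assert len(seen) == len(set(seen))

    def test_person_id_stable_under_record_reordering(self, keyed):
        receipts = [_receipt(i, _identity(i % 3)) for i in range(9)]
        records = keyed(receipts)
        ids_fwd = {c.person_id for c in cluster_persons(records, {1, 2})}
        ids_rev = {c.person_id for c in cluster_persons(list(reversed(records)), {1, 2})}
        assert ids_fwd == ids_rev

    def test_clustering_matches_ground_truth_on_error_free_corpus(self, session):
        """Oracle: on error-free synthetic data, key-code clustering must equal
        the partition induced by the true person assignment."""
        config = SynthConfig(n_persons=40, months=3, seed=11)
        registry = generate_registry(config)
        receipts = generate_receipts(registry, config)[:200]
        truth = truth_table(receipts)
        records = anonymize_receipts(receipts, DEFAULT_PATTERNS, session)
        clusters = cluster_persons(records, {1, 2})
        got = {frozenset(c.member_record_ids) for c in clusters}
        by_person = defaultdict(set)
        for rid, cert in truth.items():
            by_person[cert].add(rid)
        expected = {frozenset(v) for v in by_person.values()}
        assert got == expected

    def test_shared_name_separated_by_certificate_number(self, keyed):
        a = _identity(1, name="sato hiroshi")
        b = _identity(2, name="sato hiroshi", sex=_identity(1).sex)
        records = keyed([_receipt(0, a), _receipt(1, b)])
        assert len(cluster_persons(records, {1, 2})) == 2


class TestMatchReport:
    def _corpus(self, session, n=100, corrupt_names=10):
        outpatient = [_receipt(i, _identity(i), rx=500) for i in range(n)]
        pharmacy = [
            _receipt(1000 + i, _identity(i), rtype="pharmacy", rx=500) for i in range(n)
        ]
        for i in range(corrupt_names):
            pharmacy[i] = pharmacy[i].with_identity(
                dataclasses.replace(pharmacy[i].identity, name=f"corrupted {i}")
            )
        q = anonymize_receipts(outpatient, DEFAULT_PATTERNS, session)
        t = anonymize_receipts(pharmacy, DEFAULT_PATTERNS, session)
        return q, t

    def test_name_only_corruption_rates(self, session):
        q, t = self._corpus(session)
        assert compute_match_report(q, t, {1}).rate == pytest.approx(0.90)
        assert compute_match_report(q, t, {1, 2}).rate == pytest.approx(1.0)

    def test_zero_prescription_excluded_from_denominator(self, session):
        outpatient = [_receipt(0, _identity(0), rx=0), _receipt(1, _identity(1), rx=700)]
        pharmacy = [_receipt(2, _identity(1), rtype="pharmacy", rx=700)]
        q = anonymize_receipts(outpatient, DEFAULT_PATTERNS, session)
        t = anonymize_receipts(pharmacy, DEFAULT_PATTERNS, session)
        report = compute_match_report(q, t, {1})
        assert report.denominator == 1 and report.matched == 1

    def test_same_month_required(self, session):
        outpatient = [_receipt(0, _identity(0), month="2005-04", rx=500)]
        pharmacy = [_receipt(1, _identity(0), rtype="pharmacy", month="2005-05", rx=500)]
        q = anonymize_receipts(outpatient, DEFAULT_PATTERNS, session)
        t = anonymize_receipts(pharmacy, DEFAULT_PATTERNS, session)
        assert compute_match_report(q, t, {1, 2}).matched == 0

    def test_rates_independent_of_secret(self):
        config = SynthConfig(n_persons=50, months=2, seed=5)
        registry = generate_registry(config)
        receipts = generate_receipts(registry, config)
        receipts, _ = inject_errors(receipts, ErrorSpec(p_name=0.2), seed=9)
        outpatient = [r for r in receipts if r.receipt_type == "outpatient"]
        pharmacy = [r for r in receipts if r.receipt_type == "pharmacy"]
        reports = []
        for secret in (b"alpha", b"beta"):
            s = KeyCodeSession.from_secret(secret)
            q = anonymize_receipts(outpatient, DEFAULT_PATTERNS, s)
            t = anonymize_receipts(pharmacy, DEFAULT_PATTERNS, s)
            reports.append(compute_match_report(q, t, {1, 2}).to_dict())
        assert reports[0] == reports[1]


class TestAnonymousRecordIO:
    def test_round_trip(self, keyed, tmp_path):
        records = keyed([_receipt(i, _identity(i)) for i in range(5)])
        path = tmp_path / "codes.jsonl"
        write_anonymous_records(records, path)
        assert read_anonymous_records(path) == [
            dataclasses.replace(r, keycodes=dict(r.keycodes)) for r in records
        ]

    def test_no_identity_fields_in_output(self, keyed, tmp_path):
        receipts = [_receipt(i, _identity(i, name=f"veryuniquename{i}")) for i in range(5)]
        records = anonymize_receipts(
            receipts, DEFAULT_PATTERNS, KeyCodeSession.from_secret(b"s")
        )
        path = tmp_path / "codes.jsonl"
        write_anonymous_records(records, path)
        text = path.read_text()
        for r in receipts:
            assert r.identity.name not in text
            assert r.identity.certificate_number not in text
            assert r.identity.date_of_birth not in text
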