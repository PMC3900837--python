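# claimlink

Tooling for building a longitudinal database of health-insurance claims
("receipts") for epidemiologic and health-services research.

A receipt is the monthly claim one medical institution or pharmacy issues for
one insured person: identity fields (name, date of birth, insurance
certificate number, sex, relationship to the policy holder), free-text
disease names, and expenses.  Making a corpus of receipts research-grade
requires solving two problems:

1. **Disease names vary by institution.**  Type 2 diabetes may arrive as
   "NIDDM", "diabetes II", or "adult diabetes".  claimlink performs
   *computer-aided post-entry standardization*: names are entered as written
   and mapped afterwards by exact lookup in an updatable dictionary of known
   spelling variants → (standardized disease name, ICD-10 class).  Misses
   are reported as *unregistered* and feed dictionary growth; previously
   entered data can be re-standardized retroactively, so the automatic
   standardization rate only improves over monthly processing cycles and
   time series stay consistent.  Standardized names are finer-grained than
   ICD-10 (four distinct renal-complication diabetes diagnoses may all roll
   up to E142 yet remain separable), and suspected-diagnosis modifiers are
   carried as a flag, never merged into the name.

2. **Receipts carry personal information, and one person generates many
   receipts.**  claimlink links records *anonymously* through **key codes**:
   an ordered pattern of identity fields is serialized, padded to a fixed
   block length L, XOR-ed with a secret-keyed stream-cipher keystream (the
   fixed-length *preliminary code*), and hashed with SHA-256 into the final
   digest.  Formally, for identity fields x under pattern p,

       keycode_p(x) = H( pad(serialize_p(x)) ⊕ KS(secret, p) )

   Equal digests ⇔ equal field values, so digest equality performs name
   identification while the database never stores an identity field; the
   fixed length hides input lengths and the hash is one-way.  A pattern with
   a missing field yields no code, so several patterns are generated per
   record and combined with union (OR) logic — adding a pattern can only
   recover matches.  Insurer registry records are key-coded too, so insured
   persons with zero receipts still appear in the person clustering.

A synthetic-claims generator (registry, coupled outpatient/pharmacy receipt
streams, variant dictionaries, controlled field-level entry errors with
ground-truth logs) makes every stage testable with no real data.

## Worked example

```python
import numpy as np
import claimlink as cl

# synthetic corpus: 2 000 insured persons, 3 months of receipts
config = cl.SynthConfig(n_persons=2000, months=3, seed=42)
registry = cl.generate_registry(config)
dictionary, sampler = cl.generate_disease_dictionary(config)
receipts = cl.generate_receipts(registry, config, sampler)

# 1) standardize disease names
annotated, report = cl.standardize_batch(receipts, dictionary)
print(f"{report.standardized}/{report.total_names} names standardized "
      f"({100 * report.rate:.1f}%)")

# 2) inject entry errors on the pharmacy side, then link anonymously
pharmacy = [r for r in receipts if r.receipt_type == "pharmacy"]
outpatient = [r for r in receipts if r.receipt_type == "outpatient"]
pharmacy, _ = cl.inject_errors(pharmacy, cl.CALIBRATED_ERROR_SPEC, seed=1)

session = cl.KeyCodeSession.from_secret(b"example secret")
q = cl.anonymize_receipts(outpatient, cl.DEFAULT_PATTERNS, session)
t = cl.anonymize_receipts(pharmacy, cl.DEFAULT_PATTERNS, session)
session.destroy()  # release the decode key; digests remain comparable

for patterns in ({1}, {1, 2}):
    r = cl.compute_match_report(q, t, patterns)
    print(f"patterns {sorted(patterns)}: {r.matched}/{r.denominator} "
          f"matched ({100 * r.rate:.1f}%)")
```

Output:

```
4447/4539 names standardized (98.0%)
patterns [1]: 1382/1533 matched (90.2%)
patterns [1, 2]: 1508/1533 matched (98.4%)
```

The generator's default 1.9 % novel-name probability puts the automatic
standardization rate near 98 % (98.0 % on this small corpus).  The match
report counts outpatient receipts with a positive prescription expense (each
implies a same-month pharmacy receipt for the same person): with
pharmacy-side entry errors at the calibrated rates, the certificate+name+sex
pattern alone finds ≈ 88.5 % of the pharmacy counterparts in expectation
(90.2 % on these 1 533 receipts), and adding the
certificate+date-of-birth+relationship pattern lifts this to ≈ 98.0 % —
certificate-number errors break every pattern and account for most of the
remainder.  At the evaluation scale of 100 000 pairs the rates settle at
88.4–88.5 % and 98.0 %.

A `claimlink` console command wraps the same flow
(`synth`, `standardize`, `keygen`, `link`, `evaluate`, `pipeline`); see
`claimlink --help`.

## Layout

- `src/claimlink/model.py` — domain types (receipts, registry, dictionary) and CSV/JSONL I/O
- `src/claimlink/standardize.py` — canonicalization, modifier rules, lookup, batch reports, dictionary updates
- `src/claimlink/keycode.py` — pattern serialization, stream cipher, hash, session lifecycle
- `src/claimlink/linkage.py` — key-code indexing, matching, person clustering, match reports
- `src/claimlink/synth.py` — synthetic registries, receipts, dictionaries, error injection
- `src/claimlink/cli.py` — the `claimlink` command
- `docs/methods.md` — models, parameters, and design choices in detail
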