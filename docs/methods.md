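# Methods

This note documents the models and procedures claimlink implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the design choices made where the design was genuinely open.

## 1. The claims data model

A *receipt* is one monthly claim from one institution for one insured
person: `receipt_id`, type (inpatient / outpatient / pharmacy), service
month, institution id, an identity block (certificate number, name, sex,
date of birth, relationship to the policy holder — the values *as written*,
possibly blank or erroneous), free-text disease names (pharmacy receipts may
list none), and two money amounts with `prescription_expense ≤
total_expense`.  The insurer's *registry* holds one authoritative record per
insured person, present even when no receipts exist.

Identity fields are stored as raw strings, empty string meaning missing.
This keeps data-entry errors representable verbatim and makes "missing" a
property the key-code stage can act on, rather than a parse failure.
Dialects are UTF-8 quoted CSV and JSONL with fixed column names; dates are
ISO-8601 (`YYYY-MM` service months, `YYYY-MM-DD` births).  Reading collects
malformed rows into an error report instead of dropping them, preserves file
order, and rejects duplicate `receipt_id`s outright.

## 2. Disease-name standardization

Names are standardized *after* entry by exact dictionary lookup:

1. **Canonicalize**: Unicode NFKC (full-width/half-width unification), strip
   and collapse whitespace, lower-case ASCII letters only.  This is the
   minimal deterministic normalization that merges trivially distinct
   spellings; non-ASCII case is left alone.
2. **Split modifiers**: an ordered rule list of tokens, each restricted to
   prefix or suffix position; the longest matching token is removed at most
   once, and a `suspected`-effect token sets the suspected flag.  Suspected
   diagnoses (written to justify tests or medication) stay flagged, never
   merged into the name — downstream disease-frequency work must be able to
   exclude them.
3. **Look up**: exact match only.  Fuzzy matching is deliberately absent:
   the method's correction loop is dictionary *registration* — every miss is
   tallied by canonical base name so the dictionary maintainer can register
   it, and a no-override update can only raise the standardization rate
   (monotonicity is property-tested).

Dictionary entries map canonical variant → (standardized name, ICD-10
code).  Accepted code syntax is one letter + two digits + up to two more
alphanumerics, which covers both 3-character classes (`E11`) and dotless
4-character codes (`E142`).  Many-to-one rollups are first-class: distinct
standardized names sharing one code remain separable in output.

Updates return a new dictionary with a strictly larger version; re-mapping
an existing variant requires an explicit override and otherwise fails naming
the variant and both targets.  `restandardize` re-annotates an existing
corpus under a newer dictionary by caching each annotation's canonical
post-modifier base name and re-running only the lookup; this is exactly
equivalent to a full re-run (asserted against that oracle in tests),
including override re-mappings, and makes retroactive correction cheap.

**Rates.**  Reports carry two denominators: per disease name and per receipt
(a receipt counts only if *all* its names standardized), because both are
meaningful operationally.  The evaluation uses single-diagnosis receipts,
where the two coincide.  An empty batch has rate 1.0 by convention and is
logged.

## 3. Key codes

The anonymization pipeline per identity block and pattern:

```
serialize_p(x)  =  pattern_id byte ‖ (len(f) as 2-byte BE ‖ UTF-8(f)) for each field f
pad(m)          =  m ‖ 0x80 ‖ 0x00…          (to block length L)
prelim          =  pad(serialize_p(x)) ⊕ KS(secret, nonce = pattern_id, L)
keycode_p(x)    =  SHA-256(prelim)           (64 hex characters)
```

* Length prefixes make serialization injective (no concatenation-boundary
  ambiguity); the `0x80`-then-zeros padding is injective on payloads up to
  L − 1 bytes.  **L defaults to 64 bytes** — ample for realistic identity
  payloads — and is configurable; oversized payloads raise rather than
  truncate.
* Any empty pattern field short-circuits to MISSING: a key code cannot be
  generated from absent data.  That is why configurations carry several
  patterns; the two defaults are pattern 1 = (certificate number, name, sex)
  and pattern 2 = (certificate number, date of birth, relationship).
* The keystream is a pseudorandom generator keyed by the secret: the default
  is SHA-256 in counter mode over (secret ‖ nonce ‖ counter).  The keystream
  function is injected through the session, so any stream cipher can be
  substituted without touching the pipeline; the per-pattern nonce gives
  domain separation, so identical field values under different patterns
  cannot collide even apart from the pattern-id byte.  An all-zero
  "identity" keystream exists purely as a test hook: it makes the hash input
  equal the padded plaintext so the hash stage can be checked against an
  independent SHA-256 implementation (the system `sha256sum` tool).
* The final hash makes codes one-way and fixes their length (the cipher
  stage already fixed the pre-image length, so code length leaks nothing).

**Secret lifecycle.**  Codes are only comparable when generated under one
secret, yet monthly batches must link across time.  The resolution adopted:
a generation authority holds the persistent secret *outside* the database; a
`KeyCodeSession` loads it, emits codes, and `destroy()` zeroes the in-memory
key material, after which cryptographic calls raise.  The database stores
digests only.  Destroying the session is the in-process analogue of
releasing (deleting) the decode key: nothing retained with the data can
invert or regenerate codes.  The public API exposes no decryption
capability, and distinct secrets yield unlinkable codes (property-tested).

## 4. Linkage

Records stripped to `(record_id, kind, keycodes)` are matched by digest
equality.  **Combination is union (OR)**: a query matches if *any* in-use
pattern agrees with some target — the only semantics under which adding a
pattern is monotone, which is the point of multi-pattern generation.
Person clustering is the transitive closure (union-find) of "shares any
in-use digest", with registry records participating so zero-receipt persons
form singleton clusters.  `person_id` is the SHA-256 of the cluster's sorted
digest set, stable under record reordering.  A digest collision between
different true persons is cryptographically negligible at 256 bits and is
accepted silently; a diagnostics mode flags cluster-size outliers.

**Match statistic.**  The denominator is outpatient receipts with positive
prescription expense — exactly those for which a same-month pharmacy receipt
must exist — and a receipt counts as matched when some pharmacy record in
the *same service month* shares an in-use digest.  The same-month
restriction follows from the monthly issuance cycle; it is a package
decision, stated here because cross-month matching would score accidental
later refills as successes.  Rates are receipt-level, deterministic given
the corpus, and independent of the secret (only digests change — tested).

## 5. The synthetic generator

The generator emulates the structural features the methods depend on:

* **Registry** — unique 8-digit certificate numbers; names drawn from a
  finite romanized pool so distinct persons collide on name+sex at realistic
  corpus sizes (certificate numbers must disambiguate — tested);
  relationship consistent with age (dependents under 18 are "child",
  "child" never above 24, "self"/"spouse" require ≥ 18).
* **Receipts** — per person-month: outpatient visit probability 0.35,
  admission probability 0.02, and, given a visit, probability 0.7 of a
  positive prescription expense, which spawns exactly one coupled same-month
  pharmacy receipt with the identity copied verbatim.  At most one receipt
  per (person, institution, month).  Conservation (#pharmacy = #outpatient
  with positive prescription expense) holds pre-injection by construction.
* **Dictionary** — 500 standardized names × 3 registered variants by
  default; roughly every fifth name shares its ICD-10 code with the previous
  one, giving the many-to-one rollup structure; the name sampler emits a
  registered variant with probability 1 − p_unregistered (default
  p = 0.019) and an unmistakably novel string otherwise.
* **Errors** — injected into receipt identity blocks only, never the
  registry (the roster is the insurer's authoritative copy).  Operators:
  digit substitution / adjacent-digit swap (certificate), character
  substitution (name), sex flip, date replacement, category replacement
  (relationship); each re-draws until the serialized value actually changes,
  since a no-op "error" would be undetectable and bias calibration.  Every
  injection is logged with the original and corrupted value.

**Calibration of the evaluation corpus.**  The linkage evaluation uses
100 000 coupled outpatient/pharmacy pairs with pharmacy-side error
probabilities p_certificate = 0.0167, p_name = 0.10, p_dob = 0.034 (sex and
relationship clean).  These field rates are back-derived from the evaluation's
target operating point under the independence model:

    rate(pattern 1)   = (1 − p_cert)(1 − p_name)          ≈ 0.885
    rate(combined)    = (1 − p_cert)(1 − p_name·p_dob)    ≈ 0.980

so the single-pattern and combined match percentages sit at ≈ 88.5 % and
≈ 98.0 %, with certificate errors (present in every pattern) bounding the
combined rate.  The acceptance tolerances are three binomial standard errors
at those rates (≈ 0.30 and ≈ 0.13 percentage points at n = 100 000); the
standardization evaluation draws 200 000 single-diagnosis receipts at
p_unregistered = 0.019 (tolerance ≈ 0.09 pp around 98.1 %).

**What passing tests do not show.**  The generator uses ASCII surrogate
names, uniform expense draws, and no disease epidemiology; it does not model
Japanese orthography, OCR noise, institution-specific error profiles, or
correlated multi-field errors.  Results on it validate the *mechanics*
(injectivity, determinism, monotone combination, exact accounting) and the
calibrated operating points, not real-world error rates, which must be
measured on real corpora.

## 6. Numerical and degenerate-input choices

* All randomness flows through `numpy.random.default_rng` seeded from the
  corpus config; identical (config, seed) reproduce corpora bytewise.
* Empty standardization batch → rate 1.0 with a warning; empty match
  denominator → rate `None` (undefined), flagged in `unmatched_reasons`.
* Ties in modifier matching break by token length (longest wins); equal
  lengths fall back to rule order.
* Money amounts are integer currency units; `prescription_expense ≤
  total_expense` is validated, not clamped.
* Digest comparisons are exact string equality on lowercase hex; no
  canonicalization is ever applied to digests.

## 7. Known limitations

* Exact-match standardization cannot resolve spellings outside the
  dictionary by design; the rate is bounded by dictionary coverage.
* The production-scale configuration of this linkage approach uses dozens of
  field patterns; the engine here supports arbitrary pattern sets but ships
  only the two evaluation patterns as defaults.
* Dental, visiting-nursing, and bone-setting receipt types, OCR ingestion of
  paper receipts, and national claims interchange formats are out of scope.
* The keystream default (hash counter mode) is a PRG-based stream cipher
  suitable for deterministic pseudonymization; deployments with a mandated
  cipher (e.g. ChaCha20) should inject it via the session's keystream hook.
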