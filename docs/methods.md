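# Methods

## The screening procedure and its assumptions

The service screens every (medication, allergen) pair of a request through a
three-step cascade — same product or ingredient, same drug or ingredient
class, cross-reactive allergen — evaluated strictly in that order with the
first match reported and later steps suppressed. The minimal-step rule makes
warning attribution mutually exclusive, so per-step shares over any audit
window sum to 100%. Assumptions baked into the cascade:

- **Codes are opaque identifiers.** KD product codes, ingredient codes,
  class codes and allergen codes are compared by exact, case-sensitive
  string equality; no checksum or hierarchy is inferred from their shape.
- **Class membership is mediated by ingredients.** Both drug classes and
  ingredient classes are sets of ingredient codes; a product belongs to a
  class iff any of its ingredients does. This single mechanism implements
  both class tables and keeps combination products (multi-ingredient drugs)
  correct by construction: they inherit every class of every ingredient.
- **Class-kind allergens never match at step 1.** An allergen that *is* a
  class matches at the class step even when one of its member ingredients is
  literally prescribed; the case is still caught (the class necessarily
  contains a medication ingredient, so step 2 fires), and step 1 remains
  reserved for identity-level matches.
- **Cross-reactivity is symmetric.** Pairs are canonicalized
  (lexicographically sorted) on load, de-duplicated, and looked up
  orientation-free, so reversing a stored pair cannot change any screening
  outcome.
- **Reaction and severity codes are informational.** They are carried on
  allergen concepts for the inquiry screen and never modulate matching; the
  screening result depends only on the product/ingredient/class/pair
  structure.
- **Unknown codes are non-fatal.** A shared national service must tolerate
  client vocabulary drift, so codes missing from the knowledge base are
  skipped, surfaced in the card detail and the audit record, and never
  reject the request.

A second, deliberately naive implementation (`oracle_screen`) re-derives all
three predicates by linear scans over the raw tables and is used only as an
independent cross-check in tests and in the acceptance script.

## Service behavior choices

- **Empty result = HTTP 200 with `{"cards": []}`.** "No response" in the
  operational sense is the conformant empty card array, not a dropped
  connection.
- **One card per implicated medication**, aggregating all of its allergen
  findings in the markdown detail. This keeps physician-facing noise at one
  interruption per drug; per-finding granularity is preserved in the detail
  lines and in audit step counts. The card summary is truncated to the
  140-character bound with a trailing ellipsis; the indicator is always
  `warning` (the other CDS Hooks indicators remain representable but are not
  produced by DAI screening).
- **Prefetch is mandatory (HTTP 412 when absent).** The deployment model is
  serverless-FHIR: clients attach the patient's AllergyIntolerance bundle in
  `prefetch.allergyIntolerance`; the service performs no FHIR-server
  callbacks, and `fhirServer`/`fhirAuthorization` are accepted and ignored.
- **Patient consistency is enforced.** Any parsed resource whose
  patient/subject reference disagrees with `context.patientId` rejects the
  request with 400 — silently screening across patients is a safety hazard.
- **Status codes are closed over {200, 400, 401, 403, 412}.** Authentication
  failures map to 401 (missing/malformed/bad-signature/expired) or 403
  (valid token, client not whitelisted); all other malformed input maps to
  400 with an OperationOutcome-style body. The transport wrapper catches
  everything, so fuzzed input cannot produce a 5xx.
- **Tokens** are HMAC-SHA256 signed bearer tokens in JWT compact form with
  `sub`/`iat`/`exp` claims, minted by the bundled issuer. Default lifetime
  is 24 h (`token_lifetime_seconds`); claim layout and lifetime are this
  package's choice, as is the 
  strictness toggle `reject_code_system_mismatch` (off by default: an
  unexpected code-system URI yields a warning, not rejection, which suits an
  ecosystem where FHIR adoption is young).
- **Code-system URIs are configuration.** The KD code system and the
  allergen value set have no published canonical URIs, so the defaults are
  documented `example.org` placeholders. When several codings are present,
  the first coding in the configured system wins; otherwise the first coding
  is used with a warning.

## FHIR profiling

Only the constraints the two profiles impose are enforced: medication must
be an inline `medicationCodeableConcept` (clients do not manage Medication
resources, so `medicationReference` is rejected as an unsupported
representation); `status`, `intent` and `subject` are required;
AllergyIntolerance `category` is fixed to `medication` and `code` is
required. Must-support elements (`identifier`, `dosageInstruction`) are
accepted and ignored. Parsing is total — arbitrary JSON yields either a
typed value or a violation list — and violations are order-independent sets.
Duplicate KD codes in a draftOrders bundle are de-duplicated keeping the
first occurrence; an order bundle with zero MedicationRequest entries is a
"no orders" error, while an empty allergy bundle is a valid no-allergy
patient. This is not a generic StructureDefinition validator and does not
try to be.

## Audit trail and usage summary

Every invocation appends exactly one JSON-lines record (outcome `warning`,
`empty`, or `rejected`); an unwritable log path fails at startup rather than
dropping records later. Patient identifiers are pseudonymized with a keyed
HMAC-SHA256 (64-bit hex prefix) before logging, so the trail holds no direct
identifiers. The summary counts distinct providers and patients by exact set
cardinality, excludes rejected invocations from the check count, and rounds
percentages half-up to two decimals (`Decimal` arithmetic, so 0.125% → 0.13).
A counts-only constructor shares the same arithmetic as the streaming
summarizer, which is what makes the O(1) and streamed routes provably
identical. Corrupt log lines are skipped, counted, and reported in the
summary footer. An optional per-step breakdown is accumulated from the
records' step counts; it is reported when present but carries no external
reference values.

## Synthetic data: what it emulates and what it does not

The generator emulates the *structure* the production service runs on — a
KD-code-keyed product → ingredient → class hierarchy, a symmetric
cross-reactivity relation, and a three-kind allergen value set — plus fully
conformant order-sign payloads. It does **not** attempt Korean prescribing
patterns, real drug names (displays are pronounceable synthetic strings),
realistic class sizes, or the production case mix; passing tests therefore
demonstrate correctness of the screening and service logic, not clinical
performance on real data.

Defaults: a scenario knowledge base has 12 ingredients, 15 drugs (20%
two-ingredient combinations), 2 drug classes and 2 ingredient classes of 2–4
members, 3 cross-reactive pairs, and 8 allergens drawn ≈30% product / 20%
class / 50% substance; scenarios have 100 patients, 2 orders per patient,
and 40% allergy prevalence — small enough to screen exhaustively, rich
enough to reach all three cascade steps. Ground truth is certified at
generation time by re-screening each request with the naive oracle, so
engine tests rely on certified output rather than generator intent; a
request that cannot be constructed (e.g. planting a step-3 interaction in a
knowledge base without cross-reactive pairs) is a generation error, never a
silent fallback. All sampling flows from a single integer seed; identical
seeds give byte-identical knowledge-base serializations.

The fixed toy fixture (5 ingredients, 6 drugs, one drug class, one
ingredient class, one cross-reactive pair, 4 allergens) is arranged so that
a single substance allergen exercises every cascade outcome: step 1 via a
shared ingredient (including through a combination product), step 2 via
class co-membership, step 3 via the cross-reactive pair, and a clean
no-match.

The synthetic audit-log writer reproduces operational-report arithmetic at
deployment scale (by default 67 providers and 114,694 patients cycling over
~1M records); timestamps advance once per thousand records, which is
irrelevant to summarization and keeps generation fast.

## Problem sizes and numerical choices

Randomized suites use knowledge bases of ≤ ~35 entities, where the naive
oracle is fast and exhaustive comparison is feasible; the oracle-equivalence
check runs 200 seeded draws and the end-to-end recovery check 100 requests
(15 planted per step plus non-interacting filler). The usage-summary check
streams the full ~1M-record synthetic log (a few seconds) and cross-checks
the counts-only mode. Percentages use half-up decimal rounding everywhere;
an empty log reports percentages as not-applicable rather than dividing by
zero. Search ranking is deterministic: case-insensitive substring match
ordered by (earliest match position, allergen code), with no fuzzy or
phonetic matching.

## Known limitations

- No dose, duration, or duplicate-therapy logic — those belong to the
  national DUR program, a separate system.
- No probabilistic cross-reactivity scoring or severity grading; a pair
  either matches a step or does not.
- The whitelist, token secret, and card link are static configuration; no
  TLS termination or deployment manifests are included.
- No feedback endpoint: card acceptance/override behavior is not tracked.
- The FHIR layer validates only the profile constraints stated above, not
  full R4 conformance.
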