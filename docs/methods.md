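# Methods

## The problem and the model

Hospitals hold analysis-ready datamarts that external researchers want to
use, but patient-level rows must not leave the institution.  The platform
implements *distributed analytics*: the researcher's request travels to the
data, only aggregate results travel back.  The architecture is a set of
cooperating agents around a single trusted coordinator:

- **GUI channel** (outside the perimeter) — publishes job requests as XML
  files: a Message Master Table (MMT) listing submissions plus one
  `job_<jobID>.xml` detail per job.  It never opens a connection inward;
  the proxy initiates every exchange on a single transport, so the hospital
  side keeps complete control of the communication.
- **Proxy** (inside) — polls channels, authorises requests, resolves data
  and algorithms from certified local registries, packs each task into a
  zip **token** (descriptor XML + CSV payload), load-balances tokens over
  processors, monitors outputs, and routes results through notarisation
  and signing back to the channel.
- **Processor** — a black-box executor: watches input folders, claims each
  token by atomic rename, runs the described task via a script or
  container-image backend in an isolated working directory with a per-job
  log, and deposits an output token (result + logs) in its output folder.
- **Permission agent** — identity and access management: pluggable
  authentication profiles, group/subgroup hierarchies, item grants, and
  time-limited session tickets (256-bit random strings) so revocation acts
  at one place.
- **Notary** — hash-notarisation (content-addressed off-chain store plus a
  hash-chained append-only ledger) and the dual-signature workflow: the
  sandbox signs the report, the user verifies and countersigns, and only
  then is the report officially issued, leaving three notarised report
  artefacts (initial, sandbox-signed, countersigned).
- **Scheduler** — periodic job templates fired at fixed instants, with
  freeze/resume/remove controls.

## Protocol and ordering guarantees

A job's life is strictly ordered: MMT entry → detail read + ACK →
permission check → request notarisation (metadata only — user, datamart,
algorithm, timestamp — deliberately devoid of data) → token deposit →
`info.assigned.proc` / `info.status.job` messages → execution → output
token → result-hash notarisation → report signing → delivery →
countersignature.  A notarisation failure holds the job for retry; nothing
ever executes un-notarised.  Every proxy action is appended to an event
log, which is what the conformance tests assert ordering on.

## Cryptographic choices

- **Hashing**: SHA-256 everywhere; each digest record carries its
  algorithm id so the ledger remains self-describing.
- **Ledger**: JSON-lines, one entry per notarisation.  An entry's digest
  covers `(index, timestamp, payload digest, previous entry digest)` with
  a fixed field order, so any in-place mutation (including an unparseable
  line) is detected by recomputation.  This is a deliberate single-node
  simulation of a permissioned blockchain behind a pluggable backend
  contract; distributed consensus is out of scope.  Truncation of the tail
  is *not* detectable from the file alone — the head digest is exposed for
  external anchoring, and this limitation is documented rather than
  papered over.
- **Signatures**: Ed25519 (RFC 8032), implemented in-package over the
  edwards25519 curve with extended coordinates, validated against the
  published RFC test vectors and cross-checked against `openssl pkeyutl`
  in the test suite.  Keys serialise to standard PKCS#8 / SubjectPublicKeyInfo
  PEM.  The user countersigns the canonical sandbox-signed artefact
  (report bytes + sandbox signature as compact JSON), binding both
  parties to the same bytes.

## Parameters that matter

| parameter | default | rationale |
|---|---|---|
| session TTL | 8 h | one working day of interactive use; expiry flips checks to `auth-required`, never silently to `deny` |
| channel max duration | 1 h | proxy-imposed; a fresh channel forces re-authentication |
| poll interval (channels, folders) | 2 s | responsive without busy-waiting; tests drive polls explicitly with a fake clock |
| processor `max_parallel` | 1 (harness uses 2) | conservative default for shared hospital hardware |
| job timeout | 1 h | runaway-job guard; timed-out jobs fail with a timeout marker in the log |
| heartbeat liveness window | 30 s | a processor missing ~15 poll intervals is treated as down and jobs queue |
| PBKDF2 iterations | 50 000 | salted, iterated password hashes; unknown-user failures burn the same work as wrong-password ones |

Load balancing is least-ongoing with deterministic tie-breaks (least
forwarded, then lexically smallest id): with equal-duration jobs this
provably keeps forwarded counts within 1 across processors, and it makes
dispatch decisions reproducible in tests.

Missed scheduler instants are not back-filled (fire once, skip the
backlog): periodic analytics jobs are snapshots, and replaying a backlog
of identical snapshots has no value.

## Synthetic data

The generators emulate the *shape* of hospital datamarts, not their
clinical content: a pseudonymised patient table (age ~ N(62, 12²), gender,
one biomarker, visit year) and a two-table OMOP-style subset
(person / condition_occurrence with referential integrity, conditions per
person ~ Poisson(2)).  Every generated row carries a unique sentinel
pseudonym (`SBX-SENTINEL-…`); the mediation tests scan all GUI-bound
traffic for these sentinels to demonstrate that raw rows never cross the
perimeter.  What passing tests therefore show is *mediation* — no
patient-level row leaves on the channel — not semantic disclosure safety
of aggregate results: disclosure control (e.g. differential privacy) is an
explicit non-goal of this version.  Fixed seeds make every generated table
byte-identical between runs.

Cohort queries are conjunctions of typed predicates
(`=, ≠, <, ≤, >, ≥, in`), optionally across the person↔condition join.
Disjunction and negation are intentionally excluded: conjunctive filters
exercise the whole pipeline while keeping the semantics (and the
brute-force oracle used in tests) trivially auditable.

## Numerical and degenerate-input choices

- Timestamps are ISO-8601 UTC throughout; round-trips preserve microsecond
  precision (descriptor equality in property tests allows < 10 µs slack).
- Path safety: token payload members must be relative, unique and free of
  traversal components; extraction re-checks containment in the workdir.
- Corrupt archives, unknown backends, absent images and non-zero exits all
  converge to the same contract: a failure output token with a non-empty
  log, so the claimed/deposited conservation invariant holds for any
  input mix.
- Container images resolve only against a local store; an unknown image is
  refused, never pulled.  The built-in store is a simulated OCI-style
  registry (name → locally loaded bundle); a real container engine can be
  slotted in behind the same one-method contract.
- Empty tables (0 rows, 0 patients) are valid inputs end to end.

## Problem sizes used in the verification runs

The acceptance script and end-to-end tests use deliberately small,
seed-controlled workloads: 50–60-row datamarts, 20-job mediation and
load-balancing runs, 50-token processor conservation batches, 1,000-check
IAM oracle sweeps, 100-mutation tamper sweeps and 200-descriptor
round-trip sweeps.  These sizes already exercise every queue, tie-break
and failure path; all the verified properties (conservation, ordering,
closure equivalence, tamper detection) are size-independent invariants
rather than asymptotic estimates.

## Known limitations

- Single hospital, single proxy: federation across institutions is out of
  scope.
- The simulated ledger proves tamper-evidence, not Byzantine fault
  tolerance; truncation detection needs an external anchor.
- SQL connectors (beyond CSV) are contract-only extension points.
- Result artefacts are forwarded as the algorithm produced them; the
  platform asserts mediation, not statistical disclosure control.
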