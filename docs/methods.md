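# Methods

This document records the protocol model the package implements, the
parameters and their defaults, the scope of the synthetic data generator,
and the design decisions a user of the toolkit should know about.

## Protocol model

### Export flow (FHIR Bulk Data Access v1.0)

Three kickoff endpoints are served under the FHIR base path (`/fhir`):

- `GET /fhir/$export` — system level: every resource in the repository.
- `GET /fhir/Patient/$export` — patient level: all Patients plus the
  clinical resources (Observation, Condition, Encounter) that reference
  them via `subject`.
- `GET /fhir/Group/<id>/$export` — group level: the patient-level selection
  intersected with the group's member roster. The Group resource itself is
  never exported; rosters live in a repository-level group map.

A kickoff must carry `Prefer: respond-async` (else 422) and may carry the
three v1.0 query parameters:

- `_type` — comma-separated resource-type allowlist; unknown types are a
  422 error, never silently ignored.
- `_since` — RFC3339 instant; selection keeps resources with
  `meta.lastUpdated` **strictly greater than** the given instant (a resource
  stamped exactly at `_since` is excluded).
- `_outputFormat` — must be one of `application/fhir+ndjson`,
  `application/ndjson`, `ndjson`.

`_typeFilter` is explicitly rejected at kickoff (422) rather than ignored;
`$import` and USCDI profile validation are out of scope. Unknown parameters
are a 422 error.

A successful kickoff returns **202 Accepted** with an absolute
`Content-Location` status URL and no body. Job ids are 24-byte
URL-safe random tokens (unguessable; probing returns 404).

The status endpoint returns **202** with `X-Progress`
("k of n resource types exported") and `Retry-After` (seconds) while
running; **200** with the completion manifest and an `Expires` HTTP-date
once done; **404** for unknown/cancelled/expired jobs; **5xx** with an
OperationOutcome on failure (which the client treats as terminal, not
transient). The manifest carries exactly `transactionTime`, `request` (the
original kickoff URL), `requiresAccessToken`, `output`
(`[{type, url, count}]`) and `error` (OperationOutcome NDJSON files). The
manifest is built once at completion, so repeated polls return an identical
document. `DELETE` on the status URL cancels and forgets the job (202; any
later poll or cancel is 404). Completed jobs are retained for
`retention_minutes` (default 60) and then expire to 404.

Output files are NDJSON — one resource per line, one resource type per
file, `Content-Type: application/fhir+ndjson` — optionally split into
chunks of at most `max_lines_per_file` lines. Files can be hosted under the
FHIR base or, with `serve_files_separately`, under a distinct `/file-host`
prefix to model an external blob store.

### Authorization (SMART Backend Services)

Registered clients hold an RSA keypair; the server stores the public key,
an allowed-scope set, and optionally a `policy_group`. To authenticate, a
client posts a form-encoded request to the token endpoint with
`grant_type=client_credentials`, the standard JWT-bearer
`client_assertion_type`, a requested `scope` string, and a `client_assertion`:
an RS384-signed JWT with `iss = sub = client_id`, `aud` = the token
endpoint URL, `exp` at most 5 minutes ahead, and a single-use `jti`
(replay of an assertion is rejected as `invalid_grant`).

Granted scopes are the literal set intersection of requested and allowed
scopes (`system/<Type>.read` / `system/*.read`); an empty intersection is
`invalid_scope`. Tokens are opaque 32-byte random strings with a 300-second
lifetime; a token is rejected from the instant `now >= expires_at`.
Authorization failures are distinguishable: missing/unknown/expired tokens
are 401 `unauthenticated` (with `WWW-Authenticate: Bearer`), insufficient
scope is 403 `forbidden`. A client's `policy_group` restricts every export
it runs to that group's members — provably equal to intersecting the
selection with the group (tested against a brute-force oracle).

Token enforcement is active exactly when client registrations are
configured; the manifest's `requiresAccessToken` truthfully reflects
whether file downloads demand a token.

### Client

The client runs auth → kickoff → poll → download → validate. Polling
honors `Retry-After` exactly, falling back to a 1-second floor when the
header is absent or unparseable, with a 600-second default timeout. A 5xx
from the status endpoint is terminal. Downloads (optionally concurrent)
check the NDJSON media type; validation re-parses every file, enforces
one-type-per-file purity and manifest-count integrity, and reports
malformed lines with 1-based line numbers. Every failure raises
`ProtocolError` naming one of five stages (`auth`, `kickoff`, `status`,
`download`, `validation`); the CLI maps this to exit status 2. A corrupted
file body fails at the *validation* stage (the HTTP transfer succeeded),
which is why fault-injection tests accept `{download, validation}` for
file-stage faults.

### Conformance suite

Eighteen declarative checks in four groups (`kickoff`, `status`, `files`,
`auth`), each a record with id, group, severity and description. The runner
executes one cached kickoff→poll exchange per group (files are downloaded
only for the `files` group, so a once-firing injected fault surfaces in
exactly the matching group), never crashes on malformed or unreachable
servers (transport errors become failed checks with evidence), and emits a
versioned JSON report (`schemaVersion: "1.0"`) with per-check outcomes
(`pass`/`fail`/`skip`) and evidence strings. Checks that cannot be observed
(e.g. the in-progress state on a zero-latency server, auth checks without
credentials) skip rather than guess. `auth-insufficient-scope` is the one
`optional`-severity check: it is untestable for wildcard-scoped clients.

## Synthetic population generator

Deterministic by construction: four independent named RNG streams
(`<seed>/content`, `<seed>/counts`, `<seed>/instants`, `<seed>/groups`)
make the output reproducible and let tests replay the count stream as an
independent oracle. Parameters (`PopulationConfig`):

| Parameter | Default | Meaning |
| --- | --- | --- |
| `n_patients` | 100 | number of Patient resources |
| `resources_per_patient` | Observation 5, Condition 2, Encounter 3 | Poisson means per patient |
| `n_groups` | 2 | number of group rosters |
| `group_fill` | 0.3 | fraction of patients per group (rounded), sampled without replacement |
| `time_window` | 2019-01-01 → 2020-01-01 UTC | uniform `lastUpdated` instants |
| `seed` | 0 | master seed |

Per-patient clinical counts are Poisson draws (Knuth's algorithm) from the
counts stream; ids are readable counters (`pat-000001`, `obs-000042`);
every clinical resource carries a valid `subject` reference. Invalid
configurations raise `ConfigurationError` naming the offending field.
Fixtures are one `<Type>.ndjson` per resource type plus a sorted
`groups.json` sidecar, byte-identical across runs of the same seed. The
generator makes no claim of clinical realism — resources carry minimal
content; it exists to give the protocol machinery a referentially
consistent, deterministic population.

## Numerical and implementation choices

- **Stdlib-only runtime.** The HTTP server is `wsgiref` with a threading
  mixin; the client uses `urllib`. Crypto is a minimal hand-written
  RSASSA-PKCS1-v1_5/SHA-384 + JWS module (Miller–Rabin keygen, CRT signing,
  small DER/PEM codec), verified against OpenSSL as an external oracle.
  This keeps the declared dependencies to `click` alone.
- **Literal scope intersection.** Granted = requested ∩ allowed as string
  sets; a wildcard does not expand into per-type scopes.
- **Fault injection** (`SimulationConfig`) models latency plus one fault
  class at a time (`kickoff` → 500 at kickoff, `status` → transient 500 on
  polls, `file` → one deterministically chosen NDJSON line corrupted),
  firing `fault_times` times (`None` = always); used both for client
  diagnostics tests and conformance coverage.
- **Determinism in tests.** Test keypairs are generated from seeded RNGs;
  selection behavior is verified against a brute-force per-resource oracle
  that shares no code with the engine.

## Limitations

- No persistence: repository, jobs and tokens are in-memory.
- No TLS; transport security is out of scope for the local model.
- `_typeFilter`, `$import`, and USCDI/profile validation are intentionally
  unimplemented (the first is rejected explicitly).
- The generator's resources are structurally valid but clinically minimal.
- HTTP/1.1 via `wsgiref` is not a production server; it exists to exercise
  the wire protocol faithfully, not to scale.
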