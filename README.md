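# bulkfhir

A self-contained toolkit for the **SMART/HL7 FHIR Bulk Data Access API v1.0**
("flat FHIR" / `$export`): a reference server, a scriptable client, a
SMART Backend Services authorization server, a deterministic synthetic
population generator, and a declarative conformance test suite — all in one
package with no runtime dependencies beyond `click`.

## The problem

Population-scale health data exchange needs a standard way to pull *all*
records for a system, an entire patient panel, or an enrolled group out of a
clinical system — not one-resource-at-a-time REST calls. The Bulk Data
Access API defines that push-button export: an asynchronous kickoff
(`GET …/$export` with `Prefer: respond-async`), polling of a status endpoint
until a completion manifest appears, and download of newline-delimited JSON
(NDJSON) files, one resource type per file, under system-to-system OAuth 2.0
authorization (SMART Backend Services). This package implements both sides
of that contract plus the machinery to test any implementation of it.

## What's in the box

| Module | Role |
| --- | --- |
| `bulkfhir.fhir_core` | FHIR resources, NDJSON read/write, validation, in-memory repository |
| `bulkfhir.synthetic_population` | Seeded deterministic patient/clinical-resource generator and fixtures |
| `bulkfhir.backend_auth` | SMART Backend Services: RS384 client assertions, token issuance, scope and policy-group enforcement |
| `bulkfhir.export_engine` | Export job lifecycle: kickoff validation, selection, manifests, fault injection |
| `bulkfhir.http_surface` | The wire protocol as a WSGI app + threaded local server |
| `bulkfhir.client` | Full client flow: auth → kickoff → paced polling → download → validation |
| `bulkfhir.conformance_suite` | 18 declarative protocol checks with a versioned JSON report |
| `bulkfhir.rsa_jws` | Minimal RSA/JWS (RSASSA-PKCS1-v1_5, SHA-384) and PEM/DER codec, stdlib-only |

## Worked example

Generate a population, serve it, export it, and check conformance — all in
one process:

```python
from bulkfhir import (BulkDataApp, BulkServer, ServerConfig, BulkDataClient,
                      PopulationConfig, generate)
from bulkfhir.conformance_suite import ConformanceRunner

repo = generate(PopulationConfig(n_patients=50, n_groups=2, seed=7))
print(f"repository: {len(repo)} resources, groups: "
      f"{ {g: len(m) for g, m in sorted(repo.groups.items())} }")

server = BulkServer(BulkDataApp(repo, ServerConfig(requires_access_token=False)))
server.start()

client = BulkDataClient(server.fhir_base_url, poll_floor=0.1)
summary = client.export_download("export-out", level="patient",
                                 type_filter=["Patient", "Observation"])
for f in summary.files:
    print(f"{f.resource_type:<12} {f.line_count:>4} lines  {f.byte_size:>6} B  {f.path}")
print(f"total: {summary.total_resources} resources in {summary.polls} poll(s)")

report = ConformanceRunner(server.fhir_base_url).run("all")
t = report.totals
print(f"conformance: {t['pass']} passed, {t['fail']} failed, {t['skip']} skipped")
server.stop()
```

Output:

```
repository: 589 resources, groups: {'grp-001': 15, 'grp-002': 15}
Observation   279 lines   77930 B  export-out/Observation.1.ndjson
Patient        50 lines    8989 B  export-out/Patient.1.ndjson
total: 329 resources in 1 poll(s)
conformance: 13 passed, 0 failed, 5 skipped
```

(The five skips are the auth-group checks: the runner was given no client
credentials, and against this open server there is nothing to test.)

### The same thing from the command line

```bash
$ cat server.json
{
  "population": {"n_patients": 50, "n_groups": 2, "seed": 7},
  "requires_access_token": false,
  "retry_after": 1
}
$ bulkfhir serve --config server.json --port 8765 &
FHIR base:      http://127.0.0.1:8765/fhir
Token endpoint: http://127.0.0.1:8765/auth/token
Resources:      589 across 4 type(s); 2 group(s)

$ bulkfhir export --base-url http://127.0.0.1:8765/fhir \
    --patient --type Patient,Observation --out cli-out
status:          complete
total resources: 329
polls:           1
  Observation         279 lines     77930 B  cli-out/Observation.1.ndjson
  Patient              50 lines      8989 B  cli-out/Patient.1.ndjson
wall clock:      0.02s
JSON report:     cli-out/summary.json
```

`bulkfhir conformance --base-url … --report report.json` runs the check
catalogue against any server; `bulkfhir keygen` and registration entries in
the server config enable full SMART Backend Services authorization
(`--client-id/--key/--token-url` on the client side). Protocol failures exit
with status 2 and name the stage (`auth`, `kickoff`, `status`, `download`,
`validation`) at which they occurred.

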