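"""Executable conformance test suite for bulk-data servers.

Runs an enumerable catalogue of protocol checks against any server base
URL and produces a machine-readable report.  Checks are declarative
metadata (id, group, description, severity) paired with small response
predicates; the runner executes one scripted flow per group (a fresh
kickoff where the group needs one) and evaluates every selected predicate
against the recorded wire evidence, so report outcomes do not depend on
execution order.

Groups: ``kickoff`` (parameter/header validation and the 202 +
Content-Location contract), ``status`` (X-Progress/Retry-After, the
completion manifest and its Expires deadline), ``files`` (media type,
NDJSON purity, count integrity) and ``auth`` (SMART Backend Services
behavior).  Required checks are protocol obligations; optional checks
report ``skip`` rather than ``fail`` when the behavior cannot be
demonstrated against the target server.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Callable, Optional
from urllib.parse import urlencode, urljoin

from .backend_auth import CLIENT_ASSERTION_TYPE, build_client_assertion
from .client import ClientCredentials, _default_transport, _HttpResponse
from .fhir_core import NDJSON_MEDIA_TYPE, NdjsonParseError, read_ndjson

__all__ = [
    "ConformanceCheck",
    "CheckOutcome",
    "ConformanceReport",
    "ConformanceRunner",
    "list_checks",
    "validate_report",
    "REPORT_SCHEMA_VERSION",
]

REPORT_SCHEMA_VERSION = "1.0"
GROUPS = ("kickoff", "status", "files", "auth")


@dataclass(frozen=True)
class ConformanceCheck:
    id: str
    group: str
    description: str
    severity: str = "required"  # required | optional


@dataclass
class CheckOutcome:
    check: ConformanceCheck
    outcome: str  # pass | fail | skip
    evidence: str


@dataclass
class ConformanceReport:
    target: str
    timestamp: str
    outcomes: list[CheckOutcome] = field(default_factory=list)

    @property
    def totals(self) -> dict[str, int]:
        counts = {"pass": 0, "fail": 0, "skip": 0}
        for o in self.outcomes:
            counts[o.outcome] += 1
        return counts

    def failed_groups(self) -> set[str]:
        return {o.check.group for o in self.outcomes if o.outcome == "fail"}

    def required_all_pass(self) -> bool:
        return all(o.outcome == "pass" for o in self.outcomes
                   if o.check.severity == "required" and o.outcome != "skip")

    def to_json_dict(self) -> dict:
        return {
            "schemaVersion": REPORT_SCHEMA_VERSION,
            "target": self.target,
            "timestamp": self.timestamp,
            "totals": self.totals,
            "results": [
                {
                    "id": o.check.id,
                    "group": o.check.group,
                    "severity": o.check.severity,
                    "description": o.check.description,
                    "outcome": o.outcome,
                    "evidence": o.evidence,
                }
                for o in self.outcomes
            ],
        }


def validate_report(obj: dict) -> list[str]:
    """Check a report dict against the versioned schema; returns problems."""
    problems = []
    if obj.get("schemaVersion") != REPORT_SCHEMA_VERSION:
        problems.append(f"schemaVersion must be {REPORT_SCHEMA_VERSION!r}")
    for key, typ in (("target", str), ("timestamp", str), ("totals", dict), ("results", list)):
        if not isinstance(obj.get(key), typ):
            problems.append(f"{key} must be a {typ.__name__}")
    totals = obj.get("totals", {})
    if isinstance(totals, dict) and set(totals) != {"pass", "fail", "skip"}:
        problems.append("totals must have pass/fail/skip keys")
    counted = {"pass": 0, "fail": 0, "skip": 0}
    for res in obj.get("results", []) if isinstance(obj.get("results"), list) else []:
        for key in ("id", "group", "severity", "description", "outcome", "evidence"):
            if not isinstance(res.get(key), str):
                problems.append(f"result field {key} must be a string ({res.get('id')})")
        if res.get("outcome") not in ("pass", "fail", "skip"):
            problems.append(f"invalid outcome {res.get('outcome')!r}")
        elif res.get("group") not in GROUPS:
            problems.append(f"invalid group {res.get('group')!r}")
        else:
            counted[res["outcome"]] += 1
        if res.get("outcome") == "fail" and not res.get("evidence"):
            problems.append(f"fail without evidence: {res.get('id')}")
    if isinstance(totals, dict) and set(totals) == set(counted) and totals != counted:
        problems.append("totals do not equal outcome counts")
    return problems


# ---------------------------------------------------------------------------
# catalogue

CHECKS: list[ConformanceCheck] = [
    ConformanceCheck("kickoff-async-preference", "kickoff",
                     "Kickoff without 'Prefer: respond-async' is rejected with a "
                     "client error and no Content-Location"),
    ConformanceCheck("kickoff-content-location", "kickoff",
                     "A valid kickoff returns 202 Accepted with a Content-Location "
                     "status URL"),
    ConformanceCheck("kickoff-rejects-output-format", "kickoff",
                     "An unsupported _outputFormat is rejected with a client error"),
    ConformanceCheck("kickoff-rejects-unknown-type", "kickoff",
                     "A _type naming an unsupported resource type is rejected"),
    ConformanceCheck("kickoff-rejects-bad-since", "kickoff",
                     "An unparseable _since instant is rejected"),
    ConformanceCheck("status-in-progress-headers", "status",
                     "While the job runs, status responses are 202 with X-Progress "
                     "and Retry-After headers"),
    ConformanceCheck("status-completion-manifest", "status",
                     "Completion is 200 with a JSON manifest carrying "
                     "transactionTime, request, requiresAccessToken, output and error"),
    ConformanceCheck("status-completion-expires", "status",
                     "The completion response carries an Expires hosting deadline"),
    ConformanceCheck("status-output-entry-shape", "status",
                     "Every manifest output entry has string type/url and integer count"),
    ConformanceCheck("status-idempotent-manifest", "status",
                     "Polling a completed job again returns an identical manifest"),
    ConformanceCheck("files-content-type", "files",
                     f"File downloads carry Content-Type {NDJSON_MEDIA_TYPE}"),
    ConformanceCheck("files-ndjson-purity", "files",
                     "Every file parses as NDJSON and contains exactly the one "
                     "resource type its manifest entry declares"),
    ConformanceCheck("files-count-integrity", "files",
                     "Every file's line count equals its manifest count"),
    ConformanceCheck("auth-token-issuance", "auth",
                     "A signed client assertion is exchanged for a bearer access token"),
    ConformanceCheck("auth-missing-token", "auth",
                     "A kickoff without a bearer token is rejected with 401"),
    ConformanceCheck("auth-tampered-assertion", "auth",
                     "A tampered client assertion is rejected as invalid_client"),
    ConformanceCheck("auth-replayed-assertion", "auth",
                     "Presenting the same assertion twice is rejected"),
    ConformanceCheck("auth-insufficient-scope", "auth",
                     "A kickoff needing types beyond the granted scopes is rejected "
                     "with 403", severity="optional"),
]

_BY_ID = {c.id: c for c in CHECKS}


def list_checks() -> list[ConformanceCheck]:
    """The stable check catalogue, grouped by protocol area."""
    return list(CHECKS)


# ---------------------------------------------------------------------------
# flows

@dataclass
class _Flow:
    """Recorded wire evidence for one scripted exchange."""

    responses: dict[str, _HttpResponse] = field(default_factory=dict)
    status_polls: list[_HttpResponse] = field(default_factory=list)
    manifest: Optional[dict] = None
    files: list[tuple[dict, _HttpResponse]] = field(default_factory=list)
    transport_error: Optional[str] = None


def _show(resp: _HttpResponse, *headers: str) -> str:
    shown = {h: resp.header(h) for h in headers if resp.header(h)}
    body = resp.body[:160].decode("utf-8", "replace")
    return f"HTTP {resp.status} {shown} body={body!r}"


class ConformanceRunner:
    """Execute the catalogue (or a subset) against a server base URL."""

    def __init__(
        self,
        base_url: str,
        credentials: Optional[ClientCredentials] = None,
        *,
        request_timeout: float = 10.0,
        poll_timeout: float = 60.0,
        transport=_default_transport,
        sleep=time.sleep,
    ):
        self.base_url = base_url.rstrip("/")
        self.credentials = credentials
        self.request_timeout = request_timeout
        self.poll_timeout = poll_timeout
        self._transport = transport
        self._sleep = sleep
        self._token: Optional[str] = None
        self._flows: dict[str, _Flow] = {}

    # -- low-level ---------------------------------------------------------

    def _get(self, url: str, flow: _Flow, key: str, headers: Optional[dict] = None,
             method: str = "GET", data: Optional[bytes] = None) -> Optional[_HttpResponse]:
        try:
            resp = self._transport(method, url, headers or {}, data, self.request_timeout)
        except OSError as exc:
            flow.transport_error = f"{method} {url}: {exc}"
            return None
        flow.responses[key] = resp
        return resp

    def _auth_headers(self) -> dict[str, str]:
        headers = {"Accept": "application/fhir+json", "Prefer": "respond-async"}
        if self._token:
            headers["Authorization"] = f"Bearer {self._token}"
        return headers

    def _ensure_token(self) -> None:
        if self._token is not None or self.credentials is None:
            return
        resp = self._post_assertion()
        if resp is not None and resp.status == 200:
            try:
                self._token = json.loads(resp.body).get("access_token")
            except ValueError:
                self._token = None

    def _post_assertion(self, assertion: Optional[str] = None,
                        scopes: Optional[str] = None) -> Optional[_HttpResponse]:
        assert self.credentials is not None
        assertion = assertion or build_client_assertion(
            self.credentials.client_id, self.credentials.private_key,
            self.credentials.token_endpoint)
        form = urlencode({
            "grant_type": "client_credentials",
            "scope": scopes if scopes is not None else self.credentials.scopes,
            "client_assertion_type": CLIENT_ASSERTION_TYPE,
            "client_assertion": assertion,
        }).encode("ascii")
        try:
            return self._transport(
                "POST", self.credentials.token_endpoint,
                {"Content-Type": "application/x-www-form-urlencoded"},
                form, self.request_timeout)
        except OSError:
            return None

    # -- flows (cached per run) --------------------------------------------

    def _kickoff_flow(self) -> _Flow:
        if "kickoff" in self._flows:
            return self._flows["kickoff"]
        flow = _Flow()
        self._ensure_token()
        base = self.base_url + "/$export"
        no_prefer = {k: v for k, v in self._auth_headers().items() if k != "Prefer"}
        self._get(base, flow, "no_prefer", no_prefer)
        self._get(base + "?_outputFormat=application/xml", flow, "bad_format",
                  self._auth_headers())
        self._get(base + "?_type=NotAResourceType", flow, "bad_type", self._auth_headers())
        self._get(base + "?_since=yesterday", flow, "bad_since", self._auth_headers())
        self._get(base, flow, "valid", self._auth_headers())
        self._flows["kickoff"] = flow
        return flow

    def _export_flow(self, key: str, download: bool = False) -> _Flow:
        """A fresh kickoff → poll (→ download) exchange (cached under ``key``).

        Downloads happen only for the files group so a fault injected at the
        file stage surfaces there and not in a status-group exchange.
        """
        if key in self._flows:
            return self._flows[key]
        flow = _Flow()
        self._ensure_token()
        kick = self._get(self.base_url + "/$export", flow, "kickoff", self._auth_headers())
        self._flows[key] = flow
        if kick is None or kick.status != 202 or not kick.header("Content-Location"):
            return flow
        status_url = urljoin(self.base_url + "/", kick.header("Content-Location"))
        deadline = time.monotonic() + self.poll_timeout
        while time.monotonic() < deadline:
            resp = self._get(status_url, flow, "status", self._auth_headers())
            if resp is None:
                return flow
            flow.status_polls.append(resp)
            if resp.status == 202:
                try:
                    wait = float(resp.header("Retry-After") or 0.5)
                except ValueError:
                    wait = 0.5
                self._sleep(min(wait, 2.0))
                continue
            break
        final = flow.status_polls[-1] if flow.status_polls else None
        if final is None or final.status != 200:
            return flow
        try:
            manifest = json.loads(final.body)
        except ValueError:
            return flow
        if not isinstance(manifest, dict):
            return flow
        flow.manifest = manifest
        self._get(status_url, flow, "repoll", self._auth_headers())
        if not download:
            return flow
        for entry in manifest.get("output", []) if isinstance(manifest.get("output"), list) else []:
            if not isinstance(entry, dict) or "url" not in entry:
                continue
            url = urljoin(self.base_url + "/", str(entry["url"]))
            resp = self._get(url, flow, f"file:{entry['url']}", self._auth_headers())
            if resp is not None:
                flow.files.append((entry, resp))
        return flow

    # -- evaluation --------------------------------------------------------

    def run(self, selection: str = "all") -> ConformanceReport:
        """Run all checks, one group, or a single check id."""
        if selection == "all":
            selected = CHECKS
        elif selection in GROUPS:
            selected = [c for c in CHECKS if c.group == selection]
        elif selection in _BY_ID:
            selected = [_BY_ID[selection]]
        else:
            raise ValueError(f"unknown selection {selection!r}; use 'all', a group "
                             f"name {GROUPS}, or a check id")
        report = ConformanceReport(
            target=self.base_url,
            timestamp=datetime.now(timezone.utc).isoformat(),
        )
        evaluators = self._evaluators()
        for check in selected:
            try:
                outcome, evidence = evaluators[check.id]()
            except Exception as exc:  # a crashed evaluator is a failed check, not a crash
                outcome, evidence = "fail", f"check evaluation error: {exc}"
            report.outcomes.append(CheckOutcome(check, outcome, evidence))
        return report

    def _evaluators(self) -> dict[str, Callable[[], tuple[str, str]]]:
        return {
            "kickoff-async-preference": self._eval_async_preference,
            "kickoff-content-location": self._eval_content_location,
            "kickoff-rejects-output-format": lambda: self._eval_rejection("bad_format"),
            "kickoff-rejects-unknown-type": lambda: self._eval_rejection("bad_type"),
            "kickoff-rejects-bad-since": lambda: self._eval_rejection("bad_since"),
            "status-in-progress-headers": self._eval_in_progress,
            "status-completion-manifest": self._eval_manifest,
            "status-completion-expires": self._eval_expires,
            "status-output-entry-shape": self._eval_entry_shape,
            "status-idempotent-manifest": self._eval_idempotent,
            "files-content-type": self._eval_file_content_type,
            "files-ndjson-purity": self._eval_file_purity,
            "files-count-integrity": self._eval_file_counts,
            "auth-token-issuance": self._eval_token_issuance,
            "auth-missing-token": self._eval_missing_token,
            "auth-tampered-assertion": self._eval_tampered,
            "auth-replayed-assertion": self._eval_replay,
            "auth-insufficient-scope": self._eval_insufficient_scope,
        }

    def _flow_or_fail(self, flow: _Flow) -> Optional[str]:
        if flow.transport_error:
            return f"transport failure: {flow.transport_error}"
        return None

    def _eval_async_preference(self) -> tuple[str, str]:
        flow = self._kickoff_flow()
        resp = flow.responses.get("no_prefer")
        if resp is None:
            return "fail", self._flow_or_fail(flow) or "no response recorded"
        if 400 <= resp.status < 500 and not resp.header("Content-Location"):
            return "pass", _show(resp)
        return "fail", _show(resp, "Content-Location")

    def _eval_content_location(self) -> tuple[str, str]:
        flow = self._kickoff_flow()
        resp = flow.responses.get("valid")
        if resp is None:
            return "fail", self._flow_or_fail(flow) or "no response recorded"
        if resp.status == 202 and resp.header("Content-Location"):
            return "pass", _show(resp, "Content-Location")
        return "fail", _show(resp, "Content-Location")

    def _eval_rejection(self, key: str) -> tuple[str, str]:
        flow = self._kickoff_flow()
        resp = flow.responses.get(key)
        if resp is None:
            return "fail", self._flow_or_fail(flow) or "no response recorded"
        if 400 <= resp.status < 500:
            return "pass", _show(resp)
        return "fail", _show(resp)

    def _eval_in_progress(self) -> tuple[str, str]:
        flow = self._export_flow("status")
        in_progress = [r for r in flow.status_polls if r.status == 202]
        if in_progress:
            resp = in_progress[0]
            if resp.header("X-Progress") and resp.header("Retry-After"):
                return "pass", _show(resp, "X-Progress", "Retry-After")
            return "fail", _show(resp, "X-Progress", "Retry-After")
        if flow.manifest is not None:
            return "skip", "job completed before the first poll; in-progress state not observable"
        return "fail", self._flow_or_fail(flow) or self._last_status_evidence(flow)

    def _last_status_evidence(self, flow: _Flow) -> str:
        if flow.status_polls:
            return "final status response: " + _show(flow.status_polls[-1])
        kick = flow.responses.get("kickoff")
        return "kickoff: " + (_show(kick) if kick else "no response")

    def _eval_manifest(self) -> tuple[str, str]:
        flow = self._export_flow("status")
        if flow.manifest is None:
            return "fail", self._flow_or_fail(flow) or self._last_status_evidence(flow)
        missing = [k for k in ("transactionTime", "request", "requiresAccessToken",
                               "output", "error") if k not in flow.manifest]
        if missing:
            return "fail", f"manifest lacks fields {missing}"
        if not isinstance(flow.manifest["output"], list) or not isinstance(flow.manifest["error"], list):
            return "fail", "manifest output/error are not arrays"
        return "pass", f"manifest fields present; {len(flow.manifest['output'])} output entries"

    def _eval_expires(self) -> tuple[str, str]:
        flow = self._export_flow("status")
        final = next((r for r in flow.status_polls if r.status == 200), None)
        if final is None:
            return "fail", self._flow_or_fail(flow) or self._last_status_evidence(flow)
        if final.header("Expires"):
            return "pass", f"Expires: {final.header('Expires')}"
        return "fail", _show(final, "Expires")

    def _eval_entry_shape(self) -> tuple[str, str]:
        flow = self._export_flow("status")
        if flow.manifest is None:
            return "fail", self._flow_or_fail(flow) or self._last_status_evidence(flow)
        for entry in flow.manifest.get("output", []):
            if not (isinstance(entry, dict) and isinstance(entry.get("type"), str)
                    and isinstance(entry.get("url"), str)
                    and isinstance(entry.get("count"), int)):
                return "fail", f"malformed output entry: {entry!r}"
        return "pass", f"{len(flow.manifest.get('output', []))} entries well-shaped"

    def _eval_idempotent(self) -> tuple[str, str]:
        flow = self._export_flow("status")
        final = next((r for r in flow.status_polls if r.status == 200), None)
        repoll = flow.responses.get("repoll")
        if final is None or repoll is None:
            return "fail", self._flow_or_fail(flow) or self._last_status_evidence(flow)
        if repoll.status == 200 and repoll.body == final.body:
            return "pass", "re-poll returned an identical manifest"
        return "fail", f"re-poll differs: {_show(repoll)}"

    def _eval_file_content_type(self) -> tuple[str, str]:
        flow = self._export_flow("files", download=True)
        if not flow.files:
            if flow.manifest is not None and not flow.manifest.get("output"):
                return "skip", "export produced no files"
            return "fail", self._flow_or_fail(flow) or self._last_status_evidence(flow)
        for entry, resp in flow.files:
            ctype = resp.header("Content-Type").split(";")[0].strip()
            if resp.status != 200 or ctype != NDJSON_MEDIA_TYPE:
                return "fail", f"{entry.get('url')}: {_show(resp, 'Content-Type')}"
        return "pass", f"{len(flow.files)} file(s) served as {NDJSON_MEDIA_TYPE}"

    def _eval_file_purity(self) -> tuple[str, str]:
        flow = self._export_flow("files", download=True)
        if not flow.files:
            if flow.manifest is not None and not flow.manifest.get("output"):
                return "skip", "export produced no files"
            return "fail", self._flow_or_fail(flow) or self._last_status_evidence(flow)
        for entry, resp in flow.files:
            try:
                resources = read_ndjson(resp.body)
            except NdjsonParseError as exc:
                return "fail", f"{entry.get('url')}: {exc}"
            types = {r.resource_type for r in resources}
            if types and types != {entry.get("type")}:
                return "fail", f"{entry.get('url')}: contains {sorted(types)}, declared {entry.get('type')}"
        return "pass", f"{len(flow.files)} file(s) parse cleanly, one type each"

    def _eval_file_counts(self) -> tuple[str, str]:
        flow = self._export_flow("files", download=True)
        if not flow.files:
            if flow.manifest is not None and not flow.manifest.get("output"):
                return "skip", "export produced no files"
            return "fail", self._flow_or_fail(flow) or self._last_status_evidence(flow)
        for entry, resp in flow.files:
            lines = sum(1 for ln in resp.body.split(b"\n") if ln.strip())
            if entry.get("count") != lines:
                return "fail", f"{entry.get('url')}: manifest count {entry.get('count')} != {lines} lines"
        return "pass", "all manifest counts equal file line counts"

    # -- auth checks -------------------------------------------------------

    def _eval_token_issuance(self) -> tuple[str, str]:
        if self.credentials is None:
            return "skip", "no credentials supplied"
        resp = self._post_assertion()
        if resp is None:
            return "fail", "transport failure on token endpoint"
        if resp.status != 200:
            return "fail", _show(resp)
        try:
            payload = json.loads(resp.body)
        except ValueError:
            return "fail", "token response is not JSON"
        if payload.get("access_token") and payload.get("token_type", "").lower() == "bearer" \
                and isinstance(payload.get("expires_in"), int):
            return "pass", f"token issued; expires_in={payload['expires_in']}s scope={payload.get('scope')!r}"
        return "fail", f"token response malformed: {payload}"

    def _eval_missing_token(self) -> tuple[str, str]:
        flow = _Flow()
        resp = self._get(self.base_url + "/$export", flow, "anon",
                         {"Accept": "application/fhir+json", "Prefer": "respond-async"})
        if resp is None:
            return "fail", self._flow_or_fail(flow) or "no response"
        if resp.status == 401:
            return "pass", _show(resp)
        if resp.status == 202:
            return "skip", "server does not enforce authorization (open endpoint)"
        return "fail", _show(resp)

    def _eval_tampered(self) -> tuple[str, str]:
        if self.credentials is None:
            return "skip", "no credentials supplied"
        assertion = build_client_assertion(
            self.credentials.client_id, self.credentials.private_key,
            self.credentials.token_endpoint)
        tampered = assertion[:-2] + ("A" if assertion[-2] != "A" else "B") + assertion[-1]
        resp = self._post_assertion(assertion=tampered)
        if resp is None:
            return "fail", "transport failure on token endpoint"
        if 400 <= resp.status < 500:
            return "pass", _show(resp)
        return "fail", _show(resp)

    def _eval_replay(self) -> tuple[str, str]:
        if self.credentials is None:
            return "skip", "no credentials supplied"
        assertion = build_client_assertion(
            self.credentials.client_id, self.credentials.private_key,
            self.credentials.token_endpoint)
        first = self._post_assertion(assertion=assertion)
        second = self._post_assertion(assertion=assertion)
        if first is None or second is None:
            return "fail", "transport failure on token endpoint"
        if first.status == 200 and 400 <= second.status < 500:
            return "pass", f"first: {first.status}; replay: {_show(second)}"
        return "fail", f"first: {_show(first)}; replay: {_show(second)}"

    def _eval_insufficient_scope(self) -> tuple[str, str]:
        if self.credentials is None:
            return "skip", "no credentials supplied"
        self._ensure_token()
        if self._token is None:
            return "fail", "could not acquire a token"
        resp = self._post_assertion()
        granted = ""
        if resp is not None and resp.status == 200:
            try:
                granted = json.loads(resp.body).get("scope", "")
            except ValueError:
                pass
        if "system/*.read" in granted.split():
            return "skip", "granted scope is wildcard; narrowing not demonstrable"
        flow = _Flow()
        out = self._get(self.base_url + "/$export", flow, "broad", self._auth_headers())
        if out is None:
            return "fail", self._flow_or_fail(flow) or "no response"
        if out.status == 403:
            return "pass", _show(out)
        return "fail", _show(out)
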