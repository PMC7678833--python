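"""Bulk-data download client.

Drives the full protocol against any standards-compliant server:
optional SMART Backend Services token acquisition, kickoff with the
required headers, status polling that honors ``Retry-After`` pacing,
download of every manifest output and error file, and local validation of
the NDJSON (well-formedness, one-type-per-file purity, manifest counts).

Any protocol violation raises :class:`ProtocolError` naming the stage at
which it occurred (``auth`` | ``kickoff`` | ``status`` | ``download`` |
``validation``) so scripted callers can react precisely; the CLI maps it
to a nonzero exit status.
"""
from __future__ import annotations

import concurrent.futures
import json
import logging
import time
import urllib.error
import urllib.request
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Mapping, Optional
from urllib.parse import urlencode, urljoin, urlsplit

from .backend_auth import CLIENT_ASSERTION_TYPE, build_client_assertion
from .fhir_core import NDJSON_MEDIA_TYPE, NdjsonParseError, format_instant, read_ndjson
from .rsa_jws import RsaPrivateKey

__all__ = ["ClientCredentials", "DownloadSummary", "FileReport", "ProtocolError", "BulkDataClient"]

logger = logging.getLogger("bulkfhir.client")

STAGES = ("auth", "kickoff", "status", "download", "validation")


class ProtocolError(Exception):
    """A protocol violation or failure at a named stage of the flow."""

    def __init__(self, stage: str, message: str):
        assert stage in STAGES
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class ClientCredentials:
    client_id: str
    private_key: RsaPrivateKey
    token_endpoint: str
    scopes: str = "system/*.read"


@dataclass
class FileReport:
    resource_type: str
    path: str
    line_count: int
    byte_size: int


@dataclass
class DownloadSummary:
    """What one export run produced."""

    status: str
    files: list[FileReport] = field(default_factory=list)
    error_files: list[str] = field(default_factory=list)
    total_resources: int = 0
    elapsed_seconds: float = 0.0
    polls: int = 0
    validation_issues: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "status": self.status,
            "totalResources": self.total_resources,
            "elapsedSeconds": round(self.elapsed_seconds, 3),
            "polls": self.polls,
            "files": [vars(f) for f in self.files],
            "errorFiles": list(self.error_files),
            "validationIssues": list(self.validation_issues),
        }


@dataclass
class _HttpResponse:
    status: int
    headers: Mapping[str, str]
    body: bytes

    def header(self, name: str, default: str = "") -> str:
        for key, value in self.headers.items():
            if key.lower() == name.lower():
                return value
        return default


def _default_transport(method: str, url: str, headers: Mapping[str, str],
                       data: Optional[bytes] = None, timeout: float = 30.0) -> _HttpResponse:
    request = urllib.request.Request(url, data=data, method=method, headers=dict(headers))
    try:
        with urllib.request.urlopen(request, timeout=timeout) as resp:
            return _HttpResponse(resp.status, dict(resp.headers.items()), resp.read())
    except urllib.error.HTTPError as err:
        return _HttpResponse(err.code, dict(err.headers.items()), err.read())


class BulkDataClient:
    """Scriptable bulk-export client.

    ``transport`` and ``sleep`` are injectable for testing (the recording
    pacing test swaps them); defaults use ``urllib`` and ``time.sleep``.
    """

    def __init__(
        self,
        base_url: str,
        credentials: Optional[ClientCredentials] = None,
        *,
        poll_timeout: float = 600.0,
        poll_floor: float = 1.0,
        request_timeout: float = 30.0,
        concurrency: int = 1,
        transport=_default_transport,
        sleep=time.sleep,
        clock=time.monotonic,
    ):
        if concurrency < 1:
            raise ValueError("concurrency must be >= 1")
        self.base_url = base_url.rstrip("/")
        self.credentials = credentials
        self.poll_timeout = poll_timeout
        self.poll_floor = poll_floor
        self.request_timeout = request_timeout
        self.concurrency = concurrency
        self._transport = transport
        self._sleep = sleep
        self._clock = clock
        self._token: Optional[str] = None

    # -- auth --------------------------------------------------------------

    def acquire_token(self) -> str:
        assert self.credentials is not None
        assertion = build_client_assertion(
            self.credentials.client_id,
            self.credentials.private_key,
            self.credentials.token_endpoint,
        )
        form = urlencode({
            "grant_type": "client_credentials",
            "scope": self.credentials.scopes,
            "client_assertion_type": CLIENT_ASSERTION_TYPE,
            "client_assertion": assertion,
        }).encode("ascii")
        resp = self._request("POST", self.credentials.token_endpoint, data=form,
                             headers={"Content-Type": "application/x-www-form-urlencoded"},
                             stage="auth")
        payload = self._json_body(resp, stage="auth")
        if resp.status != 200:
            raise ProtocolError(
                "auth",
                f"token endpoint rejected the request ({resp.status}): "
                f"{payload.get('error', '?')}: {payload.get('error_description', '')}",
            )
        token = payload.get("access_token")
        if not isinstance(token, str) or not token:
            raise ProtocolError("auth", "token response lacks access_token")
        self._token = token
        return token

    # -- main flow ---------------------------------------------------------

    def export_download(
        self,
        dest: str | Path,
        level: str = "system",
        group_id: Optional[str] = None,
        type_filter: Optional[list[str]] = None,
        since: Optional[datetime | str] = None,
        output_format: Optional[str] = None,
    ) -> DownloadSummary:
        """Run kickoff → poll → download → validate; return the summary."""
        started = self._clock()
        dest = Path(dest)
        dest.mkdir(parents=True, exist_ok=True)
        if self.credentials is not None and self._token is None:
            self.acquire_token()
        status_url = self.kickoff(level, group_id, type_filter, since, output_format)
        summary = DownloadSummary(status="in_progress")
        manifest = self.poll_until_complete(status_url, summary)
        self.download_manifest(manifest, dest, summary)
        self.validate_downloads(manifest, summary)
        summary.status = "complete"
        summary.elapsed_seconds = self._clock() - started
        return summary

    def kickoff(self, level: str, group_id: Optional[str] = None,
                type_filter: Optional[list[str]] = None,
                since: Optional[datetime | str] = None,
                output_format: Optional[str] = None) -> str:
        if level == "system":
            path = "/$export"
        elif level == "patient":
            path = "/Patient/$export"
        elif level == "group":
            if not group_id:
                raise ValueError("group-level export requires group_id")
            path = f"/Group/{group_id}/$export"
        else:
            raise ValueError(f"invalid export level {level!r}")
        params: dict[str, str] = {}
        if type_filter:
            params["_type"] = ",".join(type_filter)
        if since is not None:
            params["_since"] = format_instant(since) if isinstance(since, datetime) else since
        if output_format is not None:
            params["_outputFormat"] = output_format
        url = self.base_url + path + ("?" + urlencode(params) if params else "")
        resp = self._request("GET", url, headers={
            "Accept": "application/fhir+json",
            "Prefer": "respond-async",
            **self._auth_header(),
        }, stage="kickoff")
        if resp.status != 202:
            raise ProtocolError(
                "kickoff",
                f"expected 202 Accepted, got {resp.status}: {_excerpt(resp.body)}")
        location = resp.header("Content-Location")
        if not location:
            raise ProtocolError("kickoff", "202 response lacks Content-Location header")
        return urljoin(url, location)

    def poll_until_complete(self, status_url: str, summary: DownloadSummary) -> dict:
        deadline = self._clock() + self.poll_timeout
        while True:
            resp = self._request("GET", status_url, headers=self._auth_header(), stage="status")
            summary.polls += 1
            if resp.status == 200:
                manifest = self._json_body(resp, stage="status")
                self._check_manifest(manifest)
                return manifest
            if resp.status == 202:
                retry_after = resp.header("Retry-After")
                try:
                    wait = float(retry_after) if retry_after else self.poll_floor
                except ValueError:
                    wait = self.poll_floor
                if self._clock() + wait > deadline:
                    raise ProtocolError("status", f"poll timeout after {self.poll_timeout}s")
                logger.debug("in progress (%s); waiting %ss",
                             resp.header("X-Progress", "?"), wait)
                self._sleep(wait)
                continue
            raise ProtocolError(
                "status",
                f"status endpoint returned {resp.status}: {_excerpt(resp.body)}")

    def _check_manifest(self, manifest: object) -> None:
        if not isinstance(manifest, dict):
            raise ProtocolError("status", "manifest is not a JSON object")
        for key in ("transactionTime", "request", "requiresAccessToken", "output", "error"):
            if key not in manifest:
                raise ProtocolError("status", f"manifest lacks required field {key!r}")
        if not isinstance(manifest["output"], list) or not isinstance(manifest["error"], list):
            raise ProtocolError("status", "manifest output/error must be arrays")
        for entry in manifest["output"] + manifest["error"]:
            if not isinstance(entry, dict) or "type" not in entry or "url" not in entry:
                raise ProtocolError("status", f"malformed manifest entry: {entry!r}")

    def download_manifest(self, manifest: dict, dest: Path,
                          summary: DownloadSummary) -> None:
        counters: dict[str, int] = {}
        tasks = []
        for entry in manifest["output"]:
            rtype = str(entry["type"])
            counters[rtype] = counters.get(rtype, 0) + 1
            path = dest / f"{rtype}.{counters[rtype]}.ndjson"
            tasks.append((entry, path, False))
        for k, entry in enumerate(manifest["error"], start=1):
            path = dest / f"error.{k}.ndjson"
            tasks.append((entry, path, True))

        def fetch(task):
            entry, path, is_error = task
            url = urljoin(self.base_url + "/", str(entry["url"]))
            resp = self._request("GET", url, headers=self._auth_header(), stage="download")
            if resp.status != 200:
                raise ProtocolError(
                    "download",
                    f"file {entry['url']} returned {resp.status}: {_excerpt(resp.body)}")
            content_type = resp.header("Content-Type").split(";")[0].strip()
            if content_type != NDJSON_MEDIA_TYPE:
                raise ProtocolError(
                    "download",
                    f"file {entry['url']} has Content-Type {content_type!r}, "
                    f"expected {NDJSON_MEDIA_TYPE}")
            path.write_bytes(resp.body)
            return entry, path, is_error, resp.body

        if self.concurrency > 1 and len(tasks) > 1:
            with concurrent.futures.ThreadPoolExecutor(self.concurrency) as pool:
                results = list(pool.map(fetch, tasks))
        else:
            results = [fetch(t) for t in tasks]
        for entry, path, is_error, body in results:
            if is_error:
                summary.error_files.append(str(path))
            else:
                lines = sum(1 for ln in body.split(b"\n") if ln.strip())
                summary.files.append(FileReport(str(entry["type"]), str(path), lines, len(body)))
                summary.total_resources += lines

    def validate_downloads(self, manifest: dict, summary: DownloadSummary) -> None:
        """NDJSON well-formedness, single-type purity, manifest count integrity."""
        for report, entry in zip(summary.files, manifest["output"]):
            try:
                resources = read_ndjson(Path(report.path).read_bytes())
            except NdjsonParseError as exc:
                raise ProtocolError(
                    "validation",
                    f"{report.path}: malformed NDJSON at line {exc.line_number}: {exc}")
            types = {r.resource_type for r in resources}
            if len(types) > 1:
                raise ProtocolError(
                    "validation",
                    f"{report.path}: mixed resource types {sorted(types)} in one file")
            if types and types != {report.resource_type}:
                raise ProtocolError(
                    "validation",
                    f"{report.path}: contains {types.pop()} but manifest says "
                    f"{report.resource_type}")
            declared = entry.get("count")
            if declared is not None and declared != len(resources):
                raise ProtocolError(
                    "validation",
                    f"{report.path}: manifest count {declared} != {len(resources)} lines")

    # -- plumbing ----------------------------------------------------------

    def _auth_header(self) -> dict[str, str]:
        return {"Authorization": f"Bearer {self._token}"} if self._token else {}

    def _request(self, method: str, url: str, *, headers: Mapping[str, str],
                 data: Optional[bytes] = None, stage: str) -> _HttpResponse:
        try:
            return self._transport(method, url, headers, data, self.request_timeout)
        except OSError as exc:
            raise ProtocolError(stage, f"transport failure for {url}: {exc}") from exc

    def _json_body(self, resp: _HttpResponse, stage: str) -> dict:
        try:
            payload = json.loads(resp.body.decode("utf-8"))
        except (ValueError, UnicodeDecodeError) as exc:
            raise ProtocolError(stage, f"response body is not valid JSON: {exc}") from exc
        if not isinstance(payload, dict):
            raise ProtocolError(stage, "response body is not a JSON object")
        return payload


def _excerpt(body: bytes, limit: int = 200) -> str:
    text = body.decode("utf-8", "replace").strip()
    return text[:limit] + ("…" if len(text) > limit else "")


def origin_of(url: str) -> str:
    parts = urlsplit(url)
    return f"{parts.scheme}://{parts.netloc}"
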