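"""HTTP binding of the export engine and authorization server.

A plain WSGI application exposing the bulk-data wire protocol:

==========================================  ======================================
``GET  <fhir>/$export``                      system-level kickoff → 202 + Content-Location
``GET  <fhir>/Patient/$export``              all-patients kickoff
``GET  <fhir>/Group/<id>/$export``           group kickoff
``GET  <fhir>/jobs/<job>``                   status poll → 202 + X-Progress/Retry-After,
                                             200 + manifest + Expires, or 5XX
``DELETE <fhir>/jobs/<job>``                 cancel → 202
``GET  <fhir>/jobs/<job>/files/<file>``      NDJSON download (Content-Type
                                             ``application/fhir+ndjson``)
``GET  /file-host/<job>/<file>``             same, when files are hosted under a
                                             separate prefix
``POST /auth/token``                         SMART Backend Services token endpoint
==========================================  ======================================

Every error body is an OperationOutcome.  Authorization (bearer token) is
enforced before kickoff and status whenever clients are registered, and on
file downloads when ``requires_access_token`` is set.  Job URLs embed
unguessable ids.  The app runs under any WSGI host; :class:`BulkServer`
serves it on a local port with a threaded stdlib server.
"""
from __future__ import annotations

import json
import logging
import threading
import time
from dataclasses import dataclass, field
from datetime import timedelta
from email.utils import format_datetime
from pathlib import Path
from typing import Iterable, Optional
from urllib.parse import parse_qs
from wsgiref.simple_server import WSGIRequestHandler, WSGIServer, make_server
import socketserver

from .backend_auth import (
    AuthorizationDenied,
    AuthorizationServer,
    ClientRegistration,
)
from .export_engine import (
    ExportEngine,
    ExportRequest,
    KickoffError,
    PollComplete,
    PollFailed,
    PollInProgress,
    PollTransientError,
    PollUnknown,
    SimulatedFault,
    SimulationConfig,
    parse_export_params,
)
from .fhir_core import ResourceRepository, operation_outcome, parse_instant
from .rsa_jws import RsaPublicKey
from .synthetic_population import PopulationConfig, generate, load_fixture

__all__ = ["ServerConfig", "BulkDataApp", "BulkServer", "load_server_setup"]

logger = logging.getLogger("bulkfhir.http")

FHIR_BASE_PATH = "/fhir"
FILE_HOST_PATH = "/file-host"
TOKEN_PATH = "/auth/token"

FHIR_JSON = "application/fhir+json"


@dataclass
class ServerConfig:
    """Server-side knobs; durations in the units their names state."""

    token_lifetime: int = 300          # seconds
    retry_after: int = 1               # seconds, suggested poll interval
    retention_minutes: int = 60        # manifest/file hosting deadline
    requires_access_token: bool = True
    serve_files_separately: bool = False
    max_lines_per_file: Optional[int] = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    registrations: list[ClientRegistration] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.token_lifetime <= 0 or self.retry_after <= 0 or self.retention_minutes <= 0:
            raise ValueError("durations must be positive")


class _Response:
    def __init__(self, status: int, body: bytes = b"", content_type: Optional[str] = None,
                 headers: Optional[list[tuple[str, str]]] = None):
        self.status = status
        self.body = body
        self.headers = list(headers or [])
        if content_type and body:
            self.headers.append(("Content-Type", content_type))


def _json_response(status: int, obj: object, content_type: str = "application/json",
                   headers: Optional[list[tuple[str, str]]] = None) -> _Response:
    return _Response(status, json.dumps(obj, indent=1).encode("utf-8"), content_type, headers)


def _outcome_response(status: int, diagnostics: str, code: str = "invalid",
                      headers: Optional[list[tuple[str, str]]] = None) -> _Response:
    return _json_response(status, operation_outcome("error", code, diagnostics),
                          FHIR_JSON, headers)


_STATUS_REASONS = {
    200: "OK", 202: "Accepted", 400: "Bad Request", 401: "Unauthorized",
    403: "Forbidden", 404: "Not Found", 405: "Method Not Allowed",
    406: "Not Acceptable", 422: "Unprocessable Entity", 500: "Internal Server Error",
}


class BulkDataApp:
    """WSGI application wiring the auth server and export engine together.

    Bearer-token authorization is enforced exactly when ``registrations``
    are configured; an empty registry yields an open server (useful for
    fixtures and for conformance-testing unauthenticated deployments).
    """

    def __init__(self, repository: ResourceRepository, config: Optional[ServerConfig] = None):
        self.config = config or ServerConfig()
        self.repository = repository
        #: origin (scheme://host:port) used in manifests; set when served.
        self.external_root = ""
        self.auth = AuthorizationServer(
            token_endpoint=TOKEN_PATH,  # re-pointed at the absolute URL once served
            registrations=self.config.registrations,
            token_lifetime=timedelta(seconds=self.config.token_lifetime),
        )
        self.engine = ExportEngine(
            repository,
            retry_after=self.config.retry_after,
            retention=timedelta(minutes=self.config.retention_minutes),
            max_lines_per_file=self.config.max_lines_per_file,
            requires_access_token=self.file_auth_enforced,
            simulation=self.config.simulation,
            file_url_builder=self._file_url,
        )

    @property
    def auth_enforced(self) -> bool:
        return bool(self.config.registrations)

    @property
    def file_auth_enforced(self) -> bool:
        # a server with no registered clients cannot demand tokens on files,
        # and the manifest's requiresAccessToken must say so truthfully
        return self.config.requires_access_token and self.auth_enforced

    def _file_url(self, job_id: str, file_id: str) -> str:
        if self.config.serve_files_separately:
            path = f"{FILE_HOST_PATH}/{job_id}/{file_id}"
        else:
            path = f"{FHIR_BASE_PATH}/jobs/{job_id}/files/{file_id}"
        return self.external_root + path

    # -- WSGI --------------------------------------------------------------

    def __call__(self, environ, start_response):
        method = environ["REQUEST_METHOD"]
        path = environ.get("PATH_INFO", "")
        try:
            response = self._route(method, path, environ)
        except Exception as exc:  # last-resort guard: never leak a traceback
            logger.exception("unhandled error on %s %s", method, path)
            response = _outcome_response(500, f"internal error: {exc}", code="exception")
        reason = _STATUS_REASONS.get(response.status, "Unknown")
        headers = response.headers + [("Content-Length", str(len(response.body)))]
        logger.info("%s %s -> %d", method, path, response.status)
        start_response(f"{response.status} {reason}", headers)
        return [response.body]

    def _route(self, method: str, path: str, environ) -> _Response:
        if path == TOKEN_PATH:
            if method != "POST":
                return _outcome_response(405, "token endpoint requires POST")
            return self._token(environ)
        if path.startswith(FILE_HOST_PATH + "/"):
            parts = path[len(FILE_HOST_PATH) + 1:].split("/")
            if method == "GET" and len(parts) == 2:
                return self._file(parts[0], parts[1], environ)
            return _outcome_response(404, f"no route for {path}", code="not-found")
        if path.startswith(FHIR_BASE_PATH + "/"):
            sub = path[len(FHIR_BASE_PATH):]
            if method == "GET" and sub == "/$export":
                return self._kickoff("system", None, environ)
            if method == "GET" and sub == "/Patient/$export":
                return self._kickoff("patient", None, environ)
            if method == "GET" and sub.startswith("/Group/") and sub.endswith("/$export"):
                gid = sub[len("/Group/"):-len("/$export")]
                return self._kickoff("group", gid, environ)
            if sub.startswith("/jobs/"):
                parts = sub[len("/jobs/"):].split("/")
                if len(parts) == 1:
                    if method == "GET":
                        return self._status(parts[0], environ)
                    if method == "DELETE":
                        return self._cancel(parts[0], environ)
                    return _outcome_response(405, "status endpoint allows GET and DELETE")
                if method == "GET" and len(parts) == 3 and parts[1] == "files":
                    return self._file(parts[0], parts[2], environ)
        return _outcome_response(404, f"no route for {method} {path}", code="not-found")

    # -- handlers ----------------------------------------------------------

    def _headers(self, environ) -> dict[str, str]:
        out = {}
        for key, value in environ.items():
            if key.startswith("HTTP_"):
                out[key[5:].replace("_", "-").lower()] = value
        if "CONTENT_TYPE" in environ:
            out["content-type"] = environ["CONTENT_TYPE"]
        return out

    def _bearer(self, environ) -> Optional[str]:
        auth = environ.get("HTTP_AUTHORIZATION", "")
        if auth.lower().startswith("bearer "):
            return auth[7:].strip()
        return None

    def _authenticate(self, environ, needed_types: Iterable[str] = ()) -> Optional[_Response]:
        """Return an error response when the bearer token fails, else None."""
        if not self.auth_enforced:
            return None
        try:
            decision = self.auth.authorize(self._bearer(environ), needed_types)
        except AuthorizationDenied as exc:
            status = 401 if exc.kind == "unauthenticated" else 403
            hdrs = [("WWW-Authenticate", "Bearer")] if status == 401 else None
            return _outcome_response(status, exc.description, code="security", headers=hdrs)
        environ["bulkfhir.decision"] = decision
        return None

    def _token(self, environ) -> _Response:
        try:
            length = int(environ.get("CONTENT_LENGTH") or 0)
        except ValueError:
            length = 0
        body = environ["wsgi.input"].read(length).decode("utf-8", "replace")
        form = {k: v[0] for k, v in parse_qs(body).items()}
        status, payload = self.auth.handle_token_request(form)
        return _json_response(status, payload)

    def _kickoff(self, level: str, group_id: Optional[str], environ) -> _Response:
        headers = self._headers(environ)
        params = {k: v[0] for k, v in parse_qs(environ.get("QUERY_STRING", "")).items()}
        denied = self._authenticate(environ)
        if denied:
            return denied
        try:
            type_filter, since, output_format = parse_export_params(params)
        except KickoffError as exc:
            return _json_response(exc.status, exc.outcome, FHIR_JSON)
        accept = headers.get("accept", "")
        if accept and FHIR_JSON not in accept and "*/*" not in accept:
            return _outcome_response(406, f"kickoff requires Accept: {FHIR_JSON}")
        needed = type_filter or (self.engine.supported_types - {"OperationOutcome"})
        decision = environ.get("bulkfhir.decision")
        if decision is not None and not needed <= decision.granted_types:
            return _outcome_response(
                403, f"granted scopes do not cover resource types {sorted(needed)}",
                code="security")
        policy_group = decision.policy_group if decision is not None else None
        request = ExportRequest(
            level=level,
            group_id=group_id,
            type_filter=type_filter,
            since=since,
            output_format=output_format,
            policy_group=policy_group,
            kickoff_url=self._request_url(environ),
        )
        try:
            job = self.engine.kickoff(request, headers)
        except KickoffError as exc:
            return _json_response(exc.status, exc.outcome, FHIR_JSON)
        except SimulatedFault as exc:
            return _json_response(500, exc.outcome, FHIR_JSON)
        worker = threading.Thread(target=self._run_job, args=(job,), daemon=True)
        worker.start()
        status_url = f"{self._origin(environ)}{FHIR_BASE_PATH}/jobs/{job.job_id}"
        return _Response(202, headers=[("Content-Location", status_url)])

    def _run_job(self, job) -> None:
        if self.config.simulation.latency_seconds:
            time.sleep(self.config.simulation.latency_seconds)
        try:
            self.engine.run_job(job)
        except Exception:  # run_job already marks failure; belt and braces
            logger.exception("job runner crashed for %s", job.job_id)

    def _status(self, job_id: str, environ) -> _Response:
        denied = self._authenticate(environ)
        if denied:
            return denied
        result = self.engine.poll(job_id)
        if isinstance(result, PollUnknown):
            return _outcome_response(404, f"unknown export job {job_id!r}", code="not-found")
        if isinstance(result, PollTransientError):
            return _json_response(500, result.outcome, FHIR_JSON)
        if isinstance(result, PollFailed):
            return _json_response(500, result.outcome, FHIR_JSON)
        if isinstance(result, PollInProgress):
            return _Response(202, headers=[
                ("X-Progress", result.progress_text),
                ("Retry-After", str(result.retry_after)),
            ])
        assert isinstance(result, PollComplete)
        return _json_response(
            200, result.manifest,
            headers=[("Expires", format_datetime(result.expires_at, usegmt=True))],
        )

    def _cancel(self, job_id: str, environ) -> _Response:
        denied = self._authenticate(environ)
        if denied:
            return denied
        if not self.engine.cancel_job(job_id):
            return _outcome_response(404, f"unknown export job {job_id!r}", code="not-found")
        return _json_response(
            202, operation_outcome("information", "informational", "export job cancelled"),
            FHIR_JSON)

    def _file(self, job_id: str, file_id: str, environ) -> _Response:
        if self.file_auth_enforced:
            denied = self._authenticate(environ)
            if denied:
                return denied
        result = self.engine.get_file(job_id, file_id)
        if result is None:
            return _outcome_response(404, f"no file {file_id!r} for job {job_id!r}",
                                     code="not-found")
        data, media_type = result
        return _Response(200, data, media_type)

    # -- url helpers -------------------------------------------------------

    def _origin(self, environ) -> str:
        host = environ.get("HTTP_HOST") or environ.get("SERVER_NAME", "localhost")
        return f"{environ.get('wsgi.url_scheme', 'http')}://{host}"

    def _request_url(self, environ) -> str:
        url = self._origin(environ) + environ.get("PATH_INFO", "")
        query = environ.get("QUERY_STRING", "")
        return url + ("?" + query if query else "")


class _ThreadingWSGIServer(socketserver.ThreadingMixIn, WSGIServer):
    daemon_threads = True


class _QuietHandler(WSGIRequestHandler):
    def log_message(self, fmt, *args):  # route access logs through logging
        logger.debug("%s " + fmt, self.address_string(), *args)


class BulkServer:
    """Serve a :class:`BulkDataApp` on a local port (thread per request)."""

    def __init__(self, app: BulkDataApp, host: str = "127.0.0.1", port: int = 0):
        self.app = app
        self._httpd = make_server(host, port, app,
                                  server_class=_ThreadingWSGIServer,
                                  handler_class=_QuietHandler)
        self.host, self.port = self._httpd.server_address[:2]
        app.external_root = self.root
        # assertions are audience-bound to the URL clients actually post to
        app.auth.token_endpoint = self.token_url
        self._thread: Optional[threading.Thread] = None

    @property
    def root(self) -> str:
        return f"http://{self.host}:{self.port}"

    @property
    def fhir_base_url(self) -> str:
        return self.root + FHIR_BASE_PATH

    @property
    def token_url(self) -> str:
        return self.root + TOKEN_PATH

    def start(self) -> "BulkServer":
        self._thread = threading.Thread(target=self._httpd.serve_forever,
                                        kwargs={"poll_interval": 0.05}, daemon=True)
        self._thread.start()
        return self

    def stop(self) -> None:
        self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread:
            self._thread.join(timeout=5)

    def __enter__(self) -> "BulkServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()


def load_server_setup(config_path: str | Path) -> tuple[ResourceRepository, ServerConfig]:
    """Read the JSON server-config file and materialize repository + config.

    The file holds either ``"fixture": "<dir>"`` (an NDJSON fixture
    directory) or ``"population": {...}`` (generator parameters with RFC3339
    window instants), plus any :class:`ServerConfig` field, ``simulation``
    settings, and ``registrations`` (``client_id``, ``public_key_pem``,
    ``scopes``, optional ``policy_group``).
    """
    raw = json.loads(Path(config_path).read_text())
    if "fixture" in raw:
        repository = load_fixture(raw["fixture"])
    elif "population" in raw:
        pop = dict(raw["population"])
        if "time_window" in pop:
            start, end = pop["time_window"]
            pop["time_window"] = (parse_instant(start), parse_instant(end))
        if "resources_per_patient" in pop:
            pop["resources_per_patient"] = dict(pop["resources_per_patient"])
        repository = generate(PopulationConfig(**pop))
    else:
        raise ValueError("config must provide 'fixture' or 'population'")
    sim = SimulationConfig(**raw.get("simulation", {}))
    registrations = [
        ClientRegistration(
            client_id=reg["client_id"],
            public_key=RsaPublicKey.from_pem(reg["public_key_pem"]),
            allowed_scopes=frozenset(reg["scopes"]),
            policy_group=reg.get("policy_group"),
        )
        for reg in raw.get("registrations", [])
    ]
    config = ServerConfig(
        token_lifetime=raw.get("token_lifetime", 300),
        retry_after=raw.get("retry_after", 1),
        retention_minutes=raw.get("retention_minutes", 60),
        requires_access_token=raw.get("requires_access_token", True),
        serve_files_separately=raw.get("serve_files_separately", False),
        max_lines_per_file=raw.get("max_lines_per_file"),
        simulation=sim,
        registrations=registrations,
    )
    return repository, config
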