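"""Wire-protocol behavior over a real local HTTP server."""
import json
import time
import urllib.error
import urllib.parse
import urllib.request
from datetime import datetime, timezone
from email.utils import parsedate_to_datetime

import pytest

from bulkfhir.backend_auth import ClientRegistration, build_client_assertion
from bulkfhir.export_engine import SimulationConfig
from bulkfhir.http_surface import ServerConfig, load_server_setup
from bulkfhir.synthetic_population import PopulationConfig, export_fixture, generate

ASYNC_HEADERS = {"Prefer": "respond-async", "Accept": "application/fhir+json"}


def http(method, url, headers=None, data=None):
    """Raw request returning (status, headers, body) without raising on 4xx/5xx."""
    req = urllib.request.Request(url, method=method, data=data,
                                 headers=dict(headers or {}))
    try:
        with urllib.request.urlopen(req, timeout=10) as resp:
            return resp.status, dict(resp.headers), resp.read()
    except urllib.error.HTTPError as exc:
        return exc.code, dict(exc.headers), exc.read()


def wait_for_manifest(status_url, headers=None, timeout=10.0):
    deadline = time.monotonic() + timeout
    while time.monotonic() < deadline:
        status, hdrs, body = http("GET", status_url, headers)
        if status == 200:
            return hdrs, json.loads(body)
        assert status == 202, (status, body)
        time.sleep(min(float(hdrs.get("Retry-After", "0.05")), 0.2))
    raise AssertionError("export did not complete in time")


def get_token(server, keypair, client_id="analytics-app", scope="system/*.read"):
    assertion = build_client_assertion(client_id, keypair, server.token_url)
    form = urllib.parse.urlencode({
        "grant_type": "client_credentials",
        "scope": scope,
        "client_assertion_type":
            "urn:ietf:params:oauth:client-assertion-type:jwt-bearer",
        "client_assertion": assertion,
    }).encode()
    status, _, body = http("POST", server.token_url, data=form,
                           headers={"Content-Type": "application/x-www-form-urlencoded"})
    assert status == 200, body
    return json.loads(body)["access_token"]


class TestOpenServerProtocol:
    """No registered clients → open server; pure protocol mechanics."""

    def test_kickoff_returns_202_with_content_location(self, make_server, small_repo):
        server = make_server(small_repo)
        status, headers, body = http(
            "GET", server.fhir_base_url + "/Patient/$export", ASYNC_HEADERS)
        assert status == 202
        assert headers["Content-Location"].startswith(server.fhir_base_url + "/jobs/")
        assert body == b""

    def test_kickoff_without_prefer_is_422_without_content_location(
            self, make_server, small_repo):
        server = make_server(small_repo)
        status, headers, body = http("GET", server.fhir_base_url + "/$export",
                                     {"Accept": "application/fhir+json"})
        assert status == 422
        assert "Content-Location" not in headers
        outcome = json.loads(body)
        assert outcome["resourceType"] == "OperationOutcome"
        assert "respond-async" in outcome["issue"][0]["diagnostics"]

    @pytest.mark.parametrize(
        "query, expected",
        [
            ("_type=Spaceship", 422),
            ("_since=notadate", 422),
            ("_outputFormat=text/csv", 422),
            ("_typeFilter=Patient%3Fgender%3Dmale", 422),
            ("_unknownParam=1", 422),
        ],
    )
    def test_kickoff_parameter_errors(self, make_server, small_repo, query, expected):
        server = make_server(small_repo)
        status, _, body = http(
            "GET", server.fhir_base_url + f"/$export?{query}", ASYNC_HEADERS)
        assert status == expected
        assert json.loads(body)["resourceType"] == "OperationOutcome"

    def test_unacceptable_accept_header_is_406(self, make_server, small_repo):
        server = make_server(small_repo)
        status, _, _ = http("GET", server.fhir_base_url + "/$export",
                            {"Prefer": "respond-async", "Accept": "text/html"})
        assert status == 406

    def test_unknown_group_is_404(self, make_server, small_repo):
        server = make_server(small_repo)
        status, _, _ = http(
            "GET", server.fhir_base_url + "/Group/ghost/$export", ASYNC_HEADERS)
        assert status == 404

    def test_complete_flow_headers_manifest_and_files(self, make_server, small_repo):
        server = make_server(small_repo, ServerConfig(requires_access_token=False))
        _, headers, _ = http(
            "GET", server.fhir_base_url + "/$export?_type=Patient,Observation",
            ASYNC_HEADERS)
        hdrs, manifest = wait_for_manifest(headers["Content-Location"])
        expires = parsedate_to_datetime(hdrs["Expires"])
        assert expires > datetime.now(timezone.utc)
        assert manifest["requiresAccessToken"] is False
        assert manifest["request"].endswith("/$export?_type=Patient,Observation")
        assert {e["type"] for e in manifest["output"]} == {"Patient", "Observation"}
        for entry in manifest["output"]:
            status, fhdrs, body = http("GET", entry["url"])
            assert status == 200
            assert fhdrs["Content-Type"] == "application/fhir+ndjson"
            lines = [l for l in body.decode().splitlines() if l]
            assert len(lines) == entry["count"]
            assert all(json.loads(l)["resourceType"] == entry["type"] for l in lines)

    def test_in_progress_status_has_progress_and_retry_after(
            self, make_server, small_repo):
        server = make_server(small_repo, ServerConfig(
            retry_after=2, simulation=SimulationConfig(latency_seconds=0.5)))
        _, headers, _ = http("GET", server.fhir_base_url + "/$export", ASYNC_HEADERS)
        status, hdrs, body = http("GET", headers["Content-Location"])
        assert status == 202
        assert "resource types exported" in hdrs["X-Progress"]
        assert hdrs["Retry-After"] == "2"
        assert body == b""

    def test_delete_cancels_then_404(self, make_server, small_repo):
        server = make_server(small_repo, ServerConfig(
            simulation=SimulationConfig(latency_seconds=0.5)))
        _, headers, _ = http("GET", server.fhir_base_url + "/$export", ASYNC_HEADERS)
        status_url = headers["Content-Location"]
        status, _, body = http("DELETE", status_url)
        assert status == 202
        assert json.loads(body)["resourceType"] == "OperationOutcome"
        assert http("GET", status_url)[0] == 404
        assert http("DELETE", status_url)[0] == 404

    def test_probing_opaque_job_ids_yields_404(self, make_server, small_repo):
        server = make_server(small_repo)
        for jid in ("1", "job-1", "admin", "../../etc/passwd"):
            quoted = urllib.parse.quote(jid, safe="")
            assert http("GET", f"{server.fhir_base_url}/jobs/{quoted}")[0] == 404

    def test_unrouted_paths_are_404_operation_outcomes(self, make_server, small_repo):
        server = make_server(small_repo)
        for path in ("/fhir/Observation/$export", "/fhir/", "/metadata"):
            status, _, body = http("GET", server.root + path, ASYNC_HEADERS)
            assert status == 404
            assert json.loads(body)["resourceType"] == "OperationOutcome"

    def test_status_codes_from_allowed_set_only(self, make_server, small_repo):
        """Every response the server emits uses the documented status set."""
        server = make_server(small_repo)
        allowed = {200, 202, 400, 401, 403, 404, 405, 406, 422, 500}
        probes = [
            ("GET", "/fhir/$export", ASYNC_HEADERS),
            ("GET", "/fhir/$export", {}),
            ("POST", "/fhir/$export", ASYNC_HEADERS),
            ("GET", "/auth/token", {}),
            ("POST", "/auth/token", {}),
            ("GET", "/fhir/jobs/zzz", {}),
            ("PUT", "/fhir/jobs/zzz", {}),
            ("GET", "/file-host/a/b", {}),
            ("GET", "/nowhere", {}),
        ]
        for method, path, headers in probes:
            status, _, _ = http(method, server.root + path, headers)
            assert status in allowed, (method, path, status)


class TestAuthenticatedServer:
    @pytest.fixture
    def auth_server(self, make_server, small_repo, keypair, wildcard_registration):
        return make_server(small_repo, ServerConfig(
            registrations=[wildcard_registration]))

    def test_kickoff_without_token_is_401(self, auth_server):
        status, headers, _ = http(
            "GET", auth_server.fhir_base_url + "/$export", ASYNC_HEADERS)
        assert status == 401
        assert headers.get("WWW-Authenticate") == "Bearer"

    def test_narrow_scope_kickoff_is_403(self, make_server, small_repo, keypair):
        reg = ClientRegistration("narrow", keypair.public_key,
                                 frozenset({"system/Patient.read"}))
        server = make_server(small_repo, ServerConfig(registrations=[reg]))
        token = get_token(server, keypair, "narrow", "system/Patient.read")
        bearer = {"Authorization": f"Bearer {token}", **ASYNC_HEADERS}
        # unscoped kickoff needs every supported type -> forbidden
        assert http("GET", server.fhir_base_url + "/$export", bearer)[0] == 403
        # a _type restricted to the granted scope is allowed
        status, _, _ = http(
            "GET", server.fhir_base_url + "/$export?_type=Patient", bearer)
        assert status == 202

    def test_full_authorized_flow_and_protected_files(self, auth_server, keypair):
        token = get_token(auth_server, keypair)
        bearer = {"Authorization": f"Bearer {token}"}
        _, headers, _ = http("GET", auth_server.fhir_base_url + "/Patient/$export",
                             {**bearer, **ASYNC_HEADERS})
        _, manifest = wait_for_manifest(headers["Content-Location"], bearer)
        assert manifest["requiresAccessToken"] is True
        url = manifest["output"][0]["url"]
        assert http("GET", url)[0] == 401         # tokenless download refused
        assert http("GET", url, bearer)[0] == 200

    def test_status_poll_requires_token(self, auth_server, keypair):
        token = get_token(auth_server, keypair)
        _, headers, _ = http(
            "GET", auth_server.fhir_base_url + "/Patient/$export",
            {"Authorization": f"Bearer {token}", **ASYNC_HEADERS})
        assert http("GET", headers["Content-Location"])[0] == 401

    def test_policy_group_client_sees_only_its_cohort(
            self, make_server, small_repo, keypair):
        gid = sorted(small_repo.groups)[0]
        reg = ClientRegistration("cohort-app", keypair.public_key,
                                 frozenset({"system/*.read"}), policy_group=gid)
        server = make_server(small_repo, ServerConfig(registrations=[reg]))
        token = get_token(server, keypair, "cohort-app")
        bearer = {"Authorization": f"Bearer {token}"}
        _, headers, _ = http(
            "GET", server.fhir_base_url + "/Patient/$export?_type=Patient",
            {**bearer, **ASYNC_HEADERS})
        _, manifest = wait_for_manifest(headers["Content-Location"], bearer)
        count = sum(e["count"] for e in manifest["output"])
        assert count == len(small_repo.groups[gid])


class TestSeparateFileHost:
    def test_file_urls_use_file_host_prefix(self, make_server, small_repo):
        server = make_server(small_repo, ServerConfig(
            serve_files_separately=True, requires_access_token=False))
        _, headers, _ = http(
            "GET", server.fhir_base_url + "/$export?_type=Patient", ASYNC_HEADERS)
        _, manifest = wait_for_manifest(headers["Content-Location"])
        for entry in manifest["output"]:
            assert entry["url"].startswith(server.root + "/file-host/")
            status, fhdrs, body = http("GET", entry["url"])
            assert status == 200
            assert fhdrs["Content-Type"] == "application/fhir+ndjson"
            assert len([l for l in body.splitlines() if l]) == entry["count"]


class TestServerFaults:
    def test_kickoff_fault_surfaces_as_500(self, make_server, small_repo):
        server = make_server(small_repo, ServerConfig(
            simulation=SimulationConfig(fault_stage="kickoff", fault_times=1)))
        status, _, body = http("GET", server.fhir_base_url + "/$export", ASYNC_HEADERS)
        assert status == 500
        assert json.loads(body)["resourceType"] == "OperationOutcome"
        # budget spent: next kickoff succeeds
        assert http("GET", server.fhir_base_url + "/$export", ASYNC_HEADERS)[0] == 202

    def test_status_fault_returns_500_then_recovers(self, make_server, small_repo):
        server = make_server(small_repo, ServerConfig(
            simulation=SimulationConfig(fault_stage="status", fault_times=1)))
        _, headers, _ = http("GET", server.fhir_base_url + "/$export", ASYNC_HEADERS)
        time.sleep(0.3)
        assert http("GET", headers["Content-Location"])[0] == 500
        _, manifest = wait_for_manifest(headers["Content-Location"])
        assert manifest["output"]


class TestLoadServerSetup:
    def test_population_config_with_registrations(self, tmp_path, keypair):
        config_file = tmp_path / "server.json"
        config_file.write_text(json.dumps({
            "population": {
                "n_patients": 5, "n_groups": 1, "group_fill": 0.4, "seed": 3,
                "time_window": ["2019-01-01T00:00:00Z", "2020-01-01T00:00:00Z"],
                "resources_per_patient": {"Observation": 1.0},
            },
            "retry_after": 4,
            "serve_files_separately": True,
            "registrations": [{
                "client_id": "app",
                "public_key_pem": keypair.public_key.to_pem(),
                "scopes": ["system/*.read"],
            }],
        }))
        repo, config = load_server_setup(config_file)
        assert len(repo.of_type("Patient")) == 5
        assert config.retry_after == 4
        assert config.serve_files_separately is True
        assert config.registrations[0].client_id == "app"
        assert config.registrations[0].public_key == keypair.public_key

    def test_fixture_config_round_trip(self, tmp_path):
        repo = generate(PopulationConfig(n_patients=4, n_groups=1, seed=8))
        fixture_dir = tmp_path / "fixture"
        fixture_dir.mkdir()
        export_fixture(repo, fixture_dir)
        config_file = tmp_path / "server.json"
        config_file.write_text(json.dumps({"fixture": str(fixture_dir)}))
        loaded, config = load_server_setup(config_file)
        assert loaded == repo
        assert config.registrations == []

    def test_missing_source_rejected(self, tmp_path):
        config_file = tmp_path / "server.json"
        config_file.write_text(json.dumps({"retry_after": 2}))
        with pytest.raises(ValueError):
            load_server_setup(config_file)
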