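"""Client behavior: end-to-end downloads, pacing, stage diagnostics, CLI."""
import json
from collections import Counter
from pathlib import Path

import pytest
from click.testing import CliRunner

from bulkfhir.cli import main as cli_main
from bulkfhir.client import (
    BulkDataClient,
    ClientCredentials,
    ProtocolError,
    _HttpResponse,
)
from bulkfhir.export_engine import SimulationConfig
from bulkfhir.fhir_core import read_ndjson
from bulkfhir.http_surface import ServerConfig

from selection_oracle import brute_force_select


def downloaded_multiset(dest):
    counted = Counter()
    for path in Path(dest).glob("*.ndjson"):
        if path.name.startswith("error."):
            continue
        for res in read_ndjson(path.read_bytes()):
            counted[(res.resource_type, res.id)] += 1
    return counted


class TestEndToEnd:
    def test_download_matches_oracle(self, make_server, small_repo, tmp_path):
        server = make_server(small_repo, ServerConfig(requires_access_token=False))
        client = BulkDataClient(server.fhir_base_url, poll_floor=0.05)
        summary = client.export_download(tmp_path / "out", level="patient",
                                         type_filter=["Patient", "Observation"])
        want = brute_force_select(small_repo, "patient",
                                  type_filter={"Patient", "Observation"})
        assert downloaded_multiset(tmp_path / "out") == want
        assert summary.status == "complete"
        assert summary.total_resources == sum(want.values())
        assert summary.polls >= 1
        assert summary.validation_issues == []

    def test_authenticated_flow(self, make_server, small_repo, tmp_path, keypair,
                                wildcard_registration):
        server = make_server(small_repo, ServerConfig(
            registrations=[wildcard_registration]))
        creds = ClientCredentials("analytics-app", keypair, server.token_url)
        client = BulkDataClient(server.fhir_base_url, creds, poll_floor=0.05)
        summary = client.export_download(tmp_path / "out", level="system")
        assert summary.total_resources == sum(
            brute_force_select(small_repo, "system").values())

    def test_empty_cohort_completes_with_zero_files(self, make_server, small_repo,
                                                    tmp_path):
        server = make_server(small_repo, ServerConfig(requires_access_token=False))
        client = BulkDataClient(server.fhir_base_url, poll_floor=0.05)
        summary = client.export_download(tmp_path / "out", level="system",
                                         since="2030-01-01T00:00:00Z")
        assert summary.status == "complete"
        assert summary.total_resources == 0
        assert summary.files == []

    def test_concurrent_downloads_byte_identical(self, make_server, small_repo,
                                                 tmp_path):
        server = make_server(small_repo, ServerConfig(
            requires_access_token=False, max_lines_per_file=5))
        serial = BulkDataClient(server.fhir_base_url, poll_floor=0.05, concurrency=1)
        parallel = BulkDataClient(server.fhir_base_url, poll_floor=0.05, concurrency=4)
        serial.export_download(tmp_path / "a", level="system")
        parallel.export_download(tmp_path / "b", level="system")
        names_a = sorted(p.name for p in (tmp_path / "a").glob("*.ndjson"))
        names_b = sorted(p.name for p in (tmp_path / "b").glob("*.ndjson"))
        assert names_a == names_b and len(names_a) > 1
        for name in names_a:
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes()


class TestPacing:
    """Retry-After compliance via a scripted fake transport."""

    def _scripted_client(self, responses, **kwargs):
        script = list(responses)
        calls = []

        def transport(method, url, headers, data=None, timeout=30.0):
            calls.append((method, url))
            return script.pop(0)

        sleeps = []
        client = BulkDataClient("http://fake/fhir", transport=transport,
                                sleep=sleeps.append, poll_floor=1.0,
                                poll_timeout=600, **kwargs)
        return client, sleeps, calls

    MANIFEST = json.dumps({
        "transactionTime": "2024-01-01T00:00:00Z", "request": "http://fake/fhir/$export",
        "requiresAccessToken": False, "output": [], "error": [],
    }).encode()

    def test_sleeps_exactly_retry_after(self, tmp_path):
        client, sleeps, _ = self._scripted_client([
            _HttpResponse(202, {"Content-Location": "http://fake/fhir/jobs/j1"}, b""),
            _HttpResponse(202, {"X-Progress": "0 of 2", "Retry-After": "7"}, b""),
            _HttpResponse(202, {"X-Progress": "1 of 2", "Retry-After": "3"}, b""),
            _HttpResponse(200, {}, self.MANIFEST),
        ])
        summary = client.export_download(tmp_path / "out")
        assert sleeps == [7.0, 3.0]
        assert summary.polls == 3

    def test_floor_used_when_header_absent_or_garbled(self, tmp_path):
        client, sleeps, _ = self._scripted_client([
            _HttpResponse(202, {"Content-Location": "http://fake/fhir/jobs/j1"}, b""),
            _HttpResponse(202, {}, b""),
            _HttpResponse(202, {"Retry-After": "soon"}, b""),
            _HttpResponse(200, {}, self.MANIFEST),
        ])
        client.export_download(tmp_path / "out")
        assert sleeps == [1.0, 1.0]

    def test_poll_timeout_raises_status_error(self, tmp_path):
        responses = [_HttpResponse(202, {"Content-Location": "http://fake/x"}, b"")]
        responses += [_HttpResponse(202, {"Retry-After": "400"}, b"")] * 3
        script = list(responses)
        now = [0.0]

        def transport(method, url, headers, data=None, timeout=30.0):
            return script.pop(0)

        client = BulkDataClient(
            "http://fake/fhir", transport=transport, poll_floor=1.0,
            poll_timeout=500,  # second 400s wait would overshoot the deadline
            sleep=lambda s: now.__setitem__(0, now[0] + s),
            clock=lambda: now[0])
        with pytest.raises(ProtocolError) as err:
            client.export_download(tmp_path / "out")
        assert err.value.stage == "status"
        assert "timeout" in str(err.value)


class TestStageDiagnostics:
    """Injected server faults surface as errors naming the right stage."""

    def _faulty_server(self, make_server, small_repo, stage):
        return make_server(small_repo, ServerConfig(
            requires_access_token=False,
            simulation=SimulationConfig(fault_stage=stage, fault_times=None)))

    def test_kickoff_fault(self, make_server, small_repo, tmp_path):
        server = self._faulty_server(make_server, small_repo, "kickoff")
        client = BulkDataClient(server.fhir_base_url, poll_floor=0.05)
        with pytest.raises(ProtocolError) as err:
            client.export_download(tmp_path / "out")
        assert err.value.stage == "kickoff"

    def test_status_fault_is_terminal(self, make_server, small_repo, tmp_path):
        server = self._faulty_server(make_server, small_repo, "status")
        client = BulkDataClient(server.fhir_base_url, poll_floor=0.05)
        with pytest.raises(ProtocolError) as err:
            client.export_download(tmp_path / "out")
        assert err.value.stage == "status"

    def test_file_fault_detected_with_line_number(self, make_server, small_repo,
                                                  tmp_path):
        server = self._faulty_server(make_server, small_repo, "file")
        client = BulkDataClient(server.fhir_base_url, poll_floor=0.05)
        with pytest.raises(ProtocolError) as err:
            client.export_download(tmp_path / "out")
        assert err.value.stage in ("download", "validation")
        assert "line" in str(err.value)

    def test_auth_fault_on_bad_credentials(self, make_server, small_repo, tmp_path,
                                           keypair, other_keypair,
                                           wildcard_registration):
        server = make_server(small_repo, ServerConfig(
            registrations=[wildcard_registration]))
        creds = ClientCredentials("analytics-app", other_keypair, server.token_url)
        client = BulkDataClient(server.fhir_base_url, creds, poll_floor=0.05)
        with pytest.raises(ProtocolError) as err:
            client.export_download(tmp_path / "out")
        assert err.value.stage == "auth"


class TestMalformedServers:
    """Any malformed server response becomes a ProtocolError, never a crash."""

    KICKOFF_OK = _HttpResponse(202, {"Content-Location": "http://fake/x"}, b"")

    @pytest.mark.parametrize(
        "responses, stage",
        [
            ([_HttpResponse(200, {}, b"")], "kickoff"),                # sync response
            ([_HttpResponse(202, {}, b"")], "kickoff"),                # no location
            ([KICKOFF_OK, _HttpResponse(200, {}, b"not json")], "status"),
            ([KICKOFF_OK, _HttpResponse(200, {}, b"[1,2]")], "status"),
            ([KICKOFF_OK, _HttpResponse(200, {}, b"{}")], "status"),   # fields missing
            ([KICKOFF_OK, _HttpResponse(200, {}, json.dumps({
                "transactionTime": "t", "request": "r", "requiresAccessToken": False,
                "output": [{"no": "type"}], "error": []}).encode())], "status"),
            ([KICKOFF_OK, _HttpResponse(200, {}, json.dumps({
                "transactionTime": "t", "request": "r", "requiresAccessToken": False,
                "output": [{"type": "Patient", "url": "f1", "count": 1}],
                "error": []}).encode()),
              _HttpResponse(404, {}, b"gone")], "download"),
            ([KICKOFF_OK, _HttpResponse(200, {}, json.dumps({
                "transactionTime": "t", "request": "r", "requiresAccessToken": False,
                "output": [{"type": "Patient", "url": "f1", "count": 1}],
                "error": []}).encode()),
              _HttpResponse(200, {"Content-Type": "text/plain"}, b"hi")], "download"),
            ([KICKOFF_OK, _HttpResponse(200, {}, json.dumps({
                "transactionTime": "t", "request": "r", "requiresAccessToken": False,
                "output": [{"type": "Patient", "url": "f1", "count": 5}],
                "error": []}).encode()),
              _HttpResponse(200, {"Content-Type": "application/fhir+ndjson"},
                            b'{"resourceType":"Patient","id":"p1",'
                            b'"meta":{"lastUpdated":"2020-01-01T00:00:00Z"}}\n')],
             "validation"),  # count mismatch
        ],
    )
    def test_garbage_yields_protocol_error(self, tmp_path, responses, stage):
        script = list(responses)

        def transport(method, url, headers, data=None, timeout=30.0):
            return script.pop(0)

        client = BulkDataClient("http://fake/fhir", transport=transport,
                                sleep=lambda s: None, poll_floor=0.01)
        with pytest.raises(ProtocolError) as err:
            client.export_download(tmp_path / "out")
        assert err.value.stage == stage

    def test_unreachable_server_is_transport_stage_error(self, tmp_path):
        client = BulkDataClient("http://127.0.0.1:9/fhir", request_timeout=0.5)
        with pytest.raises(ProtocolError) as err:
            client.export_download(tmp_path / "out")
        assert err.value.stage == "kickoff"


class TestCli:
    def test_export_success_writes_summary(self, make_server, small_repo, tmp_path):
        server = make_server(small_repo, ServerConfig(requires_access_token=False))
        dest = tmp_path / "out"
        result = CliRunner().invoke(cli_main, [
            "export", "--base-url", server.fhir_base_url,
            "--patient", "--type", "Patient,Condition", "--out", str(dest),
        ])
        assert result.exit_code == 0, result.output
        summary = json.loads((dest / "summary.json").read_text())
        want = brute_force_select(small_repo, "patient",
                                  type_filter={"Patient", "Condition"})
        assert summary["status"] == "complete"
        assert summary["totalResources"] == sum(want.values())
        assert "total resources" in result.output

    def test_export_with_auth_via_pem_key(self, make_server, small_repo, tmp_path,
                                          keypair, wildcard_registration):
        server = make_server(small_repo, ServerConfig(
            registrations=[wildcard_registration]))
        key_path = tmp_path / "client.pem"
        key_path.write_text(keypair.to_pem())
        result = CliRunner().invoke(cli_main, [
            "export", "--base-url", server.fhir_base_url,
            "--out", str(tmp_path / "out"),
            "--client-id", "analytics-app", "--key", str(key_path),
            "--token-url", server.token_url,
        ])
        assert result.exit_code == 0, result.output

    def test_fault_exits_nonzero_naming_stage(self, make_server, small_repo, tmp_path):
        server = make_server(small_repo, ServerConfig(
            requires_access_token=False,
            simulation=SimulationConfig(fault_stage="kickoff", fault_times=None)))
        result = CliRunner().invoke(cli_main, [
            "export", "--base-url", server.fhir_base_url, "--out", str(tmp_path / "o"),
        ])
        assert result.exit_code == 2
        assert "kickoff stage" in result.output

    def test_conflicting_level_flags_rejected(self):
        result = CliRunner().invoke(cli_main, [
            "export", "--base-url", "http://x/fhir", "--group", "g1", "--patient",
        ])
        assert result.exit_code != 0
        assert "exactly one" in result.output
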