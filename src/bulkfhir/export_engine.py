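"""Asynchronous bulk-export computation.

Implements the server side of the bulk-data workflow independent of any
HTTP framework: kickoff validation, resource selection and filtering,
partitioning into one-type-per-file NDJSON outputs, job lifecycle
(in-progress → complete/failed/cancelled, with a hosting deadline), the
completion manifest, and deterministic behavior simulation (artificial
latency and fault injection at the kickoff, status or file stage).

Selection semantics for a job:

    (level scope) ∩ (policy-group restriction) ∩ (type filter) ∩
    {r : r.last_updated > since}

where the level scope is all resources (system level), all Patients plus
clinical resources whose subject resolves (patient level), or a group's
Patients and their clinical resources (group level).  The ``_since``
comparison is strictly greater-than: a resource updated exactly at the
given instant is excluded.
"""
from __future__ import annotations

import logging
import secrets
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from random import Random
from typing import Callable, Mapping, Optional

from .fhir_core import (
    CLINICAL_RESOURCE_TYPES,
    NDJSON_MEDIA_TYPE,
    SUPPORTED_RESOURCE_TYPES,
    FhirResource,
    ResourceRepository,
    format_instant,
    ndjson_bytes,
    operation_outcome,
    parse_instant,
)

__all__ = [
    "SUPPORTED_OUTPUT_FORMATS",
    "ExportRequest",
    "ExportJob",
    "SimulationConfig",
    "KickoffError",
    "SimulatedFault",
    "PollInProgress",
    "PollComplete",
    "PollFailed",
    "PollTransientError",
    "PollUnknown",
    "ExportEngine",
    "parse_export_params",
]

logger = logging.getLogger("bulkfhir.export")

#: NDJSON is the only supported output; these labels are accepted aliases.
SUPPORTED_OUTPUT_FORMATS = ("application/fhir+ndjson", "application/ndjson", "ndjson")

DEFAULT_RETRY_AFTER = 1
DEFAULT_RETENTION = timedelta(minutes=60)


class KickoffError(Exception):
    """Kickoff request rejected; carries HTTP-equivalent status and an
    OperationOutcome body."""

    def __init__(self, status: int, diagnostics: str, code: str = "invalid"):
        super().__init__(diagnostics)
        self.status = status
        self.outcome = operation_outcome("error", code, diagnostics)


class SimulatedFault(Exception):
    """An injected fault fired at the configured stage."""

    def __init__(self, stage: str):
        super().__init__(f"simulated fault at {stage} stage")
        self.stage = stage
        self.outcome = operation_outcome("error", "exception", f"simulated {stage} failure")


@dataclass(frozen=True)
class SimulationConfig:
    """Behavior-simulation knobs: artificial latency and injected faults.

    ``fault_stage`` names where the fault manifests (``kickoff`` — the
    kickoff returns a server error; ``status`` — polls return a transient
    server error; ``file`` — downloads return a corrupt NDJSON line).
    ``fault_times`` limits how often it fires (``None`` = every time), so a
    status fault can return one error then recover.  Corruption position is
    chosen deterministically from ``seed``.
    """

    latency_seconds: float = 0.0
    fault_stage: Optional[str] = None
    fault_times: Optional[int] = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fault_stage not in (None, "kickoff", "status", "file"):
            raise ValueError(
                f"invalid fault stage {self.fault_stage!r}; expected kickoff, status or file"
            )
        if self.latency_seconds < 0:
            raise ValueError("latency_seconds must be nonnegative")


@dataclass(frozen=True)
class ExportRequest:
    """Validated parameters of one export."""

    level: str  # "patient" | "group" | "system"
    group_id: Optional[str] = None
    type_filter: Optional[frozenset[str]] = None
    since: Optional[datetime] = None
    output_format: Optional[str] = None
    policy_group: Optional[str] = None
    kickoff_url: str = ""

    def __post_init__(self) -> None:
        if self.level not in ("patient", "group", "system"):
            raise ValueError(f"invalid export level {self.level!r}")
        if (self.group_id is not None) != (self.level == "group"):
            raise ValueError("group_id is required exactly when level is 'group'")


@dataclass
class JobOutput:
    resource_type: str
    file_id: str
    count: int


@dataclass
class ExportJob:
    job_id: str
    request: ExportRequest
    state: str = "in_progress"  # in_progress | complete | failed | cancelled
    progress_done: int = 0
    progress_total: int = 0
    transaction_time: datetime = field(default_factory=lambda: datetime.now(timezone.utc))
    outputs: list[JobOutput] = field(default_factory=list)
    error_files: list[str] = field(default_factory=list)
    expires_at: Optional[datetime] = None

    @property
    def progress_text(self) -> str:
        return f"{self.progress_done} of {self.progress_total} resource types exported"


# --- poll results ----------------------------------------------------------

@dataclass(frozen=True)
class PollInProgress:
    progress_text: str
    retry_after: int


@dataclass(frozen=True)
class PollComplete:
    manifest: dict  # built once at completion; identical across polls
    expires_at: datetime


@dataclass(frozen=True)
class PollFailed:
    outcome: dict


@dataclass(frozen=True)
class PollTransientError:
    outcome: dict


@dataclass(frozen=True)
class PollUnknown:
    pass


def parse_export_params(params: Mapping[str, str],
                        supported_types: frozenset[str] = SUPPORTED_RESOURCE_TYPES
                        ) -> tuple[Optional[frozenset[str]], Optional[datetime], Optional[str]]:
    """Parse raw ``_type`` / ``_since`` / ``_outputFormat`` query parameters.

    ``_type`` is a comma-separated list of resource types.  Raises
    :class:`KickoffError` (422-equivalent) on an unparseable ``_since``, an
    unsupported type or output format, or the experimental ``_typeFilter``.
    """
    unknown = set(params) - {"_type", "_since", "_outputFormat", "_typeFilter"}
    if unknown:
        raise KickoffError(422, f"unsupported parameter(s): {sorted(unknown)}")
    if "_typeFilter" in params:
        raise KickoffError(422, "unsupported parameter: _typeFilter (experimental, not implemented)")
    type_filter: Optional[frozenset[str]] = None
    if "_type" in params:
        names = [t.strip() for t in params["_type"].split(",") if t.strip()]
        bad = [t for t in names if t not in supported_types]
        if bad:
            raise KickoffError(
                422,
                f"_type names unsupported resource type(s) {bad}; "
                f"supported types: {sorted(supported_types)}",
            )
        type_filter = frozenset(names)
    since: Optional[datetime] = None
    if "_since" in params:
        try:
            since = parse_instant(params["_since"])
        except ValueError as exc:
            raise KickoffError(422, f"unparseable _since: {exc}") from exc
    output_format: Optional[str] = None
    if "_outputFormat" in params:
        output_format = params["_outputFormat"]
        if output_format not in SUPPORTED_OUTPUT_FORMATS:
            raise KickoffError(
                422,
                f"unsupported _outputFormat {output_format!r}; "
                f"supported formats: {list(SUPPORTED_OUTPUT_FORMATS)}",
            )
    return type_filter, since, output_format


class ExportEngine:
    """Runs export jobs against an in-memory repository.

    ``file_url_builder(job_id, file_id)`` shapes the URLs written into
    manifests so the HTTP layer can host files under the FHIR base or a
    separate file host.
    """

    def __init__(
        self,
        repository: ResourceRepository,
        *,
        supported_types: frozenset[str] = SUPPORTED_RESOURCE_TYPES,
        retry_after: int = DEFAULT_RETRY_AFTER,
        retention: timedelta = DEFAULT_RETENTION,
        max_lines_per_file: Optional[int] = None,
        requires_access_token: bool = True,
        simulation: SimulationConfig = SimulationConfig(),
        file_url_builder: Optional[Callable[[str, str], str]] = None,
        clock: Callable[[], datetime] = lambda: datetime.now(timezone.utc),
    ):
        if max_lines_per_file is not None and max_lines_per_file < 1:
            raise ValueError("max_lines_per_file must be positive")
        self.repository = repository
        self.supported_types = supported_types
        self.retry_after = retry_after
        self.retention = retention
        self.max_lines_per_file = max_lines_per_file
        self.requires_access_token = requires_access_token
        self.simulation = simulation
        self.file_url_builder = file_url_builder or (
            lambda job_id, file_id: f"/jobs/{job_id}/files/{file_id}"
        )
        self.clock = clock
        self._jobs: dict[str, ExportJob] = {}
        self._files: dict[str, dict[str, bytes]] = {}  # job_id -> file_id -> bytes
        self._manifests: dict[str, dict] = {}
        self._fault_budget = simulation.fault_times
        self._fault_rng = Random(simulation.seed)

    # -- fault bookkeeping -------------------------------------------------

    def _fault_fires(self, stage: str) -> bool:
        if self.simulation.fault_stage != stage:
            return False
        if self._fault_budget is None:
            return True
        if self._fault_budget > 0:
            self._fault_budget -= 1
            return True
        return False

    # -- kickoff -----------------------------------------------------------

    def kickoff(self, request: ExportRequest, headers: Mapping[str, str]) -> ExportJob:
        """Validate a kickoff and create an in-progress job.

        ``headers`` is the incoming header map (names case-insensitive).
        Raises :class:`KickoffError` on validation failure or
        :class:`SimulatedFault` when a kickoff-stage fault is configured;
        neither creates a job.
        """
        lowered = {k.lower(): v for k, v in headers.items()}
        prefer = lowered.get("prefer", "")
        if "respond-async" not in [p.strip() for p in prefer.split(",")]:
            raise KickoffError(
                422, "kickoff requires the 'Prefer: respond-async' header", code="required"
            )
        if request.level == "group" and request.group_id not in self.repository.groups:
            raise KickoffError(404, f"no such group: {request.group_id!r}", code="not-found")
        if request.type_filter is not None:
            bad = request.type_filter - self.supported_types
            if bad:
                raise KickoffError(
                    422,
                    f"_type names unsupported resource type(s) {sorted(bad)}; "
                    f"supported types: {sorted(self.supported_types)}",
                )
        if request.output_format is not None and request.output_format not in SUPPORTED_OUTPUT_FORMATS:
            raise KickoffError(
                422,
                f"unsupported _outputFormat {request.output_format!r}; "
                f"supported formats: {list(SUPPORTED_OUTPUT_FORMATS)}",
            )
        if request.policy_group is not None and request.policy_group not in self.repository.groups:
            raise KickoffError(404, f"client policy group {request.policy_group!r} is unknown",
                               code="not-found")
        if self._fault_fires("kickoff"):
            raise SimulatedFault("kickoff")
        planned_types = request.type_filter or frozenset(self.repository.resource_types())
        job = ExportJob(
            job_id=secrets.token_urlsafe(24),
            request=request,
            transaction_time=self.clock(),
            progress_total=len(planned_types),
        )
        self._jobs[job.job_id] = job
        logger.info("job %s: kickoff level=%s", job.job_id, request.level)
        return job

    # -- selection ---------------------------------------------------------

    def _scope_patient_ids(self, request: ExportRequest) -> Optional[set[str]]:
        """Patient-id scope implied by level and policy group; None = unrestricted."""
        scope: Optional[set[str]] = None
        if request.level == "group":
            scope = set(self.repository.groups[request.group_id])
        if request.policy_group is not None:
            members = set(self.repository.groups[request.policy_group])
            scope = members if scope is None else scope & members
        return scope

    def select_resources(self, request: ExportRequest) -> list[FhirResource]:
        """Apply the selection predicate, preserving repository order."""
        scope = self._scope_patient_ids(request)
        patient_bound = request.level in ("patient", "group") or request.policy_group is not None
        selected = []
        for res in self.repository:
            if patient_bound:
                if res.resource_type == "Patient":
                    if scope is not None and res.id not in scope:
                        continue
                elif res.resource_type in CLINICAL_RESOURCE_TYPES and res.subject_ref:
                    pid = res.subject_ref.split("/", 1)[1]
                    if not self.repository.has_patient(pid):
                        continue
                    if scope is not None and pid not in scope:
                        continue
                else:
                    # patient-bounded exports carry only patient-linked data
                    continue
            if request.type_filter is not None and res.resource_type not in request.type_filter:
                continue
            if request.since is not None and not res.last_updated > request.since:
                continue
            selected.append(res)
        return selected

    # -- running -----------------------------------------------------------

    def run_job(self, job: ExportJob) -> ExportJob:
        """Execute an in-progress job to completion (or failure)."""
        if job.state != "in_progress":
            raise ValueError(f"job {job.job_id} is not in progress (state={job.state})")
        try:
            selected = self.select_resources(job.request)
            by_type: dict[str, list[FhirResource]] = {}
            for res in selected:
                by_type.setdefault(res.resource_type, []).append(res)
            job.progress_total = len(by_type)
            files = self._files.setdefault(job.job_id, {})
            for rtype in sorted(by_type):
                resources = by_type[rtype]
                chunk = self.max_lines_per_file or len(resources)
                for k in range(0, len(resources), max(chunk, 1)):
                    part = resources[k:k + chunk]
                    file_id = f"{rtype}.{k // max(chunk, 1) + 1:04d}.ndjson"
                    files[file_id] = ndjson_bytes(part)
                    job.outputs.append(JobOutput(rtype, file_id, len(part)))
                job.progress_done += 1
        except Exception as exc:  # pragma: no cover - exercised via injected failure
            logger.exception("job %s failed", job.job_id)
            files = self._files.setdefault(job.job_id, {})
            error_id = "error.0001.ndjson"
            outcome = operation_outcome("error", "exception", f"export failed: {exc}")
            files[error_id] = ndjson_bytes([_outcome_resource(outcome, self.clock())])
            job.outputs.clear()
            job.error_files.append(error_id)
            job.state = "failed"
            return job
        job.state = "complete"
        job.expires_at = self.clock() + self.retention
        self._manifests[job.job_id] = self._build_manifest(job)
        logger.info("job %s: complete, %d file(s)", job.job_id, len(job.outputs))
        return job

    def _build_manifest(self, job: ExportJob) -> dict:
        return {
            "transactionTime": format_instant(job.transaction_time),
            "request": job.request.kickoff_url,
            "requiresAccessToken": self.requires_access_token,
            "output": [
                {
                    "type": out.resource_type,
                    "url": self.file_url_builder(job.job_id, out.file_id),
                    "count": out.count,
                }
                for out in job.outputs
            ],
            "error": [
                {"type": "OperationOutcome", "url": self.file_url_builder(job.job_id, fid)}
                for fid in job.error_files
            ],
        }

    # -- polling -----------------------------------------------------------

    def poll(self, job_id: str, now: Optional[datetime] = None):
        """Return the job's status: progress, manifest, failure or unknown."""
        now = now or self.clock()
        job = self._jobs.get(job_id)
        if job is None or job.state == "cancelled":
            return PollUnknown()
        if job.state == "complete" and job.expires_at is not None and now > job.expires_at:
            return PollUnknown()
        if self._fault_fires("status"):
            return PollTransientError(SimulatedFault("status").outcome)
        if job.state == "in_progress":
            return PollInProgress(job.progress_text, self.retry_after)
        if job.state == "failed":
            return PollFailed(operation_outcome("error", "exception", "export job failed"))
        return PollComplete(self._manifests[job_id], job.expires_at)

    # -- files -------------------------------------------------------------

    def get_file(self, job_id: str, file_id: str,
                 now: Optional[datetime] = None) -> Optional[tuple[bytes, str]]:
        """Return (bytes, media type) for a hosted file, or None when the
        job/file is unknown, expired or cancelled.

        Access-token enforcement happens in the transport layer; a
        configured file-stage fault corrupts one deterministic line.
        """
        now = now or self.clock()
        job = self._jobs.get(job_id)
        if job is None or job.state not in ("complete", "failed"):
            return None
        if job.expires_at is not None and now > job.expires_at:
            return None
        data = self._files.get(job_id, {}).get(file_id)
        if data is None:
            return None
        if self._fault_fires("file"):
            data = self.corrupt_ndjson(data, self.simulation.seed)
        return data, NDJSON_MEDIA_TYPE

    @staticmethod
    def corrupt_ndjson(data: bytes, seed: int) -> bytes:
        """Mangle one line (chosen by ``seed``) into invalid JSON."""
        lines = data.split(b"\n")
        body = [i for i, ln in enumerate(lines) if ln]
        if not body:
            return data
        idx = Random(seed).choice(body)
        lines[idx] = b"{corrupt " + lines[idx][1:]
        return b"\n".join(lines)

    # -- cancellation ------------------------------------------------------

    def cancel_job(self, job_id: str) -> bool:
        """Cancel and forget a job; returns False when unknown."""
        job = self._jobs.pop(job_id, None)
        if job is None:
            return False
        self._files.pop(job_id, None)
        self._manifests.pop(job_id, None)
        logger.info("job %s: cancelled", job_id)
        return True

    def get_job(self, job_id: str) -> Optional[ExportJob]:
        return self._jobs.get(job_id)

    def with_simulation(self, simulation: SimulationConfig) -> "ExportEngine":
        """Return a new engine over the same repository with the given
        behavior simulation (zero-fault config reproduces this engine's
        behavior exactly)."""
        return ExportEngine(
            self.repository,
            supported_types=self.supported_types,
            retry_after=self.retry_after,
            retention=self.retention,
            max_lines_per_file=self.max_lines_per_file,
            requires_access_token=self.requires_access_token,
            simulation=simulation,
            file_url_builder=self.file_url_builder,
            clock=self.clock,
        )


def _outcome_resource(outcome: dict, now: datetime) -> FhirResource:
    content = {k: v for k, v in outcome.items() if k not in ("resourceType", "id")}
    return FhirResource(
        resource_type="OperationOutcome",
        id="export-error",
        last_updated=now,
        content=content,
    )
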