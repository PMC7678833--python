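"""Minimal FHIR resource model and NDJSON ("flat FHIR") serialization.

Bulk exports deliver resources as newline-delimited JSON: one complete JSON
object per line, one resource type per file.  This module holds the
per-resource unit of those files, the in-memory repository the export server
reads from, and the NDJSON reader/writer shared by server, client and the
synthetic-population generator.

The model is deliberately schema-agnostic: beyond ``resourceType``, ``id``,
``meta.lastUpdated`` and (for clinical resources) the patient reference,
every field is carried verbatim in a content tree.  Profile-level validation
(US Core / USCDI) is out of scope; transport and format are what is modelled.
"""
from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import BinaryIO, Iterable, Iterator, Mapping, Optional

__all__ = [
    "SUPPORTED_RESOURCE_TYPES",
    "CLINICAL_RESOURCE_TYPES",
    "FhirResource",
    "ResourceRepository",
    "NdjsonError",
    "LayoutViolationError",
    "SerializationError",
    "NdjsonParseError",
    "parse_instant",
    "format_instant",
    "write_ndjson",
    "read_ndjson",
    "validate_resource",
]

#: Closed set of resource types the toolkit handles.  Configurable at the
#: call sites that accept a ``supported_types`` argument; this is the default.
SUPPORTED_RESOURCE_TYPES = frozenset(
    {"Patient", "Group", "Observation", "Condition", "Encounter", "OperationOutcome"}
)

#: Types that reference a patient via ``subject``.
CLINICAL_RESOURCE_TYPES = frozenset({"Observation", "Condition", "Encounter"})

NDJSON_MEDIA_TYPE = "application/fhir+ndjson"


class NdjsonError(Exception):
    """Base class for NDJSON layout/serialization problems."""


class LayoutViolationError(NdjsonError):
    """A single NDJSON file may contain only one resource type."""


class SerializationError(NdjsonError):
    """A resource's content tree could not be rendered as JSON."""


class NdjsonParseError(NdjsonError):
    """A line of an NDJSON stream is not a valid resource.

    Carries the 1-based line number of the offending line.
    """

    def __init__(self, line_number: int, message: str):
        super().__init__(f"line {line_number}: {message}")
        self.line_number = line_number


def parse_instant(value: str) -> datetime:
    """Parse an RFC3339 instant into a timezone-aware datetime.

    FHIR instants always carry an explicit offset (``Z`` or ``+hh:mm``);
    naive timestamps are rejected because ``_since`` comparisons must be
    totally ordered.
    """
    if not isinstance(value, str) or not value:
        raise ValueError(f"not an instant: {value!r}")
    text = value[:-1] + "+00:00" if value.endswith("Z") else value
    try:
        parsed = datetime.fromisoformat(text)
    except ValueError as exc:
        raise ValueError(f"not an RFC3339 instant: {value!r}") from exc
    if parsed.tzinfo is None:
        raise ValueError(f"instant lacks a timezone offset: {value!r}")
    return parsed


def format_instant(value: datetime) -> str:
    """Serialize a timezone-aware datetime as an RFC3339 instant."""
    if value.tzinfo is None:
        raise ValueError("instant must be timezone-aware")
    return value.astimezone(timezone.utc).isoformat().replace("+00:00", "Z")


@dataclass(frozen=True)
class FhirResource:
    """One FHIR resource instance.

    Parameters
    ----------
    resource_type:
        Name from the supported set (``Patient``, ``Observation`` ...).
    id:
        Identifier, unique within its type.
    last_updated:
        The resource's ``meta.lastUpdated`` instant (timezone-aware).
    subject_ref:
        Optional ``"Patient/<id>"`` reference for clinical resources.
    content:
        All remaining fields, preserved verbatim (pass-through).
    """

    resource_type: str
    id: str
    last_updated: datetime
    subject_ref: Optional[str] = None
    content: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.resource_type:
            raise ValueError("resource_type must be nonempty")
        if not self.id:
            raise ValueError("id must be nonempty")
        if self.last_updated.tzinfo is None:
            raise ValueError("last_updated must be timezone-aware")

    @property
    def key(self) -> tuple[str, str]:
        return (self.resource_type, self.id)

    def to_json_dict(self) -> dict:
        """Render the resource as a plain FHIR JSON object."""
        obj: dict = {"resourceType": self.resource_type, "id": self.id}
        content = dict(self.content)
        meta = dict(content.pop("meta", {}) or {})
        meta["lastUpdated"] = format_instant(self.last_updated)
        obj["meta"] = meta
        if self.subject_ref is not None:
            subject = dict(content.pop("subject", {}) or {})
            subject["reference"] = self.subject_ref
            obj["subject"] = subject
        obj.update(content)
        return obj

    @classmethod
    def from_json_dict(cls, obj: Mapping[str, object]) -> "FhirResource":
        """Build a resource from a parsed FHIR JSON object.

        Raises ``ValueError`` when ``resourceType``/``id`` are missing or the
        ``meta.lastUpdated`` instant does not parse.
        """
        if not isinstance(obj, Mapping):
            raise ValueError("resource must be a JSON object")
        rtype = obj.get("resourceType")
        rid = obj.get("id")
        if not rtype or not isinstance(rtype, str):
            raise ValueError("missing resourceType")
        if not rid or not isinstance(rid, str):
            raise ValueError("missing id")
        content = {k: v for k, v in obj.items() if k not in ("resourceType", "id")}
        meta = content.get("meta") or {}
        updated_raw = meta.get("lastUpdated") if isinstance(meta, Mapping) else None
        if updated_raw is None:
            raise ValueError("missing meta.lastUpdated")
        last_updated = parse_instant(updated_raw)
        # strip lastUpdated from the retained meta so round-trips are stable
        meta = {k: v for k, v in meta.items() if k != "lastUpdated"}
        if meta:
            content["meta"] = meta
        else:
            content.pop("meta", None)
        subject_ref = None
        subject = content.get("subject")
        if isinstance(subject, Mapping) and isinstance(subject.get("reference"), str):
            subject_ref = subject["reference"]
            subject = {k: v for k, v in subject.items() if k != "reference"}
            if subject:
                content["subject"] = subject
            else:
                content.pop("subject", None)
        return cls(
            resource_type=rtype,
            id=rid,
            last_updated=last_updated,
            subject_ref=subject_ref,
            content=content,
        )

    def with_content(self, **content: object) -> "FhirResource":
        merged = dict(self.content)
        merged.update(content)
        return replace(self, content=merged)


def operation_outcome(severity: str, code: str, diagnostics: str) -> dict:
    """Build a FHIR OperationOutcome JSON object for an error or warning."""
    return {
        "resourceType": "OperationOutcome",
        "issue": [
            {"severity": severity, "code": code, "diagnostics": diagnostics}
        ],
    }


class ResourceRepository:
    """In-memory store of resources plus group rosters.

    Invariants: no duplicate ``(resource_type, id)`` pairs; every group
    member id names an existing Patient.
    """

    def __init__(
        self,
        resources: Iterable[FhirResource] = (),
        groups: Optional[Mapping[str, Iterable[str]]] = None,
    ):
        self._by_key: dict[tuple[str, str], FhirResource] = {}
        self._order: list[FhirResource] = []
        for res in resources:
            self.add(res)
        self.groups: dict[str, set[str]] = {}
        for gid, members in (groups or {}).items():
            self.set_group(gid, members)

    def add(self, resource: FhirResource) -> None:
        if resource.key in self._by_key:
            raise ValueError(f"duplicate resource {resource.key}")
        self._by_key[resource.key] = resource
        self._order.append(resource)

    def set_group(self, group_id: str, member_ids: Iterable[str]) -> None:
        members = set(member_ids)
        missing = [m for m in members if ("Patient", m) not in self._by_key]
        if missing:
            raise ValueError(
                f"group {group_id!r} names unknown patients: {sorted(missing)}"
            )
        self.groups[group_id] = members

    def __len__(self) -> int:
        return len(self._order)

    def __iter__(self) -> Iterator[FhirResource]:
        return iter(self._order)

    def get(self, resource_type: str, rid: str) -> Optional[FhirResource]:
        return self._by_key.get((resource_type, rid))

    def has_patient(self, patient_id: str) -> bool:
        return ("Patient", patient_id) in self._by_key

    def of_type(self, resource_type: str) -> list[FhirResource]:
        return [r for r in self._order if r.resource_type == resource_type]

    def resource_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self._order:
            seen.setdefault(r.resource_type, None)
        return list(seen)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResourceRepository):
            return NotImplemented
        # insertion order is preserved for iteration but is not identity
        return self._by_key == other._by_key and self.groups == other.groups


def write_ndjson(resources: Iterable[FhirResource], sink: BinaryIO) -> int:
    """Write resources as UTF-8 NDJSON, one JSON object per line.

    All resources must share one resource type (flat-FHIR layout).  Returns
    the number of lines written.
    """
    count = 0
    expected_type: Optional[str] = None
    for res in resources:
        if expected_type is None:
            expected_type = res.resource_type
        elif res.resource_type != expected_type:
            raise LayoutViolationError(
                f"mixed resource types in one file: {expected_type} and "
                f"{res.resource_type}"
            )
        try:
            line = json.dumps(
                res.to_json_dict(), separators=(",", ":"), ensure_ascii=False
            )
        except (TypeError, ValueError) as exc:
            raise SerializationError(
                f"resource {res.resource_type}/{res.id} is not serializable: {exc}"
            ) from exc
        sink.write(line.encode("utf-8"))
        sink.write(b"\n")
        count += 1
    return count


def ndjson_bytes(resources: Iterable[FhirResource]) -> bytes:
    """Convenience wrapper returning the NDJSON file content as bytes."""
    buf = io.BytesIO()
    write_ndjson(resources, buf)
    return buf.getvalue()


def read_ndjson(source: BinaryIO | bytes) -> list[FhirResource]:
    """Parse an NDJSON stream into resources, order preserved.

    Blank lines are tolerated.  A malformed line raises
    :class:`NdjsonParseError` carrying its 1-based line number.
    """
    if isinstance(source, (bytes, bytearray)):
        source = io.BytesIO(source)
    out: list[FhirResource] = []
    for lineno, raw in enumerate(source, start=1):
        try:
            text = raw.decode("utf-8").strip()
        except UnicodeDecodeError as exc:
            raise NdjsonParseError(lineno, f"line is not valid UTF-8 ({exc})") from exc
        if not text:
            continue
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise NdjsonParseError(lineno, f"invalid JSON ({exc.msg})") from exc
        try:
            out.append(FhirResource.from_json_dict(obj))
        except ValueError as exc:
            raise NdjsonParseError(lineno, str(exc)) from exc
    return out


def validate_resource(
    resource: FhirResource | Mapping[str, object],
    repository: Optional[ResourceRepository] = None,
) -> list[str]:
    """Return a list of issue descriptions (empty when valid).

    Accepts either a constructed :class:`FhirResource` or a raw parsed JSON
    object (useful for vetting untrusted input before construction).  Checks:
    type present and in the supported set, nonempty id, parseable last-updated
    instant, and — when a repository is given — that a ``subject_ref``
    resolves to an existing Patient.  Issues are returned, never raised.
    """
    issues: list[str] = []
    if isinstance(resource, FhirResource):
        rtype: object = resource.resource_type
        rid: object = resource.id
        subject_ref: object = resource.subject_ref
        try:
            parse_instant(format_instant(resource.last_updated))
        except ValueError as exc:
            issues.append(f"unparseable last-updated instant: {exc}")
    else:
        rtype = resource.get("resourceType")
        rid = resource.get("id")
        meta = resource.get("meta")
        updated = meta.get("lastUpdated") if isinstance(meta, Mapping) else None
        try:
            parse_instant(updated)  # type: ignore[arg-type]
        except (ValueError, TypeError) as exc:
            issues.append(f"unparseable last-updated instant: {exc}")
        subject = resource.get("subject")
        subject_ref = subject.get("reference") if isinstance(subject, Mapping) else None
    if not rtype or not isinstance(rtype, str):
        issues.append("missing resourceType")
    elif rtype not in SUPPORTED_RESOURCE_TYPES:
        issues.append(f"unsupported resource type {rtype!r}")
    if not rid or not isinstance(rid, str):
        issues.append("missing or empty id")
    if subject_ref is not None:
        if not isinstance(subject_ref, str) or not subject_ref.startswith("Patient/"):
            issues.append(f"subject reference {subject_ref!r} is not a Patient reference")
        elif repository is not None:
            pid = subject_ref.split("/", 1)[1]
            if not repository.has_patient(pid):
                issues.append(f"dangling subject reference {subject_ref!r}")
    return issues
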