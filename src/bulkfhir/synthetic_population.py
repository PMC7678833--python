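"""Seeded synthetic EHR population generator.

Produces a deterministic multi-patient FHIR repository — Patients, group
rosters, and clinical resources (Observations, Conditions, Encounters) with
referential links and last-updated instants — so the whole bulk-export
protocol can be exercised with no external data.

Determinism contract: an identical :class:`PopulationConfig` (including the
seed) yields a byte-identical repository.  Ids are seeded counters
(``pat-000017``) rather than UUIDs so fixtures are stable and diffable.
Demographics are minimal plausible filler; clinical realism is a non-goal —
the protocol, not the medicine, is under test.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from pathlib import Path
from random import Random
from typing import Mapping

from .fhir_core import (
    CLINICAL_RESOURCE_TYPES,
    FhirResource,
    ResourceRepository,
    ndjson_bytes,
    read_ndjson,
)

__all__ = [
    "PopulationConfig",
    "ConfigurationError",
    "generate",
    "count_stream",
    "poisson_draw",
    "export_fixture",
    "load_fixture",
]

_ID_PREFIX = {
    "Patient": "pat",
    "Observation": "obs",
    "Condition": "con",
    "Encounter": "enc",
}

_GIVEN_NAMES = [
    "Alex", "Sam", "Jordan", "Taylor", "Morgan", "Casey", "Riley", "Avery",
    "Quinn", "Rowan", "Jamie", "Drew", "Skyler", "Reese", "Emerson", "Finley",
]
_FAMILY_NAMES = [
    "Smith", "Garcia", "Chen", "Patel", "Okafor", "Nguyen", "Kim", "Silva",
    "Mueller", "Rossi", "Kowalski", "Haddad", "Johnson", "Brown", "Lopez", "Sato",
]

_OBSERVATION_CODES = [
    ("8867-4", "Heart rate"),
    ("8480-6", "Systolic blood pressure"),
    ("2339-0", "Glucose"),
    ("718-7", "Hemoglobin"),
]
_CONDITION_CODES = [
    ("44054006", "Type 2 diabetes mellitus"),
    ("38341003", "Hypertensive disorder"),
    ("195967001", "Asthma"),
    ("13645005", "COPD"),
]
_ENCOUNTER_CLASSES = ["AMB", "EMER", "IMP"]


@dataclass(frozen=True)
class PopulationConfig:
    """Knobs of the generator.

    ``resources_per_patient`` maps a clinical resource type to the mean count
    per patient; actual counts are independent Poisson draws around the mean.
    ``group_fill`` is the fraction of patients assigned to each group (drawn
    without replacement).  Last-updated instants are uniform over
    ``time_window``.
    """

    n_patients: int = 100
    resources_per_patient: Mapping[str, float] = field(
        default_factory=lambda: {"Observation": 5.0, "Condition": 2.0, "Encounter": 3.0}
    )
    n_groups: int = 2
    group_fill: float = 0.3
    time_window: tuple[datetime, datetime] = (
        datetime(2019, 1, 1, tzinfo=timezone.utc),
        datetime(2020, 1, 1, tzinfo=timezone.utc),
    )
    seed: int = 0


class ConfigurationError(ValueError):
    """Invalid generator configuration; names the offending field."""

    def __init__(self, fieldname: str, message: str):
        super().__init__(f"{fieldname}: {message}")
        self.fieldname = fieldname


def _validate(config: PopulationConfig) -> None:
    if config.n_patients < 0:
        raise ConfigurationError("n_patients", "must be nonnegative")
    if config.n_groups < 0:
        raise ConfigurationError("n_groups", "must be nonnegative")
    if not (0.0 <= config.group_fill <= 1.0):
        raise ConfigurationError("group_fill", "must lie in [0, 1]")
    for rtype, mean in config.resources_per_patient.items():
        if rtype not in CLINICAL_RESOURCE_TYPES:
            raise ConfigurationError(
                "resources_per_patient", f"{rtype!r} is not a clinical resource type"
            )
        if mean < 0:
            raise ConfigurationError("resources_per_patient", f"mean for {rtype} is negative")
    start, end = config.time_window
    if start.tzinfo is None or end.tzinfo is None:
        raise ConfigurationError("time_window", "instants must be timezone-aware")
    if not start < end:
        raise ConfigurationError("time_window", "start must precede end")


def poisson_draw(rng: Random, mean: float) -> int:
    """Poisson draw via Knuth's product-of-uniforms method.

    Adequate for the per-patient means used here (exponential underflow would
    only bite for means far beyond a plausible per-patient resource count).
    """
    if mean <= 0:
        return 0
    import math

    threshold = math.exp(-mean)
    k, product = 0, rng.random()
    while product > threshold:
        k += 1
        product *= rng.random()
    return k


def _draw_instant(rng: Random, start: datetime, end: datetime) -> datetime:
    span = (end - start).total_seconds()
    offset = rng.random() * span
    # whole seconds keep serialized instants short and comparisons unambiguous
    return (start + timedelta(seconds=int(offset))).astimezone(timezone.utc)


def count_stream(seed: int) -> Random:
    """The dedicated RNG stream from which per-patient resource counts are
    drawn: one Poisson draw per (patient, clinical type), patients in id
    order, types in sorted order.  Exposed so the counts are independently
    reproducible."""
    return Random(f"{seed}/counts")


def generate(config: PopulationConfig = PopulationConfig()) -> ResourceRepository:
    """Generate a synthetic repository from a validated config.

    Determinism contract: every random quantity comes from a named stream
    seeded from ``config.seed`` — demographics/content, per-patient counts
    (see :func:`count_stream`), last-updated instants, and group rosters —
    each with a fixed draw order, so identical configs yield identical
    repositories and each stream can be replayed on its own.
    """
    _validate(config)
    rng = Random(f"{config.seed}/content")
    counts_rng = count_stream(config.seed)
    time_rng = Random(f"{config.seed}/instants")
    group_rng = Random(f"{config.seed}/groups")
    start, end = config.time_window
    repo = ResourceRepository()

    counters = {rtype: 0 for rtype in _ID_PREFIX}

    def next_id(rtype: str) -> str:
        counters[rtype] += 1
        return f"{_ID_PREFIX[rtype]}-{counters[rtype]:06d}"

    patient_ids: list[str] = []
    for _ in range(config.n_patients):
        pid = next_id("Patient")
        patient_ids.append(pid)
        given = rng.choice(_GIVEN_NAMES)
        family = rng.choice(_FAMILY_NAMES)
        birth_year = rng.randint(1930, 2015)
        content = {
            "name": [{"given": [given], "family": family}],
            "gender": rng.choice(["female", "male", "other", "unknown"]),
            "birthDate": f"{birth_year:04d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}",
        }
        repo.add(
            FhirResource(
                resource_type="Patient",
                id=pid,
                last_updated=_draw_instant(time_rng, start, end),
                content=content,
            )
        )
        for rtype in sorted(config.resources_per_patient):
            count = poisson_draw(counts_rng, config.resources_per_patient[rtype])
            for _ in range(count):
                repo.add(_clinical_resource(rng, time_rng, rtype, next_id(rtype), pid, start, end))

    member_count = round(config.group_fill * config.n_patients)
    groups: dict[str, set[str]] = {}
    for g in range(config.n_groups):
        gid = f"grp-{g + 1:03d}"
        groups[gid] = set(group_rng.sample(patient_ids, member_count)) if member_count else set()
    for gid, members in groups.items():
        repo.set_group(gid, members)
    return repo


def _clinical_resource(
    rng: Random, time_rng: Random, rtype: str, rid: str, patient_id: str,
    start: datetime, end: datetime
) -> FhirResource:
    content: dict[str, object]
    if rtype == "Observation":
        code, display = rng.choice(_OBSERVATION_CODES)
        content = {
            "status": "final",
            "code": {"coding": [{"system": "http://loinc.org", "code": code, "display": display}]},
            "valueQuantity": {"value": round(rng.uniform(1, 200), 1)},
        }
    elif rtype == "Condition":
        code, display = rng.choice(_CONDITION_CODES)
        content = {
            "code": {"coding": [{"system": "http://snomed.info/sct", "code": code, "display": display}]},
            "clinicalStatus": {"coding": [{"code": rng.choice(["active", "resolved"])}]},
        }
    else:  # Encounter
        content = {
            "status": "finished",
            "class": {"code": rng.choice(_ENCOUNTER_CLASSES)},
        }
    return FhirResource(
        resource_type=rtype,
        id=rid,
        last_updated=_draw_instant(time_rng, start, end),
        subject_ref=f"Patient/{patient_id}",
        content=content,
    )


def export_fixture(repository: ResourceRepository, directory: str | Path) -> list[Path]:
    """Write the repository as NDJSON fixture files plus a groups sidecar.

    One ``<ResourceType>.ndjson`` per type present and a ``groups.json``
    object mapping group id to a sorted array of member patient ids.
    Returns the list of files written.
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for rtype in repository.resource_types():
            path = directory / f"{rtype}.ndjson"
            path.write_bytes(ndjson_bytes(repository.of_type(rtype)))
            written.append(path)
        sidecar = directory / "groups.json"
        sidecar.write_text(
            json.dumps(
                {gid: sorted(members) for gid, members in sorted(repository.groups.items())},
                indent=2,
            )
            + "\n"
        )
        written.append(sidecar)
        return written
    except OSError as exc:
        raise OSError(f"cannot write fixture under {directory}: {exc}") from exc


def load_fixture(directory: str | Path) -> ResourceRepository:
    """Load a fixture directory written by :func:`export_fixture`."""
    directory = Path(directory)
    resources: list[FhirResource] = []
    for path in sorted(directory.glob("*.ndjson")):
        resources.extend(read_ndjson(path.read_bytes()))
    groups: dict[str, list[str]] = {}
    sidecar = directory / "groups.json"
    if sidecar.exists():
        groups = json.loads(sidecar.read_text())
    return ResourceRepository(resources, groups)
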