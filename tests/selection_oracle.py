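"""Brute-force export-selection oracle for tests.

Applies the selection predicate naively, resource by resource, with no
shared code or data structures from the engine's set-based implementation.
Returns the multiset of (resourceType, id) keys the export should contain.
"""
from collections import Counter

CLINICAL = {"Observation", "Condition", "Encounter"}


def brute_force_select(repo, level, group_id=None, type_filter=None,
                       since=None, policy_group=None):
    members = set(repo.groups[group_id]) if level == "group" else None
    policy_members = set(repo.groups[policy_group]) if policy_group is not None else None
    patient_ids = {r.id for r in repo if r.resource_type == "Patient"}
    selected = Counter()
    for r in repo:
        # level scope
        if level == "system" and policy_members is None:
            in_scope = True
        else:
            if r.resource_type == "Patient":
                pid = r.id
            elif r.resource_type in CLINICAL and r.subject_ref:
                pid = r.subject_ref.split("/", 1)[1]
                if pid not in patient_ids:
                    continue
            else:
                continue
            in_scope = True
            if members is not None and pid not in members:
                in_scope = False
            if policy_members is not None and pid not in policy_members:
                in_scope = False
        if not in_scope:
            continue
        if type_filter is not None and r.resource_type not in type_filter:
            continue
        if since is not None and not (r.last_updated > since):
            continue
        selected[(r.resource_type, r.id)] += 1
    return selected
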