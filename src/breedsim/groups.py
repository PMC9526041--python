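"""Group creation, splitting, merging, inspection, and deletion.

Groups are the unit of every crossing and selection operation; scripting a
breeding program is mostly moving records between groups.  Membership always
partitions the live records; empty groups are dropped, and a handle is valid
only while at least one live record carries it.  Member order within a group
is creation order, so all data extraction is reproducible.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence, Union

import numpy as np

from .genome import GroupHandle, PopulationStore
from .quantgen import breeding_values

__all__ = [
    "make_group",
    "combine_groups",
    "break_into_families",
    "break_into_halfsib_families",
    "split_randomly",
    "see_group_data",
    "delete_groups",
]


def make_group(indices: Sequence[int], store: PopulationStore) -> GroupHandle:
    """Move the listed records into a fresh group (their old groups shrink)."""
    if not indices:
        raise ValueError("cannot make a group from an empty index list")
    for rid in indices:
        store.get(rid)  # validate before mutating anything
    handle = store.new_group_handle()
    store.move_records(indices, handle)
    return handle


def combine_groups(handles: Sequence[GroupHandle], store: PopulationStore) -> GroupHandle:
    """Merge groups into one; size is the sum of the input sizes."""
    ids: List[int] = []
    for h in handles:
        ids.extend(store.members(h))
    handle = store.new_group_handle()
    store.move_records(ids, handle)
    return handle


def _family_key(store: PopulationStore, rid: int):
    rec = store.get(rid)
    if rec.parent1_id is None and rec.parent2_id is None:
        return None  # founders form their own class
    return tuple(sorted((rec.parent1_id, rec.parent2_id)))


def break_into_families(group: GroupHandle, store: PopulationStore) -> List[GroupHandle]:
    """Split into full-sib families: one group per distinct unordered parent pair."""
    members = store.members(group)
    buckets: dict = {}
    for rid in members:
        buckets.setdefault(_family_key(store, rid), []).append(rid)
    out = []
    for key in buckets:  # insertion order = first-appearance order
        handle = store.new_group_handle()
        store.move_records(buckets[key], handle)
        out.append(handle)
    return out


def break_into_halfsib_families(
    group: GroupHandle, which_parent: int, store: PopulationStore
) -> List[GroupHandle]:
    """Split by the parent in slot 1 or 2 (the model has no male/female roles,
    so the caller chooses the slot)."""
    if which_parent not in (1, 2):
        raise ValueError("which_parent must be 1 or 2")
    members = store.members(group)
    buckets: dict = {}
    for rid in members:
        rec = store.get(rid)
        key = rec.parent1_id if which_parent == 1 else rec.parent2_id
        buckets.setdefault(key, []).append(rid)
    out = []
    for key in buckets:
        handle = store.new_group_handle()
        store.move_records(buckets[key], handle)
        out.append(handle)
    return out


def split_randomly(
    group: GroupHandle,
    store: PopulationStore,
    rng: np.random.Generator,
    n_subgroups: int = None,
    sizes: Sequence[int] = None,
) -> List[GroupHandle]:
    """Randomly partition a group.

    With ``sizes``, moves disjoint random subgroups of the requested sizes
    out of the group; any remainder stays behind.  With ``n_subgroups``, the
    whole group is split as evenly as possible.
    """
    if (n_subgroups is None) == (sizes is None):
        raise ValueError("give exactly one of n_subgroups or sizes")
    members = store.members(group)
    if n_subgroups is not None:
        if n_subgroups < 1:
            raise ValueError("n_subgroups must be >= 1")
        base, extra = divmod(len(members), n_subgroups)
        sizes = [base + (1 if i < extra else 0) for i in range(n_subgroups)]
    sizes = list(sizes)
    if any(s < 0 for s in sizes):
        raise ValueError("subgroup sizes must be >= 0")
    if sum(sizes) > len(members):
        raise ValueError(
            f"requested sizes sum to {sum(sizes)} but the group has {len(members)} members"
        )
    perm = rng.permutation(len(members))
    out, at = [], 0
    for size in sizes:
        chosen = [members[i] for i in perm[at : at + size]]
        at += size
        handle = store.new_group_handle()
        store.move_records(chosen, handle)
        out.append(handle)
    return out


_FIELDS = ("indices", "names", "breeding_values", "allele_strings", "parent1", "parent2", "pedigree")


def see_group_data(group: GroupHandle, field: str, store: PopulationStore) -> list:
    """One value per member in stable member order.

    Fields: indices, names, breeding_values, allele_strings, parent1,
    parent2, pedigree.
    """
    if field not in _FIELDS:
        raise ValueError(f"unknown field {field!r}; expected one of {_FIELDS}")
    ids = store.members(group)
    if field == "indices":
        return list(ids)
    if field == "breeding_values":
        return list(breeding_values(store, group))
    recs = [store.get(i) for i in ids]
    if field == "names":
        return [r.name for r in recs]
    if field == "allele_strings":
        return [r.allele_string() for r in recs]
    if field == "parent1":
        return [r.parent1_id for r in recs]
    if field == "parent2":
        return [r.parent2_id for r in recs]
    return [f"{r.name}=({r.parent1_id},{r.parent2_id})" for r in recs]


def delete_groups(handles: Union[GroupHandle, Iterable[GroupHandle]], store: PopulationStore) -> None:
    """Destroy groups and their member records; record ids are never reused."""
    if isinstance(handles, int):
        handles = [handles]
    all_ids: List[int] = []
    for h in handles:
        all_ids.extend(store.members(h))
    store.delete_records(all_ids)
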