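"""Offspring-producing operations: targeted, random and exhaustive crosses,
selfing by single-seed descent, and doubled haploids.

Every operation draws gametes from the count-location meiosis engine and
places its offspring in a fresh group.  No distinction is made between male
and female parents; the stored parent order is the call order.  Offspring
names are auto-generated as ``<op-prefix><record id>`` (cx/sf/dh), which is
stable under a fixed seed.
"""

from __future__ import annotations

from typing import List, Sequence, Tuple

import numpy as np

from .genome import GenotypeRecord, GroupHandle, PopulationStore
from .meiosis import generate_gamete

__all__ = [
    "cross",
    "cross_randomly",
    "cross_combinations",
    "cross_all_pairs",
    "self_n_times",
    "make_doubled_haploids",
]


def _make_offspring(
    store: PopulationStore,
    parent1: GenotypeRecord,
    parent2: GenotypeRecord,
    group: GroupHandle,
    rng: np.random.Generator,
    prefix: str = "cx",
) -> GenotypeRecord:
    hap1 = generate_gamete(parent1, store.map, rng)
    hap2 = generate_gamete(parent2, store.map, rng)
    rec = store.add_record("", hap1, hap2, group, parent1.id, parent2.id)
    rec.name = f"{prefix}{rec.id}"
    return rec


def cross(
    parent1_id: int,
    parent2_id: int,
    store: PopulationStore,
    rng: np.random.Generator,
    group: GroupHandle = None,
) -> GenotypeRecord:
    """One offspring from two live parents: hap1 from parent1, hap2 from parent2."""
    p1, p2 = store.get(parent1_id), store.get(parent2_id)
    if group is None:
        group = store.new_group_handle()
    return _make_offspring(store, p1, p2, group, rng)


def cross_randomly(
    group: GroupHandle,
    n_crosses: int,
    offspring_per_cross: int,
    store: PopulationStore,
    rng: np.random.Generator,
) -> GroupHandle:
    """Random crosses within a group; result size = n_crosses * offspring_per_cross.

    Both parents of each cross are drawn uniformly with replacement, redrawing
    whenever the same individual comes up twice — crossing never selfs
    (selfing is its own operation).
    """
    members = store.members(group)
    if len(members) < 2:
        raise ValueError("random crossing needs a group of >= 2 members")
    if n_crosses < 1 or offspring_per_cross < 1:
        raise ValueError("n_crosses and offspring_per_cross must be >= 1")
    out = store.new_group_handle()
    for _ in range(n_crosses):
        i = int(rng.integers(len(members)))
        j = int(rng.integers(len(members)))
        while j == i:
            j = int(rng.integers(len(members)))
        p1, p2 = store.get(members[i]), store.get(members[j])
        for _ in range(offspring_per_cross):
            _make_offspring(store, p1, p2, out, rng)
    return out


def cross_combinations(
    pairs: Sequence[Tuple[int, int]],
    offspring_per_cross: int,
    store: PopulationStore,
    rng: np.random.Generator,
) -> GroupHandle:
    """Execute exactly the listed crosses in order (all-or-nothing on bad ids)."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("empty crossing plan")
    if offspring_per_cross < 1:
        raise ValueError("offspring_per_cross must be >= 1")
    parents = [(store.get(a), store.get(b)) for a, b in pairs]  # validate up front
    out = store.new_group_handle()
    for p1, p2 in parents:
        for _ in range(offspring_per_cross):
            _make_offspring(store, p1, p2, out, rng)
    return out


def cross_all_pairs(
    group: GroupHandle, store: PopulationStore, rng: np.random.Generator
) -> GroupHandle:
    """One offspring per unordered pair of distinct group members: n(n-1)/2 total."""
    members = store.members(group)
    if len(members) < 2:
        raise ValueError("all-pairs crossing needs a group of >= 2 members")
    out = store.new_group_handle()
    for i in range(len(members)):
        for j in range(i + 1, len(members)):
            _make_offspring(store, store.get(members[i]), store.get(members[j]), out, rng)
    return out


def self_n_times(
    group: GroupHandle,
    n: int,
    store: PopulationStore,
    rng: np.random.Generator,
    n_offspring: int = 1,
) -> GroupHandle:
    """Self every group member for ``n`` sequential generations (single-seed descent).

    Each input member founds ``n_offspring`` independent lines; each line is
    advanced by selfing (two gametes from the same current individual) for n
    generations, keeping only the last.  Intermediate generations are not
    retained, so the recorded parents of each output line are the input
    member it descends from.
    """
    if n < 1:
        raise ValueError("number of selfing generations must be >= 1")
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    members = store.members(group)
    out = store.new_group_handle()
    gmap = store.map
    for rid in members:
        ancestor = store.get(rid)
        for _ in range(n_offspring):
            current = ancestor
            for _ in range(n):
                hap1 = generate_gamete(current, gmap, rng)
                hap2 = generate_gamete(current, gmap, rng)
                current = GenotypeRecord(0, "", hap1, hap2)
            rec = store.add_record("", current.hap1, current.hap2, out, rid, rid)
            rec.name = f"sf{rec.id}"
    return out


def make_doubled_haploids(
    group: GroupHandle, store: PopulationStore, rng: np.random.Generator
) -> GroupHandle:
    """One doubled haploid per member: a single gamete duplicated into both
    haplotypes, hence homozygous at every locus."""
    members = store.members(group)
    out = store.new_group_handle()
    for rid in members:
        parent = store.get(rid)
        gamete = generate_gamete(parent, store.map, rng)
        rec = store.add_record("", gamete, gamete.copy(), out, rid, rid)
        rec.name = f"dh{rec.id}"
    return out
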