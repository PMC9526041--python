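"""Core data structures shared by all simulator modules.

The genome model is a genetic (linkage) map: named markers at centimorgan
positions on named chromosomes.  Every simulated individual is a
:class:`GenotypeRecord` holding two phased haplotypes — numpy arrays of
single-byte allele characters, one per mapped marker, in map order.  All
records live in a :class:`PopulationStore`, which also owns the group
bookkeeping: every live record belongs to exactly one group, and groups are
the unit of all crossing and selection operations.

Alleles are arbitrary nonspace characters (not restricted to ACGT), so the
simulator works on SNPs and on defined Mendelian genes alike.  Map positions
are read in centimorgans and converted to Morgans (/100) wherever a
recombination rate is needed, since the crossover count per chromosome is
Poisson with mean equal to the tracked span in Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "MISSING_ALLELE",
    "Chromosome",
    "GeneticMap",
    "GenotypeRecord",
    "EffectSet",
    "PopulationStore",
    "chromosome_span",
    "haplotype_from_string",
    "haplotype_to_string",
]

#: Placeholder allele for markers absent from a late-loaded genotype file.
#: It carries breeding-value effect 0 and is transmitted like any allele.
MISSING_ALLELE = "-"

#: A group handle is a positive integer; valid iff >=1 live record carries it.
GroupHandle = int


def haplotype_from_string(s: str) -> np.ndarray:
    """Convert an allele string (one character per marker) to a haplotype array."""
    return np.frombuffer(s.encode("utf-8"), dtype="S1").copy()


def haplotype_to_string(hap: np.ndarray) -> str:
    return hap.tobytes().decode("utf-8")


@dataclass(frozen=True)
class Chromosome:
    """One linkage group: ordered markers at nondecreasing cM positions."""

    name: str
    marker_names: tuple
    positions_cm: np.ndarray  # float64, nondecreasing
    start: int = 0  # offset of this chromosome's first marker in genome-wide arrays

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_cm, dtype=float)
        object.__setattr__(self, "positions_cm", pos)
        if len(self.marker_names) == 0:
            raise ValueError(f"chromosome {self.name!r} has no markers")
        if len(self.marker_names) != len(pos):
            raise ValueError("marker_names and positions_cm lengths differ")
        if np.any(pos < 0):
            raise ValueError(f"negative map position on chromosome {self.name!r}")
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"positions on chromosome {self.name!r} are not nondecreasing")

    @property
    def n_markers(self) -> int:
        return len(self.positions_cm)

    @property
    def slice(self) -> slice:
        return slice(self.start, self.start + self.n_markers)

    @property
    def span_morgans(self) -> float:
        """Tracked span: (last - first position)/100.  Zero for a single marker."""
        return float(self.positions_cm[-1] - self.positions_cm[0]) / 100.0


class GeneticMap:
    """Ordered collection of chromosomes; marker names are unique genome-wide."""

    def __init__(self, chromosomes: Sequence[Chromosome]):
        offset = 0
        fixed = []
        for chrom in chromosomes:
            fixed.append(
                Chromosome(chrom.name, tuple(chrom.marker_names), chrom.positions_cm, offset)
            )
            offset += chrom.n_markers
        self.chromosomes: tuple = tuple(fixed)
        if not self.chromosomes:
            raise ValueError("a genetic map needs at least one chromosome")
        names = [m for c in self.chromosomes for m in c.marker_names]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique genome-wide")
        cnames = [c.name for c in self.chromosomes]
        if len(set(cnames)) != len(cnames):
            raise ValueError("chromosome names must be unique")
        self.marker_names: tuple = tuple(names)
        self.n_markers: int = len(names)
        self._marker_index: dict = {m: i for i, m in enumerate(names)}
        self._chrom_index: dict = {c.name: c for c in self.chromosomes}

    def marker_index(self, marker: str) -> int:
        return self._marker_index[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self._marker_index

    def chromosome(self, name: str) -> Chromosome:
        try:
            return self._chrom_index[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def chromosome_span(self, name: str) -> float:
        """Distance in Morgans between first and last tracked position."""
        return self.chromosome(name).span_morgans

    @property
    def positions_cm(self) -> np.ndarray:
        return np.concatenate([c.positions_cm for c in self.chromosomes])


def chromosome_span(gmap: GeneticMap, chromosome_name: str) -> float:
    """Span of a chromosome in Morgans (convenience wrapper)."""
    return gmap.chromosome_span(chromosome_name)


@dataclass
class GenotypeRecord:
    """One diploid individual: two phased haplotypes plus pedigree bookkeeping.

    Parent ids are absent for founders.  For selfed lines produced by
    single-seed descent the recorded parents are the retained ancestor (the
    member that was selfed), since intermediate generations are discarded.
    """

    id: int
    name: str
    hap1: np.ndarray  # dtype S1, one allele per mapped marker
    hap2: np.ndarray
    parent1_id: Optional[int] = None
    parent2_id: Optional[int] = None
    group: GroupHandle = 0

    def __post_init__(self) -> None:
        if self.hap1.shape != self.hap2.shape:
            raise ValueError("haplotypes differ in length")

    @property
    def n_markers(self) -> int:
        return len(self.hap1)

    def allele_string(self) -> str:
        """Phased genotype as 2 characters per locus (hap1 char then hap2 char)."""
        out = np.empty(2 * self.n_markers, dtype="S1")
        out[0::2] = self.hap1
        out[1::2] = self.hap2
        return haplotype_to_string(out)

    def heterozygosity(self) -> float:
        return float(np.mean(self.hap1 != self.hap2))


class EffectSet:
    """Additive allele effects: (marker name, allele character) -> real effect.

    Pairs absent from the mapping contribute 0 to the breeding value, which
    allows sparse effect tables.  On construction the entries are compiled
    into per-allele effect vectors over the map's marker order so breeding
    values vectorize to a handful of matrix products.
    """

    def __init__(self, entries: Mapping, gmap: GeneticMap):
        self.entries: dict = {}
        for (marker, allele), eff in entries.items():
            if marker not in gmap:
                raise KeyError(f"effect entry references unmapped marker {marker!r}")
            if len(allele) != 1 or allele.isspace():
                raise ValueError(f"allele must be one nonspace character, got {allele!r}")
            self.entries[(marker, allele)] = float(eff)
        self._gmap = gmap
        # allele byte -> dense effect vector over all markers
        vecs: dict = {}
        for (marker, allele), eff in self.entries.items():
            key = allele.encode("utf-8")
            if key not in vecs:
                vecs[key] = np.zeros(gmap.n_markers)
            vecs[key][gmap.marker_index(marker)] = eff
        self._vectors = vecs

    @property
    def allele_vectors(self) -> dict:
        return self._vectors

    def __len__(self) -> int:
        return len(self.entries)


class PopulationStore:
    """All simulated genotypes plus the group partition.

    Record ids are strictly increasing in creation order and never reused.
    Group membership partitions the live records; a group handle stays valid
    only while at least one live record carries it (empty groups are not
    retained).  Member order within a group is creation order, which makes
    all downstream data extraction and tie-breaking reproducible.
    """

    def __init__(self, gmap: GeneticMap, effects: Optional[EffectSet] = None):
        self.map = gmap
        self.effects = effects
        self._records: dict = {}  # id -> GenotypeRecord, insertion-ordered
        self._groups: dict = {}  # handle -> list of ids in creation order
        self._next_id = 1
        self._next_group = 1

    # -- record/group primitives -------------------------------------------------

    def new_group_handle(self) -> GroupHandle:
        handle = self._next_group
        self._next_group += 1
        self._groups[handle] = []
        return handle

    def add_record(
        self,
        name: str,
        hap1: np.ndarray,
        hap2: np.ndarray,
        group: GroupHandle,
        parent1_id: Optional[int] = None,
        parent2_id: Optional[int] = None,
    ) -> GenotypeRecord:
        if len(hap1) != self.map.n_markers or len(hap2) != self.map.n_markers:
            raise ValueError("haplotype length does not match the genetic map")
        for pid in (parent1_id, parent2_id):
            if pid is not None and pid >= self._next_id:
                raise KeyError(f"parent id {pid} does not exist")
        rec = GenotypeRecord(self._next_id, name, hap1, hap2, parent1_id, parent2_id, group)
        self._next_id += 1
        self._records[rec.id] = rec
        self._groups.setdefault(group, []).append(rec.id)
        return rec

    def get(self, record_id: int) -> GenotypeRecord:
        try:
            return self._records[record_id]
        except KeyError:
            raise KeyError(f"no live record with id {record_id}") from None

    def is_live(self, record_id: int) -> bool:
        return record_id in self._records

    def members(self, group: GroupHandle) -> list:
        """Member ids of a group in creation order."""
        if group not in self._groups or not self._groups[group]:
            raise KeyError(f"invalid group handle {group}")
        return list(self._groups[group])

    def group_size(self, group: GroupHandle) -> int:
        return len(self.members(group))

    def live_groups(self) -> list:
        return [g for g, ids in self._groups.items() if ids]

    def group_sizes(self) -> dict:
        return {g: len(ids) for g, ids in self._groups.items() if ids}

    @property
    def n_records(self) -> int:
        return len(self._records)

    def all_ids(self) -> list:
        return list(self._records)

    # -- mutation ------------------------------------------------------------------

    def move_records(self, ids: Iterable[int], group: GroupHandle) -> None:
        """Move records into ``group``; drops source groups that become empty."""
        ids = list(ids)
        for rid in ids:
            rec = self.get(rid)
            src = rec.group
            self._groups[src].remove(rid)
            if not self._groups[src]:
                del self._groups[src]
            rec.group = group
        bucket = self._groups.setdefault(group, [])
        bucket.extend(sorted(ids))
        bucket.sort()

    def delete_records(self, ids: Iterable[int]) -> None:
        for rid in list(ids):
            rec = self.get(rid)
            self._groups[rec.group].remove(rid)
            if not self._groups[rec.group]:
                del self._groups[rec.group]
            del self._records[rid]

    # -- bulk views ------------------------------------------------------------------

    def haplotype_matrices(self, group: GroupHandle):
        """Stack a group's haplotypes into two (n_members, n_markers) S1 arrays."""
        ids = self.members(group)
        h1 = np.stack([self._records[i].hap1 for i in ids])
        h2 = np.stack([self._records[i].hap2 for i in ids])
        return h1, h2
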