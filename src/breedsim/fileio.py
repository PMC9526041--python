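"""Readers and writers for the simulator's tab-separated text formats.

Three input tables set up a simulation:

* **Genotype matrix** — first row holds genotype names, first column holds
  marker names, every cell holds exactly two nonspace characters (the two
  alleles of a diploid locus, e.g. ``AT``).  A leading ``#phased`` comment
  line marks the file as phase-encoded (first character -> haplotype 1,
  second -> haplotype 2); without it, the phase of every heterozygous locus
  is randomized on load, independently per locus and per genotype.
* **Linkage map** — three columns ``marker  chromosome  position`` with one
  header line; positions in centimorgans, nondecreasing within a chromosome
  in file order.
* **Allele effects** — three columns ``marker  allele  effect`` with one
  header line; multiple rows per marker (one per allele) are allowed, and
  any (marker, allele) pair absent from the table contributes 0.

The genotype writer encodes phase and emits the ``#phased`` flag, so a
save/reload round trip is exact.  All writers produce byte-stable output for
a fixed store.  The matrix orientation (markers as rows, genotypes as
columns) is this package's documented convention — choose your export
accordingly when preparing founder files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .genome import (
    MISSING_ALLELE,
    Chromosome,
    EffectSet,
    GeneticMap,
    GroupHandle,
    PopulationStore,
)
from .quantgen import breeding_values

logger = logging.getLogger("breedsim")

__all__ = [
    "read_genotype_matrix",
    "read_map",
    "read_effects",
    "load_data",
    "load_more_genotypes",
    "load_different_effects",
    "save_genotypes",
    "save_breeding_values",
    "save_map",
    "save_effects",
]

PHASED_FLAG = "#phased"


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


def read_genotype_matrix(path) -> Tuple[pd.DataFrame, bool]:
    """Read a genotype matrix; returns (markers x genotypes frame, phased flag)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    phased = first.strip() == PHASED_FLAG
    frame = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, skiprows=1 if phased else 0
    )
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise FormatError(f"{path}: empty genotype matrix")
    cells = frame.to_numpy()
    lengths = np.vectorize(len)(cells.astype(str))
    if not np.all(lengths == 2):
        bad = np.argwhere(lengths != 2)[0]
        raise FormatError(
            f"{path}: cell at marker {frame.index[bad[0]]!r}, genotype "
            f"{frame.columns[bad[1]]!r} does not hold exactly 2 allele characters"
        )
    return frame, phased


def read_map(path) -> GeneticMap:
    """Read a linkage map (marker, chromosome, position-cM; one header line)."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, comment="#")
    if frame.shape[1] < 3:
        raise FormatError(f"{path}: map file needs 3 tab-separated columns")
    frame.columns = ["marker", "chromosome", "position"][: frame.shape[1]]
    frame["position"] = frame["position"].astype(float)
    chroms = []
    for name, sub in frame.groupby("chromosome", sort=False):
        chroms.append(Chromosome(str(name), tuple(sub["marker"]), sub["position"].to_numpy()))
    return GeneticMap(chroms)


def read_effects(path, gmap: GeneticMap) -> EffectSet:
    """Read an allele-effect table, dropping entries for unmapped markers."""
    frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str}, comment="#")
    if frame.shape[1] < 3:
        raise FormatError(f"{path}: effects file needs 3 tab-separated columns")
    frame.columns = ["marker", "allele", "effect"][: frame.shape[1]]
    entries = {}
    dropped = 0
    for marker, allele, eff in frame.itertuples(index=False):
        if marker not in gmap:
            dropped += 1
            continue
        entries[(marker, str(allele))] = float(eff)
    if dropped:
        logger.warning("dropped %d effect entries for markers absent from the map", dropped)
    return EffectSet(entries, gmap)


def _columns_to_haplotypes(
    column: pd.Series,
    marker_order: list,
    phased: bool,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Split one genotype column into two haplotypes, randomizing phase if unphased."""
    cells = column.reindex(marker_order).to_numpy()
    missing = pd.isna(cells)
    if missing.any():
        cells = cells.copy()
        cells[missing] = MISSING_ALLELE * 2
    hap1 = np.array([c[0] for c in cells], dtype="S1")
    hap2 = np.array([c[1] for c in cells], dtype="S1")
    if not phased:
        het = hap1 != hap2
        swap = het & (rng.random(len(hap1)) < 0.5)
        hap1[swap], hap2[swap] = hap2[swap], hap1[swap].copy()
    return hap1, hap2


def _append_genotypes(
    store: PopulationStore, frame: pd.DataFrame, phased: bool, rng: np.random.Generator
) -> GroupHandle:
    marker_order = list(store.map.marker_names)
    shared = [m for m in frame.index if m in store.map]
    if not shared:
        raise FormatError("no markers shared between the genotype matrix and the map")
    extra = len(frame.index) - len(shared)
    if extra:
        logger.warning("dropped %d matrix markers absent from the map", extra)
    n_missing = len(marker_order) - len(shared)
    if n_missing:
        logger.warning(
            "filling %d mapped markers absent from the genotype file with %r",
            n_missing,
            MISSING_ALLELE,
        )
    group = store.new_group_handle()
    for name in frame.columns:
        hap1, hap2 = _columns_to_haplotypes(frame[name], marker_order, phased, rng)
        store.add_record(str(name), hap1, hap2, group)
    return group


def load_data(
    genotype_file,
    map_file,
    effects_file=None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[PopulationStore, GroupHandle]:
    """Set up a simulation from founder genotypes, a linkage map, and optional effects.

    The tracked genome is the map restricted to markers present in the
    genotype matrix (in map order); founders all land in one new group.
    Heterozygous loci of unphased files get a random phase, each ordering
    with probability 1/2.
    """
    rng = rng if rng is not None else np.random.default_rng()
    full_map = read_map(map_file)
    frame, phased = read_genotype_matrix(genotype_file)
    present = set(frame.index)
    chroms = []
    for chrom in full_map.chromosomes:
        keep = [i for i, m in enumerate(chrom.marker_names) if m in present]
        if keep:
            chroms.append(
                Chromosome(
                    chrom.name,
                    tuple(chrom.marker_names[i] for i in keep),
                    chrom.positions_cm[keep],
                )
            )
    if not chroms:
        raise FormatError("no markers shared between the genotype matrix and the map")
    n_unmapped = len(full_map.marker_names) - sum(c.n_markers for c in chroms)
    if n_unmapped:
        logger.warning("dropped %d map markers absent from the genotype matrix", n_unmapped)
    gmap = GeneticMap(chroms)
    store = PopulationStore(gmap)
    founders = _append_genotypes(store, frame, phased, rng)
    if effects_file is not None:
        store.effects = read_effects(effects_file, gmap)
    logger.info(
        "loaded %d founders at %d markers on %d chromosomes",
        store.group_size(founders),
        gmap.n_markers,
        len(gmap.chromosomes),
    )
    return store, founders


def load_more_genotypes(
    store: PopulationStore, genotype_file, rng: Optional[np.random.Generator] = None
) -> GroupHandle:
    """Append external genotypes to an initialized store, in a fresh group.

    The tracked map is unchanged: file markers absent from the map are
    dropped with a warning, and mapped markers absent from the file are
    filled with the missing character.
    """
    rng = rng if rng is not None else np.random.default_rng()
    frame, phased = read_genotype_matrix(genotype_file)
    return _append_genotypes(store, frame, phased, rng)


def load_different_effects(store: PopulationStore, effects_file) -> EffectSet:
    """Replace the store's effect set; subsequent breeding values use the new one."""
    store.effects = read_effects(effects_file, store.map)
    return store.effects


def save_genotypes(store: PopulationStore, group: GroupHandle, out) -> None:
    """Write a group's phased genotypes in the matrix dialect (byte-stable)."""
    ids = store.members(group)
    recs = [store.get(i) for i in ids]
    with open(out, "w") as fh:
        fh.write(PHASED_FLAG + "\n")
        fh.write("marker\t" + "\t".join(r.name for r in recs) + "\n")
        h1 = np.stack([r.hap1 for r in recs])  # members x markers
        h2 = np.stack([r.hap2 for r in recs])
        cells = np.char.add(h1.astype("U1"), h2.astype("U1"))
        for j, marker in enumerate(store.map.marker_names):
            fh.write(marker + "\t" + "\t".join(cells[:, j]) + "\n")


def save_breeding_values(store: PopulationStore, group: GroupHandle, out) -> None:
    """Write one row per group member: index, name, additive breeding value."""
    ids = store.members(group)
    bvs = breeding_values(store, group)
    with open(out, "w") as fh:
        fh.write("index\tname\tbreeding_value\n")
        for rid, bv in zip(ids, bvs):
            fh.write(f"{rid}\t{store.get(rid).name}\t{bv:.10g}\n")


def save_map(gmap: GeneticMap, out) -> None:
    with open(out, "w") as fh:
        fh.write("marker\tchromosome\tposition\n")
        for chrom in gmap.chromosomes:
            for marker, pos in zip(chrom.marker_names, chrom.positions_cm):
                fh.write(f"{marker}\t{chrom.name}\t{pos:.10g}\n")


def save_effects(effects: EffectSet, out) -> None:
    with open(out, "w") as fh:
        fh.write("marker\tallele\teffect\n")
        for (marker, allele), eff in effects.entries.items():
            fh.write(f"{marker}\t{allele}\t{eff:.10g}\n")
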