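"""Synthetic founders, linkage maps, and allele-effect tables.

Everything a simulation needs can be generated here, so tests and demo runs
never download data.  Founders are exchangeable draws — loci are independent
with a per-locus minor-allele frequency, so founder populations carry no LD
structure of their own; realistic LD arises downstream through simulated
crossing and selfing.

The generators return in-memory objects *and* a writer that emits the three
input file dialects, so every test exercises the real file formats.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import numpy as np
import pandas as pd

from .genome import Chromosome, EffectSet, GeneticMap

__all__ = ["synth_map", "synth_founders", "synth_effects", "write_fixture_set"]


def synth_map(
    n_chromosomes: int,
    markers_per_chromosome: int,
    chromosome_length_cm: float,
    rng: np.random.Generator,
) -> GeneticMap:
    """Random map: markers at sorted uniform positions on equal-length chromosomes."""
    if n_chromosomes < 1 or markers_per_chromosome < 1:
        raise ValueError("counts must be >= 1")
    chroms = []
    for c in range(1, n_chromosomes + 1):
        pos = np.sort(rng.uniform(0.0, chromosome_length_cm, size=markers_per_chromosome))
        names = tuple(f"m{c}_{i+1}" for i in range(markers_per_chromosome))
        chroms.append(Chromosome(f"chr{c}", names, pos))
    return GeneticMap(chroms)


def synth_founders(
    n: int,
    gmap: GeneticMap,
    maf_range: Tuple[float, float],
    inbred: bool,
    rng: np.random.Generator,
    alleles: Tuple[str, str] = ("A", "T"),
) -> pd.DataFrame:
    """Founder genotype matrix (markers x genotypes) with biallelic loci.

    Each locus gets a minor-allele frequency drawn uniformly from
    ``maf_range``; inbred founders are homozygous at every locus (both
    allele copies identical), heterozygous founders draw the two copies
    independently.
    """
    if n < 1:
        raise ValueError("need at least one founder")
    lo, hi = maf_range
    if not (0.0 <= lo <= hi <= 0.5):
        raise ValueError("maf_range must satisfy 0 <= low <= high <= 0.5")
    m = gmap.n_markers
    maf = rng.uniform(lo, hi, size=m)
    minor, major = alleles[0], alleles[1]
    if inbred:
        is_minor = rng.random((m, n)) < maf[:, None]
        copy1 = np.where(is_minor, minor, major)
        copy2 = copy1
    else:
        copy1 = np.where(rng.random((m, n)) < maf[:, None], minor, major)
        copy2 = np.where(rng.random((m, n)) < maf[:, None], minor, major)
    cells = np.char.add(copy1.astype("U1"), copy2.astype("U1"))
    frame = pd.DataFrame(
        cells,
        index=list(gmap.marker_names),
        columns=[f"G{i+1}" for i in range(n)],
    )
    frame.index.name = "marker"
    return frame


def synth_effects(
    gmap: GeneticMap,
    proportion_causal: float,
    effect_sd: float,
    rng: np.random.Generator,
    allele: str = "A",
) -> EffectSet:
    """Sparse additive effects: a random subset of markers gets a
    Normal(0, effect_sd²) effect for one allele; all other pairs are 0."""
    if not 0.0 < proportion_causal <= 1.0:
        raise ValueError("proportion_causal must be in (0, 1]")
    if effect_sd < 0:
        raise ValueError("effect_sd must be >= 0")
    m = gmap.n_markers
    n_causal = max(1, int(round(m * proportion_causal)))
    chosen = rng.choice(m, size=n_causal, replace=False)
    chosen.sort()
    entries = {
        (gmap.marker_names[i], allele): float(rng.normal(0.0, effect_sd)) for i in chosen
    }
    return EffectSet(entries, gmap)


def write_fixture_set(
    out_dir,
    rng: np.random.Generator,
    n_founders: int = 50,
    n_chromosomes: int = 21,
    markers_per_chromosome: int = 238,
    chromosome_length_cm: float = 150.0,
    maf_range: Tuple[float, float] = (0.1, 0.5),
    inbred: bool = True,
    proportion_causal: float = 0.2,
    effect_sd: float = 1.0,
) -> dict:
    """Generate a founder/map/effects trio and write it through the file dialects.

    Defaults emulate a wheat-scale input: 50 inbred founders at ~5,000 SNPs
    on 21 chromosomes.  Returns the file paths plus the in-memory objects.
    """
    from . import fileio  # deferred: fileio imports quantgen, keep cycles out

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gmap = synth_map(n_chromosomes, markers_per_chromosome, chromosome_length_cm, rng)
    founders = synth_founders(n_founders, gmap, maf_range, inbred, rng)
    effects = synth_effects(gmap, proportion_causal, effect_sd, rng)
    paths = {
        "genotypes": out_dir / "founder-genotypes.txt",
        "map": out_dir / "genetic-map.txt",
        "effects": out_dir / "effects.txt",
    }
    founders.to_csv(paths["genotypes"], sep="\t")
    fileio.save_map(gmap, paths["map"])
    fileio.save_effects(effects, paths["effects"])
    return {"paths": paths, "map": gmap, "founders": founders, "effects": effects}
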