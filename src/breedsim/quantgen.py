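"""Additive breeding values, heritability-masked phenotypes, truncation selection.

The genotypic (breeding) value of an individual is purely additive: the sum
over all marker positions of the effect values of the marker's two alleles.
Phenotypes are simulated as P = G + E where E ~ Normal(0, Ve) and Ve is
sized from a broad-sense heritability H² = Vg/(Vg + Ve) using the group's
sample variance of breeding values:  Ve = Vg/H² - Vg.  Phenotypes are
ephemeral — recomputed per call, never stored — so repeated phenotyping of
the same group models independent trials.
"""

from __future__ import annotations

import logging
import math
from typing import Optional

import numpy as np

from .genome import EffectSet, GenotypeRecord, GroupHandle, PopulationStore

logger = logging.getLogger("breedsim")

__all__ = [
    "breeding_value",
    "breeding_values",
    "environmental_variance",
    "simulate_phenotypes",
    "select_by_gebv",
    "select_top_by_phenotype",
]


def breeding_value(record: GenotypeRecord, effects: EffectSet) -> float:
    """Additive breeding value: sum of both alleles' effects over all markers.

    (marker, allele) pairs absent from the effect set contribute 0.
    """
    total = 0.0
    for allele, vec in effects.allele_vectors.items():
        total += vec @ (record.hap1 == allele) + vec @ (record.hap2 == allele)
    return float(total)


def breeding_values(store: PopulationStore, group: GroupHandle) -> np.ndarray:
    """Breeding values of a group's members, in stable member (creation) order."""
    effects = _require_effects(store)
    h1, h2 = store.haplotype_matrices(group)
    out = np.zeros(h1.shape[0])
    for allele, vec in effects.allele_vectors.items():
        out += (h1 == allele) @ vec + (h2 == allele) @ vec
    return out


def _require_effects(store: PopulationStore) -> EffectSet:
    if store.effects is None:
        raise RuntimeError("no allele effect set loaded; breeding values unavailable")
    return store.effects


def environmental_variance(genetic_variance: float, heritability: float) -> float:
    """Ve = Vg/H² - Vg.  Zero genetic variance yields Ve = 0 (noise-free)."""
    if not 0.0 < heritability <= 1.0:
        raise ValueError(f"heritability must be in (0, 1], got {heritability}")
    if genetic_variance < 0:
        raise ValueError("variance must be >= 0")
    if genetic_variance == 0.0:
        return 0.0
    return genetic_variance / heritability - genetic_variance


def simulate_phenotypes(
    store: PopulationStore,
    group: GroupHandle,
    heritability: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """P = BV + Normal(0, Ve) per member, Ve sized so H² = Vg/(Vg+Ve) in the group.

    Vg is the unbiased (n-1) sample variance of the group's breeding values.
    H² = 1 gives P = BV exactly.
    """
    bvs = breeding_values(store, group)
    if len(bvs) < 2:
        raise ValueError("phenotype simulation needs a group of >= 2 (sample variance)")
    vg = float(np.var(bvs, ddof=1))
    ve = environmental_variance(vg, heritability)
    if ve == 0.0:
        return bvs.copy()
    return bvs + rng.normal(0.0, math.sqrt(ve), size=len(bvs))


def _selection_count(size: int, count: Optional[int], fraction: Optional[float]) -> int:
    if (count is None) == (fraction is None):
        raise ValueError("give exactly one of count or fraction")
    if count is not None:
        if not 1 <= count <= size:
            raise ValueError(f"count must be in [1, {size}], got {count}")
        return count
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    return max(1, int(math.floor(size * fraction)))


def _move_top(
    store: PopulationStore, group: GroupHandle, scores: np.ndarray, n: int, direction: str
) -> GroupHandle:
    if direction not in ("best", "worst"):
        raise ValueError("direction must be 'best' or 'worst'")
    ids = store.members(group)
    keys = -scores if direction == "best" else scores
    order = np.argsort(keys, kind="stable")  # ties fall to earlier-created members
    chosen = [ids[i] for i in order[:n]]
    dest = store.new_group_handle()
    store.move_records(chosen, dest)
    return dest


def select_by_gebv(
    store: PopulationStore,
    group: GroupHandle,
    count: Optional[int] = None,
    fraction: Optional[float] = None,
    direction: str = "best",
) -> GroupHandle:
    """Truncation selection on breeding values; selected members move to a new group.

    Fractional sizes floor (with a minimum of 1); ties at the cut go to the
    earlier-created member.
    """
    bvs = breeding_values(store, group)
    n = _selection_count(len(bvs), count, fraction)
    return _move_top(store, group, bvs, n, direction)


def select_top_by_phenotype(
    store: PopulationStore,
    group: GroupHandle,
    heritability: float,
    portion: float,
    rng: np.random.Generator,
) -> GroupHandle:
    """Phenotype the group at the given H² and move the top floor(size*portion)."""
    phenos = simulate_phenotypes(store, group, heritability, rng)
    n = _selection_count(len(phenos), None, portion)
    return _move_top(store, group, phenos, n, "best")
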