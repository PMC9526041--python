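"""Gamete generation by the count-location model of meiosis.

For each chromosome independently: the number of crossovers is drawn from a
Poisson distribution whose mean is the chromosome's tracked span in Morgans
(distance between first and last mapped position); crossover positions are
then i.i.d. uniform over that same span; a fair coin picks which homolog the
gamete starts on, and the active homolog toggles at every crossover while
reading along the markers.  There is no mutation and no crossover
interference — crossover counts in disjoint subintervals are independent,
and the recombination fraction between two markers at map distance d Morgans
is Haldane's (1 - exp(-2d))/2.

A crossover landing exactly on a marker position toggles *before* that marker
is read (deterministic tie rule; a measure-zero event for continuous draws
but reachable on zero-length spans).
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from .genome import GeneticMap, GenotypeRecord

__all__ = ["draw_crossover_count", "draw_crossover_positions", "generate_gamete"]


def draw_crossover_count(
    length_morgans: float, rng: np.random.Generator, size: Optional[int] = None
) -> Union[int, np.ndarray]:
    """Number of crossovers on a chromosome of the given genetic length.

    Poisson(length) distributed; a zero-length span always yields 0.
    With ``size`` given, returns an array of independent draws.
    """
    if length_morgans < 0:
        raise ValueError(f"chromosome length must be >= 0, got {length_morgans}")
    draws = rng.poisson(length_morgans, size=size)
    return int(draws) if size is None else draws


def draw_crossover_positions(
    count: int, span_start_cm: float, span_end_cm: float, rng: np.random.Generator
) -> np.ndarray:
    """``count`` i.i.d. Uniform(span_start, span_end) positions, sorted ascending."""
    if count < 0:
        raise ValueError("crossover count must be >= 0")
    if span_end_cm < span_start_cm:
        raise ValueError("span_end must be >= span_start")
    return np.sort(rng.uniform(span_start_cm, span_end_cm, size=count))


def generate_gamete(
    parent: GenotypeRecord, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete from ``parent``, as an S1 allele array in map order.

    Chromosomes recombine independently.  Every output allele is one of the
    parent's two alleles at that marker.
    """
    if parent.n_markers != gmap.n_markers:
        raise ValueError("parent haplotype length does not match the genetic map")
    gamete = np.empty(gmap.n_markers, dtype="S1")
    for chrom in gmap.chromosomes:
        sl = chrom.slice
        pos = chrom.positions_cm
        start = int(rng.integers(2))  # which homolog the gamete starts on
        count = int(rng.poisson(chrom.span_morgans))
        if count:
            xovers = draw_crossover_positions(count, pos[0], pos[-1], rng)
            # crossovers at exactly a marker position toggle before it is read
            active = (start + np.searchsorted(xovers, pos, side="right")) % 2
            gamete[sl] = np.where(active == 0, parent.hap1[sl], parent.hap2[sl])
        else:
            gamete[sl] = parent.hap1[sl] if start == 0 else parent.hap2[sl]
    return gamete
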