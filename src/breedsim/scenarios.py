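"""Packaged breeding-program scenarios.

Two ready-made simulations exercise the whole library surface:

* **Cyclic program** (`run_cyclic_program`): repeated
  cycles of random crossing among the current founders, selfing, phenotypic
  selection at low heritability on early unreplicated material (default
  H²=0.1, keep top 20%), selfing, more accurate selection (default H²=0.4,
  keep top 50%), and a final selfing whose progeny found the next cycle.
  Selection runs either across the whole generation or independently within
  each full-sib family.  Output is a tidy long table of per-cycle
  breeding-value mean and variance per replicate.

* **NAM validation** (`run_nam_scenario`): a nested association mapping
  design — one elite parent crossed to each of n donors, the F1s advanced by
  single-seed descent to an inbred final generation with a fixed number of
  lines per family.  Returns the family partition, the Rogers-distance
  matrix, and an LD decay profile, the summaries used to check that
  simulated offspring show the expected population structure.
"""

from __future__ import annotations

import logging
import tempfile
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import fileio
from .crossing import cross_combinations, cross_randomly, self_n_times
from .genome import GroupHandle, PopulationStore
from .groups import break_into_families, combine_groups, delete_groups
from .popgen import group_bv_summary, ld_decay_profile, rogers_distance_matrix
from .quantgen import select_top_by_phenotype
from .synth import write_fixture_set

logger = logging.getLogger("breedsim")

__all__ = ["run_cyclic_program", "run_nam_scenario", "write_nam_outputs"]


def _cycle(
    store: PopulationStore,
    g0: GroupHandle,
    rng: np.random.Generator,
    n_crosses: int,
    offspring_per_cross: int,
    heritabilities: Tuple[float, float],
    portions: Tuple[float, float],
    within_family: bool,
) -> GroupHandle:
    """One breeding cycle; returns the final selfed group (next cycle's founders)."""
    h1, h2 = heritabilities
    p1, p2 = portions
    f1 = cross_randomly(g0, n_crosses, offspring_per_cross, store, rng)

    def stages(group: GroupHandle) -> GroupHandle:
        f2 = self_n_times(group, 1, store, rng)
        f2s = select_top_by_phenotype(store, f2, h1, p1, rng)
        f3 = self_n_times(f2s, 1, store, rng)
        f3s = select_top_by_phenotype(store, f3, h2, p2, rng)
        return self_n_times(f3s, 1, store, rng)

    if within_family:
        families = break_into_families(f1, store)
        f4 = combine_groups([stages(fam) for fam in families], store)
    else:
        f4 = stages(f1)
    # end-of-cycle cleanup: only the new founders survive
    delete_groups([g for g in store.live_groups() if g != f4], store)
    return f4


def run_cyclic_program(
    n_cycles: int = 5,
    n_crosses: int = 25,
    offspring_per_cross: int = 20,
    stage_heritabilities: Tuple[float, float] = (0.1, 0.4),
    stage_portions: Tuple[float, float] = (0.2, 0.5),
    selection_mode: str = "across",
    n_replicates: int = 10,
    seed: int = 0,
    genotype_file=None,
    map_file=None,
    effects_file=None,
) -> pd.DataFrame:
    """Simulate the cyclic breeding program; tidy long output.

    When no input files are given, a wheat-scale synthetic fixture set is
    generated (50 inbred founders, ~5,000 markers on 21 chromosomes).  Every
    replicate reloads the founders and runs ``n_cycles`` cycles; the table
    holds one row per (replicate, cycle, statistic) with statistic in
    {mean_bv, var_bv} measured on the cycle's final selfed progeny.
    """
    if selection_mode not in ("across", "within_family"):
        raise ValueError("selection_mode must be 'across' or 'within_family'")
    if n_cycles < 1 or n_replicates < 1:
        raise ValueError("n_cycles and n_replicates must be >= 1")
    with tempfile.TemporaryDirectory() as tmp:
        if genotype_file is None:
            fix = write_fixture_set(tmp, np.random.default_rng([seed, 987654321]))
            genotype_file = fix["paths"]["genotypes"]
            map_file = fix["paths"]["map"]
            effects_file = fix["paths"]["effects"]
        rows = []
        for rep in range(n_replicates):
            rng = np.random.default_rng([seed, rep])
            store, g0 = fileio.load_data(genotype_file, map_file, effects_file, rng=rng)
            for cyc in range(1, n_cycles + 1):
                g0 = _cycle(
                    store,
                    g0,
                    rng,
                    n_crosses,
                    offspring_per_cross,
                    stage_heritabilities,
                    stage_portions,
                    within_family=(selection_mode == "within_family"),
                )
                mean, var = group_bv_summary(g0, store)
                rows.append((rep, cyc, "mean_bv", mean))
                rows.append((rep, cyc, "var_bv", var))
            logger.info("replicate %d done (%s selection)", rep, selection_mode)
    return pd.DataFrame(rows, columns=["replicate", "cycle", "statistic", "value"])


def run_nam_scenario(
    n_donors: int = 10,
    lines_per_family: int = 100,
    n_selfing_generations: int = 5,
    seed: int = 0,
    genotype_file=None,
    map_file=None,
    crossing_plan: Optional[Sequence[Tuple[str, str]]] = None,
    ld_bins_cm: Optional[Sequence[float]] = None,
) -> dict:
    """Simulate a NAM design and compute its validation summaries.

    Default founders are synthetic inbreds (1 elite + ``n_donors`` donors) on
    a 14-chromosome map.  The crossing plan defaults to elite x donor_k for
    every donor; an explicit plan (pairs of founder names) overrides it, so
    any pedigree — including donors sharing elite sub-parents — can be
    encoded without code changes.

    Returns a dict with the store, the final group (one group holding the
    whole final generation; split it with ``break_into_families`` to recover
    the family partition), the per-family sizes from the pedigree, the
    Rogers-distance matrix and the LD decay profile.
    """
    if n_donors < 1 or lines_per_family < 1 or n_selfing_generations < 1:
        raise ValueError("n_donors, lines_per_family, n_selfing_generations must be >= 1")
    rng = np.random.default_rng([seed, 13])
    with tempfile.TemporaryDirectory() as tmp:
        if genotype_file is None:
            fix = write_fixture_set(
                tmp,
                np.random.default_rng([seed, 123456789]),
                n_founders=n_donors + 1,
                n_chromosomes=14,
                markers_per_chromosome=75,
                chromosome_length_cm=140.0,
                inbred=True,
            )
            genotype_file = fix["paths"]["genotypes"]
            map_file = fix["paths"]["map"]
        store, founders = fileio.load_data(genotype_file, map_file, rng=rng)
    founder_ids = store.members(founders)
    by_name = {store.get(i).name: i for i in founder_ids}
    if crossing_plan is None:
        elite, donors = founder_ids[0], founder_ids[1:]
        if len(donors) < n_donors:
            raise ValueError("founder file has fewer genotypes than 1 elite + n_donors")
        pairs = [(elite, donors[k]) for k in range(n_donors)]
    else:
        pairs = [(by_name[a], by_name[b]) for a, b in crossing_plan]
    f1 = cross_combinations(pairs, 1, store, rng)
    final = self_n_times(f1, n_selfing_generations, store, rng, n_offspring=lines_per_family)
    rogers = rogers_distance_matrix(final, store)
    if ld_bins_cm is None:
        span = max(c.positions_cm[-1] for c in store.map.chromosomes)
        ld_bins_cm = np.arange(0.0, span + 10.0, 10.0)
    profile = ld_decay_profile(final, ld_bins_cm, store)
    family_sizes = _family_sizes(final, store)
    return {
        "store": store,
        "final_group": final,
        "family_sizes": family_sizes,
        "rogers_matrix": rogers,
        "ld_profile": profile,
    }


def _family_sizes(group: GroupHandle, store: PopulationStore) -> dict:
    sizes: dict = {}
    for rid in store.members(group):
        rec = store.get(rid)
        key = tuple(sorted((rec.parent1_id, rec.parent2_id)))
        sizes[key] = sizes.get(key, 0) + 1
    return sizes


def write_nam_outputs(result: dict, out_dir) -> dict:
    """Write a NAM run's genotypes, Rogers matrix and LD profile as TSV files."""
    from .popgen import save_matrix, save_profile

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": out_dir / "nam-genotypes.txt",
        "rogers": out_dir / "nam-rogers-matrix.txt",
        "ld": out_dir / "nam-ld-profile.txt",
    }
    fileio.save_genotypes(result["store"], result["final_group"], paths["genotypes"])
    save_matrix(result["rogers_matrix"], paths["rogers"])
    save_profile(result["ld_profile"], paths["ld"])
    return paths
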