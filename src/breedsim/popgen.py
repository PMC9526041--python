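"""Population-genetic summaries for validating simulated populations.

* Rogers' genetic distance between individuals (the 1972 Euclidean
  allele-frequency variant): per locus
  d = sqrt(0.5 * sum_a (p_a - q_a)^2) with p, q the within-individual allele
  frequencies (0, 1/2 or 1 for a diploid), averaged over loci.  Bounded in
  [0, 1]; 0 for identical genotypes, 1 for opposite homozygotes everywhere.
  Other software sometimes implements population-level or differently
  normalized variants — compare with care.
* LD r² between marker pairs, computed on the *tracked* haplotypes (the
  simulator knows true phase): D = p_AB - p_A p_B and
  r² = D² / (p_A(1-p_A) p_B(1-p_B)).  The decay profile averages r² over
  within-chromosome marker pairs in map-distance bins (left-closed,
  right-open).  Monomorphic markers are skipped (undefined denominator);
  markers with more than two observed alleles are skipped with a logged count.
* Per-group breeding-value mean and variance, the trajectory statistics of a
  breeding program.
"""

from __future__ import annotations

import logging
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenotypeRecord, GroupHandle, PopulationStore
from .quantgen import breeding_values

logger = logging.getLogger("breedsim")

__all__ = [
    "rogers_distance",
    "rogers_distance_matrix",
    "ld_r2",
    "ld_decay_profile",
    "group_bv_summary",
    "save_matrix",
    "save_profile",
]


def rogers_distance(a: GenotypeRecord, b: GenotypeRecord) -> float:
    """Rogers' distance between two diploid individuals, in [0, 1]."""
    if a.n_markers != b.n_markers or a.n_markers == 0:
        raise ValueError("records must share at least one mapped locus")
    # sum_a (p_a - q_a)^2 = Sp + Sq - m4/2 with Sp = 1 - het/2 and m4 the
    # number of matches among the 4 cross-haplotype comparisons
    sp = 1.0 - 0.5 * (a.hap1 != a.hap2)
    sq = 1.0 - 0.5 * (b.hap1 != b.hap2)
    m4 = (
        (a.hap1 == b.hap1).astype(np.int8)
        + (a.hap1 == b.hap2)
        + (a.hap2 == b.hap1)
        + (a.hap2 == b.hap2)
    )
    d2 = 0.5 * (sp + sq - 0.5 * m4)
    return float(np.mean(np.sqrt(np.maximum(d2, 0.0))))


def rogers_distance_matrix(group: GroupHandle, store: PopulationStore) -> pd.DataFrame:
    """Symmetric zero-diagonal Rogers-distance matrix over a group's members."""
    ids = store.members(group)
    h1, h2 = store.haplotype_matrices(group)
    h1 = h1.view(np.uint8)
    h2 = h2.view(np.uint8)
    n = len(ids)
    het_term = 1.0 - 0.5 * (h1 != h2)  # Sp per individual per locus
    out = np.zeros((n, n))
    for i in range(n - 1):
        a1, a2 = h1[i], h2[i]
        m4 = (
            (a1 == h1[i + 1 :]).astype(np.int8)
            + (a1 == h2[i + 1 :])
            + (a2 == h1[i + 1 :])
            + (a2 == h2[i + 1 :])
        )
        d2 = 0.5 * (het_term[i] + het_term[i + 1 :] - 0.5 * m4)
        out[i, i + 1 :] = np.mean(np.sqrt(np.maximum(d2, 0.0)), axis=1)
    out += out.T
    names = [store.get(i).name for i in ids]
    return pd.DataFrame(out, index=names, columns=names)


def ld_r2(haplotype_counts: np.ndarray) -> float:
    """LD r² from a 2x2 haplotype count table [[AB, Ab], [aB, ab]]."""
    counts = np.asarray(haplotype_counts, dtype=float)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("expected a 2x2 table of nonnegative haplotype counts")
    total = counts.sum()
    if total == 0:
        raise ValueError("empty haplotype table")
    p_ab = counts[0, 0] / total
    p_a = counts[0].sum() / total
    p_b = counts[:, 0].sum() / total
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom == 0:
        raise ValueError("monomorphic marker: r² undefined")
    d = p_ab - p_a * p_b
    return float(d * d / denom)


def ld_decay_profile(
    group: GroupHandle,
    distance_bins_cm: Sequence[float],
    store: PopulationStore,
) -> pd.DataFrame:
    """Mean r² of within-chromosome marker pairs per map-distance bin.

    Bins are left-closed right-open intervals over |pos_i - pos_j| in cM.
    Returns a frame with bin edges, mean r² and the pair count per bin.
    r² on 0/1 haplotype indicators is exactly the squared Pearson
    correlation, so each chromosome reduces to one correlation matrix.
    """
    edges = np.asarray(distance_bins_cm, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("distance_bins_cm must be >= 2 strictly increasing edges")
    h1, h2 = store.haplotype_matrices(group)
    haps = np.concatenate([h1, h2], axis=0)  # 2n haplotypes x markers
    sums = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1, dtype=int)
    n_multiallelic = 0
    for chrom in store.map.chromosomes:
        sub = haps[:, chrom.slice]
        pos = chrom.positions_cm
        keep = []
        for j in range(sub.shape[1]):
            alleles = np.unique(sub[:, j])
            if len(alleles) == 1:
                continue  # monomorphic: r² undefined
            if len(alleles) > 2:
                n_multiallelic += 1
                continue
            keep.append(j)
        if len(keep) < 2:
            continue
        keep = np.array(keep)
        binary = (sub[:, keep] == sub[0, keep]).astype(float)
        r = np.corrcoef(binary, rowvar=False)
        r2 = r * r
        dist = np.abs(pos[keep][:, None] - pos[keep][None, :])
        iu = np.triu_indices(len(keep), k=1)
        which = np.digitize(dist[iu], edges) - 1  # left-closed right-open
        valid = (which >= 0) & (which < len(edges) - 1)
        np.add.at(sums, which[valid], r2[iu][valid])
        np.add.at(counts, which[valid], 1)
    if n_multiallelic:
        logger.info("skipped %d markers with >2 observed alleles", n_multiallelic)
    mean_r2 = np.divide(sums, counts, out=np.full(len(sums), np.nan), where=counts > 0)
    return pd.DataFrame(
        {
            "bin_start_cm": edges[:-1],
            "bin_end_cm": edges[1:],
            "mean_r2": mean_r2,
            "n_pairs": counts,
        }
    )


def group_bv_summary(group: GroupHandle, store: PopulationStore) -> Tuple[float, float]:
    """Sample mean and (n-1) variance of a group's breeding values.

    A single-member group has undefined sample variance; it is reported as 0
    with a warning.
    """
    bvs = breeding_values(store, group)
    if len(bvs) == 1:
        logger.warning("group of size 1: breeding-value variance reported as 0")
        return float(bvs[0]), 0.0
    return float(np.mean(bvs)), float(np.var(bvs, ddof=1))


def save_matrix(matrix: pd.DataFrame, out) -> None:
    """Write a labelled square matrix as tab-separated text."""
    matrix.to_csv(out, sep="\t", float_format="%.10g")


def save_profile(profile: pd.DataFrame, out) -> None:
    """Write an LD decay profile (or any tidy table) as tab-separated text."""
    profile.to_csv(out, sep="\t", index=False, float_format="%.10g")
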