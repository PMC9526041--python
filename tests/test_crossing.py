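import numpy as np
import pytest

from breedsim.crossing import (
    cross,
    cross_all_pairs,
    cross_combinations,
    cross_randomly,
    make_doubled_haploids,
    self_n_times,
)
from breedsim.genome import Chromosome, GeneticMap, EffectSet
from breedsim.quantgen import breeding_values
from .conftest import make_store, single_locus_map


@pytest.fixture
def one_locus_store():
    gmap = single_locus_map()
    store, g = make_store(gmap, {"p1": ("A", "A"), "p2": ("a", "a")})
    return store, g


class TestCross:
    def test_identical_homozygous_parents_breed_true(self, two_chrom_map, rng):
        store, g = make_store(two_chrom_map, {"p1": ("ATATAT", "ATATAT"),
                                              "p2": ("ATATAT", "ATATAT")})
        child = cross(1, 2, store, rng)
        assert child.allele_string() == store.get(1).allele_string()

    def test_opposite_homozygotes_give_certain_heterozygote(self, one_locus_store, rng):
        store, g = one_locus_store
        for _ in range(20):
            child = cross(1, 2, store, rng)
            assert child.hap1.tobytes() == b"A" and child.hap2.tobytes() == b"a"

    def test_parent_order_is_call_order(self, one_locus_store, rng):
        store, _ = one_locus_store
        child = cross(2, 1, store, rng)
        assert (child.parent1_id, child.parent2_id) == (2, 1)

    def test_unknown_parent_is_reference_error(self, one_locus_store, rng):
        store, _ = one_locus_store
        with pytest.raises(KeyError):
            cross(1, 42, store, rng)

    def test_mendelian_segregation_1_2_1(self, rng):
        gmap = single_locus_map()
        store, g = make_store(gmap, {"h1": ("A", "a"), "h2": ("A", "a")})
        n = 10_000
        counts = {"AA": 0, "Aa": 0, "aa": 0}
        out = store.new_group_handle()
        for _ in range(n):
            child = cross(1, 2, store, rng, group=out)
            k = (child.hap1.tobytes() + child.hap2.tobytes()).decode()
            counts["Aa" if k in ("Aa", "aA") else k] += 1
        for geno, p in (("AA", 0.25), ("Aa", 0.5), ("aa", 0.25)):
            se = np.sqrt(p * (1 - p) / n)
            assert abs(counts[geno] / n - p) <= 3 * se


class TestCrossRandomly:
    def test_output_size_is_product(self, fixture_files, rng):
        from breedsim.fileio import load_data

        p = fixture_files["paths"]
        store, founders = load_data(p["genotypes"], p["map"], p["effects"], rng=rng)
        out = cross_randomly(founders, 25, 20, store, rng)
        assert store.group_size(out) == 500

    def test_never_selfs(self, one_locus_store, rng):
        store, g = one_locus_store
        out = cross_randomly(g, 50, 1, store, rng)
        for rid in store.members(out):
            rec = store.get(rid)
            assert rec.parent1_id != rec.parent2_id

    def test_pair_group_single_cross(self, one_locus_store, rng):
        store, g = one_locus_store
        out = cross_randomly(g, 1, 1, store, rng)
        rec = store.get(store.members(out)[0])
        assert {rec.parent1_id, rec.parent2_id} == {1, 2}

    def test_singleton_group_rejected(self, two_chrom_map, rng):
        store, g = make_store(two_chrom_map, {"p": ("ATATAT", "ATATAT")})
        with pytest.raises(ValueError):
            cross_randomly(g, 1, 1, store, rng)

    def test_seed_determinism(self, fixture_files):
        from breedsim.fileio import load_data

        p = fixture_files["paths"]
        runs = []
        for _ in range(2):
            rng = np.random.default_rng(77)
            store, founders = load_data(p["genotypes"], p["map"], p["effects"], rng=rng)
            out = cross_randomly(founders, 5, 3, store, rng)
            runs.append([store.get(i).allele_string() for i in store.members(out)])
        assert runs[0] == runs[1]


class TestCrossCombinations:
    def test_executes_listed_crosses_in_order(self, one_locus_store, rng):
        store, _ = one_locus_store
        out = cross_combinations([(1, 2), (2, 1)], 3, store, rng)
        recs = [store.get(i) for i in store.members(out)]
        assert len(recs) == 6
        assert [(r.parent1_id, r.parent2_id) for r in recs] == [(1, 2)] * 3 + [(2, 1)] * 3

    def test_empty_plan_rejected(self, one_locus_store, rng):
        store, _ = one_locus_store
        with pytest.raises(ValueError):
            cross_combinations([], 1, store, rng)

    def test_bad_id_fails_before_any_offspring(self, one_locus_store, rng):
        store, _ = one_locus_store
        before = store.n_records
        with pytest.raises(KeyError):
            cross_combinations([(1, 2), (1, 99)], 1, store, rng)
        assert store.n_records == before

    def test_duplicate_pairs_give_independent_offspring_sets(self, one_locus_store, rng):
        store, _ = one_locus_store
        out = cross_combinations([(1, 2), (1, 2)], 4, store, rng)
        assert store.group_size(out) == 8


class TestCrossAllPairs:
    @pytest.mark.parametrize("n, expected", [(2, 1), (5, 10)])
    def test_unordered_pair_count(self, n, expected, rng):
        gmap = single_locus_map()
        store, g = make_store(gmap, {f"p{i}": ("A", "A") for i in range(n)})
        out = cross_all_pairs(g, store, rng)
        assert store.group_size(out) == expected

    def test_offspring_heterozygous_where_parents_differ(self, two_chrom_map, rng):
        store, g = make_store(
            two_chrom_map,
            {"p1": ("AAAAAA", "AAAAAA"), "p2": ("AAATTT", "AAATTT"), "p3": ("TTTTTT", "TTTTTT")},
        )
        out = cross_all_pairs(g, store, rng)
        for rid in store.members(out):
            rec = store.get(rid)
            pa, pb = store.get(rec.parent1_id), store.get(rec.parent2_id)
            np.testing.assert_array_equal(rec.hap1 != rec.hap2, pa.hap1 != pb.hap1)


class TestSelfing:
    def test_homozygous_parent_fixed_under_selfing(self, two_chrom_map, rng):
        store, g = make_store(two_chrom_map, {"p": ("ATATAT", "ATATAT")})
        out = self_n_times(g, 4, store, rng)
        rec = store.get(store.members(out)[0])
        assert rec.allele_string() == store.get(1).allele_string()
        assert (rec.parent1_id, rec.parent2_id) == (1, 1)

    @pytest.mark.parametrize("n_gen, expected_het", [(1, 0.5), (3, 0.125)])
    def test_heterozygosity_halves_each_generation(self, n_gen, expected_het, rng):
        gmap = single_locus_map()
        store, g = make_store(gmap, {"h": ("A", "a")})
        n = 10_000
        out = self_n_times(g, n_gen, store, rng, n_offspring=n)
        het = np.mean([store.get(i).hap1[0] != store.get(i).hap2[0]
                       for i in store.members(out)])
        se = np.sqrt(expected_het * (1 - expected_het) / n)
        assert abs(het - expected_het) <= 3 * se

    def test_one_line_per_member_by_default(self, two_chrom_map, rng):
        store, g = make_store(
            two_chrom_map, {f"p{i}": ("ATATAT", "ATATAT") for i in range(7)}
        )
        out = self_n_times(g, 2, store, rng)
        assert store.group_size(out) == 7

    def test_invalid_generation_count_rejected(self, two_chrom_map, rng):
        store, g = make_store(two_chrom_map, {"p": ("ATATAT", "ATATAT")})
        with pytest.raises(ValueError):
            self_n_times(g, 0, store, rng)


class TestDoubledHaploids:
    def test_outputs_are_fully_homozygous(self, fixture_files, rng):
        from breedsim.fileio import load_data

        p = fixture_files["paths"]
        store, founders = load_data(p["genotypes"], p["map"], p["effects"], rng=rng)
        out = make_doubled_haploids(founders, store, rng)
        assert store.group_size(out) == store.group_size(founders)
        for rid in store.members(out):
            assert store.get(rid).heterozygosity() == 0.0

    def test_heterozygote_fixes_either_allele_fairly(self, rng):
        gmap = single_locus_map()
        n = 10_000
        store, g = make_store(gmap, {f"h{i}": ("A", "a") for i in range(n)})
        out = make_doubled_haploids(g, store, rng)
        frac = np.mean([store.get(i).hap1[0] == b"A" for i in store.members(out)])
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)

    def test_homozygous_parent_reproduced_exactly(self, two_chrom_map, rng):
        store, g = make_store(two_chrom_map, {"p": ("ATATAT", "ATATAT")})
        out = make_doubled_haploids(g, store, rng)
        assert store.get(store.members(out)[0]).allele_string() == "AATTAATTAATT"


class TestAdditiveMeanProperty:
    def test_random_crossing_preserves_mean_breeding_value(self, two_chrom_map, rng):
        # additivity: random mating leaves the expected BV unchanged
        effects = EffectSet(
            {("m1", "A"): 1.0, ("m2", "T"): -0.5, ("m4", "A"): 2.0, ("m6", "T"): 0.7},
            two_chrom_map,
        )
        genos = {}
        for i in range(10):
            h = "".join(rng.choice(list("AT"), 6))
            genos[f"p{i}"] = (h, h)
        store, g = make_store(two_chrom_map, genos, effects=effects)
        parent_mean = np.mean(breeding_values(store, g))
        out = cross_randomly(g, 40, 25, store, rng)
        child = breeding_values(store, out)
        se = np.std(child, ddof=1) / np.sqrt(40)  # crosses are the independent unit
        assert abs(np.mean(child) - parent_mean) <= 4 * se

    def test_pedigree_resolves_to_used_records(self, one_locus_store, rng):
        store, g = one_locus_store
        out = cross_randomly(g, 10, 2, store, rng)
        for rid in store.members(out):
            rec = store.get(rid)
            assert store.is_live(rec.parent1_id) and store.is_live(rec.parent2_id)
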