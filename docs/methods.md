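# Methods

## Genome model

The genome is a genetic (linkage) map: named markers at centimorgan
positions on named chromosomes. Positions are read in cM and converted to
Morgans (÷100) wherever a recombination rate is needed, because the
crossover process is parameterized in Morgans and genetic distance — not
physical distance — is what the meiosis model is proportional to. Within a
chromosome, positions must be nondecreasing in file order; co-located
markers (ties) are permitted and kept in file order, and a zero-length
interval correctly receives zero recombination. Alleles are arbitrary
nonspace characters, so the simulator handles SNPs and defined Mendelian
genes alike; diploidy is assumed throughout. Sex chromosomes, other
ploidies, physical maps and mutation are out of scope.

## Meiosis: the count-location model

For each chromosome independently:

1. crossover count *k* ~ Poisson(*L*), with *L* the **tracked span** in
   Morgans — the distance between the chromosome's first and last mapped
   positions;
2. crossover positions i.i.d. Uniform over that same tracked span;
3. a fair Bernoulli draw picks the starting homolog; reading along the
   markers, the active homolog toggles at every crossover passed.

Using the tracked span for both the Poisson parameter and the uniform
support is a deliberate choice: the two must refer to the same interval for
the process to be a homogeneous Poisson crossover process, under which the
recombination fraction at map distance *d* is exactly Haldane's
(1 − e^(−2d))/2. That closed form, plus Poisson moment checks and a
chi-square independence check on disjoint subintervals (no interference),
are the engine's oracles in the test suite. A crossover landing exactly on
a marker position toggles *before* the marker is read — a measure-zero
event for continuous draws, but reachable on degenerate zero-length spans,
where a deterministic tie rule keeps behavior testable. Crossover
interference and user-specified crossover distributions are not modeled.

## Pedigree and group semantics

Every record carries its two parent ids (absent for founders). Selfing by
`self_n_times` advances each line *n* generations by single-seed descent
and discards the intermediates; the recorded parents of each output line
are therefore the retained ancestor — the input member the line descends
from. This is what makes full-sib family structure recoverable by
`break_into_families` after multi-generation inbreeding (e.g. the NAM
scenario's final generation splits into one family per donor cross). The
`n_offspring` parameter spawns that many independent descent lines per
input member; it applies once, not per generation, so requesting 100 lines
selfed for 5 generations yields 100 lines, not 100⁵.

Group membership partitions the live records at all times. Empty groups do
not persist: a handle is valid only while at least one live record carries
it. Member order within a group is creation order (record ids are strictly
increasing and never reused), which fixes the output order of
`see_group_data` and the tie-break order in selection. `delete_groups` is
the only destructor.

`cross_randomly` draws both parents uniformly with replacement, redrawing
when the same individual comes up twice: crossing and selfing are distinct
operations, so random crossing never selfs. `cross_all_pairs` uses
unordered pairs without self-pairs, since parent order has no modeled
consequence. Half-sib splitting takes an explicit parent-slot argument
(1 or 2) because the model itself has no male/female roles.

## Breeding values, phenotypes, selection

The breeding value is the additive sum over markers of the effect values of
the two alleles; (marker, allele) pairs absent from the effect table
contribute 0, which supports sparse effect files. Effects are compiled to
per-allele dense vectors so group breeding values reduce to a few
boolean-matrix products; a naive per-marker, per-allele double loop serves
as the independent oracle in tests. Markers missing from a late-loaded
genotype file are filled with the `-` character, which carries effect 0 and
is transmitted like any allele.

Phenotypes are P = BV + E with E ~ N(0, Ve) and Ve = Vg/H² − Vg, where Vg
is the unbiased (n−1) sample variance of the group's breeding values and H²
is the requested broad-sense heritability in (0, 1]. H² = 1 gives P = BV
exactly. If Vg = 0 (no genetic variance in the group) Ve is defined as 0:
the 0/0 heritability is meaningless and the noise-free limit is the only
self-consistent choice. Phenotypes are ephemeral — recomputed per call —
so repeated phenotyping models independent trials.

Truncation selection takes a count or a fraction; fractional sizes floor,
with a minimum of 1 for nonempty groups (multiplying by a portion and
truncating on indexing is the reproducible reading of the usual scripting
idiom). Ties at the cut go to the earlier-created member. Dominance,
epistasis, GBLUP re-estimation and multi-trait indices are not built in;
multiple traits can be emulated by swapping effect sets.

## Population summaries

**Rogers' distance** is the individual-level 1972 variant: per locus
d = √(½ Σ_a (p_a − q_a)²) with p, q the within-individual allele
frequencies (0, ½, 1), averaged over loci; it is symmetric, zero-diagonal
and bounded in [0, 1]. Other packages implement population-level or
differently normalized variants, so cross-package comparisons need care.

**LD r²** uses the tracked haplotypes directly (the simulator knows true
phase): D = p_AB − p_A·p_B, r² = D²/(p_A(1−p_A)p_B(1−p_B)). On 0/1 allele
indicators this equals the squared Pearson correlation, so the decay
profile computes one correlation matrix per chromosome; the hand formula
remains exposed as `ld_r2` and the two routes cross-check in tests.
Monomorphic markers are skipped (undefined denominator), markers with more
than two observed alleles are skipped with a logged count, pairs are
restricted to within-chromosome, and bins are left-closed right-open in cM.
Estimates in the sparsest long-distance bins wobble with sampling noise, so
the decay checks use a rank-correlation trend test beyond the first bin
rather than strict bin-by-bin monotonicity. This phase-exact r² will differ
from genotype-correlation estimators used on real unphased data.

## File formats

The genotype matrix is markers × genotypes, tab-separated, with exactly two
nonspace characters per cell. Nothing about a diploid matrix file forces
this orientation — it is this package's documented convention, chosen and
fixed rather than inferred. Phase of heterozygous loci is randomized on
load (each ordering with probability ½, independently per locus and
genotype) unless the file starts with a `#phased` comment line; the writer
always emits that flag and encodes hap1-then-hap2 per cell, so a
save/reload round trip is exact. Map and effects files are three-column
tab-separated tables with one header line. Writers format floats with
`%.10g` and iterate in stable store order, making output byte-stable for a
fixed store — the property the determinism checks rely on. All data
warnings (dropped markers, filled markers, dropped effect entries) go
through the `breedsim` logging channel, never silently.

## Synthetic data

`breedsim.synth` generates maps (sorted uniform marker positions on
equal-length chromosomes), founders (independent biallelic loci with
per-locus minor-allele frequency drawn from a range; inbred founders fully
homozygous) and sparse normal effect tables. Defaults in
`write_fixture_set` emulate a wheat-scale input: 50 inbred founders,
21 chromosomes × 238 markers (~5,000 SNPs), 150 cM chromosomes, MAF
0.1–0.5, 20% of markers causal with N(0, 1) effects. Founder loci are
exchangeable draws, so synthetic founders carry **no LD structure or
kinship of their own** — realistic LD and family structure arise only
through simulated crossing and inbreeding. Passing tests on these fixtures
therefore validate the simulation machinery, not the realism of any
particular founder panel; structured real founders can be supplied through
the same file formats.

## Packaged scenarios

**Cyclic program** (`run_cyclic_program`): per cycle, 25 random crosses ×
20 offspring among the current founders; self; phenotype at H² = 0.1 and
keep the top 20% (early, unreplicated material); self; phenotype at
H² = 0.4 and keep the top 50% (later, more accurate trials); self; the
final progeny found the next cycle and everything else is deleted. The
*within-family* condition breaks the F1s into full-sib families and runs
the selfing/selection stages independently per family with the same
portions. Per-cycle mean and variance of breeding value are recorded on the
final selfed group of each cycle, in a tidy (replicate, cycle, statistic,
value) table. Ten replicates by default; the directional checks in the
test suite and acceptance script use 3 replicates × 5 cycles at the
wheat-scale fixture (~5,000 markers), sizes chosen to make the qualitative
contrasts (gain under selection, variance erosion, across ≥ within gain,
within ≥ across retained variance) statistically stable while keeping a
full run in tens of seconds.

**NAM** (`run_nam_scenario`): one elite parent crossed to each of
n_donors donors (default 10), one F1 per cross, advanced 5 selfing
generations (an F6 final generation) keeping 100 lines per family. The
default founder panel is synthetic inbreds on a 14-chromosome map
(durum-wheat-like, 75 markers × 140 cM per chromosome). An explicit
crossing plan (pairs of founder names) can replace the default star
design, so pedigrees with shared elite sub-parents can be encoded without
code changes. Outputs: the final group, Rogers-distance matrix (block
structure: within-family distances below between-family distances) and an
LD decay profile (default 10-cM bins over the tracked span).

## Numerical and reproducibility choices

All randomness flows through one explicit `numpy.random.Generator` per
simulation session (scenarios derive per-replicate generators from the
top-level seed via seed sequences), so a fixed seed reproduces every allele
of every record, and scenario reruns produce byte-identical output files.
Monte-Carlo tests use 3-standard-error bands (4 SE for sample-variance
checks, whose asymptotic SE is wider) at sample sizes of 10⁴–10⁵ chosen so
band widths are a few percent of the checked value. Breeding-value
equality between the vectorized path and the brute-force oracle is asserted
at 1e-9 relative tolerance but agrees to machine precision in practice.

## Known limitations

No crossover interference; no mutation; no dominance or epistasis; no
sex-specific maps or cross-direction effects; founders synthesized here are
LD-free; the LD r² is phase-exact rather than an unphased-data estimator;
runtime benchmarking against other simulators is out of scope.
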