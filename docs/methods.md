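# Methods

## Model of the genome-shuffling protocol

The simulator tracks a fixed catalogue of point-mutation loci as binary
alleles (0 = reference, 1 = variant). Genomes are haploid allele vectors
with a mating type (a/α) or diploid pairs of such vectors. One round of
genome shuffling is modelled as:

1. **Screen** the haploid spore pool: truncation selection keeps the top
   `selection_fraction` of members by fitness, then multinomially
   resamples back to `population_size` (scraping growth above the
   wild-type frontier and regrowing the scrape).
2. **Mate**: random a×α pairing without replacement; the surplus of the
   majority mating type is discarded, since plate mating offers no
   replacement mechanism.
3. **Screen** the shuffled diploids and **archive** them — the archived
   per-round samples are diploid, which is what is plated, frozen, pool
   sequenced, and what picked isolates come from.
4. **Sporulate** the selected diploids into the next round's haploid
   pool.

Fitness is additive across loci: a haploid scores `Σ sᵢxᵢ`; a diploid
scores `sᵢ` for a homozygous variant and `hᵢsᵢ` for a heterozygote
(dominance `hᵢ ∈ [0,1]`), plus Gaussian noise with standard deviation
`fitness_noise_sd`. There is no epistasis. Gradient-plate screening is
not quantified by any growth model in the source protocol, so truncation
on noisy additive fitness is the deliberate abstraction; the defaults
(`selection_fraction = 0.25`, `fitness_noise_sd = 0.3`) are round
choices of a moderately strong, imperfect screen and are documented as
arbitrary within sensible ranges.

**Mutagenesis.** Each genome independently gains variants at
`Poisson(uv_mutation_rate)` catalogue loci drawn uniformly without
replacement (default rate 6, the scale of the multi-mutation founder
clone observed in the catalogued strain). A rate above the catalogue
size is an error; Poisson draws exceeding it are truncated.

**Founder dominance.** A single high-fitness clone dominating the UV
pool is produced emergently by applying `founder_boost` (default 2)
truncation passes to the mutagenized pool before archiving it, rather
than by hard-coding a clone frequency. The validation scenarios instead
construct the founder explicitly at 60% — the frequency at which the
study's five linked mutations sat in its UV pool — because that starting
condition, not its genesis, is what the hitchhiking analysis consumes.

**Meiosis.** Each diploid yields one tetrad: two independent crossover
phase patterns, each contributing a gamete and its complementary sister,
so every tetrad segregates 2:2 at every locus. Phases follow a two-state
Markov chain along the genetic map whose per-interval switch probability
is the Haldane recombinant fraction `r = (1 − e^(−2d))/2` (map distance
`d` in Morgans); chromosome boundaries switch with probability 1/2
(independent assortment). This is exactly equivalent, at the tracked
loci, to dropping Poisson crossovers uniformly on the map with no
interference, and it admits closed-form expectations for tests. Spores
get alternating mating types (2a : 2α per tetrad). With probability
`selfing_probability` (default 0.05) a tetrad is tagged and the next
mating pairs its sister spores preferentially — the route by which
insufficiently segregated spores produce homozygous diploids.

**Observation layers.** Pooled amplicon sequencing draws per-locus
coverage from `Poisson(mean_coverage)` (default 1.35×10⁵ reads/locus,
the study's mean) and variant reads from
`Binomial(coverage, p(1−e) + (1−p)e/3)` where `e` is the per-base error
(default 0.003; a miscall hits one specific wrong base a third of the
time, so a monomorphic locus shows an expected false-variant fraction of
0.001 — safely below the 1% detection threshold). Phred-like quality
summaries are clipped normals. Isolate picking draws `n` diploids
without replacement with weight `exp(fitness_bias·w)` and reports
homo/het/none from allele doses; base-level reads, realistic chromosome
maps and UV mutation spectra are out of scope.

## Calling and filtering

The pooled estimator is the plain read fraction; its detection flag uses
an inclusive 1% threshold. The clonal variant filter is a rule table:
*called* requires evolved fraction ≥ 0.35, central base quality ≥ 40 and
flanking quality ≥ 30, and a control fraction < 0.10; passing evolved
evidence with a contaminated control (≥ 0.10) is *discarded_fp*;
anything else is *not_called*. All published thresholds are implemented
as inclusive (≥); the source text's "more than 35%" vs "≥35%" wobble is
resolved as inclusive. Controls with fewer than `control_min_coverage`
(default 5) reads are flagged uninformative and the call proceeds on
evolved evidence alone — the source's "≤5-fold" coverage remark is
ambiguous (floor vs ceiling), so this is a configurable floor, not a
guess at intent. Zygosity bands for clonal diploids (none < 0.01 ≤
ambiguous < 0.35 ≤ het < 0.90 ≤ homo) are this package's own
calibration; the original calls came from read alignments and mixed
Sanger traces without stated cut-offs.

## Effect annotation

CDS coordinates are 1-based on the coding strand with the start codon at
positions 1–3. Substitutions are classified by translating the reference
and mutated codon with the standard genetic code (via Biopython);
silent ⇔ unchanged amino acid. The SIFT rule is inclusive:
score ≤ 0.05 ⇒ affects function. Real gene sequences are not shipped;
minimal synthetic CDSs (filler alanine codons, affected codons solved by
exhaustive search to satisfy every stated substitution jointly, e.g. two
mutations in one codon) are generated at run time for classifier
validation and are labelled synthetic wherever they are written. The
ambiguous intergenic record downstream of BCS1 carries no printed
ref/alt nucleotides; it is stored without them, excluded from gene-level
counts, and given placeholder nucleotides only inside the simulator,
where alleles are binary.

## Trajectory analysis

Trends compare endpoint frequencies with a margin (default 0.02):
rising/falling beyond the margin, transient when an interior maximum
exceeds both endpoints by the margin, stable otherwise, not_detected
when no round reaches 1%. Below-threshold cells count as 0 in the
arithmetic but stay flagged absent. These rules formalize narrative
labels ("gained…but diminished"); with them, an allele that rose through
round 3 and dipped at round 5 can classify rising or transient depending
on the dip's depth — the two narratives cannot both hold under one
formal rule, and the endpoint rule is the documented choice.

Co-origin clusters are single-linkage groups of loci whose UV-pool
frequency gaps chain within `cluster_tolerance` (0.03), kept when the
cluster has ≥ 2 members and mean frequency ≥ 0.20. Chaining can in
principle admit a member farther than the tolerance from the cluster
mean; on founder-like data (several loci within ±0.01) this does not
occur. Clustering uses UV frequencies only, because co-origin evidence
lives in the starting pool. Ranking orders rising first, then
transient/stable, then falling/not-detected, breaking ties by final
frequency then locus id.

## Validation scenarios and what they show

The hitchhiking scenario places one driver (effect +1.0) and four
passengers 10 cM apart on one chromosome inside a founder clone at 60%
UV frequency, with five unlinked neutral background loci. Passengers are
modelled as mildly deleterious (−0.2): purely neutral passengers would
remain associated with the fixing driver, whereas the observed decay of
the clone's non-productive cargo implies selection against it once
recombination frees the driver. Across 100 seeded replicates the driver
classifies rising, all passengers falling, and the founder's loci form
one co-origin cluster.

Closed-form checks: tetrads segregate 2:2 exactly; one mating of a
large panmictic pool yields Hardy–Weinberg p²/2pq/q² within 3 SE;
two-locus recombinant fractions match the Haldane map function within
3 SE over 10⁴ meioses; with all effects zero and full survival, expected
allele frequencies are conserved across rounds, and r² between linked
neutral loci decays monotonically.

Problem sizes used by the tests and the acceptance script — populations
of 300–2000, 10⁴ meioses, 25–30 estimator replicates, 100 hitchhiking
replicates — were chosen as the smallest sizes at which the binomial/3-SE
bands are informative. Passing them shows the machinery is internally
consistent and reproduces the study's qualitative population genetics;
it does not show that real gradient-plate selection is additive,
noise-Gaussian or truncating, nor that real UV mutations are confined to
a 21-locus catalogue.

## Determinism

Every stochastic step consumes a generator spawned from one seed via
numpy's `SeedSequence`; pipeline outputs embed the seed and a SHA-256
config hash, and a rerun from the same config is byte-identical.
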