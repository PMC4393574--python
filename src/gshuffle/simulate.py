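"""Forward-time simulator of recursive genome shuffling (GS).

Models the protocol used to breed stress-tolerant yeast: a haploid pool
is UV-mutagenized, screened on gradient plates (truncation selection on
additive fitness with Gaussian noise), pool-mated a x alpha, the
resulting diploid pool is screened again and archived, then sporulated
through meiosis (Haldane model: crossovers form a Poisson process along
the genetic map, no interference) to seed the next round.  Genomes are
binary allele vectors over a fixed locus catalogue; all randomness flows
from one seed through numpy's splittable SeedSequence.

The module also emits the two observable layers the study produced from
such populations: pooled amplicon read counts per locus (Poisson
coverage, binomial allele sampling with a per-base sequencing error) and
Sanger-style genotype calls (homo/het/none) for picked isolates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .catalogue import LocusCatalogue

__all__ = [
    "SimulationConfig",
    "PopulationSample",
    "IsolateGenotypeMatrix",
    "wild_type_pool",
    "founder_pool",
    "uv_mutagenize",
    "population_fitness",
    "select_population",
    "mate_pool",
    "sporulate_pool",
    "run_gs_rounds",
    "simulate_amplicon_counts",
    "simulate_isolates",
    "haldane_recombination_fraction",
]

MATING_TYPE_A = 0
MATING_TYPE_ALPHA = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one genome-shuffling simulation.

    uv_mutation_rate is the Poisson mean number of catalogue loci mutated
    per genome; founder_boost is the number of extra truncation-selection
    passes applied to the UV pool before it is archived (this is what
    lets a single high-fitness clone come to dominate the pool);
    selfing_probability is the chance that a tetrad's spores are tagged
    so the next mating preferentially pairs sisters, the route to
    homozygosity when spores are insufficiently segregated.
    """

    population_size: int = 2000
    uv_mutation_rate: float = 6.0
    founder_boost: int = 2
    selection_fraction: float = 0.25
    fitness_noise_sd: float = 0.3
    selfing_probability: float = 0.05
    rounds: int = 5
    crossover_model: str = "haldane"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.uv_mutation_rate < 0:
            raise ValueError("uv_mutation_rate must be >= 0")
        if not 0 < self.selection_fraction <= 1:
            raise ValueError("selection_fraction must lie in (0, 1]")
        if self.fitness_noise_sd < 0:
            raise ValueError("fitness_noise_sd must be >= 0")
        if not 0 <= self.selfing_probability <= 1:
            raise ValueError("selfing_probability must lie in [0, 1]")
        if self.rounds < 0:
            raise ValueError("rounds must be >= 0")
        if self.founder_boost < 0:
            raise ValueError("founder_boost must be >= 0")
        if self.crossover_model != "haldane":
            raise ValueError(f"unknown crossover model {self.crossover_model!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(self.seed))


@dataclass
class PopulationSample:
    """A labelled (multi)set of same-ploidy genomes.

    ``genotypes`` is uint8 with shape (n, L) for haploids and (n, 2, L)
    for diploids.  Haploid samples carry per-member mating types and an
    optional meiosis tag (tetrad of origin; -1 = untagged) used to model
    sister-spore mating.
    """

    round_label: str
    genotypes: np.ndarray
    mating_types: Optional[np.ndarray] = None
    meiosis_tags: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.genotypes.ndim not in (2, 3):
            raise ValueError("genotypes must be (n, L) or (n, 2, L)")
        if self.genotypes.shape[0] == 0:
            raise ValueError(f"{self.round_label}: empty population")
        if self.ploidy == 1:
            if self.mating_types is None:
                raise ValueError("haploid sample requires mating_types")
            if self.mating_types.shape[0] != self.n_members:
                raise ValueError("mating_types length mismatch")
        if self.meiosis_tags is not None and self.meiosis_tags.shape[0] != self.n_members:
            raise ValueError("meiosis_tags length mismatch")

    @property
    def ploidy(self) -> int:
        return 1 if self.genotypes.ndim == 2 else 2

    @property
    def n_members(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[-1]

    def allele_doses(self) -> np.ndarray:
        """Per-member alt allele dose, shape (n, L)."""
        if self.ploidy == 1:
            return self.genotypes.astype(np.int8)
        return self.genotypes.sum(axis=1, dtype=np.int8)

    def allele_frequencies(self) -> np.ndarray:
        """Pooled alt allele frequency per locus."""
        return self.allele_doses().mean(axis=0) / self.ploidy

    def take(self, idx: np.ndarray, round_label: Optional[str] = None) -> "PopulationSample":
        return PopulationSample(
            round_label=round_label or self.round_label,
            genotypes=self.genotypes[idx],
            mating_types=None if self.mating_types is None else self.mating_types[idx],
            meiosis_tags=None if self.meiosis_tags is None else self.meiosis_tags[idx],
        )


@dataclass
class IsolateGenotypeMatrix:
    """Sanger-style genotype calls (homo/het/none) for picked isolates."""

    calls: pd.DataFrame  # index: isolate labels, columns: locus ids

    def __post_init__(self) -> None:
        bad = set(np.unique(self.calls.to_numpy())) - {"homo", "het", "none"}
        if bad:
            raise ValueError(f"invalid genotype calls: {sorted(bad)}")
        if self.calls.isna().to_numpy().any():
            raise ValueError("genotype matrix has missing calls")

    @property
    def isolates(self) -> list[str]:
        return list(self.calls.index)

    def to_tsv(self, path) -> None:
        self.calls.to_csv(path, sep="\t", index_label="isolate")

    @classmethod
    def from_tsv(cls, path) -> "IsolateGenotypeMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="isolate", comment="#"))


# ---------------------------------------------------------------------------
# Pool construction and mutagenesis
# ---------------------------------------------------------------------------

def wild_type_pool(catalogue: LocusCatalogue, n: int, label: str = "WT") -> PopulationSample:
    """An unmutagenized haploid pool, half MATa and half MATalpha."""
    genotypes = np.zeros((n, len(catalogue)), dtype=np.uint8)
    mating = np.zeros(n, dtype=np.uint8)
    mating[n // 2:] = MATING_TYPE_ALPHA
    return PopulationSample(label, genotypes, mating_types=mating)


def uv_mutagenize(
    pool: PopulationSample,
    catalogue: LocusCatalogue,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationSample:
    """Mutagenize a haploid pool: Poisson(rate) loci per genome gain alt.

    Loci are drawn uniformly without replacement, so the rate cannot
    exceed the catalogue size.
    """
    if pool.ploidy != 1:
        raise ValueError("uv_mutagenize expects a haploid pool")
    n_loci = len(catalogue)
    if config.uv_mutation_rate > n_loci:
        raise ValueError(
            f"uv_mutation_rate {config.uv_mutation_rate} exceeds catalogue size {n_loci}"
        )
    genotypes = pool.genotypes.copy()
    hits = np.minimum(rng.poisson(config.uv_mutation_rate, size=pool.n_members), n_loci)
    for i, k in enumerate(hits):
        if k:
            genotypes[i, rng.choice(n_loci, size=k, replace=False)] = 1
    return PopulationSample(
        pool.round_label, genotypes,
        mating_types=None if pool.mating_types is None else pool.mating_types.copy(),
    )


def founder_pool(
    catalogue: LocusCatalogue,
    config: SimulationConfig,
    founder_loci: Sequence[str],
    founder_frequency: float,
    rng: np.random.Generator,
    background_rate: Optional[float] = None,
    label: str = "UV",
) -> PopulationSample:
    """A UV pool in which one multi-mutation clone holds a set frequency.

    The founder clone carries alt alleles exactly at ``founder_loci``
    (both mating types, as the study's clone appeared in pools of each);
    the rest of the pool is independently mutagenized at
    ``background_rate`` (default: the config's UV rate).
    """
    if not 0 <= founder_frequency <= 1:
        raise ValueError("founder_frequency must lie in [0, 1]")
    n = config.population_size
    bg_cfg = config if background_rate is None else replace(config, uv_mutation_rate=background_rate)
    pool = uv_mutagenize(wild_type_pool(catalogue, n, label), catalogue, bg_cfg, rng)
    n_founder = int(round(founder_frequency * n))
    if n_founder:
        clone = np.zeros(len(catalogue), dtype=np.uint8)
        clone[[catalogue.index(l) for l in founder_loci]] = 1
        idx = rng.choice(n, size=n_founder, replace=False)
        pool.genotypes[idx] = clone
    return pool


# ---------------------------------------------------------------------------
# Selection
# ---------------------------------------------------------------------------

def population_fitness(
    pop: PopulationSample,
    catalogue: LocusCatalogue,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Additive fitness per member: sum of effect sizes over alt doses.

    Diploid heterozygotes contribute ``dominance * effect``; homozygous
    alt contributes the full effect.  Haploids contribute 0/1 doses.
    """
    doses = pop.allele_doses()
    if pop.ploidy == 1:
        w = doses @ catalogue.effect_sizes
    else:
        contrib = np.where(
            doses == 2, 1.0, np.where(doses == 1, catalogue.dominances, 0.0)
        )
        w = contrib @ catalogue.effect_sizes
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        w = w + rng.normal(0.0, noise_sd, size=w.shape)
    return w


def select_population(
    pop: PopulationSample,
    catalogue: LocusCatalogue,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> PopulationSample:
    """Truncation selection: keep the fittest fraction, resample to size.

    Models scraping growth above the wild-type frontier on a gradient
    plate.  Ties (e.g. all-neutral catalogues with zero noise) are broken
    uniformly at random; the survivors are multinomially resampled back
    to the configured population size.
    """
    w = population_fitness(pop, catalogue, config.fitness_noise_sd, rng)
    n = pop.n_members
    k = max(1, int(np.ceil(config.selection_fraction * n)))
    order = np.lexsort((rng.random(n), -w))  # random tie-break, fittest first
    kept = order[:k]
    resampled = kept[rng.integers(0, k, size=config.population_size)]
    return pop.take(resampled)


# ---------------------------------------------------------------------------
# Mating and meiosis
# ---------------------------------------------------------------------------

def _paired_indices(
    a_idx: np.ndarray, alpha_idx: np.ndarray, tags: Optional[np.ndarray],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair MATa with MATalpha members, preferring shared meiosis tags."""
    pairs_a, pairs_alpha = [], []
    rest_a, rest_alpha = a_idx, alpha_idx
    if tags is not None:
        rest_a_list, rest_alpha_list = [], []
        groups: dict[int, tuple[list, list]] = {}
        for i in a_idx:
            t = int(tags[i])
            if t >= 0:
                groups.setdefault(t, ([], []))[0].append(i)
            else:
                rest_a_list.append(i)
        for i in alpha_idx:
            t = int(tags[i])
            if t >= 0:
                groups.setdefault(t, ([], []))[1].append(i)
            else:
                rest_alpha_list.append(i)
        for t, (ga, galpha) in groups.items():
            m = min(len(ga), len(galpha))
            ga, galpha = list(ga), list(galpha)
            rng.shuffle(ga)
            rng.shuffle(galpha)
            pairs_a.extend(ga[:m])
            pairs_alpha.extend(galpha[:m])
            rest_a_list.extend(ga[m:])
            rest_alpha_list.extend(galpha[m:])
        rest_a = np.array(rest_a_list, dtype=np.int64)
        rest_alpha = np.array(rest_alpha_list, dtype=np.int64)
    rest_a = rng.permutation(rest_a)
    rest_alpha = rng.permutation(rest_alpha)
    m = min(len(rest_a), len(rest_alpha))
    pairs_a.extend(rest_a[:m].tolist())
    pairs_alpha.extend(rest_alpha[:m].tolist())
    return np.array(pairs_a, dtype=np.int64), np.array(pairs_alpha, dtype=np.int64)


def mate_pool(pool: PopulationSample, rng: np.random.Generator,
              round_label: Optional[str] = None) -> PopulationSample:
    """Random pool-wise mating without replacement.

    MATa cells pair with MATalpha cells (sister spores from a selfing-
    tagged tetrad pair preferentially); the surplus of the majority
    mating type is discarded — plate mating has no replacement mechanism.
    """
    if pool.ploidy != 1:
        raise ValueError("mate_pool expects a haploid pool")
    a_idx = np.flatnonzero(pool.mating_types == MATING_TYPE_A)
    alpha_idx = np.flatnonzero(pool.mating_types == MATING_TYPE_ALPHA)
    if len(a_idx) == 0 or len(alpha_idx) == 0:
        raise ValueError("mating requires both mating types in the pool")
    pa, palpha = _paired_indices(a_idx, alpha_idx, pool.meiosis_tags, rng)
    genotypes = np.stack([pool.genotypes[pa], pool.genotypes[palpha]], axis=1)
    return PopulationSample(round_label or pool.round_label, genotypes)


def haldane_recombination_fraction(distance_cm) -> np.ndarray:
    """Map distance (cM) -> recombinant fraction, r = (1 - e^(-2d))/2."""
    d_morgans = np.asarray(distance_cm, dtype=float) / 100.0
    return 0.5 * (1.0 - np.exp(-2.0 * d_morgans))


def _adjacent_switch_probs(catalogue: LocusCatalogue, order: np.ndarray) -> np.ndarray:
    """P(phase switch) between consecutive map-ordered loci.

    Within a chromosome this is the Haldane recombinant fraction of the
    interval; across a chromosome boundary assortment is independent
    (probability 1/2).
    """
    chrom = catalogue.chromosomes[order]
    pos = catalogue.map_positions[order]
    same = chrom[1:] == chrom[:-1]
    r = haldane_recombination_fraction(np.diff(pos))
    return np.where(same, r, 0.5)


def _gamete_phases(n_gametes: int, switch_probs: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Sample haplotype-phase vectors (0/1 per locus, map order).

    Equivalent to dropping Poisson crossovers on the map: the phase is a
    two-state Markov chain whose per-interval switch probability is the
    Haldane recombinant fraction.
    """
    n_loci = len(switch_probs) + 1
    flips = np.empty((n_gametes, n_loci), dtype=np.int8)
    flips[:, 0] = rng.integers(0, 2, size=n_gametes)
    flips[:, 1:] = rng.random((n_gametes, n_loci - 1)) < switch_probs
    return np.cumsum(flips, axis=1) % 2


def sporulate_pool(
    pool: PopulationSample,
    catalogue: LocusCatalogue,
    config: SimulationConfig,
    rng: np.random.Generator,
    round_label: Optional[str] = None,
) -> PopulationSample:
    """Meiosis: each diploid yields a tetrad of four haploid spores.

    Two independent crossover phase patterns are drawn per diploid; each
    pattern yields a gamete and its complementary sister, so every tetrad
    segregates 2:2 at each locus.  Spores get alternating mating types
    (two a, two alpha).  With probability ``selfing_probability`` a
    tetrad is tagged so the next mating preferentially pairs its sisters,
    modelling insufficiently segregated spores.
    """
    if pool.ploidy != 2:
        raise ValueError("sporulate_pool expects a diploid pool")
    n = pool.n_members
    order = catalogue.map_order()
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    switch = _adjacent_switch_probs(catalogue, order)

    hap1 = pool.genotypes[:, 0, :][:, order]
    hap2 = pool.genotypes[:, 1, :][:, order]
    spores = np.empty((n, 4, len(order)), dtype=np.uint8)
    for j in range(2):  # two crossover patterns -> two sister pairs
        phases = _gamete_phases(n, switch, rng)
        spores[:, 2 * j, :] = np.where(phases == 0, hap1, hap2)
        spores[:, 2 * j + 1, :] = np.where(phases == 0, hap2, hap1)
    spores = spores[:, :, inverse].reshape(n * 4, len(order))

    mating = np.tile(
        np.array([MATING_TYPE_A, MATING_TYPE_ALPHA] * 2, dtype=np.uint8), n
    )
    selfing = rng.random(n) < config.selfing_probability
    tags = np.where(selfing, np.arange(n), -1).astype(np.int64)
    tags = np.repeat(tags, 4)
    return PopulationSample(
        round_label or pool.round_label, spores, mating_types=mating, meiosis_tags=tags
    )


# ---------------------------------------------------------------------------
# The full protocol
# ---------------------------------------------------------------------------

def run_gs_rounds(
    config: SimulationConfig,
    catalogue: LocusCatalogue,
    rng: Optional[np.random.Generator] = None,
    initial_pool: Optional[PopulationSample] = None,
) -> list[PopulationSample]:
    """Run UV mutagenesis plus ``config.rounds`` rounds of shuffling.

    Returns the archived samples: the (haploid) UV pool, then one diploid
    sample per round, labelled R1..Rn — the pools that are plated,
    screened and frozen between rounds.  Each round is: screen the spore
    pool, mate, screen the shuffled diploids, archive, sporulate.
    """
    if rng is None:
        rng = config.rng()
    if initial_pool is None:
        pool = wild_type_pool(catalogue, config.population_size, "UV")
        pool = uv_mutagenize(pool, catalogue, config, rng)
        for _ in range(config.founder_boost):
            pool = select_population(pool, catalogue, config, rng)
    else:
        if initial_pool.ploidy != 1:
            raise ValueError("initial_pool must be haploid")
        pool = initial_pool.take(np.arange(initial_pool.n_members), round_label="UV")
    samples = [pool]
    for r in range(1, config.rounds + 1):
        label = f"R{r}"
        selected = select_population(pool, catalogue, config, rng)
        diploids = mate_pool(selected, rng, round_label=label)
        diploids = select_population(diploids, catalogue, config, rng)
        samples.append(diploids)
        if r < config.rounds:
            pool = sporulate_pool(diploids, catalogue, config, rng, round_label=label)
    return samples


# ---------------------------------------------------------------------------
# Observation layers
# ---------------------------------------------------------------------------

def simulate_amplicon_counts(
    pop: PopulationSample,
    catalogue: LocusCatalogue,
    mean_coverage: float,
    error_rate: float,
    rng: np.random.Generator,
    qual_central: tuple[float, float] = (45.0, 2.0),
    qual_flank: tuple[float, float] = (36.0, 2.0),
) -> pd.DataFrame:
    """Pooled amplicon sequencing of every catalogue locus.

    Coverage is Poisson(mean_coverage) per locus; each read reports the
    alt allele with probability p(1-e) + (1-p)e/3, where p is the pooled
    alt frequency and e the per-base error rate (a miscalled base hits a
    specific wrong nucleotide a third of the time).  Phred-like quality
    summaries are drawn from clipped normals given as (mean, sd).
    """
    if mean_coverage <= 0:
        raise ValueError("mean_coverage must be > 0")
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must lie in [0, 1)")
    p = pop.allele_frequencies()
    coverage = rng.poisson(mean_coverage, size=len(p))
    p_obs = p * (1.0 - error_rate) + (1.0 - p) * error_rate / 3.0
    alt = rng.binomial(coverage, p_obs)
    qc = np.clip(rng.normal(*qual_central, size=len(p)), 0, None)
    qf = np.clip(rng.normal(*qual_flank, size=len(p)), 0, None)
    return pd.DataFrame(
        {
            "sample": pop.round_label,
            "locus_id": catalogue.ids,
            "total_reads": coverage,
            "alt_reads": alt,
            "qual_central": np.round(qc, 1),
            "qual_flank_min": np.round(qf, 1),
        }
    )


def simulate_isolates(
    pop: PopulationSample,
    catalogue: LocusCatalogue,
    n: int,
    fitness_bias: float,
    rng: np.random.Generator,
    label_prefix: Optional[str] = None,
) -> IsolateGenotypeMatrix:
    """Pick n diploid isolates, biased toward high fitness, and genotype them.

    Isolates are drawn without replacement with probability proportional
    to exp(fitness_bias * w); fitness_bias 0 is a uniform draw (random
    colonies), larger values model picking from the frontier of growth.
    """
    if pop.ploidy != 2:
        raise ValueError("simulate_isolates expects a diploid population")
    if n <= 0:
        raise ValueError("n must be positive")
    if n > pop.n_members:
        raise ValueError(f"cannot draw {n} isolates from {pop.n_members} members")
    if fitness_bias < 0:
        raise ValueError("fitness_bias must be >= 0")
    w = population_fitness(pop, catalogue)
    logits = fitness_bias * w
    probs = np.exp(logits - logits.max())
    probs /= probs.sum()
    idx = rng.choice(pop.n_members, size=n, replace=False, p=probs)
    doses = pop.allele_doses()[idx]
    calls = np.full(doses.shape, "none", dtype=object)
    calls[doses == 1] = "het"
    calls[doses == 2] = "homo"
    prefix = label_prefix or pop.round_label
    labels = [f"{prefix}-{chr(ord('a') + i) if i < 26 else i + 1}" for i in range(n)]
    return IsolateGenotypeMatrix(
        pd.DataFrame(calls, index=labels, columns=catalogue.ids)
    )


def true_frequency_table(samples: Sequence[PopulationSample],
                         catalogue: LocusCatalogue) -> pd.DataFrame:
    """Long-format truth table of per-round pooled allele frequencies."""
    rows = []
    for s in samples:
        freqs = s.allele_frequencies()
        for lid, f in zip(catalogue.ids, freqs):
            rows.append({"sample": s.round_label, "locus_id": lid, "true_frequency": f})
    return pd.DataFrame(rows)
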