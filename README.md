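# gshuffle

Tools for deconstructing the genetics of **genome-shuffled microbial
populations**: a forward-time simulator of recursive breeding under
selection, a pooled-sequencing allele-frequency caller with
false-positive filtering, codon-level mutation annotation, and
trajectory analysis that separates productive driver mutations from
hitchhiking passengers.

## The problem

Genome shuffling (GS) evolves a complex trait — here, yeast tolerance to
an inhibitory lignocellulosic substrate — by UV-mutagenizing a haploid
pool, screening it on gradient plates, then recursively mating the
survivors (*MAT*a × *MAT*α), screening the shuffled diploids, and
sporulating them into the next round. Resequencing an evolved clone
yields a catalogue of point mutations, but not their importance. Deep
amplicon sequencing of the *archived pools* does: the frequency of reads
carrying each mutation, `f = alt_reads / total_reads`, tracked per round,
reveals which alleles selection amplifies and which merely hitchhiked in
from a founder clone and are crossed out by recombination.

The package implements the quantitative machinery of that analysis:

- **Simulator** — binary allele vectors over a locus catalogue; additive
  fitness `w = Σᵢ sᵢ·xᵢ` (heterozygotes scaled by dominance `hᵢ`) with
  Gaussian noise and truncation selection; random pool mating without
  replacement; meiosis under the **Haldane model**, where the
  recombinant fraction at map distance *d* Morgans is
  `r = (1 − e^(−2d))/2`; binomial read sampling at Poisson coverage with
  a per-base error `e` (observed fraction `p(1−e) + (1−p)e/3`); and
  Sanger-style genotyping of picked diploid isolates.
- **Caller** — pooled frequency with a 1% detection threshold; the
  dual-sample filter (call at evolved fraction ≥ 0.35 with base
  qualities ≥ 40 central / ≥ 30 flanking, discard as a false positive
  when the wild-type control shows the variant in ≥ 10% of reads);
  zygosity bands for clonal samples.
- **Effects** — codon translation of CDS substitutions
  (missense/silent) and the SIFT rule (score ≤ 0.05 ⇒ predicted to
  affect function).
- **Trajectories** — trend labels (rising / falling / transient /
  stable / not detected), single-linkage **co-origin clustering** of
  starting-pool frequencies (loci born in one founder clone share its
  frequency), reconciliation of pool estimates against isolate allele
  counts `(2·n_homo + n_het)/(2N)`, and candidate ranking.

A 21-mutation catalogue from a GS-evolved tolerant strain ships with the
package and drives annotation and the default simulation scenario.

## Worked example

```bash
gshuffle run --seed 7 --out out/
```

simulates five GS rounds over the packaged catalogue, sequences the
archived UV/R1/R3/R5 pools at 1.35×10⁵ reads per locus, genotypes 20
isolates and one deep-sequenced clone, and writes the full report
(frequency matrix, trajectories, clusters, ranking, variant TSV+VCF,
`summary.json`). The catalogue summary it prints:

```json
{
  "total": 21, "orf_snps": 16, "orf_genes": 12,
  "missense": 14, "silent": 2, "non_orf": 5,
  "homozygous": 2, "sift_affects_function": 10, "sift_tolerated": 4
}
```

i.e. 21 point mutations, 16 of them in 12 ORFs (14 missense, 2 silent),
5 in UTR/intergenic regions, 2 homozygous; 10 of the 14 scored missense
changes are predicted to affect protein function. The trajectory table
(first lines):

```
locus_id    trend   first_frequency  final_frequency
NRG1_137    rising  0.642            0.997
UBP7_2466   rising  0.823            0.997
ART5_454    rising  0.598            0.997
```

and the isolate reconciliation reports a mean absolute deviation of
0.013 between pool-sequencing and 20-isolate Sanger frequencies with a
rank correlation of 0.94 — single colonies recover the pool picture.
Same seed, same config ⇒ byte-identical outputs.

Subcommands `simulate`, `callfreq`, `filter`, `annotate` and
`trajectory` expose the individual stages on TSV inputs; see
`gshuffle --help`.

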