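"""Mutation catalogue: records, loading, validation and summary counts.

The catalogue is the set of point mutations discovered by resequencing a
genome-shuffled (GS) evolved diploid yeast strain against its wild-type
parent.  Each record carries the affected gene, the region class of the
change (coding, 5'/3' UTR, or intergenic when the affected gene is
ambiguous), the nucleotide substitution in CDS-relative or offset
coordinates, the zygosity observed in the evolved clone, and — for
missense changes — a SIFT conservation score.

A companion locus table (:class:`LocusCatalogue`) gives the same sites a
genetic-map embedding (chromosome, centimorgan position) plus the fitness
parameters (effect size, dominance) used by the forward simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MutationRecord",
    "Locus",
    "LocusCatalogue",
    "load_mutation_catalogue",
    "summarize_catalogue",
    "default_locus_catalogue",
    "roman_to_int",
    "CatalogueError",
]

REGIONS = ("CDS", "UTR5", "UTR3", "intergenic")
ZYGOSITIES = ("homo", "het")
_NUCLEOTIDES = set("ACGT")

_ROMAN = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100}


class CatalogueError(ValueError):
    """Raised for malformed catalogue files or invalid records."""


def roman_to_int(label: str) -> int:
    """Convert a roman-numeral chromosome label (I..XVI) to an integer."""
    s = label.strip().upper()
    if s.isdigit():
        return int(s)
    total, prev = 0, 0
    for ch in reversed(s):
        if ch not in _ROMAN:
            raise CatalogueError(f"not a roman numeral: {label!r}")
        v = _ROMAN[ch]
        total = total - v if v < prev else total + v
        prev = max(prev, v)
    if total <= 0:
        raise CatalogueError(f"not a roman numeral: {label!r}")
    return total


@dataclass(frozen=True)
class MutationRecord:
    """One catalogued point mutation.

    ``position`` is a 1-based CDS coordinate for coding records, and an
    unsigned offset in bp (with ``direction`` giving upstream/downstream
    of the named gene) for UTR and intergenic records.
    """

    gene: str
    chromosome: str
    region: str
    position: int
    ref: Optional[str]
    alt: Optional[str]
    protein_change: Optional[str]
    zygosity: str
    sift_score: Optional[float] = None
    group_tag: Optional[str] = None
    direction: Optional[str] = None

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise CatalogueError(f"{self.gene}: unknown region {self.region!r}")
        if self.zygosity not in ZYGOSITIES:
            raise CatalogueError(f"{self.gene}: unknown zygosity {self.zygosity!r}")
        if self.position < 1:
            raise CatalogueError(f"{self.gene}: position must be >= 1")
        for allele, name in ((self.ref, "ref"), (self.alt, "alt")):
            if allele is not None and allele not in _NUCLEOTIDES:
                raise CatalogueError(f"{self.gene}: bad {name} allele {allele!r}")
        if self.ref is not None and self.alt is not None and self.ref == self.alt:
            raise CatalogueError(f"{self.gene}: ref and alt alleles are identical")
        if self.region == "CDS":
            if not self.protein_change:
                raise CatalogueError(f"{self.gene}: CDS record lacks protein_change")
            if self.ref is None or self.alt is None:
                raise CatalogueError(f"{self.gene}: CDS record lacks ref/alt alleles")
        elif self.protein_change:
            raise CatalogueError(
                f"{self.gene}: non-CDS record carries protein_change {self.protein_change!r}"
            )
        if self.sift_score is not None:
            if not self.is_missense:
                raise CatalogueError(f"{self.gene}: SIFT score on a non-missense record")
            if not 0.0 <= self.sift_score <= 1.0:
                raise CatalogueError(f"{self.gene}: SIFT score outside [0, 1]")

    @property
    def is_orf(self) -> bool:
        return self.region == "CDS"

    @property
    def is_missense(self) -> bool:
        return self.is_orf and self.protein_change != "silent"

    @property
    def is_silent(self) -> bool:
        return self.is_orf and self.protein_change == "silent"

    @property
    def locus_id(self) -> str:
        return f"{self.gene}_{self.position}"


def _cell(value: object) -> Optional[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip()
    return s if s not in ("", ".", "-", "NA") else None


def load_mutation_catalogue(path=None) -> list[MutationRecord]:
    """Load and validate a mutation-catalogue TSV.

    With no ``path`` the packaged catalogue of the GS-evolved strain is
    returned (21 records: 20 table rows plus the ambiguous intergenic
    SNP downstream of BCS1).
    """
    if path is None:
        src = resources.files("gshuffle.data").joinpath("r57_catalogue.tsv")
        with resources.as_file(src) as p:
            return load_mutation_catalogue(p)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"gene", "chromosome", "region", "position", "ref", "alt",
                "protein_change", "zygosity", "sift_score"}
    missing = required - set(df.columns)
    if missing:
        raise CatalogueError(f"catalogue missing required columns: {sorted(missing)}")
    if df.empty:
        warnings.warn("mutation catalogue is empty", stacklevel=2)
        return []
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            pos_str = _cell(d["position"])
            if pos_str is None or not pos_str.lstrip("+-").isdigit():
                raise CatalogueError(f"malformed position {d['position']!r}")
            score = _cell(d.get("sift_score"))
            records.append(
                MutationRecord(
                    gene=str(d["gene"]).strip(),
                    chromosome=str(d["chromosome"]).strip(),
                    region=str(d["region"]).strip(),
                    position=int(pos_str),
                    ref=_cell(d["ref"]),
                    alt=_cell(d["alt"]),
                    protein_change=_cell(d["protein_change"]),
                    zygosity=str(d["zygosity"]).strip(),
                    sift_score=float(score) if score is not None else None,
                    group_tag=_cell(d.get("group_tag")),
                    direction=_cell(d.get("direction")),
                )
            )
        except CatalogueError as exc:
            raise CatalogueError(f"row {i}: {exc}") from None
    return records


def summarize_catalogue(records: Iterable[MutationRecord], sift_threshold: float = 0.05) -> dict:
    """Count record classes across a validated catalogue.

    Returns totals, ORF/non-ORF splits, missense/silent splits, zygosity
    counts and the number of missense records whose SIFT score predicts
    an effect on protein function (score <= ``sift_threshold``).
    """
    recs = list(records)
    orf = [r for r in recs if r.is_orf]
    missense = [r for r in recs if r.is_missense]
    scored = [r for r in missense if r.sift_score is not None]
    return {
        "total": len(recs),
        "orf_snps": len(orf),
        "orf_genes": len({r.gene for r in orf}),
        "missense": len(missense),
        "silent": sum(r.is_silent for r in recs),
        "non_orf": sum(not r.is_orf for r in recs),
        "utr": sum(r.region in ("UTR5", "UTR3") for r in recs),
        "intergenic": sum(r.region == "intergenic" for r in recs),
        "homozygous": sum(r.zygosity == "homo" for r in recs),
        "heterozygous": sum(r.zygosity == "het" for r in recs),
        "sift_scored": len(scored),
        "sift_affects_function": sum(r.sift_score <= sift_threshold for r in scored),
        "sift_tolerated": sum(r.sift_score > sift_threshold for r in scored),
    }


# ---------------------------------------------------------------------------
# Simulator locus catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Locus:
    """A tracked site on the simulator's genetic map.

    ``effect_size`` is the additive fitness increment of the alt allele
    (per haploid dose; heterozygotes are scaled by ``dominance``).
    """

    id: str
    chromosome: int
    map_position: float  # centimorgans
    ref_allele: str
    alt_allele: str
    region: str = "CDS"
    effect_size: float = 0.0
    dominance: float = 0.5

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise CatalogueError(f"{self.id}: ref and alt alleles are identical")
        if self.map_position < 0:
            raise CatalogueError(f"{self.id}: map_position must be >= 0")
        if self.region not in REGIONS:
            raise CatalogueError(f"{self.id}: unknown region {self.region!r}")
        if not 0.0 <= self.dominance <= 1.0:
            raise CatalogueError(f"{self.id}: dominance must lie in [0, 1]")


class LocusCatalogue:
    """Ordered collection of loci with cached numpy views.

    Loci on the same chromosome must have distinct map positions; ids
    must be unique.  The stored order is the allele-vector order used by
    every genome in the simulator.
    """

    def __init__(self, loci: Sequence[Locus]):
        loci = list(loci)
        ids = [l.id for l in loci]
        if len(set(ids)) != len(ids):
            raise CatalogueError("duplicate locus ids in catalogue")
        seen = set()
        for l in loci:
            key = (l.chromosome, l.map_position)
            if key in seen:
                raise CatalogueError(
                    f"{l.id}: duplicate map position {l.map_position} on chromosome {l.chromosome}"
                )
            seen.add(key)
        self.loci = loci
        self.ids = ids
        self.chromosomes = np.array([l.chromosome for l in loci], dtype=np.int32)
        self.map_positions = np.array([l.map_position for l in loci], dtype=float)
        self.effect_sizes = np.array([l.effect_size for l in loci], dtype=float)
        self.dominances = np.array([l.dominance for l in loci], dtype=float)
        self._index = {lid: i for i, lid in enumerate(ids)}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[Locus]:
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> Locus:
        return self.loci[self._index[locus_id]]

    def index(self, locus_id: str) -> int:
        return self._index[locus_id]

    def map_order(self) -> np.ndarray:
        """Indices sorting loci by (chromosome, map position)."""
        return np.lexsort((self.map_positions, self.chromosomes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "chromosome": self.chromosomes,
                "map_position_cM": self.map_positions,
                "ref": [l.ref_allele for l in self.loci],
                "alt": [l.alt_allele for l in self.loci],
                "region": [l.region for l in self.loci],
                "effect_size": self.effect_sizes,
                "dominance": self.dominances,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "LocusCatalogue":
        df = pd.read_csv(path, sep="\t", comment="#")
        loci = [
            Locus(
                id=str(r.id),
                chromosome=int(r.chromosome),
                map_position=float(r.map_position_cM),
                ref_allele=str(r.ref),
                alt_allele=str(r.alt),
                region=str(r.region),
                effect_size=float(r.effect_size),
                dominance=float(r.dominance),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(loci)


# Fitness parameters for the default simulated study condition: alleles the
# evolved-pool sequencing showed rising get positive effects (the validated
# deubiquitinase driver the largest), clone-linked passengers that fell are
# mildly deleterious, silent partners are neutral and tightly linked to
# their missense neighbour.  The transcriptional-repressor allele is nearly
# recessive (low dominance), matching its frequency dip after mating.
_DEFAULT_FITNESS = {
    # locus_id: (effect_size, dominance)
    "NRG1_137": (0.6, 0.1),
    "UBP7_2466": (1.0, 0.5),
    "ART5_454": (0.4, 0.5),
    "SSA1_91": (0.3, 0.5),
    "GDH1_47": (0.45, 0.5),
    "GDH1_68": (0.45, 0.5),
    "ARO1_1283": (0.4, 0.5),
    "ARO1_1284": (0.0, 0.5),
    "STE5_512": (0.3, 0.5),
    "STE5_2649": (0.0, 0.5),
    "MAL11_310": (0.3, 0.5),
    "MAL11_482": (0.3, 0.5),
    "GSH1_73": (0.5, 0.5),
    "PBP1_191": (-0.2, 0.5),
    "FIT3_42": (0.0, 0.5),
    "NOP58_25": (0.0, 0.5),
    "YNL058C_7": (-0.2, 0.5),
    "DOP1_40": (-0.1, 0.5),
    "TOF2_2141": (0.05, 0.5),
    "SGO1_575": (-0.2, 0.5),
    "BCS1_3prime_43": (-0.2, 0.5),
}

# Intra-gene offsets use ~0.35 cM/kb; unrelated genes on a chromosome are
# spread 40 cM apart so they assort nearly freely.
_GENE_SPACING_CM = 40.0
_CM_PER_BP = 0.00035


def default_locus_catalogue(records: Optional[Sequence[MutationRecord]] = None) -> LocusCatalogue:
    """Embed the mutation catalogue on a synthetic genetic map.

    Genes are spaced 40 cM apart along their (real) chromosome in order
    of appearance; multiple mutations within one gene sit at their
    CDS-distance apart (0.35 cM/kb), so same-gene pairs are tightly
    linked.  Fitness parameters come from the default study-condition
    table.  Records lacking printed ref/alt nucleotides get placeholder
    alleles — the simulator only tracks binary allele states.
    """
    if records is None:
        records = load_mutation_catalogue()
    next_slot: dict[int, float] = {}
    gene_anchor: dict[str, tuple[int, float, int]] = {}  # gene -> (chrom, anchor cM, anchor pos)
    loci = []
    for rec in records:
        chrom = roman_to_int(rec.chromosome)
        if rec.gene in gene_anchor:
            achrom, acm, apos = gene_anchor[rec.gene]
            pos_cm = acm + abs(rec.position - apos) * _CM_PER_BP
        else:
            pos_cm = next_slot.get(chrom, 0.0)
            next_slot[chrom] = pos_cm + _GENE_SPACING_CM
            gene_anchor[rec.gene] = (chrom, pos_cm, rec.position)
        effect, dom = _DEFAULT_FITNESS.get(rec.locus_id, (0.0, 0.5))
        loci.append(
            Locus(
                id=rec.locus_id,
                chromosome=chrom,
                map_position=round(pos_cm, 6),
                ref_allele=rec.ref or "A",
                alt_allele=rec.alt or "C",
                region=rec.region,
                effect_size=effect,
                dominance=dom,
            )
        )
    return LocusCatalogue(loci)
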