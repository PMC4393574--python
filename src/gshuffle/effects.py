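"""Codon-level effect classification and SIFT-threshold prediction.

Coding changes are classified by translating the reference and mutated
codon with the standard genetic code: a substitution is *silent* when
the amino acid is unchanged and *missense* otherwise.  CDS coordinates
are 1-based on the coding strand with the start codon occupying
positions 1-3.

SIFT scores (conservation-based predictions of substitution impact) are
inputs, never computed here; the classification rule is the standard
one: a score of at most 0.05 predicts an effect on protein function.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq
from Bio import SeqIO

from .catalogue import MutationRecord

__all__ = [
    "EffectClass",
    "classify_coding_change",
    "sift_classify",
    "synthesize_gene_cds",
    "synthesize_cds_fasta",
    "read_cds_fasta",
    "SIFT_THRESHOLD",
]

SIFT_THRESHOLD = 0.05
_BASES = "ACGT"
_FILLER_CODON = "GCT"  # alanine


@dataclass(frozen=True)
class EffectClass:
    kind: str  # "missense" | "silent"
    codon_index: int  # 1-based
    aa_ref: str
    aa_alt: str

    def __post_init__(self):
        if (self.kind == "silent") != (self.aa_ref == self.aa_alt):
            raise ValueError("kind 'silent' requires aa_ref == aa_alt and vice versa")

    @property
    def protein_change(self) -> str:
        if self.kind == "silent":
            return "silent"
        return f"{self.aa_ref}{self.codon_index}{self.aa_alt}"


def classify_coding_change(cds: str, position: int, ref: str, alt: str) -> EffectClass:
    """Classify a single-base substitution within a CDS.

    ``position`` is 1-based; ``cds`` must be a whole number of codons and
    must carry ``ref`` at the given position.
    """
    cds = str(cds).upper()
    ref, alt = ref.upper(), alt.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if not 1 <= position <= len(cds):
        raise ValueError(f"position {position} outside CDS of length {len(cds)}")
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    found = cds[position - 1]
    if found != ref:
        raise ValueError(
            f"reference mismatch at CDS position {position}: expected {ref}, found {found}"
        )
    codon_index = (position - 1) // 3 + 1
    start = (codon_index - 1) * 3
    codon = cds[start:start + 3]
    mutated = codon[: (position - 1) % 3] + alt + codon[(position - 1) % 3 + 1:]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    kind = "silent" if aa_ref == aa_alt else "missense"
    return EffectClass(kind=kind, codon_index=codon_index, aa_ref=aa_ref, aa_alt=aa_alt)


def sift_classify(score: float) -> str:
    """Apply the SIFT phenotype rule: <= 0.05 predicts altered function."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"SIFT score {score} outside [0, 1]")
    return "affects_function" if score <= SIFT_THRESHOLD else "tolerated"


# ---------------------------------------------------------------------------
# Synthetic CDS construction
#
# The catalogue states CDS-relative substitutions and their protein
# consequences, but not the gene sequences themselves.  For testing the
# classifier we build minimal synthetic CDSs whose affected codons are
# chosen (by exhaustive search over the 64 codons) to reproduce every
# stated substitution, including multiple mutations within one codon.
# ---------------------------------------------------------------------------

def _parse_protein_change(rec: MutationRecord) -> tuple[Optional[str], Optional[str], int]:
    """Return (aa_ref, aa_alt, codon_index); amino acids None for silent."""
    codon_index = (rec.position - 1) // 3 + 1
    if rec.protein_change == "silent":
        return None, None, codon_index
    pc = rec.protein_change
    aa_ref, aa_alt = pc[0], pc[-1]
    stated = int(pc[1:-1])
    if stated != codon_index:
        raise ValueError(
            f"{rec.gene}: protein change {pc} inconsistent with CDS position "
            f"{rec.position} (codon {codon_index})"
        )
    return aa_ref, aa_alt, codon_index


def _solve_codon(constraints) -> str:
    """Find a codon satisfying all (offset, ref, alt, aa_ref, aa_alt) constraints.

    ``aa_ref``/``aa_alt`` of None means the substitution must be silent.
    """
    for codon in ("".join(p) for p in product(_BASES, repeat=3)):
        aa = str(Seq(codon).translate())
        ok = True
        for offset, ref, alt, aa_ref, aa_alt in constraints:
            if codon[offset] != ref:
                ok = False
                break
            mutated = codon[:offset] + alt + codon[offset + 1:]
            aa_mut = str(Seq(mutated).translate())
            if aa_ref is None:  # silent
                if aa_mut != aa:
                    ok = False
                    break
            elif aa != aa_ref or aa_mut != aa_alt:
                ok = False
                break
        if ok:
            return codon
    raise ValueError(f"no codon satisfies constraints {constraints}")


def synthesize_gene_cds(records: Sequence[MutationRecord]) -> str:
    """Build a minimal CDS consistent with all CDS records of one gene."""
    recs = [r for r in records if r.region == "CDS"]
    if not recs:
        raise ValueError("no CDS records supplied")
    genes = {r.gene for r in recs}
    if len(genes) != 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    by_codon: dict[int, list] = {}
    for rec in recs:
        aa_ref, aa_alt, codon_index = _parse_protein_change(rec)
        offset = (rec.position - 1) % 3
        by_codon.setdefault(codon_index, []).append((offset, rec.ref, rec.alt, aa_ref, aa_alt))
    n_codons = max(by_codon) + 1  # one spare codon past the last mutation
    codons = [_FILLER_CODON] * n_codons
    codons[0] = "ATG"
    for codon_index, constraints in by_codon.items():
        if codon_index == 1 and constraints:
            raise ValueError("cannot place a mutation in the start codon of a synthetic CDS")
        codons[codon_index - 1] = _solve_codon(constraints)
    return "".join(codons)


def synthesize_cds_fasta(records: Iterable[MutationRecord], path) -> dict[str, str]:
    """Write synthetic CDSs for every gene with coding records to FASTA.

    Returns the gene -> sequence mapping that was written.  Sequences are
    synthetic minimal constructs, not the organism's genes.
    """
    by_gene: dict[str, list[MutationRecord]] = {}
    for rec in records:
        if rec.region == "CDS":
            by_gene.setdefault(rec.gene, []).append(rec)
    seqs = {gene: synthesize_gene_cds(recs) for gene, recs in sorted(by_gene.items())}
    with open(path, "w") as fh:
        for gene, seq in seqs.items():
            fh.write(f">{gene} synthetic minimal CDS\n{seq}\n")
    return seqs


def read_cds_fasta(path) -> dict[str, str]:
    """Read a CDS FASTA into a gene -> sequence mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
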