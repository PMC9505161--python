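"""Core domain types shared across the pipeline.

Coordinates are 1-based and intervals are closed (GFF3 convention)
throughout. Base counts are always expressed in reference plus-strand
base space; ``fwd``/``rev`` on RNA pools refer to the orientation of the
transcript relative to the reference plus strand (the strand-specific
protocol is resolved upstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np

BASES = ("A", "C", "G", "T")
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


class ValidationError(ValueError):
    """Raised when parsed data violates a domain invariant."""


def complement(base: str) -> str:
    return COMPLEMENT[base]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


@dataclass
class GenomeRecord:
    """A plastome (or contig) sequence.

    Plastomes are typically circular; positions are linearised on the
    deposited sequence and features spanning the origin are represented
    as split exons.
    """

    id: str
    sequence: str
    circular: bool = True
    has_ambiguous: bool = False

    def __post_init__(self) -> None:
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(
                f"genome {self.id!r}: non-nucleotide character(s) {sorted(bad)}"
            )
        if "N" in self.sequence:
            self.has_ambiguous = True

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based position, with circular wrap-around."""
        if self.circular:
            return self.sequence[(pos - 1) % self.length]
        if not 1 <= pos <= self.length:
            raise IndexError(f"position {pos} outside linear genome of length {self.length}")
        return self.sequence[pos - 1]


@dataclass
class GeneModel:
    """A gene with ordered exons on one strand of the plastome."""

    gene_id: str
    biotype: str  # CDS, tRNA or rRNA
    strand: str  # '+' or '-'
    exons: list  # list of (start, end), 1-based closed, ascending
    codon_start: int = 1
    partial: bool = False

    def __post_init__(self) -> None:
        if self.biotype not in ("CDS", "tRNA", "rRNA"):
            raise ValidationError(f"{self.gene_id}: unknown biotype {self.biotype!r}")
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        prev_end = 0
        for start, end in self.exons:
            if start <= prev_end:
                raise ValidationError(f"{self.gene_id}: overlapping or unsorted exons")
            if end < start:
                raise ValidationError(f"{self.gene_id}: exon end < start")
            prev_end = end
        if self.biotype == "CDS":
            if (self.spliced_length - (self.codon_start - 1)) % 3 != 0:
                self.partial = True

    @property
    def span(self) -> tuple:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def spliced_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def contains(self, pos: int) -> bool:
        lo, hi = self.span
        return lo <= pos <= hi

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def spliced_position(self, pos: int) -> Optional[int]:
        """1-based position of a genomic site within the spliced,
        sense-strand gene sequence, or None if the site is not exonic."""
        if not self.in_exon(pos):
            return None
        offset = 0  # 0-based along plus strand of the spliced sequence
        for s, e in self.exons:
            if s <= pos <= e:
                offset += pos - s
                break
            offset += e - s + 1
        if self.strand == "+":
            return offset + 1
        return self.spliced_length - offset

    def spliced_sequence(self, genome: GenomeRecord) -> str:
        """Sense-strand spliced sequence of the gene."""
        seq = "".join(genome.sequence[s - 1 : e] for s, e in self.exons)
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class PileupRecord:
    """Per-position DNA and strand-specific RNA base counts.

    ``*_clean`` pools exclude reads carrying an indel within the indel
    window of the position; ``*_all`` pools include them.
    """

    chrom: str
    pos: int
    ref_base: str
    dna: np.ndarray
    rna_fwd_clean: np.ndarray
    rna_rev_clean: np.ndarray
    rna_fwd_all: np.ndarray
    rna_rev_all: np.ndarray

    def __post_init__(self) -> None:
        for name in ("dna", "rna_fwd_clean", "rna_rev_clean", "rna_fwd_all", "rna_rev_all"):
            v = np.asarray(getattr(self, name), dtype=np.int64)
            if v.shape != (4,) or (v < 0).any():
                raise ValidationError(f"{self.chrom}:{self.pos}: bad count vector {name}")
            setattr(self, name, v)
        if (self.rna_fwd_clean > self.rna_fwd_all).any() or (
            self.rna_rev_clean > self.rna_rev_all
        ).any():
            raise ValidationError(f"{self.chrom}:{self.pos}: clean counts exceed all counts")
        if self.ref_base not in BASES:
            raise ValidationError(f"{self.chrom}:{self.pos}: bad ref base {self.ref_base!r}")


# Column order of the site-table TSV; round-trips losslessly.
SITE_TABLE_COLUMNS = [
    "chrom", "pos", "strand", "type", "efficiency", "dna_depth", "rna_depth",
    "p_value", "rescued", "region", "gene_id", "site_label", "codon_pos",
    "ref_codon", "edit_codon", "aa_ref", "aa_edit", "synonymous",
    "hydropathy", "context",
]


@dataclass
class EditingSite:
    """A called RNA-editing site, expressed on the transcribed strand."""

    chrom: str
    pos: int
    strand: str  # transcribed strand, '+' or '-'
    ref_sense: str
    edit_sense: str
    efficiency: float
    dna_depth: int
    rna_depth: int
    p_value: float
    rescued: bool = False
    gta_supported: bool = False
    ambiguous_strand: bool = False
    antisense_candidate: bool = False
    # annotation fields (site_annotator)
    region: Optional[str] = None
    gene_id: Optional[str] = None
    site_label: Optional[str] = None
    codon_pos: Optional[int] = None
    ref_codon: Optional[str] = None
    edit_codon: Optional[str] = None
    aa_ref: Optional[str] = None
    aa_edit: Optional[str] = None
    synonymous: Optional[bool] = None
    hydropathy: Optional[str] = None
    context: Optional[str] = None

    @property
    def type(self) -> str:
        """Editing type on the transcribed strand, with T written as U."""
        u = {"T": "U"}
        return f"{u.get(self.ref_sense, self.ref_sense)}-to-{u.get(self.edit_sense, self.edit_sense)}"

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValidationError(f"{self.chrom}:{self.pos}: efficiency outside [0,1]")
        if self.strand not in "+-":
            raise ValidationError(f"{self.chrom}:{self.pos}: bad strand")
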