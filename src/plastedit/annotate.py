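"""Genomic-context and coding-consequence annotation of editing sites.

Region assignment, gene-relative site labels ("<gene>-<spliced pos>"),
codon position and amino-acid change under the plastid/bacterial genetic
code (NCBI table 11), hydropathy transitions under a configurable
two-class partition of the residues, and flanking-context extraction
with position-frequency aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .core import BASES, EditingSite, GeneModel, GenomeRecord, ValidationError, revcomp

log = logging.getLogger(__name__)

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]

# precedence when features overlap
_REGION_ORDER = ["CDS", "tRNA", "rRNA"]


@dataclass(frozen=True)
class HydropathyScheme:
    """Two-class partition of the 20 amino acids.

    The default places P and G with the hydrophobics, so that Ser->Leu
    is a hydrophilic->hydrophobic transition and Pro->Leu maintains
    hydrophobicity. Stop codons are their own category.
    """

    hydrophobic: frozenset = frozenset("ACFGILMPVW")

    def __post_init__(self) -> None:
        rest = set("ACDEFGHIKLMNPQRSTVWY") - set(self.hydrophobic)
        object.__setattr__(self, "_hydrophilic", frozenset(rest))

    def klass(self, aa: str) -> str:
        if aa == "*":
            return "stop"
        if aa in self.hydrophobic:
            return "phob"
        if aa in self._hydrophilic:
            return "phil"
        raise ValidationError(f"unknown amino-acid symbol {aa!r}")


DEFAULT_SCHEME = HydropathyScheme()


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def hydropathy_change(aa_ref: str, aa_edit: str,
                      scheme: HydropathyScheme = DEFAULT_SCHEME) -> str:
    """Transition label for an amino-acid change."""
    if aa_edit == "*" and aa_ref != "*":
        return "stop-gain"
    if aa_ref == "*" and aa_edit != "*":
        return "stop-loss"
    if aa_ref == aa_edit:
        return "maintained"
    a, b = scheme.klass(aa_ref), scheme.klass(aa_edit)
    if a == b:
        return "maintained"
    return f"{a}->{b}"


def locate(site: EditingSite, genes: List[GeneModel]) -> EditingSite:
    """Assign region (CDS > tRNA > rRNA > intron > intergenic), gene and
    spliced-position label."""
    exonic = [g for g in genes if g.in_exon(site.pos)]
    for biotype in _REGION_ORDER:
        for g in exonic:
            if g.biotype == biotype:
                site.region = biotype
                site.gene_id = g.gene_id
                site.site_label = f"{g.gene_id}-{g.spliced_position(site.pos)}"
                return site
    spanning = [g for g in genes if g.contains(site.pos)]
    if spanning:
        site.region = "intron"
        site.gene_id = spanning[0].gene_id
        site.site_label = None
        return site
    site.region = "intergenic"
    site.gene_id = None
    site.site_label = None
    return site


def codon_effect(
    site: EditingSite,
    gene: GeneModel,
    genome: GenomeRecord,
    scheme: HydropathyScheme = DEFAULT_SCHEME,
) -> EditingSite:
    """Fill codon position, ref/edit codons, amino acids, synonymy and
    hydropathy for a CDS site.

    The codon is read off the spliced sense-strand sequence; the edited
    codon substitutes the edited base. An edit whose codon becomes ATG
    is flagged start-gain (it is not re-annotated as a CDS extension).
    """
    if gene.partial:
        raise ValidationError(f"{gene.gene_id} is flagged partial; no codon annotation")
    sense = gene.spliced_sequence(genome)
    sp = gene.spliced_position(site.pos)
    if sp is None or sp > len(sense):
        raise ValidationError(f"{site.chrom}:{site.pos} beyond spliced length of {gene.gene_id}")
    if sense[sp - 1] != site.ref_sense:
        raise ValidationError(
            f"{site.chrom}:{site.pos}: sense base {sense[sp - 1]} does not match "
            f"site reference {site.ref_sense}"
        )
    offset = sp - gene.codon_start  # 0-based within the reading frame
    if offset < 0:
        raise ValidationError(f"{site.chrom}:{site.pos} upstream of reading frame")
    codon_pos = offset % 3 + 1
    cstart = sp - 1 - (codon_pos - 1)
    ref_codon = sense[cstart : cstart + 3]
    if len(ref_codon) < 3:
        raise ValidationError(f"{site.chrom}:{site.pos}: truncated terminal codon")
    edit_codon = ref_codon[: codon_pos - 1] + site.edit_sense + ref_codon[codon_pos:]
    aa_ref = translate_codon(ref_codon)
    aa_edit = translate_codon(edit_codon)
    site.codon_pos = codon_pos
    site.ref_codon = ref_codon
    site.edit_codon = edit_codon
    site.aa_ref = aa_ref
    site.aa_edit = aa_edit
    site.synonymous = aa_ref == aa_edit
    if edit_codon == "ATG" and ref_codon != "ATG":
        site.hydropathy = "start-gain"
    else:
        site.hydropathy = hydropathy_change(aa_ref, aa_edit, scheme)
    return site


def context(site: EditingSite, genome: GenomeRecord, k: int = 5) -> str:
    """2k+1 sense-strand window centred on the site.

    Circular genomes wrap around; on linear genomes a window that runs
    off the end is truncated (logged). Minus-strand sites return the
    reverse complement of the genomic window.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if genome.circular:
        window = "".join(genome.base(p) for p in range(site.pos - k, site.pos + k + 1))
    else:
        lo = max(1, site.pos - k)
        hi = min(genome.length, site.pos + k)
        if lo != site.pos - k or hi != site.pos + k:
            log.warning("%s:%d: context window truncated at genome edge",
                        site.chrom, site.pos)
        window = genome.sequence[lo - 1 : hi]
    return window if site.strand == "+" else revcomp(window)


def minus_one_base(site: EditingSite, genome: GenomeRecord) -> str:
    """Sense-strand base immediately 5' of the site."""
    if site.strand == "+":
        return genome.base(site.pos - 1)
    from .core import complement

    return complement(genome.base(site.pos + 1))


def position_frequency_matrix(
    sites: List[EditingSite], genome: GenomeRecord, k: int = 5
) -> pd.DataFrame:
    """Base-frequency matrix over aligned sense-strand contexts.

    Rows A/C/G/T, columns are offsets -k..+k relative to the edited
    base; each column sums to 1 (given >= 1 site).
    """
    counts = np.zeros((4, 2 * k + 1))
    base_row = {b: i for i, b in enumerate(BASES)}
    for s in sites:
        win = context(s, genome, k)
        for j, b in enumerate(win):
            if b in base_row:
                counts[base_row[b], j] += 1
    colsums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(colsums > 0, counts / np.maximum(colsums, 1), 0.0)
    return pd.DataFrame(freqs, index=list(BASES), columns=range(-k, k + 1))


def annotate_site(
    site: EditingSite,
    genes: List[GeneModel],
    genome: GenomeRecord,
    scheme: HydropathyScheme = DEFAULT_SCHEME,
    k: int = 5,
) -> EditingSite:
    """Full annotation: region/label, codon consequence (CDS only,
    non-partial genes), flanking context."""
    locate(site, genes)
    if site.region == "CDS":
        gene = next(g for g in genes if g.gene_id == site.gene_id)
        if not gene.partial:
            codon_effect(site, gene, genome, scheme)
    site.context = context(site, genome, k)
    return site


def annotate_sites(sites, genes, genome, scheme=DEFAULT_SCHEME, k: int = 5):
    return [annotate_site(s, genes, genome, scheme, k) for s in sites]
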