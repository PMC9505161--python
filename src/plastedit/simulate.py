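"""Synthetic plastome, gene-model, editing-site and pileup generator.

The generator emulates the statistical structure of chloroplast RNA
editing in gymnosperms: C-to-U sites with high editing efficiency and a
pyrimidine-biased -1 context concentrated on codon positions 1-2, rarer
G-to-A sites with low efficiency and an A-biased -1 context, genomic
polymorphism decoys that a DNA-naive caller would miscall, and
indel-adjacent sites whose clean read pool is depleted so that only the
indel-inclusive pool reveals them.

Counts are simulated directly (no read-level simulation): the pipeline
consumes per-position base counts, so read mapping adds nothing the
caller can see beyond the clean/all pool split, which is modelled
explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import dendropy
import numpy as np
import pandas as pd

from .core import BASE_INDEX, BASES, GeneModel, GenomeRecord, ValidationError, complement
from .io import Pileup, PILEUP_COLUMNS

PYRIMIDINES = {"C", "T"}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Depths are Poisson means; efficiencies are Beta draws truncated
    below at ``min_true_efficiency`` (an editing site whose efficiency
    is below the detection floor is observationally indistinguishable
    from an unedited position).
    """

    genome_length: int = 30_000
    n_cds: int = 18
    n_trna: int = 4
    n_rrna: int = 2
    cds_length_range: Tuple[int, int] = (300, 1200)
    small_gene_length_range: Tuple[int, int] = (70, 300)
    n_ctu_sites: int = 80
    n_gta_sites: int = 8
    ctu_beta: Tuple[float, float] = (8.0, 2.0)
    gta_beta: Tuple[float, float] = (2.0, 8.0)
    min_true_efficiency: float = 0.10
    dna_depth: float = 30.0
    rna_depth: float = 100.0
    error_rate: float = 0.001
    polymorphism_decoy_count: int = 10
    decoy_allele_fraction: float = 0.5
    indel_adjacent_count: int = 5
    indel_window: int = 4
    clean_suppression: float = 0.98
    ctu_pyrimidine_bias: float = 0.65
    gta_a_bias: float = 0.70
    ctu_codon_weights: Tuple[float, float, float] = (0.45, 0.45, 0.10)
    intergenic_rna_fraction: float = 0.10
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("min_true_efficiency", "error_rate", "decoy_allele_fraction",
                     "clean_suppression", "ctu_pyrimidine_bias", "gta_a_bias",
                     "intergenic_rna_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1]")
        if abs(sum(self.ctu_codon_weights) - 1.0) > 1e-9:
            raise ValidationError("ctu_codon_weights must sum to 1")


@dataclass
class PlantedSite:
    chrom: str
    pos: int
    strand: str  # transcribed strand
    type: str  # "C-to-U" or "G-to-A" on the sense strand
    efficiency: float
    gene_id: str
    is_indel_adjacent: bool = False


@dataclass
class SimTruth:
    """Planted ground truth: editing sites plus DNA-polymorphism decoys
    (decoys are genomic polymorphisms, never editing sites)."""

    sites: List[PlantedSite]
    decoy_positions: List[int]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": s.chrom, "pos": s.pos, "strand": s.strand,
                    "type": s.type, "efficiency": s.efficiency,
                    "gene_id": s.gene_id, "is_indel_adjacent": s.is_indel_adjacent,
                }
                for s in self.sites
            ]
        )


STOP_CODONS = {"TAA", "TAG", "TGA"}


def _random_cds(length: int, rng: np.random.Generator) -> str:
    """Random CDS: ATG start, no internal stops, one stop codon."""
    n_internal = length // 3 - 2
    codons = []
    while len(codons) < n_internal:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(codons) + stop


def simulate_reference(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> Tuple[GenomeRecord, List[GeneModel]]:
    """Simulate a plastome-like reference with non-overlapping genes on
    both strands and intergenic gaps between them."""
    rng = rng or np.random.default_rng(config.seed)
    L = config.genome_length
    seq = list(rng.choice(list("ACGT"), size=L))

    plan = []
    for i in range(config.n_cds):
        lo, hi = config.cds_length_range
        length = 3 * int(rng.integers(lo // 3, hi // 3 + 1))
        plan.append((f"cds{i + 1:02d}", "CDS", length))
    for i in range(config.n_trna):
        lo, hi = config.small_gene_length_range
        plan.append((f"trn{i + 1:02d}", "tRNA", int(rng.integers(lo, hi))))
    for i in range(config.n_rrna):
        plan.append((f"rrn{i + 1:02d}", "rRNA", int(rng.integers(200, 400))))
    rng.shuffle(plan)

    footprint = sum(p[2] for p in plan)
    n_gaps = len(plan) + 1
    slack = L - footprint - n_gaps * 20
    if slack < 0:
        raise ValidationError(
            f"cannot pack {footprint} bp of genes into {L} bp genome; "
            "increase genome_length"
        )
    # distribute the slack over the gaps (each gap >= 20 bp)
    cuts = np.sort(rng.integers(0, slack + 1, size=n_gaps - 1))
    gap_extra = np.diff(np.concatenate([[0], cuts, [slack]]))
    gaps = 20 + gap_extra

    genes: List[GeneModel] = []
    cursor = 0
    for (gid, biotype, length), gap in zip(plan, gaps):
        cursor += int(gap)
        start = cursor + 1  # 1-based
        end = cursor + length
        strand = "+" if rng.random() < 0.5 else "-"
        if biotype == "CDS":
            sense = _random_cds(length, rng)
            genomic = sense if strand == "+" else "".join(
                complement(b) for b in reversed(sense)
            )
            seq[start - 1 : end] = list(genomic)
        genes.append(
            GeneModel(gene_id=gid, biotype=biotype, strand=strand,
                      exons=[(start, end)], codon_start=1)
        )
        cursor = end
    genome = GenomeRecord(id="sim_plastome", sequence="".join(seq), circular=True)
    return genome, genes


def _truncated_beta(a: float, b: float, floor: float, rng: np.random.Generator) -> float:
    while True:
        x = rng.beta(a, b)
        if x >= floor:
            return float(x)


def _eligible(genome, genes, sense_base, biotypes):
    """(pos, strand, gene_id, codon_pos, minus1_sense) for every exonic
    position whose sense-strand base equals ``sense_base``."""
    out = []
    for g in genes:
        if g.biotype not in biotypes:
            continue
        sense_seq = g.spliced_sequence(genome)
        for s, e in g.exons:
            for pos in range(s, e + 1):
                sp = g.spliced_position(pos)
                if sense_seq[sp - 1] != sense_base:
                    continue
                minus1 = sense_seq[sp - 2] if sp >= 2 else None
                codon_pos = ((sp - g.codon_start) % 3) + 1 if g.biotype == "CDS" else None
                if g.biotype == "CDS" and sp < g.codon_start:
                    codon_pos = None
                out.append((pos, g.strand, g.gene_id, codon_pos, minus1))
    return out


def plant_sites(
    genome: GenomeRecord,
    genes: List[GeneModel],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimTruth:
    """Plant editing sites and polymorphism decoys.

    C-to-U sites go to sense-strand C positions in CDS genes with the
    configured codon-position weights and -1 pyrimidine bias; G-to-A
    sites go to sense-strand G positions in any gene with the configured
    -1 A bias. A site on a minus-strand gene therefore sits on a genomic
    G (C-to-U) or C (G-to-A).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    taken: set = set()
    sites: List[PlantedSite] = []

    def pick(pool, want_pred):
        """Pick an unused position, preferring those satisfying the
        context predicate."""
        cand = [x for x in pool if x[0] not in taken and want_pred(x[4])]
        if not cand:
            cand = [x for x in pool if x[0] not in taken]
        if not cand:
            return None
        return cand[rng.integers(len(cand))]

    # --- C-to-U in CDS, codon-position weighted, -1 pyrimidine biased
    ctu_pool = _eligible(genome, genes, "C", {"CDS"})
    by_codon = {1: [], 2: [], 3: []}
    for x in ctu_pool:
        if x[3] in by_codon:
            by_codon[x[3]].append(x)
    if config.n_ctu_sites > len(ctu_pool):
        raise ValidationError(
            f"only {len(ctu_pool)} eligible C-to-U positions for "
            f"{config.n_ctu_sites} requested sites"
        )
    for _ in range(config.n_ctu_sites):
        cp = 1 + rng.choice(3, p=np.asarray(config.ctu_codon_weights))
        pyr = rng.random() < config.ctu_pyrimidine_bias
        pred = (lambda m: m in PYRIMIDINES) if pyr else (lambda m: m is not None and m not in PYRIMIDINES)
        chosen = pick(by_codon[cp], pred) or pick(ctu_pool, pred)
        if chosen is None:
            raise ValidationError("ran out of eligible C-to-U positions")
        pos, strand, gid, _, _ = chosen
        taken.add(pos)
        sites.append(PlantedSite(
            chrom=genome.id, pos=pos, strand=strand, type="C-to-U",
            efficiency=_truncated_beta(*config.ctu_beta, config.min_true_efficiency, rng),
            gene_id=gid,
        ))

    # --- G-to-A in any gene, -1 A biased
    gta_pool = _eligible(genome, genes, "G", {"CDS", "tRNA", "rRNA"})
    if config.n_gta_sites > len(gta_pool):
        raise ValidationError(
            f"only {len(gta_pool)} eligible G-to-A positions for "
            f"{config.n_gta_sites} requested sites"
        )
    for _ in range(config.n_gta_sites):
        want_a = rng.random() < config.gta_a_bias
        pred = (lambda m: m == "A") if want_a else (lambda m: m is not None and m != "A")
        chosen = pick(gta_pool, pred)
        if chosen is None:
            raise ValidationError("ran out of eligible G-to-A positions")
        pos, strand, gid, _, _ = chosen
        taken.add(pos)
        sites.append(PlantedSite(
            chrom=genome.id, pos=pos, strand=strand, type="G-to-A",
            efficiency=_truncated_beta(*config.gta_beta, config.min_true_efficiency, rng),
            gene_id=gid,
        ))

    # --- indel-adjacent flags on a subset of planted sites
    n_indel = min(config.indel_adjacent_count, len(sites))
    for i in rng.choice(len(sites), size=n_indel, replace=False):
        sites[i].is_indel_adjacent = True

    # --- DNA polymorphism decoys on exonic positions (transcribed, so the
    #     RNA also shows both alleles: bait for a DNA-naive caller)
    exonic = sorted(
        {p for g in genes for s, e in g.exons for p in range(s, e + 1)} - taken
    )
    decoys = sorted(
        int(p) for p in rng.choice(exonic, size=config.polymorphism_decoy_count,
                                   replace=False)
    )
    return SimTruth(sites=sites, decoy_positions=decoys)


def _spread_errors(counts: np.ndarray, ref_idx: np.ndarray, depth: np.ndarray,
                   e: float, rng: np.random.Generator) -> None:
    """Move Binomial(depth, e) reads from the reference base to random
    other bases, in place."""
    n_err = rng.binomial(depth, e)
    for i in np.nonzero(n_err)[0]:
        take = min(int(n_err[i]), int(counts[i, ref_idx[i]]))
        for _ in range(take):
            j = (ref_idx[i] + 1 + rng.integers(3)) % 4
            counts[i, ref_idx[i]] -= 1
            counts[i, j] += 1


def simulate_pileups(
    genome: GenomeRecord,
    genes: List[GeneModel],
    truth: SimTruth,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> Pileup:
    """Simulate the matched DNA / strand-specific RNA pileup table.

    DNA depth is Poisson with misincorporations at the error rate; decoy
    positions carry two DNA alleles (and matching RNA). RNA depth on the
    orientation of the covering gene is Poisson(rna_depth); intergenic
    and antisense coverage is a configurable background fraction. Edited
    sites mix edited and reference bases per their true efficiency. At
    indel-adjacent sites the clean pools retain only (1 - suppression)
    of the reads, mimicking indel-bearing reads excluded near the site.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    L = genome.length
    ref_idx = np.fromiter((BASE_INDEX[b] for b in genome.sequence), dtype=np.int64, count=L)
    e = config.error_rate

    # --- DNA counts
    dna_depth = rng.poisson(config.dna_depth, size=L)
    dna = np.zeros((L, 4), dtype=np.int64)
    dna[np.arange(L), ref_idx] = dna_depth
    _spread_errors(dna, ref_idx, dna_depth, e, rng)

    # --- RNA depth per orientation
    fwd_depth = np.full(L, config.rna_depth * config.intergenic_rna_fraction)
    rev_depth = np.full(L, config.rna_depth * config.intergenic_rna_fraction)
    for g in genes:
        for s, ee in g.exons:
            if g.strand == "+":
                fwd_depth[s - 1 : ee] = config.rna_depth
            else:
                rev_depth[s - 1 : ee] = config.rna_depth
    fwd_n = rng.poisson(fwd_depth)
    rev_n = rng.poisson(rev_depth)
    rna = {}
    for name, n in (("fwd", fwd_n), ("rev", rev_n)):
        m = np.zeros((L, 4), dtype=np.int64)
        m[np.arange(L), ref_idx] = n
        _spread_errors(m, ref_idx, n, e, rng)
        rna[name] = m

    # --- edited sites: move Binomial(depth, efficiency) reads ref -> alt
    for s in truth.sites:
        i = s.pos - 1
        pool = rna["fwd"] if s.strand == "+" else rna["rev"]
        ref_b = genome.sequence[i]
        if s.type == "C-to-U":
            alt_b = "T" if s.strand == "+" else "A"
        else:  # G-to-A
            alt_b = "A" if s.strand == "+" else "T"
        depth_here = int(pool[i].sum())
        edited = min(int(rng.binomial(depth_here, s.efficiency)),
                     int(pool[i, BASE_INDEX[ref_b]]))
        pool[i, BASE_INDEX[ref_b]] -= edited
        pool[i, BASE_INDEX[alt_b]] += edited

    # --- decoys: second DNA allele mirrored in the RNA
    for pos in truth.decoy_positions:
        i = pos - 1
        r = ref_idx[i]
        alt = (r + 1 + rng.integers(3)) % 4
        for pool, n in ((dna, dna_depth[i]),):
            alt_n = min(int(rng.binomial(int(n), config.decoy_allele_fraction)),
                        int(pool[i, r]))
            pool[i, r] -= alt_n
            pool[i, alt] += alt_n
        for name in ("fwd", "rev"):
            n = int(rna[name][i].sum())
            alt_n = min(int(rng.binomial(n, config.decoy_allele_fraction)),
                        int(rna[name][i, r]))
            rna[name][i, r] -= alt_n
            rna[name][i, alt] += alt_n

    # --- clean vs all pools
    all_fwd, all_rev = rna["fwd"], rna["rev"]
    clean_fwd, clean_rev = all_fwd.copy(), all_rev.copy()
    for s in truth.sites:
        if not s.is_indel_adjacent:
            continue
        i = s.pos - 1
        keep = 1.0 - config.clean_suppression
        clean_fwd[i] = rng.binomial(all_fwd[i], keep)
        clean_rev[i] = rng.binomial(all_rev[i], keep)

    frame = pd.DataFrame({
        "chrom": genome.id,
        "pos": np.arange(1, L + 1),
        "ref": list(genome.sequence),
    })
    for tag, m in (("dna", dna), ("rna_fwd_clean", clean_fwd),
                   ("rna_rev_clean", clean_rev), ("rna_fwd_all", all_fwd),
                   ("rna_rev_all", all_rev)):
        for j, b in enumerate(BASES):
            frame[f"{tag}_{b}"] = m[:, j]
    return Pileup(frame[PILEUP_COLUMNS], config.indel_window)


def simulate_dataset(config: SimConfig):
    """Reference + genes + truth + pileup from one config (one species)."""
    rng = np.random.default_rng(config.seed)
    genome, genes = simulate_reference(config, rng)
    truth = plant_sites(genome, genes, config, rng)
    pileup = simulate_pileups(genome, genes, truth, config, rng)
    return genome, genes, truth, pileup


def simulate_site_matrix(
    tree: dendropy.Tree,
    gain: float,
    loss: float,
    n_sites: int,
    seed: int = 17,
) -> pd.DataFrame:
    """Evolve presence/absence characters along a rooted tree under the
    two-state Markov chain, root state drawn from the stationary
    distribution. Returns a species x site 0/1 matrix."""
    if gain <= 0 or loss <= 0:
        raise ValidationError("gain and loss rates must be positive")
    rng = np.random.default_rng(seed)
    lam = gain + loss
    pi1 = gain / lam
    states = {}
    root = tree.seed_node
    states[root] = (rng.random(n_sites) < pi1).astype(np.int8)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        t = node.edge.length or 0.0
        decay = np.exp(-lam * t)
        parent = states[node.parent_node]
        p1 = pi1 + (parent - pi1) * decay  # P(child = 1 | parent)
        states[node] = (rng.random(n_sites) < p1).astype(np.int8)
    rows = {
        leaf.taxon.label: states[leaf]
        for leaf in tree.leaf_node_iter()
    }
    return pd.DataFrame(rows).T
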