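"""RNA-editing site calling from matched DNA/strand-specific-RNA pileups.

A site is called per transcript orientation when, on that orientation's
clean counts: the DNA consensus is the reference at high major-allele
fraction (rejecting genomic polymorphism and heterozygosity), RNA depth
and edited-read support clear their floors, the edited-read count is
inconsistent with the sequencing error rate under a one-sided binomial
test, the editing efficiency (edited / total covering RNA reads) clears
its floor, and the edited reads are concentrated on the calling
orientation (strand purity).

Sites masked in the clean pool by nearby indels are rescued by
re-applying the same rule set to the indel-inclusive ("all") pools; the
rescue never overrides a DNA-level rejection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import stats

from .core import BASE_INDEX, BASES, EditingSite, GeneModel, ValidationError, complement
from .io import Pileup

log = logging.getLogger(__name__)


@dataclass
class CallerParams:
    min_dna_depth: int = 10
    min_rna_depth: int = 10
    min_edited_reads: int = 3
    dna_major_allele_min_fraction: float = 0.95
    error_rate: float = 0.001
    alpha: float = 1e-3
    min_efficiency: float = 0.05
    strand_purity: float = 0.90
    rescue_enabled: bool = True
    gta_cooccurrence_window: int = 150

    def __post_init__(self) -> None:
        for name in ("dna_major_allele_min_fraction", "error_rate", "alpha",
                     "min_efficiency", "strand_purity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0,1]")
        for name in ("min_dna_depth", "min_rna_depth", "min_edited_reads",
                     "gta_cooccurrence_window"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _strand_stats(counts: np.ndarray, ref_idx: np.ndarray):
    """Depth, best alternative base and its count, per row.

    Ties between alternative bases break toward the alphabetically first
    base (A < C < G < T).
    """
    depth = counts.sum(axis=1)
    alt = counts.copy()
    alt[np.arange(len(alt)), ref_idx] = -1
    alt_idx = alt.argmax(axis=1)
    k = counts[np.arange(len(counts)), alt_idx]
    k = np.where(alt_idx == ref_idx, 0, k)  # all-ref rows have no alternative
    return depth, alt_idx, k


def _dna_filter(dna: np.ndarray, ref_idx: np.ndarray, params: CallerParams):
    """Mask of positions whose DNA evidence supports a homozygous
    reference genotype. Positions whose DNA consensus differs from the
    reference are rejected and logged as possible assembly errors."""
    depth = dna.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        major_idx = dna.argmax(axis=1)
        major_frac = np.where(depth > 0, dna[np.arange(len(dna)), major_idx] / np.maximum(depth, 1), 0.0)
    consensus_mismatch = (depth >= params.min_dna_depth) & (major_idx != ref_idx) & (
        major_frac >= params.dna_major_allele_min_fraction
    )
    for i in np.nonzero(consensus_mismatch)[0]:
        log.warning(
            "position row %d: DNA consensus differs from reference "
            "(possible assembly error); site skipped", i
        )
    ok = (
        (depth >= params.min_dna_depth)
        & (major_idx == ref_idx)
        & (major_frac >= params.dna_major_allele_min_fraction)
    )
    return ok, depth


def _evaluate(
    counts_this: np.ndarray,
    counts_other: np.ndarray,
    dna_ok: np.ndarray,
    ref_idx: np.ndarray,
    params: CallerParams,
):
    """Apply the RNA-side rule set on one orientation's count pool.

    Returns (pass, ambiguous, depth, alt_idx, k, pvalue, rna_fail) where
    ``rna_fail`` marks rows failing the depth or edited-read floor (the
    rescue-eligible failures) and ``ambiguous`` rows pass everything but
    strand purity.
    """
    depth, alt_idx, k = _strand_stats(counts_this, ref_idx)
    depth_ok = depth >= params.min_rna_depth
    k_ok = k >= params.min_edited_reads
    pval = np.ones(len(depth))
    cand = dna_ok & depth_ok & k_ok
    if cand.any():
        idx = np.nonzero(cand)[0]
        pval[idx] = stats.binom.sf(k[idx] - 1, depth[idx], params.error_rate)
    with np.errstate(invalid="ignore", divide="ignore"):
        eff = np.where(depth > 0, k / np.maximum(depth, 1), 0.0)
    other_k = counts_other[np.arange(len(counts_other)), alt_idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        purity = np.where(k + other_k > 0, k / np.maximum(k + other_k, 1), 0.0)
    base_pass = cand & (pval <= params.alpha) & (eff >= params.min_efficiency)
    passed = base_pass & (purity >= params.strand_purity)
    ambiguous = base_pass & ~passed
    rna_fail = dna_ok & (~depth_ok | ~k_ok)
    return passed, ambiguous, depth, alt_idx, k, pval, rna_fail


def _emit(pileup, i, orient, ref_base, alt_idx, depth, k, pval, dna_depth, rescued):
    strand = "+" if orient == "fwd" else "-"
    alt_base = BASES[alt_idx]
    if strand == "+":
        ref_sense, edit_sense = ref_base, alt_base
    else:
        ref_sense, edit_sense = complement(ref_base), complement(alt_base)
    f = pileup.frame
    return EditingSite(
        chrom=f["chrom"].iat[i],
        pos=int(f["pos"].iat[i]),
        strand=strand,
        ref_sense=ref_sense,
        edit_sense=edit_sense,
        efficiency=float(k / depth),
        dna_depth=int(dna_depth),
        rna_depth=int(depth),
        p_value=float(pval),
        rescued=rescued,
    )


def call_sites(pileup: Pileup, params: Optional[CallerParams] = None) -> List[EditingSite]:
    """Call editing sites on both orientations from the clean pools.

    Sites passing every criterion except strand purity are flagged
    ambiguous and suppressed from the output. If ``params.rescue_enabled``
    the indel rescue pass is applied afterwards (see
    :func:`rescue_indel_adjacent`).
    """
    params = params or CallerParams()
    sites = _call_clean(pileup, params)
    if params.rescue_enabled:
        sites = sites + rescue_indel_adjacent(pileup, sites, params)
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    return sites


def _call_clean(pileup: Pileup, params: CallerParams) -> List[EditingSite]:
    f = pileup.frame
    if len(f) == 0:
        return []
    ref_idx = f["ref"].map(BASE_INDEX).to_numpy()
    dna = f[[f"dna_{b}" for b in BASES]].to_numpy()
    dna_ok, dna_depth = _dna_filter(dna, ref_idx, params)
    sites: List[EditingSite] = []
    pools = {
        o: f[[f"rna_{o}_clean_{b}" for b in BASES]].to_numpy() for o in ("fwd", "rev")
    }
    for orient, other in (("fwd", "rev"), ("rev", "fwd")):
        passed, _, depth, alt_idx, k, pval, _ = _evaluate(
            pools[orient], pools[other], dna_ok, ref_idx, params
        )
        for i in np.nonzero(passed)[0]:
            sites.append(
                _emit(pileup, i, orient, f["ref"].iat[i], alt_idx[i],
                      depth[i], k[i], pval[i], dna_depth[i], rescued=False)
            )
    return sites


def rescue_indel_adjacent(
    pileup: Pileup, preliminary: List[EditingSite], params: Optional[CallerParams] = None
) -> List[EditingSite]:
    """Rescue sites masked by indel-adjacent read exclusion.

    Positions that pass the DNA filter but fail only the RNA depth or
    edited-read floor on the clean pool are re-evaluated on the
    indel-inclusive pools; those passing the full rule set there are
    emitted with ``rescued=True``. DNA-level rejections are final.
    """
    params = params or CallerParams()
    f = pileup.frame
    if len(f) == 0:
        return []
    ref_idx = f["ref"].map(BASE_INDEX).to_numpy()
    dna = f[[f"dna_{b}" for b in BASES]].to_numpy()
    dna_ok, dna_depth = _dna_filter(dna, ref_idx, params)
    called = {(s.chrom, s.pos, s.strand) for s in preliminary}
    clean = {o: f[[f"rna_{o}_clean_{b}" for b in BASES]].to_numpy() for o in ("fwd", "rev")}
    allp = {o: f[[f"rna_{o}_all_{b}" for b in BASES]].to_numpy() for o in ("fwd", "rev")}
    rescued: List[EditingSite] = []
    for orient, other in (("fwd", "rev"), ("rev", "fwd")):
        strand = "+" if orient == "fwd" else "-"
        _, _, _, _, _, _, rna_fail = _evaluate(
            clean[orient], clean[other], dna_ok, ref_idx, params
        )
        passed, _, depth, alt_idx, k, pval, _ = _evaluate(
            allp[orient], allp[other], dna_ok, ref_idx, params
        )
        for i in np.nonzero(passed & rna_fail)[0]:
            key = (f["chrom"].iat[i], int(f["pos"].iat[i]), strand)
            if key in called:
                continue
            rescued.append(
                _emit(pileup, i, orient, f["ref"].iat[i], alt_idx[i],
                      depth[i], k[i], pval[i], dna_depth[i], rescued=True)
            )
    return rescued


def classify_type(site: EditingSite, genes: List[GeneModel]) -> EditingSite:
    """Validate the read-derived transcribed strand against annotation.

    The editing type is already expressed on the transcribed strand
    (complementing genomic bases for minus-strand sites, U for T); a
    genomic G-to-A change inside a minus-strand gene is therefore a
    C-to-U event. When the read-derived strand contradicts the
    containing gene's strand the site keeps the read-derived strand and
    is flagged as an antisense-transcript candidate.
    """
    containing = [g for g in genes if g.contains(site.pos)]
    if containing and all(g.strand != site.strand for g in containing):
        site.antisense_candidate = True
        log.warning(
            "%s:%d read orientation contradicts annotation strand: "
            "antisense-transcript candidate", site.chrom, site.pos
        )
    return site


def flag_gta_support(
    sites: List[EditingSite], params: Optional[CallerParams] = None
) -> List[EditingSite]:
    """Flag each G-to-A site supported by a same-strand C-to-U site
    within the co-occurrence window (inclusive at the boundary)."""
    params = params or CallerParams()
    w = params.gta_cooccurrence_window
    ctu = [(s.chrom, s.strand, s.pos) for s in sites if s.type == "C-to-U"]
    for s in sites:
        if s.type != "G-to-A":
            continue
        s.gta_supported = any(
            c == s.chrom and st == s.strand and abs(p - s.pos) <= w
            for c, st, p in ctu
        )
    return sites
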