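# Methods

## Problem setting

Chloroplast RNA editing alters single bases post-transcriptionally, so a
transcript differs from its genomic template at specific positions. With
DNA-seq and strand-specific RNA-seq from the *same individual*, an
editing site appears as a position where the DNA is homozygous for the
reference base while a consistent fraction of RNA reads on one
orientation carries a different base. Same-individual data are essential:
they exclude the inter-individual polymorphisms that mimic editing when
genome and transcriptome come from different plants. The two editing
types handled here are C-to-U (abundant, efficiently edited, pyrimidine-
biased −1 context, concentrated at codon positions 1–2) and G-to-A
(rare, low-efficiency, A-biased −1 context). Types are defined on the
transcribed strand: a genomic G→A variant inside a minus-strand gene is
a C-to-U event.

## Calling model

Input is a per-position pileup with five count pools: DNA, and RNA
forward/reverse × clean/all. "Clean" excludes reads with an indel within
±w bp of the position (w is carried in the file header); "all" includes
them. All pools are in reference plus-strand base space; fwd/rev encode
transcript orientation, with the library-prep protocol resolved
upstream.

Per orientation, a site is called on the clean pool when all of:

| criterion | default | role |
|---|---|---|
| DNA depth | ≥ 10 | genotype confidence |
| DNA major allele = reference, fraction | ≥ 0.95 | rejects polymorphism/heterozygosity |
| RNA depth n | ≥ 10 | estimation floor |
| edited reads k | ≥ 3 | minimum support |
| binomial tail P(X ≥ k \| n, e), e = 0.001 | ≤ 10⁻³ | sequencing-error null |
| efficiency k/n | ≥ 0.05 | biological floor |
| strand purity k/(k + k_other) | ≥ 0.90 | orientation consistency |

Positions whose DNA consensus differs from the reference are skipped
with a possible-assembly-error warning, never called. Sites passing
everything except purity are flagged ambiguous and suppressed. The
thresholds follow common practice for organellar editing callers
(upstream tools ship comparable defaults without printing them); every
one is a `CallerParams` field. No multiple-testing correction is applied
by default. Ties between alternative bases break toward the
alphabetically first base — with ≥ 3 supporting reads and a binomial
test they are effectively impossible except in degenerate inputs.

**Indel rescue.** Indels near a site divert its covering reads out of
the clean pool, which can silence a genuine site (the motivating
phenomenon was G-to-A sites validated by RT-PCR but absent from
clean-pool calls). Positions that pass the DNA filter but fail *only*
the RNA depth or edited-read floor on the clean pool are re-evaluated on
the all pool under the full rule set and emitted with `rescued=true`.
The rescue is count-pool-based rather than realignment-based: the
pipeline consumes counts, and re-evaluation on the indel-inclusive pool
reproduces the effect deterministically. A DNA-level rejection is final.

**G-to-A plausibility.** Each G-to-A site is flagged `gta_supported`
when a called same-strand C-to-U site lies within 150 bp (inclusive
boundary) — co-occurring canonical editing on the same transcript is
corroborating evidence for the rarer type.

## Annotation

Region precedence when features overlap is CDS > tRNA > rRNA > intron >
intergenic (overlaps are rare in plastomes; the order is a convention).
Site labels are `<gene>-<position in the spliced sense-strand gene
sequence>`. Codons are translated with NCBI table 11 (plastid/bacterial).
Codon position is ((spliced offset − codon_start + 1 − 1) mod 3) + 1.
The hydropathy partition is configurable; the default places
{A,C,F,G,I,L,M,P,V,W} as hydrophobic, chosen so that Ser→Leu reads
hydrophilic→hydrophobic and Pro→Leu maintains hydrophobicity — the two
canonical C-to-U amino-acid changes. Stop codons are their own category
(stop-gain/stop-loss); an edit whose codon becomes ATG is flagged
start-gain but the gene model is not re-annotated. Context windows are
sense-strand, reverse-complemented for minus-strand sites, with circular
wrap-around on circular genomes and truncation (logged) on linear ones.

Coordinates are 1-based closed throughout (GFF3 convention). Circular
genomes are linearised on the deposited sequence; origin-spanning
features are represented as split exons, as in GenBank plastome records.

## Synthetic cohort

The generator emulates the statistical structure of the real data so
that every downstream stage is testable without sequencing data:

- **Efficiencies**: Beta(8,2) for C-to-U ("highly efficiently edited"),
  Beta(2,8) for G-to-A ("generally low"), truncated below at 0.10. The
  truncation is a modelling statement: a planted "site" edited below the
  caller's efficiency floor is observationally indistinguishable from an
  unedited position, and real site inventories are built from sites
  detectable above noise.
- **Context bias**: planting positions are chosen so the −1 sense base
  is a pyrimidine with probability 0.65 (C-to-U) or an A with
  probability 0.70 (G-to-A).
- **Codon positions**: C-to-U sites follow weights 0.45/0.45/0.10 over
  codon positions 1/2/3.
- **Depths**: DNA Poisson(30), RNA Poisson(100) on the transcribed
  orientation of genes; intergenic/antisense background at 10% of RNA
  depth; per-base error 0.001.
- **Decoys**: genomic polymorphisms (two DNA alleles at fraction 0.5,
  mirrored in the RNA) planted at exonic positions — bait that a caller
  without the DNA filter would miscall.
- **Indel masking**: a subset of planted sites keeps only 2% of its RNA
  reads in the clean pools (suppression 0.98), reliably below the
  RNA-depth floor, so these sites genuinely require rescue. Counts are
  simulated directly rather than via reads: the pipeline consumes
  counts, and the clean/all split is the only read-level effect it can
  see.

What the generator does **not** model: mapping artefacts, inverted-repeat
duplication, paralogous nuclear/mitochondrial transfer (RNA-level
polymorphism at rRNA sites is represented simply as partial efficiency),
position-autocorrelated coverage, and library-specific error spectra.
Passing tests therefore demonstrate correctness of the decision rules
and estimators under the stated noise model, not robustness to mapping
pathology.

## Gain/loss model

Presence/absence characters evolve under the two-state chain with gain
rate g and loss rate l; π₁ = g/(g+l), transition probabilities
P(t) = Π + e^{−(g+l)t}(I − Π) with Π the stationary projector. The root
prior defaults to stationary (overridable). Likelihoods use Felsenstein
pruning vectorised over sites; missing entries (gene absent in a
species) contribute partial likelihood 1 to both states. Rates are fit
by Nelder-Mead in log space from g = l = 1 (deterministic); degenerate
all-present/all-absent matrices drive a rate to its bound with a
warning. An optional K-category rate mixture (fixed multipliers, equal
weights) is provided; the default is K = 1 — per-branch event tallies
are reproducible in structure without a full mixture machinery, and the
single-pair model keeps the rates identifiable at the matrix sizes used
here. Only the product (rate × branch length) is identifiable, as the
rescaling-invariance test asserts.

Per-branch expected gains and losses combine (i) the joint posterior of
the branch-endpoint states from the up-down algorithm with (ii) the
closed-form conditional expectation of 0→1 / 1→0 transition counts on a
branch, obtained by integrating P_{ai}(s) q_{ij} P_{jb}(t−s) over the
branch (the two-state chain has eigenvalues 0 and −(g+l), so the
integral is elementary). Whether published per-branch integers of this
kind are expectations, MAP counts or parsimony reconstructions is
generally ambiguous; this package outputs expectations (with Fitch
parsimony available as the discrete counterpart) and the expectation
provably dominates the parsimony minimum per site.

Two oracles guard the implementation: exhaustive enumeration of internal
states (trees ≤ 5 tips) for the likelihood, and an exact conditional
stochastic-mapping sampler — forward simulation of full jump histories,
rejection on the observed tip pattern — for the expected counts. The
rejection sampler is exponential in pattern improbability and is
intended for the small trees it is used on; that is its role.

The packaged 19-taxon gymnosperm tree follows the published lineage
topology (Cycadales + Ginkgoaceae sister to the rest; Pinaceae sister to
Gnetales; Conifer II as the remaining clade); its branch lengths are
invented, since the source phylogeny is a cladogram. It is a simulation
scaffold, not an inference result.

## Association statistics

The cohort summary counts sites per species × type over codon positions
1/2/3, silent/nonsynonymous, and tRNA/rRNA/intron/intergenic, enforcing
the identities coding = 1st + 2nd + 3rd = silent + nonsynonymous and
total = coding + non-coding. The published 19-species summary table is
packaged as a fixture and satisfies these identities exactly (totals
1364 C-to-U / 71 G-to-A). Pearson correlations use the product-moment
formula with the two-sided t-transform p-value (n − 2 df), requiring
n ≥ 3 and non-constant inputs; missing feature values are dropped
pairwise. The real cohort's correlation coefficients depend on
per-species feature values not shipped here; the operation is validated
on synthetic features with planted correlations instead.

## Problem sizes and numerical choices

Simulation studies default to 30 kb genomes with ~24 genes, 80 C-to-U +
8 G-to-A sites, 10 decoys and 5 indel-masked sites per species; caller
benchmarks aggregate 5 seeds, rate-recovery benchmarks 10 seeds × 2000
sites on the 19-taxon tree. These sizes give stable metrics (binomial
noise on recall at ~400 planted clean sites is ±1%) at interactive run
times. Alignment-based homology mapping keys sites by alignment column;
with gapless alignments this coincides with the per-gene nucleotide
index. The built-in Needleman-Wunsch (match 1, mismatch −1, gap −2,
deterministic tie-breaking toward diagonal/up) exists for self-contained
tests; real cohorts should supply aligner-produced per-gene FASTAs.

## Known limitations

- Strand assignment for intergenic sites rests on read orientation
  alone; antisense transcription inside genes is flagged, not resolved.
- Inverted-repeat copies are reported as separate genomic positions;
  no IR deduplication is attempted.
- The rescue re-tests the all pool with the same binomial null, which
  is slightly anticonservative if indel-bearing reads have elevated
  error rates; per-pool error rates would be a straightforward
  extension.
- The G-to-A support flag is evidence annotation, not a filter; callers
  wanting stricter G-to-A handling should filter on it downstream.
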