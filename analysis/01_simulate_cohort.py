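#!/usr/bin/env python
"""Simulate a synthetic chloroplast cohort.

One plastome-like reference is shared by all cohort species (so that
sites are directly homologous across species); each species gets its own
planted editing sites, polymorphism decoys, indel-masked sites and
matched DNA/RNA pileups. Writes FASTA, GFF3, truth tables and pileups
under results/cohort/.
"""

import argparse
from pathlib import Path

import numpy as np

import plastedit as pe

SPECIES = {  # species -> lineage, mirroring a small multi-lineage cohort
    "cycad_A": "Cycadales", "cycad_B": "Cycadales",
    "ginkgo_A": "Ginkgoaceae",
    "pine_A": "Pinaceae", "pine_B": "Pinaceae",
    "gnetum_A": "Gnetales",
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=17)
    ap.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = pe.SimConfig(genome_length=15_000, n_cds=10, n_trna=2, n_rrna=1,
                       n_ctu_sites=45, n_gta_sites=5, indel_adjacent_count=4,
                       seed=args.seed)
    rng = np.random.default_rng(args.seed)
    genome, genes = pe.simulate_reference(cfg, rng)
    pe.write_genome([genome], args.outdir / "reference.fasta")
    pe.write_genes(genes, args.outdir / "genes.gff3", chrom=genome.id)

    for i, sp in enumerate(SPECIES):
        rng_sp = np.random.default_rng(args.seed + 100 + i)
        truth = pe.plant_sites(genome, genes, cfg, rng_sp)
        pileup = pe.simulate_pileups(genome, genes, truth, cfg, rng_sp)
        pe.write_pileup(pileup, args.outdir / f"{sp}.pileup.tsv")
        truth.frame().to_csv(args.outdir / f"{sp}.truth.tsv", sep="\t", index=False)
        print(f"{sp}: {len(truth.sites)} planted sites "
              f"({sum(s.is_indel_adjacent for s in truth.sites)} indel-masked), "
              f"{len(truth.decoy_positions)} decoys")
    (args.outdir / "lineages.tsv").write_text(
        "species\tlineage\n" + "".join(f"{s}\t{l}\n" for s, l in SPECIES.items())
    )
    print(f"wrote cohort to {args.outdir}")


if __name__ == "__main__":
    main()
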