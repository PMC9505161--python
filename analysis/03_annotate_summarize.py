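#!/usr/bin/env python
"""Annotate called sites and build the cohort summary table.

Adds region, codon-consequence, hydropathy and flanking-context
annotations, writes annotated per-species tables, the per-species
summary (codon positions, silent/nonsynonymous, region counts), the
-1-context position-frequency matrix, and compares the synthetic
cohort's shape against the packaged 19-species gymnosperm summary.
"""

import argparse
from pathlib import Path

import plastedit as pe


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--sites", type=Path, default=Path("results/sites"))
    ap.add_argument("--outdir", type=Path, default=Path("results/annotated"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    (genome,) = pe.read_genome(args.cohort / "reference.fasta")
    genes = pe.read_genes(args.cohort / "genes.gff3")
    per_species = {}
    for path in sorted(args.sites.glob("*.sites.tsv")):
        sp = path.name.replace(".sites.tsv", "")
        sites = pe.annotate_sites(pe.read_site_table(path), genes, genome)
        pe.write_site_table(sites, args.outdir / f"{sp}.annotated.tsv")
        per_species[sp] = sites

    summary = pe.summarize_cohort(per_species)
    summary.to_csv(args.outdir / "cohort_summary.tsv", sep="\t", index=False)
    totals = pe.cohort_totals(summary)
    print("synthetic cohort totals:", totals)

    ctu = [s for sites in per_species.values() for s in sites if s.type == "C-to-U"]
    pfm = pe.position_frequency_matrix(ctu, genome, k=5)
    pfm.to_csv(args.outdir / "ctu_context_pfm.tsv", sep="\t")
    print(f"C-to-U -1 pyrimidine mass: {pfm.loc['C', -1] + pfm.loc['T', -1]:.3f} "
          f"(generator setting 0.65)")

    t1 = pe.load_table1()
    print("published gymnosperm cohort totals:", pe.cohort_totals(t1))


if __name__ == "__main__":
    main()
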