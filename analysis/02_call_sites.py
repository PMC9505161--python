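#!/usr/bin/env python
"""Call editing sites for every cohort species from its pileup.

Applies the matched-DNA/RNA calling rules with indel rescue, validates
read-derived strands against the annotation, flags G-to-A sites with
nearby same-strand C-to-U support, and reports recall/precision against
the planted truth. Writes per-species site tables.
"""

import argparse
from pathlib import Path

import pandas as pd

import plastedit as pe


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--outdir", type=Path, default=Path("results/sites"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genes = pe.read_genes(args.cohort / "genes.gff3")
    for pileup_path in sorted(args.cohort.glob("*.pileup.tsv")):
        sp = pileup_path.name.replace(".pileup.tsv", "")
        pileup = pe.read_pileup(pileup_path)
        sites = pe.call_sites(pileup)
        sites = [pe.classify_type(s, genes) for s in sites]
        sites = pe.flag_gta_support(sites)
        pe.write_site_table(sites, args.outdir / f"{sp}.sites.tsv")

        truth = pd.read_csv(args.cohort / f"{sp}.truth.tsv", sep="\t")
        truth_keys = set(zip(truth["pos"], truth["strand"]))
        called = {(s.pos, s.strand) for s in sites}
        tp = len(called & truth_keys)
        print(f"{sp}: {len(sites)} called "
              f"({sum(s.rescued for s in sites)} rescued), "
              f"recall {tp / len(truth_keys):.3f}, "
              f"precision {tp / len(called):.3f}")


if __name__ == "__main__":
    main()
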