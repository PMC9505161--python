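import numpy as np
import pandas as pd
import pytest

import plastedit as pe
from plastedit.io import PILEUP_COLUMNS


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated species at reduced scale (fast, deterministic)."""
    cfg = pe.SimConfig(genome_length=12_000, n_cds=8, n_trna=2, n_rrna=1,
                       n_ctu_sites=40, n_gta_sites=6, polymorphism_decoy_count=6,
                       indel_adjacent_count=3, seed=11)
    genome, genes, truth, pileup = pe.simulate_dataset(cfg)
    return cfg, genome, genes, truth, pileup


def make_pileup(rows, w=4):
    """Build a Pileup from compact row dicts.

    Each row: pos, ref, and optional base-count dicts under the keys
    dna / fwd_clean / rev_clean / fwd_all / rev_all (all-pools default
    to the clean pools).
    """
    out = []
    for r in rows:
        rec = {"chrom": r.get("chrom", "p"), "pos": r["pos"], "ref": r["ref"]}
        pools = {
            "dna": r.get("dna", {}),
            "rna_fwd_clean": r.get("fwd_clean", {}),
            "rna_rev_clean": r.get("rev_clean", {}),
            "rna_fwd_all": r.get("fwd_all", r.get("fwd_clean", {})),
            "rna_rev_all": r.get("rev_all", r.get("rev_clean", {})),
        }
        for tag, counts in pools.items():
            for b in "ACGT":
                rec[f"{tag}_{b}"] = counts.get(b, 0)
        out.append(rec)
    frame = pd.DataFrame(out, columns=PILEUP_COLUMNS)
    return pe.Pileup(frame, w)
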