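"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each rule from first principles in the
plainest possible style (per-row loops, direct scipy calls) so they
share no code path with the vectorised implementation they check.
"""

from itertools import product

import numpy as np
from scipy import stats

BASES = "ACGT"
COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_force_call(pileup, params):
    """Exhaustive application of the calling rule set, row by row.

    Returns a set of (pos, strand, edit_base_sense, rescued) tuples.
    """
    out = set()
    frame = pileup.frame
    for _, row in frame.iterrows():
        ref = row["ref"]
        dna = {b: row[f"dna_{b}"] for b in BASES}
        dna_depth = sum(dna.values())
        if dna_depth < params.min_dna_depth:
            continue
        major = max(BASES, key=lambda b: dna[b])
        if major != ref or dna[major] / dna_depth < params.dna_major_allele_min_fraction:
            continue
        def evaluate(pool, orient, other):
            """Full RNA-side rule set on one pool; returns the edit base
            (genomic space) if every criterion holds, else None. Also
            reports whether the depth/edited-read floors held."""
            counts = {b: row[f"rna_{orient}_{pool}_{b}"] for b in BASES}
            othr = {b: row[f"rna_{other}_{pool}_{b}"] for b in BASES}
            n = sum(counts.values())
            alt = sorted((b for b in BASES if b != ref),
                         key=lambda b: (-counts[b], b))[0]
            k = counts[alt]
            floors = n >= params.min_rna_depth and k >= params.min_edited_reads
            if not floors:
                return None, floors
            if stats.binom.sf(k - 1, n, params.error_rate) > params.alpha:
                return None, floors
            if k / n < params.min_efficiency:
                return None, floors
            if k / (k + othr[alt]) < params.strand_purity:
                return None, floors
            return alt, floors

        for strand, orient, other in (("+", "fwd", "rev"), ("-", "rev", "fwd")):
            alt, clean_floors = evaluate("clean", orient, other)
            if alt is not None:
                edit_sense = alt if strand == "+" else COMP[alt]
                out.add((int(row["pos"]), strand, edit_sense, False))
                continue
            if params.rescue_enabled and not clean_floors:
                alt, _ = evaluate("all", orient, other)
                if alt is not None:
                    edit_sense = alt if strand == "+" else COMP[alt]
                    out.add((int(row["pos"]), strand, edit_sense, True))
    return out


def enumeration_likelihood(matrix, ti, model):
    """Sum over all internal-state assignments (trees of <= ~6 tips)."""
    internal = [i for i in range(len(ti.nodes)) if ti.children[i]]
    loglik = 0.0
    for site in matrix.columns:
        obs = {lbl: matrix.loc[lbl, site] for lbl in matrix.index}
        total = 0.0
        tip_states = {}
        for i, lbl in ti.tip_label.items():
            v = obs.get(lbl, np.nan)
            tip_states[i] = [0, 1] if np.isnan(v) else [int(v)]
        tip_ids = list(tip_states)
        for assign in product([0, 1], repeat=len(internal)):
            st = dict(zip(internal, assign))
            for tips in product(*(tip_states[i] for i in tip_ids)):
                st.update(dict(zip(tip_ids, tips)))
                p = model.prior()[st[ti.root]]
                for b in range(len(ti.nodes)):
                    if ti.parent[b] >= 0:
                        P = model.transition(ti.length[b])
                        p *= P[st[ti.parent[b]], st[b]]
                total += p
        loglik += np.log(total)
    return loglik


def enumeration_fitch(pattern, ti):
    """Minimal changes by exhaustive enumeration of internal states."""
    internal = [i for i in range(len(ti.nodes)) if ti.children[i]]
    best = np.inf
    tip_states = {}
    for i, lbl in ti.tip_label.items():
        v = pattern.get(lbl, np.nan)
        tip_states[i] = [0, 1] if (v is None or (isinstance(v, float) and np.isnan(v))) else [int(v)]
    tip_ids = list(tip_states)
    for assign in product([0, 1], repeat=len(internal)):
        st = dict(zip(internal, assign))
        for tips in product(*(tip_states[i] for i in tip_ids)):
            st.update(dict(zip(tip_ids, tips)))
            changes = sum(
                st[b] != st[ti.parent[b]]
                for b in range(len(ti.nodes))
                if ti.parent[b] >= 0
            )
            best = min(best, changes)
    return int(best)


def random_pileup_frame(rng, n_positions=120, chrom="c"):
    """Random pileup rows exercising the caller's decision boundaries."""
    import pandas as pd

    rows = []
    for pos in range(1, n_positions + 1):
        ref = BASES[rng.integers(4)]
        style = rng.integers(6)
        dna = {b: 0 for b in BASES}
        if style == 0:  # shallow DNA
            dna[ref] = int(rng.integers(0, 10))
        elif style == 1:  # polymorphic
            dna[ref] = int(rng.integers(10, 30))
            dna[BASES[(BASES.index(ref) + 1) % 4]] = int(rng.integers(3, 20))
        elif style == 2:  # consensus mismatch
            dna[BASES[(BASES.index(ref) + 1) % 4]] = int(rng.integers(15, 40))
        else:
            dna[ref] = int(rng.integers(10, 60))
        row = {"chrom": chrom, "pos": pos, "ref": ref}
        for b in BASES:
            row[f"dna_{b}"] = dna[b]
        for orient in ("fwd", "rev"):
            alln = {b: 0 for b in BASES}
            depth = int(rng.integers(0, 60))
            alt = BASES[rng.integers(4)]
            frac = rng.random()
            edited = int(round(depth * frac)) if alt != ref else 0
            alln[ref] = depth - edited
            alln[alt] = alln.get(alt, 0) + edited
            keep = rng.random()
            clean = {b: int(rng.binomial(alln[b], keep)) if rng.integers(2) else alln[b]
                     for b in BASES}
            for b in BASES:
                row[f"rna_{orient}_clean_{b}"] = clean[b]
                row[f"rna_{orient}_all_{b}"] = alln[b]
        rows.append(row)
    return pd.DataFrame(rows)
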