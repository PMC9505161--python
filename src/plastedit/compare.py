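"""Cross-species homology mapping of editing sites, intersection counts
and per-gene editing-site density.

Homologous sites are keyed by (gene, alignment column) from per-gene
multiple alignments supplied as inputs; a small progressive
Needleman-Wunsch aligner (match 1, mismatch -1, gap -2) is included for
self-contained tests only.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import EditingSite, GeneModel, ValidationError


def map_to_columns(
    alignments: Dict[str, Dict[str, str]],
    sites_per_species: Dict[str, List[Tuple[str, int]]],
    spliced_sequences: Optional[Dict[str, Dict[str, str]]] = None,
) -> Tuple[pd.DataFrame, List[Tuple[str, str, int]]]:
    """Assemble the species x homologous-site presence matrix.

    Parameters
    ----------
    alignments
        gene_id -> {species -> aligned (gapped) sequence}.
    sites_per_species
        species -> list of (gene_id, spliced 1-based position) sites.
    spliced_sequences
        optional gene_id -> {species -> ungapped spliced sequence}; when
        given, each species' ungapped alignment row must equal it.

    Returns the matrix (1 present, 0 absent, NaN when the species lacks
    the gene) with columns labelled ``gene:column`` (1-based alignment
    column), plus the list of unmapped sites (gene without an alignment,
    or species missing from the gene's alignment).
    """
    species = sorted(sites_per_species)
    # position -> column lookup per (gene, species)
    colmap: Dict[Tuple[str, str], np.ndarray] = {}
    for gene, rows in alignments.items():
        ncol = {len(s) for s in rows.values()}
        if len(ncol) > 1:
            raise ValidationError(f"{gene}: aligned sequences differ in length")
        for sp, aligned in rows.items():
            ungapped = aligned.replace("-", "")
            if spliced_sequences and gene in spliced_sequences and sp in spliced_sequences[gene]:
                if ungapped != spliced_sequences[gene][sp]:
                    raise ValidationError(
                        f"ungapped alignment row does not match spliced gene "
                        f"sequence for species {sp!r}, gene {gene!r}"
                    )
            cols = [i + 1 for i, ch in enumerate(aligned) if ch != "-"]
            colmap[(gene, sp)] = np.asarray(cols, dtype=np.int64)

    present: Dict[str, Dict[str, int]] = {sp: {} for sp in species}
    unmapped: List[Tuple[str, str, int]] = []
    columns: set = set()
    for sp, sites in sites_per_species.items():
        for gene, pos in sites:
            key = (gene, sp)
            if key not in colmap:
                unmapped.append((sp, gene, pos))
                continue
            cols = colmap[key]
            if not 1 <= pos <= len(cols):
                raise ValidationError(
                    f"site {gene}:{pos} beyond ungapped length for species {sp!r}"
                )
            label = f"{gene}:{cols[pos - 1]}"
            present[sp][label] = 1
            columns.add(label)

    def _sort_key(label: str):
        gene, col = label.rsplit(":", 1)
        return (gene, int(col))

    col_order = sorted(columns, key=_sort_key)
    matrix = pd.DataFrame(np.nan, index=species, columns=col_order)
    for label in col_order:
        gene = label.rsplit(":", 1)[0]
        for sp in species:
            if (gene, sp) in colmap:
                matrix.loc[sp, label] = present[sp].get(label, 0)
    return matrix, unmapped


def intersections(matrix: pd.DataFrame, lineages: Dict[str, str]) -> Dict:
    """UpSet-style intersection counts at lineage level.

    A column belongs to a lineage if >= 1 member species is present (1);
    a lineage whose members are all missing (NaN) for a column does not
    enter that column's combination key. Returns exclusive combination
    counts (UpSet cells), pairwise shared counts, and per-lineage
    specific counts.
    """
    if matrix.empty:
        raise ValidationError("empty site matrix")
    missing = set(matrix.index) - set(lineages)
    if missing:
        raise ValidationError(f"species without lineage assignment: {sorted(missing)}")
    lineage_names = sorted(set(lineages.values()))
    members = {lin: [sp for sp in matrix.index if lineages[sp] == lin]
               for lin in lineage_names}
    exclusive: Dict[Tuple[str, ...], int] = {}
    pairwise = {pair: 0 for pair in combinations(lineage_names, 2)}
    for col in matrix.columns:
        v = matrix[col]
        combo = tuple(sorted(
            lin for lin in lineage_names
            if (v[members[lin]] == 1).any()
        ))
        if not combo:
            continue
        exclusive[combo] = exclusive.get(combo, 0) + 1
        for pair in combinations(combo, 2):
            pairwise[pair] += 1
    specific = {
        lin: exclusive.get((lin,), 0) for lin in lineage_names
    }
    return {"exclusive": exclusive, "pairwise": pairwise, "specific": specific}


def density(sites: Iterable[EditingSite], genes: List[GeneModel]) -> pd.DataFrame:
    """Editing sites per 1000 bp of spliced gene length, per gene."""
    counts = {g.gene_id: 0 for g in genes}
    for s in sites:
        if s.gene_id in counts and s.region in ("CDS", "tRNA", "rRNA"):
            counts[s.gene_id] += 1
    rows = []
    for g in genes:
        length = g.spliced_length
        if length == 0:
            raise ValidationError(f"{g.gene_id}: zero-length gene")
        rows.append({
            "gene_id": g.gene_id,
            "n_sites": counts[g.gene_id],
            "spliced_length": length,
            "density_per_kb": 1000.0 * counts[g.gene_id] / length,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Minimal progressive aligner for self-contained tests (match 1,
# mismatch -1, gap -2). Production alignments are inputs to
# map_to_columns, produced by a proper aligner.

MATCH, MISMATCH, GAP = 1, -1, -2


def needleman_wunsch(a: str, b: str) -> Tuple[str, str]:
    """Global pairwise alignment; ties prefer diagonal, then up (gap in b)."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    score[:, 0] = GAP * np.arange(n + 1)
    score[0, :] = GAP * np.arange(m + 1)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d = score[i - 1, j - 1] + (MATCH if a[i - 1] == b[j - 1] else MISMATCH)
            u = score[i - 1, j] + GAP
            l = score[i, j - 1] + GAP
            best = max(d, u, l)
            score[i, j] = best
            ptr[i, j] = 0 if best == d else (1 if best == u else 2)
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif p == 1:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def _merge_center(a: str, b: str) -> str:
    """Merge two gapped versions of the same ungapped center sequence."""
    out = []
    i = j = 0
    while i < len(a) or j < len(b):
        ca = a[i] if i < len(a) else None
        cb = b[j] if j < len(b) else None
        if ca is not None and cb is not None and ca != "-" and cb != "-":
            out.append(ca); i += 1; j += 1
        elif ca == "-" and cb == "-":
            out.append("-"); i += 1; j += 1
        elif ca == "-":
            out.append("-"); i += 1
        else:
            out.append("-"); j += 1
    return "".join(out)


def _project(gs: str, gc: str, master: str) -> str:
    """Re-gap ``gs`` (aligned against gapped center ``gc``) onto the
    merged master center."""
    out = []
    j = 0
    for ch in master:
        if j < len(gc) and ((ch != "-" and gc[j] != "-") or (ch == "-" and gc[j] == "-")):
            out.append(gs[j]); j += 1
        else:
            out.append("-")
    return "".join(out)


def progressive_align(seqs: Dict[str, str]) -> Dict[str, str]:
    """Center-star progressive alignment against the first sequence.

    Adequate for the near-identical gene sequences used in tests; not a
    substitute for a real MSA tool.
    """
    names = list(seqs)
    if not names:
        return {}
    if len(names) == 1:
        return dict(seqs)
    center = seqs[names[0]]
    pairs = {name: needleman_wunsch(center, seqs[name]) for name in names[1:]}
    master = center
    for gc, _ in pairs.values():
        master = _merge_center(master, gc)
    rows = {names[0]: master}
    for name in names[1:]:
        gc, gs = pairs[name]
        rows[name] = _project(gs, gc, master)
    return rows
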