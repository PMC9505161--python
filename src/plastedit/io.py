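"""Readers and writers for every external representation the pipeline touches.

Formats: FASTA (genomes, via Biopython), GFF3 (gene models), Newick
(species tree, via dendropy), the pileup TSV (header ``#indel_window=<w>``
then 21 tab-separated columns) and the site-table TSV.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, List, Optional

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

from .core import (
    BASES,
    EditingSite,
    FormatError,
    GeneModel,
    GenomeRecord,
    PileupRecord,
    SITE_TABLE_COLUMNS,
    ValidationError,
)

log = logging.getLogger(__name__)

PILEUP_COLUMNS = (
    ["chrom", "pos", "ref"]
    + [f"dna_{b}" for b in BASES]
    + [f"rna_fwd_clean_{b}" for b in BASES]
    + [f"rna_rev_clean_{b}" for b in BASES]
    + [f"rna_fwd_all_{b}" for b in BASES]
    + [f"rna_rev_all_{b}" for b in BASES]
)


def read_genome(path, circular: bool = True) -> List[GenomeRecord]:
    """Read all records of a FASTA file as GenomeRecords (file order)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        g = GenomeRecord(id=rec.id, sequence=seq, circular=circular)
        if g.has_ambiguous:
            log.warning("genome %s contains ambiguous (N) bases", g.id)
        records.append(g)
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_genome(records: Iterable[GenomeRecord], path) -> None:
    with open(path, "w") as fh:
        for g in records:
            fh.write(f">{g.id}\n")
            for i in range(0, len(g.sequence), 70):
                fh.write(g.sequence[i : i + 70] + "\n")


_BIOTYPES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _attr(attrs: str, *keys: str) -> Optional[str]:
    d = {}
    for item in attrs.strip().split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            d[k.strip()] = v.strip()
    for k in keys:
        if k in d:
            return d[k]
    return None


def read_genes(path) -> List[GeneModel]:
    """Parse a GFF3 file into GeneModels.

    Exon/CDS features are grouped per gene via their ID/gene/Parent
    attribute; strand and phase propagate to the model. Features of
    unknown biotype are skipped with a warning.
    """
    groups: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, phase, attrs = parts
            if ftype == "gene":
                continue  # intervals come from exon/CDS features
            if ftype == "exon":
                continue  # paired with a typed feature; the typed line is authoritative
            if ftype not in _BIOTYPES:
                log.warning("%s:%d: skipping feature of unknown biotype %r", path, lineno, ftype)
                continue
            gid = _attr(attrs, "ID", "gene", "Parent")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: feature lacks ID/gene/Parent attribute")
            gid = gid.split(".")[0]
            key = (gid, ftype)
            entry = groups.setdefault(key, {"strand": strand, "exons": [], "phase": None})
            entry["exons"].append((int(start), int(end)))
            if strand != entry["strand"]:
                raise ValidationError(f"{gid}: inconsistent strand across exons")
            if phase in ("0", "1", "2"):
                # codon_start derives from the phase of the 5'-most CDS segment
                key5 = int(start) if strand == "+" else -int(end)
                if entry["phase"] is None or key5 < entry["phase"][0]:
                    entry["phase"] = (key5, int(phase))
    genes = []
    for (gid, ftype), entry in groups.items():
        codon_start = entry["phase"][1] + 1 if entry["phase"] is not None else 1
        genes.append(
            GeneModel(
                gene_id=gid,
                biotype=ftype,
                strand=entry["strand"],
                exons=entry["exons"],
                codon_start=codon_start,
            )
        )
    genes.sort(key=lambda g: g.span)
    return genes


def write_genes(genes: Iterable[GeneModel], path, chrom: str = "plastome") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = g.span
            fh.write(
                f"{chrom}\tplastedit\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons):
                phase = "."
                if g.biotype == "CDS":
                    first = i == 0 if g.strand == "+" else i == len(g.exons) - 1
                    phase = str(g.codon_start - 1) if first else "0"
                fh.write(
                    f"{chrom}\tplastedit\t{g.biotype}\t{s}\t{e}\t.\t{g.strand}\t{phase}\t"
                    f"ID={g.gene_id}.{i};Parent={g.gene_id}\n"
                )


class Pileup:
    """A pileup table: one row per position, plus the indel window ``w``."""

    def __init__(self, frame: pd.DataFrame, indel_window: int):
        self.frame = frame.reset_index(drop=True)
        self.indel_window = int(indel_window)
        self._validate()

    def _validate(self) -> None:
        f = self.frame
        counts = f[PILEUP_COLUMNS[3:]].to_numpy()
        if (counts < 0).any():
            raise ValidationError("negative counts in pileup")
        for pool in ("rna_fwd", "rna_rev"):
            clean = f[[f"{pool}_clean_{b}" for b in BASES]].to_numpy()
            allc = f[[f"{pool}_all_{b}" for b in BASES]].to_numpy()
            bad = np.nonzero((clean > allc).any(axis=1))[0]
            if bad.size:
                r = f.iloc[bad[0]]
                raise ValidationError(
                    f"{r['chrom']}:{r['pos']}: clean counts exceed all counts"
                )
        for chrom, sub in f.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if (np.diff(pos) <= 0).any():
                i = int(np.nonzero(np.diff(pos) <= 0)[0][0])
                raise ValidationError(
                    f"{chrom}: positions not strictly increasing at row {sub.index[i + 1] + 2}"
                )

    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterable[PileupRecord]:
        f = self.frame
        dna = f[[f"dna_{b}" for b in BASES]].to_numpy()
        pools = {
            p: f[[f"{p}_{b}" for b in BASES]].to_numpy()
            for p in ("rna_fwd_clean", "rna_rev_clean", "rna_fwd_all", "rna_rev_all")
        }
        for i in range(len(f)):
            yield PileupRecord(
                chrom=f["chrom"].iat[i],
                pos=int(f["pos"].iat[i]),
                ref_base=f["ref"].iat[i],
                dna=dna[i],
                rna_fwd_clean=pools["rna_fwd_clean"][i],
                rna_rev_clean=pools["rna_rev_clean"][i],
                rna_fwd_all=pools["rna_fwd_all"][i],
                rna_rev_all=pools["rna_rev_all"][i],
            )

    @classmethod
    def from_records(cls, records: Iterable[PileupRecord], indel_window: int) -> "Pileup":
        rows = []
        for r in records:
            rows.append(
                [r.chrom, r.pos, r.ref_base]
                + list(r.dna)
                + list(r.rna_fwd_clean)
                + list(r.rna_rev_clean)
                + list(r.rna_fwd_all)
                + list(r.rna_rev_all)
            )
        frame = pd.DataFrame(rows, columns=PILEUP_COLUMNS)
        return cls(frame, indel_window)


def read_pileup(path) -> Pileup:
    """Read the pileup TSV (``#indel_window=<w>`` header, 21 columns)."""
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#indel_window="):
            raise FormatError(f"{path}: missing '#indel_window=<w>' header line")
        w = int(first.split("=", 1)[1])
        frame = pd.read_csv(fh, sep="\t", dtype={"chrom": str, "ref": str})
    missing = set(PILEUP_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return Pileup(frame[PILEUP_COLUMNS], w)


def write_pileup(pileup: Pileup, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#indel_window={pileup.indel_window}\n")
        pileup.frame.to_csv(fh, sep="\t", index=False)


def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Raises for an unrooted (trifurcating-root) tree and for duplicate
    tip labels; zero-length branches are permitted but logged.
    """
    src = str(path_or_string)
    try:
        if src.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=src, schema=schema,
                                     suppress_internal_node_taxa=True)
        else:
            tree = dendropy.Tree.get(path=src, schema=schema,
                                     suppress_internal_node_taxa=True)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValidationError(f"duplicate tip label(s): {exc}") from exc
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        raise ValidationError(
            "tree root is a polytomy: root the tree on an outgroup before use"
        )
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate tip label(s): {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValidationError("tree has branches without lengths")
        if edge.length == 0:
            log.warning("zero-length branch above %s", edge.head_node)
    return tree


def write_site_table(sites: List[EditingSite], path) -> None:
    """Write the fixed-column site-table TSV (round-trips losslessly)."""
    sites_to_frame(sites).to_csv(path, sep="\t", index=False, float_format="%.17g")


def sites_to_frame(sites: List[EditingSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append({
            "chrom": s.chrom, "pos": s.pos, "strand": s.strand, "type": s.type,
            "efficiency": s.efficiency, "dna_depth": s.dna_depth,
            "rna_depth": s.rna_depth, "p_value": s.p_value, "rescued": s.rescued,
            "region": s.region, "gene_id": s.gene_id, "site_label": s.site_label,
            "codon_pos": s.codon_pos, "ref_codon": s.ref_codon,
            "edit_codon": s.edit_codon, "aa_ref": s.aa_ref, "aa_edit": s.aa_edit,
            "synonymous": s.synonymous, "hydropathy": s.hydropathy,
            "context": s.context,
        })
    return pd.DataFrame(rows, columns=SITE_TABLE_COLUMNS)


def read_site_table(path) -> List[EditingSite]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                        float_precision="round_trip")
    sites = []

    def _opt(v):
        return None if pd.isna(v) else v

    for _, r in frame.iterrows():
        ref_u, edit_u = r["type"].split("-to-")
        t = {"U": "T"}
        codon_pos = _opt(r["codon_pos"])
        syn = _opt(r["synonymous"])
        sites.append(EditingSite(
            chrom=r["chrom"], pos=int(r["pos"]), strand=r["strand"],
            ref_sense=t.get(ref_u, ref_u), edit_sense=t.get(edit_u, edit_u),
            efficiency=float(r["efficiency"]), dna_depth=int(r["dna_depth"]),
            rna_depth=int(r["rna_depth"]), p_value=float(r["p_value"]),
            rescued=bool(r["rescued"]), region=_opt(r["region"]),
            gene_id=_opt(r["gene_id"]), site_label=_opt(r["site_label"]),
            codon_pos=None if codon_pos is None else int(codon_pos),
            ref_codon=_opt(r["ref_codon"]), edit_codon=_opt(r["edit_codon"]),
            aa_ref=_opt(r["aa_ref"]), aa_edit=_opt(r["aa_edit"]),
            synonymous=None if syn is None else bool(syn),
            hydropathy=_opt(r["hydropathy"]), context=_opt(r["context"]),
        ))
    return sites


def read_features(path) -> pd.DataFrame:
    """Read the per-species feature table (plastome size, GC/C content,
    substitution rates, editing-site counts)."""
    f = pd.read_csv(path, sep="\t")
    for col in ("gc_content", "c_content"):
        if col in f.columns:
            v = f[col].dropna()
            if ((v < 0) | (v > 1)).any():
                raise ValidationError(f"{col}: fractions must lie in [0,1]")
    for col in ("dN", "dS", "RN", "RS"):
        if col in f.columns and (f[col].dropna() < 0).any():
            raise ValidationError(f"{col}: rates must be non-negative")
    return f
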