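"""Cohort-level summaries and Pearson correlations.

``summarize_cohort`` builds the per-species-by-editing-type summary
table (totals, codon-position counts, silent/nonsynonymous split,
tRNA/rRNA/intron/intergenic counts) with its marginal identities
enforced; ``correlate_features`` tests plastome features against
editing-site abundance.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import EditingSite, ValidationError

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "species", "type", "total", "codon1", "codon2", "codon3",
    "silent", "nonsynonymous", "tRNA", "rRNA", "intron", "intergenic",
]

FACTORS = ["plastome_size", "gc_content", "c_content", "dN", "dS", "RN", "RS"]


@dataclass
class CorrelationResult:
    factor: str
    r: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValidationError("correlation coefficient outside [-1,1]")


def pearson(x, y, factor: str = "") -> CorrelationResult:
    """Product-moment correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("pearson: input lengths differ")
    n = len(x)
    if n < 3:
        raise ValidationError("pearson: need n >= 3 for a p-value")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("constant input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(factor=factor, r=float(r), p_value=float(p), n=n)


def correlate_features(features: pd.DataFrame) -> List[CorrelationResult]:
    """Correlate each available factor against n_editing_sites,
    dropping incomplete rows pairwise; constant factors are skipped
    with a warning."""
    if "n_editing_sites" not in features.columns:
        raise ValidationError("feature table lacks n_editing_sites")
    out = []
    for factor in FACTORS:
        if factor not in features.columns:
            continue
        sub = features[[factor, "n_editing_sites"]].dropna()
        if len(sub) < 3:
            log.warning("%s: fewer than 3 complete rows; skipped", factor)
            continue
        if np.ptp(sub[factor].to_numpy()) == 0:
            log.warning("%s: constant factor column; skipped", factor)
            continue
        out.append(pearson(sub[factor], sub["n_editing_sites"], factor=factor))
    return out


def _summary_row(species: str, etype: str, sites: List[EditingSite]) -> Dict:
    coding = [s for s in sites if s.region == "CDS" and s.codon_pos is not None]
    row = {
        "species": species,
        "type": etype,
        "total": len(sites),
        "codon1": sum(1 for s in coding if s.codon_pos == 1),
        "codon2": sum(1 for s in coding if s.codon_pos == 2),
        "codon3": sum(1 for s in coding if s.codon_pos == 3),
        "silent": sum(1 for s in coding if s.synonymous),
        "nonsynonymous": sum(1 for s in coding if not s.synonymous),
        "tRNA": sum(1 for s in sites if s.region == "tRNA"),
        "rRNA": sum(1 for s in sites if s.region == "rRNA"),
        "intron": sum(1 for s in sites if s.region == "intron"),
        "intergenic": sum(1 for s in sites if s.region == "intergenic"),
    }
    return row


def _check_identities(frame: pd.DataFrame) -> None:
    coding = frame["codon1"] + frame["codon2"] + frame["codon3"]
    if not (coding == frame["silent"] + frame["nonsynonymous"]).all():
        raise ValidationError("summary identity violated: coding != silent + nonsynonymous")
    noncoding = frame["tRNA"] + frame["rRNA"] + frame["intron"] + frame["intergenic"]
    if not (frame["total"] == coding + noncoding).all():
        raise ValidationError("summary identity violated: total != coding + noncoding")


def summarize_cohort(per_species: Dict[str, List[EditingSite]]) -> pd.DataFrame:
    """Per species x editing type summary with a Total row per type.

    Requires annotated sites. Raises on marginal-identity violations
    (coding = 1st + 2nd + 3rd = silent + nonsynonymous; total = coding
    + non-coding).
    """
    rows = []
    types_seen = set()
    for species, sites in per_species.items():
        by_type: Dict[str, List[EditingSite]] = {}
        for s in sites:
            by_type.setdefault(s.type, []).append(s)
        for etype in sorted(by_type):
            rows.append(_summary_row(species, etype, by_type[etype]))
            types_seen.add(etype)
    frame = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    if frame.empty:
        frame = pd.DataFrame(columns=SUMMARY_COLUMNS)
        total = {c: 0 for c in SUMMARY_COLUMNS[2:]}
        total.update({"species": "Total", "type": "all"})
        return pd.concat([frame, pd.DataFrame([total])], ignore_index=True)
    _check_identities(frame)
    totals = []
    for etype in sorted(types_seen):
        sub = frame[frame["type"] == etype]
        t = {"species": "Total", "type": etype}
        for c in SUMMARY_COLUMNS[2:]:
            t[c] = int(sub[c].sum())
        totals.append(t)
    return pd.concat([frame, pd.DataFrame(totals)], ignore_index=True)


def load_table1() -> pd.DataFrame:
    """The packaged per-species gymnosperm cohort summary (19 species,
    C-to-U and G-to-A rows), in SUMMARY_COLUMNS shape without Total
    rows."""
    ref = importlib.resources.files("plastedit.data").joinpath("table1.tsv")
    with importlib.resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t")
    frame = frame[SUMMARY_COLUMNS]
    _check_identities(frame)
    return frame


def cohort_totals(frame: pd.DataFrame) -> Dict[str, int]:
    """Per-type grand totals of a summary frame (Total rows excluded)."""
    body = frame[frame["species"] != "Total"]
    return {
        etype: int(body.loc[body["type"] == etype, "total"].sum())
        for etype in body["type"].unique()
    }


def species_totals(frame: pd.DataFrame) -> pd.Series:
    """Total editing sites per species across types."""
    body = frame[frame["species"] != "Total"]
    return body.groupby("species", sort=False)["total"].sum()
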