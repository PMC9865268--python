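"""Promoter scanning for cis-regulatory elements.

Matching is exact against IUPAC degenerate consensus strings from a
built-in plant catalogue (ABRE, MBS, LTR, G-box, and friends), on both
strands.  This deliberately avoids position-weight-matrix scoring: the
downstream claims are presence/absence and position, for which exact
IUPAC matching is deterministic and auditable.

Positions are 1-based from the promoter 5' end (reading toward the
ATG); minus-strand hits are reported at plus-strand coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seq_io import revcomp

__all__ = [
    "CisElement",
    "CisHit",
    "IUPAC_CODES",
    "BUILTIN_CATALOG",
    "load_catalog",
    "scan_promoter",
    "scan_promoters",
    "summarize_categories",
    "match_probability",
]

# IUPAC degenerate nucleotide codes.  N in a *promoter* never matches
# any consensus symbol; N in a consensus matches any promoter base.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

CATEGORIES = ("light", "hormone", "stress", "growth/metabolic")

# Elements associated with the drought response (ABA-responsive element
# and the MYB binding site of drought-inducible promoters).
DROUGHT_ELEMENTS = frozenset({"ABRE", "MBS"})


@dataclass(frozen=True)
class CisElement:
    """A named cis-regulatory element with an IUPAC consensus."""

    name: str
    consensus: str
    category: str

    def __post_init__(self) -> None:
        if len(self.consensus) < 4:
            raise ValueError(f"{self.name}: consensus shorter than 4 bases")
        bad = sorted(set(self.consensus.upper()) - set(IUPAC_CODES))
        if bad:
            raise ValueError(f"{self.name}: invalid IUPAC symbol(s) {bad}")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")
        object.__setattr__(self, "consensus", self.consensus.upper())


@dataclass(frozen=True)
class CisHit:
    """One element occurrence on a promoter."""

    gene_id: str
    element: str
    category: str
    start: int  # 1-based on the plus (promoter) strand
    strand: str
    matched: str


# Published PlantCARE consensus strings for the element families the
# promoter survey reports: light, hormone (ABA/SA/MeJA/GA/IAA), stress
# (drought/low-temperature/defense/anaerobic) and growth/metabolic.
BUILTIN_CATALOG: tuple[CisElement, ...] = (
    CisElement("ABRE", "ACGTG", "hormone"),
    CisElement("MBS", "CAACTG", "stress"),
    CisElement("LTR", "CCGAAA", "stress"),
    CisElement("ARE", "AAACCA", "stress"),
    CisElement("TC-rich", "ATTCTCTAAC", "stress"),
    CisElement("W-box", "TTGACC", "stress"),
    CisElement("CGTCA-motif", "CGTCA", "hormone"),
    CisElement("TGACG-motif", "TGACG", "hormone"),
    CisElement("TCA-element", "CCATCTTTTT", "hormone"),
    CisElement("GARE-motif", "TCTGTTG", "hormone"),
    CisElement("P-box", "CCTTTTG", "hormone"),
    CisElement("TGA-element", "AACGAC", "hormone"),
    CisElement("G-box", "CACGTG", "light"),
    CisElement("Box4", "ATTAAT", "light"),
    CisElement("GT1-motif", "GGTTAA", "light"),
    CisElement("I-box", "GATAAGGR", "light"),
    CisElement("CAT-box", "GCCACT", "growth/metabolic"),
    CisElement("O2-site", "GATGACATGG", "growth/metabolic"),
    CisElement("CCGTCC-box", "CCGTCC", "growth/metabolic"),
)


def load_catalog(path: str | Path | None = None) -> list[CisElement]:
    """Load a catalogue from a name/consensus/category TSV, or the builtin."""
    if path is None:
        return list(BUILTIN_CATALOG)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "consensus", "category"}
    if not required <= set(df.columns):
        raise ValueError(f"catalogue TSV must have columns {sorted(required)}")
    return [
        CisElement(str(r["name"]), str(r["consensus"]), str(r["category"]))
        for _, r in df.iterrows()
    ]


def _iupac_match(window: str, consensus: str) -> bool:
    for base, code in zip(window, consensus):
        if base not in IUPAC_CODES[code]:  # promoter N is never in a code set
            return False
    return True


def scan_promoter(
    gene_id: str, promoter: str, catalog: Sequence[CisElement] | None = None
) -> list[CisHit]:
    """All IUPAC-compatible element matches on both strands of a promoter.

    Overlapping hits are all reported.  Minus-strand matches (the
    reverse complement of the consensus on the plus strand) are given at
    plus-strand coordinates with strand "−" represented as ``"-"``.
    """
    if catalog is None:
        catalog = BUILTIN_CATALOG
    promoter = promoter.upper()
    hits: list[CisHit] = []
    for element in catalog:
        m = len(element.consensus)
        rc_consensus = revcomp(element.consensus)
        for start0 in range(len(promoter) - m + 1):
            window = promoter[start0 : start0 + m]
            if "N" in window:
                continue
            if _iupac_match(window, element.consensus):
                hits.append(
                    CisHit(gene_id, element.name, element.category, start0 + 1, "+", window)
                )
            if _iupac_match(window, rc_consensus):
                hits.append(
                    CisHit(gene_id, element.name, element.category, start0 + 1, "-", window)
                )
    hits.sort(key=lambda h: (h.start, h.element, h.strand))
    return hits


def scan_promoters(
    promoters: Mapping[str, str], catalog: Sequence[CisElement] | None = None
) -> list[CisHit]:
    hits: list[CisHit] = []
    for gene_id in promoters:
        hits.extend(scan_promoter(gene_id, promoters[gene_id], catalog))
    return hits


def summarize_categories(hits: Iterable[CisHit], gene_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-gene element counts by functional category.

    Returns a DataFrame indexed by gene with one column per category plus
    a boolean ``drought_flag`` (true iff the gene has ≥ 1 ABRE or MBS hit).
    """
    hits = list(hits)
    genes = list(gene_ids) if gene_ids is not None else sorted({h.gene_id for h in hits})
    df = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"), columns=list(CATEGORIES))
    flags = pd.Series(False, index=df.index, name="drought_flag")
    for hit in hits:
        if hit.gene_id not in df.index:
            continue
        df.loc[hit.gene_id, hit.category] += 1
        if hit.element in DROUGHT_ELEMENTS:
            flags.loc[hit.gene_id] = True
    df["drought_flag"] = flags
    return df


def match_probability(consensus: str) -> float:
    """Per-window probability that an i.i.d. uniform ACGT window matches
    the consensus on the plus strand."""
    p = 1.0
    for code in consensus.upper():
        p *= len(IUPAC_CODES[code]) / 4.0
    return p
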