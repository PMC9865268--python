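"""FASTA/GFF3 readers and sequence extraction.

Coordinate conventions used throughout the package:

* genome coordinates are 1-based inclusive, as in GFF3;
* intervals are stored sorted ascending regardless of strand;
* a gene's promoter is the stretch immediately 5' of its CDS start
  (the ATG), reverse-complemented for minus-strand genes.

When a locus has several mRNAs, :func:`read_gff3` keeps the isoform with
the longest total CDS — the standard convention in gene-family surveys.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "GeneModel",
    "SequenceRecord",
    "FastaParseError",
    "Gff3ParseError",
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "extract_cds",
    "translate",
    "extract_promoter",
    "revcomp",
]


class FastaParseError(ValueError):
    """Raised for malformed or inconsistent FASTA input."""


class Gff3ParseError(ValueError):
    """Raised for malformed GFF3 input (e.g. broken Parent linkage)."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence; upper-case, whitespace-free."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("sequence record with empty id")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """One mRNA's coordinate skeleton on the genome.

    ``cds_intervals`` and ``exon_intervals`` are lists of ``(start, end)``
    tuples, 1-based inclusive, sorted ascending and non-overlapping.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_intervals: list[tuple[int, int]] = field(default_factory=list)
    exon_intervals: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        for name in ("cds_intervals", "exon_intervals"):
            ivals = sorted(getattr(self, name))
            for start, end in ivals:
                if start > end:
                    raise ValueError(f"{self.gene_id}: interval {start}>{end} in {name}")
            for (_, e1), (s2, _) in zip(ivals, ivals[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.gene_id}: overlapping intervals in {name}")
            setattr(self, name, ivals)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        ivals = self.exon_intervals or self.cds_intervals
        return ivals[0][0], ivals[-1][1]

    @property
    def cds_start(self) -> int:
        """Genome position of the first CDS base in transcription order."""
        if self.strand == "+":
            return self.cds_intervals[0][0]
        return self.cds_intervals[-1][1]


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | Path, alphabet: str = "auto") -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Sequences are upper-cased and whitespace-stripped.  Duplicate ids and
    empty files raise :class:`FastaParseError`.  ``alphabet`` may be
    ``"nucleotide"``, ``"protein"`` or ``"auto"`` (no check).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if not first:
            raise FastaParseError(f"{path}: empty file")
        if first != ">":
            raise FastaParseError(f"{path}: line 1: expected '>' header")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seen:
                raise FastaParseError(f"{path}: duplicated id {rec.id!r}")
            seen.add(rec.id)
            seq = str(rec.seq).upper().replace(" ", "")
            if alphabet == "nucleotide" and not set(seq) <= NUCLEOTIDE_ALPHABET:
                bad = sorted(set(seq) - NUCLEOTIDE_ALPHABET)
                raise FastaParseError(f"{path}: {rec.id}: non-nucleotide symbols {bad}")
            if alphabet == "protein" and not set(seq) <= PROTEIN_ALPHABET:
                bad = sorted(set(seq) - PROTEIN_ALPHABET)
                raise FastaParseError(f"{path}: {rec.id}: non-protein symbols {bad}")
            records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in col9.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            continue
        key, _, value = part.partition("=")
        attrs[key] = value
    return attrs


def read_gff3(path: str | Path, longest_isoform: bool = True) -> list[GeneModel]:
    """Parse gene/mRNA/CDS/exon features from a GFF3 file.

    Returns one :class:`GeneModel` per mRNA (or per gene when
    ``longest_isoform`` is set, keeping the mRNA with the longest CDS).
    mRNAs without CDS features are skipped with a logged warning.  CDS or
    exon rows whose Parent is not a known mRNA raise
    :class:`Gff3ParseError`.
    """
    path = Path(path)
    mrna_info: dict[str, dict] = {}
    mrna_gene: dict[str, str] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise Gff3ParseError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
            if ftype not in {"mRNA", "CDS", "exon"}:
                continue
            attrs = _parse_attributes(col9)
            start, end = int(start_s), int(end_s)
            if ftype == "mRNA":
                mid = attrs.get("ID")
                if not mid:
                    raise Gff3ParseError(f"{path}:{lineno}: mRNA without ID")
                mrna_info[mid] = {"chrom": chrom, "strand": strand, "cds": [], "exon": []}
                mrna_gene[mid] = attrs.get("Parent", mid)
                order.append(mid)
            else:
                parent = attrs.get("Parent")
                if parent is None:
                    raise Gff3ParseError(f"{path}:{lineno}: {ftype} feature without Parent")
                for pid in parent.split(","):
                    if pid not in mrna_info:
                        raise Gff3ParseError(
                            f"{path}:{lineno}: {ftype} Parent={pid!r} does not match any mRNA"
                        )
                    mrna_info[pid]["cds" if ftype == "CDS" else "exon"].append((start, end))

    models: list[GeneModel] = []
    for mid in order:
        info = mrna_info[mid]
        if not info["cds"]:
            logger.warning("%s: mRNA %s has no CDS features; skipped", path, mid)
            continue
        models.append(
            GeneModel(
                gene_id=mid,
                chromosome=info["chrom"],
                strand=info["strand"],
                cds_intervals=info["cds"],
                exon_intervals=info["exon"] or list(info["cds"]),
            )
        )
    if longest_isoform:
        best: dict[str, GeneModel] = {}
        for gm in models:
            locus = mrna_gene.get(gm.gene_id, gm.gene_id)
            if locus not in best or gm.cds_length > best[locus].cds_length:
                best[locus] = gm
        kept = set(id(gm) for gm in best.values())
        models = [gm for gm in models if id(gm) in kept]
    return models


def _chromosome_of(genome: Mapping[str, SequenceRecord], gm: GeneModel) -> str:
    if gm.chromosome not in genome:
        raise KeyError(f"{gm.gene_id}: chromosome {gm.chromosome!r} absent from genome")
    return genome[gm.chromosome].seq


def extract_cds(genome: Mapping[str, SequenceRecord], gm: GeneModel) -> str:
    """Concatenated CDS of a gene, in transcription order (5'→3' mRNA)."""
    chrom = _chromosome_of(genome, gm)
    parts = []
    for start, end in gm.cds_intervals:
        if start < 1 or end > len(chrom):
            raise ValueError(
                f"{gm.gene_id}: CDS interval ({start},{end}) outside chromosome "
                f"{gm.chromosome} (length {len(chrom)})"
            )
        parts.append(chrom[start - 1 : end])
    cds = "".join(parts)
    return revcomp(cds) if gm.strand == "-" else cds


def translate(cds: str, internal_stop: str = "error") -> str:
    """Translate a CDS with the standard genetic code.

    A trailing stop codon is removed.  An internal stop raises
    ``ValueError`` by default; with ``internal_stop="X"`` it is emitted as
    ``X``.  Codons containing non-ACGT characters translate to ``X``.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    aa: list[str] = []
    n_codons = len(cds) // 3
    for i in range(n_codons):
        codon = cds[3 * i : 3 * i + 3].upper()
        if set(codon) <= set("ACGT"):
            res = str(Seq(codon).translate())
        else:
            res = "X"
        if res == "*":
            if i == n_codons - 1:
                break
            if internal_stop == "error":
                raise ValueError(f"internal stop codon at codon {i + 1}")
            res = "X"
        aa.append(res)
    return "".join(aa)


def extract_promoter(
    genome: Mapping[str, SequenceRecord], gm: GeneModel, length: int = 2000
) -> str:
    """The ``length`` bases immediately upstream of the CDS start (ATG).

    Strand-aware: for minus-strand genes the promoter lies 3' of the CDS
    end in genome coordinates and is returned reverse-complemented, so the
    output always reads 5'→3' toward the ATG.  Truncated with a logged
    warning at the contig edge.
    """
    chrom = _chromosome_of(genome, gm)
    if gm.strand == "+":
        end = gm.cds_start - 1  # last promoter base, genome coords
        start = max(1, end - length + 1)
        promoter = chrom[start - 1 : end]
    else:
        start = gm.cds_start + 1
        end = min(len(chrom), start + length - 1)
        promoter = revcomp(chrom[start - 1 : end])
    if len(promoter) < length:
        logger.warning(
            "%s: promoter truncated to %d bp at contig edge", gm.gene_id, len(promoter)
        )
    return promoter
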