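"""Synthetic inputs with ground truth for every pipeline stage.

The generators emulate the data a gene-family survey consumes:

* a small multi-chromosome genome carrying a planted protein family
  that shares a conserved domain, alongside domain-free decoy genes,
  with full GFF3 annotation and promoters carrying planted
  cis-regulatory elements at known positions;
* duplicate CDS pairs evolved from a common ancestor at a chosen
  synonymous divergence (Ks) and nonsynonymous/synonymous ratio (ω),
  under a Jukes–Cantor-style proposal process with ω-thinning — the
  same assumptions the Nei–Gojobori estimator makes, so recovery tests
  probe the estimator rather than model mismatch;
* FPKM / qPCR-Ct / phenotype tables with known fold changes and
  survival structure.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import promoter_cis
from .duplication_kaks import codon_sites
from .promoter_cis import BUILTIN_CATALOG, CisElement, IUPAC_CODES
from .seq_io import GeneModel, SequenceRecord, revcomp, translate, write_fasta

__all__ = [
    "TruthTable",
    "FamilyGenome",
    "simulate_family_genome",
    "evolve_codon_pair",
    "plant_cis_elements",
    "simulate_tables",
    "reverse_translate",
    "write_family_genome",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = {"TAA", "TAG", "TGA"}

# amino acid -> codons, from the standard genetic code
_CODONS_FOR: dict[str, list[str]] = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODONS_FOR.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR:
    _CODONS_FOR[aa].sort()


@dataclass
class TruthTable:
    """Ground truth recorded by the genome generator."""

    seed: int
    members: list[str] = field(default_factory=list)
    decoys: list[str] = field(default_factory=list)
    classes: dict[str, int] = field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    pair_params: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    promoter_elements: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    domain_consensus: str = ""
    seed_alignment: list[str] = field(default_factory=list)


@dataclass
class FamilyGenome:
    """Generator output bundle: genome, annotation, sequences, truth."""

    genome: dict[str, SequenceRecord]
    models: dict[str, GeneModel]
    proteins: dict[str, str]  # members + decoys
    cds: dict[str, str]  # members + decoys (without stop codon)
    promoters: dict[str, str]  # member promoters (2 kb, 5'->3')
    alignment: dict[str, str]  # member proteins, equal length (trivial MSA)
    truth: TruthTable


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [aa for aa in AMINO_ACIDS if aa != out[i]]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """A random CDS encoding the protein (uniform codon choice, no stop)."""
    return "".join(
        _CODONS_FOR[aa][int(rng.integers(len(_CODONS_FOR[aa])))] for aa in protein
    )


def evolve_codon_pair(
    ancestral_cds: str,
    target_ks: float,
    omega: float,
    seed: int,
) -> tuple[str, str, dict[str, float]]:
    """Evolve two descendant CDS from an ancestor at known Ks and ω.

    Each lineage receives a Poisson(Ks/2 × S) number of synonymous
    substitutions (S = Nei–Gojobori synonymous sites of the ancestor).
    Single-base changes are proposed uniformly; stop-creating proposals
    are rejected; nonsynonymous proposals are accepted with probability
    ω (for ω ≤ 1) and synonymous proposals thinned by 1/ω (for ω > 1).
    Returns the two descendants and realized event counts.
    """
    if len(ancestral_cds) % 3 != 0:
        raise ValueError("ancestral CDS length not divisible by 3")
    if target_ks < 0:
        raise ValueError("target Ks must be non-negative")
    if omega < 0:
        raise ValueError("omega must be non-negative")
    for i in range(0, len(ancestral_cds), 3):
        if ancestral_cds[i : i + 3] in _STOPS:
            raise ValueError("ancestral CDS contains a stop codon")
    if target_ks > 2.0:
        warnings.warn("target Ks beyond the saturation regime (> 2.0)", stacklevel=2)

    rng = np.random.default_rng(seed)
    s_sites = sum(codon_sites(ancestral_cds[i : i + 3])[1] for i in range(0, len(ancestral_cds), 3))
    p_syn_accept = 1.0 if omega <= 1 or omega == 0 else 1.0 / omega
    p_nonsyn_accept = min(1.0, omega)

    def one_lineage(seq: str) -> tuple[str, int, int]:
        target_syn = int(rng.poisson(target_ks / 2.0 * s_sites))
        out = list(seq)
        syn_events = nonsyn_events = 0
        while syn_events < target_syn:
            pos = int(rng.integers(len(out)))
            old = out[pos]
            new = "ACGT"[int(rng.integers(4))]
            if new == old:
                continue
            c0 = 3 * (pos // 3)
            codon_old = "".join(out[c0 : c0 + 3])
            out[pos] = new
            codon_new = "".join(out[c0 : c0 + 3])
            if codon_new in _STOPS:
                out[pos] = old
                continue
            syn = translate(codon_old) == translate(codon_new)
            accept_p = p_syn_accept if syn else p_nonsyn_accept
            if rng.random() < accept_p:
                if syn:
                    syn_events += 1
                else:
                    nonsyn_events += 1
            else:
                out[pos] = old
        return "".join(out), syn_events, nonsyn_events

    cds_a, syn_a, nonsyn_a = one_lineage(ancestral_cds)
    cds_b, syn_b, nonsyn_b = one_lineage(ancestral_cds)
    counts = {
        "syn_a": syn_a,
        "nonsyn_a": nonsyn_a,
        "syn_b": syn_b,
        "nonsyn_b": nonsyn_b,
        "syn_total": syn_a + syn_b,
        "nonsyn_total": nonsyn_a + nonsyn_b,
        "s_sites_ancestor": s_sites,
    }
    return cds_a, cds_b, counts


def _instantiate_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Concrete ACGT realization of an IUPAC consensus."""
    out = []
    for code in consensus.upper():
        options = sorted(IUPAC_CODES[code])
        out.append(options[int(rng.integers(len(options)))])
    return "".join(out)


def plant_cis_elements(
    promoter_length: int,
    elements: Sequence[tuple[CisElement | str, int, str]],
    seed: int,
    avoid_catalog: Sequence[CisElement] | None = None,
    max_clean_iter: int = 100,
) -> tuple[str, list[tuple[str, int, str]]]:
    """Random promoter with elements written at requested positions.

    ``elements`` lists ``(element-or-name, 1-based position, strand)``;
    minus-strand elements are written reverse-complemented.  Requested
    plants must not overlap nor run past the promoter end.  The random
    background is re-randomized wherever it spuriously matches an
    element of ``avoid_catalog`` (default: the planted elements), so a
    scan for those elements recovers exactly the planted truth.
    """
    by_name = {el.name: el for el in BUILTIN_CATALOG}
    resolved: list[tuple[CisElement, int, str]] = []
    for el, pos, strand in elements:
        element = by_name[el] if isinstance(el, str) else el
        if strand not in {"+", "-"}:
            raise ValueError(f"{element.name}: strand must be + or -")
        if pos < 1 or pos + len(element.consensus) - 1 > promoter_length:
            raise ValueError(
                f"{element.name}: plant at {pos} outside promoter of length {promoter_length}"
            )
        resolved.append((element, pos, strand))
    occupied: list[tuple[int, int]] = []
    for element, pos, _ in sorted(resolved, key=lambda t: t[1]):
        span = (pos, pos + len(element.consensus) - 1)
        for s, e in occupied:
            if span[0] <= e and s <= span[1]:
                raise ValueError(f"{element.name}: plant at {pos} overlaps another plant")
        occupied.append(span)

    rng = np.random.default_rng(seed)
    promoter = list(rng.choice(list("ACGT"), size=promoter_length))
    planted_mask = np.zeros(promoter_length, dtype=bool)
    truth: list[tuple[str, int, str]] = []
    for element, pos, strand in resolved:
        instance = _instantiate_consensus(element.consensus, rng)
        if strand == "-":
            instance = revcomp(instance)
        promoter[pos - 1 : pos - 1 + len(instance)] = list(instance)
        planted_mask[pos - 1 : pos - 1 + len(instance)] = True
        truth.append((element.name, pos, strand))

    catalog = list(avoid_catalog) if avoid_catalog is not None else [el for el, _, _ in resolved]
    truth_set = set(truth)
    for _ in range(max_clean_iter):
        seq = "".join(promoter)
        spurious = [
            hit
            for hit in promoter_cis.scan_promoter("p", seq, catalog)
            if (hit.element, hit.start, hit.strand) not in truth_set
        ]
        if not spurious:
            break
        for hit in spurious:
            for offset in range(len(hit.matched)):
                idx = hit.start - 1 + offset
                if not planted_mask[idx]:
                    promoter[idx] = "ACGT"[int(rng.integers(4))]
    else:
        raise RuntimeError("could not clean spurious element matches from background")
    return "".join(promoter), truth


def _split_exons(cds_with_stop: str, n_exons: int, rng: np.random.Generator) -> list[str]:
    """Split a CDS into n_exons non-empty pieces (not codon-aligned)."""
    n = len(cds_with_stop)
    n_exons = max(1, min(n_exons, n // 3))
    if n_exons == 1:
        return [cds_with_stop]
    cuts = sorted(rng.choice(np.arange(1, n), size=n_exons - 1, replace=False))
    pieces = []
    prev = 0
    for cut in cuts:
        pieces.append(cds_with_stop[prev:cut])
        prev = cut
    pieces.append(cds_with_stop[prev:])
    return pieces


_DEFAULT_PLANTS = ("ABRE", "MBS")


def simulate_family_genome(
    n_chromosomes: int = 7,
    n_members: int = 18,
    n_decoys: int = 50,
    seed: int = 7,
    protein_length: int = 220,
    domain_length: int = 60,
    class_sizes: Sequence[int] | None = None,
    promoter_length: int = 2000,
) -> FamilyGenome:
    """Genome + annotation carrying a planted gene family.

    Members share a conserved domain (a fixed consensus mutated ~5–10%
    per lineage) embedded in otherwise clade-specific sequence; the
    family splits into three clades (sizes mirroring the 14/1/3 shape at
    the default 18 members).  Two duplicate pairs are created by codon
    evolution from a common ancestor at known (Ks, ω), one in the large
    clade and one in the small multi-gene clade.  Decoys are random
    domain-free proteins.  Every member promoter carries planted ABRE
    and MBS drought elements at recorded positions.
    """
    if n_members < 2:
        raise ValueError("need at least 2 family members")
    if class_sizes is None:
        if n_members >= 6:
            class_sizes = (n_members - 4, 1, 3)
        else:
            class_sizes = (n_members,)
    if sum(class_sizes) != n_members:
        raise ValueError("class sizes must sum to n_members")

    rng = np.random.default_rng(seed)
    truth = TruthTable(seed=seed)
    flank_left = (protein_length - domain_length) // 2
    domain_consensus = _random_protein(rng, domain_length)
    truth.domain_consensus = domain_consensus
    truth.seed_alignment = [_mutate_protein(domain_consensus, 0.05, rng) for _ in range(8)]

    member_ids = [f"mem{i + 1:02d}" for i in range(n_members)]
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}

    # clade ancestors: independent flanks, lightly diverged domain copies
    idx = 0
    clade_of: dict[str, int] = {}
    for clade_no, size in enumerate(class_sizes, start=1):
        left = _random_protein(rng, flank_left)
        right = _random_protein(rng, protein_length - flank_left - domain_length)
        clade_domain = _mutate_protein(domain_consensus, 0.05, rng)
        ancestor = left + clade_domain + right
        for _ in range(size):
            gid = member_ids[idx]
            clade_of[gid] = clade_no
            flanks_rate, domain_rate = 0.25, 0.05
            mutated = (
                _mutate_protein(ancestor[:flank_left], flanks_rate, rng)
                + _mutate_protein(ancestor[flank_left : flank_left + domain_length], domain_rate, rng)
                + _mutate_protein(ancestor[flank_left + domain_length :], flanks_rate, rng)
            )
            proteins[gid] = mutated
            idx += 1
    truth.members = list(member_ids)
    truth.classes = clade_of

    # duplicate pairs by codon evolution at known (Ks, omega)
    dup_specs: list[tuple[str, str, float, float]] = []
    by_clade: dict[int, list[str]] = {}
    for gid, cl in clade_of.items():
        by_clade.setdefault(cl, []).append(gid)
    if len(class_sizes) >= 3 and class_sizes[2] >= 2:
        a, b = by_clade[3][0], by_clade[3][1]
        dup_specs.append((a, b, 0.05, 0.3))
    if class_sizes[0] >= 2:
        a, b = by_clade[1][0], by_clade[1][1]
        dup_specs.append((a, b, 0.10, 0.3))

    for gid in member_ids:
        cds[gid] = reverse_translate(proteins[gid], rng)
    for gene_a, gene_b, ks, om in dup_specs:
        ancestor_cds = cds[gene_a]
        cds_a, cds_b, _ = evolve_codon_pair(ancestor_cds, ks, om, seed=int(rng.integers(2**31)))
        cds[gene_a], cds[gene_b] = cds_a, cds_b
        proteins[gene_a] = translate(cds_a)
        proteins[gene_b] = translate(cds_b)
        truth.duplicate_pairs.append((gene_a, gene_b))
        truth.pair_params[(gene_a, gene_b)] = (ks, om)

    decoy_ids = [f"dec{i + 1:02d}" for i in range(n_decoys)]
    for gid in decoy_ids:
        proteins[gid] = _random_protein(rng, int(rng.integers(150, 401)))
        cds[gid] = reverse_translate(proteins[gid], rng)
    truth.decoys = list(decoy_ids)

    # promoters with planted drought elements (members only)
    promoters: dict[str, str] = {}
    for gid in member_ids:
        plants = []
        used: list[tuple[int, int]] = []
        for name in _DEFAULT_PLANTS:
            m = len(next(el for el in BUILTIN_CATALOG if el.name == name).consensus)
            while True:
                pos = int(rng.integers(50, promoter_length - m - 50))
                if all(pos + m < s or e < pos for s, e in used):
                    used.append((pos, pos + m - 1))
                    break
            strand = "+" if rng.random() < 0.5 else "-"
            plants.append((name, pos, strand))
        promoter, planted = plant_cis_elements(
            promoter_length, plants, seed=int(rng.integers(2**31))
        )
        promoters[gid] = promoter
        truth.promoter_elements[gid] = planted

    # assemble chromosomes: [promoter][gene body][gap] packed left to right
    all_ids = member_ids + decoy_ids
    order = list(rng.permutation(all_ids))
    chrom_seqs: dict[str, list[str]] = {f"chr{i + 1}": [] for i in range(n_chromosomes)}
    chrom_len: dict[str, int] = {name: 0 for name in chrom_seqs}
    models: dict[str, GeneModel] = {}

    def rand_bases(n: int) -> str:
        return "".join(rng.choice(list("ACGT"), size=n))

    for gid in order:
        chrom = f"chr{int(rng.integers(n_chromosomes)) + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        cds_full = cds[gid] + ["TAA", "TAG", "TGA"][int(rng.integers(3))]
        n_exons = int(rng.integers(1, 35))
        exon_pieces = _split_exons(cds_full, n_exons, rng)
        pre_mrna_parts: list[str] = []
        exon_spans: list[tuple[int, int]] = []  # 0-based offsets in pre-mRNA
        offset = 0
        for i, piece in enumerate(exon_pieces):
            if i > 0:
                intron = rand_bases(int(rng.integers(60, 201)))
                pre_mrna_parts.append(intron)
                offset += len(intron)
            exon_spans.append((offset, offset + len(piece) - 1))
            pre_mrna_parts.append(piece)
            offset += len(piece)
        pre_mrna = "".join(pre_mrna_parts)

        promoter = promoters.get(gid, rand_bases(promoter_length))
        gap = rand_bases(int(rng.integers(300, 801)))
        start0 = chrom_len[chrom]  # 0-based start of this gene block
        if strand == "+":
            block = promoter + pre_mrna + gap
            body_start = start0 + len(promoter) + 1  # 1-based
            intervals = [
                (body_start + s, body_start + e) for s, e in exon_spans
            ]
        else:
            block = gap + revcomp(pre_mrna) + revcomp(promoter)
            body_start = start0 + len(gap) + 1
            body_end = body_start + len(pre_mrna) - 1
            intervals = sorted(
                (body_end - e, body_end - s) for s, e in exon_spans
            )
        chrom_seqs[chrom].append(block)
        chrom_len[chrom] += len(block)
        models[gid] = GeneModel(
            gene_id=gid,
            chromosome=chrom,
            strand=strand,
            cds_intervals=intervals,
            exon_intervals=list(intervals),
        )

    genome = {
        name: SequenceRecord(name, "".join(parts) + rand_bases(500))
        for name, parts in chrom_seqs.items()
    }
    alignment = {gid: proteins[gid] for gid in member_ids}
    return FamilyGenome(
        genome=genome,
        models=models,
        proteins=proteins,
        cds=cds,
        promoters=promoters,
        alignment=alignment,
        truth=truth,
    )


def gff3_text(models: Mapping[str, GeneModel]) -> str:
    """Serialize gene models as GFF3 (gene/mRNA/exon/CDS rows)."""
    lines = ["##gff-version 3"]
    for gid in models:
        gm = models[gid]
        start, end = gm.span
        lines.append(
            f"{gm.chromosome}\tgenefam\tgene\t{start}\t{end}\t.\t{gm.strand}\t.\tID=gene:{gid}"
        )
        lines.append(
            f"{gm.chromosome}\tgenefam\tmRNA\t{start}\t{end}\t.\t{gm.strand}\t.\t"
            f"ID={gid};Parent=gene:{gid}"
        )
        for s, e in gm.exon_intervals:
            lines.append(
                f"{gm.chromosome}\tgenefam\texon\t{s}\t{e}\t.\t{gm.strand}\t.\tParent={gid}"
            )
        for s, e in gm.cds_intervals:
            lines.append(
                f"{gm.chromosome}\tgenefam\tCDS\t{s}\t{e}\t.\t{gm.strand}\t0\tParent={gid}"
            )
    return "\n".join(lines) + "\n"


def write_family_genome(fam: FamilyGenome, outdir: str | Path) -> None:
    """Write genome FASTA, GFF3, protein/CDS FASTA and a truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(fam.genome.values(), outdir / "genome.fasta")
    write_fasta(
        (SequenceRecord(gid, fam.proteins[gid]) for gid in sorted(fam.proteins)),
        outdir / "proteins.fasta",
    )
    write_fasta(
        (SequenceRecord(gid, fam.cds[gid]) for gid in sorted(fam.cds)),
        outdir / "cds.fasta",
    )
    (outdir / "annotation.gff3").write_text(gff3_text(fam.models))
    rows = []
    for gid in fam.truth.members:
        rows.append({"gene_id": gid, "role": "member", "clade": fam.truth.classes[gid]})
    for gid in fam.truth.decoys:
        rows.append({"gene_id": gid, "role": "decoy", "clade": 0})
    pd.DataFrame(rows).to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    elem_rows = [
        {"gene_id": gid, "element": name, "position": pos, "strand": strand}
        for gid, plants in fam.truth.promoter_elements.items()
        for name, pos, strand in plants
    ]
    pd.DataFrame(elem_rows).to_csv(outdir / "truth_elements.tsv", sep="\t", index=False)


@dataclass(frozen=True)
class TableDesign:
    """Design of the simulated expression/phenotype tables."""

    lines: tuple[str, ...] = ("B73", "Zheng58", "Qi319")
    timepoints: tuple[int, ...] = (0, 3, 7, 10, 14)
    genes: tuple[str, ...] = tuple(f"mem{i + 1:02d}" for i in range(18))
    n_tissues: int = 23
    ct_sd: float = 0.15
    n_reps: int = 3
    # survival counts per line under water stress (16 plants per replicate)
    survival: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"Qi319": (10, 16), "Zheng58": (9, 16), "B73": (3, 16)}
    )


def simulate_tables(
    design: TableDesign | None = None,
    true_folds: Mapping[tuple[str, str, int], float] | None = None,
    seed: int = 0,
):
    """FPKM matrix, qPCR Ct records and phenotype records with truth.

    ``true_folds`` maps (line, gene, timepoint) to the planted fold
    change relative to timepoint 0 (default 1 everywhere).  Returns a
    dict with keys ``fpkm`` (DataFrame), ``qpcr`` (list of
    :class:`~genefam.expression_phenotype.QpcrRecord`), ``phenotype``
    (list of records), and ``truth``.
    """
    from .expression_phenotype import PhenotypeRecord, QpcrRecord

    design = design or TableDesign()
    if design.ct_sd < 0:
        raise ValueError("Ct noise SD must be non-negative")
    rng = np.random.default_rng(seed)

    tissues = [f"tissue{i + 1:02d}" for i in range(design.n_tissues)]
    base = 2.0 ** rng.normal(3.0, 1.5, size=(len(design.genes), design.n_tissues))
    fpkm = pd.DataFrame(
        np.round(base * rng.lognormal(0.0, 0.3, size=base.shape), 3),
        index=list(design.genes),
        columns=tissues,
    )

    folds: dict[tuple[str, str, int], float] = {}
    qpcr: list[QpcrRecord] = []
    for line in design.lines:
        for gene in design.genes:
            base_offset = float(rng.uniform(2.0, 8.0))
            for tp in design.timepoints:
                fold = 1.0 if tp == design.timepoints[0] else (
                    (true_folds or {}).get((line, gene, tp), 1.0)
                )
                folds[(line, gene, tp)] = fold
                ref = tuple(
                    float(c) for c in rng.normal(20.0, design.ct_sd, size=design.n_reps)
                )
                target_mean = 20.0 + base_offset - np.log2(fold)
                target = tuple(
                    float(c) for c in rng.normal(target_mean, design.ct_sd, size=design.n_reps)
                )
                qpcr.append(QpcrRecord(f"{line}_d{tp}", gene, target, ref))

    phenotype: list[PhenotypeRecord] = []
    for line in design.lines:
        survived, total = design.survival.get(line, (12, 16))
        rwc_final = 40.0 + 25.0 * survived / total  # tolerant lines stay wetter
        tw = float(rng.uniform(2.8, 3.2))
        dw = float(rng.uniform(0.9, 1.1))
        fw_ws = dw + (tw - dw) * rwc_final / 100.0
        phenotype.append(PhenotypeRecord(line, "WW", tw * 0.98, tw, dw, total, total))
        phenotype.append(PhenotypeRecord(line, "WS", fw_ws, tw, dw, survived, total))

    truth = {"folds": folds, "survival": dict(design.survival), "seed": seed}
    return {"fpkm": fpkm, "qpcr": qpcr, "phenotype": phenotype, "truth": truth}
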