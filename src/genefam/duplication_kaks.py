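"""Duplicate gene pairs, Ka/Ks by Nei–Gojobori, and divergence dating.

The estimator is the classical Nei–Gojobori (1986) method: synonymous
and nonsynonymous site counts are obtained per codon by enumerating all
nine single-base changes (per position, the synonymous fraction is
taken over the non-stop changes — nonsense mutations are eliminated —
and every codon carries exactly 3 sites); substitution
counts between codon pairs average over all orderings of the observed
differences, excluding pathways that pass through a stop codon; the
Jukes–Cantor multiple-hit correction d = −(3/4)·ln(1 − 4p/3) is applied
to the synonymous and nonsynonymous proportions separately.

Divergence dating follows the molecular-clock formula T = Ks / (2λ)
with a default clock rate λ = 1.5e-8 synonymous substitutions per site
per year; pairs with Ks above a saturation cutoff (default 2.0) are not
dated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seq_io import GeneModel, translate

__all__ = [
    "ParalogPair",
    "CodonAlignment",
    "NeiGojoboriResult",
    "global_align",
    "find_duplicates",
    "classify_duplication",
    "codon_align",
    "codon_sites",
    "codon_differences",
    "nei_gojobori",
    "jukes_cantor",
    "divergence_time",
    "classify_selection",
    "analyze_pairs",
    "DEFAULT_CLOCK_RATE",
    "DEFAULT_KS_MAX",
]

DEFAULT_CLOCK_RATE = 1.5e-8  # synonymous substitutions / site / year
DEFAULT_KS_MAX = 2.0  # Ks saturation cutoff for dating

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class ParalogPair:
    """A duplicate gene pair and its evolutionary summary."""

    gene_a: str
    gene_b: str
    identity: float
    coverage: float
    ka: float | None = None
    ks: float | None = None
    omega: float | None = None
    divergence_mya: float | None = None
    selection: str | None = None
    dup_type: str | None = None


@dataclass(frozen=True)
class CodonAlignment:
    """Gap-free, equal-length, stop-free codon alignment of two CDS."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("codon alignment rows differ in length")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("codon alignment length not divisible by 3")
        for seq in (self.seq_a, self.seq_b):
            for i in range(0, len(seq), 3):
                if seq[i : i + 3] in _STOPS:
                    raise ValueError(f"stop codon at position {i + 1}")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_pairs(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class NeiGojoboriResult:
    n_codons: int
    n_sites: float  # nonsynonymous sites (averaged over both sequences)
    s_sites: float  # synonymous sites
    nd: float  # nonsynonymous differences
    sd: float  # synonymous differences
    pn: float
    ps: float
    ka: float | None  # None when pN saturates the JC correction
    ks: float | None

    @property
    def omega(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0:
            return None
        return self.ka / self.ks

    @property
    def saturated(self) -> bool:
        return self.ka is None or self.ks is None


def _make_aligner(gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def global_align(
    protein_a: str,
    protein_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[float, float, tuple[str, str]]:
    """Needleman–Wunsch global alignment of two proteins.

    Returns ``(identity_percent, coverage, (gapped_a, gapped_b))`` where
    identity is over aligned (both non-gap) columns and coverage is
    aligned columns / max sequence length.
    """
    if not protein_a or not protein_b:
        raise ValueError("empty protein sequence")
    aligner = _make_aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(protein_a.upper(), protein_b.upper())[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    aligned = identical = 0
    for ca, cb in zip(row_a, row_b):
        if ca != "-" and cb != "-":
            aligned += 1
            if ca == cb:
                identical += 1
    identity = 100.0 * identical / aligned if aligned else 0.0
    coverage = aligned / max(len(protein_a), len(protein_b))
    return identity, coverage, (row_a, row_b)


def find_duplicates(
    members: Mapping[str, str],
    identity_min: float = 85.0,
    coverage_min: float = 0.75,
) -> list[ParalogPair]:
    """All unordered member pairs with identity > ``identity_min`` percent
    AND coverage > ``coverage_min`` (both strict), sorted by id pair."""
    pairs: list[ParalogPair] = []
    for gene_a, gene_b in itertools.combinations(sorted(members), 2):
        identity, coverage, _ = global_align(members[gene_a], members[gene_b])
        if identity > identity_min and coverage > coverage_min:
            pairs.append(ParalogPair(gene_a, gene_b, identity, coverage))
    return pairs


def classify_duplication(
    gm_a: GeneModel,
    gm_b: GeneModel,
    all_models: Sequence[GeneModel] | None = None,
    tandem_window: int = 100_000,
    tandem_max_intervening: int = 5,
) -> str:
    """Tandem vs segmental duplication from gene-pair geometry.

    Tandem requires the same chromosome and either a gap of at most
    ``tandem_window`` bp or at most ``tandem_max_intervening`` annotated
    genes between the pair (counted from ``all_models`` when given;
    without an annotation set, distance alone decides).
    """
    if gm_a.chromosome != gm_b.chromosome:
        return "segmental"
    (a_start, a_end), (b_start, b_end) = gm_a.span, gm_b.span
    if a_start > b_start:
        (a_start, a_end), (b_start, b_end) = (b_start, b_end), (a_start, a_end)
    distance = max(0, b_start - a_end)
    if distance <= tandem_window:
        return "tandem"
    if all_models is not None:
        intervening = sum(
            1
            for gm in all_models
            if gm.chromosome == gm_a.chromosome
            and gm.gene_id not in (gm_a.gene_id, gm_b.gene_id)
            and gm.span[0] > a_end
            and gm.span[1] < b_start
        )
        if intervening <= tandem_max_intervening:
            return "tandem"
    return "segmental"


def codon_align(cds_a: str, cds_b: str, protein_alignment: tuple[str, str]) -> CodonAlignment:
    """Back-translate a protein alignment onto the two CDS.

    Each aligned residue column expands to its source codon; columns with
    a gap in either row are dropped, yielding a gap-free codon alignment.
    """
    row_a, row_b = protein_alignment
    out_a: list[str] = []
    out_b: list[str] = []
    ia = ib = 0
    for ca, cb in zip(row_a, row_b):
        codon_a = cds_a[3 * ia : 3 * ia + 3] if ca != "-" else None
        codon_b = cds_b[3 * ib : 3 * ib + 3] if cb != "-" else None
        if ca != "-":
            if ca != "X" and str(Seq(codon_a).translate()) != ca:
                raise ValueError(f"CDS A codon {codon_a} at residue {ia + 1} does not encode {ca}")
            ia += 1
        if cb != "-":
            if cb != "X" and str(Seq(codon_b).translate()) != cb:
                raise ValueError(f"CDS B codon {codon_b} at residue {ib + 1} does not encode {cb}")
            ib += 1
        if codon_a is not None and codon_b is not None:
            out_a.append(codon_a)
            out_b.append(codon_b)
    return CodonAlignment("".join(out_a), "".join(out_b))


def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def _codon_sites_uncached(codon: str) -> tuple[float, float]:
    aa = _translate_codon(codon)
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant in _STOPS:  # nonsense mutations are eliminated
                continue
            valid += 1
            if _translate_codon(mutant) == aa:
                syn += 1
        if valid:
            s += syn / valid
    return 3.0 - s, s


_SITES_CACHE: dict[str, tuple[float, float]] = {}


def codon_sites(codon: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) site counts of one codon; sums to 3.

    Per codon position the synonymous site fraction is the proportion of
    amino-acid-preserving changes among the non-stop single-base changes
    at that position (nonsense mutations are eliminated from the count);
    the nonsynonymous count is the complement to 3.
    """
    codon = codon.upper()
    if codon not in _SITES_CACHE:
        _SITES_CACHE[codon] = _codon_sites_uncached(codon)
    return _SITES_CACHE[codon]


def codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(nonsynonymous, synonymous) differences between two codons.

    Averages over all orderings of the differing positions; pathways that
    pass through a stop codon are excluded.  Should every pathway hit a
    stop (possible only for 2–3 differences), all pathways are used with
    stop-entering steps counted as nonsynonymous.
    """
    codon_a, codon_b = codon_a.upper(), codon_b.upper()
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        current = codon_a
        nd = sd = 0
        hit_stop = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in _STOPS:
                hit_stop = True
                nd += 1
            elif _translate_codon(nxt) == _translate_codon(current) and current not in _STOPS:
                sd += 1
            else:
                nd += 1
            current = nxt
        all_paths.append((nd, sd))
        if not hit_stop:
            valid.append((nd, sd))
    paths = valid or all_paths
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


def jukes_cantor(p: float) -> float | None:
    """Multiple-hit correction d = −(3/4)·ln(1 − 4p/3); None at saturation."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def nei_gojobori(aln: CodonAlignment) -> NeiGojoboriResult:
    """Nei–Gojobori Ka/Ks over a codon alignment.

    Site counts are averaged over the two sequences; ``ka``/``ks`` are
    ``None`` when the corresponding proportion saturates the Jukes–Cantor
    correction (p ≥ 3/4).
    """
    n_a = s_a = n_b = s_b = 0.0
    nd = sd = 0.0
    for codon_a, codon_b in aln.codon_pairs():
        na, sa = codon_sites(codon_a)
        nb, sb = codon_sites(codon_b)
        n_a += na
        s_a += sa
        n_b += nb
        s_b += sb
        d_n, d_s = codon_differences(codon_a, codon_b)
        nd += d_n
        sd += d_s
    n_sites = (n_a + n_b) / 2.0
    s_sites = (s_a + s_b) / 2.0
    pn = nd / n_sites if n_sites else 0.0
    ps = sd / s_sites if s_sites else 0.0
    return NeiGojoboriResult(
        n_codons=aln.n_codons,
        n_sites=n_sites,
        s_sites=s_sites,
        nd=nd,
        sd=sd,
        pn=pn,
        ps=ps,
        ka=jukes_cantor(pn),
        ks=jukes_cantor(ps),
    )


def divergence_time(
    ks: float,
    clock_rate: float = DEFAULT_CLOCK_RATE,
    ks_max: float = DEFAULT_KS_MAX,
) -> float | None:
    """Duplication age in million years: T = Ks / (2λ).

    Returns ``None`` (discarded) when Ks exceeds ``ks_max``, guarding
    against synonymous-site saturation.
    """
    if ks < 0:
        raise ValueError("Ks must be non-negative")
    if ks > ks_max:
        return None
    return ks / (2.0 * clock_rate) / 1e6


def classify_selection(omega: float) -> str:
    """purifying (ω < 1), positive (ω > 1) or neutral (ω = 1)."""
    if omega < 1.0:
        return "purifying"
    if omega > 1.0:
        return "positive"
    return "neutral"


def analyze_pairs(
    proteins: Mapping[str, str],
    cds: Mapping[str, str],
    gene_models: Mapping[str, GeneModel] | None = None,
    identity_min: float = 85.0,
    coverage_min: float = 0.75,
    clock_rate: float = DEFAULT_CLOCK_RATE,
    ks_max: float = DEFAULT_KS_MAX,
) -> list[ParalogPair]:
    """Full duplicate-pair analysis: detect, estimate Ka/Ks, date, classify."""
    pairs = find_duplicates(proteins, identity_min, coverage_min)
    models = list(gene_models.values()) if gene_models else None
    for pair in pairs:
        _, _, rows = global_align(proteins[pair.gene_a], proteins[pair.gene_b])
        aln = codon_align(cds[pair.gene_a], cds[pair.gene_b], rows)
        result = nei_gojobori(aln)
        pair.ka, pair.ks = result.ka, result.ks
        pair.omega = result.omega
        if pair.omega is not None:
            pair.selection = classify_selection(pair.omega)
        if pair.ks is not None:
            pair.divergence_mya = divergence_time(pair.ks, clock_rate, ks_max)
        if gene_models is not None:
            pair.dup_type = classify_duplication(
                gene_models[pair.gene_a], gene_models[pair.gene_b], models
            )
    return pairs
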