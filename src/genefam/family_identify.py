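"""Family-member selection from domain-search evidence.

The module consumes the tabular outputs of the standard search tools
(hmmsearch ``--domtblout``, BLAST ``-outfmt 6``) and applies the
E-value threshold / redundancy-removal logic of a gene-family survey.
It additionally ships a light position-specific scoring matrix (PSSM)
scanner so the whole pipeline is executable offline: a profile is built
from a seed alignment, scanned over a proteome, and calibrated on
shuffled sequences to attach approximate E-values (Gumbel fit on
shuffle maxima, in the Karlin–Altschul spirit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DomainHit",
    "ScoringProfile",
    "parse_domain_table",
    "build_profile",
    "profile_scan",
    "calibrate_profile",
    "score_threshold_for_evalue",
    "select_members",
    "AMINO_ACIDS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_SCORE_FLOOR = -20.0  # guard for log2(0) with zero pseudocount


@dataclass(frozen=True)
class DomainHit:
    """One domain match on a protein (one row of a search table)."""

    protein_id: str
    domain_name: str
    evalue: float | None  # None for uncalibrated PSSM hits
    ali_start: int
    ali_end: int
    score: float

    def __post_init__(self) -> None:
        if self.evalue is not None and self.evalue <= 0:
            raise ValueError(f"{self.protein_id}: E-value must be positive")
        if self.ali_start > self.ali_end:
            raise ValueError(f"{self.protein_id}: ali_start > ali_end")


@dataclass
class ScoringProfile:
    """Per-position log-odds scores over the 20 amino acids."""

    name: str
    columns: np.ndarray  # (length, 20) log2-odds
    background: np.ndarray  # (20,) frequencies summing to 1
    pseudocount: float
    calibration: tuple[float, float] | None = field(default=None)  # Gumbel (loc, scale)

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.columns.shape[0] < 6:
            raise ValueError("profile must have at least 6 columns")
        if self.columns.shape[1] != 20 or self.background.shape != (20,):
            raise ValueError("profile requires 20-letter columns and background")
        if not math.isclose(float(self.background.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")

    def __len__(self) -> int:
        return self.columns.shape[0]


def parse_domain_table(path: str | Path, dialect: str) -> list[DomainHit]:
    """Parse a search-tool table into :class:`DomainHit` rows.

    ``dialect`` is ``"hmmsearch_domtbl"`` (per-domain table; the
    independent i-Evalue and per-domain bit score are used) or
    ``"blast_tab"`` (12-column ``-outfmt 6``; E-value in column 11,
    query taken as the protein).  Comment lines (#) are skipped.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if dialect == "hmmsearch_domtbl":
                    if len(fields) < 22:
                        raise ValueError("too few columns")
                    hits.append(
                        DomainHit(
                            protein_id=fields[0],
                            domain_name=fields[3],
                            evalue=float(fields[12]),
                            ali_start=int(fields[17]),
                            ali_end=int(fields[18]),
                            score=float(fields[13]),
                        )
                    )
                elif dialect == "blast_tab":
                    if len(fields) < 12:
                        raise ValueError("too few columns")
                    hits.append(
                        DomainHit(
                            protein_id=fields[0],
                            domain_name=fields[1],
                            evalue=float(fields[10]),
                            ali_start=int(fields[6]),
                            ali_end=int(fields[7]),
                            score=float(fields[11]),
                        )
                    )
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except ValueError as exc:
                if "unknown dialect" in str(exc):
                    raise
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def build_profile(
    seed_alignment: Sequence[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
    name: str = "profile",
) -> ScoringProfile:
    """Log-odds profile from a gap-aligned protein seed alignment.

    Per kept column the score of letter a is
    log2((freq_a + pc·bg_a) / ((1 + pc)·bg_a)); columns with more than
    50% gaps are dropped; −inf scores (possible only at pc = 0) are
    floored.
    """
    if len(seed_alignment) < 2:
        raise ValueError("need at least 2 seed sequences")
    lengths = {len(s) for s in seed_alignment}
    if len(lengths) != 1:
        raise ValueError("seed sequences must have equal aligned length")
    if background is None:
        background = np.full(20, 1.0 / 20.0)
    rows = [s.upper() for s in seed_alignment]
    n_rows = len(rows)
    columns: list[np.ndarray] = []
    for j in range(lengths.pop()):
        col = [row[j] for row in rows]
        n_gaps = sum(1 for c in col if c == "-")
        if n_gaps > n_rows / 2:
            continue
        counts = np.zeros(20)
        for c in col:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        total = counts.sum()
        if total == 0:
            continue
        freq = counts / total
        with np.errstate(divide="ignore"):
            scores = np.log2((freq + pseudocount * background) / ((1 + pseudocount) * background))
        scores = np.maximum(scores, _SCORE_FLOOR)
        columns.append(scores)
    return ScoringProfile(name, np.array(columns), background, pseudocount)


def _window_scores(protein: str, profile: ScoringProfile) -> np.ndarray:
    """Summed log-odds of every window of the profile's length."""
    m = len(profile)
    n = len(protein)
    if n < m:
        return np.empty(0)
    idx = np.array([_AA_INDEX.get(aa, -1) for aa in protein.upper()])
    per_pos = np.empty((n, m))
    for j in range(m):
        col = profile.columns[j]
        per_pos[:, j] = np.where(idx >= 0, col[np.clip(idx, 0, 19)], _SCORE_FLOOR / 4)
    scores = np.empty(n - m + 1)
    for start in range(n - m + 1):
        scores[start] = per_pos[np.arange(start, start + m), np.arange(m)].sum()
    return scores


def _hit_evalue(profile: ScoringProfile, score: float) -> float | None:
    if profile.calibration is None:
        return None
    loc, scale = profile.calibration
    # Gumbel right-tail survival; expected-count style E-value
    return float(np.exp(-(score - loc) / scale))


def profile_scan(
    protein_id: str,
    protein: str,
    profile: ScoringProfile,
    score_threshold: float,
) -> list[DomainHit]:
    """All windows scoring at or above threshold, merged when overlapping.

    Overlapping hits (> 50% of the profile length) are greedily merged
    keeping the best-scoring window.  A protein shorter than the profile
    yields an empty list.  E-values are attached when the profile is
    calibrated.
    """
    scores = _window_scores(protein, profile)
    m = len(profile)
    candidates = [
        (float(scores[s]), s) for s in range(len(scores)) if scores[s] >= score_threshold
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    kept: list[tuple[float, int]] = []
    for score, start in candidates:
        if all(abs(start - ks) >= m / 2 for _, ks in kept):
            kept.append((score, start))
    kept.sort(key=lambda t: t[1])
    return [
        DomainHit(
            protein_id=protein_id,
            domain_name=profile.name,
            evalue=_hit_evalue(profile, score),
            ali_start=start + 1,
            ali_end=start + m,
            score=score,
        )
        for score, start in kept
    ]


def calibrate_profile(
    profile: ScoringProfile,
    sequences: Sequence[str],
    n_shuffles: int = 1000,
    seed: int = 0,
) -> ScoringProfile:
    """Fit a Gumbel null on max window scores of shuffled sequences.

    Each shuffle permutes the residues of a randomly chosen input
    sequence (preserving composition) and records the best window score;
    a Gumbel location/scale fit on those maxima calibrates the E-value
    transform.  Seeded and deterministic.
    """
    rng = np.random.default_rng(seed)
    seqs = [s.upper() for s in sequences if len(s) >= len(profile)]
    if not seqs:
        raise ValueError("no sequence at least as long as the profile")
    maxima = np.empty(n_shuffles)
    for i in range(n_shuffles):
        seq = seqs[int(rng.integers(len(seqs)))]
        shuffled = "".join(rng.permutation(list(seq)))
        scores = _window_scores(shuffled, profile)
        maxima[i] = scores.max()
    loc, scale = stats.gumbel_r.fit(maxima)
    profile.calibration = (float(loc), float(scale))
    return profile


def score_threshold_for_evalue(profile: ScoringProfile, evalue: float) -> float:
    """Score whose calibrated E-value equals ``evalue``."""
    if profile.calibration is None:
        raise ValueError("profile is not calibrated")
    loc, scale = profile.calibration
    return loc - scale * math.log(evalue)


def select_members(
    hits: Iterable[DomainHit] | Mapping[str, Iterable[DomainHit]],
    evalue_max: float = 1e-10,
    require_sources: str = "any",
    gene_map: Mapping[str, str] | None = None,
    lengths: Mapping[str, int] | None = None,
) -> list[str]:
    """Protein ids passing the E-value cut, one representative per locus.

    ``hits`` is a flat hit list or a mapping of evidence source → hit
    list; with ``require_sources="any"`` the qualifying sets are
    unioned, with ``"all"`` intersected.  When ``gene_map`` (protein →
    locus) is given, isoforms collapse to the longest (``lengths``,
    protein → residue count; ties by id).  Returns a sorted list.
    """
    if require_sources not in {"any", "all"}:
        raise ValueError("require_sources must be 'any' or 'all'")
    if isinstance(hits, Mapping):
        per_source = [
            {h.protein_id for h in source_hits if h.evalue is not None and h.evalue <= evalue_max}
            for source_hits in hits.values()
        ]
        if not per_source:
            return []
        ids = set.union(*per_source) if require_sources == "any" else set.intersection(*per_source)
    else:
        ids = {h.protein_id for h in hits if h.evalue is not None and h.evalue <= evalue_max}
    if gene_map is None:
        return sorted(ids)
    best: dict[str, str] = {}
    for pid in sorted(ids):
        locus = gene_map.get(pid, pid)
        if locus not in best:
            best[locus] = pid
        elif lengths is not None and lengths.get(pid, 0) > lengths.get(best[locus], 0):
            best[locus] = pid
    return sorted(best.values())
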