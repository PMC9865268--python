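"""Physicochemical profiling of proteins from sequence alone.

Implements the classical ProtParam statistics: average molecular weight,
theoretical isoelectric point (Henderson–Hasselbalch charge model solved
by bisection), Guruprasad instability index, aliphatic index and
Kyte–Doolittle GRAVY, plus the hydropathy (GRAVY < 0 → hydrophilic) and
stability (II > 40 → unstable) dichotomies.

Constant tables (average residue masses, Kyte–Doolittle hydropathies,
the Guruprasad dipeptide weights) come from Biopython's data modules.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data.IUPACData import protein_weights
from Bio.SeqUtils.ProtParamData import DIWV, kd

__all__ = [
    "PhysicoChemProfile",
    "molecular_weight",
    "net_charge",
    "theoretical_pi",
    "instability_index",
    "aliphatic_index",
    "gravy",
    "classify_hydropathy",
    "classify_stability",
    "profile",
    "WATER_MASS",
]

WATER_MASS = 18.01524

# residue (= amino acid minus water) average masses
_RESIDUE_MASS = {aa: mw - WATER_MASS for aa, mw in protein_weights.items()}
_MEAN_RESIDUE_MASS = sum(_RESIDUE_MASS.values()) / len(_RESIDUE_MASS)

# ExPASy/Bjellqvist pKa values: termini (terminal pKa depends on the
# terminal residue) and the seven ionizable side chains.
PKA_BJELLQVIST = {
    "Cterm_default": 3.55,
    "Cterm": {"D": 4.55, "E": 4.75},
    "Nterm_default": 7.50,
    "Nterm": {"A": 7.59, "M": 7.00, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.70},
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
    "H": 5.98,
    "K": 10.00,
    "R": 12.00,
}

# EMBOSS iep defaults, selectable as an alternative charge model.
PKA_EMBOSS = {
    "Cterm_default": 3.60,
    "Cterm": {},
    "Nterm_default": 8.60,
    "Nterm": {},
    "D": 3.90,
    "E": 4.10,
    "C": 8.50,
    "Y": 10.10,
    "H": 6.50,
    "K": 10.80,
    "R": 12.50,
}

_PKA_SETS = {"bjellqvist": PKA_BJELLQVIST, "emboss": PKA_EMBOSS}

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


@dataclass(frozen=True)
class PhysicoChemProfile:
    """Per-protein physicochemical summary (one table row)."""

    protein_id: str
    length: int
    mw: float
    pi: float
    instability_index: float
    aliphatic_index: float
    gravy: float
    hydropathy_class: str
    stability_class: str


def _check_nonempty(protein: str) -> str:
    if not protein:
        raise ValueError("empty protein sequence")
    return protein.upper()


def molecular_weight(protein: str) -> float:
    """Average molecular weight in Daltons (residue masses + one water).

    ``X`` contributes the mean of the twenty residue masses.
    """
    protein = _check_nonempty(protein)
    total = WATER_MASS
    for aa in protein:
        if aa == "X":
            total += _MEAN_RESIDUE_MASS
        elif aa in _RESIDUE_MASS:
            total += _RESIDUE_MASS[aa]
        else:
            raise ValueError(f"unknown amino acid {aa!r}")
    return total


def net_charge(protein: str, ph: float, pka_set: str = "bjellqvist") -> float:
    """Net charge at a given pH under the Henderson–Hasselbalch model.

    Positive groups (N-terminus, H, K, R) contribute 1/(1+10^(pH−pKa));
    negative groups (C-terminus, D, E, C, Y) contribute −1/(1+10^(pKa−pH)).
    """
    protein = _check_nonempty(protein)
    pka = _PKA_SETS[pka_set]
    nterm_pka = pka["Nterm"].get(protein[0], pka["Nterm_default"])
    cterm_pka = pka["Cterm"].get(protein[-1], pka["Cterm_default"])
    charge = 1.0 / (1.0 + 10 ** (ph - nterm_pka))
    charge -= 1.0 / (1.0 + 10 ** (cterm_pka - ph))
    for aa in _BASIC:
        n = protein.count(aa)
        if n:
            charge += n / (1.0 + 10 ** (ph - pka[aa]))
    for aa in _ACIDIC:
        n = protein.count(aa)
        if n:
            charge -= n / (1.0 + 10 ** (pka[aa] - ph))
    return charge


def theoretical_pi(protein: str, tol: float = 1e-3, pka_set: str = "bjellqvist") -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The charge is strictly decreasing in pH, so the root is unique.
    """
    protein = _check_nonempty(protein)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def instability_index(protein: str) -> float:
    """Guruprasad instability index: (10/L) Σ DIWV(x_i, x_{i+1}).

    Values above 40 conventionally predict an unstable protein in vitro.
    Requires length ≥ 2 (the statistic is over dipeptides).
    """
    protein = _check_nonempty(protein)
    if len(protein) < 2:
        raise ValueError("instability index needs at least 2 residues")
    total = 0.0
    for a, b in zip(protein, protein[1:]):
        total += DIWV.get(a, {}).get(b, 0.0)
    return total * 10.0 / len(protein)


def aliphatic_index(protein: str) -> float:
    """Relative volume of aliphatic side chains (Ala, Val, Ile, Leu).

    AI = X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu), with X in mole percent.
    """
    protein = _check_nonempty(protein)
    n = len(protein)
    x = {aa: 100.0 * protein.count(aa) / n for aa in "AVIL"}
    return x["A"] + 2.9 * x["V"] + 3.9 * (x["I"] + x["L"])


def gravy(protein: str) -> float:
    """Grand average of hydropathicity (mean Kyte–Doolittle score).

    ``X`` residues are excluded from both numerator and denominator.
    """
    protein = _check_nonempty(protein)
    scores = [kd[aa] for aa in protein if aa in kd]
    if not scores:
        raise ValueError("no scorable residues")
    return sum(scores) / len(scores)


def classify_hydropathy(gravy_value: float) -> str:
    """Hydrophilic iff GRAVY < 0, else hydrophobic."""
    return "hydrophilic" if gravy_value < 0 else "hydrophobic"


def classify_stability(ii: float) -> str:
    """Unstable iff instability index > 40 (ProtParam convention)."""
    return "unstable" if ii > 40 else "stable"


def profile(protein_id: str, protein: str, pka_set: str = "bjellqvist") -> PhysicoChemProfile:
    """All statistics for one protein, bundled as a profile row."""
    protein = _check_nonempty(protein)
    g = gravy(protein)
    ii = instability_index(protein)
    return PhysicoChemProfile(
        protein_id=protein_id,
        length=len(protein),
        mw=molecular_weight(protein),
        pi=theoretical_pi(protein, pka_set=pka_set),
        instability_index=ii,
        aliphatic_index=aliphatic_index(protein),
        gravy=g,
        hydropathy_class=classify_hydropathy(g),
        stability_class=classify_stability(ii),
    )
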