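"""Expression matrices and drought-phenotype formulas.

Covers the arithmetic of the downstream analyses: log2(FPKM + 1)
heatmap transform, Livak 2^-ddCt relative qPCR expression against a
reference gene and calibrator sample, percent survival, and leaf
relative water content RWC = (FW − DW)/(TW − DW) × 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QpcrRecord",
    "PhenotypeRecord",
    "log2_fpkm",
    "relative_expression",
    "survival_rate",
    "relative_water_content",
    "expression_heatmap",
]


@dataclass(frozen=True)
class QpcrRecord:
    """Ct replicates of a target gene and the reference gene in one sample."""

    sample: str
    gene: str
    ct_target: tuple[float, ...]
    ct_reference: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.ct_target or not self.ct_reference:
            raise ValueError(f"{self.sample}/{self.gene}: need >=1 Ct replicate each")
        for ct in (*self.ct_target, *self.ct_reference):
            if not 0 < ct < 45:
                raise ValueError(f"{self.sample}/{self.gene}: Ct {ct} outside (0, 45)")

    @property
    def delta_ct(self) -> float:
        return float(np.mean(self.ct_target) - np.mean(self.ct_reference))


@dataclass(frozen=True)
class PhenotypeRecord:
    """One line × treatment phenotype observation."""

    line: str
    treatment: str  # WW (well-watered) or WS (water-stressed)
    fresh_weight: float
    turgid_weight: float
    dry_weight: float
    survived: int
    total: int

    def __post_init__(self) -> None:
        if self.treatment not in {"WW", "WS"}:
            raise ValueError(f"{self.line}: treatment must be WW or WS")
        if self.dry_weight > self.turgid_weight:
            raise ValueError(f"{self.line}: dry weight exceeds turgid weight")
        if not 0 <= self.survived <= self.total:
            raise ValueError(f"{self.line}: survived outside [0, total]")


def log2_fpkm(matrix: pd.DataFrame | np.ndarray, pseudocount: float = 1.0):
    """Elementwise log2(FPKM + pseudocount); rejects negative entries."""
    values = np.asarray(matrix, dtype=float)
    if (values < 0).any():
        raise ValueError("FPKM matrix contains negative entries")
    out = np.log2(values + pseudocount)
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


def relative_expression(record: QpcrRecord, calibrator: QpcrRecord) -> float:
    """Livak fold change 2^-(dCt_sample − dCt_calibrator).

    dCt is the mean target Ct minus the mean reference-gene Ct within a
    sample; the calibrator (untreated/time-zero) sample anchors fold 1.
    """
    return float(2.0 ** -(record.delta_ct - calibrator.delta_ct))


def survival_rate(survived: int, total: int) -> float:
    """Percent survival = survived / total × 100."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= survived <= total:
        raise ValueError("survived must lie in [0, total]")
    return 100.0 * survived / total


def relative_water_content(fw: float, tw: float, dw: float) -> float:
    """Leaf RWC percent = (FW − DW) / (TW − DW) × 100."""
    if tw <= dw:
        raise ValueError("turgid weight must exceed dry weight")
    if fw < dw:
        raise ValueError("fresh weight below dry weight")
    return 100.0 * (fw - dw) / (tw - dw)


def expression_heatmap(
    matrix: pd.DataFrame,
    path: str,
    row_order: Sequence[str] | None = None,
    pseudocount: float = 1.0,
) -> None:
    """Render a log2(FPKM+1) heatmap to file (cosmetic convenience)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    data = log2_fpkm(matrix, pseudocount)
    if row_order is not None:
        data = data.loc[list(row_order)]
    height = max(3.0, 0.3 * data.shape[0])
    fig, ax = plt.subplots(figsize=(max(4.0, 0.4 * data.shape[1]), height))
    sns.heatmap(data, cmap="RdGy_r", ax=ax, cbar_kws={"label": "log2(FPKM+1)"})
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
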