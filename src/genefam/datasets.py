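"""Published reference tables for the maize serine-peptidase S8 family.

Two small published tables ship with the package as worked-example
inputs: the per-protein GRAVY column from the family characterization
table, and the Ka/Ks values reported for the three paralogous gene
pairs.  They let the classification and dating operations run without
any sequence download.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["maize_sps8_gravy", "maize_sps8_paralog_pairs"]

# GRAVY (grand average of hydropathicity) per family member.
_GRAVY = {
    "ZmSPS8.1.3": 0.054,
    "ZmSPS8.1.9": 0.108,
    "ZmSPS8.1.10": -0.007,
    "ZmSPS8.1.4": 0.009,
    "ZmSPS8.1.5": 0.15,
    "ZmSPS8.2.0": -0.026,
    "ZmSPS8.1.14": -0.461,
    "ZmSPS8.1.12": 0.074,
    "ZmSPS8.1.6": 0.024,
    "ZmSPS8.1.8": -0.153,
    "ZmSPS8.1.1": -0.039,
    "ZmSPS8.1.13": -0.012,
    "ZmSPS8.3.2": -0.137,
    "ZmSPS8.3.1": 0.324,
    "ZmSPS8.1.11": 0.239,
    "ZmSPS8.1.2": 0.106,
    "ZmSPS8.1.7": -0.055,
    "ZmSPS8.3.3": -0.238,
}

# Reported alignment coverage and Ka/Ks per paralogous pair.
_PAIRS = [
    ("ZmSPS8.3.2", "ZmSPS8.3.3", 0.993, 0.004817359, 0.014907323),
    ("ZmSPS8.3.1", "ZmSPS8.3.2", 0.957, 0.062432033, 0.038079244),
    ("ZmSPS8.3.3", "ZmSPS8.3.1", 0.966, 0.558916065, 0.803034338),
]


def maize_sps8_gravy() -> pd.Series:
    """GRAVY values of the 18 maize serine-peptidase S8 proteins."""
    return pd.Series(_GRAVY, name="gravy")


def maize_sps8_paralog_pairs() -> pd.DataFrame:
    """Published Ka and Ks of the three maize SPS8 paralogous pairs."""
    return pd.DataFrame(
        _PAIRS, columns=["gene_a", "gene_b", "coverage", "Ka", "Ks"]
    )
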