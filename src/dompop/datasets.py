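"""Published reference values bundled for worked examples and validation.

These tables come from a published ISSR survey of *Haloxylon salicornicum*
(Rimth saltbush) sampled at six locations in Kuwait — the study whose
analysis workflow this package reimplements.  Only printed summary tables
are included (the underlying 108 × 195 band matrix is supplementary data and
not redistributed here): the per-primer informativeness table, the pairwise
population F_ST / Nei-distance matrix, and the overall AMOVA fixation index.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["primer_reference_table", "pairwise_fst_reference",
           "pairwise_nei_d_reference", "AMOVA_FST", "POPULATIONS"]

POPULATIONS = ["Al-Subiya", "Om-Qaser", "Al-Ritqa",
               "Al-Shagaya", "Al-Abraq", "Al-Abdally"]

#: Overall AMOVA fixation index reported for the six populations.
AMOVA_FST = 0.221

# primer, SB, PB, PPB, PIC, RP, MRP, MI, H'
_PRIMER_ROWS = [
    ("ISSR 7",   14, 12,  85.7, 0.46, 2.3, 0.20, 5.5, 0.290),
    ("ISSR 3",   11, 10,  90.9, 0.45, 4.9, 0.49, 4.5, 0.266),
    ("ISSR 826", 21, 19,  90.5, 0.42, 6.6, 0.35, 8.0, 0.504),
    ("ISSR 5",   15, 10,  66.7, 0.40, 6.7, 0.67, 4.0, 0.347),
    ("ISSR 10",  10, 10, 100.0, 0.38, 4.1, 0.41, 3.8, 0.262),
    ("ISSR 2",   16, 14,  87.5, 0.37, 6.5, 0.46, 5.2, 0.424),
    ("ISSR 8",    8,  8, 100.0, 0.34, 3.2, 0.40, 2.7, 0.221),
    ("ISSR 810", 10,  8,  80.0, 0.34, 2.8, 0.35, 2.7, 0.260),
    ("ISSR 820", 11, 10,  90.9, 0.34, 4.3, 0.43, 3.4, 0.300),
    ("ISSR 17",  13, 13, 100.0, 0.26, 3.9, 0.30, 3.4, 0.376),
    ("ISSR 809",  8,  7,  87.5, 0.25, 2.2, 0.32, 1.8, 0.233),
    ("ISSR 11",   9,  8,  88.9, 0.23, 2.4, 0.31, 1.8, 0.263),
    ("ISSR 18",  12,  9,  75.0, 0.22, 3.1, 0.35, 2.0, 0.352),
    ("ISSR 12",  12, 12, 100.0, 0.20, 2.8, 0.24, 2.4, 0.360),
    ("ISSR 13",  10,  8,  80.0, 0.18, 1.7, 0.22, 1.4, 0.300),
    ("ISSR 23",  15,  9,  60.0, 0.18, 2.5, 0.28, 1.6, 0.445),
]

# upper triangle of the published pairwise F_ST matrix, row-major
_FST_UPPER = [
    0.130, 0.165, 0.194, 0.270, 0.390,
    0.094, 0.135, 0.238, 0.365,
    0.113, 0.236, 0.365,
    0.138, 0.352,
    0.447,
]

# lower triangle of the published pairwise Nei genetic distances, row-major
_NEI_LOWER = [
    0.066,
    0.076, 0.052,
    0.079, 0.058, 0.047,
    0.114, 0.103, 0.093, 0.050,
    0.187, 0.173, 0.162, 0.129, 0.092,
]


def primer_reference_table() -> pd.DataFrame:
    """Published per-primer statistics (16 primers, 195 bands)."""
    return pd.DataFrame(
        _PRIMER_ROWS,
        columns=["primer", "SB", "PB", "PPB", "PIC", "RP", "MRP", "MI", "Hp"],
    ).set_index("primer")


def _symmetric_from_triangle(values, upper: bool) -> pd.DataFrame:
    K = len(POPULATIONS)
    mat = np.zeros((K, K))
    it = iter(values)
    for i in range(K):
        for j in range(i + 1, K):
            v = next(it)
            mat[i, j] = mat[j, i] = v
    return pd.DataFrame(mat, index=POPULATIONS, columns=POPULATIONS)


def pairwise_fst_reference() -> pd.DataFrame:
    """Published 6 × 6 pairwise F_ST matrix (symmetrized)."""
    return _symmetric_from_triangle(_FST_UPPER, upper=True)


def pairwise_nei_d_reference() -> pd.DataFrame:
    """Published 6 × 6 pairwise Nei genetic distance matrix (symmetrized)."""
    return _symmetric_from_triangle(_NEI_LOWER, upper=False)
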