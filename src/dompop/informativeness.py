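"""Per-primer marker informativeness statistics.

For a dominant band locus with band frequency p the two observable phenotype
classes (band present, band absent) play the role of alleles, giving

* PIC  = 1 − p² − (1 − p)² = 2p(1 − p), maximal 0.5 at p = ½;
* Ib   = 1 − 2|0.5 − p|   (band informativeness, Prevost & Wilkinson);
* RP   = Σ Ib over a primer's bands (resolving power);
* MRP  = RP / PB           (mean resolving power per polymorphic band);
* MI   = PIC × EMR         (marker index, EMR taken as the polymorphic-band
  count PB — the convention that reproduces published primer tables);
* H'   = −[p ln p + (1−p) ln(1−p)]  (Shannon index, natural log).

:func:`primer_table` assembles these per primer, adds the column means, and
reports the Pearson correlation between (PIC, MI) and (PIC, RP) columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .marker_data import MarkerMatrix, band_frequencies, classify_loci

__all__ = [
    "pic_locus",
    "band_informativeness",
    "resolving_power",
    "marker_index",
    "mean_resolving_power",
    "shannon_locus",
    "shannon_primer",
    "primer_table",
]


def _check_unit(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("band frequency outside [0, 1]")
    return p


def pic_locus(p) -> np.ndarray | float:
    """Two-state polymorphic information content 2p(1−p)."""
    p = _check_unit(p)
    return 2.0 * p * (1.0 - p)


def band_informativeness(p) -> np.ndarray | float:
    """Ib = 1 − 2|0.5 − p|; 1 at p = 0.5, 0 for fixed bands."""
    p = _check_unit(p)
    return 1.0 - 2.0 * np.abs(0.5 - p)


def shannon_locus(p) -> np.ndarray | float:
    """Shannon index of the two band states, with 0·ln 0 := 0."""
    p = _check_unit(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -(np.where(p > 0, p * np.log(p), 0.0)
              + np.where(p < 1, (1 - p) * np.log(1 - p), 0.0))
    return h


def marker_index(pic: float, pb: int) -> float:
    """MI = PIC × EMR with EMR = polymorphic-band count."""
    if pb <= 0:
        return float("nan")
    return pic * pb


def mean_resolving_power(rp: float, pb: int) -> float:
    """MRP = RP / PB; NaN for a primer with no polymorphic band."""
    if pb <= 0:
        return float("nan")
    return rp / pb


def _primer_freqs(m: MarkerMatrix, primer: str) -> np.ndarray:
    p = band_frequencies(m, "pooled").loc["pooled"]
    return p[m.loci_of_primer(primer)].to_numpy()


def resolving_power(m: MarkerMatrix, primer: str) -> float:
    """RP = Σ Ib over all scored bands of the primer."""
    return float(band_informativeness(_primer_freqs(m, primer)).sum())


def shannon_primer(m: MarkerMatrix, primer: str) -> float:
    """Mean per-locus Shannon index over the primer's bands."""
    return float(shannon_locus(_primer_freqs(m, primer)).mean())


def primer_table(m: MarkerMatrix) -> pd.DataFrame:
    """Per-primer statistics table with an ``Average`` row.

    Columns: SB, PB, PPB, PIC (mean per-locus over all scored bands), RP,
    MRP, MI, Hp.  Pearson correlations between the per-primer (PIC, MI) and
    (PIC, RP) columns — both r and r², with two-sided p — are attached as
    ``result.attrs["correlations"]`` (NaN with < 3 primers or a constant
    column).
    """
    counts = classify_loci(m)
    rows = []
    for primer in m.primers:
        p = _primer_freqs(m, primer)
        sb = int(counts.loc[primer, "SB"])
        pb = int(counts.loc[primer, "PB"])
        pic = float(pic_locus(p).mean())
        rp = float(band_informativeness(p).sum())
        rows.append({
            "primer": primer, "SB": sb, "PB": pb,
            "PPB": float(counts.loc[primer, "PPB"]),
            "PIC": pic, "RP": rp,
            "MRP": mean_resolving_power(rp, pb),
            "MI": marker_index(pic, pb),
            "Hp": float(shannon_locus(p).mean()),
        })
    table = pd.DataFrame(rows).set_index("primer")
    avg = table.mean(numeric_only=True)
    table.loc["Average"] = avg

    body = table.drop(index="Average")
    corr: dict[str, dict[str, float]] = {}
    for a, b in (("PIC", "MI"), ("PIC", "RP")):
        key = f"{a}~{b}"
        x, y = body[a].to_numpy(), body[b].to_numpy()
        if len(body) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0 or np.any(np.isnan(y)):
            corr[key] = {"r": np.nan, "r2": np.nan, "p": np.nan}
        else:
            res = stats.pearsonr(x, y)
            corr[key] = {"r": float(res.statistic),
                         "r2": float(res.statistic ** 2),
                         "p": float(res.pvalue)}
    table.attrs["correlations"] = corr
    return table
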