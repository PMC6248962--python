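"""Within-population diversity statistics for dominant markers.

Two allele-frequency conventions are supported, because the common desktop
packages disagree on how to treat a dominant 0/1 locus:

``band_state``
    The band phenotypes themselves are the two states, with frequencies
    (p, 1−p).  This is the convention behind GenAlEx's binary He/uHe.

``dominant_hwe``
    The locus is a diploid biallelic gene under Hardy–Weinberg equilibrium
    with a recessive null allele: band absence has frequency (1−p) = q²,
    so q̂ = √(1−p).  Optionally the Lynch–Milligan small-sample correction
    q̂ = √x / (1 − Var(x)/(8x²)) with x = 1−p and Var(x) = x(1−x)/N is
    applied.  This approximates POPGene-style Nei gene diversity (h').

Per locus with state frequencies (f₁, f₂): Na = number of states present,
Ne = 1/Σf², I = −Σ f ln f, He = 1 − Σf², uHe = He·2N/(2N−1).  Population
summaries are unweighted means over all loci (monomorphic loci included).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_data import MarkerMatrix, band_frequencies

__all__ = ["FreqModel", "locus_state_freqs", "pop_diversity", "diversity_table"]


@dataclass(frozen=True)
class FreqModel:
    """Allele-frequency convention for a dominant locus."""

    name: str = "band_state"          # band_state | dominant_hwe
    estimator: str = "sqrt"           # sqrt | lynch_milligan (dominant_hwe only)

    def __post_init__(self) -> None:
        if self.name not in ("band_state", "dominant_hwe"):
            raise ValueError(f"unknown frequency model {self.name!r}")
        if self.estimator not in ("sqrt", "lynch_milligan"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


def locus_state_freqs(p, model: FreqModel = FreqModel(), n: int | None = None):
    """State-frequency pairs (f₁, f₂) for band frequency p.

    band_state returns (p, 1−p); dominant_hwe returns the inferred allele
    frequencies (p̂, q̂) with q̂ = √(1−p), optionally Lynch–Milligan corrected
    (needs the scored sample count ``n``).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("band frequency outside [0, 1]")
    if model.name == "band_state":
        return p, 1.0 - p
    x = 1.0 - p                         # band-absent phenotype frequency
    q = np.sqrt(x)
    if model.estimator == "lynch_milligan" and n is not None:
        var_x = x * (1.0 - x) / n
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = 1.0 - var_x / (8.0 * np.square(x))
        q = np.where(x > 0, np.sqrt(x) / np.where(corr > 0, corr, 1.0), 0.0)
        q = np.clip(q, 0.0, 1.0)
    return 1.0 - q, q


def _locus_stats(f1: np.ndarray, f2: np.ndarray) -> dict[str, np.ndarray]:
    fsq = f1 ** 2 + f2 ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        i = -(np.where(f1 > 0, f1 * np.log(f1), 0.0)
              + np.where(f2 > 0, f2 * np.log(f2), 0.0))
    return {
        "Na": (f1 > 0).astype(float) + (f2 > 0).astype(float),
        "Ne": 1.0 / fsq,
        "I": i,
        "He": 1.0 - fsq,
    }


def pop_diversity(m: MarkerMatrix, pop: str,
                  model: FreqModel = FreqModel()) -> dict[str, float]:
    """Diversity summary for one population (unweighted means over loci)."""
    idx = m.pop_indices(pop)
    n = idx.size
    if n < 2:
        raise ValueError(f"population {pop!r} has {n} sample(s); need >= 2")
    freqs = band_frequencies(m, "per_population")
    p = freqs.loc[pop].to_numpy()
    ok = ~np.isnan(p)
    p = p[ok]
    f1, f2 = locus_state_freqs(p, model, n=n)
    per_locus = _locus_stats(f1, f2)
    he = float(per_locus["He"].mean())
    h1, h2 = locus_state_freqs(p, FreqModel("dominant_hwe"), n=n)
    hprime = float(_locus_stats(h1, h2)["He"].mean())
    poly = (p > 0) & (p < 1)
    return {
        "pop": pop,
        "N": n,
        "Na": float(per_locus["Na"].mean()),
        "Ne": float(per_locus["Ne"].mean()),
        "I": float(per_locus["I"].mean()),
        "He": he,
        "uHe": he * 2 * n / (2 * n - 1),
        "hprime": hprime,
        "pctP": 100.0 * float(poly.mean()),
    }


def diversity_table(m: MarkerMatrix, model: FreqModel = FreqModel()) -> pd.DataFrame:
    """Per-population diversity rows plus an unweighted ``Mean`` row."""
    rows = [pop_diversity(m, pop, model) for pop in m.populations]
    table = pd.DataFrame(rows).set_index("pop")
    table.loc["Mean"] = table.mean(numeric_only=True)
    table.attrs["model"] = model
    return table
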