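"""Population differentiation, gene flow, and genetic distances.

Nei's diversity partition on state frequencies (unweighted population
means, the POPGene convention):

    H_S = mean over pops and loci of h_k = 1 − Σ f²
    H_T = mean over loci of 1 − Σ f̄²,  f̄ = unweighted mean state frequency
    G_ST = (H_T − H_S) / H_T

with Hedrick's standardized G'_ST = G_ST (K−1+H_S) / [(K−1)(1−H_S)] and
Jost's D = [(H_T−H_S)/(1−H_S)] · K/(K−1).

Gene flow under the island model: N_M = ¼ (1/F_ST − 1).

Nei's (1972) standard distance between two populations:
    I = Σ_l Σ_s x y / √(Σ_l Σ x² · Σ_l Σ y²),   D_s = −ln I

Slatkin's linearization F_ST/(1−F_ST) prepares a pairwise-F_ST matrix for
isolation-by-distance regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import FreqModel, locus_state_freqs
from .marker_data import MarkerMatrix, band_frequencies

__all__ = [
    "DifferentiationSummary",
    "diversity_partition",
    "gene_flow",
    "nei_distance",
    "nei_distance_matrix",
    "slatkin_linearized",
    "combined_distance_table",
]


@dataclass
class DifferentiationSummary:
    HT: float
    HS: float
    GST: float
    GprimeST: float
    D_jost: float
    NM: float
    K: int
    model: str


def _pop_state_freqs(m: MarkerMatrix, model: FreqModel) -> np.ndarray:
    """(K, L, 2) array of per-population state frequencies."""
    freqs = band_frequencies(m, "per_population")
    out = []
    for pop in m.populations:
        p = freqs.loc[pop].to_numpy()
        f1, f2 = locus_state_freqs(p, model, n=int(m.pop_sizes[pop]))
        out.append(np.stack([f1, f2], axis=-1))
    return np.stack(out)  # K x L x 2


def diversity_partition(m: MarkerMatrix, model: FreqModel = FreqModel(),
                        weighted: bool = False,
                        fst: float | None = None) -> DifferentiationSummary:
    """Nei H_T/H_S partition with Hedrick and Jost corrections.

    ``weighted=True`` weights populations by sample size when averaging
    state frequencies and within-population diversities; the default gives
    every population equal weight.  The gene-flow estimate N_M uses the
    AMOVA fixation index when one is supplied via ``fst`` (the convention
    of pairing N_M with Φ_ST), else falls back to G_ST.
    """
    K = len(m.populations)
    if K < 2:
        raise ValueError("need at least 2 populations")
    f = _pop_state_freqs(m, model)                     # K x L x 2
    if weighted:
        w = np.array([m.pop_sizes[p] for p in m.populations], dtype=float)
        w /= w.sum()
    else:
        w = np.full(K, 1.0 / K)
    h_k = 1.0 - np.square(f).sum(axis=-1)              # K x L
    HS = float((h_k * w[:, None]).sum(axis=0).mean())
    fbar = (f * w[:, None, None]).sum(axis=0)          # L x 2
    HT = float((1.0 - np.square(fbar).sum(axis=-1)).mean())
    if HT == 0:
        raise ValueError("all loci monomorphic across populations; G_ST undefined")
    GST = (HT - HS) / HT
    Gp = GST * (K - 1 + HS) / ((K - 1) * (1.0 - HS)) if HS < 1 else np.nan
    D = ((HT - HS) / (1.0 - HS)) * K / (K - 1) if HS < 1 else np.nan
    nm = gene_flow(fst if fst is not None else GST)
    return DifferentiationSummary(HT=HT, HS=HS, GST=GST, GprimeST=Gp,
                                  D_jost=D, NM=nm, K=K, model=model.name)


def gene_flow(fst: float) -> float:
    """Island-model migrant estimate N_M = ¼ (1/F_ST − 1)."""
    if not np.isfinite(fst) or fst <= 0:
        warnings.warn("gene flow undefined for F_ST <= 0; returning NaN")
        return float("nan")
    if fst > 1:
        raise ValueError("F_ST above 1")
    return 0.25 * (1.0 / fst - 1.0)


def nei_distance(m: MarkerMatrix, pop_a: str, pop_b: str,
                 model: FreqModel = FreqModel()) -> float:
    """Nei (1972) standard genetic distance D_s = −ln I between two pops."""
    freqs = band_frequencies(m, "per_population")
    fa = np.stack(locus_state_freqs(freqs.loc[pop_a].to_numpy(), model,
                                    n=int(m.pop_sizes[pop_a])), axis=-1)
    fb = np.stack(locus_state_freqs(freqs.loc[pop_b].to_numpy(), model,
                                    n=int(m.pop_sizes[pop_b])), axis=-1)
    jxy = float((fa * fb).sum())
    jx = float(np.square(fa).sum())
    jy = float(np.square(fb).sum())
    identity = jxy / np.sqrt(jx * jy)
    if identity <= 0:
        warnings.warn("zero genetic identity; Nei distance infinite → NaN")
        return float("nan")
    return -np.log(identity)


def nei_distance_matrix(m: MarkerMatrix,
                        model: FreqModel = FreqModel()) -> pd.DataFrame:
    pops = m.populations
    K = len(pops)
    d = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            d[a, b] = d[b, a] = nei_distance(m, pops[a], pops[b], model)
    return pd.DataFrame(d, index=pops, columns=pops)


def slatkin_linearized(fst_matrix: pd.DataFrame) -> pd.DataFrame:
    """Elementwise F_ST/(1−F_ST); entries at F_ST = 1 become NaN."""
    f = np.asarray(fst_matrix, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        lin = np.where(f < 1, f / (1.0 - f), np.nan)
    np.fill_diagonal(lin, 0.0)
    return pd.DataFrame(lin, index=fst_matrix.index, columns=fst_matrix.columns)


def combined_distance_table(nei_d: pd.DataFrame, fst: pd.DataFrame) -> pd.DataFrame:
    """Combined matrix: Nei D_s below the diagonal, F_ST above (report layout)."""
    pops = list(nei_d.index)
    out = pd.DataFrame("***", index=pops, columns=pops, dtype=object)
    for a in range(len(pops)):
        for b in range(len(pops)):
            if a < b:
                out.iat[a, b] = round(float(fst.iat[a, b]), 3)
            elif a > b:
                out.iat[a, b] = round(float(nei_d.iat[a, b]), 3)
    return out
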