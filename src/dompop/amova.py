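"""Analysis of molecular variance (AMOVA) for binary band profiles.

The distance between two samples is the band-mismatch count — the squared
Euclidean distance on 0/1 profiles and the convention desktop AMOVA tools
apply to dominant (RFLP/AFLP/ISSR) data.  With missing scores the mismatch
count over mutually scored loci is rescaled by n_loci / n_shared.

The one-level decomposition follows Excoffier's squared-distance identity
SS = (1/n) Σ_{i<j} d²(i,j):

    SS_total  = (1/N) Σ_{i<j} d(i,j)            over all pairs
    SS_within = Σ_k (1/n_k) Σ_{i<j in k} d(i,j)
    SS_among  = SS_total − SS_within
    σ²_b = SS_within / (N − K)
    σ²_a = (SS_among/(K−1) − σ²_b) / n0,   n0 = (N − Σn_k²/N)/(K−1)
    Φ_ST = σ²_a / (σ²_a + σ²_b)

Significance is assessed by permuting individuals among populations holding
the population sizes fixed; the observed statistic is counted in both the
tail and the denominator, so p ≥ 1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_data import MarkerMatrix

__all__ = ["AMOVAResult", "squared_distances", "amova", "amova_matrix",
           "pairwise_fst", "amova_table"]


@dataclass
class AMOVAResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ss_total: float
    sigma2_among: float
    sigma2_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int
    seed: int | None
    negative_variance: bool = False


def squared_distances(m: MarkerMatrix) -> pd.DataFrame:
    """Pairwise band-mismatch counts (squared Euclidean on 0/1 profiles).

    Pairs with missing scores count mismatches over mutually scored loci and
    rescale by n_loci / n_shared.  A pair sharing no scored locus is an
    error.
    """
    if m.n_samples < 2:
        raise ValueError("need at least 2 samples")
    X = m.bands
    scored = (~np.isnan(X)).astype(float)
    X0 = np.nan_to_num(X, nan=0.0)
    # mismatches = x(1-y) + y(1-x) over shared loci
    shared = scored @ scored.T
    if np.any(shared[~np.eye(m.n_samples, dtype=bool)] == 0):
        i, j = np.argwhere((shared == 0) & ~np.eye(m.n_samples, dtype=bool))[0]
        raise ValueError(
            f"samples {m.sample_ids[i]!r} and {m.sample_ids[j]!r} share no scored locus"
        )
    ones = scored - X0 * scored  # indicator of scored zero
    mism = X0 @ ones.T + ones @ X0.T
    d = mism * (m.n_loci / shared)
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=m.sample_ids, columns=m.sample_ids)


def _phi_from_groups(d: np.ndarray, groups: list[np.ndarray],
                     pair_sum_total: float, n0: float,
                     df_among: int, df_within: int):
    n = d.shape[0]
    ss_total = pair_sum_total / n
    ss_within = 0.0
    for idx in groups:
        sub = d[np.ix_(idx, idx)]
        ss_within += sub.sum() / (2.0 * idx.size)
    ss_among = ss_total - ss_within
    s2_w = ss_within / df_within
    s2_a = (ss_among / df_among - s2_w) / n0
    denom = s2_a + s2_w
    phi = s2_a / denom if denom != 0 else np.nan
    return phi, ss_total, ss_within, ss_among, s2_a, s2_w


def amova(d: pd.DataFrame, pops: list[str], n_perm: int = 10100,
          seed: int | None = None, clamp_negative: bool = False) -> AMOVAResult:
    """One-level AMOVA with a permutation test on Φ_ST.

    ``d`` is a square squared-distance matrix (see :func:`squared_distances`),
    ``pops`` one population label per sample.  ``n_perm = 0`` skips the test
    (p = NaN).  Negative among-population variance components are reported as
    is (Φ_ST may be negative) unless ``clamp_negative``.
    """
    dm = np.asarray(d, dtype=float)
    labels = np.asarray(pops)
    n = dm.shape[0]
    if dm.shape != (n, n) or len(labels) != n:
        raise ValueError("distance matrix and population labels disagree in size")
    pop_names = list(dict.fromkeys(labels))
    k = len(pop_names)
    if k < 2:
        raise ValueError("need at least 2 populations")
    groups = [np.flatnonzero(labels == p) for p in pop_names]
    sizes = np.array([g.size for g in groups])
    if np.any(sizes < 2):
        small = pop_names[int(np.argmin(sizes))]
        raise ValueError(f"population {small!r} has fewer than 2 samples")
    df_among, df_within = k - 1, n - k
    n0 = (n - float(np.square(sizes).sum()) / n) / df_among
    pair_sum = dm.sum()  # = 2 Σ_{i<j} d(i,j)
    phi, ss_t, ss_w, ss_a, s2_a, s2_w = _phi_from_groups(
        dm, groups, pair_sum / 2.0, n0, df_among, df_within)

    negative = s2_a < 0
    if clamp_negative and negative:
        s2_a = 0.0
        phi = 0.0

    p_value = np.nan
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        hits = 1  # observed counted in tail
        order = np.arange(n)
        bounds = np.cumsum(sizes)[:-1]
        for _ in range(n_perm):
            rng.shuffle(order)
            perm_groups = np.split(order.copy(), bounds)
            phi_p, *_ = _phi_from_groups(dm, perm_groups, pair_sum / 2.0,
                                         n0, df_among, df_within)
            if phi_p >= phi - 1e-12:
                hits += 1
        p_value = hits / (n_perm + 1)

    total_var = s2_a + s2_w
    return AMOVAResult(
        df_among=df_among, df_within=df_within,
        ss_among=ss_a, ss_within=ss_w, ss_total=ss_t,
        sigma2_among=s2_a, sigma2_within=s2_w,
        pct_among=100.0 * s2_a / total_var if total_var else np.nan,
        pct_within=100.0 * s2_w / total_var if total_var else np.nan,
        phi_st=phi, p_value=p_value, n_permutations=n_perm, seed=seed,
        negative_variance=bool(negative),
    )


def amova_matrix(m: MarkerMatrix, n_perm: int = 10100,
                 seed: int | None = None, **kw) -> AMOVAResult:
    """Convenience: squared distances + AMOVA straight from a MarkerMatrix."""
    return amova(squared_distances(m), m.pop_labels, n_perm=n_perm, seed=seed, **kw)


def pairwise_fst(m: MarkerMatrix, n_perm: int = 1000,
                 seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Φ_ST matrix (two-population AMOVA per pair) with p-values."""
    pops = m.populations
    d_all = squared_distances(m).to_numpy()
    labels = np.asarray(m.pop_labels)
    K = len(pops)
    fst = np.zeros((K, K))
    pval = np.full((K, K), np.nan)
    ss = np.random.SeedSequence(seed if seed is not None else 0)
    pair_seeds = iter(ss.generate_state(K * K))
    for a in range(K):
        for b in range(a + 1, K):
            idx = np.flatnonzero((labels == pops[a]) | (labels == pops[b]))
            res = amova(d_all[np.ix_(idx, idx)], list(labels[idx]),
                        n_perm=n_perm,
                        seed=int(next(pair_seeds)) if seed is not None else None)
            fst[a, b] = fst[b, a] = res.phi_st
            pval[a, b] = pval[b, a] = res.p_value
    return (pd.DataFrame(fst, index=pops, columns=pops),
            pd.DataFrame(pval, index=pops, columns=pops))


def amova_table(res: AMOVAResult) -> pd.DataFrame:
    """AMOVA summary in the conventional layout (one row per stratum)."""
    return pd.DataFrame(
        {
            "df": [res.df_among, res.df_within, res.df_among + res.df_within],
            "SS": [res.ss_among, res.ss_within, res.ss_total],
            "Est.Var": [res.sigma2_among, res.sigma2_within,
                        res.sigma2_among + res.sigma2_within],
            "%": [res.pct_among, res.pct_within, 100.0],
            "Phi_ST": [np.nan, np.nan, res.phi_st],
            "P": [np.nan, np.nan, res.p_value],
        },
        index=["Among Pops", "Within Pops", "Total"],
    )
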