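"""Principal coordinate analysis and Mantel isolation-by-distance testing.

PCoA (classical/metric multidimensional scaling) double-centres a distance
matrix and eigendecomposes it.  Two centering dialects are provided because
desktop packages disagree on whether the supplied matrix holds distances or
already-squared distances:

``gower_squared``
    B = −½ J (D∘D) J — the textbook Torgerson/Gower transform for a matrix
    of raw distances.  Library default.

``gower_raw``
    B = −½ J D J — treats the entries themselves as squared distances.
    This is the dialect that matches published GenAlEx-style ordinations of
    pairwise-F_ST matrices, and is the canonical one in pipeline reports of
    F_ST ordinations.

Percent variation per axis is each positive eigenvalue's share of the
positive-eigenvalue total; negative eigenvalues (non-Euclidean input) are
excluded from the denominator.

The Mantel test correlates the upper triangles of two distance matrices and
assesses significance by jointly permuting rows and columns of the second
matrix (one-tailed upper by default).  Geographic distances are great-circle
(haversine) kilometres between population centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_data import GeoTable, MarkerMatrix

__all__ = ["PCoAResult", "MantelResult", "pcoa", "geographic_distance",
           "haversine_km", "mantel", "EARTH_RADIUS_KM"]

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius


@dataclass
class PCoAResult:
    coordinates: pd.DataFrame      # points x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray        # all eigenvalues, descending
    percent: np.ndarray            # positive-axis percents of positive total
    dialect: str


@dataclass
class MantelResult:
    r: float
    r2: float
    p_value: float
    n_perm: int
    seed: int | None


def pcoa(d: pd.DataFrame, dialect: str = "gower_squared") -> PCoAResult:
    """Classical PCoA of a symmetric zero-diagonal distance matrix (K ≥ 3)."""
    D = np.asarray(d, dtype=float)
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCoA needs at least 3 points")
    if D.shape != (n, n) or not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("input must be a symmetric matrix with zero diagonal")
    if dialect == "gower_squared":
        A = -0.5 * D ** 2
    elif dialect == "gower_raw":
        A = -0.5 * D
    else:
        raise ValueError(f"unknown PCoA dialect {dialect!r}")
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    pos = w > 1e-12 * max(1.0, abs(w[0]))
    coords = V[:, pos] * np.sqrt(w[pos])
    percent = 100.0 * w[pos] / w[pos].sum()
    labels = list(d.index) if isinstance(d, pd.DataFrame) else list(range(n))
    axes = [f"Axis{i + 1}" for i in range(int(pos.sum()))]
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        eigenvalues=w, percent=percent, dialect=dialect,
    )


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray | float:
    """Great-circle distance in km between decimal-degree points."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat, dlon = lat2 - lat1, lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def geographic_distance(g: GeoTable, m: MarkerMatrix) -> pd.DataFrame:
    """Great-circle km between population centroids (mean lat/lon)."""
    g.check_against(m)
    pop_of = dict(zip(m.sample_ids, m.pop_labels))
    pops = m.populations
    lats, lons = {p: [] for p in pops}, {p: [] for p in pops}
    for sid, lat, lon in zip(g.sample_ids, g.latitude, g.longitude):
        p = pop_of[sid]
        lats[p].append(lat)
        lons[p].append(lon)
    empty = [p for p in pops if not lats[p]]
    if empty:
        raise ValueError(f"no coordinates for population(s) {empty}")
    clat = np.array([np.mean(lats[p]) for p in pops])
    clon = np.array([np.mean(lons[p]) for p in pops])
    d = haversine_km(clat[:, None], clon[:, None], clat[None, :], clon[None, :])
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=pops, columns=pops)


def _upper(a: np.ndarray) -> np.ndarray:
    return a[np.triu_indices_from(a, k=1)]


def mantel(dx: pd.DataFrame, dy: pd.DataFrame, n_perm: int = 10000,
           seed: int | None = None, alternative: str = "greater") -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the vectorized upper triangles; p is the
    fraction of permutations (rows+columns of ``dy`` permuted jointly) whose
    r is at least the observed (one-tailed upper; ``alternative="two-sided"``
    uses |r|), with the observed permutation included.
    """
    X = np.asarray(dx, dtype=float)
    Y = np.asarray(dy, dtype=float)
    if X.shape != Y.shape or X.shape[0] != X.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    if (isinstance(dx, pd.DataFrame) and isinstance(dy, pd.DataFrame)
            and list(dx.index) != list(dy.index)):
        raise ValueError("matrix labels do not match")
    n = X.shape[0]
    if n < 4:
        warnings.warn("Mantel test on fewer than 4 points has very few "
                      "distinct permutations")
    x = _upper(X)
    if np.ptp(x) == 0 or np.ptp(_upper(Y)) == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")
    x = (x - x.mean()) / x.std()

    def corr(mat: np.ndarray) -> float:
        y = _upper(mat)
        y = (y - y.mean()) / y.std()
        return float((x * y).mean())

    r_obs = corr(Y)
    stat = abs(r_obs) if alternative == "two-sided" else r_obs
    rng = np.random.default_rng(seed)
    hits = 1
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(Y[np.ix_(perm, perm)])
        if (abs(r_p) if alternative == "two-sided" else r_p) >= stat - 1e-12:
            hits += 1
    return MantelResult(r=r_obs, r2=r_obs ** 2, p_value=hits / (n_perm + 1),
                        n_perm=n_perm, seed=seed)
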