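"""Spatial structure: great-circle distances, equal-frequency distance
classes, Moran's I correlograms with permutation tests, and PCNM spatial
eigenvector filters.

The correlogram follows the classic form: all site pairs are sorted by
great-circle distance and split into k classes holding an equal number of
pairs; within each class, binary weights (1 for member pairs, 0 elsewhere)
enter Moran's I with the n/S0 normalization.  Positive I in a class means
sites that far apart carry similar values.

PCNM (principal coordinates of neighbour matrices) filters are the
positive-eigenvalue eigenvectors of the double-centered, truncated distance
matrix; the leading filters describe broad-scale spatial gradients and serve
as covariates that absorb spatial autocorrelation in regression residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .community import _site_rng

__all__ = [
    "EARTH_RADIUS_KM",
    "SiteTable",
    "Correlogram",
    "SpatialFilters",
    "geodesic_km",
    "pair_distance_matrix",
    "equal_count_classes",
    "morans_i",
    "correlogram",
    "pcnm_filters",
]

EARTH_RADIUS_KM = 6371.0

EDAPHIC_CLASSES = ("sedimentary", "crystalline", "inselberg")


class SiteTable:
    """Sites with coordinates, edaphic class and climate covariates.

    Wraps a DataFrame indexed by site id with at least ``lat``/``lon``
    columns (decimal degrees); an optional ``substrate`` column must draw
    from {sedimentary, crystalline, inselberg}.
    """

    def __init__(self, table: pd.DataFrame):
        df = table.copy()
        for col in ("lat", "lon"):
            if col not in df.columns:
                raise ValueError(f"site table needs a {col!r} column")
        if df.index.duplicated().any():
            raise ValueError("duplicate site ids")
        if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
            raise ValueError("coordinates out of range")
        if "substrate" in df.columns:
            bad = set(df["substrate"]) - set(EDAPHIC_CLASSES)
            if bad:
                raise ValueError(f"unknown edaphic classes: {sorted(bad)}")
        self.table = df

    @property
    def sites(self) -> list:
        return list(self.table.index)

    @property
    def coords(self) -> np.ndarray:
        return self.table[["lat", "lon"]].to_numpy(dtype=float)

    def covariate(self, name: str) -> pd.Series:
        return self.table[name]

    @classmethod
    def from_csv(cls, path) -> "SiteTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def __len__(self) -> int:
        return len(self.table)


def geodesic_km(a: Sequence[float], b: Sequence[float]) -> float:
    """Great-circle distance (km) between (lat, lon) points, haversine on a
    spherical earth of radius 6371 km."""
    (lat1, lon1), (lat2, lon2) = a, b
    for lat, lon in ((lat1, lon1), (lat2, lon2)):
        if abs(lat) > 90 or abs(lon) > 180:
            raise ValueError(f"coordinates out of range: ({lat}, {lon})")
    p1, l1, p2, l2 = np.radians([lat1, lon1, lat2, lon2])
    h = np.sin((p2 - p1) / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin((l2 - l1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def pair_distance_matrix(sites: SiteTable, *, planar: bool = False) -> pd.DataFrame:
    """Symmetric site-by-site distance matrix in km.

    Haversine by default; ``planar=True`` treats (lat, lon) as already
    projected planar coordinates in km.
    """
    X = sites.coords
    if planar:
        diff = X[:, None, :] - X[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=2))
    else:
        lat = np.radians(X[:, 0])[:, None]
        lon = np.radians(X[:, 1])[:, None]
        h = (np.sin((lat - lat.T) / 2) ** 2
             + np.cos(lat) * np.cos(lat.T) * np.sin((lon - lon.T) / 2) ** 2)
        D = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=sites.sites, columns=sites.sites)


def equal_count_classes(distances: Sequence[float], k: int = 6
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Split pair distances into k consecutive classes of (near-)equal size.

    Pairs are stable-sorted by (distance, input position) and cut into k
    groups; when the pair count is not divisible by k the first ``remainder``
    classes take one extra pair.  Returns (class index per input pair,
    per-class centroid = mean member distance).
    """
    d = np.asarray(distances, dtype=float)
    m = d.size
    if k <= 0 or k > m:
        raise ValueError(f"need 1 <= k <= {m} classes, got {k}")
    order = np.argsort(d, kind="stable")
    base, rem = divmod(m, k)
    sizes = np.full(k, base, dtype=int)
    sizes[:rem] += 1
    classes = np.empty(m, dtype=int)
    start = 0
    for c, size in enumerate(sizes):
        classes[order[start:start + size]] = c
        start += size
    centroids = np.array([d[classes == c].mean() for c in range(k)])
    return classes, centroids


def morans_i(values: Sequence[float], weights: np.ndarray) -> float:
    """Moran's I: (n/S0) * sum_ij w_ij (x_i-xbar)(x_j-xbar) / sum_i (x_i-xbar)^2.

    Weights must be symmetric, nonnegative, zero on the diagonal and not all
    zero; values must vary.
    """
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("Moran's I needs at least 3 sites")
    if W.shape != (n, n):
        raise ValueError("weights shape does not match values")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix must have a zero diagonal")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    S0 = W.sum()
    if S0 == 0:
        raise ValueError("all-zero weight matrix")
    xc = x - x.mean()
    denom = (xc ** 2).sum()
    if denom == 0:
        raise ValueError("zero variance in values: Moran's I undefined")
    return float(n / S0 * (W * np.outer(xc, xc)).sum() / denom)


@dataclass(frozen=True)
class Correlogram:
    """Per-distance-class Moran's I with permutation p-values."""

    centroids_km: np.ndarray
    pair_counts: np.ndarray
    morans: np.ndarray           # NaN where the class is degenerate
    p_values: np.ndarray
    k: int
    n_perm: int
    weighting: str = "binary"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "centroid_km": self.centroids_km,
            "n_pairs": self.pair_counts,
            "morans_i": self.morans,
            "p": self.p_values,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _class_weight_matrices(sites: SiteTable, k: int, *, planar: bool = False
                           ) -> tuple[list[np.ndarray], np.ndarray, np.ndarray]:
    n = len(sites)
    D = pair_distance_matrix(sites, planar=planar).to_numpy()
    pairs = list(combinations(range(n), 2))
    d = np.array([D[i, j] for i, j in pairs])
    classes, centroids = equal_count_classes(d, k)
    mats = []
    counts = np.zeros(k, dtype=int)
    for c in range(k):
        W = np.zeros((n, n))
        for (i, j), cl in zip(pairs, classes):
            if cl == c:
                W[i, j] = W[j, i] = 1.0
                counts[c] += 1
        mats.append(W)
    return mats, centroids, counts


def correlogram(values: Sequence[float], sites: SiteTable, k: int = 6,
                n_perm: int = 999, seed: int = 0, *,
                row_standardize: bool = False, planar: bool = False
                ) -> Correlogram:
    """Moran's I correlogram over k equal-count distance classes.

    Binary within-class weights by default (row-standardized optional).
    Per-class two-sided p-values come from shuffling the value vector across
    sites (add-one smoothed rank).  Classes in which every involved site is
    isolated report I as NaN.
    """
    x = np.asarray(values, dtype=float)
    n = len(sites)
    if n < 4:
        raise ValueError("correlogram needs at least 4 sites")
    if x.size != n:
        raise ValueError("values length does not match the site table")
    mats, centroids, counts = _class_weight_matrices(sites, k, planar=planar)
    weighting = "row-standardized" if row_standardize else "binary"
    if row_standardize:
        stan = []
        for W in mats:
            rs = W.sum(axis=1, keepdims=True)
            Wr = np.divide(W, rs, out=np.zeros_like(W), where=rs > 0)
            stan.append((Wr + Wr.T) / 2)  # keep symmetry for the statistic
        mats = stan

    rng = _site_rng(seed, "correlogram")
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    morans = np.full(k, np.nan)
    pvals = np.full(k, np.nan)
    for c, W in enumerate(mats):
        if W.sum() == 0:
            continue
        obs = morans_i(x, W)
        null = np.array([morans_i(x[p], W) for p in perms])
        more_extreme = np.abs(null - null.mean()) >= np.abs(obs - null.mean()) - 1e-12
        pvals[c] = (1 + int(more_extreme.sum())) / (n_perm + 1)
        morans[c] = obs
    return Correlogram(centroids_km=centroids, pair_counts=counts,
                       morans=morans, p_values=pvals, k=k, n_perm=n_perm,
                       weighting=weighting)


@dataclass(frozen=True)
class SpatialFilters:
    """Positive-eigenvalue PCNM eigenvectors, broadest scale first."""

    eigenvalues: np.ndarray
    vectors: pd.DataFrame        # sites x filters, columns F1, F2, ...
    truncation_km: float

    @property
    def n_filters(self) -> int:
        return self.vectors.shape[1]

    def filter(self, i: int = 0) -> pd.Series:
        """The i-th filter (0 = first/broadest)."""
        return self.vectors.iloc[:, i]

    def to_csv(self, path) -> None:
        out = self.vectors.copy()
        out.loc["_eigenvalue"] = self.eigenvalues
        out.to_csv(path)


def pcnm_filters(sites: SiteTable, truncation: float | None = None, *,
                 planar: bool = False, tol: float = 1e-8) -> SpatialFilters:
    """PCNM spatial eigenvector filters.

    The inter-site distance matrix is truncated at ``truncation`` km (by
    default the largest edge of the minimum spanning tree, guaranteeing a
    connected neighbour graph); distances beyond the threshold are replaced
    by 4x the threshold.  Principal-coordinates analysis of the truncated
    matrix (double-centering of -D^2/2, symmetric eigendecomposition) yields
    the filters: eigenvectors with positive eigenvalues, sorted by
    descending eigenvalue, each centered and mutually orthogonal.
    """
    D = pair_distance_matrix(sites, planar=planar).to_numpy()
    n = D.shape[0]
    if n < 3:
        raise ValueError("PCNM needs at least 3 sites")
    offdiag = D[~np.eye(n, dtype=bool)]
    if np.all(offdiag == 0):
        raise ValueError("all sites coincide: PCNM undefined")
    if truncation is None:
        mst = minimum_spanning_tree(D).toarray()
        truncation = float(mst.max())
    if truncation <= 0:
        raise ValueError("truncation distance must be positive")
    Dt = np.where(D > truncation, 4.0 * truncation, D)
    np.fill_diagonal(Dt, 0.0)

    A = -0.5 * Dt ** 2
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = J @ A @ J
    B = (B + B.T) / 2
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    scale = max(abs(evals[0]), 1.0)
    keep = evals > tol * scale
    evals, evecs = evals[keep], evecs[:, keep]
    # deterministic sign: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        lead = np.argmax(np.abs(evecs[:, j]))
        if evecs[lead, j] < 0:
            evecs[:, j] = -evecs[:, j]
    cols = [f"F{i + 1}" for i in range(evecs.shape[1])]
    vectors = pd.DataFrame(evecs, index=sites.sites, columns=cols)
    return SpatialFilters(eigenvalues=evals, vectors=vectors,
                          truncation_km=float(truncation))
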